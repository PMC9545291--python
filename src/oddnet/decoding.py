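"""Time-resolved MVPA: per-animal time-wise and temporal-generalisation
decoding of stimulus condition from epoched evoked potentials.

At every time sample a linear maximum-margin classifier (SVM, C = 1) is
trained to separate two condition sets using the two channel amplitudes as
features.  The larger class is randomly under-sampled to match the smaller,
stratified 10-fold cross-validation is run, and the whole procedure is
repeated 5 times with fresh under-sampling and fold allocation; the
reported accuracy is the mean over all folds and repeats.  Temporal
generalisation trains at one time sample and tests at every other,
producing a train-time x test-time accuracy matrix whose diagonal
approximates the time-wise map.

Features are z-scored per time sample with training-fold statistics, so
accuracies are invariant to a common rescaling of all amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import EpochedTrials

#: The eight binary contrasts: (paradigm, class_a conditions, class_b conditions).
CONTRASTS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "fSD": ("frequency", ("S",), ("fD1", "fD2")),
    "fSD1": ("frequency", ("S",), ("fD1",)),
    "fSD2": ("frequency", ("S",), ("fD2",)),
    "fD1D2": ("frequency", ("fD1",), ("fD2",)),
    "iSD": ("intensity", ("S",), ("iD1", "iD2")),
    "iSD1": ("intensity", ("S",), ("iD1",)),
    "iSD2": ("intensity", ("S",), ("iD2",)),
    "iD1D2": ("intensity", ("iD1",), ("iD2",)),
}


@dataclass(frozen=True)
class Contrast:
    """One binary decoding contrast between two disjoint condition sets."""

    name: str
    paradigm: str
    class_a: tuple[str, ...]
    class_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.class_a) & set(self.class_b):
            raise ValueError("class sets must be disjoint")

    @classmethod
    def named(cls, name: str) -> "Contrast":
        if name not in CONTRASTS:
            raise ValueError(f"unknown contrast {name!r}; choose from {sorted(CONTRASTS)}")
        paradigm, a, b = CONTRASTS[name]
        return cls(name, paradigm, a, b)


@dataclass
class DecodingMap:
    """Per-animal time-wise accuracies, shape (n_animals, n_times), in [0, 1]."""

    accuracies: np.ndarray
    contrast: str
    rate: float = 100.0

    def group_mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)


@dataclass
class TemporalGeneralizationMap:
    """Per-animal train-time x test-time accuracies (n_animals, T, T)."""

    accuracies: np.ndarray
    contrast: str
    rate: float = 100.0

    def group_mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.accuracies, axis1=1, axis2=2)


def _contrast_arrays(
    trials: EpochedTrials, contrast: Contrast
) -> tuple[np.ndarray, np.ndarray]:
    """Feature tensor (n, T, n_channels) and binary labels (a -> 0, b -> 1)."""
    lab = trials.labels
    in_par = lab["paradigm"].to_numpy() == contrast.paradigm
    cond = lab["condition"].to_numpy()
    a = in_par & np.isin(cond, contrast.class_a)
    b = in_par & np.isin(cond, contrast.class_b)
    X = np.asarray(trials.amplitudes, dtype=float)[a | b].transpose(0, 2, 1)
    y = np.where(np.isin(cond[a | b], contrast.class_b), 1, 0)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError(f"contrast {contrast.name}: a class is empty")
    return X, y


def _undersample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices equalising the two class counts by random under-sampling."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n = min(idx0.size, idx1.size)
    keep0 = rng.choice(idx0, size=n, replace=False) if idx0.size > n else idx0
    keep1 = rng.choice(idx1, size=n, replace=False) if idx1.size > n else idx1
    return np.sort(np.concatenate([keep0, keep1]))


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random stratified fold assignment; returns test-index arrays."""
    assignment = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        assignment[perm] = np.arange(perm.size) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def fit_linear_svm_batch(
    X: np.ndarray, y01: np.ndarray, C: float = 1.0, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Fit T independent linear SVMs sharing their labels, one per time point.

    Solves the L2-regularised squared-hinge primal (the LinearSVC
    objective, bias handled as an augmented regularised feature)

        min_w 0.5 ||w||^2 + C sum_i max(0, 1 - y_i <x_i, w>)^2

    for every slice ``X[t]`` at once with a safeguarded active-set Newton
    method; the objective is strongly convex and piecewise quadratic, so a
    handful of Newton steps reaches machine precision.  Fitting all time
    points in one vectorised solver is what makes whole-cohort decoding
    tractable; a unit test pins its solutions to ``sklearn`` LinearSVC.

    Parameters
    ----------
    X : array (T, n, f)
        Per-time-point feature matrices.
    y01 : array (n,)
        Binary labels in {0, 1}.

    Returns
    -------
    w : (T, f) weights, b : (T,) intercepts.
    """
    T, n, f = X.shape
    y = np.where(np.asarray(y01) > 0, 1.0, -1.0)
    Xa = np.concatenate([X, np.ones((T, n, 1))], axis=2)  # augmented bias column
    yX = y[None, :, None] * Xa
    w = np.zeros((T, f + 1))

    def objective(wc: np.ndarray) -> np.ndarray:
        v = np.einsum("tnf,tf->tn", yX, wc)
        loss = np.maximum(0.0, 1.0 - v)
        return 0.5 * np.sum(wc * wc, axis=1) + C * np.sum(loss * loss, axis=1)

    eye = np.eye(f + 1)
    obj = objective(w)
    for _ in range(max_iter):
        v = np.einsum("tnf,tf->tn", yX, w)
        slack = np.maximum(0.0, 1.0 - v)
        grad = w - 2.0 * C * np.einsum("tn,tnf->tf", slack, yX)
        if np.abs(grad).max() <= tol * max(1.0, np.abs(obj).max()):
            break
        active = (slack > 0).astype(float)
        H = eye[None] + 2.0 * C * np.einsum("tn,tnf,tng->tfg", active, Xa, Xa)
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # backtracking: per-problem step halving until the objective decreases
        scale = np.ones(T)
        for _ in range(20):
            new_w = w - scale[:, None] * step
            new_obj = objective(new_w)
            bad = new_obj > obj + 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        improved = new_obj <= obj + 1e-12
        w = np.where(improved[:, None], new_w, w)
        obj = np.where(improved, new_obj, obj)
        if not improved.any():
            break
    return w[:, :f], w[:, f]


def _decode_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    repeats: int,
    rng: np.random.Generator,
    generalize: bool,
) -> np.ndarray:
    """Shared CV engine; returns (T,) or (T, T) mean accuracy."""
    n_t = X.shape[1]
    acc = np.zeros((n_t, n_t) if generalize else n_t)
    n_cells = 0
    for _ in range(repeats):
        keep = _undersample(y, rng)
        Xr, yr = X[keep], y[keep]
        if min((yr == 0).sum(), (yr == 1).sum()) < folds:
            raise ValueError("each class needs at least `folds` trials")
        for test_idx in _stratified_folds(yr, folds, rng):
            train_mask = np.ones(yr.size, dtype=bool)
            train_mask[test_idx] = False
            Xtr, ytr = Xr[train_mask], yr[train_mask]
            Xte, yte = Xr[test_idx], yr[test_idx]
            # per-time-sample z-scoring with training-fold statistics
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
            W, b = fit_linear_svm_batch(Xtr.transpose(1, 0, 2), ytr)
            if generalize:
                # classifier trained at t, applied at every test time u
                scores = np.einsum("nuf,tf->ntu", Xte, W) + b[None, :, None]
                correct = ((scores > 0).astype(int) == yte[:, None, None])
                acc += correct.mean(axis=0)
            else:
                scores = np.einsum("ntf,tf->nt", Xte, W) + b[None, :]
                acc += ((scores > 0).astype(int) == yte[:, None]).mean(axis=0)
            n_cells += 1
    return acc / n_cells


def timewise_decode(
    trials: EpochedTrials,
    contrast: Contrast | str,
    folds: int = 10,
    repeats: int = 5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Time-wise decoding accuracy for one animal; returns (n_times,)."""
    contrast = Contrast.named(contrast) if isinstance(contrast, str) else contrast
    X, y = _contrast_arrays(trials, contrast)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _decode_cv(X, y, folds, repeats, rng, generalize=False)


def temporal_generalization(
    trials: EpochedTrials,
    contrast: Contrast | str,
    folds: int = 10,
    repeats: int = 5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Train-time x test-time accuracy matrix for one animal; (T, T)."""
    contrast = Contrast.named(contrast) if isinstance(contrast, str) else contrast
    X, y = _contrast_arrays(trials, contrast)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _decode_cv(X, y, folds, repeats, rng, generalize=True)


def decode_cohort(
    trials: EpochedTrials,
    contrast: Contrast | str,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    generalize: bool = False,
    label_permute: bool = False,
) -> DecodingMap | TemporalGeneralizationMap:
    """Decode every animal separately; one reproducible child seed each.

    ``label_permute`` shuffles condition labels within each animal before
    decoding — the empirical chance-level control.
    """
    contrast = Contrast.named(contrast) if isinstance(contrast, str) else contrast
    animals = sorted(trials.labels["animal"].unique())
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(animals))
    maps = []
    for a, child in zip(animals, children):
        mask = (trials.labels["animal"] == a).to_numpy()
        sub = EpochedTrials(
            trials.amplitudes[mask],
            trials.labels.loc[mask].reset_index(drop=True),
            trials.rate,
            trials.window,
        )
        rng = np.random.default_rng(child)
        if label_permute:
            lab = sub.labels.copy()
            par = lab["paradigm"].to_numpy() == contrast.paradigm
            idx = np.flatnonzero(par)
            perm = rng.permutation(idx)
            for col in ("condition", "local_condition"):
                vals = lab[col].to_numpy().copy()
                vals[idx] = vals[perm]
                lab[col] = vals
            sub.labels = lab
        fn = temporal_generalization if generalize else timewise_decode
        maps.append(fn(sub, contrast, folds=folds, repeats=repeats, seed=rng))
    arr = np.stack(maps)
    if generalize:
        return TemporalGeneralizationMap(arr, contrast.name, trials.rate)
    return DecodingMap(arr, contrast.name, trials.rate)
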