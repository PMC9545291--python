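"""Group-level cluster-based permutation inference on decoding maps.

Per grid point, a one-sample t statistic of (accuracy - chance) across
animals is computed.  Points whose two-sided p falls below the
cluster-forming threshold (alpha) form candidate clusters under the
declared adjacency — neighbouring samples in 1-D, 4-connectivity in 2-D —
separately for positive and negative t.  Each cluster's mass is the sum of
t inside it.  The null distribution records, for each of ``n_perm`` random
sign-flips of the per-animal difference maps, the maximal absolute cluster
mass over both signs; a cluster's p-value is
``(1 + #{null >= |mass|}) / (1 + n_perm)``.

Sign-flipping is exact under the exchangeability of the per-animal signs
about chance, and taking the maximum over the whole grid (and both signs)
controls the family-wise error rate at alpha.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats


@dataclass
class Cluster:
    """One supra-threshold cluster: member indices, signed mass, p-value."""

    indices: np.ndarray  # (k,) flat indices into the map grid
    mass: float
    p_value: float
    sign: int

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


@dataclass
class ClusterResult:
    """All candidate clusters for one map, plus test configuration."""

    clusters: list[Cluster]
    shape: tuple[int, ...]
    alpha: float
    n_permutations: int
    t_map: np.ndarray = field(default=None, repr=False)
    t_threshold: float = float("nan")

    def significance_mask(self, alpha: float | None = None) -> np.ndarray:
        """Boolean grid marking members of clusters with p <= alpha."""
        alpha = self.alpha if alpha is None else alpha
        mask = np.zeros(int(np.prod(self.shape)), dtype=bool)
        for c in self.clusters:
            if c.p_value <= alpha:
                mask[c.indices] = True
        return mask.reshape(self.shape)

    def significant_clusters(self, alpha: float | None = None) -> list[Cluster]:
        alpha = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value <= alpha]

    def to_json(self, rate: float = 100.0, t0: float = -0.1) -> str:
        """Serialise cluster extents (in seconds along each axis), mass, p."""
        items = []
        for c in self.clusters:
            coords = np.unravel_index(c.indices, self.shape)
            extent = {
                f"axis{i}_s": [float(t0 + coords[i].min() / rate),
                               float(t0 + coords[i].max() / rate)]
                for i in range(len(self.shape))
            }
            items.append(
                {"mass": c.mass, "p_value": c.p_value, "sign": c.sign,
                 "n_points": int(c.indices.size), **extent}
            )
        return json.dumps(
            {"alpha": self.alpha, "n_permutations": self.n_permutations,
             "clusters": items},
            indent=2,
        )


def _t_threshold(n: int, alpha: float) -> float:
    return float(stats.t.ppf(1 - alpha / 2, df=n - 1))


def _t_maps(signed: np.ndarray) -> np.ndarray:
    """Rows of one-sample t statistics; ``signed`` is (n_maps, A, P)."""
    n = signed.shape[-2]
    m = signed.mean(axis=-2)
    var = signed.var(axis=-2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _clusters_1d(t: np.ndarray, thr: float) -> list[tuple[np.ndarray, float, int]]:
    out = []
    for sign in (1, -1):
        mask = sign * t > thr
        if not mask.any():
            continue
        lab, n_lab = ndimage.label(mask)
        for k in range(1, n_lab + 1):
            idx = np.flatnonzero(lab == k)
            out.append((idx, float(t[idx].sum()), sign))
    return out


def _clusters_nd(t: np.ndarray, thr: float) -> list[tuple[np.ndarray, float, int]]:
    structure = ndimage.generate_binary_structure(t.ndim, 1)  # 4-connectivity in 2-D
    out = []
    flat_t = t.ravel()
    for sign in (1, -1):
        lab, n_lab = ndimage.label(sign * t > thr, structure=structure)
        for k in range(1, n_lab + 1):
            idx = np.flatnonzero(lab.ravel() == k)
            out.append((idx, float(flat_t[idx].sum()), sign))
    return out


def _max_run_mass(t_rows: np.ndarray, thr: float) -> np.ndarray:
    """Per row, the maximal |sum of t| over supra-threshold runs, both signs.

    Fully vectorised across rows: runs never span the inserted all-below
    separator column, so one flattened pass finds every run.
    """
    n_rows, n_pts = t_rows.shape
    best = np.zeros(n_rows)
    for sign in (1.0, -1.0):
        vals = sign * t_rows
        mask = vals > thr
        # separator column breaks runs between rows
        padded = np.zeros((n_rows, n_pts + 1), dtype=bool)
        padded[:, :n_pts] = mask
        flat_mask = padded.ravel()
        flat_vals = np.zeros(flat_mask.size)
        flat_vals.reshape(n_rows, n_pts + 1)[:, :n_pts] = vals
        edges = np.diff(flat_mask.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if flat_mask[0]:
            starts = np.concatenate([[0], starts])
        if flat_mask[-1]:
            ends = np.concatenate([ends, [flat_mask.size]])
        if starts.size == 0:
            continue
        csum = np.concatenate([[0.0], np.cumsum(flat_vals)])
        masses = csum[ends] - csum[starts]
        rows = starts // (n_pts + 1)
        np.maximum.at(best, rows, masses)
    return best


def cluster_permutation(
    maps: np.ndarray,
    chance: float = 0.5,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    adjacency: str = "auto",
) -> ClusterResult:
    """Cluster-based sign-flip permutation test against chance.

    Parameters
    ----------
    maps : array, (n_animals, T) or (n_animals, T, T)
        Per-animal accuracy maps.
    chance : float
        Null accuracy level subtracted before testing.
    alpha : float
        Both the two-sided cluster-forming threshold and the family-wise
        significance level.
    n_perm : int
        Number of random sign-flip permutations (>= 100 recommended).
    seed : int or Generator
        Randomness source for the sign flips.
    adjacency : str
        "auto" uses run-adjacency in 1-D and 4-connectivity in 2-D.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim not in (2, 3):
        raise ValueError("maps must be (animals, T) or (animals, T1, T2)")
    n_animals = maps.shape[0]
    if n_animals < 2:
        raise ValueError("cluster permutation needs at least 2 animals")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    shape = maps.shape[1:]
    d = (maps - chance).reshape(n_animals, -1)  # (A, P)
    thr = _t_threshold(n_animals, alpha)
    t_obs = _t_maps(d[None])[0].reshape(shape)

    observed = (
        _clusters_1d(t_obs, thr) if t_obs.ndim == 1 else _clusters_nd(t_obs, thr)
    )

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_animals))
    null_max = np.zeros(n_perm)
    if t_obs.ndim == 1:
        # all permutations at once: (n_perm, A, P) -> t rows
        t_null = _t_maps(signs[:, :, None] * d[None])
        null_max = _max_run_mass(t_null, thr)
    else:
        block = 200  # bound memory on the T*T grid
        for lo in range(0, n_perm, block):
            sl = signs[lo : lo + block]
            t_null = _t_maps(sl[:, :, None] * d[None])
            for j, row in enumerate(t_null):
                cl = _clusters_nd(row.reshape(shape), thr)
                null_max[lo + j] = max((abs(m) for _, m, _ in cl), default=0.0)

    clusters = []
    for idx, mass, sign in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(Cluster(indices=idx, mass=mass, p_value=float(p), sign=sign))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(
        clusters=clusters,
        shape=shape,
        alpha=alpha,
        n_permutations=n_perm,
        t_map=t_obs,
        t_threshold=thr,
    )
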