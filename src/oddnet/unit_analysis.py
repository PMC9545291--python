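"""Hidden-unit characterisation: temporal-response-field taxonomy, PCA
views of the activation tensor, and sample-entropy summaries.

Each of the 256 hidden units is categorised per stimulus condition from
its 111-sample activation trace by a fixed decision cascade on the latency
of its activation peak — zero (flat at zero), alpha (pre-stimulus /
periodic background), onset (peak during a tone), offset (up to 50 ms
after a tone), safety (50-150 ms after a tone), danger (150-450 ms after
the first tone) and other — and the most frequent per-condition category
becomes the unit's modal label.  Signal regularity is quantified with the
Richman-Moorman sample entropy (m = 2, tolerance 0.15 x SD), and three
PCA projections summarise condition-, layer- and unit-level structure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .rnn_model import ActivationRecord
from .stimuli import CONDITIONS, N_FRAMES, WINDOW

CATEGORIES = ("zero", "alpha", "onset", "offset", "safety", "danger", "other")

#: stimulus-on windows: first tone 0-0.1 s, second (standard) tone 0.55-0.65 s
ONSET_WINDOWS = ((0.0, 0.1), (0.55, 0.65))
OFFSET_WINDOWS = ((0.1, 0.15), (0.65, 0.7))
SAFETY_WINDOWS = ((0.15, 0.25), (0.7, 0.8))
DANGER_WINDOW = (0.25, 0.55)

_ZERO_TOL = 1e-10


def _grid(n: int = N_FRAMES, rate: float = 100.0) -> np.ndarray:
    return WINDOW[0] + np.arange(n) / rate


def _in_any(t: float, windows, half_open: bool) -> bool:
    # half-open (lo, hi]; the first onset window is closed at 0
    for lo, hi in windows:
        if half_open:
            if lo < t <= hi + 1e-9:
                return True
        elif lo - 1e-9 <= t <= hi + 1e-9:
            return True
    return False


def categorize_unit(trace: np.ndarray, rate: float = 100.0) -> str:
    """Category of one activation trace on the -0.1..1.0 s grid.

    The cascade: zero -> alpha -> onset -> offset -> safety -> danger ->
    other.  "Peak" is the global argmax (earliest sample on ties).  The
    alpha rule fires when the peak precedes stimulus onset, or when some
    pre-stimulus sample exceeds the trace mean by three trace SDs while
    the post-stimulus peak stays below half the pre-stimulus peak.
    """
    trace = np.asarray(trace, dtype=float)
    t = _grid(trace.size, rate)
    if np.max(np.abs(trace)) < _ZERO_TOL:
        return "zero"
    peak_t = float(t[int(np.argmax(trace))])
    pre = t < 0
    if peak_t < 0:
        return "alpha"
    if pre.any():
        mu, sd = trace.mean(), trace.std()
        pre_peak = trace[pre].max()
        post_peak = trace[~pre].max()
        if sd > 0 and pre_peak > mu + 3 * sd and post_peak < 0.5 * pre_peak:
            return "alpha"
    if _in_any(peak_t, ONSET_WINDOWS, half_open=False):
        return "onset"
    if _in_any(peak_t, OFFSET_WINDOWS, half_open=True):
        return "offset"
    if _in_any(peak_t, SAFETY_WINDOWS, half_open=True):
        return "safety"
    if _in_any(peak_t, (DANGER_WINDOW,), half_open=True):
        return "danger"
    return "other"


def modal_category(per_condition: list[str] | tuple[str, ...]) -> str:
    """Most frequent category; ties broken by the cascade order."""
    counts = Counter(per_condition)
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    return min(tied, key=CATEGORIES.index)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.15) -> float:
    """Richman-Moorman sample entropy with tolerance ``r x SD(x)``.

    Counts ordered template pairs (i != j, i, j < N - m) whose Chebyshev
    distance is within tolerance at length m (count B) and length m + 1
    (count A) and returns ``-ln(A / B)``.  Conventions: a constant series
    returns 0; if no (m+1)-matches exist but B > 0 the maximal defined
    value ``-ln(1 / B)`` is returned; if B = 0 the result is 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd
    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n - m, m + 1)
    d_m = np.max(
        np.abs(emb[:, None, :m] - emb[None, :, :m]), axis=-1
    )  # distances between m-templates (restricted to the n - m of them)
    d_m1 = np.max(np.abs(emb[:, None] - emb[None, :]), axis=-1)
    off = ~np.eye(emb.shape[0], dtype=bool)
    B = int(np.sum((d_m <= tol) & off))
    A = int(np.sum((d_m1 <= tol) & off))
    if B == 0:
        return 0.0
    if A == 0:
        return float(-np.log(1.0 / B))
    return float(-np.log(A / B))


@dataclass
class UnitCatalog:
    """Per-unit taxonomy and entropies.

    ``table`` has one row per unit (layer 1-4, unit 0-63) with that unit's
    per-condition categories, modal category, and per-condition sample
    entropies.
    """

    table: pd.DataFrame
    conditions: tuple[str, ...] = CONDITIONS

    @property
    def n_units(self) -> int:
        return len(self.table)

    def category_counts(self) -> pd.DataFrame:
        """Modal-category counts per layer (rows: category, cols: layer + total)."""
        out = pd.DataFrame(
            0, index=list(CATEGORIES),
            columns=[f"layer{l}" for l in sorted(self.table["layer"].unique())],
        )
        for layer, grp in self.table.groupby("layer"):
            for cat, n in grp["modal_category"].value_counts().items():
                out.loc[cat, f"layer{layer}"] = int(n)
        out["total"] = out.sum(axis=1)
        return out


def categorize_model(record: ActivationRecord, rate: float = 100.0) -> UnitCatalog:
    """Categorise every hidden unit of a model from its activation record."""
    rows = []
    conds = record.conditions
    for layer_i in range(next(iter(record.activations.values())).shape[0]):
        n_units = next(iter(record.activations.values())).shape[1]
        for u in range(n_units):
            cats = {c: categorize_unit(record.activations[c][layer_i, u], rate) for c in conds}
            ents = {c: sample_entropy(record.activations[c][layer_i, u]) for c in conds}
            rows.append(
                {"layer": layer_i + 1, "unit": u,
                 **{f"category_{c}": cats[c] for c in conds},
                 "modal_category": modal_category([cats[c] for c in conds]),
                 **{f"entropy_{c}": ents[c] for c in conds}}
            )
    return UnitCatalog(table=pd.DataFrame(rows), conditions=tuple(conds))


@dataclass
class EntropySummary:
    """Entropy summaries mirroring the layer/condition/category views.

    ``zero_counts``: units with zero entropy, per layer x condition.
    ``nonzero_mean``: mean entropy of the nonzero-entropy units per
    layer x condition (NaN where a cell is empty).  ``layer_median`` /
    ``condition_median``: medians over all units.  ``category_stats``:
    mean and SD per modal category of the per-unit entropy averaged over
    conditions first (NaN for empty categories).
    """

    zero_counts: pd.DataFrame
    nonzero_mean: pd.DataFrame
    layer_median: pd.Series
    condition_median: pd.Series
    category_stats: pd.DataFrame


def summarize_entropy(catalog: UnitCatalog) -> EntropySummary:
    """Aggregate the catalog's per-unit, per-condition entropies."""
    tab = catalog.table
    conds = list(catalog.conditions)
    layers = sorted(tab["layer"].unique())
    ent = tab[[f"entropy_{c}" for c in conds]].to_numpy()

    zero_counts = pd.DataFrame(index=layers, columns=conds, dtype=float)
    nonzero_mean = pd.DataFrame(index=layers, columns=conds, dtype=float)
    for li, layer in enumerate(layers):
        sel = (tab["layer"] == layer).to_numpy()
        for ci, c in enumerate(conds):
            col = ent[sel, ci]
            zero_counts.loc[layer, c] = int((col == 0).sum())
            nz = col[col > 0]
            nonzero_mean.loc[layer, c] = nz.mean() if nz.size else np.nan

    layer_median = pd.Series(
        {layer: np.median(ent[(tab["layer"] == layer).to_numpy()]) for layer in layers},
        name="median_entropy",
    )
    condition_median = pd.Series(
        {c: np.median(ent[:, ci]) for ci, c in enumerate(conds)}, name="median_entropy"
    )

    unit_mean = ent.mean(axis=1)
    rows = []
    for cat in CATEGORIES:
        sel = (tab["modal_category"] == cat).to_numpy()
        rows.append(
            {"category": cat, "n": int(sel.sum()),
             "mean": float(unit_mean[sel].mean()) if sel.any() else np.nan,
             "sd": float(unit_mean[sel].std()) if sel.any() else np.nan}
        )
    return EntropySummary(
        zero_counts=zero_counts.astype(int),
        nonzero_mean=nonzero_mean,
        layer_median=layer_median,
        condition_median=condition_median,
        category_stats=pd.DataFrame(rows),
    )


@dataclass
class PCAView:
    """One PCA projection: scores (n x 2) and explained-variance fractions."""

    scores: np.ndarray
    explained_variance: np.ndarray
    row_labels: list


def pca_views(record: ActivationRecord) -> dict[str, PCAView | list[PCAView]]:
    """The three standard PCA projections of the activation tensor.

    1. ``conditions``: 5 x (layers*units*time) = 5 x 28 416 — one point per
       stimulus condition.
    2. ``layers``: 4 x (conditions*units*time) = 4 x 35 520 — one point per
       layer.
    3. ``units_by_layer``: per layer, 64 x (conditions*time) = 64 x 555 —
       one point per unit.
    Each matrix is feature-mean-centred and projected to 2 components.
    """
    stacked = record.stacked()  # (C, L, U, T)
    C, L, U, T = stacked.shape

    def _project(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if np.allclose(mat.var(axis=0), 0):  # degenerate: all rows identical
            return np.zeros((mat.shape[0], 2)), np.zeros(2)
        pca = PCA(n_components=2, svd_solver="full")
        scores = pca.fit_transform(mat)
        return scores, pca.explained_variance_ratio_

    cond_mat = stacked.reshape(C, L * U * T)
    s1, ev1 = _project(cond_mat)
    layer_mat = stacked.transpose(1, 0, 2, 3).reshape(L, C * U * T)
    s2, ev2 = _project(layer_mat)
    per_layer = []
    for l in range(L):
        unit_mat = stacked[:, l].transpose(1, 0, 2).reshape(U, C * T)
        s3, ev3 = _project(unit_mat)
        per_layer.append(PCAView(s3, ev3, [f"unit{u}" for u in range(U)]))
    return {
        "conditions": PCAView(s1, ev1, list(record.conditions)),
        "layers": PCAView(s2, ev2, [f"layer{l + 1}" for l in range(L)]),
        "units_by_layer": per_layer,
    }
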