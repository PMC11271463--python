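"""Stacked diversity change and the climate × land-use interaction typology.

Per-species presence/absence maps are stacked into per-cell species
richness (SR), loss (L) and gain (G) surfaces.  For each cell the loss (or
gain) counts under the dynamic-land-use scenario (a), the dynamic-climate
scenario (b) and the combined scenario (c) are classified as:

* only climate    a = 0 and b > 0
* only LULC       a > 0 and b = 0
* synergistic     c > a + b
* additive        c = a + b
* antagonistic    c < a + b      (for a, b > 0)
* none            a = b = c = 0

Classification happens on integer per-combination counts; only the final
percentages are averaged across (threshold, GCM) combinations.  A Moran's
I correlogram on model residuals quantifies residual spatial
autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

CAT_NONE = "none"
CAT_SYNERGISTIC = "synergistic"
CAT_ADDITIVE = "additive"
CAT_ONLY_CLIMATE = "only_climate"
CAT_ANTAGONISTIC = "antagonistic"
CAT_ONLY_LULC = "only_LULC"
CATEGORIES = (
    CAT_SYNERGISTIC, CAT_ADDITIVE, CAT_ONLY_CLIMATE, CAT_ANTAGONISTIC,
    CAT_ONLY_LULC,
)


@dataclass
class DiversityMaps:
    """Per-cell richness, loss, gain and delta grids."""

    SR_current: np.ndarray
    SR_future: np.ndarray
    L: np.ndarray
    G: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.SR_future - self.SR_current


def stack_diversity(
    current_maps: Mapping[str, np.ndarray],
    future_maps: Mapping[str, np.ndarray],
) -> DiversityMaps:
    """Stack per-species binary maps into SR/L/G surfaces.

    ``L`` counts species present now but absent in the future per cell;
    ``G`` the reverse; by construction SR_future = SR_current − L + G.
    """
    if set(current_maps) != set(future_maps):
        raise InputError("current and future map species sets differ")
    if not current_maps:
        raise InputError("empty species set")
    species = sorted(current_maps)
    cur = np.stack([np.asarray(current_maps[s], dtype=bool) for s in species])
    fut = np.stack([np.asarray(future_maps[s], dtype=bool) for s in species])
    if cur.shape != fut.shape:
        raise InputError("current/future grids are not aligned")
    return DiversityMaps(
        SR_current=cur.sum(axis=0).astype(int),
        SR_future=fut.sum(axis=0).astype(int),
        L=(cur & ~fut).sum(axis=0).astype(int),
        G=(~cur & fut).sum(axis=0).astype(int),
    )


def classify_interaction(a: int, b: int, c: int) -> str:
    """Classify one cell's (a, b, c) loss-or-gain counts.

    a = dynamic land use, b = dynamic climate, c = dynamic land-climate.
    Single-driver cells (a = 0 or b = 0) are classified before the
    synergy comparison so they never enter the c vs a + b test.
    """
    if a < 0 or b < 0 or c < 0:
        raise InputError("counts must be non-negative")
    if a == 0 and b == 0 and c == 0:
        return CAT_NONE
    if a == 0 and b > 0:
        return CAT_ONLY_CLIMATE
    if a > 0 and b == 0:
        return CAT_ONLY_LULC
    if c > a + b:
        return CAT_SYNERGISTIC
    if c == a + b:
        return CAT_ADDITIVE
    return CAT_ANTAGONISTIC


@dataclass
class InteractionRaster:
    """Per-cell (a, b, c) counts and categories for one combination."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    category: np.ndarray  # object array of category strings
    mode: str             # "loss" or "gain"

    @classmethod
    def from_counts(cls, a: np.ndarray, b: np.ndarray, c: np.ndarray,
                    mode: str) -> "InteractionRaster":
        a = np.asarray(a, dtype=int)
        b = np.asarray(b, dtype=int)
        c = np.asarray(c, dtype=int)
        if not (a.shape == b.shape == c.shape):
            raise InputError("count grids are not aligned")
        cat = np.empty(a.shape, dtype=object)
        for idx in np.ndindex(a.shape):
            cat[idx] = classify_interaction(int(a[idx]), int(b[idx]), int(c[idx]))
        return cls(a, b, c, cat, mode)


def interaction_summary(
    rasters: Sequence[InteractionRaster],
) -> pd.DataFrame:
    """Category percentages, averaged across (threshold, GCM) combinations.

    Per combination, percentages are computed over cells with an
    interaction (category ≠ none); combinations without any such cell are
    skipped with a warning; the output is the across-combination mean per
    mode (loss/gain), one row per mode, columns ordered as the five
    categories.
    """
    if not rasters:
        raise InputError("no interaction rasters given")
    rows: dict[str, list[np.ndarray]] = {}
    for ras in rasters:
        flat = ras.category.ravel()
        usable = flat != CAT_NONE
        n = int(usable.sum())
        if n == 0:
            warnings.warn("combination with no classifiable cells skipped")
            continue
        pct = np.array([
            100.0 * np.sum(flat[usable] == cat) / n for cat in CATEGORIES
        ])
        rows.setdefault(ras.mode, []).append(pct)
    if not rows:
        raise InputError("no combination had classifiable cells")
    data = {mode: np.mean(np.stack(v), axis=0) for mode, v in rows.items()}
    return pd.DataFrame.from_dict(data, orient="index", columns=list(CATEGORIES))


# ---------------------------------------------------------------------------
# Moran's I correlogram
# ---------------------------------------------------------------------------

def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with an arbitrary (symmetric, zero-diagonal) weight matrix."""
    z = values - values.mean()
    W = weights.sum()
    if W == 0:
        raise InputError("empty weight matrix")
    n = values.size
    return float((n / W) * (z @ weights @ z) / (z @ z))


def morans_correlogram(
    points: np.ndarray,
    residuals: np.ndarray,
    distance_breaks: Sequence[float],
    n_permutations: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I per distance class with permutation p-values.

    ``points`` is (n, 2) planar km coordinates; ``residuals`` the per-point
    model residuals (observed 0/1 minus predicted score).  Binary weights
    connect pairs whose distance falls in each half-open class
    ``[break_i, break_{i+1})``.  Empty classes are dropped with a warning.
    The returned frame has one row per class (midpoint, I, p, n_pairs) and
    carries the across-class mean I and the fraction of significant
    classes (α = 0.05) in ``df.attrs``.
    """
    points = np.asarray(points, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if points.shape[0] < 10:
        raise InputError("need at least 10 points")
    if points.shape[0] != residuals.size:
        raise InputError("points/residuals length mismatch")
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(residuals.size) for _ in range(n_permutations)]
    rows = []
    for lo, hi in zip(distance_breaks[:-1], distance_breaks[1:]):
        w = ((d >= lo) & (d < hi)).astype(float)
        np.fill_diagonal(w, 0.0)
        n_pairs = int(w.sum() / 2)
        if n_pairs == 0:
            warnings.warn(f"empty distance class [{lo}, {hi}); dropped")
            continue
        i_obs = morans_i(residuals, w)
        null = np.array([morans_i(residuals[p], w) for p in perms])
        e_i = -1.0 / (residuals.size - 1)
        p = (np.sum(np.abs(null - e_i) >= abs(i_obs - e_i)) + 1) / (n_permutations + 1)
        rows.append({"midpoint": 0.5 * (lo + hi), "I": i_obs, "p": float(p),
                     "n_pairs": n_pairs})
    if not rows:
        raise InputError("every distance class was empty")
    df = pd.DataFrame(rows)
    df.attrs["mean_I"] = float(df["I"].mean())
    df.attrs["frac_significant"] = float(np.mean(df["p"] < 0.05))
    return df
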