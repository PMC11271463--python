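"""Scenario projection: thresholding, binarization, dispersal constraint.

Continuous suitability maps are binarized under three threshold schemes —
equalize sensitivity and specificity (SensSpec), maximize TSS
(MaxSensSpec), and the nearest-rank 10th percentile of training presence
scores (TenPerc) — and future presences are cropped to the area reachable
under a fixed annual dispersal rate: the minimum convex polygon of the
occurrences dilated by rate × horizon (e.g. 1 km/yr over 2010–2070 gives a
60 km buffer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely

from .errors import AlignmentError, InputError
from .geodata import Cell, EnvStack, OccurrenceSet

SCHEME_SENSSPEC = "SensSpec"
SCHEME_MAXSENSSPEC = "MaxSensSpec"
SCHEME_TENPERC = "TenPerc"
SCHEMES = (SCHEME_SENSSPEC, SCHEME_MAXSENSSPEC, SCHEME_TENPERC)


@dataclass
class ThresholdRule:
    scheme: str
    value: float


def compute_threshold(
    scheme: str,
    training_presence_scores: Sequence[float],
    training_background_scores: Sequence[float],
) -> ThresholdRule:
    """Derive a binarization threshold from training scores.

    SensSpec minimizes |sensitivity − specificity| over observed scores
    (ties resolved toward higher sensitivity + specificity, then the lower
    score); MaxSensSpec maximizes sensitivity + specificity − 1 (lowest
    such score on ties); TenPerc is the nearest-rank 10th percentile of
    the training presence scores.  Presence rule everywhere: score ≥ value.
    """
    pos = np.sort(np.asarray(training_presence_scores, dtype=float))
    neg = np.asarray(training_background_scores, dtype=float)
    if pos.size < 2:
        raise InputError("need at least 2 presence scores")
    if scheme == SCHEME_TENPERC:
        rank = int(np.ceil(0.10 * pos.size))  # nearest-rank, 1-based
        return ThresholdRule(scheme, float(pos[max(rank, 1) - 1]))
    if scheme not in (SCHEME_SENSSPEC, SCHEME_MAXSENSSPEC):
        raise InputError(f"unknown threshold scheme {scheme!r}")
    cand = np.unique(np.concatenate([pos, neg]))
    best_t, best_key = None, None
    for t in cand:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        if scheme == SCHEME_SENSSPEC:
            key = (abs(sens - spec), -(sens + spec), -t)
        else:
            key = (-(sens + spec - 1.0), -t)  # ties -> the stricter threshold
        if best_key is None or key < best_key:
            best_key, best_t = key, t
    return ThresholdRule(scheme, float(best_t))


def binarize(suitability: np.ndarray, rule: ThresholdRule) -> np.ndarray:
    """Presence/absence grid: cell ≥ threshold → present; NaN → absent.

    Nodata (NaN) cells are never presences; callers keep the stack's
    nodata mask alongside if they need to distinguish absence from nodata.
    """
    with np.errstate(invalid="ignore"):
        return np.asarray(suitability >= rule.value) & np.isfinite(suitability)


@dataclass
class DispersalConstraint:
    """Reachable-area mask: buffered minimum convex polygon."""

    mcp: shapely.Geometry
    buffer_km: float
    mask: np.ndarray


def dispersal_mask(
    occurrences: OccurrenceSet,
    rate_km_per_yr: float,
    year_from: int,
    year_to: int,
    grid: EnvStack,
) -> DispersalConstraint:
    """Area reachable from the occurrences at a fixed annual dispersal rate.

    The minimum convex polygon of the occurrence points (a segment for two
    points) is dilated by ``rate × (year_to − year_from)`` km; the mask
    holds cells whose centroid falls inside the dilated polygon.
    Occurrence cells themselves are always inside the mask.
    """
    if rate_km_per_yr < 0:
        raise InputError("dispersal rate must be non-negative")
    if year_to <= year_from:
        raise InputError("year_to must be after year_from")
    if len(occurrences.cell_ids) < 2:
        raise InputError("need at least 2 occurrence cells")
    buffer_km = rate_km_per_yr * (year_to - year_from)
    pts = shapely.MultiPoint(
        [grid.cell_center(c) for c in occurrences.cell_ids]
    )
    mcp = pts.convex_hull  # Polygon, LineString or Point
    poly = mcp.buffer(buffer_km) if buffer_km > 0 else mcp
    rows, cols = np.meshgrid(
        np.arange(grid.nrows), np.arange(grid.ncols), indexing="ij"
    )
    x0, y0 = grid.origin
    xs = x0 + (cols + 0.5) * grid.cell_size
    ys = y0 + (rows + 0.5) * grid.cell_size
    mask = shapely.intersects_xy(poly, xs.ravel(), ys.ravel()).reshape(grid.shape)
    for c in occurrences.cell_ids:  # invariant: occurrences never cropped
        mask[c] = True
    return DispersalConstraint(mcp, buffer_km, mask)


def apply_dispersal(binary_map: np.ndarray,
                    constraint: DispersalConstraint) -> np.ndarray:
    """Force cells outside the reachable area to absent."""
    if binary_map.shape != constraint.mask.shape:
        raise AlignmentError("binary map and dispersal mask shapes differ")
    return binary_map & constraint.mask


PredictionKey = tuple[str, str | None, str | None, str]


def enumerate_predictions(
    n_thresholds: int = 3, n_gcm: int = 3, n_ssp: int = 2
) -> list[PredictionKey]:
    """All (scenario, gcm, ssp, threshold) keys the pipeline produces.

    current × thresholds, dynamic-climate × (gcm × ssp × thresholds),
    dynamic-LULC × (ssp × thresholds) — GCM-free because climate is held
    constant there — and dynamic-both × (gcm × ssp × thresholds).  Under
    the defaults (3 thresholds, 3 GCMs, 2 SSPs) this is 45 keys per
    species.
    """
    schemes = list(SCHEMES[:n_thresholds])
    if n_thresholds > len(SCHEMES):
        schemes += [f"thr{i}" for i in range(len(SCHEMES), n_thresholds)]
    gcms = [f"gcm{g + 1}" for g in range(n_gcm)]
    ssps = ["mild", "severe"][:n_ssp] + [
        f"ssp{i}" for i in range(2, n_ssp) if n_ssp > 2
    ]
    keys: list[PredictionKey] = []
    for t in schemes:
        keys.append(("current", None, None, t))
    for gcm in gcms:
        for ssp in ssps:
            for t in schemes:
                keys.append(("climate", gcm, ssp, t))
    for ssp in ssps:
        for t in schemes:
            keys.append(("lulc", None, ssp, t))
    for gcm in gcms:
        for ssp in ssps:
            for t in schemes:
                keys.append(("both", gcm, ssp, t))
    assert len(keys) == len(set(keys))
    return keys
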