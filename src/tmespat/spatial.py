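"""Spatial colocalization statistics on cell point patterns.

Two statistics over a ladder of radii (default 50, 100, ..., 600 um):

Normalized mixing score (NMS)
    ``NMS = [I_rt * n_r (n_r - 1) / 2] / [I_rr * n_r * n_t]`` where
    ``I_rt`` is the number of reference-target pairs within the radius
    and ``I_rr`` the number of distinct reference-reference pairs. The
    raw mixing ratio ``I_rt / I_rr`` is normalized by the ratio of the
    maximal pair counts, so the score is ~1 under complete spatial
    randomness and grows with reference-target colocalization. With no
    co-located reference pairs (``I_rr = 0``) the score is undefined
    (NaN), not infinite.

Aggregated entropy gradient
    For each radius, reference and target cells are counted inside the
    radius around every reference cell (the center cell included) and
    pooled; the Shannon entropy (log2) of the pooled two-class
    composition is 1 at perfect balance and 0 for a single class. The
    slope of the entropy curve across the two smallest radii classifies
    the pattern: negative slope = attraction (colocalization strongest
    close to the reference cells), positive = repulsion, |slope| <= eps
    = flat.

Pair counting uses a KD-tree and matches the O(n^2) definition exactly;
distances are Euclidean in um and the radius boundary is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import IMMUNE_CLASSES

DEFAULT_RADII: tuple[float, ...] = tuple(float(r) for r in range(50, 601, 50))
FLAT_EPS = 1e-4  # |slope| below this (per um) is a zero slope

PATTERNS = ("attraction", "repulsion", "flat", "undefined")


@dataclass(frozen=True)
class InteractionCounts:
    i_rt: int  # reference-target pairs within radius
    i_rr: int  # distinct reference-reference pairs within radius
    n_r: int
    n_t: int


def _as_points(xy) -> np.ndarray:
    pts = np.asarray(xy, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of coordinates in um")
    return pts


def count_interactions(ref_xy, tgt_xy, radius: float) -> InteractionCounts:
    """Count reference-target and reference-reference pairs within
    ``radius`` (inclusive). Self-pairs are excluded; duplicated
    coordinates count as distinct cells."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    ref = _as_points(ref_xy)
    tgt = _as_points(tgt_xy)
    n_r, n_t = ref.shape[0], tgt.shape[0]
    if n_r == 0:
        return InteractionCounts(0, 0, 0, n_t)
    ref_tree = cKDTree(ref)
    i_rt = int(ref_tree.count_neighbors(cKDTree(tgt), radius)) if n_t else 0
    # count_neighbors on itself counts ordered pairs incl. the n self-pairs
    i_rr = (int(ref_tree.count_neighbors(ref_tree, radius)) - n_r) // 2
    return InteractionCounts(i_rt=i_rt, i_rr=i_rr, n_r=n_r, n_t=n_t)


def nms(counts: InteractionCounts) -> float:
    """Normalized mixing score from pair counts; NaN when undefined."""
    if counts.n_r < 2:
        raise ValueError("need at least two reference cells")
    if counts.n_t < 1:
        raise ValueError("need at least one target cell")
    if counts.i_rr == 0:
        return math.nan
    max_rr = counts.n_r * (counts.n_r - 1) / 2.0
    max_rt = counts.n_r * counts.n_t
    return (counts.i_rt * max_rr) / (counts.i_rr * max_rt)


def nms_curve(ref_xy, tgt_xy, radii: Sequence[float] = DEFAULT_RADII) -> pd.DataFrame:
    """NMS per ladder radius; undefined radii propagate as NaN."""
    rows = []
    for r in radii:
        counts = count_interactions(ref_xy, tgt_xy, r)
        rows.append({"radius": float(r), "value": nms(counts)})
    return pd.DataFrame(rows)


def aggregated_entropy(ref_xy, tgt_xy, radius: float) -> float:
    """Pooled two-class Shannon entropy within ``radius`` of reference
    cells. Counts include the center reference cell, so the reference
    pool is never empty; ``0 * log2 0`` is taken as 0."""
    ref = _as_points(ref_xy)
    tgt = _as_points(tgt_xy)
    if ref.shape[0] == 0:
        raise ValueError("no reference cells")
    ref_tree = cKDTree(ref)
    n_ref_pooled = int(ref_tree.count_neighbors(ref_tree, radius))  # incl. centers
    n_tgt_pooled = (
        int(ref_tree.count_neighbors(cKDTree(tgt), radius)) if tgt.shape[0] else 0
    )
    p = n_ref_pooled / (n_ref_pooled + n_tgt_pooled)
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * math.log2(q)
    return h


def entropy_curve(ref_xy, tgt_xy, radii: Sequence[float] = DEFAULT_RADII) -> pd.DataFrame:
    rows = [
        {"radius": float(r), "value": aggregated_entropy(ref_xy, tgt_xy, r)}
        for r in radii
    ]
    return pd.DataFrame(rows)


def classify_pattern(slope: float, eps: float = FLAT_EPS) -> str:
    if math.isnan(slope):
        return "undefined"
    if slope < -eps:
        return "attraction"
    if slope > eps:
        return "repulsion"
    return "flat"


def entropy_gradient(
    ref_xy,
    tgt_xy,
    radii: Sequence[float] = DEFAULT_RADII,
    eps: float = FLAT_EPS,
) -> tuple[pd.DataFrame, float, str]:
    """Entropy curve plus the slope over the two smallest radii and the
    attraction/repulsion/flat pattern label."""
    radii = [float(r) for r in radii]
    if len(radii) < 2:
        raise ValueError("radius ladder must have at least two radii")
    curve = entropy_curve(ref_xy, tgt_xy, radii)
    h1, h2 = curve["value"].iloc[0], curve["value"].iloc[1]
    slope = (
        (h2 - h1) / (radii[1] - radii[0])
        if not (math.isnan(h1) or math.isnan(h2))
        else math.nan
    )
    return curve, slope, classify_pattern(slope, eps)


def stitch_cores(
    extents: Mapping[str, tuple[float, float]], max_radius: float
) -> dict[str, tuple[float, float]]:
    """Offsets placing cores on a grid with boundary gaps > ``max_radius``.

    Guarantees no cross-core pair of cells can fall within any ladder
    radius, so statistics on the stitched frame decompose into per-core
    sums. Returns core_id -> (dx, dy) in um.
    """
    ids = list(extents)
    if not ids:
        raise ValueError("no cores to stitch")
    max_w = max(extents[c][0] for c in ids)
    max_h = max(extents[c][1] for c in ids)
    pitch_x = max_w + max_radius + 1.0
    pitch_y = max_h + max_radius + 1.0
    ncol = int(math.ceil(math.sqrt(len(ids))))
    return {
        cid: ((i % ncol) * pitch_x, (i // ncol) * pitch_y)
        for i, cid in enumerate(ids)
    }


def stitch_patient_cells(cells: pd.DataFrame, max_radius: float) -> pd.DataFrame:
    """Apply :func:`stitch_cores` to one patient's cell table, returning
    a copy with stitched coordinates."""
    extents = {
        str(core): (float(grp["x_um"].max()), float(grp["y_um"].max()))
        for core, grp in cells.groupby("core_id")
    }
    offsets = stitch_cores(extents, max_radius)
    out = cells.copy()
    out["x_um"] = [
        x + offsets[c][0] for x, c in zip(cells["x_um"], cells["core_id"].astype(str))
    ]
    out["y_um"] = [
        y + offsets[c][1] for y, c in zip(cells["y_um"], cells["core_id"].astype(str))
    ]
    return out


def patient_spatial_analysis(
    cells: pd.DataFrame,
    reference_classes: Sequence[str] = ("immune",) + tuple(IMMUNE_CLASSES),
    target_class: str = "tumor",
    radii: Sequence[float] = DEFAULT_RADII,
    eps: float = FLAT_EPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NMS and entropy curves plus pattern labels per patient and
    reference class.

    The pseudo-class ``"immune"`` pools the four immune subtypes as the
    reference population. Patients with fewer than two reference cells
    or no target cell yield NaN curves and an ``undefined`` pattern.
    Multi-core patients are stitched before analysis.
    """
    radii = [float(r) for r in radii]
    curve_rows: list[pd.DataFrame] = []
    pattern_rows = []
    for patient_id, grp in cells.groupby("patient_id", sort=True):
        stitched = stitch_patient_cells(grp, max(radii))
        tgt = stitched.loc[stitched["cell_class"] == target_class, ["x_um", "y_um"]].to_numpy()
        for ref_class in reference_classes:
            if ref_class == "immune":
                mask = stitched["cell_class"].isin(IMMUNE_CLASSES)
            else:
                mask = stitched["cell_class"] == ref_class
            ref = stitched.loc[mask, ["x_um", "y_um"]].to_numpy()
            if ref.shape[0] < 2 or tgt.shape[0] < 1:
                nan_curve = pd.DataFrame(
                    {"radius": radii, "value": [math.nan] * len(radii)}
                )
                for metric, cv in (("nms", nan_curve), ("entropy", nan_curve)):
                    curve_rows.append(
                        cv.assign(
                            patient_id=patient_id,
                            reference_class=ref_class,
                            metric=metric,
                        )
                    )
                pattern_rows.append(
                    {
                        "patient_id": patient_id,
                        "reference_class": ref_class,
                        "slope": math.nan,
                        "pattern": "undefined",
                    }
                )
                continue
            ncv = nms_curve(ref, tgt, radii)
            ecv, slope, pattern = entropy_gradient(ref, tgt, radii, eps)
            curve_rows.append(
                ncv.assign(patient_id=patient_id, reference_class=ref_class, metric="nms")
            )
            curve_rows.append(
                ecv.assign(
                    patient_id=patient_id, reference_class=ref_class, metric="entropy"
                )
            )
            pattern_rows.append(
                {
                    "patient_id": patient_id,
                    "reference_class": ref_class,
                    "slope": slope,
                    "pattern": pattern,
                }
            )
    curves = pd.concat(curve_rows, ignore_index=True)[
        ["patient_id", "reference_class", "metric", "radius", "value"]
    ]
    patterns = pd.DataFrame(pattern_rows)
    return curves, patterns
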