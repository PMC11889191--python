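"""Marker cutoff determination and cell classification.

Cutoffs: an annotation-guided rule for most markers (minimum annotated
positive intensity, replaced by an ECDF kneepoint when one is prominent,
which demotes low-level outliers to negative) and Otsu's method for
cytokeratin, whose pooled intensity distribution is bimodal.

Classification: positive/negative marker calls in each marker's
designated cellular region, then an ordered rule table mapping call
vectors to a single immune subtype, with PD-1/PD-L1 co-expression flags
attached independently of the class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MARKER_REGIONS, MARKERS

KNEE_THRESHOLD = 0.1  # normalized perpendicular distance declaring a kneepoint
OTSU_BINS = 256


def normalize_intensity(raw_photons: float, exposure_time: float) -> float:
    """Photon count normalized to exposure time."""
    if exposure_time <= 0:
        raise ValueError("exposure_time must be positive")
    if raw_photons < 0:
        raise ValueError("raw_photons must be nonnegative")
    return raw_photons / exposure_time


def ecdf_cutoff(
    positives: Sequence[float],
    background: Sequence[float] | None = None,
    knee_threshold: float = KNEE_THRESHOLD,
    detect_knee: bool = True,
) -> tuple[float, dict]:
    """Annotation-guided cutoff from the ECDF of annotated positive cells.

    If the positive ECDF rises without a prominent kneepoint, the cutoff
    is the minimal annotated positive intensity. A prominent kneepoint
    moves the cutoff to the knee, so isolated low-level outliers below it
    count as negative. The knee score is the maximum perpendicular
    distance of the normalized ECDF *below* the chord joining its
    endpoints: a delayed rise (convex start) marks outliers separated
    from the main mass, whereas an ordinary right-skewed positive
    distribution bends above the chord and is left alone.

    Returns ``(cutoff, diagnostics)``; diagnostics carry the ECDF, the
    knee score, the method used, and the fraction of background
    (all-negative annotated) intensities at or above the cutoff.
    """
    x = np.sort(np.asarray(positives, dtype=float))
    if x.size == 0:
        raise ValueError("no annotated positive intensities")
    n = x.size
    v = np.arange(1, n + 1) / n
    knee_score = 0.0
    knee_index = 0
    method = "ecdf_min"
    cutoff = float(x[0])
    if detect_knee and n >= 3 and x[-1] > x[0]:
        u = (x - x[0]) / (x[-1] - x[0])
        # signed perpendicular distance from chord (u0,v0)-(u_{n-1},v_{n-1});
        # positive = ECDF below the chord (delayed rise)
        du, dv = u[-1] - u[0], v[-1] - v[0]
        norm = float(np.hypot(du, dv))
        dist = (dv * (u - u[0]) - du * (v - v[0])) / norm
        knee_index = int(np.argmax(dist))
        knee_score = float(dist[knee_index])
        if knee_score > knee_threshold:
            cutoff = float(x[knee_index])
            method = "kneepoint"
    diagnostics = {
        "ecdf_x": x,
        "ecdf_y": v,
        "knee_score": knee_score,
        "knee_index": knee_index,
        "method": method,
        "background_exceed_frac": (
            float(np.mean(np.asarray(background, float) >= cutoff))
            if background is not None and len(background) > 0
            else np.nan
        ),
    }
    return cutoff, diagnostics


def otsu_cutoff(intensities: Sequence[float], n_bins: int = OTSU_BINS) -> float:
    """Otsu threshold: minimize the weighted intra-class variance.

    Candidate thresholds are the interior edges of ``n_bins`` equal-width
    bins spanning the data range; variances are computed exactly on the
    raw values via prefix sums. Ties break toward the smaller cutoff.
    Cells with intensity >= cutoff are called positive.
    """
    x = np.sort(np.asarray(intensities, dtype=float))
    if x.size < 2:
        raise ValueError("need at least two intensities")
    if x[0] == x[-1]:
        raise ValueError("all intensities identical; no threshold exists")
    edges = np.linspace(x[0], x[-1], n_bins + 1)[1:-1]
    k = np.searchsorted(x, edges, side="left")  # size of the left (< t) group
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    n = x.size
    sum_l, sum_r = cs[k], cs[n] - cs[k]
    ss_l, ss_r = cs2[k], cs2[n] - cs2[k]
    with np.errstate(divide="ignore", invalid="ignore"):
        within = np.where(k > 0, ss_l - sum_l**2 / np.maximum(k, 1), 0.0) + np.where(
            k < n, ss_r - sum_r**2 / np.maximum(n - k, 1), 0.0
        )
    return float(edges[int(np.argmin(within))])  # argmin takes the first tie


def make_cutoff_table(rows: Iterable[tuple[str, str, str, float]]) -> pd.DataFrame:
    """Assemble a cutoff table: (marker, region, method, cutoff)."""
    df = pd.DataFrame(rows, columns=["marker", "region", "method", "cutoff"])
    if (df["cutoff"] < 0).any():
        raise ValueError("cutoffs must be nonnegative")
    if df["marker"].duplicated().any():
        raise ValueError("one cutoff per marker")
    return df


def determine_cutoffs(
    cells: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    markers: Sequence[str] = MARKERS,
) -> pd.DataFrame:
    """Derive the full cutoff table for a cohort.

    CK uses Otsu on the pooled cytoplasmic intensity of all cells (its
    distribution is bimodal: non-CK vs CK+ populations). Every other
    marker uses the annotation-guided ECDF rule; without annotations it
    falls back to Otsu on the pooled designated-region intensity.
    """
    rows = []
    neg_pool = None
    if annotations is not None:
        neg_pool = annotations[annotations["annotation"] == "negative_all"]
    for marker in markers:
        region = MARKER_REGIONS[marker]
        col = f"{marker}_{region}"
        if col not in cells.columns:
            raise KeyError(f"missing intensity column {col!r}")
        if marker == "CK" or annotations is None:
            rows.append((marker, region, "otsu", otsu_cutoff(cells[col].to_numpy())))
            continue
        pos = annotations.query("marker == @marker and annotation == 'positive'")[
            "intensity"
        ].to_numpy()
        if pos.size == 0:
            rows.append((marker, region, "otsu", otsu_cutoff(cells[col].to_numpy())))
            continue
        bg = (
            neg_pool.query("marker == @marker")["intensity"].to_numpy()
            if neg_pool is not None
            else None
        )
        cutoff, diag = ecdf_cutoff(pos, background=bg)
        rows.append((marker, region, diag["method"], cutoff))
    return make_cutoff_table(rows)


def apply_cutoffs(cells: pd.DataFrame, cutoffs: pd.DataFrame) -> pd.DataFrame:
    """Positive/negative call per cell x marker (inclusive >= cutoff)."""
    calls = pd.DataFrame(index=cells.index)
    for row in cutoffs.itertuples(index=False):
        col = f"{row.marker}_{row.region}"
        if col not in cells.columns:
            raise KeyError(f"missing intensity column {col!r} for marker {row.marker!r}")
        calls[row.marker] = cells[col].to_numpy() >= row.cutoff
    return calls


@dataclass(frozen=True)
class Rule:
    """One classification rule: all ``all_of`` positive, all ``none_of``
    negative. Rules are evaluated in priority order; first match wins."""

    label: str
    all_of: tuple[str, ...] = ()
    none_of: tuple[str, ...] = ()


#: Lineage-dominance rule order: epithelial CK first, then the myeloid
#: marker CD68, then FoxP3 (so CD4+FoxP3+ cells are regulatory T cells),
#: then CD8, then CD4; anything else is "other".
DEFAULT_RULES: tuple[Rule, ...] = (
    Rule("tumor", all_of=("CK",)),
    Rule("macrophage", all_of=("CD68",), none_of=("CK",)),
    Rule("t_regulatory", all_of=("FoxP3",), none_of=("CK", "CD68")),
    Rule("cytotoxic_t", all_of=("CD8",), none_of=("CK", "CD68", "FoxP3")),
    Rule("t_helper", all_of=("CD4",), none_of=("CK", "CD68", "FoxP3", "CD8")),
)

FALLBACK_CLASS = "other"


def rules_from_config(spec: Sequence[Mapping]) -> tuple[Rule, ...]:
    """Build a rule table from a config list of mappings with keys
    ``label``, ``all_of``, ``none_of``."""
    return tuple(
        Rule(
            label=r["label"],
            all_of=tuple(r.get("all_of", ())),
            none_of=tuple(r.get("none_of", ())),
        )
        for r in spec
    )


def classify_cells(
    calls: pd.DataFrame,
    rules: Sequence[Rule] = DEFAULT_RULES,
    pd1_marker: str = "PD1",
    pdl1_marker: str = "PDL1",
) -> pd.DataFrame:
    """Assign each cell exactly one class plus checkpoint flags.

    Returns a frame aligned to ``calls`` with columns ``cell_class``,
    ``pd1_pos``, ``pdl1_pos``. Cells matching no rule become
    ``"other"``; the checkpoint flags are independent of the class.
    """
    n = len(calls)
    label = np.full(n, FALLBACK_CLASS, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in rules:
        match = unassigned.copy()
        for m in rule.all_of:
            match &= calls[m].to_numpy(bool)
        for m in rule.none_of:
            match &= ~calls[m].to_numpy(bool)
        label[match] = rule.label
        unassigned &= ~match
    out = pd.DataFrame(index=calls.index)
    out["cell_class"] = label
    out["pd1_pos"] = (
        calls[pd1_marker].to_numpy(bool) if pd1_marker in calls else False
    )
    out["pdl1_pos"] = (
        calls[pdl1_marker].to_numpy(bool) if pdl1_marker in calls else False
    )
    return out


def phenotype_cells(
    cells: pd.DataFrame,
    cutoffs: pd.DataFrame,
    rules: Sequence[Rule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Cutoffs -> calls -> classes, returning the cell table with
    ``cell_class``/``pd1_pos``/``pdl1_pos`` appended."""
    calls = apply_cutoffs(cells, cutoffs)
    classified = classify_cells(calls, rules)
    return pd.concat([cells.reset_index(drop=True), classified.reset_index(drop=True)], axis=1)
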