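"""Digital tumor-infiltrating-lymphocyte (dTIL) metrics.

Five scores are derived from H&E cell-classifier annotations
(lymphocyte / tumor / fibroblast / "other" counts and areas):

- eTILs (%)   = 100 * TILs / (tumor cells + TILs)
- etTILs (%)  = 100 * TILs / all detected cells
- esTILs (%)  = 100 * TILs / stromal cells (TILs + fibroblasts + other)
- eaTILs      = TILs / analyzed tumor-region area (cells per mm^2)
- easTILs (%) = 100 * TILs area / stroma area, capped at 100

Intratumoral TILs are included throughout. A zero denominator yields a
missing value (NaN), never zero, so callers can decide exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

METRIC_NAMES = ("etils_pct", "ettils_pct", "estils_pct", "eatils_per_mm2", "eastils_pct")


@dataclass(frozen=True)
class DTILsInput:
    """Per-sample classifier annotations: counts and areas."""

    n_tils: float
    n_tumor: float
    n_fibro: float
    n_other: float
    tils_area_mm2: float
    stroma_area_mm2: float
    tumor_region_area_mm2: float

    def __post_init__(self) -> None:
        for name in (
            "n_tils",
            "n_tumor",
            "n_fibro",
            "n_other",
            "tils_area_mm2",
            "stroma_area_mm2",
            "tumor_region_area_mm2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class DTILsMetrics:
    etils_pct: float
    ettils_pct: float
    estils_pct: float
    eatils_per_mm2: float
    eastils_pct: float
    eastils_uncapped_pct: float  # diagnostic: easTILs before the 100% cap

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_dtils(inp: DTILsInput, ettils_includes_tils: bool = True) -> DTILsMetrics:
    """Compute the five dTIL metrics for one sample.

    ``ettils_includes_tils`` selects the reading of the etTILs
    denominator ("all detected cells"): with TILs included (default) or
    restricted to tumor + fibroblast + other cells.
    """
    t = inp.n_tils
    all_cells = t + inp.n_tumor + inp.n_fibro + inp.n_other
    if not ettils_includes_tils:
        all_cells = inp.n_tumor + inp.n_fibro + inp.n_other
    eas_raw = 100.0 * _ratio(inp.tils_area_mm2, inp.stroma_area_mm2)
    return DTILsMetrics(
        etils_pct=100.0 * _ratio(t, t + inp.n_tumor),
        ettils_pct=100.0 * _ratio(t, all_cells),
        estils_pct=100.0 * _ratio(t, t + inp.n_fibro + inp.n_other),
        eatils_per_mm2=_ratio(t, inp.tumor_region_area_mm2),
        eastils_pct=min(eas_raw, 100.0) if not math.isnan(eas_raw) else eas_raw,
        eastils_uncapped_pct=eas_raw,
    )


def merge_inputs(inputs: Iterable[DTILsInput]) -> DTILsInput:
    """Pool multiple cores of one patient by summing counts and areas."""
    inputs = list(inputs)
    if not inputs:
        raise ValueError("no inputs to merge")
    return DTILsInput(
        n_tils=sum(i.n_tils for i in inputs),
        n_tumor=sum(i.n_tumor for i in inputs),
        n_fibro=sum(i.n_fibro for i in inputs),
        n_other=sum(i.n_other for i in inputs),
        tils_area_mm2=sum(i.tils_area_mm2 for i in inputs),
        stroma_area_mm2=sum(i.stroma_area_mm2 for i in inputs),
        tumor_region_area_mm2=sum(i.tumor_region_area_mm2 for i in inputs),
    )


def dtils_from_annotations(
    annotations: pd.DataFrame, ettils_includes_tils: bool = True
) -> pd.DataFrame:
    """Per-patient dTILs from a per-core annotation table.

    Cores of the same patient are merged by summing counts and areas
    before the ratios are taken.
    """
    required = {
        "patient_id",
        "n_tils",
        "n_tumor",
        "n_fibro",
        "n_other",
        "tils_area_mm2",
        "stroma_area_mm2",
        "tumor_region_area_mm2",
    }
    missing = required - set(annotations.columns)
    if missing:
        raise KeyError(f"annotation table missing columns: {sorted(missing)}")
    rows = []
    for patient_id, grp in annotations.groupby("patient_id", sort=True):
        merged = merge_inputs(
            DTILsInput(
                n_tils=r.n_tils,
                n_tumor=r.n_tumor,
                n_fibro=r.n_fibro,
                n_other=r.n_other,
                tils_area_mm2=r.tils_area_mm2,
                stroma_area_mm2=r.stroma_area_mm2,
                tumor_region_area_mm2=r.tumor_region_area_mm2,
            )
            for r in grp.itertuples(index=False)
        )
        m = compute_dtils(merged, ettils_includes_tils=ettils_includes_tils)
        rows.append({"patient_id": patient_id, **m.as_dict(), "eastils_uncapped_pct": m.eastils_uncapped_pct})
    return pd.DataFrame(rows)


def summarize_dtils(
    metrics: pd.DataFrame, clinical: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Cohort summary: median/range per metric (optionally per subtype)
    and the pairwise Spearman correlation matrix among the five metrics."""
    if len(metrics) == 0:
        raise ValueError("no samples to summarize")
    present = [m for m in METRIC_NAMES if m in metrics.columns]
    rows = []
    for m in present:
        v = metrics[m].dropna()
        rows.append(
            {
                "metric": m,
                "n": len(v),
                "median": v.median(),
                "min": v.min(),
                "max": v.max(),
                "subtype": "all",
            }
        )
    if clinical is not None and "subtype" in clinical.columns:
        merged = metrics.merge(clinical[["patient_id", "subtype"]], on="patient_id")
        for (sub,), grp in merged.groupby(["subtype"], sort=True):
            for m in present:
                v = grp[m].dropna()
                if len(v) == 0:
                    continue
                rows.append(
                    {
                        "metric": m,
                        "n": len(v),
                        "median": v.median(),
                        "min": v.min(),
                        "max": v.max(),
                        "subtype": sub,
                    }
                )
    summary = pd.DataFrame(rows)

    k = len(present)
    rho = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            pair = metrics[[present[i], present[j]]].dropna()
            if i == j:
                rho[i, j] = 1.0
            elif len(pair) >= 3:
                r = spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
                rho[i, j] = r
    corr = pd.DataFrame(rho, index=present, columns=present)
    return {"summary": summary, "spearman": corr}
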