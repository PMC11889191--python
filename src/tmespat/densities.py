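"""Per-patient, per-class, per-compartment cell densities.

Multiple TMA cores of one patient are merged by pooling counts and
pooling compartment areas (never by averaging per-core densities), and
the pooled count is divided by the pooled area — matching how cell
abundance is normalized to total tissue area. A patient whose cores have
zero area in a compartment gets a missing density there. Densities are
log2-transformed with a pseudocount for display.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

COMPARTMENTS = ("total", "tumor", "stroma")
ALL_CLASS = "all"

#: Checkpoint-flagged subclasses are emitted alongside (overlapping with)
#: their parent class, e.g. ``cytotoxic_t/pd1_pos``.
CHECKPOINT_FLAGS = (("pd1_pos", "pd1_pos"), ("pdl1_pos", "pdl1_pos"))


def log2_density(density: float, pseudocount: float = 1.0):
    """log2(density + pseudocount); default pseudocount 1 cell/mm^2."""
    d = np.asarray(density, dtype=float)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("density must be nonnegative")
    out = np.log2(d + pseudocount)
    return float(out) if np.isscalar(density) else out


def compute_densities(
    cells: pd.DataFrame,
    areas: pd.DataFrame,
    pseudocount: float = 1.0,
    include_checkpoint_subclasses: bool = True,
) -> pd.DataFrame:
    """Long-format density table.

    Parameters
    ----------
    cells:
        Classified cell table with ``patient_id``, ``core_id``,
        ``compartment`` and ``cell_class`` (plus optional ``pd1_pos`` /
        ``pdl1_pos`` flags).
    areas:
        Per-core compartment areas (``core_id``, ``tumor_area_mm2``,
        ``stroma_area_mm2``, ``total_area_mm2``), optionally with
        ``patient_id`` for cores that contributed no cells.

    Returns one row per (patient, class, compartment) with the pooled
    count, pooled area, density and its log2 transform. Classes include
    every observed class, the ``all``-cells aggregate and, optionally,
    checkpoint-flagged subclasses.
    """
    missing_cores = set(cells["core_id"]) - set(areas["core_id"])
    if missing_cores:
        raise ValueError(f"cores without an area row: {sorted(missing_cores)}")

    core_to_patient = dict(zip(cells["core_id"], cells["patient_id"]))
    if "patient_id" in areas.columns:
        core_to_patient.update(zip(areas["core_id"], areas["patient_id"]))
    areas = areas.assign(_patient=[core_to_patient[c] for c in areas["core_id"]])
    pooled_areas = areas.groupby("_patient")[
        ["tumor_area_mm2", "stroma_area_mm2", "total_area_mm2"]
    ].sum()

    classes = sorted(set(cells["cell_class"]))
    variants: list[tuple[str, pd.DataFrame]] = [(ALL_CLASS, cells)]
    variants += [(c, cells[cells["cell_class"] == c]) for c in classes]
    if include_checkpoint_subclasses:
        for flag_col, suffix in CHECKPOINT_FLAGS:
            if flag_col not in cells.columns:
                continue
            flagged = cells[cells[flag_col].astype(bool)]
            for c in classes:
                variants.append((f"{c}/{suffix}", flagged[flagged["cell_class"] == c]))

    rows = []
    for patient_id, parea in pooled_areas.iterrows():
        areas_by_comp = {
            "total": float(parea["total_area_mm2"]),
            "tumor": float(parea["tumor_area_mm2"]),
            "stroma": float(parea["stroma_area_mm2"]),
        }
        for cls, sub in variants:
            psub = sub[sub["patient_id"] == patient_id]
            counts = {
                "total": len(psub),
                "tumor": int((psub["compartment"] == "tumor").sum()),
                "stroma": int((psub["compartment"] == "stroma").sum()),
            }
            for comp in COMPARTMENTS:
                area = areas_by_comp[comp]
                density = counts[comp] / area if area > 0 else math.nan
                rows.append(
                    {
                        "patient_id": patient_id,
                        "cell_class": cls,
                        "compartment": comp,
                        "n_cells": counts[comp],
                        "area_mm2": area,
                        "density_per_mm2": density,
                        "log2_density": (
                            log2_density(density, pseudocount)
                            if not math.isnan(density)
                            else math.nan
                        ),
                    }
                )
    return pd.DataFrame(rows)
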