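"""Synthetic tissue-microarray generator.

Emulates the post-segmentation data a multiplex-immunofluorescence
workflow produces: per-cell coordinate tables on small TMA cores with a
tumor/stroma compartment geometry, class-conditional marker intensities,
per-core compartment areas, and per-patient clinical labels. Tumor cells
occupy blob-shaped tumor nests; immune cells are placed by thinning a
homogeneous Poisson candidate process so that the immune intensity either
increases toward tumor cells (attraction), is independent of them (CSR),
or is suppressed near them (repulsion).

All randomness flows from ``SimConfig.seed`` through one
``numpy.random.Generator``; repeated runs are bit-reproducible.

Ground-truth class labels are kept out of the analysis tables: writers
put them in a separate ``truth.csv``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import (
    CLASS_POSITIVE_MARKERS,
    IMMUNE_CLASSES,
    MARKER_REGIONS,
    MARKERS,
    REGIONS,
    SimConfig,
)

GRID_UM = 1.0  # rasterization step for area bookkeeping, um
#: Nominal lymphocyte footprint used for the TILs-area summaries, mm^2.
LYMPHOCYTE_AREA_MM2 = 35e-6

TRUTH_COLUMNS = ("true_class", "pd1_true", "pdl1_true")


@dataclass
class CoreGeometry:
    """Rasterized core: boolean masks on a 1 um grid plus exact areas."""

    core_mask: np.ndarray
    tumor_mask: np.ndarray
    width_um: float
    height_um: float

    @property
    def tumor_area_mm2(self) -> float:
        return float(self.tumor_mask.sum()) * (GRID_UM**2) * 1e-6

    @property
    def stroma_area_mm2(self) -> float:
        return float((self.core_mask & ~self.tumor_mask).sum()) * (GRID_UM**2) * 1e-6


def _make_geometry(config: SimConfig, rng: np.random.Generator) -> CoreGeometry:
    """Rasterize the core outline and carve blob-shaped tumor nests.

    The tumor region is the upper level set of a sum of random Gaussian
    bumps, thresholded at the quantile that puts exactly
    ``tumor_fraction`` of core pixels inside — the fraction is exact by
    construction while the geometry stays nest-like.
    """
    w_um, h_um = config.core_shape.extent_um
    nx, ny = int(round(w_um / GRID_UM)), int(round(h_um / GRID_UM))
    # pixel-center coordinates
    xs = (np.arange(nx) + 0.5) * GRID_UM
    ys = (np.arange(ny) + 0.5) * GRID_UM
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    if config.core_shape.kind == "disc":
        r = w_um / 2.0
        core_mask = (X - r) ** 2 + (Y - r) ** 2 <= r**2
    else:
        core_mask = np.ones((nx, ny), dtype=bool)

    n_bumps = config.n_blobs
    lo, hi = config.blob_sigma_um
    cx = rng.uniform(0, w_um, n_bumps)
    cy = rng.uniform(0, h_um, n_bumps)
    sigma = rng.uniform(lo, hi, n_bumps)
    amp = rng.uniform(0.5, 1.0, n_bumps)
    field = np.zeros((nx, ny))
    for i in range(n_bumps):
        # each bump only touches its 4-sigma neighborhood
        r4 = 4.0 * sigma[i]
        x0, x1 = np.searchsorted(xs, [cx[i] - r4, cx[i] + r4])
        y0, y1 = np.searchsorted(ys, [cy[i] - r4, cy[i] + r4])
        if x0 >= x1 or y0 >= y1:
            continue
        field[x0:x1, y0:y1] += amp[i] * np.exp(
            -(
                (X[x0:x1, y0:y1] - cx[i]) ** 2
                + (Y[x0:x1, y0:y1] - cy[i]) ** 2
            )
            / (2.0 * sigma[i] ** 2)
        )
    thresh = np.quantile(field[core_mask], 1.0 - config.tumor_fraction)
    tumor_mask = core_mask & (field >= thresh)
    return CoreGeometry(core_mask, tumor_mask, w_um, h_um)


def _sample_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions inside a pixel mask: pick pixels, jitter within."""
    idx = np.flatnonzero(mask)
    if idx.size == 0 or n == 0:
        return np.empty((0, 2))
    chosen = rng.choice(idx, size=n, replace=True)
    ix, iy = np.unravel_index(chosen, mask.shape)
    x = (ix + rng.uniform(0, 1, n)) * GRID_UM
    y = (iy + rng.uniform(0, 1, n)) * GRID_UM
    return np.column_stack([x, y])


def _acceptance(regime: str, d: np.ndarray, tau: float) -> np.ndarray:
    if regime == "csr" or tau == 0:
        return np.ones_like(d)
    if regime == "attraction":
        return np.exp(-d / tau)
    if regime == "repulsion":
        return 1.0 - np.exp(-d / tau)
    raise ValueError(f"unknown mixing regime {regime!r}")


def _place_class(
    geom: CoreGeometry,
    density: float,
    regime: str,
    tau: float,
    tumor_xy: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place one non-tumor cell class by thinning a Poisson candidate set.

    The candidate rate is inflated by the mean acceptance probability
    (estimated on probe points) so the realized density matches the
    configured one in expectation.
    """
    total_area = geom.tumor_area_mm2 + geom.stroma_area_mm2
    if density <= 0 or total_area <= 0:
        return np.empty((0, 2))
    if regime == "csr" or tumor_xy.shape[0] == 0:
        n = rng.poisson(density * total_area)
        return _sample_in_mask(geom.core_mask, n, rng)
    tree = cKDTree(tumor_xy)
    probes = _sample_in_mask(geom.core_mask, 2000, rng)
    d_probe, _ = tree.query(probes, k=1)
    p_bar = float(np.mean(_acceptance(regime, d_probe, tau)))
    p_bar = max(p_bar, 1e-4)
    n_cand = rng.poisson(density * total_area / p_bar)
    cand = _sample_in_mask(geom.core_mask, n_cand, rng)
    if cand.shape[0] == 0:
        return cand
    d, _ = tree.query(cand, k=1)
    keep = rng.uniform(0, 1, cand.shape[0]) < _acceptance(regime, d, tau)
    return cand[keep]


def generate_cores(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate cells, per-core compartment areas, and clinical labels.

    Returns ``(cells, areas, clinical)``. The cell table carries the
    ground-truth columns ``true_class``/``pd1_true``/``pdl1_true``; file
    writers split these into a separate truth table so the analysis input
    never contains them.
    """
    rng = np.random.default_rng(config.seed)
    cell_rows: list[pd.DataFrame] = []
    area_rows = []
    clin_rows = []
    subtypes = list(config.subtype_probs)
    subtype_p = np.array([config.subtype_probs[s] for s in subtypes], float)
    subtype_p /= subtype_p.sum()
    tp53s = list(config.tp53_probs)
    tp53_p = np.array([config.tp53_probs[s] for s in tp53s], float)
    tp53_p /= tp53_p.sum()

    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        clin_rows.append(
            {
                "patient_id": patient_id,
                "pcr": int(rng.uniform() < 0.3),
                "subtype": subtypes[rng.choice(len(subtypes), p=subtype_p)],
                "tp53": tp53s[rng.choice(len(tp53s), p=tp53_p)],
            }
        )
        for c in range(config.cores_per_patient):
            core_id = f"{patient_id}-C{c}"
            geom = _make_geometry(config, rng)
            densities = config.cell_density_per_class
            n_tumor = rng.poisson(densities.get("tumor", 0.0) * geom.tumor_area_mm2)
            tumor_xy = _sample_in_mask(geom.tumor_mask, n_tumor, rng)
            placed: dict[str, np.ndarray] = {"tumor": tumor_xy}
            for cls in densities:
                if cls == "tumor":
                    continue
                regime = config.mixing_regime if cls in IMMUNE_CLASSES else "csr"
                placed[cls] = _place_class(
                    geom, densities[cls], regime, config.mixing_strength, tumor_xy, rng
                )
            xy = np.vstack([placed[c_] for c_ in placed])
            labels = np.concatenate(
                [np.full(placed[c_].shape[0], c_, dtype=object) for c_ in placed]
            )
            ix = np.clip((xy[:, 0] / GRID_UM).astype(int), 0, geom.tumor_mask.shape[0] - 1)
            iy = np.clip((xy[:, 1] / GRID_UM).astype(int), 0, geom.tumor_mask.shape[1] - 1)
            compartment = np.where(geom.tumor_mask[ix, iy], "tumor", "stroma")
            n = xy.shape[0]
            pd1 = np.array(
                [rng.uniform() < config.pd1_rates.get(c_, 0.0) for c_ in labels], bool
            )
            pdl1 = np.array(
                [rng.uniform() < config.pdl1_rates.get(c_, 0.0) for c_ in labels], bool
            )
            cell_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": [f"{core_id}-{i:05d}" for i in range(n)],
                        "patient_id": patient_id,
                        "core_id": core_id,
                        "x_um": xy[:, 0],
                        "y_um": xy[:, 1],
                        "compartment": compartment,
                        "true_class": labels.astype(str),
                        "pd1_true": pd1,
                        "pdl1_true": pdl1,
                    }
                )
            )
            tumor_area = geom.tumor_area_mm2
            stroma_area = geom.stroma_area_mm2
            area_rows.append(
                {
                    "core_id": core_id,
                    "patient_id": patient_id,
                    "tumor_area_mm2": tumor_area,
                    "stroma_area_mm2": stroma_area,
                    "total_area_mm2": tumor_area + stroma_area,
                }
            )

    cells = pd.concat(cell_rows, ignore_index=True)
    areas = pd.DataFrame(area_rows)
    clinical = pd.DataFrame(clin_rows)
    return cells, areas, clinical


def generate_intensities(cells: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Fill per-marker, per-region intensity columns ``<marker>_<region>``.

    A cell draws from a marker's positive log-normal component only in
    that marker's designated region and only when its true class (or
    checkpoint flag) expresses the marker; every other draw comes from
    the negative component.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = cells.copy()
    n = len(out)
    classes = out["true_class"].to_numpy()
    for marker in MARKERS:
        model = config.marker_models.get(marker)
        if model is None:
            raise KeyError(f"no intensity model for marker {marker!r}")
        if marker == "PD1":
            positive = out["pd1_true"].to_numpy(bool)
        elif marker == "PDL1":
            positive = out["pdl1_true"].to_numpy(bool)
        else:
            positive = np.array(
                [marker in CLASS_POSITIVE_MARKERS.get(c, frozenset()) for c in classes]
            )
        designated = MARKER_REGIONS[marker]
        for region in REGIONS:
            mean = np.full(n, model.neg_mean)
            sd = np.full(n, model.neg_sd)
            if region == designated:
                mean[positive] = model.pos_mean
                sd[positive] = model.pos_sd
            out[f"{marker}_{region}"] = np.exp(rng.normal(mean, sd))
    return out


def generate_outcomes(features: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw pCR labels from the logistic outcome model.

    ``features`` is a per-patient frame (index = patient_id) whose columns
    include every coefficient name in the outcome model. Features are
    standardized before entering the linear predictor.
    """
    model = config.outcome_model
    missing = [k for k in model.coefficients if k not in features.columns]
    if missing:
        raise KeyError(f"outcome model names absent from features: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    logit = np.full(len(features), float(model.intercept))
    for name, coef in model.coefficients.items():
        col = features[name].to_numpy(float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        logit += coef * z
    p = 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame(
        {"patient_id": features.index, "pcr": (rng.uniform(size=len(p)) < p).astype(int)}
    )


def split_truth(cells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the generator's ground-truth columns out of the cell table."""
    truth = cells[["cell_id", *TRUTH_COLUMNS]].copy()
    return cells.drop(columns=list(TRUTH_COLUMNS)), truth


def make_annotations(
    cells: pd.DataFrame,
    rng: np.random.Generator,
    n_pos: int = 100,
    n_neg: int = 200,
) -> pd.DataFrame:
    """Emulate manual phenotyping annotations.

    For each marker, sample intensities (in its designated region) from
    cells truly positive for it, plus one shared pool of cells negative
    for every marker. Long format: (marker, cell_id, intensity,
    annotation) with annotation in {positive, negative_all}.
    """
    rows = []
    classes = cells["true_class"].to_numpy()
    for marker in MARKERS:
        if marker == "PD1":
            mask = cells["pd1_true"].to_numpy(bool)
        elif marker == "PDL1":
            mask = cells["pdl1_true"].to_numpy(bool)
        else:
            mask = np.array(
                [marker in CLASS_POSITIVE_MARKERS.get(c, frozenset()) for c in classes]
            )
        col = f"{marker}_{MARKER_REGIONS[marker]}"
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        take = rng.choice(idx, size=min(n_pos, idx.size), replace=False)
        for i in take:
            rows.append(
                {
                    "marker": marker,
                    "cell_id": cells["cell_id"].iat[i],
                    "intensity": cells[col].iat[i],
                    "annotation": "positive",
                }
            )
    neg_mask = np.array(
        [
            len(CLASS_POSITIVE_MARKERS.get(c, frozenset())) == 0
            for c in classes
        ]
    )
    neg_mask &= ~cells["pd1_true"].to_numpy(bool) & ~cells["pdl1_true"].to_numpy(bool)
    neg_idx = np.flatnonzero(neg_mask)
    take = rng.choice(neg_idx, size=min(n_neg, neg_idx.size), replace=False)
    for marker in MARKERS:
        col = f"{marker}_{MARKER_REGIONS[marker]}"
        for i in take:
            rows.append(
                {
                    "marker": marker,
                    "cell_id": cells["cell_id"].iat[i],
                    "intensity": cells[col].iat[i],
                    "annotation": "negative_all",
                }
            )
    return pd.DataFrame(rows)


def make_cnn_annotations(cells: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Tabulate per-core H&E-classifier-style annotations for dTIL scoring.

    Maps the synthetic truth onto the four H&E classes: lymphocytes
    (T cells), tumor cells, fibroblasts (unclassified stromal-compartment
    cells) and "other" (macrophages plus unclassified cells inside tumor
    nests). TILs area uses a nominal lymphocyte footprint.
    """
    lymph = {"t_helper", "cytotoxic_t", "t_regulatory"}
    rows = []
    by_core = cells.groupby("core_id", sort=True)
    areas_ix = areas.set_index("core_id")
    for core_id, grp in by_core:
        cls = grp["true_class"]
        n_tils = int(cls.isin(lymph).sum())
        n_tumor = int((cls == "tumor").sum())
        n_fibro = int(((cls == "other") & (grp["compartment"] == "stroma")).sum())
        n_other = int(
            (cls == "macrophage").sum()
            + ((cls == "other") & (grp["compartment"] == "tumor")).sum()
        )
        arow = areas_ix.loc[core_id]
        rows.append(
            {
                "core_id": core_id,
                "patient_id": grp["patient_id"].iat[0],
                "n_tils": n_tils,
                "n_tumor": n_tumor,
                "n_fibro": n_fibro,
                "n_other": n_other,
                "tils_area_mm2": n_tils * LYMPHOCYTE_AREA_MM2,
                "stroma_area_mm2": float(arow["stroma_area_mm2"]),
                "tumor_region_area_mm2": float(arow["tumor_area_mm2"]),
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Run the full generator: cells with intensities, areas, clinical,
    truth, phenotyping annotations, and H&E-style per-core annotations."""
    cells, areas, clinical = generate_cores(config)
    cells = generate_intensities(cells, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    annotations = make_annotations(cells, rng)
    cnn = make_cnn_annotations(cells, areas)
    cells_out, truth = split_truth(cells)
    return {
        "cells": cells_out,
        "areas": areas,
        "clinical": clinical,
        "truth": truth,
        "annotations": annotations,
        "cnn_annotations": cnn,
    }
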