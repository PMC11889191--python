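"""Pipeline stages and the run manifest.

Every stage exchanges flat CSV files inside one output directory, so a
run of a clinical-adjacent analysis stays auditable: simulate ->
phenotype -> dtils / densities -> spatial -> report. Re-running with the
same config and seed reproduces byte-identical outputs; the manifest
records the seed, a hash of the resolved configuration, and the files
each stage wrote (never timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    compare_metric_by_group,
    correlation_matrix,
    pattern_test,
    summarize_nms_by_group,
)
from .config import SimConfig, parse_radii, sim_config_from_dict
from .densities import compute_densities
from .dtils import METRIC_NAMES, dtils_from_annotations
from .phenotyping import DEFAULT_RULES, determine_cutoffs, phenotype_cells, rules_from_config
from .spatial import DEFAULT_RADII, FLAT_EPS, patient_spatial_analysis
from .synthetic import simulate_cohort

FLOAT_FORMAT = "%.10g"

STAGES = ("simulate", "phenotype", "dtils", "densities", "spatial", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (parsed from YAML)."""

    sim: SimConfig = field(default_factory=SimConfig)
    radii: Sequence[float] = DEFAULT_RADII
    flat_eps: float = FLAT_EPS
    pseudocount: float = 1.0
    ettils_includes_tils: bool = True
    rules: Sequence = DEFAULT_RULES
    stages: Sequence[str] = STAGES

    @classmethod
    def from_dict(cls, d: Mapping, seed: int | None = None) -> "RunConfig":
        d = dict(d or {})
        sim = sim_config_from_dict(d.get("sim", {}))
        if seed is not None:
            sim = sim.with_(seed=int(seed))
        rules = (
            rules_from_config(d["rules"]) if d.get("rules") else DEFAULT_RULES
        )
        stages = tuple(d.get("stages", STAGES))
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return cls(
            sim=sim,
            radii=parse_radii(d.get("radii", list(DEFAULT_RADII))),
            flat_eps=float(d.get("flat_eps", FLAT_EPS)),
            pseudocount=float(d.get("pseudocount", 1.0)),
            ettils_includes_tils=bool(d.get("ettils_includes_tils", True)),
            rules=rules,
            stages=stages,
        )

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, seed=seed)

    def digest(self) -> str:
        """Stable hash of the resolved configuration."""
        blob = json.dumps(
            {
                "sim": repr(self.sim),
                "radii": list(self.radii),
                "flat_eps": self.flat_eps,
                "pseudocount": self.pseudocount,
                "ettils_includes_tils": self.ettils_includes_tils,
                "rules": [repr(r) for r in self.rules],
                "stages": list(self.stages),
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path.name


def _read(outdir: Path, name: str, stage: str) -> pd.DataFrame:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires {path} - run the upstream stage first"
        )
    return pd.read_csv(path)


def stage_simulate(cfg: RunConfig, outdir: Path) -> list[str]:
    tables = simulate_cohort(cfg.sim)
    return [
        _write(tables[name], outdir / f"{name}.csv")
        for name in ("cells", "areas", "clinical", "truth", "annotations", "cnn_annotations")
    ]


def stage_phenotype(cfg: RunConfig, outdir: Path) -> list[str]:
    cells = _read(outdir, "cells.csv", "phenotype")
    ann_path = outdir / "annotations.csv"
    annotations = pd.read_csv(ann_path) if ann_path.exists() else None
    cutoffs = determine_cutoffs(cells, annotations)
    classified = phenotype_cells(cells, cutoffs, cfg.rules)
    return [
        _write(cutoffs, outdir / "cutoffs.csv"),
        _write(classified, outdir / "classified_cells.csv"),
    ]


def stage_dtils(cfg: RunConfig, outdir: Path) -> list[str]:
    ann = _read(outdir, "cnn_annotations.csv", "dtils")
    table = dtils_from_annotations(ann, ettils_includes_tils=cfg.ettils_includes_tils)
    return [_write(table, outdir / "dtils.csv")]


def stage_densities(cfg: RunConfig, outdir: Path) -> list[str]:
    cells = _read(outdir, "classified_cells.csv", "densities")
    areas = _read(outdir, "areas.csv", "densities")
    dens = compute_densities(cells, areas, pseudocount=cfg.pseudocount)
    return [_write(dens, outdir / "densities.csv")]


def stage_spatial(cfg: RunConfig, outdir: Path) -> list[str]:
    cells = _read(outdir, "classified_cells.csv", "spatial")
    curves, patterns = patient_spatial_analysis(
        cells, radii=cfg.radii, eps=cfg.flat_eps
    )
    return [
        _write(curves, outdir / "spatial_curves.csv"),
        _write(patterns, outdir / "patterns.csv"),
    ]


def _comparison_rows(comp) -> list[dict]:
    rows = []
    for lab, n, med, iqr in zip(comp.groups, comp.n, comp.median, comp.iqr):
        rows.append(
            {
                "metric": comp.metric,
                "grouping": comp.grouping,
                "group": lab,
                "n": n,
                "median": med,
                "iqr": iqr,
                "test": comp.test,
                "statistic": comp.statistic,
                "p_value": comp.p_value,
            }
        )
    return rows


def stage_report(cfg: RunConfig, outdir: Path) -> list[str]:
    clinical = _read(outdir, "clinical.csv", "report")
    dtils = _read(outdir, "dtils.csv", "report")
    densities = _read(outdir, "densities.csv", "report")
    curves = _read(outdir, "spatial_curves.csv", "report")
    patterns = _read(outdir, "patterns.csv", "report")

    comp_rows: list[dict] = []
    merged = dtils.merge(clinical[["patient_id", "pcr"]], on="patient_id")
    for metric in METRIC_NAMES:
        vals, grp = merged[metric].to_numpy(float), merged["pcr"].to_numpy()
        if len(np.unique(grp[~np.isnan(vals)])) >= 2:
            comp_rows += _comparison_rows(
                compare_metric_by_group(vals, grp, metric=metric, grouping="pcr")
            )
    dens_merged = densities.merge(clinical[["patient_id", "pcr"]], on="patient_id")
    for (cls, comp_name), grp in dens_merged.groupby(["cell_class", "compartment"]):
        if "/" in cls:  # checkpoint subclasses stay out of the default report
            continue
        vals = grp["log2_density"].to_numpy(float)
        labels = grp["pcr"].to_numpy()
        if len(np.unique(labels[~np.isnan(vals)])) >= 2:
            comp_rows += _comparison_rows(
                compare_metric_by_group(
                    vals,
                    labels,
                    metric=f"log2_density[{cls},{comp_name}]",
                    grouping="pcr",
                )
            )
    comparisons = pd.DataFrame(comp_rows)

    pat = patterns[patterns["reference_class"] == "immune"].merge(
        clinical[["patient_id", "pcr"]], on="patient_id"
    )
    pat = pat[pat["pattern"].isin(["attraction", "repulsion"])]
    cont_rows = []
    if len(pat) and pat["pcr"].nunique() >= 2 and pat["pattern"].nunique() >= 2:
        table = pd.crosstab(pat["pattern"], pat["pcr"])
        name, stat, p = pattern_test(table.to_numpy())
        for pattern_label in table.index:
            for pcr_val in table.columns:
                cont_rows.append(
                    {
                        "pattern": pattern_label,
                        "pcr": pcr_val,
                        "n": int(table.loc[pattern_label, pcr_val]),
                        "test": name,
                        "statistic": stat,
                        "p_value": p,
                    }
                )
    contingency = pd.DataFrame(
        cont_rows, columns=["pattern", "pcr", "n", "test", "statistic", "p_value"]
    )

    rho, pval = correlation_matrix(dtils[list(METRIC_NAMES)])
    corr_rows = [
        {
            "metric_a": a,
            "metric_b": b,
            "spearman_rho": rho.loc[a, b],
            "p_value": pval.loc[a, b],
        }
        for a in rho.index
        for b in rho.columns
    ]
    correlations = pd.DataFrame(corr_rows)

    radar = summarize_nms_by_group(curves, clinical, group_col="pcr")

    return [
        _write(comparisons, outdir / "comparisons.csv"),
        _write(contingency, outdir / "contingency.csv"),
        _write(correlations, outdir / "correlations.csv"),
        _write(radar, outdir / "radar_table.csv"),
    ]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "phenotype": stage_phenotype,
    "dtils": stage_dtils,
    "densities": stage_densities,
    "spatial": stage_spatial,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Run the configured stages and write ``manifest.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        outputs[stage] = _STAGE_FUNCS[stage](cfg, outdir)
    manifest = {
        "package": "tmespat",
        "version": __version__,
        "seed": cfg.sim.seed,
        "config_sha256": cfg.digest(),
        "stages": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
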