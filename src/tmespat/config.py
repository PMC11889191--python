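"""Configuration objects for the synthetic TMA generator and the pipeline.

The defaults encode the study conditions the analysis assumes: 0.6 mm
circular TMA cores (alternatively 0.93 x 0.7 mm rectangular imaging
fields), a tumor/stroma compartment split, per-class cell densities on
the order of hundreds of cells per mm^2, and two-component log-normal
marker intensity models (negative background vs. positive signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

MARKERS = ("CK", "CD4", "CD8", "FoxP3", "CD68", "PD1", "PDL1")
REGIONS = ("nucleus", "cytoplasm", "whole")

#: Cellular region in which each marker is quantified. FoxP3 is a nuclear
#: transcription factor; CD4 stains diffusely so the whole-cell mean is
#: used; every other marker is read in the cytoplasm.
MARKER_REGIONS: Mapping[str, str] = {
    "CK": "cytoplasm",
    "CD4": "whole",
    "CD8": "cytoplasm",
    "FoxP3": "nucleus",
    "CD68": "cytoplasm",
    "PD1": "cytoplasm",
    "PDL1": "cytoplasm",
}

IMMUNE_CLASSES = ("t_helper", "cytotoxic_t", "t_regulatory", "macrophage")
CELL_CLASSES = ("tumor",) + IMMUNE_CLASSES + ("other",)

#: Ground-truth lineage markers expressed by each synthetic cell class.
CLASS_POSITIVE_MARKERS: Mapping[str, frozenset] = {
    "tumor": frozenset({"CK"}),
    "macrophage": frozenset({"CD68"}),
    "t_regulatory": frozenset({"CD4", "FoxP3"}),
    "cytotoxic_t": frozenset({"CD8"}),
    "t_helper": frozenset({"CD4"}),
    "other": frozenset(),
}


@dataclass(frozen=True)
class MarkerModel:
    """Two-component intensity model for one marker, on the log scale.

    Intensities are drawn log-normally: ``exp(N(mean, sd))``. The negative
    component models background/bleed-through; the positive component the
    true signal. Defaults give well-separated components (~e^2.5 / e^0
    fold difference), mimicking a clean multiplex panel.
    """

    neg_mean: float = 0.0
    neg_sd: float = 0.35
    pos_mean: float = 2.5
    pos_sd: float = 0.35


@dataclass(frozen=True)
class CoreShape:
    """TMA core geometry: a disc (default 0.6 mm diameter) or a rectangle
    (default 0.93 x 0.7 mm, the size of one multispectral imaging field)."""

    kind: str = "disc"
    diameter_mm: float = 0.6
    width_mm: float = 0.93
    height_mm: float = 0.7

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "rect"):
            raise ValueError(f"unknown core shape {self.kind!r}")

    @property
    def extent_um(self) -> tuple[float, float]:
        if self.kind == "disc":
            d = self.diameter_mm * 1000.0
            return (d, d)
        return (self.width_mm * 1000.0, self.height_mm * 1000.0)

    @property
    def area_mm2(self) -> float:
        if self.kind == "disc":
            import math

            return math.pi * (self.diameter_mm / 2.0) ** 2
        return self.width_mm * self.height_mm


DEFAULT_DENSITIES: Mapping[str, float] = {
    "tumor": 800.0,
    "cytotoxic_t": 200.0,
    "t_helper": 200.0,
    "t_regulatory": 100.0,
    "macrophage": 120.0,
    "other": 300.0,
}

#: Fraction of cells of each class that co-express the checkpoint markers.
DEFAULT_PD1_RATES: Mapping[str, float] = {
    "t_helper": 0.2,
    "cytotoxic_t": 0.2,
    "t_regulatory": 0.2,
    "macrophage": 0.05,
    "tumor": 0.01,
    "other": 0.01,
}
DEFAULT_PDL1_RATES: Mapping[str, float] = {
    "tumor": 0.2,
    "macrophage": 0.2,
    "t_helper": 0.05,
    "cytotoxic_t": 0.05,
    "t_regulatory": 0.05,
    "other": 0.01,
}


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model linking per-patient features to the pCR label:
    ``pcr ~ Bernoulli(sigmoid(intercept + coef . standardized features))``."""

    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort."""

    n_patients: int = 24
    cores_per_patient: int = 2
    core_shape: CoreShape = field(default_factory=CoreShape)
    tumor_fraction: float = 0.3
    cell_density_per_class: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    mixing_regime: str = "csr"
    mixing_strength: float = 30.0  # tau, in um
    n_blobs: int = 20
    blob_sigma_um: tuple[float, float] = (20.0, 60.0)
    marker_models: Mapping[str, MarkerModel] = field(
        default_factory=lambda: {m: MarkerModel() for m in MARKERS}
    )
    pd1_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PD1_RATES))
    pdl1_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PDL1_RATES))
    subtype_probs: Mapping[str, float] = field(
        default_factory=lambda: {"TN": 0.3, "HER2+": 0.3, "HR+/HER2-": 0.4}
    )
    tp53_probs: Mapping[str, float] = field(
        default_factory=lambda: {"mutated": 0.45, "wildtype": 0.45, "unknown": 0.1}
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tumor_fraction < 1.0):
            raise ValueError("tumor_fraction must lie in (0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (1 <= self.cores_per_patient <= 3):
            raise ValueError("cores_per_patient must be in 1..3")
        if self.mixing_regime not in ("attraction", "csr", "repulsion"):
            raise ValueError(f"unknown mixing_regime {self.mixing_regime!r}")
        if self.mixing_strength < 0:
            raise ValueError("mixing_strength must be nonnegative")
        for cls, d in self.cell_density_per_class.items():
            if d < 0:
                raise ValueError(f"negative density for class {cls!r}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def sim_config_from_dict(d: Mapping) -> SimConfig:
    """Build a :class:`SimConfig` from a plain (YAML-loaded) mapping."""
    d = dict(d)
    if "core_shape" in d and not isinstance(d["core_shape"], CoreShape):
        d["core_shape"] = CoreShape(**d["core_shape"])
    if "marker_models" in d:
        mm = {}
        for k, v in d["marker_models"].items():
            mm[k] = v if isinstance(v, MarkerModel) else MarkerModel(**v)
        d["marker_models"] = mm
    if "outcome_model" in d and not isinstance(d["outcome_model"], OutcomeModel):
        d["outcome_model"] = OutcomeModel(**d["outcome_model"])
    return SimConfig(**d)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return sim_config_from_dict(yaml.safe_load(fh) or {})


def parse_radii(spec: str | Sequence[float]) -> list[float]:
    """Parse a radius ladder. Accepts ``"50:600:50"`` or a sequence."""
    if isinstance(spec, str):
        start, stop, step = (float(x) for x in spec.split(":"))
        out = []
        r = start
        while r <= stop + 1e-9:
            out.append(r)
            r += step
    else:
        out = [float(r) for r in spec]
    if any(r <= 0 for r in out) or any(b <= a for a, b in zip(out, out[1:])):
        raise ValueError("radii must be positive and strictly increasing")
    return out
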