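"""Synthetic multicentre phenotype data with known ground truth.

The generator emulates the structure of a multicentre wild-type haematology
screen: each centre measures the same traits on its own animals, with
centre-specific location/scale shifts (different equipment), batch (test-date)
random variation shared by animals processed on the same date, a body-weight
covariate that differs between the sexes, and a trait-specific sex effect of
known standardised magnitude ``true_d``.

For centre c, trait t and animal j the raw value is

    value = offset_c + scale_c * ( true_d * sigma_ref * 1[male]
                                   + beta_bw * (bw_j - mean bw)
                                   + b_{c,t,batch(j)} + e_j )

with b ~ N(0, batch_sd^2), e ~ N(0, residual_sd^2) and
sigma_ref = sqrt(batch_sd^2 + residual_sd^2), so the population
standardised male-female difference (net of the body-weight covariate)
equals ``true_d`` exactly.  ``true_d`` may be a single number or one value
per centre, which is how the scenario presets express between-centre
disagreement.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from math import sqrt
from typing import Dict, List, Sequence, Union

import numpy as np

from .errors import ValidationError
from .types import MeasurementRecord, Sex

__all__ = ["TraitSpec", "SimulationConfig", "generate", "impc_mimic_config", "scenario_preset"]

_BASE_DATE = datetime.date(2018, 1, 1)

#: Default trait set for the IMPC-mimic configuration: 22 haematology traits
#: with standardised sex effects spanning the range seen in real screens
#: (males higher for counts such as red blood cells, females higher for cell
#: volumes and haemoglobin indices; the two rarely-measured LUC traits are
#: given small synthetic effects).
_HAEMATOLOGY_TRAITS: List[tuple] = [
    ("platelet_count", 1.25),
    ("white_blood_cell_count", 1.17),
    ("lymphocyte_cell_count", 1.01),
    ("neutrophil_cell_count", 0.80),
    ("monocyte_cell_count", 0.62),
    ("red_blood_cell_count", 0.55),
    ("red_blood_cell_distribution_width", 0.53),
    ("haematocrit", 0.38),
    ("eosinophil_cell_count", 0.35),
    ("lymphocyte_differential_count", -0.32),
    ("mean_cell_volume", -0.47),
    ("mean_platelet_volume", -0.51),
    ("mean_cell_haemoglobin_concentration", -0.52),
    ("mean_corpuscular_haemoglobin", -0.90),
    ("luc_count", 0.10),
    ("luc_differential_count", -0.10),
    ("neutrophil_differential_count", 0.35),
    ("basophil_cell_count", 0.25),
    ("haemoglobin", 0.13),
    ("monocyte_differential_count", 0.03),
    ("eosinophil_differential_count", -0.06),
    ("basophil_differential_count", -0.16),
]


@dataclass
class TraitSpec:
    """One simulated trait: its true standardised sex effect and body-weight slope.

    ``true_d`` is scalar (same effect in every centre) or a sequence with one
    value per centre.
    """

    trait_id: str
    true_d: Union[float, Sequence[float]] = 0.0
    beta_bw: float = 0.01  # standardised units per gram


@dataclass
class SimulationConfig:
    n_centres: int = 11
    traits: List[TraitSpec] = field(default_factory=list)
    n_per_sex: int = 50
    centre_offsets: List[float] = field(default_factory=list)
    centre_scales: List[float] = field(default_factory=list)
    n_batches: int = 10
    batch_sd: float = 0.25
    residual_sd: float = 1.0
    bw_mean_male: float = 31.0  # grams
    bw_mean_female: float = 25.0
    bw_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_centres < 1 or self.n_per_sex < 1 or self.n_batches < 1:
            raise ValidationError("n_centres, n_per_sex, n_batches must be positive")
        if self.residual_sd <= 0 or self.batch_sd < 0 or self.bw_sd <= 0:
            raise ValidationError("residual_sd, bw_sd must be positive; batch_sd >= 0")
        if self.bw_mean_male <= 0 or self.bw_mean_female <= 0:
            raise ValidationError("body-weight means must be positive (grams)")
        if self.centre_offsets and len(self.centre_offsets) != self.n_centres:
            raise ValidationError("centre_offsets length must equal n_centres")
        if self.centre_scales:
            if len(self.centre_scales) != self.n_centres:
                raise ValidationError("centre_scales length must equal n_centres")
            if any(s <= 0 for s in self.centre_scales):
                raise ValidationError("centre_scales must be positive")
        for t in self.traits:
            if not np.isscalar(t.true_d) and len(t.true_d) != self.n_centres:
                raise ValidationError(
                    f"{t.trait_id}: per-centre true_d needs {self.n_centres} values"
                )


def _trait_d(spec: TraitSpec, centre_idx: int) -> float:
    if np.isscalar(spec.true_d):
        return float(spec.true_d)
    return float(spec.true_d[centre_idx])


def generate(config: SimulationConfig) -> List[MeasurementRecord]:
    """Simulate one multicentre dataset; identical config + seed give identical output."""
    if not config.traits:
        raise ValidationError("config.traits must be non-empty")
    rng = np.random.default_rng(config.seed)

    offsets = (
        np.asarray(config.centre_offsets, dtype=float)
        if config.centre_offsets
        else rng.normal(0.0, 2.0, config.n_centres)
    )
    scales = (
        np.asarray(config.centre_scales, dtype=float)
        if config.centre_scales
        else rng.uniform(0.7, 1.3, config.n_centres)
    )

    sigma_ref = sqrt(config.batch_sd**2 + config.residual_sd**2)
    bw_grand_mean = 0.5 * (config.bw_mean_male + config.bw_mean_female)
    n = config.n_per_sex
    records: List[MeasurementRecord] = []

    for ci in range(config.n_centres):
        centre_id = f"centre_{ci + 1:02d}"
        sexes = [Sex.MALE] * n + [Sex.FEMALE] * n
        is_male = np.array([1.0] * n + [0.0] * n)
        bw_mu = np.where(is_male == 1.0, config.bw_mean_male, config.bw_mean_female)
        bw = np.maximum(rng.normal(bw_mu, config.bw_sd), 1.0)  # grams, floored
        batch_idx = rng.integers(0, config.n_batches, size=2 * n)
        batch_dates = [
            _BASE_DATE + datetime.timedelta(days=7 * int(b)) for b in batch_idx
        ]
        for spec in config.traits:
            d = _trait_d(spec, ci)
            batch_effects = rng.normal(0.0, config.batch_sd, config.n_batches)
            noise = rng.normal(0.0, config.residual_sd, 2 * n)
            core = (
                d * sigma_ref * is_male
                + spec.beta_bw * (bw - bw_grand_mean)
                + batch_effects[batch_idx]
                + noise
            )
            values = offsets[ci] + scales[ci] * core
            for j in range(2 * n):
                records.append(
                    MeasurementRecord(
                        centre_id=centre_id,
                        specimen_id=f"{centre_id}_a{j + 1:04d}",
                        sex=sexes[j],
                        body_weight=float(bw[j]),
                        batch=batch_dates[j],
                        strain="C57BL/6N",
                        trait_id=spec.trait_id,
                        value=float(values[j]),
                    )
                )
    return records


def impc_mimic_config(seed: int = 0, n_per_sex: int = 50) -> SimulationConfig:
    """Default configuration emulating an 11-centre, 22-trait haematology screen.

    Centre offsets are drawn once from N(0, 2^2) in trait units and scales
    from U(0.7, 1.3) inside :func:`generate` (seeded), mimicking
    equipment-driven location/scale shifts between centres.
    """
    return SimulationConfig(
        n_centres=11,
        traits=[TraitSpec(t, d) for t, d in _HAEMATOLOGY_TRAITS],
        n_per_sex=n_per_sex,
        seed=seed,
    )


# Scenario presets: qualitative 4-centre patterns of agreement/disagreement.
# Borderline significance is induced through true_d and sample size so each
# preset exercises the full pipeline (simulation -> per-centre fit -> FDR ->
# consensus), never by injecting p-values directly.
_SCENARIOS: Dict[str, dict] = {
    # all four centres significant, same direction -> global consensus
    "S1": dict(true_d=(0.8, 0.8, 0.8, 0.8), n_per_sex=100),
    # two significant, two null -> not clear
    "S2": dict(true_d=(0.8, 0.8, 0.02, 0.02), n_per_sex=60),
    # two significant, two not but one borderline -> not clear
    "S3": dict(true_d=(0.8, 0.8, 0.35, 0.02), n_per_sex=50),
    # two strongly significant, two with p far from significance -> not clear
    "S4": dict(true_d=(1.2, 1.2, 0.0, 0.0), n_per_sex=100),
    # all significant but two per direction -> directionality penalty fires
    "S5": dict(true_d=(0.8, 0.8, -0.8, -0.8), n_per_sex=100),
    # mixed: two positive significant, one negative significant, one borderline
    "S6": dict(true_d=(0.8, 0.8, -0.8, 0.3), n_per_sex=50),
}


def scenario_preset(name: str, seed: int = 0) -> SimulationConfig:
    """4-centre simulation preset for one of the canonical scenarios S1-S6."""
    key = name.upper()
    if key not in _SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; expected S1..S6")
    s = _SCENARIOS[key]
    return SimulationConfig(
        n_centres=4,
        traits=[TraitSpec(f"trait_{key}", s["true_d"])],
        n_per_sex=s["n_per_sex"],
        centre_offsets=[0.0, 1.5, -1.0, 0.5],
        centre_scales=[1.0, 0.9, 1.1, 1.0],
        seed=seed,
    )
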