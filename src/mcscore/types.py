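"""Domain types shared across the pipeline.

The pipeline moves through three representations: raw per-animal measurements
(:class:`MeasurementRecord`), per-centre per-trait test summaries
(:class:`CentreTestResult`), and the global per-trait consensus outcome
(:class:`ConsensusOutcome`).  Effect sizes follow the male-positive convention:
a positive standardised effect size means males present higher values.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


_SEX_ALIASES = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
}


def parse_sex(token: str) -> Sex:
    """Parse a sex token ("male"/"female", "M"/"F", any case)."""
    try:
        return _SEX_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown sex token: {token!r}") from None


class Decision(str, enum.Enum):
    """Classification of a trait's multicentre evidence."""

    INSUFFICIENT_CENTRES = "INSUFFICIENT_CENTRES"
    INSUFFICIENT_INFO = "INSUFFICIENT_INFO"
    CONSENSUS = "CONSENSUS"
    NO_CONSENSUS = "NO_CONSENSUS"


class Direction(str, enum.Enum):
    MALE_HIGHER = "MALE_HIGHER"
    FEMALE_HIGHER = "FEMALE_HIGHER"
    NONE = "NONE"


@dataclass
class MeasurementRecord:
    """One animal x trait observation.

    ``body_weight`` may be ``None`` (missing); such records are excluded from
    model fitting with a logged count, since body weight is a model covariate.
    """

    centre_id: str
    specimen_id: str
    sex: Sex
    body_weight: Optional[float]  # grams
    batch: datetime.date  # date the test was performed
    strain: str
    trait_id: str
    value: float

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            self.sex = parse_sex(self.sex)
        if not math.isfinite(self.value):
            raise ValidationError(
                f"non-finite value for {self.centre_id}/{self.specimen_id}/{self.trait_id}"
            )
        if self.body_weight is not None:
            bw = float(self.body_weight)
            if not math.isfinite(bw):
                self.body_weight = None
            elif bw <= 0:
                raise ValidationError(
                    f"non-positive body weight for {self.centre_id}/{self.specimen_id}"
                )


@dataclass
class CentreTestResult:
    """Per-centre, per-trait sexual-dimorphism test output.

    ``effect_size`` is the standardised effect size rho_i (Cohen's d scale,
    positive = males higher); ``q_value`` stays unset until an FDR pass.
    """

    centre_id: str
    trait_id: str
    n_male: int
    n_female: int
    effect_size: float
    effect_se: float
    p_value: float
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(
                f"p_value {self.p_value} outside [0,1] for "
                f"{self.centre_id}/{self.trait_id}"
            )
        if self.q_value is not None:
            # q-values are probabilities; clamp tiny float excursions
            self.q_value = min(1.0, max(0.0, float(self.q_value)))
        if self.n_male >= 2 and self.n_female >= 2 and self.effect_se <= 0:
            raise ValidationError(
                f"effect_se must be positive for {self.centre_id}/{self.trait_id}"
            )


@dataclass
class ConsensusParams:
    """Tunable parameters of the consensus score.

    Defaults (c=3, q_hat=0.05, rho_hat=0.5) are the recommended preliminary
    values for high-throughput screens; ``total_centres`` is M, the study-wide
    number of centres, which may exceed the number reporting a given trait.
    """

    c: int = 3
    q_hat: float = 0.05
    rho_hat: float = 0.5
    total_centres: Optional[int] = None  # M; default: number of reporting centres

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValidationError("c must be non-negative")
        if not 0.0 < self.q_hat <= 1.0:
            raise ValidationError("q_hat must lie in (0, 1]")
        if self.rho_hat <= 0:
            raise ValidationError("rho_hat must be positive")
        if self.total_centres is not None and self.total_centres < 1:
            raise ValidationError("total_centres must be positive")


@dataclass
class ConsensusOutcome:
    """Per-trait consensus result: penalty, score, -log10 score and decision."""

    trait_id: str
    m_bar: int
    penalty: float
    score: Optional[float]
    neglog_score: Optional[float]
    decision: Decision
    direction: Direction
    mean_effect: float


@dataclass
class MetaOutcome:
    """Random-effects (DerSimonian-Laird) meta-analysis summary."""

    pooled_effect: float
    pooled_se: float
    z: float
    p_pooled: float
    tau2: float
    Q: float
    df: int
    p_heterogeneity: float  # NaN when df == 0 (single study)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; mirrors module-level defaults."""

    fdr_scope: str = "per_centre"  # or "global"
    c: int = 3
    q_hat: float = 0.05
    rho_hat: float = 0.5
    total_centres: Optional[int] = None
    min_per_sex: int = 50
    impc_mode: bool = False  # when True, enforce min_per_sex pre-filter
    fallback_fixed_effects: bool = True
    rounding: int = 2  # decimals in printed report (files keep full precision)
    alpha: float = 0.05  # significance level for the all-agree baseline
    run_baselines: bool = True

    consensus_params: "ConsensusParams" = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if self.fdr_scope not in ("per_centre", "global"):
            raise ValidationError("fdr_scope must be 'per_centre' or 'global'")
        self.consensus_params = ConsensusParams(
            c=self.c, q_hat=self.q_hat, rho_hat=self.rho_hat,
            total_centres=self.total_centres,
        )
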