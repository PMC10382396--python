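"""End-to-end pipeline: raw measurements -> per-centre tests -> FDR -> consensus.

Stages follow the method's flowchart: standardise within centre, fit the sex
model per centre x trait, correct p-values across the configured family,
count the centres reporting each trait, and score/classify the trait, with
the two literature baselines run alongside for comparison.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import baselines, consensus, multiplicity
from .centre_stats import fit_sex_model
from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .types import (
    CentreTestResult,
    ConsensusOutcome,
    MeasurementRecord,
    PipelineConfig,
    Sex,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "centre_statistics", "score_results", "run_pipeline"]


@dataclass
class PipelineResult:
    centre_results: List[CentreTestResult]
    outcomes: List[ConsensusOutcome]
    scores: pd.DataFrame
    comparison: Optional[pd.DataFrame] = None
    skipped_groups: List[Tuple[str, str, str]] = field(default_factory=list)


def centre_statistics(
    records: Sequence[MeasurementRecord], config: Optional[PipelineConfig] = None
) -> Tuple[List[CentreTestResult], List[Tuple[str, str, str]]]:
    """Fit the sex model for every centre x trait group.

    Groups that cannot be fitted (one sex absent, too few animals, zero
    variance, or below the per-sex minimum in IMPC mode) are skipped and
    reported as (centre, trait, reason) tuples rather than failing the run.
    """
    config = config or PipelineConfig()
    groups: Dict[Tuple[str, str], List[MeasurementRecord]] = defaultdict(list)
    for r in records:
        groups[(r.centre_id, r.trait_id)].append(r)
    results: List[CentreTestResult] = []
    skipped: List[Tuple[str, str, str]] = []
    for (centre_id, trait_id), recs in sorted(groups.items()):
        if config.impc_mode:
            n_m = sum(1 for r in recs if r.sex is Sex.MALE)
            n_f = sum(1 for r in recs if r.sex is Sex.FEMALE)
            if min(n_m, n_f) < config.min_per_sex:
                skipped.append(
                    (centre_id, trait_id,
                     f"below minimum of {config.min_per_sex} per sex")
                )
                continue
        try:
            results.append(
                fit_sex_model(
                    recs, fallback_fixed_effects=config.fallback_fixed_effects
                )
            )
        except (InsufficientDataError, DegenerateInputError) as exc:
            skipped.append((centre_id, trait_id, str(exc)))
    for centre_id, trait_id, reason in skipped:
        logger.info("skipped %s/%s: %s", centre_id, trait_id, reason)
    return results, skipped


def score_results(
    centre_results: Sequence[CentreTestResult],
    config: Optional[PipelineConfig] = None,
) -> List[ConsensusOutcome]:
    """FDR-correct and score per-centre results, one outcome per trait."""
    config = config or PipelineConfig()
    results = multiplicity.apply_fdr(list(centre_results), scope=config.fdr_scope)
    by_trait: Dict[str, List[CentreTestResult]] = defaultdict(list)
    for r in results:
        by_trait[r.trait_id].append(r)
    return [
        consensus.consensus_score(trait_results, config.consensus_params)
        for _, trait_results in sorted(by_trait.items())
    ]


def _scores_frame(outcomes: Sequence[ConsensusOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait_id": o.trait_id,
                "m_bar": o.m_bar,
                "penalty": o.penalty,
                "score": o.score,
                "neglog_score": o.neglog_score,
                "decision": o.decision.value,
                "direction": o.direction.value,
                "mean_effect_size": o.mean_effect,
                "inference": consensus.classify(o),
            }
            for o in outcomes
        ]
    )


def _comparison_frame(
    centre_results: Sequence[CentreTestResult],
    outcomes: Sequence[ConsensusOutcome],
    alpha: float,
) -> pd.DataFrame:
    by_trait: Dict[str, List[CentreTestResult]] = defaultdict(list)
    for r in centre_results:
        by_trait[r.trait_id].append(r)
    rows = []
    for o in outcomes:
        trait_results = by_trait[o.trait_id]
        agree = baselines.all_agree(trait_results, alpha=alpha)
        meta = baselines.random_effects_meta(
            [r.effect_size for r in trait_results],
            [r.effect_se for r in trait_results],
        )
        rows.append(
            {
                "trait_id": o.trait_id,
                "consensus_decision": o.decision.value,
                "all_agree": agree.agree,
                "meta_pooled_effect": meta.pooled_effect,
                "meta_p_pooled": meta.p_pooled,
                "meta_p_heterogeneity": meta.p_heterogeneity,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    records: Sequence[MeasurementRecord],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full analysis on raw measurement records."""
    config = config or PipelineConfig()
    records = list(records)
    if not records:
        raise ValidationError("no measurement records supplied")
    n_centres = len({r.centre_id for r in records})
    n_traits = len({r.trait_id for r in records})
    logger.info(
        "pipeline start: %d records, %d centres, %d traits",
        len(records), n_centres, n_traits,
    )

    centre_results, skipped = centre_statistics(records, config)
    if not centre_results:
        raise ValidationError("no centre x trait group could be analysed")
    logger.info(
        "per-centre stage: %d results, %d groups skipped",
        len(centre_results), len(skipped),
    )

    outcomes = score_results(centre_results, config)
    counts = Counter(o.decision.value for o in outcomes)
    logger.info("decision summary: %s", dict(counts))

    comparison = None
    if config.run_baselines:
        comparison = _comparison_frame(centre_results, outcomes, config.alpha)
    return PipelineResult(
        centre_results=centre_results,
        outcomes=outcomes,
        scores=_scores_frame(outcomes),
        comparison=comparison,
        skipped_groups=skipped,
    )
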