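"""The multicentre consensus score.

For a trait measured by M_bar of the study's M centres, each reporting an
FDR-corrected q-value q_i and a standardised effect size rho_i (male-positive
Cohen's d scale), the consensus score is

    s = [ sum_i q_i * sqrt(|rho_i|) / (M_bar^2 * q_hat * sqrt(rho_hat)) ]
        * max(M / 2, M_bar)                      if M_bar * P > c
    s = 1                                        otherwise,

where P = |sum_i Sign(rho_i)| / M_bar penalises disagreement on the effect
direction (Sign(0) = 0), and c, q_hat, rho_hat are the minimum net-centre
threshold and the expected q-value and effect size (defaults 3, 0.05, 0.5).
Evidence is read on the -log10 scale: -log10(s) > 0 declares consensus, with
the direction given by the sign of the mean effect size.  Scoring requires
more than c reporting centres; M_bar * P > c is evaluated as the integer
comparison |sum_i Sign(rho_i)| > c, immune to floating-point noise.

Smaller q_i or smaller |rho_i| can only shrink s, so more significant centres
never weaken the evidence of consensus.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .types import CentreTestResult, ConsensusOutcome, ConsensusParams, Decision, Direction

__all__ = [
    "direction_penalty",
    "consensus_score",
    "neglog_score",
    "classify",
    "calibrate_rho_hat",
]

#: Report phrases for each decision class.
_DECISION_PHRASES = {
    (Decision.CONSENSUS, Direction.MALE_HIGHER): "Males Higher",
    (Decision.CONSENSUS, Direction.FEMALE_HIGHER): "Female Higher",
    Decision.NO_CONSENSUS: "Not enough signal between or across centres to detect SD",
    Decision.INSUFFICIENT_INFO: "Not enough signal between or across centres to detect SD",
    Decision.INSUFFICIENT_CENTRES: "Does not reach the minimum requirements for this analysis",
}


def direction_penalty(effect_sizes: Sequence[float]) -> float:
    """Directionality penalty P = |sum_i Sign(rho_i)| / M_bar, in [0, 1]."""
    rho = np.asarray(effect_sizes, dtype=float)
    if rho.size == 0:
        raise DegenerateInputError("direction_penalty needs a non-empty list")
    return float(abs(np.sign(rho).sum()) / rho.size)


def neglog_score(score: float) -> float:
    """-log10 of a positive consensus score."""
    if score <= 0:
        raise ValidationError(f"score must be positive, got {score}")
    return -math.log10(score)


def consensus_score(
    results: Sequence[CentreTestResult],
    params: Optional[ConsensusParams] = None,
) -> ConsensusOutcome:
    """Score one trait's per-centre results and classify the outcome.

    Every result must carry ``q_value`` (run ``apply_fdr`` first) and
    ``effect_size``.  M_bar is the number of results; params.total_centres is
    M (defaults to M_bar).
    """
    params = params or ConsensusParams()
    results = list(results)
    if not results:
        raise DegenerateInputError("consensus_score needs at least one centre result")
    traits = {r.trait_id for r in results}
    if len(traits) != 1:
        raise ValidationError(f"results span multiple traits: {sorted(traits)}")
    trait_id = results[0].trait_id
    missing_q = [r.centre_id for r in results if r.q_value is None]
    if missing_q:
        raise ValidationError(
            f"{trait_id}: centres {missing_q} have no q_value; run apply_fdr first"
        )

    m_bar = len(results)
    M = params.total_centres if params.total_centres is not None else m_bar
    if M < m_bar:
        raise ValidationError(
            f"{trait_id}: total_centres M={M} smaller than reporting centres M_bar={m_bar}"
        )

    rho = np.array([r.effect_size for r in results], dtype=float)
    q = np.clip([r.q_value for r in results], 0.0, 1.0)
    net_sign = int(round(abs(np.sign(rho).sum())))  # = m_bar * P, an integer
    penalty = net_sign / m_bar
    mean_effect = float(rho.mean())

    if m_bar <= params.c:
        return ConsensusOutcome(
            trait_id=trait_id, m_bar=m_bar, penalty=penalty, score=None,
            neglog_score=None, decision=Decision.INSUFFICIENT_CENTRES,
            direction=Direction.NONE, mean_effect=mean_effect,
        )

    if net_sign <= params.c:  # M_bar * P <= c: directions cancel, no information
        return ConsensusOutcome(
            trait_id=trait_id, m_bar=m_bar, penalty=penalty, score=1.0,
            neglog_score=0.0, decision=Decision.INSUFFICIENT_INFO,
            direction=Direction.NONE, mean_effect=mean_effect,
        )

    numerator = float(np.sum(q * np.sqrt(np.abs(rho))))
    denominator = m_bar**2 * params.q_hat * math.sqrt(params.rho_hat)
    score = numerator / denominator * max(M / 2.0, float(m_bar))
    if score <= 0:
        # all rho_i = 0 cannot reach here (net_sign would be 0); q_i all 0 can
        score = float(np.finfo(float).tiny)
    nl = neglog_score(score)
    decision = Decision.CONSENSUS if nl > 0 else Decision.NO_CONSENSUS
    if decision is Decision.CONSENSUS:
        direction = Direction.MALE_HIGHER if mean_effect > 0 else Direction.FEMALE_HIGHER
    else:
        direction = Direction.NONE
    return ConsensusOutcome(
        trait_id=trait_id, m_bar=m_bar, penalty=penalty, score=score,
        neglog_score=nl, decision=decision, direction=direction,
        mean_effect=mean_effect,
    )


def classify(outcome: ConsensusOutcome) -> str:
    """Map a :class:`ConsensusOutcome` to its report phrase."""
    if outcome.decision is Decision.CONSENSUS:
        return _DECISION_PHRASES[(outcome.decision, outcome.direction)]
    return _DECISION_PHRASES[outcome.decision]


def calibrate_rho_hat(
    effect_sizes: Iterable[float], trim_fraction: float = 0.10
) -> float:
    """Empirical expected effect size: trimmed mean of |effect sizes|.

    Removes floor(trim_fraction * n) values from each tail of the sorted
    absolute effect sizes and averages the rest; the default 10% trim gives a
    robust field-wide estimate to use as rho_hat.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValidationError("trim_fraction must lie in [0, 0.5)")
    x = np.abs(np.asarray(list(effect_sizes), dtype=float))
    if x.size == 0:
        raise DegenerateInputError("calibrate_rho_hat needs a non-empty list")
    k = int(math.floor(trim_fraction * x.size))
    if 2 * k >= x.size:
        raise DegenerateInputError("trimming removed every value")
    # scipy's trim_mean cuts floor(p*n) per tail, matching the definition above
    return float(stats.trim_mean(x, trim_fraction))
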