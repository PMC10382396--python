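"""Comparison baselines: the all-centres-agree rule and random-effects meta-analysis.

Both are deliberately self-contained re-implementations so they can be run
side by side with the consensus score on the same per-centre results.  The
meta-analysis uses the closed-form DerSimonian-Laird between-centre variance
estimator with Cochran's Q heterogeneity test (REML, the default of some
meta-analysis packages, can give slightly different tau^2; DL is the classic
method-of-moments choice and is dependency-free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .types import CentreTestResult, Direction, MetaOutcome

__all__ = ["AllAgreeOutcome", "all_agree", "random_effects_meta"]


@dataclass
class AllAgreeOutcome:
    """Binary vote: do all centres report a significant effect of one sign?"""

    agree: bool
    direction: Direction


def all_agree(results: Sequence[CentreTestResult], alpha: float = 0.05) -> AllAgreeOutcome:
    """All-centres-agree rule: every q_value < alpha and all effect signs equal.

    The rule itself ignores any minimum-centre requirement; it is the naive
    global-consensus criterion the score is compared against.
    """
    results = list(results)
    if not results:
        raise DegenerateInputError("all_agree needs at least one centre result")
    if any(r.q_value is None for r in results):
        raise ValidationError("all_agree requires q_values; run apply_fdr first")
    signs = {int(np.sign(r.effect_size)) for r in results}
    significant = all(r.q_value < alpha for r in results)
    if significant and len(signs) == 1 and 0 not in signs:
        direction = Direction.MALE_HIGHER if signs == {1} else Direction.FEMALE_HIGHER
        return AllAgreeOutcome(agree=True, direction=direction)
    return AllAgreeOutcome(agree=False, direction=Direction.NONE)


def random_effects_meta(
    effects: Sequence[float], ses: Sequence[float]
) -> MetaOutcome:
    """DerSimonian-Laird random-effects pooling of per-centre effects.

    Fixed-effect weights w_i = 1/se_i^2 give Cochran's
    Q = sum w_i (y_i - y_FE)^2 and
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effect
    weights 1/(se_i^2 + tau^2) then pool the effects, with a two-sided normal
    test on the pooled effect and a chi-square(k-1) test on Q.

    With a single study the pooled effect is that study's effect and the
    heterogeneity p-value is NaN.
    """
    y = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise DegenerateInputError("random_effects_meta needs at least one study")
    if y.shape != se.shape:
        raise ValidationError("effects and ses must have matching lengths")
    if np.any(se <= 0):
        raise ValidationError("standard errors must be positive")

    k = y.size
    if k == 1:
        return MetaOutcome(
            pooled_effect=float(y[0]), pooled_se=float(se[0]),
            z=float(y[0] / se[0]),
            p_pooled=float(2 * stats.norm.sf(abs(y[0] / se[0]))),
            tau2=0.0, Q=0.0, df=0, p_heterogeneity=float("nan"),
        )

    w = 1.0 / se**2
    y_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - y_fe) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0

    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * y) / np.sum(w_re))
    pooled_se = float(math.sqrt(1.0 / np.sum(w_re)))
    z = pooled / pooled_se
    return MetaOutcome(
        pooled_effect=pooled,
        pooled_se=pooled_se,
        z=float(z),
        p_pooled=float(2 * stats.norm.sf(abs(z))),
        tau2=float(tau2),
        Q=Q,
        df=k - 1,
        p_heterogeneity=float(stats.chi2.sf(Q, k - 1)),
    )
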