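"""Per-centre standardisation and sexual-dimorphism testing.

Each centre's raw trait values are z-scored within the centre (pooling both
sexes), which removes centre-specific location and scale shifts such as those
caused by different measuring equipment.  The sex effect is then estimated on
the standardised scale from the linear mixed model

    value ~ Sex + BodyWeight,  batch as a random intercept,

falling back to ordinary least squares when the random effect cannot be
fitted (fewer than three batches, or a singular fit).  The reported effect
size is the model-adjusted standardised mean difference

    d = beta_sex / sqrt(sigma2_batch + sigma2_resid),

which in the no-covariate, single-batch case reduces exactly to the
two-sample Cohen's d, with the p-value of the pooled two-sample t-test.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateInputError, InsufficientDataError
from .types import CentreTestResult, MeasurementRecord, Sex

logger = logging.getLogger(__name__)

__all__ = ["standardise", "cohens_d", "effect_se", "fit_sex_model"]


def standardise(values: Sequence[float], *, context: str = "") -> np.ndarray:
    """z-score ``values``: subtract the sample mean, divide by the sample SD (n-1).

    Affine-equivariant (a*x + b, a > 0, maps to the same output as x) and
    idempotent.  Raises :class:`DegenerateInputError` on fewer than two values
    or zero variance; ``context`` (e.g. "centre/trait") is included in the
    message.
    """
    x = np.asarray(values, dtype=float)
    where = f" ({context})" if context else ""
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError(f"standardise needs >=2 values{where}")
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError(f"non-finite values passed to standardise{where}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(f"zero variance, cannot standardise{where}")
    return (x - x.mean()) / sd


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d: (mean_a - mean_b) / pooled SD, pooled with n_a + n_b - 2."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("cohens_d needs >=2 values per group")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise DegenerateInputError("zero pooled variance in cohens_d")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def effect_se(d: float, n_a: int, n_b: int) -> float:
    """Large-sample standard error of Cohen's d.

    sqrt((n_a + n_b) / (n_a * n_b) + d^2 / (2 * (n_a + n_b)))
    """
    if n_a < 2 or n_b < 2:
        raise DegenerateInputError("effect_se requires n_a, n_b >= 2")
    n = n_a + n_b
    return math.sqrt(n / (n_a * n_b) + d * d / (2 * n))


def _fit_ols(y: np.ndarray, X: np.ndarray, sex_col: int):
    res = sm.OLS(y, X).fit()
    beta = res.params[sex_col]
    p = float(res.pvalues[sex_col])
    sigma2 = float(res.mse_resid)
    return float(beta), p, sigma2


def _fit_mixed(y: np.ndarray, X: np.ndarray, groups: np.ndarray, sex_col: int):
    """Random-intercept fit; returns (beta, p, sigma2_total) or None if degenerate."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="lbfgs")
        except Exception:  # singular/ill-conditioned fits fall back to OLS
            return None
    beta = float(res.params[sex_col])
    p = float(res.pvalues[sex_col])
    var_batch = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = var_batch + float(res.scale)
    if not (math.isfinite(beta) and math.isfinite(p) and sigma2 > 0):
        return None
    return beta, p, sigma2


def fit_sex_model(
    records: Iterable[MeasurementRecord],
    *,
    fallback_fixed_effects: bool = True,
) -> CentreTestResult:
    """Estimate the sex effect for one centre x trait group of records.

    Returns a :class:`CentreTestResult` with ``q_value`` unset.  Records with
    missing body weight are dropped (counted in the log).  Raises
    :class:`InsufficientDataError` unless both sexes have >=2 animals.
    """
    recs = list(records)
    if not recs:
        raise InsufficientDataError("no records supplied")
    centres = {r.centre_id for r in recs}
    traits = {r.trait_id for r in recs}
    if len(centres) != 1 or len(traits) != 1:
        raise InsufficientDataError(
            f"fit_sex_model expects one centre x trait group, got {centres} x {traits}"
        )
    centre_id, trait_id = recs[0].centre_id, recs[0].trait_id
    context = f"{centre_id}/{trait_id}"

    n_missing_bw = sum(1 for r in recs if r.body_weight is None)
    if n_missing_bw:
        logger.info("%s: dropped %d records with missing body weight", context, n_missing_bw)
        recs = [r for r in recs if r.body_weight is not None]

    males = [r for r in recs if r.sex is Sex.MALE]
    females = [r for r in recs if r.sex is Sex.FEMALE]
    if len(males) < 2 or len(females) < 2:
        raise InsufficientDataError(
            f"{context}: need >=2 animals of each sex "
            f"(got {len(males)} male, {len(females)} female)"
        )

    y = standardise([r.value for r in recs], context=context)
    is_male = np.array([1.0 if r.sex is Sex.MALE else 0.0 for r in recs])
    bw = np.array([r.body_weight for r in recs], dtype=float)
    batches = np.array([r.batch.isoformat() for r in recs])

    cols = [np.ones(len(recs)), is_male]
    sex_col = 1
    if np.ptp(bw) > 0:  # constant body weight would make the design singular
        cols.append(bw - bw.mean())
    X = np.column_stack(cols)

    n_batches = len(set(batches.tolist()))
    fit = None
    if n_batches >= 3:
        fit = _fit_mixed(y, X, batches, sex_col)
        if fit is None:
            if not fallback_fixed_effects:
                raise InsufficientDataError(f"{context}: singular mixed-model fit")
            logger.warning("%s: mixed model singular, falling back to fixed effects", context)
    elif n_batches > 1:
        logger.warning(
            "%s: only %d batches, using fixed-effect model", context, n_batches
        )
    if fit is None:
        fit = _fit_ols(y, X, sex_col)

    beta, p_value, sigma2 = fit
    if sigma2 <= 0:
        raise DegenerateInputError(f"{context}: zero residual variance")
    d = beta / math.sqrt(sigma2)
    return CentreTestResult(
        centre_id=centre_id,
        trait_id=trait_id,
        n_male=len(males),
        n_female=len(females),
        effect_size=d,
        effect_se=effect_se(d, len(males), len(females)),
        p_value=min(1.0, max(0.0, p_value)),
    )
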