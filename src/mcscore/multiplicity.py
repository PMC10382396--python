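"""Benjamini-Hochberg FDR correction of per-centre p-values.

The multiple-testing family is configurable: ``per_centre`` (default)
corrects each centre's p-values across its own traits; ``global`` corrects
all centre x trait results jointly.
"""

from __future__ import annotations

import logging
from typing import List, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .types import CentreTestResult

logger = logging.getLogger(__name__)

__all__ = ["bh_adjust", "apply_fdr"]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j>=i} p_(j) * m / j on the sorted scale, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(
    results: List[CentreTestResult], scope: str = "per_centre"
) -> List[CentreTestResult]:
    """Set ``q_value`` on every result, correcting within families given by ``scope``.

    ``per_centre``: one family per centre (all its traits); ``global``: a
    single family over all results.  Returns the same list, mutated.
    """
    if scope not in ("per_centre", "global"):
        raise ValidationError(f"unknown FDR scope: {scope!r}")
    if not results:
        logger.warning("apply_fdr called on an empty result list")
        return results
    if any(r.p_value is None for r in results):
        raise ValidationError("every result needs p_value set before FDR")

    if scope == "global":
        families = {"__all__": list(range(len(results)))}
    else:
        families: dict = {}
        for i, r in enumerate(results):
            families.setdefault(r.centre_id, []).append(i)

    for idx in families.values():
        q = bh_adjust([results[i].p_value for i in idx])
        for i, qi in zip(idx, q):
            results[i].q_value = float(qi)
    return results
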