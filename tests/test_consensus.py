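"""The consensus score, its directionality penalty and decision logic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcscore import (
    calibrate_rho_hat,
    classify,
    consensus_score,
    direction_penalty,
    neglog_score,
)
from mcscore.errors import DegenerateInputError, ValidationError
from mcscore.types import ConsensusParams, Decision, Direction


def eq1_reference(q, rho, q_hat=0.05, rho_hat=0.5, c=3, M=None):
    """Independent one-line transcription of the score definition."""
    q, rho = np.asarray(q, float), np.asarray(rho, float)
    m_bar = len(q)
    M = m_bar if M is None else M
    if abs(np.sign(rho).sum()) <= c:
        return 1.0
    return float(
        np.sum(q * np.sqrt(np.abs(rho)))
        / (m_bar**2 * q_hat * math.sqrt(rho_hat))
        * max(M / 2, m_bar)
    )


def trait_results(make_result, rhos, qs):
    return [
        make_result(f"c{i}", "trait", effect_size=r, q_value=q, p_value=min(q, 1.0))
        for i, (r, q) in enumerate(zip(rhos, qs))
    ]


class TestDirectionPenalty:
    @pytest.mark.parametrize(
        "rhos, expected",
        [
            ((0.5, 0.3, 0.9, 0.1), 1.0),
            ((0.5, 0.3, -0.9, -0.1), 0.0),
            ((0.5, 0.3, 0.9, -0.1), 0.5),
            ((0.5, 0.0, -0.3), 0.0),  # Sign(0) = 0
        ],
    )
    def test_known_values(self, rhos, expected):
        assert direction_penalty(rhos) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            direction_penalty([])

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=20))
    def test_penalty_times_m_bar_is_integer(self, rhos):
        p = direction_penalty(rhos)
        assert 0.0 <= p <= 1.0
        assert (p * len(rhos)) == pytest.approx(round(p * len(rhos)))


class TestNeglogScore:
    def test_identity_and_table_values(self):
        assert neglog_score(1.0) == 0.0
        # printed scores and their printed -log values pin the base-10 convention
        assert round(neglog_score(0.45), 2) == 0.35
        assert round(neglog_score(0.69), 2) == 0.16

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            neglog_score(0.0)


class TestConsensusScore:
    def test_cancellation_identity(self, make_result):
        """All centres at exactly the expected q and rho: numerator cancels."""
        res = trait_results(make_result, [0.5] * 4, [0.05] * 4)
        out = consensus_score(res, ConsensusParams(total_centres=4))
        assert out.score == 1.0
        assert out.neglog_score == 0.0
        assert out.decision is Decision.NO_CONSENSUS
        assert out.direction is Direction.NONE

    def test_direction_gate_fires_on_balanced_signs(self, make_result):
        res = trait_results(make_result, [0.6, 0.4, -0.5, -0.3], [0.01, 0.01, 0.01, 0.01])
        out = consensus_score(res)
        assert out.score == 1.0
        assert out.decision is Decision.INSUFFICIENT_INFO
        assert out.penalty == 0.0

    def test_hand_worked_consensus_case(self, make_result):
        res = trait_results(
            make_result, [0.6, 0.5, 0.7, 0.55], [0.01, 0.02, 0.03, 0.04]
        )
        out = consensus_score(res, ConsensusParams(total_centres=4))
        assert out.score == pytest.approx(0.542016, abs=1e-4)
        assert out.neglog_score == pytest.approx(0.266, abs=1e-3)
        assert out.decision is Decision.CONSENSUS
        assert out.direction is Direction.MALE_HIGHER

    def test_three_centres_insufficient(self, make_result):
        out = consensus_score(trait_results(make_result, [0.5] * 3, [0.01] * 3))
        assert out.decision is Decision.INSUFFICIENT_CENTRES
        assert out.score is None and out.neglog_score is None

    def test_female_direction_from_negative_mean(self, make_result):
        res = trait_results(make_result, [-0.6, -0.5, -0.7, -0.4], [0.01] * 4)
        out = consensus_score(res)
        assert out.decision is Decision.CONSENSUS
        assert out.direction is Direction.FEMALE_HIGHER
        assert out.mean_effect < 0

    def test_missing_q_values_instruct_fdr(self, make_result):
        res = [make_result(f"c{i}", "trait", q_value=None) for i in range(4)]
        with pytest.raises(ValidationError, match="apply_fdr"):
            consensus_score(res)

    def test_m_smaller_than_m_bar_rejected(self, make_result):
        res = trait_results(make_result, [0.5] * 5, [0.01] * 5)
        with pytest.raises(ValidationError):
            consensus_score(res, ConsensusParams(total_centres=4))

    def test_permutation_invariance(self, make_result):
        rhos, qs = [0.6, -0.1, 0.8, 0.3, 0.7], [0.01, 0.4, 0.002, 0.06, 0.03]
        a = consensus_score(trait_results(make_result, rhos, qs))
        b = consensus_score(trait_results(make_result, rhos[::-1], qs[::-1]))
        assert a.score == pytest.approx(b.score)
        assert a.decision == b.decision and a.direction == b.direction

    @given(
        qs=st.lists(st.floats(0.001, 0.999), min_size=4, max_size=12),
        data=st.data(),
    )
    def test_oracle_equivalence_random_configs(self, make_result, qs, data):
        n = len(qs)
        rhos = data.draw(
            st.lists(st.floats(-2, 2), min_size=n, max_size=n)
        )
        M = data.draw(st.integers(n, 2 * n))
        out = consensus_score(
            trait_results(make_result, rhos, qs), ConsensusParams(total_centres=M)
        )
        assert out.score == pytest.approx(
            eq1_reference(qs, rhos, M=M), abs=1e-12, rel=1e-12
        )

    @given(st.integers(0, 3), st.floats(0.001, 0.2), st.floats(0.1, 1.5))
    def test_monotone_in_q_and_rho(self, idx, dq, drho):
        """Shrinking any q_i or |rho_i| never increases the score."""
        qs = [0.04, 0.03, 0.02, 0.01]
        rhos = [0.6, 0.5, 0.7, 0.4]
        base = eq1_reference(qs, rhos)
        q2 = list(qs)
        q2[idx] = max(qs[idx] - dq, 1e-6)
        assert eq1_reference(q2, rhos) <= base + 1e-15
        r2 = list(rhos)
        r2[idx] = max(rhos[idx] - drho, 1e-6)
        assert eq1_reference(qs, r2) <= base + 1e-15

    def test_scenario_table_signs(self, make_result):
        """Qualitative score pattern across canonical 4-centre scenarios."""
        # everything above expectation -> S > 1
        worse = consensus_score(trait_results(make_result, [0.8] * 4, [0.3] * 4))
        assert worse.score > 1 and worse.decision is Decision.NO_CONSENSUS
        # everything below expectation -> S < 1
        better = consensus_score(trait_results(make_result, [0.3] * 4, [0.01] * 4))
        assert better.score < 1 and better.decision is Decision.CONSENSUS
        # mixed large/small effects stay finite and valid (sqrt compression)
        mixed = consensus_score(
            trait_results(make_result, [1.8, 1.6, 0.2, 0.3], [0.01] * 4)
        )
        assert math.isfinite(mixed.score) and mixed.score > 0
        for x in (0.04, 0.25, 1.0, 2.25):
            assert (math.sqrt(x) > x) == (x < 1)


class TestClassify:
    def test_report_phrases(self, make_result):
        male = consensus_score(trait_results(make_result, [0.6] * 4, [0.01] * 4))
        assert classify(male) == "Males Higher"
        female = consensus_score(trait_results(make_result, [-0.6] * 4, [0.01] * 4))
        assert classify(female) == "Female Higher"
        nosig = consensus_score(trait_results(make_result, [0.5] * 4, [0.05] * 4))
        assert classify(nosig) == "Not enough signal between or across centres to detect SD"
        few = consensus_score(trait_results(make_result, [0.5] * 3, [0.01] * 3))
        assert classify(few) == "Does not reach the minimum requirements for this analysis"


class TestCalibrateRhoHat:
    def test_ten_point_example(self):
        assert calibrate_rho_hat(range(1, 11), 0.10) == pytest.approx(5.5)

    def test_zero_trim_is_mean_of_absolutes(self):
        assert calibrate_rho_hat([-1, 2, -3], 0.0) == pytest.approx(2.0)

    @given(st.floats(0.1, 5), st.floats(0, 0.49), st.integers(3, 30))
    def test_constant_vector_invariant(self, value, trim, n):
        assert calibrate_rho_hat([value] * n, trim) == pytest.approx(value)

    def test_invalid_trim_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_rho_hat([1, 2, 3], 0.5)
        with pytest.raises(DegenerateInputError):
            calibrate_rho_hat([], 0.1)
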