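"""Channel decomposition: transition matrix, MI/IA from (P_X, Gamma), simulation."""

import numpy as np
import pytest

from infagree import (
    ContingencyTable,
    DegenerateTableError,
    ProbabilityVector,
    TransitionMatrix,
    ia_from_channel,
    joint_from_channel,
    joint_from_table,
    mi_from_channel,
    mutual_information,
    sensitivity_specificity,
    simulate_ratings,
    transition_matrix,
)
from conftest import random_channel, random_table


def identity_gamma(q=2):
    return TransitionMatrix(np.eye(q))


class TestTransitionMatrix:
    def test_columns_must_be_stochastic(self):
        with pytest.raises(ValueError):
            TransitionMatrix(np.array([[0.9, 0.5], [0.2, 0.5]]))

    def test_identity_table_gives_identity_channel(self):
        g = transition_matrix(ContingencyTable([[10, 0], [0, 40]]))
        assert np.array_equal(g.probs, np.eye(2))

    def test_scenario5_conditionals(self, scenario5):
        g = transition_matrix(scenario5)  # X = column rater, totals 43 and 7
        expected = np.array([[40 / 43, 5 / 7], [3 / 43, 2 / 7]])
        assert np.allclose(g.probs, expected, atol=1e-12)

    def test_transpose_flag_conditions_on_rows(self, scenario5):
        g = transition_matrix(scenario5, transpose=True)  # totals 45 and 5
        expected = np.array([[40 / 45, 3 / 5], [5 / 45, 2 / 5]])
        assert np.allclose(g.probs, expected, atol=1e-12)

    def test_empty_conditioning_category_named_in_error(self):
        with pytest.raises(DegenerateTableError, match="2"):
            transition_matrix(ContingencyTable([[3, 0], [4, 0]]))


class TestChannelDecomposition:
    def test_constant_channel_gives_zero_mi(self):
        gamma = TransitionMatrix(np.array([[0.7, 0.7], [0.3, 0.3]]))
        px = ProbabilityVector(np.array([0.25, 0.75]))
        assert mi_from_channel(px, gamma, base=2) == pytest.approx(0.0, abs=1e-12)
        assert ia_from_channel(px, gamma) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_channel_uniform_input(self):
        px = ProbabilityVector(np.array([0.5, 0.5]))
        assert mi_from_channel(px, identity_gamma(), base=2) == pytest.approx(1.0)
        assert ia_from_channel(px, identity_gamma()) == pytest.approx(1.0)

    def test_identity_channel_any_nondegenerate_input(self):
        px = ProbabilityVector(np.array([0.9, 0.1]))
        assert ia_from_channel(px, identity_gamma()) == pytest.approx(1.0)

    def test_scenario5_round_trip(self, scenario5):
        px = ProbabilityVector(scenario5.col_totals / scenario5.n)
        gamma = transition_matrix(scenario5)
        direct = mutual_information(joint_from_table(scenario5), base=2)
        assert mi_from_channel(px, gamma, base=2) == pytest.approx(direct, abs=1e-12)
        assert mi_from_channel(px, gamma, base=2) == pytest.approx(0.0342, abs=5e-5)
        assert ia_from_channel(px, gamma) == pytest.approx(0.0729, abs=5e-5)

    def test_decomposition_equals_direct_mi(self, rng):
        for _ in range(200):
            q = int(rng.integers(2, 5))
            px, gamma = random_channel(rng, q)
            joint = joint_from_channel(px, gamma)
            assert abs(
                mi_from_channel(px, gamma, base=2) - mutual_information(joint, base=2)
            ) < 1e-10

    def test_prevalence_sweep_fixed_channel(self, rng):
        """Sweeping P_X at fixed Gamma moves MI/IA, but Gamma is recoverable exactly."""
        _, gamma = random_channel(rng, 2)
        ias = []
        for p1 in (0.1, 0.3, 0.5, 0.7):
            px = ProbabilityVector(np.array([p1, 1 - p1]))
            joint = joint_from_channel(px, gamma)
            # recover the channel from the induced joint by column normalisation
            recovered = joint.probs / joint.probs.sum(axis=0)
            assert np.max(np.abs(recovered - gamma.probs)) < 1e-12
            ias.append(ia_from_channel(px, gamma))
        assert max(ias) - min(ias) > 1e-6  # prevalence does move the index

    def test_dimension_mismatch(self):
        px = ProbabilityVector(np.array([0.5, 0.3, 0.2]))
        with pytest.raises(ValueError, match="mismatch"):
            mi_from_channel(px, identity_gamma(2))

    def test_degenerate_induced_marginal(self):
        px = ProbabilityVector(np.array([1.0, 0.0]))
        with pytest.raises(DegenerateTableError):
            ia_from_channel(px, identity_gamma())


class TestSensitivitySpecificity:
    def test_identity_channel(self):
        assert sensitivity_specificity(identity_gamma()) == (1.0, 1.0)

    def test_uninformative_channel(self):
        g = TransitionMatrix(np.full((2, 2), 0.5))
        assert sensitivity_specificity(g) == (0.5, 0.5)

    def test_scenario5(self, scenario5):
        se, sp = sensitivity_specificity(transition_matrix(scenario5))
        assert se == pytest.approx(0.9302, abs=5e-5)
        assert sp == pytest.approx(0.2857, abs=5e-5)

    def test_needs_binary_channel(self):
        with pytest.raises(ValueError):
            sensitivity_specificity(identity_gamma(3))


class TestSimulateRatings:
    def test_same_seed_same_table(self):
        px = ProbabilityVector(np.array([0.6, 0.4]))
        gamma = TransitionMatrix(np.array([[0.8, 0.3], [0.2, 0.7]]))
        a = simulate_ratings(px, gamma, 500, seed=7)
        b = simulate_ratings(px, gamma, 500, seed=7)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_ratings(px, gamma, 500, seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_noiseless_channel_is_diagonal(self):
        px = ProbabilityVector(np.array([0.3, 0.3, 0.4]))
        t = simulate_ratings(px, identity_gamma(3), 300, seed=1)
        assert np.count_nonzero(t.counts - np.diag(np.diag(t.counts))) == 0
        assert t.n == 300

    def test_channel_recovery_error_shrinks_as_root_n(self):
        """Empirical-Gamma error decays ~ 1/sqrt(n) over a grid of sizes."""
        px = ProbabilityVector(np.array([0.9, 0.1]))
        gamma = TransitionMatrix(np.array([[0.93, 0.71], [0.07, 0.29]]))
        errs = {}
        for n in (500, 50_000):
            errors = []
            for seed in range(30):
                t = simulate_ratings(px, gamma, n, seed=seed)
                if (t.col_totals == 0).any():
                    continue
                g = transition_matrix(t)
                errors.append(np.max(np.abs(g.probs - gamma.probs)))
            errs[n] = np.median(errors)
        # 100x more samples: error should drop by roughly 10x; allow slack 3x
        assert errs[50_000] < errs[500] / 3
        assert errs[50_000] < 0.02

    def test_invalid_n(self):
        px = ProbabilityVector(np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            simulate_ratings(px, identity_gamma(), 0, seed=1)
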