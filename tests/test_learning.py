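"""CPT estimation, marginals, and the root-marginal consistency solve."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import safetybn as sb
from safetybn.inference import DiscreteDistribution
from safetybn.learning import (SmoothingPrior, estimate_cpts, load_records,
                               node_marginals, save_records,
                               solve_consistent_root_marginal,
                               sparsity_report)
from safetybn.network import BayesianNetwork, NodeSpec, uniform_cpt
from safetybn.reference import (SAFETY_ATTITUDE_MARGINAL,
                                WORKING_EXPERIENCE_MARGINAL,
                                safety_attitude_reference_cpt)


def binary_root_network():
    nodes = {"y": NodeSpec("y", ("A", "B"), (), role="outcome")}
    bn = BayesianNetwork(nodes)
    bn.cpts["y"] = uniform_cpt(bn, "y")
    return bn


class TestEstimateCpts:
    @pytest.mark.parametrize("alpha,expected", [
        (0.0, (0.75, 0.25)),      # plain MLE on A,A,A,B
        (1.0, (4 / 6, 2 / 6)),    # Laplace: (3+1)/(4+2), (1+1)/(4+2)
    ])
    def test_parentless_binary_counts(self, alpha, expected):
        bn = binary_root_network()
        records = [{"y": s} for s in "AAAB"]
        fitted = estimate_cpts(records, bn, alpha)
        np.testing.assert_allclose(fitted.cpts["y"].probabilities[0],
                                   expected, atol=1e-12)

    @given(st.lists(st.sampled_from("AB"), min_size=1, max_size=40),
           st.floats(min_value=0.0, max_value=5.0))
    def test_smoothed_counting_closed_form(self, obs, alpha):
        """Estimated cells follow (count + a) / (n + 2a) and rows sum to 1."""
        bn = binary_root_network()
        fitted = estimate_cpts([{"y": s} for s in obs], bn, alpha)
        row = fitted.cpts["y"].probabilities[0]
        n_a = obs.count("A")
        expected = (n_a + alpha) / (len(obs) + 2 * alpha)
        assert row[0] == pytest.approx(expected, abs=1e-12)
        assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_records_rejected(self, accident_bn):
        with pytest.raises(ValueError, match="no records"):
            estimate_cpts([], accident_bn, 1.0)

    def test_unknown_state_names_record_and_node(self, accident_bn):
        rec = {n: accident_bn.nodes[n].states[0] for n in accident_bn.nodes}
        bad = dict(rec, safety_procedures="Stellar")
        with pytest.raises(ValueError, match=r"record 1.*safety_procedures"):
            estimate_cpts([rec, bad], accident_bn, 1.0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            SmoothingPrior(-0.5)

    def test_alpha_zero_unseen_rows_uniform_and_reported(self, ground_truth):
        cfg = sb.GeneratorConfig(seed=5, n_respondents=200,
                                 ground_truth=ground_truth)
        records = sb.sample_states(cfg)
        fitted = estimate_cpts(records, ground_truth, 0.0)
        report = sparsity_report(records, ground_truth)
        empty = report["number_of_accidents"]
        assert len(empty) > 1500  # 200 records cannot cover 2187 rows
        cpt = fitted.cpts["number_of_accidents"]
        for cfg_row in empty[:20]:
            np.testing.assert_allclose(cpt.row(cfg_row), [0.5, 0.5])
        assert sb.validate_network(fitted) == []

    def test_recovery_of_reference_cpt_moderate_n(self, recovery_truth):
        """Sampling from the installed reference attitude CPT and
        re-counting recovers it within sampling error."""
        cfg = sb.GeneratorConfig(seed=8, n_respondents=20_000,
                                 ground_truth=recovery_truth)
        fitted = estimate_cpts(sb.sample_states(cfg), recovery_truth, 1.0)
        err = np.abs(fitted.cpts["safety_attitude"].probabilities
                     - recovery_truth.cpts["safety_attitude"].probabilities)
        assert err.max() <= 0.03


class TestNodeMarginals:
    def test_uniform_network_all_thirds(self, accident_bn):
        marg = node_marginals(accident_bn)
        for node, dist in marg.items():
            k = accident_bn.nodes[node].n_states
            np.testing.assert_allclose(dist.probabilities, np.full(k, 1 / k),
                                       atol=1e-12)

    def test_each_marginal_sums_to_one(self, ground_truth):
        for dist in node_marginals(ground_truth).values():
            assert abs(dist.probabilities.sum() - 1.0) <= 1e-9

    def test_root_marginal_equals_cpt_row(self, ground_truth):
        marg = node_marginals(ground_truth)["working_experience"]
        np.testing.assert_allclose(
            marg.probabilities,
            ground_truth.cpts["working_experience"].probabilities[0],
            atol=1e-12)

    def test_learned_root_marginal_matches_generator(self, ground_truth):
        """At n=155, the learned experience marginal sits within binomial
        error of the generator's (0.329, 0.203, 0.468)."""
        cfg = sb.GeneratorConfig(seed=2)
        fitted = estimate_cpts(sb.sample_states(cfg), ground_truth, 1.0)
        got = node_marginals(fitted)["working_experience"].probabilities
        target = WORKING_EXPERIENCE_MARGINAL
        tol = 4 * np.sqrt(target * (1 - target) / 155) + 0.01
        assert np.all(np.abs(got - target) <= tol)


class TestConsistencySolve:
    def _reference_inputs(self, accident_bn):
        cpt = safety_attitude_reference_cpt(accident_bn)
        exp = DiscreteDistribution("working_experience",
                                   ("Short", "Medium", "Long"),
                                   WORKING_EXPERIENCE_MARGINAL)
        att = DiscreteDistribution("safety_attitude",
                                   ("Good", "Average", "Poor"),
                                   SAFETY_ATTITUDE_MARGINAL)
        return cpt, exp, att

    def test_reference_numbers_are_internally_consistent(self, accident_bn):
        """The published CPT, experience marginal, and attitude marginal are
        mutually consistent: a workmate marginal near (0.64, 0.34, 0.02)
        reproduces the attitude marginal with residual < 0.01."""
        cpt, exp, att = self._reference_inputs(accident_bn)
        dist, residual = solve_consistent_root_marginal(cpt, exp, att)
        assert residual < 0.01
        # frozen grid-search oracle optimum (step 0.002): (0.644, 0.336, 0.020)
        np.testing.assert_allclose(dist.probabilities, (0.644, 0.336, 0.020),
                                   atol=0.02)
        assert dist.probabilities.min() >= 0
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_recovers_constructed_consistent_marginal(self, accident_bn):
        cpt, exp, _ = self._reference_inputs(accident_bn)
        p_true = np.array([0.5, 0.3, 0.2])
        T = cpt.probabilities.reshape(3, 3, 3)
        child = np.einsum("i,j,ijk->k", exp.probabilities, p_true, T)
        dist, residual = solve_consistent_root_marginal(
            cpt, exp, DiscreteDistribution("safety_attitude",
                                           ("Good", "Average", "Poor"), child))
        assert residual == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(dist.probabilities, p_true, atol=1e-4)

    def test_infeasible_child_gives_positive_residual_no_error(self,
                                                               accident_bn):
        cpt, exp, _ = self._reference_inputs(accident_bn)
        child = DiscreteDistribution("safety_attitude",
                                     ("Good", "Average", "Poor"),
                                     np.array([0.01, 0.01, 0.98]))
        dist, residual = solve_consistent_root_marginal(cpt, exp, child)
        assert residual > 0.05
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_known_marginal_must_match_an_axis(self, accident_bn):
        cpt, _, att = self._reference_inputs(accident_bn)
        wrong = DiscreteDistribution("x", ("u", "v", "w"),
                                     np.array([0.3, 0.3, 0.4]))
        with pytest.raises(ValueError, match="neither CPT parent axis"):
            solve_consistent_root_marginal(cpt, wrong, att)


class TestRecordIO:
    def test_csv_round_trip(self, tmp_path, ground_truth):
        cfg = sb.GeneratorConfig(seed=1, n_respondents=50,
                                 ground_truth=ground_truth)
        records = sb.sample_states(cfg)
        path = save_records(records, ground_truth, tmp_path / "records.csv")
        back = load_records(path, ground_truth)
        assert back == records
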