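"""Two-component Gaussian mixture EM and Bayes-factor classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patkit.classification import (
    BF_THRESHOLDS,
    classification_table,
    classify,
    fit_two_component_gmm,
    membership,
)


def sample_mixture(rng, n=500, mu=(0.25, 0.55), sd=(0.08, 0.12)):
    # balanced draw: exactly n/2 per component (designed recovery experiment)
    half = n // 2
    x = np.concatenate(
        [rng.normal(mu[0], sd[0], half), rng.normal(mu[1], sd[1], n - half)]
    )
    return np.clip(x, 0.0, 1.0)


class TestFit:
    def test_parameter_recovery_across_seeds(self):
        """Aggregate recovery error over 20 replicate fits stays within the
        estimation-noise bounds; every fit is non-degenerate and ordered."""
        errs = []
        for seed in range(20):
            x = sample_mixture(np.random.default_rng(seed))
            p = fit_two_component_gmm(x)
            assert not p.degenerate
            assert p.mu_N < p.mu_I
            errs.append([abs(p.mu_N - 0.25), abs(p.mu_I - 0.55), abs(p.w_N - 0.5)])
        mean_err = np.mean(errs, axis=0)
        assert mean_err[0] < 0.03 and mean_err[1] < 0.03
        assert mean_err[2] < 0.08

    def test_component_order_convention(self, rng):
        p = fit_two_component_gmm(sample_mixture(rng))
        assert p.mu_N < p.mu_I
        assert p.w_N + p.w_I == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_input_flagged_degenerate(self):
        p = fit_two_component_gmm([0.4] * 20)
        assert p.degenerate

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_two_component_gmm([0.1] * 9)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_two_component_gmm([0.2] * 9 + [1.2])

    def test_loglik_close_to_sklearn_oracle(self, rng):
        """Independent EM cross-check: our fit should reach a likelihood at
        least as good as (or negligibly below) sklearn's."""
        sklearn = pytest.importorskip("sklearn.mixture")
        x = sample_mixture(rng)
        ours = fit_two_component_gmm(x)
        gm = sklearn.GaussianMixture(
            n_components=2, n_init=5, random_state=0, tol=1e-8, reg_covar=1e-10
        ).fit(x.reshape(-1, 1))
        assert ours.loglik >= gm.score(x.reshape(-1, 1)) * x.size - 0.5
        means = np.sort(gm.means_.ravel())
        assert ours.mu_N == pytest.approx(means[0], abs=0.01)
        assert ours.mu_I == pytest.approx(means[1], abs=0.01)


class TestMembership:
    @pytest.fixture
    def params(self, rng):
        return fit_two_component_gmm(sample_mixture(rng))

    def test_z_score_zero_at_component_mean(self, params):
        assert membership(params.mu_I, params).z_I == pytest.approx(0.0, abs=1e-12)
        assert membership(params.mu_N, params).z_N == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_midpoint_is_even_odds(self):
        from patkit.classification import MixtureParameters

        p = MixtureParameters(
            w_N=0.5, w_I=0.5, mu_N=0.3, mu_I=0.7, sigma_N=0.1, sigma_I=0.1,
            loglik=0.0, n_iter=1,
        )
        m = membership(0.5, p)
        assert m.p_N == pytest.approx(0.5, abs=1e-12)
        assert m.bf == pytest.approx(1.0, abs=1e-10)

    def test_probabilities_match_density_ratio_oracle(self, rng, params):
        """Independently coded weighted-normal-density oracle, 200 draws."""
        for _ in range(200):
            s = float(rng.uniform(0, 1))
            m = membership(s, params)
            d_n = (
                params.w_N
                / (params.sigma_N * math.sqrt(2 * math.pi))
                * math.exp(-0.5 * ((s - params.mu_N) / params.sigma_N) ** 2)
            )
            d_i = (
                params.w_I
                / (params.sigma_I * math.sqrt(2 * math.pi))
                * math.exp(-0.5 * ((s - params.mu_I) / params.sigma_I) ** 2)
            )
            assert m.p_I == pytest.approx(d_i / (d_n + d_i), abs=1e-10)
            assert m.p_N + m.p_I == pytest.approx(1.0, abs=1e-10)

    def test_unweighted_variant_drops_mixture_weights(self):
        from patkit.classification import MixtureParameters

        p = MixtureParameters(
            w_N=0.9, w_I=0.1, mu_N=0.3, mu_I=0.7, sigma_N=0.1, sigma_I=0.1,
            loglik=0.0, n_iter=1,
        )
        m = membership(0.5, p, weighted=False)
        assert m.p_N == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_params_rejected(self):
        p = fit_two_component_gmm([0.4] * 20)
        with pytest.raises(ValueError, match="degenerate"):
            membership(0.4, p)


class TestClassify:
    @pytest.mark.parametrize("thr", BF_THRESHOLDS)
    def test_exact_threshold_is_unclassified(self, thr):
        assert classify(thr, thr) == "unclassified"
        assert classify(1.0 / thr, thr) == "unclassified"

    @pytest.mark.parametrize(
        "bf, thr, label",
        [
            (31.0, 30.0, "interoceptive"),
            (0.02, 30.0, "non-interoceptive"),  # 1/0.02 = 50 > 30
            (4.0, 3.0, "interoceptive"),
            (9.9, 10.0, "unclassified"),
        ],
    )
    def test_known_labels(self, bf, thr, label):
        assert classify(bf, thr) == label

    def test_nonpositive_bf_rejected(self):
        with pytest.raises(ValueError):
            classify(0.0, 3.0)

    @given(st.floats(1e-6, 1e6), st.sampled_from([3.0, 10.0, 30.0]))
    @settings(max_examples=300)
    def test_reciprocal_label_symmetry(self, bf, thr):
        a, b = classify(bf, thr), classify(1.0 / bf, thr)
        if a == "unclassified":
            assert b == "unclassified"
        else:
            assert {a, b} == {"interoceptive", "non-interoceptive"}


class TestClassificationTable:
    @pytest.fixture
    def table_inputs(self, rng):
        params = fit_two_component_gmm(sample_mixture(rng, n=200))
        scores = sample_mixture(rng, n=120)
        members = {f"p{i}": membership(s, params) for i, s in enumerate(scores)}
        groups = {f"p{i}": "laboratory" if i % 2 else "remote" for i in range(120)}
        return members, groups

    def test_rows_partition_group_sizes(self, table_inputs):
        members, groups = table_inputs
        table = classification_table(members, groups)
        labels = ["non-interoceptive", "unclassified", "interoceptive"]
        for _, row in table.iterrows():
            n_group = sum(1 for g in groups.values() if g == row["group"])
            assert sum(row[k] for k in labels) == n_group

    def test_unclassified_nondecreasing_in_threshold(self, table_inputs):
        members, groups = table_inputs
        table = classification_table(members, groups)
        for grp in ("laboratory", "remote"):
            sub = table[table["group"] == grp].sort_values("threshold")
            u = sub["unclassified"].tolist()
            assert u == sorted(u)

    def test_ground_truth_recovery_on_separated_cohort(self):
        """Well-separated mixture (high kappa vs uniform): >= 90% of true
        labels recovered at BF3."""
        from patkit.consistency import mean_resultant_length
        from patkit.synthetic_data import ParticipantProfile, sample_response_phase

        rng = np.random.default_rng(7)
        truth, scores = [], []
        for i in range(200):
            intero = i < 100
            profile = ParticipantProfile(
                participant_id=f"p{i}", is_interoceptive=intero,
                kappa=8.0 if intero else 0.0, mu_phase=1.0,
                age=25.0, sex="female", group="laboratory",
            )
            angles = [sample_response_phase(profile, rng) for _ in range(17)]
            truth.append(intero)
            scores.append(mean_resultant_length(angles))
        params = fit_two_component_gmm(np.array(scores))
        correct = total = 0
        for intero, s in zip(truth, scores):
            label = membership(s, params).label_bf3
            if label != "unclassified":
                total += 1
                correct += label == ("interoceptive" if intero else "non-interoceptive")
        assert total >= 0.9 * len(truth)
        assert correct / total >= 0.9
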