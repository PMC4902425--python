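"""Inverse-variance pooling, heterogeneity, and sensitivity analyses."""

import math

import numpy as np
import pytest

from metamr.errors import UsageError
from metamr.effect_models import annotate_hwe, compute_effects
from metamr.meta_engine import (
    dl_tau_squared,
    heterogeneity,
    hwe_exclusion,
    leave_one_out,
    pool_auto,
    pool_fixed,
    pool_random,
    select_model,
    subgroup_analysis,
)
from metamr.study_data import EffectEstimate, GenotypeCounts, StudyRecord

from conftest import make_study


def eff(theta, se, sid="s", model="allele"):
    return EffectEstimate(sid, model, theta, se)


def effs(thetas, ses):
    return [eff(t, s, sid=f"s{i}") for i, (t, s) in enumerate(zip(thetas, ses))]


class TestFixedPooling:
    def test_single_study_is_identity(self):
        r = pool_fixed([eff(0.5, 0.2)])
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)
        assert (r.Q, r.q_p, r.i_squared) == (0.0, 1.0, 0.0)

    def test_equal_weights_average(self):
        r = pool_fixed(effs([0.0, 1.0], [1.0, 1.0]))
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.se == pytest.approx(1 / math.sqrt(2))

    def test_identical_effects_have_zero_q(self):
        r = pool_fixed(effs([0.3] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]))
        assert r.pooled_log_or == pytest.approx(0.3)
        assert r.Q == pytest.approx(0.0, abs=1e-12)
        assert r.q_p == pytest.approx(1.0)

    def test_weights_sum_to_one(self):
        r = pool_fixed(effs([0.1, 0.4, -0.2], [0.1, 0.25, 0.4]))
        assert sum(r.weights) == pytest.approx(1.0, abs=1e-9)

    def test_empty_collection_rejected(self):
        with pytest.raises(UsageError):
            pool_fixed([])

    def test_ci_brackets_the_pooled_or(self):
        r = pool_fixed(effs([0.2, 0.5], [0.3, 0.2]))
        assert r.ci_low <= r.pooled_or <= r.ci_high


class TestHeterogeneity:
    def test_q_hand_computation(self):
        Q, q_p, i2 = heterogeneity(effs([0.0, 1.0], [1.0, 1.0]))
        assert Q == pytest.approx(0.5)
        assert i2 == 0.0  # truncated: Q < k-1

    def test_i2_fifty_percent(self):
        Q, _, i2 = heterogeneity(effs([0.0, 2.0], [1.0, 1.0]))
        assert Q == pytest.approx(2.0)
        assert i2 == pytest.approx(50.0)

    def test_i2_invariant_under_common_rescaling(self):
        thetas, ses = [0.1, 0.9, -0.3, 0.5], [0.2, 0.3, 0.15, 0.25]
        _, _, i2 = heterogeneity(effs(thetas, ses))
        c = 3.7  # scaling deviations and SEs together preserves Q
        mean = float(np.average(thetas, weights=1 / np.array(ses) ** 2))
        scaled = [mean + c * (t - mean) for t in thetas]
        _, _, i2_scaled = heterogeneity(effs(scaled, [c * s for s in ses]))
        assert i2_scaled == pytest.approx(i2, abs=1e-9)


class TestRandomPooling:
    def test_dl_hand_computation(self):
        r = pool_random(effs([0.0, 2.0], [1.0, 1.0]))
        assert r.tau_squared == pytest.approx(1.0)
        assert r.pooled_log_or == pytest.approx(1.0)
        assert r.se == pytest.approx(1.0)

    def test_truncation_reduces_to_fixed(self):
        collection = effs([0.0, 1.0], [1.0, 1.0])  # Q = 0.5 < k-1
        assert dl_tau_squared(collection) == 0.0
        f, r = pool_fixed(collection), pool_random(collection)
        assert r.pooled_log_or == f.pooled_log_or
        assert r.se == f.se

    def test_single_study_has_zero_tau2(self):
        r = pool_random([eff(0.5, 0.2)])
        assert r.tau_squared == 0.0
        assert r.pooled_log_or == pytest.approx(0.5)

    def test_random_se_at_least_fixed_se(self):
        collection = effs([0.0, 1.0, -0.5, 2.0], [0.2, 0.3, 0.25, 0.4])
        assert pool_random(collection).se >= pool_fixed(collection).se


@pytest.mark.parametrize(
    "q_p, i2, expected",
    [(0.5, 10.0, "fixed"), (0.05, 30.0, "random"), (0.5, 60.0, "random")],
)
def test_selection_rule_thresholds(q_p, i2, expected):
    assert select_model(q_p, i2) == expected


class TestOracleEquivalence:
    """Pooling must agree with weighted least squares on a constant."""

    @staticmethod
    def _wls_oracle(thetas, ses, tau2=0.0):
        w = 1.0 / (np.asarray(ses) ** 2 + tau2)
        X = np.sqrt(w)[:, None]  # weighted design for intercept-only model
        y = np.sqrt(w) * np.asarray(thetas)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        se = 1.0 / math.sqrt((X * X).sum())
        return float(beta[0]), se

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_fixed_matches_wls(self, k):
        rng = np.random.default_rng(k)
        thetas, ses = rng.normal(0, 1, k), rng.uniform(0.1, 0.5, k)
        r = pool_fixed(effs(thetas, ses))
        b, se = self._wls_oracle(thetas, ses)
        assert r.pooled_log_or == pytest.approx(b, abs=1e-10)
        assert r.se == pytest.approx(se, abs=1e-10)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_random_matches_wls_at_dl_tau2(self, k):
        rng = np.random.default_rng(100 + k)
        thetas, ses = rng.normal(0, 1.5, k), rng.uniform(0.1, 0.5, k)
        collection = effs(thetas, ses)
        tau2 = dl_tau_squared(collection)
        r = pool_random(collection)
        b, se = self._wls_oracle(thetas, ses, tau2)
        assert r.pooled_log_or == pytest.approx(b, abs=1e-10)
        assert r.se == pytest.approx(se, abs=1e-10)


class TestSubgroups:
    def _studies(self, n, ethnicity="Asian", seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            counts = rng.integers(10, 80, 6)
            out.append(make_study(
                study_id=f"{ethnicity}_{i}", ethnicity=ethnicity,
                cases=tuple(int(c) for c in counts[:3]),
                controls=tuple(int(c) for c in counts[3:]),
            ))
        return out

    def test_single_stratum_equals_overall(self):
        studies = self._studies(5)
        by_eth = subgroup_analysis(studies, "allele", "ethnicity")
        assert list(by_eth) == ["Asian"]
        overall = pool_auto(compute_effects(studies, "allele"))
        assert by_eth["Asian"].primary.pooled_log_or == overall.primary.pooled_log_or

    def test_identical_strata_give_identical_results(self):
        a = self._studies(4, "Asian", seed=1)
        c = [make_study(study_id=f"c{i}", ethnicity="Caucasian",
                        cases=(s.cases.n_cc, s.cases.n_ct, s.cases.n_tt),
                        controls=(s.controls.n_cc, s.controls.n_ct, s.controls.n_tt))
             for i, s in enumerate(a)]
        by_eth = subgroup_analysis(a + c, "allele", "ethnicity")
        assert by_eth["Asian"].primary.pooled_log_or == pytest.approx(
            by_eth["Caucasian"].primary.pooled_log_or
        )

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(UsageError):
            subgroup_analysis(self._studies(3), "allele", "year")


class TestLeaveOneOut:
    def test_two_identical_studies(self):
        studies = [make_study(study_id="a"), make_study(study_id="b")]
        rows = leave_one_out(studies, "allele")
        single = pool_auto(compute_effects(studies[:1], "allele")).primary
        assert len(rows) == 2
        for _, pooled in rows:
            assert pooled.pooled_log_or == pytest.approx(single.pooled_log_or)

    def test_omitting_the_outlier_moves_pooled_or_toward_null(self):
        nulls = [make_study(study_id=f"n{i}", cases=(25, 50, 25), controls=(25, 50, 25))
                 for i in range(10)]
        outlier = make_study(study_id="outlier", cases=(5, 40, 55), controls=(55, 40, 5))
        rows = leave_one_out(nulls + [outlier], "allele")
        distances = {sid: abs(p.pooled_log_or) for sid, p in rows}
        assert min(distances, key=distances.get) == "outlier"

    def test_needs_at_least_two_studies(self):
        with pytest.raises(UsageError):
            leave_one_out([make_study()], "allele")


class TestHweExclusion:
    def test_all_in_hwe_equals_overall(self):
        studies = [make_study(study_id=f"s{i}", controls=(25, 50, 25)) for i in range(4)]
        annotate_hwe(studies)
        r = hwe_exclusion(studies, "allele")
        overall = pool_auto(compute_effects(studies, "allele")).primary
        assert r.pooled_log_or == pytest.approx(overall.pooled_log_or)
        assert r.k == 4

    def test_violating_studies_are_dropped(self):
        good = [make_study(study_id=f"g{i}", controls=(25, 50, 25)) for i in range(3)]
        bad = [make_study(study_id=f"b{i}", controls=(50, 0, 50)) for i in range(2)]
        studies = good + bad
        annotate_hwe(studies)
        assert hwe_exclusion(studies, "allele").k == 3

    def test_empty_subset_rejected(self):
        studies = [make_study(study_id="b", controls=(50, 0, 50))]
        annotate_hwe(studies)
        with pytest.raises(UsageError):
            hwe_exclusion(studies, "allele")
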