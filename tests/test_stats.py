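"""Mann-Whitney conventions, BH-FDR, and the moderation model."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, strategies as st

from netswitch import bh_fdr, mann_whitney, moderation_test
from netswitch.simulate import generate_accuracy


def ranks_with_alert_sum(n_drowsy, n_alert, rank_sum_alert):
    """Deterministically construct pooled-rank data (values = ranks) whose
    alert group has the requested rank sum."""
    alert = list(range(1, n_alert + 1))
    total = n_drowsy + n_alert
    while sum(alert) < rank_sum_alert:
        for i in reversed(range(n_alert)):
            cap = total if i == n_alert - 1 else alert[i + 1] - 1
            if alert[i] < cap:
                alert[i] += min(cap - alert[i], rank_sum_alert - sum(alert))
                break
    drowsy = [r for r in range(1, total + 1) if r not in alert]
    return np.array(drowsy, float), np.array(alert, float)


class TestMannWhitney:
    @pytest.mark.parametrize(
        "rank_sum_alert,U,z,r,rm_d,rm_a",
        [
            (73, 102.0, 2.77, 0.59, 15.00, 7.30),
            (85, 90.0, 1.98, 0.42, 14.00, 8.50),
            (78, 97.0, 2.44, 0.52, 14.58, 7.80),
            (89, 86.0, 1.71, 0.37, 13.67, 8.90),
        ],
    )
    def test_printed_vu_rank_statistics(self, rank_sum_alert, U, z, r, rm_d, rm_a):
        """Published drowsy-vs-alert rank statistics (N=22: 12 drowsy,
        10 alert) reproduce from the rank means alone."""
        d, a = ranks_with_alert_sum(12, 10, rank_sum_alert)
        c = mann_whitney(d, a)
        assert c.U == U
        assert round(c.z, 2) == z
        assert round(c.r, 2) == r
        assert round(c.rank_mean_drowsy, 2) == rm_d
        assert round(c.rank_mean_alert, 2) == rm_a

    def test_identical_groups_give_null_statistics(self):
        x = np.ones(6)
        c = mann_whitney(x[:3], x[3:])
        assert c.U == pytest.approx(3 * 3 / 2)
        assert c.z == 0.0
        assert c.p == 1.0

    def test_exact_small_sample_p_by_enumeration(self):
        """drowsy {1,2,3} vs alert {4,5,6}: the exact two-sided p over all
        rank splits is 0.1; the normal approximation must be close."""
        drowsy = np.array([1.0, 2.0, 3.0])
        alert = np.array([4.0, 5.0, 6.0])
        c = mann_whitney(drowsy, alert)
        assert c.U == 0.0  # the most extreme split
        # exact enumeration oracle over all C(6,3)=20 group assignments
        pooled = np.arange(1, 7)
        us = []
        for alert_idx in itertools.combinations(range(6), 3):
            a = pooled[list(alert_idx)]
            r_alert = a.sum()
            us.append(3 * 3 + 3 * 4 / 2 - r_alert)
        us = np.array(us)
        exact_p = np.mean(np.abs(us - 4.5) >= abs(c.U - 4.5))
        assert exact_p == pytest.approx(0.1)
        # scipy's exact method agrees with the enumeration oracle
        ref = sps.mannwhitneyu(drowsy, alert, alternative="two-sided",
                               method="exact")
        assert ref.pvalue == pytest.approx(exact_p)

    def test_antisymmetry_under_group_swap(self, rng):
        d = rng.standard_normal(9)
        a = rng.standard_normal(7)
        c1 = mann_whitney(d, a)
        c2 = mann_whitney(a, d)
        assert c2.z == pytest.approx(-c1.z)
        assert c2.r == pytest.approx(-c1.r)
        assert c2.U == pytest.approx(9 * 7 - c1.U)

    def test_matches_scipy_u_and_p_on_tie_free_data(self, rng):
        d = rng.standard_normal(12)
        a = rng.standard_normal(10)
        c = mann_whitney(d, a)
        # the reported U counts drowsy-over-alert pairs, i.e. scipy's U of
        # the drowsy sample
        ref = sps.mannwhitneyu(d, a, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert c.U == pytest.approx(ref.statistic)
        assert c.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_z_close_to_exact_enumeration_z(self, rng):
        # tie-free groups of size 8: the exact null quantile of U translated
        # to a z-equivalent agrees with the normal approximation within 0.1
        d = rng.standard_normal(8)
        a = rng.standard_normal(8)
        c = mann_whitney(d, a)
        ref = sps.mannwhitneyu(a, d, alternative="two-sided", method="exact")
        z_exact = sps.norm.isf(ref.pvalue / 2) * np.sign(c.z)
        assert abs(c.z - z_exact) <= 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney(np.array([]), np.array([1.0]))


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.04])), [0.04])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(5)), np.ones(5))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_never_decreases_p_and_order_invariant(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        perm = np.random.default_rng(0).permutation(p.size)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)


class TestModeration:
    def test_opposite_simple_slopes_recovered(self):
        # planted negative interaction strong enough to flip the drowsy slope
        rng = np.random.default_rng(1)
        sw = rng.uniform(0, 1, 60)
        states = ["alert"] * 30 + ["drowsy"] * 30
        model = generate_accuracy(sw, states, beta_interaction=-25.0,
                                  noise_sd=0.1, seed=2, beta1=10.0)
        fit = moderation_test(model.accuracy, sw, states)
        alert_slope, drowsy_slope = fit.simple_slopes()
        assert alert_slope > 0 > drowsy_slope

    def test_rank_deficient_design_rejected(self):
        acc = np.arange(10.0)
        sw = np.ones(10)
        states = ["alert"] * 5 + ["drowsy"] * 5
        with pytest.raises(ValueError, match="constant|rank"):
            moderation_test(acc, sw, states)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="both arousal levels"):
            moderation_test(np.arange(6.0), np.arange(6.0), ["alert"] * 6)

    def test_interaction_p_matches_statsmodels_convention(self):
        rng = np.random.default_rng(3)
        sw = rng.uniform(0, 1, 50)
        states = list(rng.choice(["alert", "drowsy"], 50))
        if "alert" not in states or "drowsy" not in states:
            states[0], states[1] = "alert", "drowsy"
        acc = rng.standard_normal(50)
        fit = moderation_test(acc, sw, states)
        assert 0 <= fit.interaction_p <= 1
        assert fit.standard_errors.shape == (4,)
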