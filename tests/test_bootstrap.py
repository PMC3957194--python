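"""Unit tests for stratified resampling and bootstrap intervals."""

import math

import numpy as np
import pytest
from scipy import stats

import pathmap as pm
from pathmap.bootstrap import indirect_draws
from pathmap.exceptions import InsufficientGroupsError
from pathmap.paths import PathVariables, fit_mediator, fit_outcome


def _bc_oracle(draws, point, alpha):
    """Direct enumeration of the bias-corrected interval from sorted draws."""
    draws = sorted(draws)
    R = len(draws)
    below = sum(1 for d in draws if d < point)
    prop = min(max(below / R, 1 / (2 * R)), 1 - 1 / (2 * R))
    z0 = stats.norm.ppf(prop)
    ends = []
    for z in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        p = stats.norm.cdf(2 * z0 + z)
        k = min(max(math.ceil(p * R), 1), R)
        ends.append(draws[k - 1])
    return ends[0], ends[1], z0


class TestResamplePlan:
    def test_stratification_holds_every_row(self):
        labels = [0, 0, 1, 1, 1]
        settings = pm.BootstrapSettings(n_resamples=100, seed=1)
        plan = pm.make_resample_plan(labels, settings)
        A = np.asarray(labels)
        assert plan.indices.shape == (100, 5)
        assert (A[plan.indices[:, plan.young_columns]] == 0).all()
        assert (A[plan.indices[:, plan.old_columns]] == 1).all()

    def test_deterministic_under_seed(self):
        labels = np.repeat([0, 1], [10, 12])
        s = pm.BootstrapSettings(n_resamples=200, seed=42)
        p1 = pm.make_resample_plan(labels, s)
        p2 = pm.make_resample_plan(labels, s)
        np.testing.assert_array_equal(p1.indices, p2.indices)

    def test_within_group_sampling_frequencies_binomial(self):
        n_per = 20
        labels = np.repeat([0, 1], n_per)
        settings = pm.BootstrapSettings(n_resamples=5000, seed=3)
        plan = pm.make_resample_plan(labels, settings)
        counts = np.bincount(plan.indices.ravel(), minlength=2 * n_per)
        # each subject is drawn n_per times per resample with prob 1/n_per
        expected = settings.n_resamples
        sd = math.sqrt(settings.n_resamples * n_per * (1 / n_per) * (1 - 1 / n_per))
        assert (np.abs(counts - expected) < 3 * sd).all()

    def test_empty_stratum_rejected(self):
        with pytest.raises(InsufficientGroupsError):
            pm.make_resample_plan([0, 0, 0], pm.BootstrapSettings(n_resamples=100))


class TestBCInterval:
    def test_symmetric_draws_reduce_to_percentile(self, rng):
        draws = np.concatenate([np.linspace(-1, 1, 500)])
        point = 0.0  # exactly the median -> z0 = 0
        lo, hi, z0 = pm.bc_interval(draws, point, 0.05)
        assert z0 == pytest.approx(0.0, abs=1e-12)
        plo, phi = pm.percentile_interval(draws, 0.05)
        assert (lo, hi) == (plo, phi)

    def test_matches_enumeration_oracle(self):
        draws = np.arange(1.0, 101.0)
        lo, hi, z0 = pm.bc_interval(draws, 50.5, 0.05)
        olo, ohi, oz0 = _bc_oracle(list(draws), 50.5, 0.05)
        assert (lo, hi) == (olo, ohi)
        assert z0 == pytest.approx(oz0)

    def test_matches_oracle_on_random_asymmetric_draws(self, rng):
        for _ in range(20):
            draws = rng.gamma(2.0, 1.0, size=rng.integers(100, 400))
            point = float(rng.gamma(2.0, 1.0))
            got = pm.bc_interval(draws, point, 0.05)
            want = _bc_oracle(list(draws), point, 0.05)
            assert got[0] == want[0] and got[1] == want[1]

    def test_all_draws_above_point_clamps_z0(self):
        draws = np.linspace(1.0, 2.0, 5000)
        lo, hi, z0 = pm.bc_interval(draws, 0.0, 0.05)
        assert z0 == pytest.approx(stats.norm.ppf(1 / 10000))
        assert np.isfinite([lo, hi]).all()

    def test_identical_draws_degenerate(self):
        lo, hi, z0 = pm.bc_interval(np.full(200, 1.5), 1.5, 0.05)
        assert lo == hi == 1.5


class TestBCaInterval:
    def test_symmetric_jackknife_reduces_to_bc(self, rng):
        draws = rng.normal(size=1000)
        jack = np.linspace(-1, 1, 11)  # perfectly symmetric -> accel = 0
        lo, hi, z0, accel = pm.bca_interval(draws, 0.1, 0.05, jack)
        assert accel == pytest.approx(0.0, abs=1e-15)
        blo, bhi, bz0 = pm.bc_interval(draws, 0.1, 0.05)
        assert (lo, hi, z0) == (blo, bhi, bz0)

    def test_acceleration_matches_hand_formula(self, rng):
        jack = np.array([1.0, 2.0, 2.5, 4.0, 8.0])
        centred = jack.mean() - jack
        expected = np.sum(centred**3) / (6 * np.sum(centred**2) ** 1.5)
        draws = rng.normal(size=500)
        *_, accel = pm.bca_interval(draws, 0.0, 0.05, jack)
        assert accel == pytest.approx(expected)

    def test_zero_jackknife_variance_falls_back_to_bc(self, rng):
        draws = rng.normal(size=500)
        lo, hi, z0, accel = pm.bca_interval(draws, 0.0, 0.05, np.full(7, 2.0))
        assert accel == 0.0
        assert (lo, hi, z0) == pm.bc_interval(draws, 0.0, 0.05)

    def test_bc_and_bca_close_when_skew_small(self, seeded_vars):
        settings = pm.BootstrapSettings(n_resamples=2000, seed=5, ci_method="bca")
        plan = pm.make_resample_plan(seeded_vars.A, settings)
        bca = pm.bootstrap_indirect(seeded_vars, "moderated", plan, settings)
        bc = pm.bootstrap_indirect(
            seeded_vars, "moderated", plan,
            pm.BootstrapSettings(n_resamples=2000, seed=5))
        width = bc.old.upper - bc.old.lower
        assert abs(bca.old.lower - bc.old.lower) < 0.25 * width
        assert abs(bca.old.upper - bc.old.upper) < 0.25 * width


class TestBootstrapIndirect:
    def test_vectorised_refits_match_scalar_refits(self, seeded_vars):
        settings = pm.BootstrapSettings(n_resamples=100, seed=11)
        plan = pm.make_resample_plan(seeded_vars.A, settings)
        dy, do, good = indirect_draws(seeded_vars.B, seeded_vars.C, plan,
                                      "moderated")
        assert good.all()
        for r in (0, 17, 99):
            idx = plan.indices[r]
            sub = PathVariables(seeded_vars.A[idx], seeded_vars.B[idx],
                                seeded_vars.C[idx])
            med = fit_mediator(sub)
            out = fit_outcome(sub, "moderated")
            a, b, v = med.a.estimate, out.b.estimate, out.v.estimate
            assert dy[r] == pytest.approx(a * b, rel=1e-9)
            assert do[r] == pytest.approx(a * (b + v), rel=1e-9)

    def test_simple_kind_gives_identical_groups(self, seeded_vars):
        settings = pm.BootstrapSettings(n_resamples=500, seed=2)
        plan = pm.make_resample_plan(seeded_vars.A, settings)
        res = pm.bootstrap_indirect(seeded_vars, "simple", plan, settings)
        assert res.young.point == res.old.point
        assert (res.young.lower, res.young.upper) == (res.old.lower, res.old.upper)

    def test_strong_effect_detected_in_both_groups(self, rng):
        A = np.repeat([0.0, 1.0], 40)
        B = 1.0 * A + rng.normal(0, 0.1, 80)
        C = 1.0 * B + rng.normal(0, 0.1, 80)
        vars = PathVariables.from_arrays(A, B, C)
        settings = pm.BootstrapSettings(n_resamples=1000, seed=7)
        plan = pm.make_resample_plan(A, settings)
        res = pm.bootstrap_indirect(vars, "moderated", plan, settings)
        assert res.young.significant and res.old.significant

    def test_bit_identical_under_same_seed(self, seeded_vars):
        settings = pm.BootstrapSettings(n_resamples=500, seed=123)
        out = []
        for _ in range(2):
            plan = pm.make_resample_plan(seeded_vars.A, settings)
            res = pm.bootstrap_indirect(seeded_vars, "moderated", plan, settings)
            out.append((res.young.lower, res.young.upper,
                        res.old.lower, res.old.upper))
        assert out[0] == out[1]

    def test_ci_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n_per in (30, 300):
            A = np.repeat([0.0, 1.0], n_per)
            B = 0.6 * A + rng.normal(0, 1, 2 * n_per)
            C = 0.3 * B + rng.normal(0, 0.5, 2 * n_per)
            vars = PathVariables.from_arrays(A, B, C)
            settings = pm.BootstrapSettings(n_resamples=800, seed=4)
            plan = pm.make_resample_plan(A, settings)
            res = pm.bootstrap_indirect(vars, "simple", plan, settings)
            widths.append(res.old.upper - res.old.lower)
        assert widths[1] < widths[0]


class TestSobel:
    def test_zero_a_path(self):
        a = pm.CoefficientEstimate(0.0, 0.1, 0.0, 1.0)
        b = pm.CoefficientEstimate(1.0, 0.1, 10.0, 0.0)
        z, p = pm.sobel_test(a, b)
        assert z == 0.0 and p == 1.0

    def test_hand_evaluated_formula(self):
        a = pm.CoefficientEstimate(1.0, 0.1, 10.0, 0.0)
        b = pm.CoefficientEstimate(1.0, 0.1, 10.0, 0.0)
        z, p = pm.sobel_test(a, b)
        assert z == pytest.approx(1.0 / math.sqrt(0.02))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_agrees_with_bootstrap_on_clear_effects(self, rng):
        agree = 0
        for i in range(20):
            A = np.repeat([0.0, 1.0], 60)
            effect = 0.0 if i % 2 == 0 else 0.8
            B = effect * A + rng.normal(0, 1, 120)
            C = 0.5 * B + rng.normal(0, 1, 120)
            vars = PathVariables.from_arrays(A, B, C)
            med = fit_mediator(vars)
            out = fit_outcome(vars, "simple")
            _, p = pm.sobel_test(med.a, out.b)
            settings = pm.BootstrapSettings(n_resamples=500, seed=i)
            plan = pm.make_resample_plan(A, settings)
            res = pm.bootstrap_indirect(vars, "simple", plan, settings)
            agree += (p < 0.05) == res.old.significant
        assert agree >= 16
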