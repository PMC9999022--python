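"""Fractional-polynomial basis, interval likelihood, NMA fit and HR application."""

import numpy as np
import pytest

from seqcea.curves import IPDSet, SurvivalCurve
from seqcea.fp_nma import (FPCoefficients, FPModelSpec, build_interval_data,
                           fit_fp_nma, fp_basis, fp_log_hr, hr_apply)
from seqcea.synthetic_data import generate_network


def coeffs(d, unit=1.0):
    return FPCoefficients("trt", "ref", np.asarray(d, float), time_unit_per_year=unit)


class TestFPBasis:
    def test_t1_second_element(self):
        for p in (-2.0, -1.0, 1.0, 2.0):
            assert fp_basis(1.0, FPModelSpec(1, (p,)))[1] == pytest.approx(1.0)
        assert fp_basis(1.0, FPModelSpec(1, (0.0,)))[1] == pytest.approx(0.0)

    def test_negative_power_arithmetic(self):
        b = fp_basis(4.0, FPModelSpec(1, (-2.0,)))
        np.testing.assert_allclose(b, [1.0, 0.0625])

    def test_second_order_distinct_powers(self):
        b = fp_basis(4.0, FPModelSpec(2, (-0.5, 0.0)))
        np.testing.assert_allclose(b, [1.0, 0.5, np.log(4.0)])

    def test_repeated_power(self):
        b = fp_basis(4.0, FPModelSpec(2, (1.0, 1.0)))
        np.testing.assert_allclose(b, [1.0, 4.0, 4.0 * np.log(4.0)])

    def test_domain_and_spec_validation(self):
        with pytest.raises(ValueError):
            fp_basis(0.0, FPModelSpec(1, (-2.0,)))
        with pytest.raises(ValueError):
            FPModelSpec(1, (0.7,))
        with pytest.raises(ValueError):
            FPModelSpec(2, (-2.0,))


class TestFPLogHR:
    def test_zero_coefficients_identity(self):
        spec = FPModelSpec(1, (-2.0,))
        t = np.linspace(0.5, 50, 100)
        np.testing.assert_allclose(fp_log_hr(t, coeffs([0, 0]), spec), 0.0)

    def test_scale_is_long_run_limit(self):
        # first-order p=-2: the time term vanishes as t grows
        spec = FPModelSpec(1, (-2.0,))
        lhr = fp_log_hr(1e6, coeffs([-1.255, 0.934]), spec)
        assert lhr == pytest.approx(-1.255, abs=1e-9)

    def test_second_order_arithmetic(self):
        # second-line OS contrast shape at t=6 (months-scale arithmetic check)
        spec = FPModelSpec(2, (-0.5, 0.0))
        lhr = fp_log_hr(6.0, coeffs([2.231, -3.328, -0.677]), spec)
        expected = 2.231 - 3.328 * 6 ** -0.5 - 0.677 * np.log(6)
        assert lhr == pytest.approx(expected, abs=1e-12)
        assert lhr == pytest.approx(-0.34, abs=0.01)

    def test_order_mismatch_rejected(self):
        with pytest.raises(ValueError, match="order"):
            fp_log_hr(1.0, coeffs([0.1, 0.2, 0.3]), FPModelSpec(1, (-2.0,)))


class TestBuildIntervalData:
    def test_hand_count(self):
        ipd = IPDSet([0.5, 1.5], [1, 0])
        data = build_interval_data({"a": ipd}, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(data.events["a"], [1, 0])
        np.testing.assert_allclose(data.exposure["a"], [1.5, 0.5])

    def test_event_totals_conserved(self, rng):
        t = rng.exponential(1.0, 300)
        ipd = IPDSet(t, np.ones(300, int))
        data = build_interval_data({"a": ipd}, np.linspace(0, t.max() + 0.1, 12))
        assert data.events["a"].sum() == 300

    def test_edges_excluding_data_rejected(self):
        ipd = IPDSet([0.5], [1])
        with pytest.raises(ValueError):
            build_interval_data({"a": ipd}, [10.0, 11.0])

    def test_interval_rates_near_truth(self, rng):
        t = rng.exponential(1 / 2.0, 1000)
        ipd = IPDSet(t, np.ones(1000, int))
        data = build_interval_data({"a": ipd}, np.linspace(0, 1.0, 6))
        rates = data.events["a"][:3] / data.exposure["a"][:3]
        assert np.all(np.abs(rates / 2.0 - 1) < 0.15)


class TestFitFPNMA:
    def test_constant_hr_recovery(self):
        ipd, manifest = generate_network({"trtA": (np.log(0.7), 0.0)},
                                         n_per_arm=500, seed=11)
        data = build_interval_data(ipd, np.linspace(0, 3.0, 11))
        res = fit_fp_nma(data, manifest, FPModelSpec(1, (-2.0,)), "ref",
                         seed=1, n_draws=6000, n_burn=6000)
        c = res.coefficients["trtA"]
        assert c.ci_low[0] <= np.log(0.7) <= c.ci_high[0]
        assert c.ci_low[1] <= 0.0 <= c.ci_high[1]

    def test_null_network_covers_zero(self):
        ipd, manifest = generate_network({"trtA": (0.0, 0.0)}, n_per_arm=400, seed=3)
        data = build_interval_data(ipd, np.linspace(0, 3.0, 11))
        res = fit_fp_nma(data, manifest, FPModelSpec(1, (-2.0,)), "ref",
                         seed=2, n_draws=6000, n_burn=6000)
        c = res.coefficients["trtA"]
        assert np.all(c.ci_low <= 0.0) and np.all(c.ci_high >= 0.0)

    def test_disconnected_network_rejected(self):
        ipd, _ = generate_network({"trtA": (0.0, 0.0)}, n_per_arm=50, seed=4)
        # a study that never compares against anything reachable from 'ref'
        manifest = [
            {"study": "s1", "arm": "study1:ref", "treatment": "ref"},
            {"study": "s2", "arm": "study1:trtA", "treatment": "island"},
        ]
        data = build_interval_data(ipd, np.linspace(0, 3.0, 6))
        with pytest.raises(ValueError, match="disconnected"):
            fit_fp_nma(data, manifest, FPModelSpec(1, (-2.0,)), "ref", n_draws=200,
                       n_burn=200)


class TestHRApply:
    @pytest.fixture()
    def exp_curve(self):
        t = np.linspace(0, 10, 2001)
        return SurvivalCurve(t, np.exp(-1.0 * t))

    def test_unit_hr_identity(self, exp_curve):
        out = hr_apply(exp_curve, coeffs([0.0, 0.0]), FPModelSpec(1, (-2.0,)))
        np.testing.assert_allclose(out.survival, exp_curve.survival, atol=1e-12)

    def test_constant_hr_closed_form(self, exp_curve):
        out = hr_apply(exp_curve, coeffs([np.log(0.5), 0.0]), FPModelSpec(1, (-2.0,)),
                       floor=1e-9)
        np.testing.assert_allclose(out.survival, np.exp(-0.5 * exp_curve.times),
                                   atol=1e-4)

    def test_negation_consistency(self, exp_curve):
        # same basis floor both ways so the per-interval HRs cancel exactly
        spec = FPModelSpec(1, (-2.0,))
        fwd = hr_apply(exp_curve, coeffs([-0.8, 0.5]), spec, floor=0.5)
        back = hr_apply(fwd, coeffs([0.8, -0.5]), spec, floor=0.5)
        np.testing.assert_allclose(back.survival, exp_curve.survival, atol=2e-4)

    def test_output_is_valid_curve(self, exp_curve):
        out = hr_apply(exp_curve, coeffs([1.5, -2.0]), FPModelSpec(1, (-2.0,)))
        out.validate()   # monotone, [0, 1], S(0)=1

    def test_zero_hazard_reference_warns(self):
        t = np.linspace(0, 5, 100)
        flat = SurvivalCurve(t, np.ones_like(t))
        with pytest.warns(UserWarning, match="zero hazard"):
            out = hr_apply(flat, coeffs([1.0, 0.0]), FPModelSpec(1, (-2.0,)))
        np.testing.assert_allclose(out.survival, 1.0)

    def test_effect_horizon_reverts_to_reference_hazard(self, exp_curve):
        spec = FPModelSpec(1, (-2.0,))
        out = hr_apply(exp_curve, coeffs([np.log(0.3), 0.0]), spec,
                       floor=1e-9, effect_horizon=2.0)
        h = out.interval_hazards()
        mid = 0.5 * (out.times[1:] + out.times[:-1])
        np.testing.assert_allclose(h[mid > 2.0], 1.0, rtol=1e-6)
        np.testing.assert_allclose(h[mid < 2.0], 0.3, rtol=1e-6)


class TestDIC:
    def test_dic_prefers_true_power(self):
        """True p=-2 time profile beats a mis-specified p=1 profile by DIC."""
        wins = 0
        reps = 10
        spec_true = FPModelSpec(1, (-2.0,))
        spec_wrong = FPModelSpec(1, (1.0,))
        edges = np.concatenate([np.linspace(0, 0.5, 7), np.linspace(0.7, 2.0, 6)])
        for rep in range(reps):
            ipd, manifest = generate_network({"trtA": (-0.5, 2.0)}, n_per_arm=400,
                                             powers=(-2.0,), time_unit_per_year=12.0,
                                             cutoff=2.0, censor_rate=0.05,
                                             seed=900 + rep)
            data = build_interval_data(ipd, edges)
            kw = dict(n_draws=3000, n_burn=3000, seed=rep, time_unit_per_year=12.0)
            dic_true = fit_fp_nma(data, manifest, spec_true, "ref", **kw).dic
            dic_wrong = fit_fp_nma(data, manifest, spec_wrong, "ref", **kw).dic
            wins += dic_true <= dic_wrong
        assert wins >= 0.7 * reps
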