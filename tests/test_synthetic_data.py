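"""Ground-truth generators: profiles, toy MC alchemy, two-state chains."""

import numpy as np
import pytest

from ticycle import (
    HarmonicSpec,
    LJPairSpec,
    ProfileSpec,
    estimate_leg,
    gen_dvdl_profile,
    gen_twostate_series,
    harmonic_exact_dg,
    softcore_lj_oracle_dg,
    statistical_inefficiency,
    ti_integrate,
    toy_harmonic_sim,
    toy_softcore_lj,
)
from ticycle.synthetic_data import _softcore_dvdl, _softcore_v


class TestProfileGenerator:
    def test_noiseless_linear_profile_is_exact(self, schedule12):
        spec = ProfileSpec(coefficients=(0.0, 2.0), noise_sigma=0.0,
                           samples_per_window=10, seed=0)
        windows, truth = gen_dvdl_profile(spec, schedule12)
        assert truth == 1.0
        means = [w.samples.mean() for w in windows]
        assert ti_integrate(schedule12, means) == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_recovered_within_clt_band(self, schedule12):
        spec = ProfileSpec(coefficients=(2.5,), noise_sigma=1.0,
                           samples_per_window=10_000, seed=4)
        windows, truth = gen_dvdl_profile(spec, schedule12)
        leg = estimate_leg("complex", schedule12, windows)
        assert abs(leg.estimate.delta_g - truth) < 3 * leg.estimate.sigma

    def test_same_seed_is_bit_identical(self, schedule12):
        spec = ProfileSpec(samples_per_window=100, seed=77)
        wa, _ = gen_dvdl_profile(spec, schedule12)
        wb, _ = gen_dvdl_profile(spec, schedule12)
        for a, b in zip(wa, wb):
            assert np.array_equal(a.samples, b.samples)

    def test_noise_autocorrelation_matches_requested_phi(self, schedule12):
        spec = ProfileSpec(coefficients=(0.0,), ar1_phi=0.8,
                           samples_per_window=200_000, seed=8)
        windows, _ = gen_dvdl_profile(spec, schedule12)
        g = statistical_inefficiency(windows[0].samples)
        assert g == pytest.approx((1 + 0.8) / (1 - 0.8), rel=0.15)

    def test_transient_decays_within_equilibration_fraction(self, schedule12):
        spec = ProfileSpec(coefficients=(0.0,), noise_sigma=0.0,
                           equilibration_offset=10.0, samples_per_window=1000,
                           seed=0)
        windows, _ = gen_dvdl_profile(spec, schedule12)
        s = windows[0].samples
        assert s[0] == pytest.approx(10.0)
        assert abs(s[100]) < 0.1   # < 1% of the offset past the 10% mark
        assert abs(s[-1]) < 1e-6

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            ProfileSpec(ar1_phi=1.0)


class TestHarmonicSimulator:
    def test_null_transformation_gives_zero(self, schedule12):
        spec = HarmonicSpec(k0=2.0, k1=2.0, kT=1.0, mc_steps=2000, seed=0)
        windows, _ = toy_harmonic_sim(spec, schedule12)
        leg = estimate_leg("complex", schedule12, windows)
        assert leg.estimate.delta_g == 0.0 and leg.estimate.sigma == 0.0

    def test_recovers_closed_form_within_three_sigma(self, schedule12):
        spec = HarmonicSpec(k0=1.0, k1=4.0, kT=1.0, mc_steps=50_000, seed=3)
        windows, acceptance = toy_harmonic_sim(spec, schedule12)
        leg = estimate_leg("complex", schedule12, windows)
        exact = harmonic_exact_dg(spec)
        assert exact == pytest.approx(0.6931, abs=1e-4)
        assert abs(leg.estimate.delta_g - exact) < 3 * leg.estimate.sigma
        # burn-in tuning should land near the 40% target
        assert all(0.2 < rate < 0.6 for rate in acceptance.values())

    def test_equipartition_at_fixed_lambda(self, schedule12):
        # ⟨x²⟩ = kT/k(λ): recover it from the recorded ∂V/∂λ = ½(k1−k0)x²
        spec = HarmonicSpec(k0=1.0, k1=4.0, kT=1.3, mc_steps=50_000, seed=6)
        windows, _ = toy_harmonic_sim(spec, schedule12)
        from ticycle import DvdlSeries, window_stats

        for w in windows[::4]:
            k_lam = (1 - w.lam) * spec.k0 + w.lam * spec.k1
            x2 = w.samples / (0.5 * (spec.k1 - spec.k0))
            stats = window_stats(DvdlSeries(lam=w.lam, samples=x2), 0.0)
            assert abs(stats.mean - spec.kT / k_lam) < 3 * stats.sem

    def test_dg_scales_linearly_with_kt(self):
        a = HarmonicSpec(k0=1.0, k1=4.0, kT=1.0)
        b = HarmonicSpec(k0=1.0, k1=4.0, kT=2.5)
        assert harmonic_exact_dg(b) == pytest.approx(2.5 * harmonic_exact_dg(a))

    def test_determinism(self, schedule12):
        spec = HarmonicSpec(mc_steps=500, seed=99)
        wa, _ = toy_harmonic_sim(spec, schedule12)
        wb, _ = toy_harmonic_sim(spec, schedule12)
        for a, b in zip(wa, wb):
            assert np.array_equal(a.samples, b.samples)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            HarmonicSpec(k0=-1.0)


class TestSoftcoreLJ:
    def test_lambda_one_recovers_plain_lj(self):
        r = np.linspace(2.0, 6.0, 50)
        eps, sig = 0.5, 3.0
        plain = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
        assert np.allclose(_softcore_v(r, 1.0, eps, sig, 0.5), plain)

    def test_lambda_zero_is_noninteracting(self):
        r = np.linspace(0.1, 6.0, 50)
        assert np.allclose(_softcore_v(r, 0.0, 0.5, 3.0, 0.5), 0.0)
        # the softcore keeps ∂V/∂λ finite even at r → 0
        assert np.isfinite(_softcore_dvdl(1e-6, 0.0, 0.5, 3.0, 0.5))

    def test_dvdl_matches_finite_difference(self):
        r, eps, sig, alpha = 3.2, 0.5, 3.0, 0.5
        for lam in (0.1, 0.5, 0.9):
            h = 1e-6
            fd = (_softcore_v(r, lam + h, eps, sig, alpha)
                  - _softcore_v(r, lam - h, eps, sig, alpha)) / (2 * h)
            assert _softcore_dvdl(r, lam, eps, sig, alpha) == pytest.approx(
                fd, rel=1e-5
            )

    def test_pipeline_agrees_with_partition_integral_oracle(self, schedule12):
        spec = LJPairSpec(epsilon=0.5, sigma=3.0, alpha=0.5, kT=0.59248,
                          mc_steps=50_000, seed=11)
        windows, oracle, _ = toy_softcore_lj(spec, schedule12)
        leg = estimate_leg("complex", schedule12, windows)
        assert oracle == pytest.approx(softcore_lj_oracle_dg(spec))
        assert abs(leg.estimate.delta_g - oracle) < 3 * leg.estimate.sigma

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            LJPairSpec(epsilon=0.0)


class TestTwoStateGenerator:
    def test_degenerate_weights_give_single_state(self):
        values = gen_twostate_series([1.0, 0.0], [4.0, 8.0], [0.2, 0.2],
                                     n=2000, seed=0)
        assert values.max() < 6.0  # never visits the empty state

    def test_same_seed_identical(self):
        a = gen_twostate_series([0.7, 0.3], [0.0, 5.0], [0.5, 0.5], n=500, seed=5)
        b = gen_twostate_series([0.7, 0.3], [0.0, 5.0], [0.5, 0.5], n=500, seed=5)
        assert np.array_equal(a, b)

    def test_periodic_output_wrapped(self):
        values = gen_twostate_series([0.5, 0.5], [170.0, -170.0], [10.0, 10.0],
                                     n=2000, seed=2, periodic=True)
        assert values.min() >= -180.0 and values.max() < 180.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            gen_twostate_series([0.5, 0.2], [0, 1], [1, 1], n=10)
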