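"""Equilibration discard, statistical inefficiency, SEM and convergence."""

import numpy as np
import pytest
from scipy.signal import lfilter

from ticycle import (
    DegenerateSeriesError,
    DvdlSeries,
    convergence_profile,
    discard_equilibration,
    gauss_legendre_schedule,
    statistical_inefficiency,
    subsample_uncorrelated,
    ti_integrate,
    window_stats,
)


def ar1(rng, n, phi, sigma=1.0):
    eps = rng.normal(0.0, sigma * np.sqrt(1 - phi**2), size=n)
    x = lfilter([1.0], [1.0, -phi], eps)
    x[0] = rng.normal(0.0, sigma)
    return x


class TestDiscard:
    def test_ten_percent_of_hundred(self):
        s = DvdlSeries(lam=0.5, samples=np.arange(100.0))
        out = discard_equilibration(s, 0.1)
        assert len(out) == 90
        assert out.samples[0] == 10.0

    def test_zero_fraction_is_identity(self):
        s = DvdlSeries(lam=0.5, samples=np.arange(7.0))
        assert np.array_equal(discard_equilibration(s, 0.0).samples, s.samples)

    def test_floor_convention(self):
        # N=5, fraction .9: ⌊4.5⌋ = 4 removed, one sample kept
        s = DvdlSeries(lam=0.5, samples=np.arange(5.0))
        assert len(discard_equilibration(s, 0.9)) == 1

    def test_exact_tie_removes_exact_count(self):
        s = DvdlSeries(lam=0.5, samples=np.arange(10.0))
        assert len(discard_equilibration(s, 0.2)) == 8

    @pytest.mark.parametrize("fraction", [-0.1, 1.0, 1.5])
    def test_fraction_out_of_range(self, fraction):
        s = DvdlSeries(lam=0.5, samples=np.arange(10.0))
        with pytest.raises(ValueError):
            discard_equilibration(s, fraction)


class TestStatisticalInefficiency:
    def test_white_noise_limit(self, rng):
        g = statistical_inefficiency(rng.normal(size=100_000))
        assert g == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("phi", [0.5, 0.8, 0.9])
    def test_ar1_matches_analytic_inefficiency(self, phi):
        rng = np.random.default_rng(1000 + int(10 * phi))
        g = statistical_inefficiency(ar1(rng, 1_000_000, phi))
        expect = (1 + phi) / (1 - phi)
        assert g == pytest.approx(expect, rel=0.10)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            statistical_inefficiency(np.full(100, 3.0))

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            statistical_inefficiency(np.array([1.0]))

    def test_matches_statsmodels_autocovariance_route(self, rng):
        # independent oracle: same truncation rule on statsmodels' ACF
        sm = pytest.importorskip("statsmodels.tsa.stattools")
        x = ar1(rng, 20_000, 0.8)
        c = sm.acf(x, nlags=len(x) // 2, fft=True)[1:]
        stop = np.flatnonzero(c <= 0)
        c = c[: stop[0]] if len(stop) else c
        oracle = max(1.0, 1.0 + 2.0 * c.sum())
        assert statistical_inefficiency(x) == pytest.approx(oracle, rel=1e-6)


class TestSubsample:
    def test_g_one_keeps_everything(self):
        assert np.array_equal(subsample_uncorrelated(np.arange(5), 1.0), np.arange(5))

    def test_stride_is_ceiling_of_g(self):
        assert np.array_equal(
            subsample_uncorrelated(np.arange(10), 3.0), [0, 3, 6, 9]
        )
        assert np.array_equal(
            subsample_uncorrelated(np.arange(10), 2.2), [0, 3, 6, 9]
        )

    def test_g_equal_n_leaves_one_index(self):
        assert np.array_equal(subsample_uncorrelated(np.arange(10), 10.0), [0])


class TestWindowStats:
    def test_iid_mean_and_sem(self, rng):
        s = DvdlSeries(lam=0.5, samples=rng.normal(2.0, 1.0, size=10_000))
        st = window_stats(s, equilibration_fraction=0.0)
        assert abs(st.mean - 2.0) < 3 * st.sem
        assert st.sem == pytest.approx(0.01, rel=0.15)

    def test_two_state_arithmetic_mean(self):
        s = DvdlSeries(lam=0.5, samples=np.array([1.0, 1, 1, 3, 3, 3]))
        assert window_stats(s, 0.0).mean == pytest.approx(2.0)

    def test_ar1_sem_inflated_by_sqrt_g(self):
        rng = np.random.default_rng(7)
        x = ar1(rng, 200_000, 0.9)
        s = DvdlSeries(lam=0.5, samples=x)
        st = window_stats(s, equilibration_fraction=0.0)
        naive = np.std(x, ddof=1) / np.sqrt(len(x))
        assert st.sem / naive == pytest.approx(np.sqrt(st.g), rel=0.25)
        assert st.g > 5.0

    def test_sem_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(11)
        sems = []
        sizes = [4_000, 16_000, 64_000]
        for n in sizes:
            x = rng.normal(size=n)
            sems.append(window_stats(DvdlSeries(lam=0.5, samples=x), 0.0).sem)
        slope = np.polyfit(np.log(sizes), np.log(sems), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_constant_window_has_zero_error(self):
        s = DvdlSeries(lam=0.5, samples=np.zeros(100))
        st = window_stats(s, 0.0)
        assert st.mean == 0.0 and st.sem == 0.0 and st.g == 1.0


class TestConvergence:
    @pytest.fixture()
    def legs(self, rng):
        sched = gauss_legendre_schedule(4)
        cpx = [
            DvdlSeries(lam=l, samples=3.0 + rng.normal(size=400))
            for l in sched.nodes
        ]
        apo = [
            DvdlSeries(lam=l, samples=1.0 + rng.normal(size=400))
            for l in sched.nodes
        ]
        return sched, cpx, apo

    def test_single_chunk_equals_full_estimate(self, legs):
        sched, cpx, apo = legs
        prof = convergence_profile(cpx, apo, sched, n_chunks=1)
        full_means = lambda ws: [
            np.mean(w.samples[len(w.samples) // 10:]) for w in ws
        ]
        expect = ti_integrate(sched, full_means(cpx)) - ti_integrate(
            sched, full_means(apo)
        )
        assert prof == [(1.0, pytest.approx(expect))]

    def test_time_reversal_swaps_directions(self, legs):
        sched, cpx, apo = legs
        fwd = convergence_profile(
            cpx, apo, sched, n_chunks=5, direction="forward",
            equilibration_fraction=0.0,
        )
        rev_of_flipped = convergence_profile(
            [DvdlSeries(lam=w.lam, samples=w.samples[::-1]) for w in cpx],
            [DvdlSeries(lam=w.lam, samples=w.samples[::-1]) for w in apo],
            sched, n_chunks=5, direction="reverse",
            equilibration_fraction=0.0,
        )
        for (fa, da), (fb, db) in zip(fwd, rev_of_flipped):
            assert fa == fb and da == pytest.approx(db)

    def test_forward_reverse_agree_on_stationary_data(self, legs):
        sched, cpx, apo = legs
        fwd = convergence_profile(cpx, apo, sched, n_chunks=8, direction="forward")
        rev = convergence_profile(cpx, apo, sched, n_chunks=8, direction="reverse")
        # both end on the identical full-data estimate
        assert fwd[-1][1] == pytest.approx(rev[-1][1])
        # and the half-data estimates agree within combined statistical noise
        from ticycle import estimate_leg

        sigma = np.hypot(
            estimate_leg("complex", sched, cpx).estimate.sigma,
            estimate_leg("apo", sched, apo).estimate.sigma,
        )
        assert abs(fwd[3][1] - rev[3][1]) < 3 * np.sqrt(2) * sigma

    def test_invalid_arguments(self, legs):
        sched, cpx, apo = legs
        with pytest.raises(ValueError):
            convergence_profile(cpx, apo, sched, n_chunks=0)
        with pytest.raises(ValueError):
            convergence_profile(cpx, apo, sched, direction="sideways")
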