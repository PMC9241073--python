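"""Synthetic inputs with known ground truth for validating the pipeline.

Three generator families stand in for production MD output:

* **Profile windows** — each λ window's ∂V/∂λ series is a smooth
  polynomial mean profile m(λ) plus stationary AR(1) noise and an
  initial exponential equilibration transient.  The ground-truth ΔG is
  the analytic integral ∫₀¹ m dλ, so estimator bias and error
  calibration can be checked exactly.

* **Toy Monte-Carlo alchemy** — a Metropolis-sampled 1-D harmonic
  oscillator whose force constant interpolates k(λ) = (1−λ)k₀ + λk₁
  (exact ΔG = (kT/2)·ln(k₁/k₀)), and a single softcore Lennard-Jones
  pair in a spherical volume whose reference ΔG comes from a 1-D radial
  configurational integral.  These exercise the full chain from
  Boltzmann sampling through quadrature, including the softcore
  endpoint behaviour at λ → 0.

* **Two-state descriptor series** — a hidden two-state Markov chain
  with prescribed stationary occupancies and Gaussian emissions,
  mimicking the bimodal side-chain descriptors (a distance, a dihedral)
  used to pick starting conformations.

All randomness flows from one explicit seed; equal seeds give
bit-identical output.  The Metropolis kernels consume pre-drawn random
arrays, so the optional numba acceleration changes speed only, never
results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .ti_core import LambdaSchedule
from .uncertainty import DvdlSeries

__all__ = [
    "ProfileSpec",
    "HarmonicSpec",
    "LJPairSpec",
    "gen_dvdl_profile",
    "toy_harmonic_sim",
    "harmonic_exact_dg",
    "toy_softcore_lj",
    "softcore_lj_oracle_dg",
    "gen_twostate_series",
]


def _maybe_njit(fn):
    """JIT-compile a sequential MC kernel when numba is importable."""
    try:
        import numba
    except ImportError:  # pragma: no cover - numba present in dev env
        return fn
    return numba.njit(cache=False)(fn)


# ---------------------------------------------------------------------------
# Analytic dV/dλ profile windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileSpec:
    """Synthetic ∂V/∂λ window ensemble with analytic ground truth.

    ``coefficients`` are ascending polynomial coefficients of the mean
    profile m(λ) in kcal/mol: m(λ) = c₀ + c₁λ + c₂λ² + …  The AR(1)
    noise has stationary standard deviation ``noise_sigma`` and lag-one
    correlation ``ar1_phi`` (statistical inefficiency (1+φ)/(1−φ)).
    ``equilibration_offset`` is the initial amplitude of an exponential
    transient that decays over the first ``equilibration_fraction`` of
    each window, emulating an unequilibrated start.
    """

    coefficients: tuple = (0.0, 2.0)
    noise_sigma: float = 1.0
    ar1_phi: float = 0.9
    equilibration_offset: float = 0.0
    equilibration_fraction: float = 0.1
    samples_per_window: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ValueError("AR(1) coefficient must satisfy 0 <= phi < 1")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be non-negative")
        if self.samples_per_window < 1:
            raise ValueError("need at least one sample per window")

    def mean(self, lam) -> np.ndarray:
        return np.polynomial.polynomial.polyval(lam, np.asarray(self.coefficients))

    @property
    def ground_truth_dg(self) -> float:
        """Analytic ∫₀¹ m(λ) dλ = Σ cₖ/(k+1)."""
        c = np.asarray(self.coefficients, dtype=float)
        return float(np.sum(c / (np.arange(len(c)) + 1.0)))


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal sd sigma."""
    if sigma == 0.0:
        return np.zeros(n)
    innov_sd = sigma * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    for t in range(1, n):  # short recurrence; scipy.signal.lfilter equivalent
        x[t] = phi * x[t - 1] + eps[t]
    return x


def gen_dvdl_profile(
    spec: ProfileSpec, schedule: LambdaSchedule
) -> tuple[list[DvdlSeries], float]:
    """Generate one ∂V/∂λ window per schedule node.

    Each window i holds m(λᵢ) + AR(1) noise + a transient
    A·exp(−5t/(fN)) that has decayed to <1% of A by the end of the
    equilibration fraction f.  Returns (windows, ground-truth ΔG).
    """
    ss = np.random.SeedSequence(spec.seed)
    windows = []
    n = spec.samples_per_window
    t = np.arange(n)
    f = max(spec.equilibration_fraction, 1e-12)
    transient = spec.equilibration_offset * np.exp(-5.0 * t / (f * n))
    for lam, child in zip(schedule.nodes, ss.spawn(len(schedule))):
        rng = np.random.default_rng(child)
        samples = (
            float(spec.mean(lam))
            + _ar1_noise(rng, n, spec.ar1_phi, spec.noise_sigma)
            + transient
        )
        windows.append(DvdlSeries(lam=float(lam), samples=samples))
    return windows, spec.ground_truth_dg


# ---------------------------------------------------------------------------
# Toy Metropolis Monte-Carlo alchemical systems
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicSpec:
    """Harmonic oscillator k₀ → k₁ transformation, V(x;λ) = ½k(λ)x²."""

    k0: float = 1.0
    k1: float = 4.0
    kT: float = 1.0
    mc_steps: int = 50_000
    step_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k0, self.k1, self.kT) <= 0.0:
            raise ValueError("k0, k1 and kT must all be positive")


@dataclass(frozen=True)
class LJPairSpec:
    """One particle pair in a sphere, softcore-coupled Lennard-Jones.

    The interaction is scaled by λ through the separation-shifted
    softcore form (α in reduced units; the λ=0 endpoint is an ideal,
    non-interacting pair; λ=1 recovers plain LJ):

        V(r; λ) = 4ελ [ (α(1−λ) + (r/σ)⁶)⁻² − (α(1−λ) + (r/σ)⁶)⁻¹ ]
    """

    epsilon: float = 0.5
    sigma: float = 3.0
    box_length: float = 12.0
    alpha: float = 0.5
    kT: float = 0.59248
    mc_steps: int = 50_000
    step_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epsilon, self.sigma, self.box_length, self.kT) <= 0.0:
            raise ValueError("epsilon, sigma, box_length and kT must be positive")

    @property
    def radius(self) -> float:
        """Radius of the spherical sampling volume (half the box edge)."""
        return self.box_length / 2.0


def harmonic_exact_dg(spec: HarmonicSpec) -> float:
    """Closed-form ΔG = (kT/2)·ln(k₁/k₀) for the harmonic toy system."""
    return 0.5 * spec.kT * math.log(spec.k1 / spec.k0)


def _softcore_v(r, lam, eps, sig, alpha):
    s = alpha * (1.0 - lam) + (r / sig) ** 6
    return 4.0 * eps * lam * (s**-2 - s**-1)


def _softcore_dvdl(r, lam, eps, sig, alpha):
    s = alpha * (1.0 - lam) + (r / sig) ** 6
    return 4.0 * eps * (s**-2 - s**-1) + 4.0 * eps * lam * alpha * (
        2.0 * s**-3 - s**-2
    )


def softcore_lj_oracle_dg(spec: LJPairSpec) -> float:
    """Reference ΔG = −kT·ln(Z₁/Z₀) from the radial configurational integral.

    Z(λ) = ∫₀^R r² exp(−V(r;λ)/kT) dr, evaluated by adaptive
    quadrature; independent of the Monte-Carlo/TI route it checks.
    """
    R = spec.radius

    def z(lam: float) -> float:
        val, _ = quad(
            lambda r: r * r
            * math.exp(-_softcore_v(r, lam, spec.epsilon, spec.sigma, spec.alpha) / spec.kT),
            0.0,
            R,
            limit=200,
        )
        return val

    return -spec.kT * math.log(z(1.0) / z(0.0))


def _harmonic_kernel(x0, k, kT, step, prop, u, out):
    x = x0
    acc = 0
    for i in range(len(prop)):
        xn = x + step * prop[i]
        dv = 0.5 * k * (xn * xn - x * x)
        if dv <= 0.0 or u[i] < math.exp(-dv / kT):
            x = xn
            acc += 1
        out[i] = x
    return acc


def _lj_kernel(r0, lam, eps, sig, alpha, kT, rmax, step, prop, u, out):
    r = r0
    acc = 0
    s = alpha * (1.0 - lam) + (r / sig) ** 6
    v = 4.0 * eps * lam * (1.0 / (s * s) - 1.0 / s)
    for i in range(len(prop)):
        rn = r + step * prop[i]
        if rn <= 0.0 or rn > rmax:
            out[i] = r
            continue
        sn = alpha * (1.0 - lam) + (rn / sig) ** 6
        vn = 4.0 * eps * lam * (1.0 / (sn * sn) - 1.0 / sn)
        # radial measure: stationary density ∝ r² exp(−V/kT)
        ratio = (rn / r) * (rn / r) * math.exp(-(vn - v) / kT)
        if u[i] < ratio:
            r = rn
            v = vn
            acc += 1
        out[i] = r
    return acc


_harmonic_kernel = _maybe_njit(_harmonic_kernel)
_lj_kernel = _maybe_njit(_lj_kernel)

#: Metropolis acceptance targeted during step-size burn-in
_TARGET_ACCEPTANCE = 0.4
_TUNE_ROUNDS = 25
_TUNE_STEPS = 200


def _tune_and_run(kernel_args, run_kernel, rng, step0, n_steps):
    """Auto-tune the proposal step toward ~40% acceptance, then sample.

    Burn-in (tuning) draws are discarded; the production run returns
    (trajectory, acceptance_rate, tuned_step).
    """
    step = step0
    buf = np.empty(_TUNE_STEPS)
    state = None
    for _ in range(_TUNE_ROUNDS):
        prop = rng.uniform(-1.0, 1.0, _TUNE_STEPS)
        u = rng.random(_TUNE_STEPS)
        acc = run_kernel(kernel_args, state, step, prop, u, buf)
        state = buf[-1]
        rate = acc / _TUNE_STEPS
        if rate > _TARGET_ACCEPTANCE + 0.05:
            step *= 1.25
        elif rate < _TARGET_ACCEPTANCE - 0.05:
            step /= 1.25
    out = np.empty(n_steps)
    prop = rng.uniform(-1.0, 1.0, n_steps)
    u = rng.random(n_steps)
    acc = run_kernel(kernel_args, state, step, prop, u, out)
    return out, acc / n_steps, step


def toy_harmonic_sim(
    spec: HarmonicSpec, schedule: LambdaSchedule
) -> tuple[list[DvdlSeries], dict]:
    """Metropolis-sample each λ window of the harmonic transformation.

    At each node, x is sampled under V(x;λ) = ½[(1−λ)k₀ + λk₁]x² and
    ∂V/∂λ = ½(k₁−k₀)x² is recorded.  Returns (windows, diagnostics);
    diagnostics maps λ → acceptance rate.  The exact result is
    :func:`harmonic_exact_dg`.
    """
    ss = np.random.SeedSequence(spec.seed)
    windows, acceptance = [], {}
    dk = 0.5 * (spec.k1 - spec.k0)
    for lam, child in zip(schedule.nodes, ss.spawn(len(schedule))):
        rng = np.random.default_rng(child)
        k = (1.0 - lam) * spec.k0 + lam * spec.k1
        x0 = rng.normal(0.0, math.sqrt(spec.kT / k))

        def run(args, state, step, prop, u, out, k=k, x0=x0):
            return _harmonic_kernel(
                x0 if state is None else state, k, spec.kT, step, prop, u, out
            )

        traj, rate, _ = _tune_and_run(None, run, rng, spec.step_size, spec.mc_steps)
        windows.append(DvdlSeries(lam=float(lam), samples=dk * traj * traj))
        acceptance[float(lam)] = rate
    return windows, acceptance


def toy_softcore_lj(
    spec: LJPairSpec, schedule: LambdaSchedule
) -> tuple[list[DvdlSeries], float, dict]:
    """Metropolis-sample the softcore LJ pair at each λ window.

    The radial coordinate r ∈ (0, R] is sampled with the r² volume
    Jacobian in the acceptance ratio; ∂V/∂λ is recorded analytically.
    Returns (windows, oracle ΔG, acceptance diagnostics).
    """
    ss = np.random.SeedSequence(spec.seed)
    windows, acceptance = [], {}
    R = spec.radius
    for lam, child in zip(schedule.nodes, ss.spawn(len(schedule))):
        rng = np.random.default_rng(child)
        r0 = R * rng.random() ** (1.0 / 3.0)  # uniform in the sphere

        def run(args, state, step, prop, u, out, lam=lam, r0=r0):
            return _lj_kernel(
                r0 if state is None else state,
                lam, spec.epsilon, spec.sigma, spec.alpha, spec.kT, R,
                step, prop, u, out,
            )

        traj, rate, _ = _tune_and_run(None, run, rng, spec.step_size, spec.mc_steps)
        dvdl = _softcore_dvdl(traj, lam, spec.epsilon, spec.sigma, spec.alpha)
        windows.append(DvdlSeries(lam=float(lam), samples=dvdl))
        acceptance[float(lam)] = rate
    return windows, softcore_lj_oracle_dg(spec), acceptance


# ---------------------------------------------------------------------------
# Two-state descriptor series
# ---------------------------------------------------------------------------


def gen_twostate_series(
    weights,
    means,
    widths,
    n: int,
    seed: int = 0,
    ar1_phi: float = 0.0,
    periodic: bool = False,
    switch_rate: float = 0.1,
) -> np.ndarray:
    """Hidden two-state Markov chain with Gaussian emissions.

    The chain's transition matrix is P = (1−ρ)I + ρ·1wᵀ with switching
    rate ρ, giving stationary occupancies exactly equal to ``weights``
    and a mean dwell time of 1/ρ frames.  Emission noise per state is
    Gaussian with the state's width, optionally AR(1)-correlated with
    coefficient ``ar1_phi``.  Periodic output is wrapped to
    [−180°, 180°).

    Returns the raw descriptor values; pair with
    :class:`~ticycle.conf_states.DescriptorSeries` for state analysis.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) != len(means) or len(w) != len(widths):
        raise ValueError("weights, means and widths must have equal length")
    if np.any(w < 0.0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    if not (0.0 < switch_rate <= 1.0):
        raise ValueError("switch_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    k = len(w)
    states = np.empty(n, dtype=np.intp)
    states[0] = rng.choice(k, p=w)
    switches = rng.random(n) < switch_rate
    resample = rng.choice(k, p=w, size=n)
    for t in range(1, n):
        states[t] = resample[t] if switches[t] else states[t - 1]
    noise = rng.normal(0.0, 1.0, size=n)
    if ar1_phi:
        if not (0.0 <= ar1_phi < 1.0):
            raise ValueError("ar1_phi must be in [0, 1)")
        corr = np.empty(n)
        corr[0] = noise[0]
        c = math.sqrt(1.0 - ar1_phi**2)
        for t in range(1, n):
            corr[t] = ar1_phi * corr[t - 1] + c * noise[t]
        noise = corr
    values = np.asarray(means, dtype=float)[states] + np.asarray(widths, dtype=float)[states] * noise
    if periodic:
        values = (values + 180.0) % 360.0 - 180.0
    return values
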