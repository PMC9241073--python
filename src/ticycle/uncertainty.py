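"""Per-window statistics of autocorrelated ∂V/∂λ time series.

MD time series are serially correlated, so the naive SEM σ/√N
underestimates the true sampling error.  The statistical inefficiency

    g = 1 + 2 Σ_t C(t),   C(t) = normalized autocovariance,

truncated at the first non-positive C(t), measures how many correlated
samples equal one independent one.  Each window is processed as: discard
an initial equilibration fraction, estimate g, subsample every ⌈g⌉-th
frame, and compute mean and SEM from the (approximately uncorrelated)
subsample.  Convergence of a full cycle is monitored by recomputing
ΔΔG on growing forward prefixes and reverse suffixes of every window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .ti_core import LambdaSchedule, ti_integrate

__all__ = [
    "DvdlSeries",
    "WindowStats",
    "DegenerateSeriesError",
    "discard_equilibration",
    "statistical_inefficiency",
    "subsample_uncorrelated",
    "window_stats",
    "convergence_profile",
]

DEFAULT_EQUILIBRATION_FRACTION = 0.1


class DegenerateSeriesError(ValueError):
    """Raised for series too short or too uniform to carry statistics."""


@dataclass(frozen=True)
class DvdlSeries:
    """One λ window's ∂V/∂λ samples (kcal/mol), in simulation order."""

    lam: float
    samples: np.ndarray
    dt: float = 1.0  # time per sample; metadata only

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or len(samples) < 1:
            raise ValueError("a window series needs at least one sample")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"λ = {self.lam} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class WindowStats:
    """Summary of one window: mean ± SEM with inefficiency bookkeeping."""

    mean: float
    sem: float
    g: float
    n_eff: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.g < 1.0:
            raise ValueError("statistical inefficiency must be >= 1")
        if self.sem < 0.0:
            raise ValueError("SEM must be non-negative")


def discard_equilibration(
    series: DvdlSeries, fraction: float = DEFAULT_EQUILIBRATION_FRACTION
) -> DvdlSeries:
    """Drop the first ⌊fraction·N⌋ samples as equilibration transient."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"equilibration fraction must be in [0, 1), got {fraction}")
    n_drop = math.floor(fraction * len(series))
    if n_drop >= len(series):
        raise DegenerateSeriesError("discard would leave an empty series")
    return replace(series, samples=series.samples[n_drop:])


def statistical_inefficiency(samples) -> float:
    """Estimate g = 1 + 2·ΣC(t) from the sample autocovariance.

    The normalized autocovariance is computed by FFT and summed until
    its first crossing below zero — a simple, robust truncation at the
    series lengths used here.  Result is clamped to g ≥ 1.

    Raises :class:`DegenerateSeriesError` for constant or length-<2 input.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DegenerateSeriesError("need at least 2 samples to estimate g")
    n = len(x)
    dx = x - x.mean()
    var = np.dot(dx, dx) / n
    if var <= 0.0 or not np.isfinite(var):
        raise DegenerateSeriesError("zero-variance (constant) series")
    # biased autocovariance via FFT, normalized so C(0) = 1
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(dx, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    c = acov / var
    tail = c[1:]
    crossings = np.flatnonzero(tail <= 0.0)
    t_max = crossings[0] if len(crossings) else len(tail)
    g = 1.0 + 2.0 * tail[:t_max].sum()
    return max(g, 1.0)


def subsample_uncorrelated(series, g: float) -> np.ndarray:
    """Indices of an (approximately) uncorrelated subsample.

    Every ⌈g⌉-th frame starting from the first retained one; always at
    least one index.  ``series`` may be a DvdlSeries or a plain array.
    """
    if g < 1.0:
        raise ValueError("g must be >= 1")
    n = len(series)
    stride = math.ceil(g)
    return np.arange(0, n, stride)


def window_stats(
    series: DvdlSeries,
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> WindowStats:
    """Mean ± SEM of one window after equilibration discard.

    The mean uses every retained sample; the SEM comes from the variance
    (n−1 denominator) of the ⌈g⌉-strided subsample divided by the
    subsample size, which bakes the autocorrelation penalty into the
    error bar.
    """
    prod = discard_equilibration(series, equilibration_fraction)
    x = prod.samples
    if len(x) < 2:
        raise DegenerateSeriesError("fewer than 2 samples after discard")
    if np.ptp(x) == 0.0:
        # a constant window (e.g. a null transformation) has zero error
        return WindowStats(
            mean=float(x[0]), sem=0.0, g=1.0, n_eff=float(len(x)), n_samples=len(x)
        )
    g = statistical_inefficiency(x)
    idx = subsample_uncorrelated(x, g)
    sub = x[idx]
    if len(sub) > 1:
        sem = float(np.std(sub, ddof=1) / np.sqrt(len(sub)))
    else:
        sem = float(np.std(x, ddof=1) * np.sqrt(g / len(x)))
    return WindowStats(
        mean=float(x.mean()),
        sem=sem,
        g=float(g),
        n_eff=len(x) / g,
        n_samples=len(x),
    )


def _ddg_from_windows(
    complex_windows, apo_windows, schedule_complex, schedule_apo
) -> float:
    dg = {}
    for env, windows, sched in (
        ("complex", complex_windows, schedule_complex),
        ("apo", apo_windows, schedule_apo),
    ):
        means = [float(np.mean(w)) for w in windows]
        dg[env] = ti_integrate(sched, means)
    return dg["complex"] - dg["apo"]


def convergence_profile(
    complex_windows,
    apo_windows,
    schedule_complex: LambdaSchedule,
    schedule_apo: LambdaSchedule | None = None,
    n_chunks: int = 10,
    direction: str = "forward",
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> list[tuple[float, float]]:
    """ΔΔG as a function of accumulated simulation time.

    After per-window equilibration discard, ΔΔG is recomputed on
    cumulative prefixes (``direction="forward"``) or suffixes
    (``"reverse"``) covering fractions k/n_chunks of each window,
    k = 1..n_chunks.  A flat profile, and forward/reverse agreement,
    indicate a converged estimate.

    Returns a list of (time fraction, ΔΔG in kcal/mol).
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    if schedule_apo is None:
        schedule_apo = schedule_complex

    def production(series):
        return discard_equilibration(series, equilibration_fraction).samples

    cpx = [production(w) for w in complex_windows]
    apo = [production(w) for w in apo_windows]

    profile = []
    for k in range(1, n_chunks + 1):
        frac = k / n_chunks

        def segment(x, frac=frac):
            m = max(int(round(frac * len(x))), 1)
            if m < 2:
                raise DegenerateSeriesError(
                    "convergence chunk shorter than 2 samples"
                )
            return x[:m] if direction == "forward" else x[-m:]

        ddg = _ddg_from_windows(
            [segment(x) for x in cpx],
            [segment(x) for x in apo],
            schedule_complex,
            schedule_apo,
        )
        profile.append((frac, ddg))
    return profile
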