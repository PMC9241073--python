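"""Conformational-state analysis of a scalar side-chain descriptor.

Alchemical transformations started from a sparsely-visited side-chain
rotamer can converge to the wrong answer; the cure is to start from the
most populated conformational state.  This module finds the states of a
mutating residue from a 1-D descriptor time series — a distance (Å) or
a dihedral angle (degrees, periodic) — by histogramming: states are
maximal contiguous runs of occupied bins separated by empty bins, each
with an occupancy (fraction of frames) and a mode (center of its
fullest bin).  Sub-threshold states are merged into their nearest
neighbour, and a representative frame (value closest to the dominant
mode) is proposed as the transformation's starting structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DescriptorSeries",
    "ConfStateSummary",
    "histogram_states",
    "representative_frame",
    "dominant_state",
    "DEFAULT_DIHEDRAL_BINS",
    "DEFAULT_DISTANCE_BIN_WIDTH",
]

#: default histogram resolution: 72 bins (5°) for dihedrals, 0.2 Å for distances
DEFAULT_DIHEDRAL_BINS = 72
DEFAULT_DISTANCE_BIN_WIDTH = 0.2
DEFAULT_MIN_OCCUPANCY = 0.01


@dataclass(frozen=True)
class DescriptorSeries:
    """Ordered scalar descriptor values (Å, or degrees when periodic)."""

    values: np.ndarray
    periodic: bool = False
    period: float = 360.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) < 1:
            raise ValueError("descriptor series must hold at least one value")
        if self.periodic and self.period <= 0.0:
            raise ValueError("period must be positive for a periodic descriptor")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ConfStateSummary:
    """States with occupancies and modes, plus frame membership."""

    states: tuple  # of (label, occupancy, mode)
    dominant: str
    representative_index: int
    members: dict = field(compare=False, repr=False, default_factory=dict)

    def occupancy(self, label: str) -> float:
        for name, occ, _ in self.states:
            if name == label:
                return occ
        raise KeyError(f"no state labelled {label!r}")

    def mode(self, label: str) -> float:
        for name, _, mode in self.states:
            if name == label:
                return mode
        raise KeyError(f"no state labelled {label!r}")


def _circular_distance(a: float, b: float, period: float) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def histogram_states(
    series: DescriptorSeries,
    n_bins: int | None = None,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
) -> ConfStateSummary:
    """Split a descriptor distribution into conformational states.

    The histogram covers one period for periodic descriptors (default
    72 bins) or the data range at 0.2 Å resolution for distances.
    States are contiguous occupied-bin runs, wrapped across the
    boundary when periodic; runs below ``min_occupancy`` merge into the
    state with the nearest mode.  Labels ``state_1, state_2, …`` follow
    ascending mode value.
    """
    if not (0.0 <= min_occupancy < 0.5):
        raise ValueError("min_occupancy must lie in [0, 0.5)")
    x = series.values
    n = len(x)
    if series.periodic:
        period = series.period
        lo = -period / 2.0
        x = (x - lo) % period + lo
        if n_bins is None:
            n_bins = DEFAULT_DIHEDRAL_BINS
        if n_bins < 2:
            raise ValueError("need at least 2 bins")
        width = period / n_bins
    else:
        lo = float(x.min())
        span = float(x.max() - lo)
        if n_bins is None:
            n_bins = max(2, math.ceil(span / DEFAULT_DISTANCE_BIN_WIDTH))
            width = DEFAULT_DISTANCE_BIN_WIDTH
        else:
            if n_bins < 2:
                raise ValueError("need at least 2 bins")
            width = span / n_bins if span > 0.0 else 1.0

    bin_of = np.minimum(((x - lo) / width).astype(int), n_bins - 1)
    counts = np.bincount(bin_of, minlength=n_bins)

    # contiguous occupied runs
    occupied = counts > 0
    runs = []
    start = None
    for i in range(n_bins):
        if occupied[i] and start is None:
            start = i
        elif not occupied[i] and start is not None:
            runs.append(list(range(start, i)))
            start = None
    if start is not None:
        runs.append(list(range(start, n_bins)))
    if series.periodic and len(runs) > 1 and occupied[0] and occupied[-1]:
        runs[0] = runs.pop() + runs[0]  # wrap across ±period/2

    def center(b: int) -> float:
        c = lo + (b + 0.5) * width
        if series.periodic:
            c = (c - lo) % series.period + lo
        return c

    def run_mode(bins) -> float:
        best = max(bins, key=lambda b: (counts[b], -b))
        return center(best)

    states = [
        {"bins": set(r), "count": int(counts[list(r)].sum()), "mode": run_mode(r)}
        for r in runs
    ]

    # merge sub-threshold states into the mode-nearest neighbour
    while len(states) > 1:
        occ = [s["count"] / n for s in states]
        small = min(range(len(states)), key=lambda i: occ[i])
        if occ[small] >= min_occupancy:
            break
        others = [i for i in range(len(states)) if i != small]

        def dist(i):
            a, b = states[small]["mode"], states[i]["mode"]
            if series.periodic:
                return _circular_distance(a, b, series.period)
            return abs(a - b)

        host = min(others, key=dist)
        states[host]["bins"] |= states[small]["bins"]
        states[host]["count"] += states[small]["count"]
        merged_bins = states[host]["bins"]
        states[host]["mode"] = run_mode(sorted(merged_bins))
        del states[small]

    states.sort(key=lambda s: s["mode"])
    labelled = []
    members = {}
    for i, s in enumerate(states, start=1):
        label = f"state_{i}"
        labelled.append((label, s["count"] / n, s["mode"]))
        bin_set = np.zeros(n_bins, dtype=bool)
        bin_set[list(s["bins"])] = True
        members[label] = np.flatnonzero(bin_set[bin_of])

    dominant = max(labelled, key=lambda t: (t[1], -t[2]))[0]
    summary = ConfStateSummary(
        states=tuple(labelled),
        dominant=dominant,
        representative_index=0,
        members=members,
    )
    rep = representative_frame(series, summary, dominant)
    return ConfStateSummary(
        states=summary.states,
        dominant=dominant,
        representative_index=rep,
        members=members,
    )


def representative_frame(
    series: DescriptorSeries, summary: ConfStateSummary, state: str
) -> int:
    """Index of the frame whose value is nearest the state's mode.

    Ties resolve to the earliest frame.  Distances are circular for
    periodic descriptors.
    """
    if state not in summary.members:
        raise KeyError(f"no state labelled {state!r}")
    idx = summary.members[state]
    if len(idx) == 0:
        raise ValueError(f"state {state!r} has no member frames")
    mode = summary.mode(state)
    vals = series.values[idx]
    if series.periodic:
        d = np.abs(vals - mode) % series.period
        d = np.minimum(d, series.period - d)
    else:
        d = np.abs(vals - mode)
    return int(idx[np.argmin(d)])


def dominant_state(summary: ConfStateSummary) -> str:
    """Label of the most populated state; ties go to the lower mode."""
    if not summary.states:
        raise ValueError("summary holds no states")
    return max(summary.states, key=lambda t: (t[1], -t[2]))[0]
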