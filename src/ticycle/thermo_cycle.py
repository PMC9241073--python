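"""Thermodynamic-cycle combination of the two transformation legs.

A relative binding free energy exploits path independence: mutating the
GTPase in the effector-bound complex and in the unbound (apo) protein
closes a cycle, so

    ΔΔG_b = ΔG(complex leg) − ΔG(apo leg),
    σ²_ΔΔG = σ²_complex + σ²_apo.

Charge-changing mutations additionally need co-ion bookkeeping: the
simulation box's net charge must stay constant, so annealing a negative
side-chain charge converts a Na⁺ ion into a water molecule and creating
a positive charge does the same, while annealing a positive charge runs
the conversion in reverse.  Here the co-ion rule is planned and
validated as metadata; no solvated simulation is run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ti_core import FreeEnergyEstimate, LambdaSchedule, ti_error, ti_integrate
from .uncertainty import (
    DEFAULT_EQUILIBRATION_FRACTION,
    DvdlSeries,
    WindowStats,
    window_stats,
)

__all__ = [
    "SIDECHAIN_FORMAL_CHARGE",
    "CoionPlan",
    "TransformationLeg",
    "CycleResult",
    "residue_charge_delta",
    "plan_coion",
    "estimate_leg",
    "compute_cycle",
]

#: formal side-chain charge at pH 7 (histidine neutral by convention)
SIDECHAIN_FORMAL_CHARGE = {
    "ALA": 0, "ARG": +1, "ASN": 0, "ASP": -1, "CYS": 0,
    "GLN": 0, "GLU": -1, "GLY": 0, "HIS": 0, "ILE": 0,
    "LEU": 0, "LYS": +1, "MET": 0, "PHE": 0, "PRO": 0,
    "SER": 0, "THR": 0, "TRP": 0, "TYR": 0, "VAL": 0,
}

_COION_ACTIONS = ("none", "na_to_water", "water_to_na")


@dataclass(frozen=True)
class CoionPlan:
    """Counter-transformation keeping the box charge-neutral."""

    action: str
    protein_charge_delta: int

    def __post_init__(self) -> None:
        if self.action not in _COION_ACTIONS:
            raise ValueError(f"unknown co-ion action {self.action!r}")
        if (self.action == "none") != (self.protein_charge_delta == 0):
            raise ValueError(
                "co-ion action 'none' is valid exactly when the protein "
                f"charge change is 0 (got {self.action!r} with "
                f"Δq = {self.protein_charge_delta:+d})"
            )


@dataclass(frozen=True)
class TransformationLeg:
    """One environment's transformation: schedule, window stats, ΔG ± σ."""

    environment: str
    estimate: FreeEnergyEstimate
    schedule: LambdaSchedule
    window_stats: tuple

    def __post_init__(self) -> None:
        if self.environment not in ("complex", "apo"):
            raise ValueError(f"environment must be 'complex' or 'apo', got {self.environment!r}")
        if len(self.window_stats) != len(self.schedule):
            raise ValueError("one WindowStats entry required per schedule node")


@dataclass(frozen=True)
class CycleResult:
    """ΔΔG_b of one mutation with the two legs it came from."""

    mutation_label: str
    ddg: float
    sigma: float
    complex_leg: TransformationLeg
    apo_leg: TransformationLeg
    coion: CoionPlan


def residue_charge_delta(source_residue: str, target_residue: str) -> int:
    """Formal side-chain charge change (target − source) at pH 7."""
    charges = []
    for code in (source_residue, target_residue):
        key = code.upper()
        if key not in SIDECHAIN_FORMAL_CHARGE:
            raise KeyError(f"unknown residue code {code!r}")
        charges.append(SIDECHAIN_FORMAL_CHARGE[key])
    return charges[1] - charges[0]


def plan_coion(charge_delta: int) -> CoionPlan:
    """Pick the co-ion counter-transformation for a protein charge change.

    Creating a positive charge or annealing a negative one (Δq = +1)
    converts a Na⁺ ion into water; annealing a positive charge
    (Δq = −1) converts a water molecule into Na⁺.  |Δq| > 1 never
    arises for single mutations at fixed protonation and is rejected.
    """
    if charge_delta == 0:
        return CoionPlan(action="none", protein_charge_delta=0)
    if charge_delta == +1:
        return CoionPlan(action="na_to_water", protein_charge_delta=+1)
    if charge_delta == -1:
        return CoionPlan(action="water_to_na", protein_charge_delta=-1)
    raise ValueError(
        f"unsupported transformation: |Δq| = {abs(charge_delta)} > 1"
    )


def estimate_leg(
    environment: str,
    schedule: LambdaSchedule,
    windows: list[DvdlSeries],
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> TransformationLeg:
    """Run the per-window statistics and TI quadrature for one leg."""
    if len(windows) != len(schedule):
        raise ValueError(
            f"{environment} leg has {len(windows)} windows for a "
            f"{len(schedule)}-node schedule"
        )
    stats = tuple(window_stats(w, equilibration_fraction) for w in windows)
    dg = ti_integrate(schedule, [s.mean for s in stats])
    sigma = ti_error(schedule, [s.sem for s in stats])
    return TransformationLeg(
        environment=environment,
        estimate=FreeEnergyEstimate(delta_g=dg, sigma=sigma, n_windows=len(schedule)),
        schedule=schedule,
        window_stats=stats,
    )


def combine_legs(
    mutation_label: str,
    complex_leg: TransformationLeg,
    apo_leg: TransformationLeg,
    coion: CoionPlan | None = None,
) -> CycleResult:
    """Close the cycle: ΔΔG = ΔG_complex − ΔG_apo, errors in quadrature."""
    if complex_leg.environment != "complex" or apo_leg.environment != "apo":
        raise ValueError("legs must be tagged 'complex' and 'apo' respectively")
    ddg = complex_leg.estimate.delta_g - apo_leg.estimate.delta_g
    sigma = float(np.hypot(complex_leg.estimate.sigma, apo_leg.estimate.sigma))
    return CycleResult(
        mutation_label=mutation_label,
        ddg=ddg,
        sigma=sigma,
        complex_leg=complex_leg,
        apo_leg=apo_leg,
        coion=coion if coion is not None else plan_coion(0),
    )


def compute_cycle(manifest) -> CycleResult:
    """Full pipeline from a cycle manifest to ΔΔG_b ± σ.

    For each leg: read its schedule and window files, discard the
    equilibration fraction, compute per-window statistics, and integrate.
    The co-ion plan is derived from the mutation's residue codes unless
    the manifest overrides it.

    ``manifest`` is a :class:`~ticycle.io_formats.CycleManifest` (or any
    object with the same fields).
    """
    from .io_formats import read_dvdl_window, read_schedule

    legs = {}
    schedules = {}
    for spec in manifest.legs:
        schedule = read_schedule(spec.schedule_path)
        if len(spec.window_paths) != len(schedule):
            raise ValueError(
                f"{spec.environment} leg lists {len(spec.window_paths)} window "
                f"files for a {len(schedule)}-node schedule"
            )
        windows = [read_dvdl_window(p) for p in spec.window_paths]
        for node, w in zip(schedule.nodes, windows):
            if abs(w.lam - node) > 1e-6:
                raise ValueError(
                    f"window file λ = {w.lam} does not match schedule node {node}"
                )
        legs[spec.environment] = estimate_leg(
            spec.environment, schedule, windows, manifest.equilibration_fraction
        )
        schedules[spec.environment] = schedule
    if len(schedules) == 2 and len(schedules["complex"]) != len(schedules["apo"]):
        warnings.warn(
            "complex and apo legs use different schedules; ΔG per leg is "
            "schedule-local, proceeding",
            stacklevel=2,
        )

    delta = residue_charge_delta(manifest.source_residue, manifest.target_residue)
    policy = manifest.coion_policy
    if policy == "auto":
        coion = plan_coion(delta)
    elif policy == "none":
        if delta != 0:
            warnings.warn(
                f"coion_policy 'none' with a charge-changing mutation "
                f"(Δq = {delta:+d}); box neutrality will not hold",
                stacklevel=2,
            )
        coion = CoionPlan(action="none", protein_charge_delta=0)
    else:
        coion = CoionPlan(action=policy, protein_charge_delta=delta)

    return combine_legs(manifest.mutation_label, legs["complex"], legs["apo"], coion)
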