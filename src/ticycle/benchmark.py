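"""Experimental Kd benchmark for computed relative binding free energies.

Dissociation constants convert to binding free energies through
ΔG_b = RT·ln K_d, so a mutation's experimental relative binding free
energy is ΔΔG_b = RT·ln(K_d,mut / K_d,wt) — units of K_d cancel.  The
experimental uncertainty follows first-order propagation through the
log using the variant's K_d only: σ_ΔΔG = RT·σ_Kd/K_d.  "> x" bound
constants are converted at the bound value and flagged.

Against the CDC42/PAK1 mutant panel (16 interface mutations measured
by surface-plasmon-resonance-style equilibrium binding, wild-type
K_d = 20 ± 4 nM) these conversions feed mean-absolute-error and
Pearson-correlation summaries of any computed ΔΔG_b column: the final
alchemical estimates, the superseded initial ones, direct MM/GBSA, or
MM/GBSA alanine scanning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "BenchmarkRecord",
    "BenchmarkStats",
    "dg_from_kd",
    "ddg_exp",
    "ddg_exp_error",
    "mae",
    "pearson",
    "alanine_subset",
    "run_benchmark",
]

#: gas constant in kcal/(mol·K)
R_KCAL_PER_MOL_K = 1.9872e-3

#: conversion temperature reproducing the published experimental column
#: (standard conditions; the simulations themselves ran warmer)
DEFAULT_TEMPERATURE_K = 298.15

_WILDTYPE_LABELS = frozenset({"wild-type", "wildtype", "wt"})

#: computed-ΔΔG column selected by each benchmark method
_METHOD_ATTRS = {
    "alchemical": "ddg_comp",
    "initial": "ddg_initial",
    "mmgbsa": "ddg_mmgbsa",
    "alanine_scan": "ddg_alascan",
}


@dataclass(frozen=True)
class BenchmarkRecord:
    """One mutation's experimental K_d and computed ΔΔG_b columns.

    All energies kcal/mol, K_d in nM.  ``ddg_exp_printed`` is the
    published experimental value (kept separately because one row's
    printed value is inconsistent with its own K_d); ``ddg_exp`` /
    ``ddg_exp_sd`` are filled from K_d by :func:`run_benchmark`.
    Optional computed columns default to NaN when unreported.
    """

    mutation_label: str
    kd: float
    kd_sd: float | None = None
    kd_is_lower_bound: bool = False
    ddg_exp_printed: float = math.nan
    ddg_exp_printed_sd: float = math.nan
    ddg_comp: float = math.nan
    ddg_comp_sd: float = math.nan
    ddg_mmgbsa: float = math.nan
    ddg_mmgbsa_sd: float = math.nan
    ddg_alascan: float = math.nan
    ddg_alascan_sd: float = math.nan
    ddg_initial: float = math.nan
    ddg_initial_sd: float = math.nan
    ddg_initial_refined: float = math.nan
    ddg_initial_refined_sd: float = math.nan
    ddg_exp: float = math.nan
    ddg_exp_sd: float = math.nan

    def __post_init__(self) -> None:
        if not self.kd > 0.0:
            raise ValueError(f"{self.mutation_label}: K_d must be positive, got {self.kd}")
        if self.kd_is_lower_bound and self.kd_sd is not None:
            raise ValueError(
                f"{self.mutation_label}: a lower-bound K_d carries no standard deviation"
            )
        if self.kd_sd is not None and self.kd_sd < 0.0:
            raise ValueError(f"{self.mutation_label}: K_d standard deviation must be >= 0")

    @property
    def is_wildtype(self) -> bool:
        return self.mutation_label.lower() in _WILDTYPE_LABELS


@dataclass(frozen=True)
class BenchmarkStats:
    """Aggregate accuracy of one computed column against experiment."""

    n: int
    mae: float
    pearson_r: float | None
    subset_label: str

    def summary_line(self) -> str:
        """Printed-style summary: MAE to 1 decimal, r to 2."""
        r_txt = f"{self.pearson_r:.2f}" if self.pearson_r is not None else "n/a"
        return (
            f"{self.subset_label}: n={self.n}  MAE={self.mae:.1f} kcal/mol  r={r_txt}"
        )


def dg_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free energy ΔG_b = RT·ln K_d in kcal/mol (K_d in molar)."""
    if not kd > 0.0:
        raise ValueError(f"K_d must be positive, got {kd}")
    if not temperature > 0.0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL_PER_MOL_K * temperature * math.log(kd)


def ddg_exp(
    kd_mut: float, kd_wt: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Experimental ΔΔG_b = RT·ln(K_d,mut/K_d,wt); K_d units cancel."""
    if not (kd_mut > 0.0 and kd_wt > 0.0):
        raise ValueError("both K_d values must be positive")
    if not temperature > 0.0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL_PER_MOL_K * temperature * math.log(kd_mut / kd_wt)


def ddg_exp_error(
    kd: float, kd_sd: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """First-order error of RT·ln K_d: σ = RT·σ_Kd/K_d (variant only)."""
    if not kd > 0.0:
        raise ValueError(f"K_d must be positive, got {kd}")
    if kd_sd < 0.0:
        raise ValueError(f"K_d standard deviation must be >= 0, got {kd_sd}")
    return R_KCAL_PER_MOL_K * temperature * kd_sd / kd


def mae(pairs) -> float:
    """Mean absolute error of (experimental, computed) pairs, kcal/mol."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("MAE of an empty pair list is undefined")
    return float(np.mean(np.abs(arr[:, 1] - arr[:, 0])))


def pearson(pairs) -> float:
    """Sample Pearson correlation of (experimental, computed) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("Pearson correlation needs at least 2 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("Pearson correlation undefined for zero-variance data")
    return float(np.corrcoef(x, y)[0, 1])


def alanine_subset(records) -> list[BenchmarkRecord]:
    """The mutations-to-alanine subset (labels ending in 'A')."""
    return [
        r for r in records if not r.is_wildtype and r.mutation_label.endswith("A")
    ]


def _wildtype_kd(records) -> float:
    wt = [r for r in records if r.is_wildtype]
    if len(wt) != 1:
        raise ValueError(
            f"need exactly one wild-type reference row, found {len(wt)}"
        )
    return wt[0].kd


def run_benchmark(
    records,
    temperature: float = DEFAULT_TEMPERATURE_K,
    method: str = "alchemical",
    subset=None,
    include_wildtype: bool = False,
    use_printed_experimental: bool = True,
) -> tuple[BenchmarkStats, pd.DataFrame]:
    """Score one computed-ΔΔG column against the K_d-derived experiment.

    Fills ``ddg_exp``/``ddg_exp_sd`` from K_d relative to the wild-type
    row (bound K_d values are converted at the bound and flagged), then
    computes MAE and Pearson r over every record carrying the selected
    method's estimate.  By default the published experimental value is
    preferred where available (``use_printed_experimental``) and the
    wild-type self-transformation is excluded from the statistics.

    ``subset`` is either an iterable of mutation labels or the string
    ``"alanine"``.  Returns (stats, scatter-ready per-record table).
    """
    if method not in _METHOD_ATTRS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHOD_ATTRS)}")
    records = list(records)
    kd_wt = _wildtype_kd(records)

    filled = []
    for rec in records:
        exp = ddg_exp(rec.kd, kd_wt, temperature)
        exp_sd = (
            ddg_exp_error(rec.kd, rec.kd_sd, temperature)
            if rec.kd_sd is not None
            else math.nan
        )
        filled.append(replace(rec, ddg_exp=exp, ddg_exp_sd=exp_sd))

    if subset == "alanine":
        keep = {r.mutation_label for r in alanine_subset(filled)}
        subset_label = f"{method}/alanine"
    elif subset is not None:
        keep = set(subset)
        subset_label = f"{method}/custom"
    else:
        keep = {r.mutation_label for r in filled}
        subset_label = f"{method}/all"

    attr = _METHOD_ATTRS[method]
    pairs = []
    rows = []
    for rec in filled:
        comp = getattr(rec, attr)
        if method == "initial" and math.isnan(comp):
            comp = rec.ddg_comp  # only four estimates were superseded
        exp_used = (
            rec.ddg_exp_printed
            if use_printed_experimental and not math.isnan(rec.ddg_exp_printed)
            else rec.ddg_exp
        )
        scorable = (
            rec.mutation_label in keep
            and not math.isnan(comp)
            and (include_wildtype or not rec.is_wildtype)
        )
        rows.append(
            {
                "mutation": rec.mutation_label,
                "kd_nM": rec.kd,
                "kd_is_lower_bound": rec.kd_is_lower_bound,
                "ddg_exp_kcal": exp_used,
                "ddg_exp_kd_derived_kcal": rec.ddg_exp,
                "ddg_exp_sd_kcal": rec.ddg_exp_sd,
                "ddg_comp_kcal": comp,
                "in_statistics": scorable,
            }
        )
        if scorable:
            pairs.append((exp_used, comp))

    if not pairs:
        raise ValueError("no scorable records for the requested method/subset")

    mae_val = mae(pairs)
    try:
        r_val = pearson(pairs)
    except ValueError as err:
        warnings.warn(f"Pearson r omitted: {err}", stacklevel=2)
        r_val = None
    stats = BenchmarkStats(
        n=len(pairs), mae=mae_val, pearson_r=r_val, subset_label=subset_label
    )
    return stats, pd.DataFrame(rows)
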