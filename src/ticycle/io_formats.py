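"""On-disk formats: schedules, ∂V/∂λ windows, manifests, benchmark tables.

All files are hand-editable plain text.  Energies are kcal/mol and
temperatures kelvin everywhere on disk; no unit autodetection.  Readers
reject malformed input (naming the offending line) rather than silently
repairing it, and numeric round trips preserve full float precision.

Formats
-------
schedule (TSV)      two columns ``lambda  weight``; ``#`` comments.
window (TSV)        header ``# lambda=<float>`` then two columns
                    ``step_or_time  dvdl``.
cycle manifest      YAML mirroring :class:`CycleManifest`; window paths
                    are resolved relative to the manifest file.
benchmark table     CSV with header; typographic minus signs ("–", "−")
                    are normalized to ASCII on read.
results             JSON key/value document, re-readable.
"""

from __future__ import annotations

import io as _stdio
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmark import BenchmarkRecord, BenchmarkStats
from .ti_core import LambdaSchedule
from .uncertainty import DEFAULT_EQUILIBRATION_FRACTION, DvdlSeries

__all__ = [
    "FormatError",
    "LegSpec",
    "CycleManifest",
    "read_schedule",
    "write_schedule",
    "read_dvdl_window",
    "write_dvdl_window",
    "extract_dvdl_from_engine_log",
    "read_manifest",
    "read_benchmark_table",
    "load_table1",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """A file violates its expected on-disk dialect."""

    def __init__(self, path, message: str, line: int | None = None):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


# ---------------------------------------------------------------------------
# Cycle manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LegSpec:
    """One transformation environment: its schedule and window files."""

    environment: str
    schedule_path: Path
    window_paths: tuple

    def __post_init__(self) -> None:
        if self.environment not in ("complex", "apo"):
            raise ValueError(
                f"leg environment must be 'complex' or 'apo', got {self.environment!r}"
            )
        if len(self.window_paths) < 1:
            raise ValueError(f"{self.environment} leg lists no window files")


@dataclass(frozen=True)
class CycleManifest:
    """Everything needed to compute one mutation's ΔΔG_b cycle."""

    mutation_label: str
    position: int
    source_residue: str
    target_residue: str
    legs: tuple
    temperature: float = 303.0
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION
    coion_policy: str = "auto"

    def __post_init__(self) -> None:
        envs = sorted(leg.environment for leg in self.legs)
        if envs != ["apo", "complex"]:
            raise ValueError(
                f"manifest needs exactly one 'complex' and one 'apo' leg, got {envs}"
            )
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive (kelvin)")


def read_manifest(path) -> CycleManifest:
    """Read a YAML cycle manifest; leg paths resolve relative to it."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise FormatError(path, f"invalid YAML: {err}") from err
    if not isinstance(doc, dict):
        raise FormatError(path, "manifest must be a YAML mapping")
    base = path.parent
    try:
        legs = []
        for env, spec in doc["legs"].items():
            legs.append(
                LegSpec(
                    environment=env,
                    schedule_path=base / spec["schedule"],
                    window_paths=tuple(base / w for w in spec["windows"]),
                )
            )
        return CycleManifest(
            mutation_label=str(doc["mutation_label"]),
            position=int(doc["position"]),
            source_residue=str(doc["source_residue"]).upper(),
            target_residue=str(doc["target_residue"]).upper(),
            legs=tuple(legs),
            temperature=float(doc.get("temperature", 303.0)),
            equilibration_fraction=float(
                doc.get("equilibration_fraction", DEFAULT_EQUILIBRATION_FRACTION)
            ),
            coion_policy=str(doc.get("coion_policy", "auto")),
        )
    except (KeyError, TypeError, ValueError) as err:
        raise FormatError(path, f"bad manifest field: {err}") from err


# ---------------------------------------------------------------------------
# λ schedules
# ---------------------------------------------------------------------------


def read_schedule(path) -> LambdaSchedule:
    """Read a two-column (λ, weight) schedule file."""
    path = Path(path)
    nodes, weights = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(
                path, f"expected 'lambda weight', got {raw!r}", line=lineno
            )
        try:
            lam, w = float(parts[0]), float(parts[1])
        except ValueError:
            raise FormatError(path, f"non-numeric entry in {raw!r}", line=lineno)
        if nodes and lam <= nodes[-1]:
            raise FormatError(
                path, f"λ values must increase strictly ({nodes[-1]} → {lam})",
                line=lineno,
            )
        nodes.append(lam)
        weights.append(w)
    if not nodes:
        raise FormatError(path, "schedule file contains no data lines")
    try:
        return LambdaSchedule(nodes=np.array(nodes), weights=np.array(weights))
    except ValueError as err:
        raise FormatError(path, str(err)) from err


def write_schedule(schedule: LambdaSchedule, path) -> None:
    path = Path(path)
    lines = ["# lambda\tweight"]
    for lam, w in zip(schedule.nodes, schedule.weights):
        lines.append(f"{lam:.17g}\t{w:.17g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ∂V/∂λ window files
# ---------------------------------------------------------------------------

_LAMBDA_HEADER = re.compile(r"^#\s*lambda\s*=\s*([0-9.eE+-]+)\s*$")


def read_dvdl_window(path) -> DvdlSeries:
    """Read one window file: ``# lambda=<float>`` header, then samples."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(path, "empty file")
    m = _LAMBDA_HEADER.match(lines[0])
    if m is None:
        raise FormatError(
            path, f"first line must be '# lambda=<float>', got {lines[0]!r}", line=1
        )
    lam = float(m.group(1))
    times, values = [], []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(
                path, f"expected 'time dvdl', got {raw!r}", line=lineno
            )
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError:
            raise FormatError(path, f"non-numeric sample in {raw!r}", line=lineno)
    if not values:
        raise FormatError(path, "window file has a header but no samples")
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    return DvdlSeries(lam=lam, samples=np.array(values), dt=dt)


def write_dvdl_window(series: DvdlSeries, path) -> None:
    path = Path(path)
    lines = [f"# lambda={series.lam:.17g}"]
    for i, v in enumerate(series.samples):
        lines.append(f"{i * series.dt:.17g}\t{v:.17g}")
    path.write_text("\n".join(lines) + "\n")


_NUMBER = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def extract_dvdl_from_engine_log(path, skip_trailing: int = 0, lam: float | None = None) -> DvdlSeries:
    """Pull ∂V/∂λ samples out of an MD-engine text log.

    Takes the last numeric field of every line containing the literal
    token ``DV/DL``, in file order.  ``skip_trailing`` drops that many
    final matches (engine logs often end with average/RMS summary
    blocks that repeat the token).  The window's λ is taken from a
    ``lambda = <float>`` line when present, else from the ``lam``
    argument, else 0.
    """
    path = Path(path)
    values = []
    detected_lam = None
    for raw in path.read_text().splitlines():
        if detected_lam is None:
            m = re.search(r"\blambda\s*=\s*([0-9.]+)", raw, flags=re.IGNORECASE)
            if m:
                detected_lam = float(m.group(1))
        if "DV/DL" in raw:
            nums = _NUMBER.findall(raw.split("DV/DL", 1)[1])
            if nums:
                values.append(float(nums[-1]))
    if skip_trailing:
        values = values[: len(values) - skip_trailing]
    if not values:
        raise FormatError(path, "no DV/DL samples found")
    if lam is None:
        lam = detected_lam if detected_lam is not None else 0.0
    return DvdlSeries(lam=lam, samples=np.array(values))


# ---------------------------------------------------------------------------
# Benchmark tables
# ---------------------------------------------------------------------------

_MANDATORY_BENCH_COLS = ("mutation", "kd_nM", "kd_sd_nM", "kd_is_lower_bound")

#: CSV column → BenchmarkRecord field for the optional energy columns
_BENCH_ENERGY_COLS = {
    "ddg_exp_printed_kcal": "ddg_exp_printed",
    "ddg_exp_printed_sd_kcal": "ddg_exp_printed_sd",
    "ddg_comp_kcal": "ddg_comp",
    "ddg_comp_sd_kcal": "ddg_comp_sd",
    "ddg_mmgbsa_kcal": "ddg_mmgbsa",
    "ddg_mmgbsa_sd_kcal": "ddg_mmgbsa_sd",
    "ddg_alascan_kcal": "ddg_alascan",
    "ddg_alascan_sd_kcal": "ddg_alascan_sd",
    "ddg_initial_kcal": "ddg_initial",
    "ddg_initial_sd_kcal": "ddg_initial_sd",
    "ddg_initial_refined_kcal": "ddg_initial_refined",
    "ddg_initial_refined_sd_kcal": "ddg_initial_refined_sd",
}

_TRUE_TOKENS = {"true", "1", "yes"}
_FALSE_TOKENS = {"false", "0", "no", ""}


def read_benchmark_table(path) -> list[BenchmarkRecord]:
    """Read a benchmark CSV into one :class:`BenchmarkRecord` per row."""
    path = Path(path)
    text = path.read_text().replace("–", "-").replace("−", "-")
    try:
        df = pd.read_csv(_stdio.StringIO(text), dtype=str, keep_default_na=False)
    except pd.errors.ParserError as err:
        raise FormatError(path, f"unparsable CSV: {err}") from err
    missing = [c for c in _MANDATORY_BENCH_COLS if c not in df.columns]
    if missing:
        raise FormatError(path, f"missing mandatory column(s): {', '.join(missing)}")

    records = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        label = row["mutation"].strip()
        if not label:
            raise FormatError(path, "empty mutation label", line=lineno)
        flag_txt = row["kd_is_lower_bound"].strip().lower()
        if flag_txt in _TRUE_TOKENS:
            is_bound = True
        elif flag_txt in _FALSE_TOKENS:
            is_bound = False
        else:
            raise FormatError(
                path, f"bad kd_is_lower_bound value {row['kd_is_lower_bound']!r}",
                line=lineno,
            )
        try:
            kd = float(row["kd_nM"])
        except ValueError:
            raise FormatError(path, f"non-numeric kd_nM {row['kd_nM']!r}", line=lineno)
        sd_txt = row["kd_sd_nM"].strip()
        kd_sd = None if sd_txt == "" else float(sd_txt)
        kwargs = {}
        for col, attr in _BENCH_ENERGY_COLS.items():
            if col in df.columns:
                txt = row[col].strip()
                if txt:
                    try:
                        kwargs[attr] = float(txt)
                    except ValueError:
                        raise FormatError(
                            path, f"non-numeric {col} value {txt!r}", line=lineno
                        )
        try:
            records.append(
                BenchmarkRecord(
                    mutation_label=label,
                    kd=kd,
                    kd_sd=kd_sd,
                    kd_is_lower_bound=is_bound,
                    **kwargs,
                )
            )
        except ValueError as err:
            raise FormatError(path, str(err), line=lineno) from err
    if not records:
        raise FormatError(path, "benchmark table has no data rows")
    return records


def load_table1() -> list[BenchmarkRecord]:
    """The packaged CDC42/PAK1 mutant benchmark table (17 rows)."""
    with resources.as_file(
        resources.files("ticycle").joinpath("data/table1.csv")
    ) as p:
        return read_benchmark_table(p)


# ---------------------------------------------------------------------------
# Results documents
# ---------------------------------------------------------------------------


def _leg_payload(leg) -> dict:
    return {
        "environment": leg.environment,
        "delta_g_kcal": leg.estimate.delta_g,
        "sigma_kcal": leg.estimate.sigma,
        "n_windows": leg.estimate.n_windows,
        "lambdas": [float(x) for x in leg.schedule.nodes],
        "weights": [float(x) for x in leg.schedule.weights],
        "window_stats": [
            {
                "mean": s.mean,
                "sem": s.sem,
                "g": s.g,
                "n_eff": s.n_eff,
                "n_samples": s.n_samples,
            }
            for s in leg.window_stats
        ],
    }


def write_results(result, path, convergence: dict | None = None) -> None:
    """Serialize a cycle result or benchmark summary as re-readable JSON.

    ``convergence`` may carry ``{"forward": [...], "reverse": [...]}``
    profiles of (time fraction, ΔΔG) pairs to embed alongside a cycle
    result.
    """
    from .thermo_cycle import CycleResult  # local import avoids a cycle

    path = Path(path)
    if isinstance(result, CycleResult):
        doc = {
            "kind": "cycle_result",
            "mutation_label": result.mutation_label,
            "ddg_kcal": result.ddg,
            "sigma_kcal": result.sigma,
            "coion": {
                "action": result.coion.action,
                "protein_charge_delta": result.coion.protein_charge_delta,
            },
            "legs": [
                _leg_payload(result.complex_leg),
                _leg_payload(result.apo_leg),
            ],
            "convergence": {
                direction: [[float(f), float(d)] for f, d in profile]
                for direction, profile in (convergence or {}).items()
            },
        }
    elif isinstance(result, BenchmarkStats):
        doc = {
            "kind": "benchmark_stats",
            "subset_label": result.subset_label,
            "n": result.n,
            "mae_kcal": result.mae,
            "pearson_r": result.pearson_r,
            "summary": result.summary_line(),
        }
    else:
        raise TypeError(
            f"write_results accepts CycleResult or BenchmarkStats, got {type(result).__name__}"
        )
    path.write_text(json.dumps(doc, indent=2) + "\n")


def read_results(path) -> dict:
    """Read back a :func:`write_results` document as a plain dict."""
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise FormatError(path, f"invalid JSON: {err}") from err
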