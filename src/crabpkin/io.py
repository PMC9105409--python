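"""File formats, run configuration and fit reports.

Formats are deliberately plain: velocity tables and fluorescence traces
are CSV, run configuration is TOML with explicit unit suffixes
(``_nM``, ``_uM``, ``_per_min``), and reports are JSON.  Unit suffixes are
mandatory in the config because the source assays mix µM protein stocks
with nM dissociation constants, and silent unit mistakes are the dominant
failure mode in this kind of analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .enzyme_kinetics import VelocityDataset
from .errors import TableFormatError
from .presets import BINDERS, ENZYMES
from .stoppedflow import FluorescenceTrace

__all__ = [
    "read_velocity_table",
    "write_velocity_table",
    "read_trace_csv",
    "write_trace_csv",
    "read_trace_manifest",
    "RunConfig",
    "FitReport",
    "load_config",
]

_REQUIRED_COLUMNS = ("substrate_nM", "velocity_pmol_min_pmol")
_OPTIONAL_COLUMNS = (
    "replicate",
    "axis",
    "design",
    "total_atra_nM",
    "binder",
)


def read_velocity_table(
    path: str | Path,
    *,
    enzyme_total: float = 0.5,
    binder_kd: float | None = None,
) -> VelocityDataset:
    """Read a velocity table CSV into a :class:`VelocityDataset`.

    Required columns: ``substrate_nM``, ``velocity_pmol_min_pmol``.
    Optional: ``replicate``, ``axis``, ``design``, ``total_atra_nM``,
    ``binder``.  Metadata columns must be constant within a file.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise TableFormatError(f"{path}: table is empty")
    if (df["substrate_nM"] < 0).any():
        raise TableFormatError(f"{path}: negative substrate concentrations")

    def _const(col: str, default):
        if col in df.columns:
            vals = df[col].dropna().unique()
            if len(vals) > 1:
                raise TableFormatError(f"{path}: column {col!r} must be constant")
            if len(vals) == 1:
                return vals[0]
        return default

    replicate = df["replicate"].to_numpy() if "replicate" in df.columns else None
    if replicate is not None:
        dup = df.duplicated(subset=["substrate_nM", "replicate"])
        if dup.any():
            pairs = df.loc[dup, ["substrate_nM", "replicate"]].to_records(index=False)
            raise TableFormatError(
                f"{path}: duplicate (substrate, replicate) rows: {list(pairs)[:5]}"
            )
    axis = str(_const("axis", "total_atRA"))
    design = str(_const("design", "saturation"))
    total_atra = _const("total_atra_nM", None)
    binder = _const("binder", None)
    return VelocityDataset(
        substrate_axis=axis,  # type: ignore[arg-type]
        substrate=df["substrate_nM"].to_numpy(dtype=float),
        velocity=df["velocity_pmol_min_pmol"].to_numpy(dtype=float),
        enzyme_total=enzyme_total,
        binder_kd=binder_kd,
        replicate=replicate,
        design=design,  # type: ignore[arg-type]
        total_atra=float(total_atra) if total_atra is not None else None,
        binder=str(binder) if binder is not None else None,
    )


def write_velocity_table(data: VelocityDataset, path: str | Path) -> None:
    """Write a dataset in the CSV dialect :func:`read_velocity_table` reads."""
    df = pd.DataFrame(
        {
            "substrate_nM": data.substrate,
            "velocity_pmol_min_pmol": data.velocity,
        }
    )
    if data.replicate is not None:
        df["replicate"] = data.replicate
    df["axis"] = data.substrate_axis
    df["design"] = data.design
    if data.total_atra is not None:
        df["total_atra_nM"] = data.total_atra
    if data.binder is not None:
        df["binder"] = data.binder
    df.to_csv(path, index=False)


def read_trace_csv(
    path: str | Path, *, mixed_binder_total: float, mixed_ligand_total: float
) -> FluorescenceTrace:
    """Read one injection trace (columns ``time_s``, ``fluorescence``)."""
    df = pd.read_csv(path)
    for col in ("time_s", "fluorescence"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(dtype=float),
        signal=df["fluorescence"].to_numpy(dtype=float),
        mixed_binder_total=mixed_binder_total,
        mixed_ligand_total=mixed_ligand_total,
    )


def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "fluorescence": trace.signal}).to_csv(
        path, index=False
    )


def read_trace_manifest(path: str | Path) -> list[FluorescenceTrace]:
    """Read a TOML manifest listing injection files with mixed totals.

    Layout::

        binder_total_nM = 500.0
        ligand_total_nM = 2000.0
        files = ["inj1.csv", "inj2.csv"]
    """
    path = Path(path)
    with open(path, "rb") as fh:
        manifest = tomllib.load(fh)
    for key in ("binder_total_nM", "ligand_total_nM", "files"):
        if key not in manifest:
            raise TableFormatError(f"{path}: manifest missing key {key!r}")
    return [
        read_trace_csv(
            path.parent / f,
            mixed_binder_total=float(manifest["binder_total_nM"]),
            mixed_ligand_total=float(manifest["ligand_total_nM"]),
        )
        for f in manifest["files"]
    ]


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_KEYS = {
    "seed",
    "binder",
    "enzyme",
    "enzyme_km_nM",
    "enzyme_kcat_per_min",
    "binder_kd_nM",
    "enzyme_total_nM",
    "noise_cv",
    "fluorescence_noise_frac",
    "stages",
    "n_sf_experiments",
    "n_injections",
    "n_replicates",
}

_STAGES = ("binding", "kinetics", "freedrug", "ppi")


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration.

    Enzyme constants may come from a named preset (``CYP3A4``, ``CYP2C8``,
    ``CYP26A1``) or be given explicitly; binder constants (K_d and the
    stopped-flow rate constants) come from the ``CRABP1``/``CRABP2``
    presets or an explicit ``binder_kd_nM``.
    """

    seed: int = 0
    binder: str | None = "CRABP1"
    enzyme: str | None = "CYP26A1"
    enzyme_km_nM: float | None = None
    enzyme_kcat_per_min: float | None = None
    binder_kd_nM: float | None = None
    enzyme_total_nM: float = 0.5
    noise_cv: float = 0.05
    fluorescence_noise_frac: float = 0.02
    stages: tuple[str, ...] = _STAGES
    n_sf_experiments: int = 3
    n_injections: int = 5
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in _STAGES:
                raise ValueError(f"unknown stage {stage!r}; valid: {_STAGES}")
        if self.enzyme is not None and self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme preset {self.enzyme!r}")
        if self.binder is not None and self.binder not in BINDERS:
            raise ValueError(f"unknown binder preset {self.binder!r}")
        if self.enzyme is None and (
            self.enzyme_km_nM is None or self.enzyme_kcat_per_min is None
        ):
            raise ValueError("custom enzyme requires enzyme_km_nM and enzyme_kcat_per_min")
        if "ppi" in self.stages and self.binder is None and self.binder_kd_nM is None:
            raise ValueError(
                "the PPI stage needs a K_d source: a binder preset or binder_kd_nM"
            )
        if self.enzyme_total_nM <= 0:
            raise ValueError("enzyme_total_nM must be > 0")

    @property
    def km_nM(self) -> float:
        if self.enzyme_km_nM is not None:
            return self.enzyme_km_nM
        return ENZYMES[self.enzyme].km_nM

    @property
    def kcat_per_min(self) -> float:
        if self.enzyme_kcat_per_min is not None:
            return self.enzyme_kcat_per_min
        return ENZYMES[self.enzyme].kcat_per_min

    @property
    def kd_nM(self) -> float:
        if self.binder_kd_nM is not None:
            return self.binder_kd_nM
        if self.binder is None:
            raise ValueError("no K_d source configured")
        return BINDERS[self.binder].kd_nM


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration; unknown keys rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# reports


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


@dataclass
class FitReport:
    """Serializable record of one pipeline stage."""

    stage: str
    parameters: dict[str, Any]
    fixed: dict[str, Any] = field(default_factory=dict)
    diagnostics: dict[str, Any] = field(default_factory=dict)
    settings: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    input_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(_jsonify(dataclasses.asdict(self)), **kwargs)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(indent=2) + "\n")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
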