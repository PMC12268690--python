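"""Shared readers/writers, run manifests and the pipeline driver.

File dialects:

* tables — CSV with unit-suffixed headers (``temperature_K``,
  ``solubility_mol_per_L``, ``concentration_mM``, ``velocity_nm_s`` ...);
  the suffix is authoritative and mM columns are converted to mol/L on
  request, never silently;
* height maps — plain-text grids with ``#`` header lines
  (``# rows= cols= pixel_size_nm= time_s=``) followed by
  whitespace-delimited heights in nm, one file per frame.
"""
from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError, SchemaError

__all__ = [
    "read_table",
    "write_table",
    "read_heightmap",
    "write_heightmap",
    "read_heightmap_series",
    "RunManifest",
    "run_pipeline",
]


def read_table(path: str | Path, expected_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally enforcing the leading header columns."""
    df = pd.read_csv(path)
    if expected_columns is not None:
        found = list(df.columns[: len(expected_columns)])
        if found != list(expected_columns):
            raise SchemaError(
                f"header mismatch in {path}: expected {list(expected_columns)}, found {found}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


_UNIT_FACTORS = {"mM": 1e-3, "mol_per_L": 1.0, "M": 1.0}


def column_in_mol_per_L(df: pd.DataFrame, stem: str) -> np.ndarray:
    """Return a concentration column in mol/L, honoring its unit suffix.

    Accepts ``<stem>_mM``, ``<stem>_mol_per_L`` or ``<stem>_M``.
    """
    for suffix, factor in _UNIT_FACTORS.items():
        name = f"{stem}_{suffix}"
        if name in df.columns:
            return df[name].to_numpy(dtype=float) * factor
    raise SchemaError(
        f"no column '{stem}_<unit>' with a recognized unit suffix "
        f"({', '.join(_UNIT_FACTORS)}) in {list(df.columns)}"
    )


def write_heightmap(
    frame: np.ndarray, path: str | Path, pixel_size_nm: float, time_s: float = 0.0
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows, cols = frame.shape
    header = f"# rows={rows} cols={cols} pixel_size_nm={pixel_size_nm!r} time_s={time_s!r}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, frame, fmt="%.17g")
    return path


_HEADER_RE = re.compile(
    r"#\s*rows=(\d+)\s+cols=(\d+)\s+pixel_size_nm=([\d.eE+-]+)\s+time_s=([\d.eE+-]+)"
)


def read_heightmap(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read one frame; returns (grid, pixel_size_nm, time_s)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        m = _HEADER_RE.match(first)
        if m is None:
            raise ParseError(f"missing or malformed header line in {path}: {first!r}")
        rows, cols = int(m.group(1)), int(m.group(2))
        pixel_size, time_s = float(m.group(3)), float(m.group(4))
        values: list[list[float]] = []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            row = [float(tok) for tok in line.split()]
            if values and len(row) != len(values[0]):
                raise ParseError(f"ragged row at line {ln} of {path}")
            values.append(row)
    grid = np.array(values, dtype=float)
    if grid.shape != (rows, cols):
        raise ParseError(
            f"grid shape {grid.shape} does not match header ({rows}, {cols}) in {path}"
        )
    return grid, pixel_size, time_s


def read_heightmap_series(directory: str | Path):
    """Read every ``*.txt`` frame in a directory, ordered by time."""
    from .tracking import HeightMapSeries

    paths = sorted(Path(directory).glob("*.txt"))
    if not paths:
        raise ParseError(f"no frame files in {directory}")
    loaded = [read_heightmap(p) for p in paths]
    loaded.sort(key=lambda x: x[2])
    pixel_sizes = {x[1] for x in loaded}
    if len(pixel_sizes) > 1:
        raise ParseError(f"inconsistent pixel sizes across frames: {pixel_sizes}")
    return HeightMapSeries(
        frames=tuple(x[0] for x in loaded),
        pixel_size=loaded[0][1],
        timestamps=tuple(x[2] for x in loaded),
        metadata={"source": str(directory)},
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Append-only provenance record of a pipeline run."""

    tool_version: str = __version__
    subcommand: str = ""
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stages: list = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def record_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs.append({"path": str(p), "sha256": _sha256(p)})

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "tool_version": self.tool_version,
            "subcommand": self.subcommand,
            "config": self.config,
            "seeds": self.seeds,
            "input_hashes": self.input_hashes,
            "outputs": self.outputs,
            "stages": self.stages,
            "started": self.started,
            "finished": time.time(),
        }
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_synth_solubility(params: dict, ctx: dict, out_dir: Path) -> dict:
    from .synth import gen_solubility

    points, manifest = gen_solubility(**params)
    df = pd.DataFrame(
        {
            "temperature_K": [p.temperature for p in points],
            "solubility_mol_per_L": [p.solubility for p in points],
            "sd": [p.uncertainty if p.uncertainty is not None else 0.0 for p in points],
        }
    )
    path = write_table(df, out_dir / "solubility.csv")
    ctx["solubility_csv"] = path
    return {"truth": manifest, "rows": len(df)}


def _stage_fit_vant_hoff(params: dict, ctx: dict, out_dir: Path) -> dict:
    from .thermo import SolubilityPoint, fit_vant_hoff

    df = read_table(ctx["solubility_csv"], ["temperature_K", "solubility_mol_per_L"])
    pts = [
        SolubilityPoint(t, s, u if u > 0 else None)
        for t, s, u in zip(
            df["temperature_K"], df["solubility_mol_per_L"], df.get("sd", pd.Series([0.0] * len(df)))
        )
    ]
    fit = fit_vant_hoff(pts, **params)
    report = {
        "enthalpy_J_per_mol": fit.enthalpy,
        "entropy_J_per_mol_K": fit.entropy,
        "enthalpy_se": fit.enthalpy_se,
        "entropy_se": fit.entropy_se,
        "gibbs_298_J_per_mol": fit.gibbs(298.15),
        "r_squared": fit.r_squared,
    }
    (out_dir / "vant_hoff.json").write_text(json.dumps(report, indent=2))
    ctx["vant_hoff"] = report
    return report


def _stage_synth_vc(params: dict, ctx: dict, out_dir: Path) -> dict:
    from .synth import gen_vc

    data, manifest = gen_vc(**params)
    df = pd.DataFrame(
        {
            "concentration_mM": np.asarray(data.concentrations) * 1e3,
            "velocity_nm_s": data.velocities,
        }
    )
    path = write_table(df, out_dir / "vc.csv")
    ctx["vc_csv"] = path
    ctx["vc_Ce"] = data.Ce
    return {"truth": manifest}


def _stage_fit_kinetics(params: dict, ctx: dict, out_dir: Path) -> dict:
    from .kinetics import VCDataset, fit_linear_bcf, fit_kink_limited, fit_power_law, select_model

    df = read_table(ctx["vc_csv"], ["concentration_mM", "velocity_nm_s"])
    data = VCDataset.from_arrays(
        column_in_mol_per_L(df, "concentration"), df["velocity_nm_s"], ctx["vc_Ce"]
    )
    fits = [fit_linear_bcf(data), fit_power_law(data), fit_kink_limited(data)]
    ranking = select_model(fits)
    report = {
        "ranking": [
            {"model": f.model, "beta": f.beta, "order_m": f.order_m, "delta_aicc": d}
            for f, d in ranking
        ]
    }
    (out_dir / "kinetics.json").write_text(json.dumps(report, indent=2))
    ctx["kinetics"] = report
    return report


_STAGES: dict[str, Callable[[dict, dict, Path], dict]] = {
    "synth_solubility": _stage_synth_solubility,
    "fit_vant_hoff": _stage_fit_vant_hoff,
    "synth_vc": _stage_synth_vc,
    "fit_kinetics": _stage_fit_kinetics,
}


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute an ordered stage list with inter-stage file contracts.

    ``config`` is ``{"stages": [{"name": ..., "params": {...}}, ...]}``.
    Failures are re-raised as :class:`StageError` naming the stage.  An
    empty stage list yields an empty (but valid) manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(subcommand="pipeline", config=config)
    ctx: dict = {}
    for stage in config.get("stages", []):
        name = stage["name"]
        if name not in _STAGES:
            raise StageError(name, KeyError(f"unknown stage {name!r}"))
        params = dict(stage.get("params", {}))
        if "seed" in params:
            manifest.seeds[name] = params["seed"]
        try:
            summary = _STAGES[name](params, ctx, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage attribution
            raise StageError(name, exc) from exc
        manifest.stages.append({"name": name, "summary": summary})
    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.record_output(p)
    manifest.write(out / "manifest.json")
    return manifest
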