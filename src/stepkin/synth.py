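"""Seeded generators emulating every measured input of the study.

Each generator is a pure function of (parameters, seed) — reruns are
bit-identical — and returns both the synthetic dataset and a ground-truth
manifest used by recovery tests.  The defaults mimic the scales of the real
measurements (solubility ≈ 13.5 mM at 25 °C, step velocities 0.1–10 nm/s,
step risers 2.413/1.2065 nm, UV series 1–20 mM); all outputs are synthetic
and labeled as such.

Noise models: multiplicative lognormal for concentration-like quantities,
additive Gaussian for heights and velocities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DomainError
from .kinetics import AbsorbanceSeries, VCDataset
from .thermo import SolubilityPoint, solubility_from_thermo
from .tracking import HeightMapSeries

__all__ = [
    "gen_solubility",
    "gen_height_series",
    "gen_vc",
    "gen_absorbance",
    "gen_groove_fixture",
    "StepLayoutItem",
    "DEFAULT_THERMO",
]

#: Generating thermodynamic parameters used across examples (synthetic, but
#: chosen to mimic the crystallization of theophylline from n-octanol).
DEFAULT_THERMO = {"enthalpy": -20.5e3, "entropy": -34.0}


def gen_solubility(
    enthalpy: float = DEFAULT_THERMO["enthalpy"],
    entropy: float = DEFAULT_THERMO["entropy"],
    temperatures: Sequence[float] = (283.15, 288.15, 293.15, 300.15),
    rel_noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[SolubilityPoint], dict]:
    """Ce(T) observations on an exact van 't Hoff line times lognormal noise.

    The default temperatures mimic batches equilibrated at 10/15/20/27 °C.
    """
    if rel_noise < 0:
        raise DomainError("rel_noise must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for t in temperatures:
        ce = solubility_from_thermo(enthalpy, entropy, t)
        noisy = ce * math.exp(rng.normal(0.0, rel_noise)) if rel_noise > 0 else ce
        unc = ce * rel_noise if rel_noise > 0 else None
        points.append(SolubilityPoint(temperature=t, solubility=noisy, uncertainty=unc))
    manifest = {
        "kind": "solubility",
        "enthalpy_J_per_mol": enthalpy,
        "entropy_J_per_mol_K": entropy,
        "temperatures_K": list(temperatures),
        "rel_noise": rel_noise,
        "seed": seed,
    }
    return points, manifest


@dataclass(frozen=True)
class StepLayoutItem:
    """One step riser in a synthetic terrace staircase."""

    position_nm: float  # riser position at t = 0, along the fast scan axis
    height_class: str  # "full" | "half"
    velocity_nm_s: float  # advance rate (positive moves toward +x)


def gen_height_series(
    layout: Sequence[StepLayoutItem],
    a_nm: float = 2.413,
    pixel_size: float = 4.0,
    shape: tuple[int, int] = (32, 256),
    frame_times: Sequence[float] = tuple(float(t) for t in range(0, 100, 10)),
    noise_sd: float = 0.1,
    drift_nm_s: float = 0.0,
    seed: int = 0,
) -> tuple[HeightMapSeries, dict]:
    """Frames of an advancing terrace staircase with Gaussian pixel noise.

    The staircase descends toward +x: each riser drops by its class height
    (full = a, half = a/2).  Risers advance at their own velocities; an
    optional lateral drift shifts the whole frame.  Steps crossing each
    other within the series make the fixture unusable and raise an error.
    The manifest records exact positions per frame and the velocities.
    """
    if not layout:
        raise ConfigError("layout needs at least one step")
    for item in layout:
        if item.height_class not in ("full", "half"):
            raise ConfigError(f"height_class must be full|half, got {item.height_class!r}")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    x = np.arange(cols) * pixel_size
    frames = []
    truth_positions = []
    order0 = np.argsort([it.position_nm for it in layout])
    for t in frame_times:
        pos = [it.position_nm + it.velocity_nm_s * t + drift_nm_s * t for it in layout]
        if np.any(np.diff(np.array(pos)[order0]) <= 0):
            raise ConfigError(f"steps collide at t = {t}")
        profile = np.zeros(cols)
        for it, p in zip(layout, pos):
            drop = a_nm if it.height_class == "full" else a_nm / 2.0
            profile -= drop * (x >= p)
        frame = np.tile(profile, (rows, 1))
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames.append(frame)
        truth_positions.append(pos)
    series = HeightMapSeries(
        frames=tuple(frames),
        pixel_size=pixel_size,
        timestamps=tuple(float(t) for t in frame_times),
        metadata={"synthetic": True, "a_nm": a_nm, "seed": seed},
    )
    manifest = {
        "kind": "height_series",
        "a_nm": a_nm,
        "riser_heights_nm": [a_nm if it.height_class == "full" else a_nm / 2 for it in layout],
        "velocities_nm_s": [it.velocity_nm_s for it in layout],
        "positions_nm": truth_positions,
        "frame_times_s": list(frame_times),
        "noise_sd_nm": noise_sd,
        "drift_nm_s": drift_nm_s,
        "seed": seed,
    }
    return series, manifest


def gen_vc(
    beta: float,
    order_m: float,
    Ce: float = 0.0135,
    c_grid: Sequence[float] | None = None,
    rel_noise: float = 0.0,
    seed: int = 0,
    direction_label: str = "",
) -> tuple[VCDataset, dict]:
    """v = β·(C/Ce − 1)^m with multiplicative lognormal noise.

    The default grid spans 14–20 mM above the 13.5 mM solubility,
    mirroring the measured concentration range.
    """
    if c_grid is None:
        c_grid = tuple(Ce * s for s in (1.05, 1.11, 1.2, 1.3, 1.37, 1.48))
    rng = np.random.default_rng(seed)
    c = np.asarray(c_grid, dtype=float)
    sig = np.clip(c / Ce - 1.0, 0.0, None)
    v = beta * sig**order_m
    if rel_noise > 0:
        v = v * np.exp(rng.normal(0.0, rel_noise, size=v.shape))
    sds = np.abs(beta * sig**order_m) * rel_noise if rel_noise > 0 else None
    data = VCDataset.from_arrays(c, v, Ce, velocity_sds=sds, direction_label=direction_label)
    manifest = {
        "kind": "vc",
        "beta_nm_s": beta,
        "order_m": order_m,
        "Ce_mol_L": Ce,
        "rel_noise": rel_noise,
        "seed": seed,
    }
    return data, manifest


def gen_absorbance(
    epsilon_l: float = 50.0,
    c_grid: Sequence[float] | None = None,
    dimerization_K: float = 0.0,
    epsilon_dimer_ratio: float = 1.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength: float = 270.0,
) -> tuple[AbsorbanceSeries, dict]:
    """Beer–Lambert series, optionally with a monomer–dimer equilibrium.

    With K = 0 the series is exactly A = εl·C.  With K > 0 the monomer
    concentration solves the mass balance M + 2K·M² = C exactly (positive
    root) and A = εl·M + r·εl·K·M² with r the dimer/monomer absorptivity
    ratio (r ≠ 2 produces curvature).  Default grid: 1–20 mM.
    """
    if c_grid is None:
        c_grid = tuple(x * 1e-3 for x in (1, 2, 4, 6, 8, 10, 12, 14, 17, 20))
    rng = np.random.default_rng(seed)
    c = np.asarray(c_grid, dtype=float)
    if dimerization_K > 0:
        m = (-1.0 + np.sqrt(1.0 + 8.0 * dimerization_K * c)) / (4.0 * dimerization_K)
        d = dimerization_K * m**2
        a = epsilon_l * m + epsilon_dimer_ratio * epsilon_l * d
        mass_balance_residual = float(np.max(np.abs(m + 2 * d - c)))
    else:
        m = c
        a = epsilon_l * c
        mass_balance_residual = 0.0
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    series = AbsorbanceSeries(
        concentrations=tuple(float(x) for x in c),
        absorbances=tuple(float(x) for x in a),
        wavelength=wavelength,
    )
    manifest = {
        "kind": "absorbance",
        "epsilon_l": epsilon_l,
        "dimerization_K_L_mol": dimerization_K,
        "epsilon_dimer_ratio": epsilon_dimer_ratio,
        "noise_sd": noise_sd,
        "mass_balance_residual": mass_balance_residual,
        "monomer_mol_L": [float(x) for x in m],
        "seed": seed,
    }
    return series, manifest


def gen_groove_fixture(
    dimensions: tuple[int, int] = (64, 64),
    orientation: str = "001",
    width: int = 6,
    depth: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """A full monolayer with a centered groove etched into it.

    Round-trips exactly through :func:`stepkin.kmc.etch_groove`; the
    manifest records the footprint so healing runs can score refill.
    """
    from .kmc import etch_groove  # local import to avoid jit import cost here

    full = np.ones(dimensions, dtype=np.uint8)
    etched = etch_groove(full, orientation=orientation, width=width, depth=depth)
    l0, l1 = dimensions
    if orientation == "001":
        r0 = (l0 - width) // 2
        footprint = {"axis": 0, "start": r0, "width": width}
        n_vac = width * l1 * depth
    else:
        c0 = (l1 - width) // 2
        footprint = {"axis": 1, "start": c0, "width": width}
        n_vac = width * l0 * depth
    manifest = {
        "kind": "groove_fixture",
        "dimensions": list(dimensions),
        "orientation": orientation,
        "width": width,
        "depth": depth,
        "footprint": footprint,
        "vacancy_count": int(n_vac),
        "seed": seed,
    }
    assert int((etched == 0).sum()) == n_vac
    return etched, manifest
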