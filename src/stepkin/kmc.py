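"""Rejection-free kinetic Monte Carlo engines for the step-growth mechanisms.

Two seeded engines:

* :func:`simulate_step_edge` — a restricted solid-on-solid (RSOS) step edge
  with neighbor height differences limited to {−1, 0, +1}.  This model is
  chosen deliberately: its equilibrium kink density is exactly
  ``2/[exp(ω/kBT)+2]`` (the unrestricted SOS model gives ``2/[exp(ω/kBT)+1]``
  instead), so the simulation can be checked against the same closed form
  the analysis uses.  Attachment is supplied at every edge site (direct
  incorporation from an abundant 3D supply field); growth at kink-poor
  edges proceeds by 1D nucleation of new molecule rows, which is what makes
  v(C) superlinear at high kink energy.

* :func:`simulate_surface` — an anisotropic lattice gas of one (200)
  monolayer with nearest-neighbor bonds along [010] and [001] and a
  diagonal [011] bond (the H-bond chain), used for island-shape and
  groove-healing experiments.

Rates
-----
Every move's forward/backward rate ratio equals the Boltzmann factor of its
grand-potential change (detailed balance; audited exhaustively before every
run, failure is fatal).  Two rate laws satisfying that condition are
offered: ``"glauber"`` (default), ν/(1+exp(βΔΦ)), whose rates are bounded
by the attempt frequency ν and which therefore remains efficient at high
kink energy; and ``"split"``, attachment ∝ C/Ce with detachment
∝ exp(−ΔE/RT), the textbook splitting, which is numerically stiff when
detachment of a freshly attached adatom is strongly downhill.

Units: the engines work in lattice units (site spacings, events, 1/ν time);
the physical mapping (site = b or c spacing, layer = a/2) belongs in run
metadata, not in the dynamics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import ndimage

from .constants import R_GAS
from .errors import ConfigError, DomainError, SimulationError
from .kinetics import VCDataset

__all__ = [
    "StepSimConfig",
    "SurfaceSimConfig",
    "SimResult",
    "SurfaceResult",
    "HealResult",
    "simulate_step_edge",
    "velocity_curve",
    "simulate_surface",
    "etch_groove",
    "heal",
    "measure_kink_density",
    "audit_step_rates",
    "audit_surface_rates",
]

_RNG_NOTE = "numba MT19937, np.random.seed(seed) per run"


# ---------------------------------------------------------------------------
# configs and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepSimConfig:
    """Configuration of one RSOS step-edge run.

    ``boundary`` selects the edge topology, and the right choice depends on
    the observable.  ``"free"`` ends sample the exact three-state product
    measure over height differences, so the equilibrium kink density can be
    validated against the closed form at any edge length; a ``"periodic"``
    ring instead pins the winding number Σ(Δh) = 0 (suppressing the kink
    density at high ω, where kinks would have to appear in bulk pairs) but
    models an isolated infinite step with no boundary kink sources — the
    correct geometry for v(C) curves, where growth at kink-poor edges must
    proceed by 1D row nucleation in the bulk rather than from the ends.
    """

    edge_length: int  # sites, >= 32
    kink_energy: float  # ω, J/mol
    saturation_ratio: float  # C/Ce
    n_events: int
    seed: int
    attempt_frequency: float = 1.0  # 1/s
    temperature: float = 298.15  # K
    burn_in_fraction: float = 0.25
    n_batches: int = 16
    rate_law: str = "glauber"  # or "split"
    boundary: str = "free"  # or "periodic"

    def __post_init__(self) -> None:
        if self.edge_length < 32:
            raise ConfigError(f"edge_length must be >= 32, got {self.edge_length}")
        if self.boundary not in ("free", "periodic"):
            raise ConfigError(f"boundary must be 'free' or 'periodic', got {self.boundary!r}")
        if self.n_events <= 0:
            raise ConfigError("n_events must be > 0")
        if self.kink_energy < 0:
            raise DomainError("kink_energy must be >= 0")
        if self.saturation_ratio <= 0:
            raise DomainError("saturation_ratio must be > 0")
        if self.rate_law not in ("glauber", "split"):
            raise ConfigError(f"unknown rate_law {self.rate_law!r}")
        if not 0 <= self.burn_in_fraction < 1:
            raise ConfigError("burn_in_fraction must be in [0, 1)")
        if self.n_batches < 2:
            raise ConfigError("n_batches must be >= 2")


@dataclass(frozen=True)
class SurfaceSimConfig:
    """Configuration of one (200)-monolayer lattice-gas run."""

    dimensions: tuple[int, int]  # (sites along [010], sites along [001])
    bond_010: float  # J/mol, π-stack chain direction
    bond_001: float  # J/mol, in-plane vdW direction
    bond_011: float  # J/mol, H-bond diagonal
    chemical_potential: float  # Δμ, J/mol
    n_events: int
    seed: int
    attempt_frequency: float = 1.0
    temperature: float = 298.15
    rate_law: str = "glauber"

    def __post_init__(self) -> None:
        if min(self.dimensions) < 64:
            raise ConfigError(f"dimensions must be >= 64x64, got {self.dimensions}")
        if self.n_events <= 0:
            raise ConfigError("n_events must be > 0")
        if min(self.bond_010, self.bond_001, self.bond_011) < 0:
            raise DomainError("bond energies must be >= 0")
        if self.rate_law not in ("glauber", "split"):
            raise ConfigError(f"unknown rate_law {self.rate_law!r}")


@dataclass(frozen=True)
class SimResult:
    """Observables of one step-edge run."""

    mean_velocity: float  # sites/s (rows of the step advanced per second)
    velocity_se: float
    kink_density: float  # unitless in [0, 1]
    kink_density_se: float
    roughness: float  # sites (std of the edge height)
    n_attach: int
    n_detach: int
    sim_time: float  # s, measurement window
    config: StepSimConfig
    rng: str = _RNG_NOTE

    def __post_init__(self) -> None:
        if not 0.0 <= self.kink_density <= 1.0:
            raise SimulationError(f"kink density {self.kink_density} outside [0, 1]")
        if self.kink_density_se < 0 or self.velocity_se < 0:
            raise SimulationError("standard errors must be >= 0")


@dataclass(frozen=True)
class SurfaceResult:
    """Final lattice and bookkeeping of one surface run."""

    occupancy: np.ndarray  # (L010, L001) uint8
    n_attach: int
    n_detach: int
    sim_time: float
    snapshots: tuple[np.ndarray, ...] = field(default_factory=tuple)
    config: SurfaceSimConfig | None = None
    rng: str = _RNG_NOTE


@dataclass(frozen=True)
class HealResult:
    healed_fraction: float  # refilled / etched sites
    void_count: int  # connected vacancy clusters at the end state
    interface_roughness: float  # unlike nearest-neighbor pairs in the end state
    n_etched: int
    result: SurfaceResult | None = None


# ---------------------------------------------------------------------------
# rate formulas (python mirrors of the kernels, used by the audits)
# ---------------------------------------------------------------------------


def _step_delta_e(dl: int | None, dr: int | None, up: bool) -> int:
    """Energy change of h[i] ± 1 in units of ω; None marks a free end."""
    s = 1 if up else -1
    d_e = 0
    if dl is not None:
        d_e += abs(dl + s) - abs(dl)
    if dr is not None:
        d_e += abs(dr - s) - abs(dr)
    return d_e


def _step_attach_rate(dl: int | None, dr: int | None, beta_omega: float, ln_s: float, glauber: bool) -> float:
    if (dl is not None and dl > 0) or (dr is not None and dr < 0):
        return 0.0
    d_e = beta_omega * _step_delta_e(dl, dr, True)
    if glauber:
        return 1.0 / (1.0 + math.exp(d_e - ln_s))
    return math.exp(ln_s)


def _step_detach_rate(dl: int | None, dr: int | None, beta_omega: float, ln_s: float, glauber: bool) -> float:
    if (dl is not None and dl < 0) or (dr is not None and dr > 0):
        return 0.0
    d_e = beta_omega * _step_delta_e(dl, dr, False)
    if glauber:
        return 1.0 / (1.0 + math.exp(d_e + ln_s))
    return math.exp(-d_e)


def audit_step_rates(beta_omega: float, ln_s: float, glauber: bool, tol: float = 1e-12) -> None:
    """Exhaustive detailed-balance audit of the step-edge rate catalog.

    For every admissible (left, right) height-difference pair — including
    the free-end cases, marked None — the attachment rate and the
    detachment rate of the resulting configuration must satisfy
    r_fwd/r_bwd = exp(−β(ΔE − Δμ)).  Failure is fatal.
    """
    for dl in (-1, 0, 1, None):
        for dr in (-1, 0, 1, None):
            fwd = _step_attach_rate(dl, dr, beta_omega, ln_s, glauber)
            if fwd == 0.0:
                continue
            d_e = beta_omega * _step_delta_e(dl, dr, True)
            dl2 = None if dl is None else dl + 1
            dr2 = None if dr is None else dr - 1
            bwd = _step_detach_rate(dl2, dr2, beta_omega, ln_s, glauber)
            if bwd == 0.0:
                raise SimulationError(f"irreversible move at (dl={dl}, dr={dr})")
            expected = math.exp(-(d_e - ln_s))
            if abs(fwd / bwd - expected) > tol * max(1.0, expected):
                raise SimulationError(
                    f"detailed balance violated at (dl={dl}, dr={dr}): "
                    f"ratio {fwd / bwd}, expected {expected}"
                )


def _surface_attach_rate(bond_sum: float, beta_mu: float, glauber: bool) -> float:
    d_phi = -bond_sum - beta_mu
    if glauber:
        return 1.0 / (1.0 + math.exp(d_phi))
    return math.exp(beta_mu)


def _surface_detach_rate(bond_sum: float, beta_mu: float, glauber: bool) -> float:
    d_phi = bond_sum + beta_mu
    if glauber:
        return 1.0 / (1.0 + math.exp(d_phi))
    return math.exp(-bond_sum)


def audit_surface_rates(
    beta_bonds: tuple[float, float, float], beta_mu: float, glauber: bool, tol: float = 1e-12
) -> None:
    """Detailed-balance audit over every attainable neighbor bond sum."""
    b010, b001, b011 = beta_bonds
    sums = set()
    for n010 in range(3):
        for n001 in range(3):
            for n011 in range(3):
                sums.add(n010 * b010 + n001 * b001 + n011 * b011)
    for s in sorted(sums):
        fwd = _surface_attach_rate(s, beta_mu, glauber)
        bwd = _surface_detach_rate(s, beta_mu, glauber)
        expected = math.exp(s + beta_mu)
        if abs(fwd / bwd - expected) > tol * max(1.0, expected):
            raise SimulationError(
                f"detailed balance violated at bond sum {s}: ratio {fwd / bwd}, "
                f"expected {expected}"
            )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _step_site_rates(h, i, n, beta_omega, ln_s, glauber, periodic):  # pragma: no cover - jitted
    has_l = periodic or i > 0
    has_r = periodic or i < n - 1
    im = i - 1 if i > 0 else n - 1
    ip = i + 1 if i < n - 1 else 0
    dl = h[i] - h[im] if has_l else 0
    dr = h[ip] - h[i] if has_r else 0
    ra = 0.0
    rd = 0.0
    attach_ok = (not has_l or dl <= 0) and (not has_r or dr >= 0)
    detach_ok = (not has_l or dl >= 0) and (not has_r or dr <= 0)
    if attach_ok:
        d_e = 0.0
        if has_l:
            d_e += abs(dl + 1) - abs(dl)
        if has_r:
            d_e += abs(dr - 1) - abs(dr)
        d_e *= beta_omega
        if glauber:
            ra = 1.0 / (1.0 + math.exp(d_e - ln_s))
        else:
            ra = math.exp(ln_s)
    if detach_ok:
        d_e = 0.0
        if has_l:
            d_e += abs(dl - 1) - abs(dl)
        if has_r:
            d_e += abs(dr + 1) - abs(dr)
        d_e *= beta_omega
        if glauber:
            rd = 1.0 / (1.0 + math.exp(d_e + ln_s))
        else:
            rd = math.exp(-d_e)
    return ra, rd


@njit(cache=True)
def _step_edge_kernel(
    h, beta_omega, ln_s, n_events, burn_in, n_batches, seed, glauber, periodic
):  # pragma: no cover - jitted
    np.random.seed(seed)
    n = h.shape[0]
    ra = np.zeros(n)
    rd = np.zeros(n)
    for i in range(n):
        ra[i], rd[i] = _step_site_rates(h, i, n, beta_omega, ln_s, glauber, periodic)
    r_tot = ra.sum() + rd.sum()

    n_bonds = n if periodic else n - 1
    nk = 0
    for i in range(n_bonds):
        ip = i + 1 if i < n - 1 else 0
        if h[ip] - h[i] != 0:
            nk += 1

    meas_events = n_events - burn_in
    batch_size = meas_events // n_batches
    if batch_size < 1:
        batch_size = 1
    batch_kink = np.zeros(n_batches)
    batch_time = np.zeros(n_batches)
    batch_net = np.zeros(n_batches)
    kink_time = 0.0
    total_time = 0.0
    n_att = 0
    n_det = 0

    for ev in range(n_events):
        if ev % 4096 == 0:
            r_tot = ra.sum() + rd.sum()
        u = np.random.random() * r_tot
        site = -1
        attach = True
        acc = 0.0
        for j in range(n):
            acc += ra[j]
            if acc >= u:
                site = j
                break
        if site < 0:
            for j in range(n):
                acc += rd[j]
                if acc >= u:
                    site = j
                    attach = False
                    break
        if site < 0:
            site = n - 1
            attach = rd[site] == 0.0
        dt = -math.log(np.random.random()) / r_tot

        b = 0
        measuring = ev >= burn_in
        if measuring:
            b = (ev - burn_in) // batch_size
            if b >= n_batches:
                b = n_batches - 1
            kink_time += nk * dt
            total_time += dt
            batch_kink[b] += nk * dt
            batch_time[b] += dt

        has_l = periodic or site > 0
        has_r = periodic or site < n - 1
        im = site - 1 if site > 0 else n - 1
        ip = site + 1 if site < n - 1 else 0
        dl_old = h[site] - h[im] if has_l else 0
        dr_old = h[ip] - h[site] if has_r else 0
        if attach:
            h[site] += 1
            if measuring:
                n_att += 1
                batch_net[b] += 1.0
        else:
            h[site] -= 1
            if measuring:
                n_det += 1
                batch_net[b] -= 1.0
        if has_l:
            dl_new = h[site] - h[im]
            if dl_old != 0:
                nk -= 1
            if dl_new != 0:
                nk += 1
        if has_r:
            dr_new = h[ip] - h[site]
            if dr_old != 0:
                nk -= 1
            if dr_new != 0:
                nk += 1
        for j in (im, site, ip):
            if j == site or (j == im and has_l) or (j == ip and has_r):
                r_tot -= ra[j] + rd[j]
                ra[j], rd[j] = _step_site_rates(h, j, n, beta_omega, ln_s, glauber, periodic)
                r_tot += ra[j] + rd[j]

    return kink_time, total_time, batch_kink, batch_time, batch_net, n_att, n_det


@njit(cache=True)
def _surface_site_rate(
    occ, i, j, l0, l1, b010, b001, b011, beta_mu, glauber
):  # pragma: no cover - jitted
    ip = i + 1 if i < l0 - 1 else 0
    im = i - 1 if i > 0 else l0 - 1
    jp = j + 1 if j < l1 - 1 else 0
    jm = j - 1 if j > 0 else l1 - 1
    s = (
        b010 * (occ[ip, j] + occ[im, j])
        + b001 * (occ[i, jp] + occ[i, jm])
        + b011 * (occ[ip, jp] + occ[im, jm])
    )
    if occ[i, j] == 0:
        d_phi = -s - beta_mu
        if glauber:
            return 1.0 / (1.0 + math.exp(d_phi))
        return math.exp(beta_mu)
    d_phi = s + beta_mu
    if glauber:
        return 1.0 / (1.0 + math.exp(d_phi))
    return math.exp(-s)


@njit(cache=True)
def _surface_kernel(
    occ, b010, b001, b011, beta_mu, n_events, seed, glauber
):  # pragma: no cover - jitted
    np.random.seed(seed)
    l0, l1 = occ.shape
    nsite = l0 * l1
    rates = np.zeros(nsite)
    for i in range(l0):
        for j in range(l1):
            rates[i * l1 + j] = _surface_site_rate(
                occ, i, j, l0, l1, b010, b001, b011, beta_mu, glauber
            )
    r_tot = rates.sum()
    t = 0.0
    n_att = 0
    n_det = 0
    for ev in range(n_events):
        if ev % 2048 == 0:
            r_tot = rates.sum()
        u = np.random.random() * r_tot
        idx = -1
        acc = 0.0
        for k in range(nsite):
            acc += rates[k]
            if acc >= u:
                idx = k
                break
        if idx < 0:
            idx = nsite - 1
        t += -math.log(np.random.random()) / r_tot
        i = idx // l1
        j = idx % l1
        if occ[i, j] == 0:
            occ[i, j] = 1
            n_att += 1
        else:
            occ[i, j] = 0
            n_det += 1
        ip = i + 1 if i < l0 - 1 else 0
        im = i - 1 if i > 0 else l0 - 1
        jp = j + 1 if j < l1 - 1 else 0
        jm = j - 1 if j > 0 else l1 - 1
        for ii, jj in ((i, j), (ip, j), (im, j), (i, jp), (i, jm), (ip, jp), (im, jm)):
            k = ii * l1 + jj
            r_tot -= rates[k]
            rates[k] = _surface_site_rate(
                occ, ii, jj, l0, l1, b010, b001, b011, beta_mu, glauber
            )
            r_tot += rates[k]
    return t, n_att, n_det


# ---------------------------------------------------------------------------
# public driver functions
# ---------------------------------------------------------------------------


def measure_kink_density(heights: np.ndarray) -> float:
    """Kinks per site of a periodic edge profile: bonds with Δh ≠ 0.

    The zero-entropy alternating configuration (two molecules of a new row
    alternating with two vacancies, heights ...1,1,0,0,1,1,0,0...) counts to
    exactly 0.5.
    """
    h = np.asarray(heights)
    if h.ndim != 1 or h.size < 2:
        raise DomainError("need a 1D profile with >= 2 sites")
    d = np.diff(np.concatenate([h, h[:1]]))
    return float(np.count_nonzero(d)) / h.size


def simulate_step_edge(config: StepSimConfig, initial_heights: np.ndarray | None = None) -> SimResult:
    """Run one RSOS step-edge trajectory and return its observables.

    The edge starts flat (or from ``initial_heights``), equilibrates for
    ``burn_in_fraction`` of the events, and is then measured: the mean
    velocity (net attachments per site per unit time), the time-averaged
    kink density with a batch-means standard error, and the final edge
    roughness.  At C/Ce = 1 detailed balance makes the velocity zero and
    the kink density equal to the analytic 2/[exp(ω/RT)+2].
    """
    beta_omega = config.kink_energy / (R_GAS * config.temperature)
    ln_s = math.log(config.saturation_ratio)
    glauber = config.rate_law == "glauber"
    audit_step_rates(beta_omega, ln_s, glauber)

    if initial_heights is None:
        h = np.zeros(config.edge_length, dtype=np.int64)
    else:
        h = np.asarray(initial_heights, dtype=np.int64).copy()
        if h.size != config.edge_length:
            raise ConfigError("initial_heights length does not match edge_length")
        if np.any(np.abs(np.diff(h)) > 1):
            raise ConfigError("initial_heights violates the RSOS |Δh| <= 1 restriction")

    periodic = config.boundary == "periodic"
    if periodic and initial_heights is not None and abs(h[0] - h[-1]) > 1:
        raise ConfigError("initial_heights violates the RSOS restriction at the wrap bond")
    burn_in = int(config.burn_in_fraction * config.n_events)
    kink_time, total_time, batch_kink, batch_time, batch_net, n_att, n_det = _step_edge_kernel(
        h,
        beta_omega,
        ln_s,
        config.n_events,
        burn_in,
        config.n_batches,
        config.seed % (2**31),
        glauber,
        periodic,
    )
    if total_time <= 0:
        raise SimulationError("no measurement time accumulated; increase n_events")
    n = config.edge_length
    nu = config.attempt_frequency
    n_bonds = n if periodic else n - 1
    kink_density = kink_time / (total_time * n_bonds)
    ok = batch_time > 0
    batch_dens = batch_kink[ok] / (batch_time[ok] * n_bonds)
    batch_vel = batch_net[ok] / (batch_time[ok] * n) * nu
    nb = int(ok.sum())
    kink_se = float(np.std(batch_dens, ddof=1) / math.sqrt(nb)) if nb > 1 else 0.0
    vel_se = float(np.std(batch_vel, ddof=1) / math.sqrt(nb)) if nb > 1 else 0.0
    velocity = (n_att - n_det) / (n * total_time) * nu
    return SimResult(
        mean_velocity=velocity,
        velocity_se=vel_se,
        kink_density=float(kink_density),
        kink_density_se=kink_se,
        roughness=float(np.std(h)),
        n_attach=int(n_att),
        n_detach=int(n_det),
        sim_time=total_time / nu,
        config=config,
    )


def velocity_curve(
    config: StepSimConfig, saturation_grid: np.ndarray, Ce: float = 1.0
) -> tuple[VCDataset, list[SimResult]]:
    """Step velocity over a C/Ce grid, packaged for the kinetics fits.

    Each grid point runs :func:`simulate_step_edge` with a seed derived
    from the config seed and the point index, so the curve is reproducible
    point by point.  Concentrations are reported as S·Ce (lattice
    concentration units when Ce = 1).
    """
    grid = np.asarray(saturation_grid, dtype=float)
    if grid.size < 2:
        raise ConfigError("saturation grid needs > 1 point")
    results = []
    for k, s in enumerate(grid):
        cfg = replace(config, saturation_ratio=float(s), seed=(config.seed * 1000 + k) % (2**31))
        results.append(simulate_step_edge(cfg))
    data = VCDataset.from_arrays(
        concentrations=grid * Ce,
        velocities=[r.mean_velocity for r in results],
        Ce=Ce,
        velocity_sds=[r.velocity_se for r in results],
        direction_label=f"rsos omega={config.kink_energy:g} J/mol",
    )
    return data, results


def simulate_surface(
    config: SurfaceSimConfig,
    initial_occupancy: np.ndarray | None = None,
    n_snapshots: int = 0,
) -> SurfaceResult:
    """Run the anisotropic (200) lattice gas; returns the final occupancy.

    Axis 0 runs along [010] (π-stack chain), axis 1 along [001]; the
    diagonal bond connects (i, j) to (i+1, j+1), standing in for the [011]
    H-bond chain.  Periodic boundaries.  Snapshots, when requested, are
    taken at equal event intervals.
    """
    rt = R_GAS * config.temperature
    beta_bonds = (config.bond_010 / rt, config.bond_001 / rt, config.bond_011 / rt)
    # The config's Δμ is measured from solid-solution coexistence.  By
    # particle-hole symmetry the lattice gas coexists at
    # μ_coex = −(E010 + E001 + E011) (half the per-molecule bond sum), so
    # the kernel's bare chemical potential is offset by that amount: at
    # Δμ = 0 a flat interface neither grows nor dissolves, and an isolated
    # adatom in the open region is penalized by the full bond sum.
    mu_bare = config.chemical_potential - (config.bond_010 + config.bond_001 + config.bond_011)
    beta_mu = mu_bare / rt
    glauber = config.rate_law == "glauber"
    audit_surface_rates(beta_bonds, beta_mu, glauber)

    l0, l1 = config.dimensions
    if initial_occupancy is None:
        occ = np.zeros((l0, l1), dtype=np.uint8)
    else:
        occ = np.asarray(initial_occupancy, dtype=np.uint8).copy()
        if occ.shape != (l0, l1):
            raise ConfigError(f"initial occupancy shape {occ.shape} != {config.dimensions}")

    chunks = max(n_snapshots, 1)
    per_chunk = config.n_events // chunks
    leftover = config.n_events - per_chunk * chunks
    snapshots = []
    t_total = 0.0
    n_att = 0
    n_det = 0
    for c in range(chunks):
        n_ev = per_chunk + (leftover if c == chunks - 1 else 0)
        if n_ev <= 0:
            continue
        t, a, d = _surface_kernel(
            occ,
            beta_bonds[0],
            beta_bonds[1],
            beta_bonds[2],
            beta_mu,
            n_ev,
            (config.seed * 97 + c) % (2**31),
            glauber,
        )
        t_total += t
        n_att += a
        n_det += d
        if n_snapshots:
            snapshots.append(occ.copy())
    return SurfaceResult(
        occupancy=occ,
        n_attach=int(n_att),
        n_detach=int(n_det),
        sim_time=t_total / config.attempt_frequency,
        snapshots=tuple(snapshots),
        config=config,
    )


def island_aspect(occupancy: np.ndarray) -> float:
    """Aspect ratio (extent along [010] / extent along [001]) of the largest island.

    Uses the square-rooted second moments of the largest connected cluster
    about its center of mass; assumes the island does not wrap the periodic
    boundary (start islands centered).
    """
    occ = np.asarray(occupancy)
    labels, n = ndimage.label(occ)
    if n == 0:
        raise DomainError("no occupied sites")
    sizes = ndimage.sum_labels(np.ones_like(occ), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    ii, jj = np.nonzero(labels == biggest)
    v0 = float(np.var(ii))
    v1 = float(np.var(jj))
    if v1 == 0:
        return float("inf")
    return math.sqrt(v0 / v1)


def etch_groove(
    lattice: np.ndarray, orientation: str, width: int, depth: int = 1
) -> np.ndarray:
    """Clear a centered groove footprint spanning the lattice.

    ``orientation`` names the groove's long axis: ``"001"`` grooves run
    along [001] (axis 1) and their walls advance along [010] when healing;
    ``"010"`` grooves are the transpose.  The surface model is a single
    (200) monolayer, so ``depth`` must be 1.
    """
    if orientation not in ("010", "001"):
        raise ConfigError(f"orientation must be '010' or '001', got {orientation!r}")
    if depth != 1:
        raise ConfigError("the surface engine models one monolayer; depth must be 1")
    occ = np.asarray(lattice, dtype=np.uint8).copy()
    l0, l1 = occ.shape
    if orientation == "001":
        if width >= l0:
            raise ConfigError(f"groove width {width} does not fit across {l0} sites")
        r0 = (l0 - width) // 2
        occ[r0 : r0 + width, :] = 0
    else:
        if width >= l1:
            raise ConfigError(f"groove width {width} does not fit across {l1} sites")
        c0 = (l1 - width) // 2
        occ[:, c0 : c0 + width] = 0
    return occ


def heal(
    lattice: np.ndarray,
    config: SurfaceSimConfig,
    n_snapshots: int = 0,
) -> HealResult:
    """Regrow an etched lattice at the config's supersaturation.

    ``healed_fraction`` is the fraction of initially vacant sites refilled
    at the end; ``void_count`` the number of connected clusters of groove
    sites never refilled (the quantitative stand-in for "voids and
    crevices"); ``interface_roughness`` the count of unlike
    nearest-neighbor pairs over the whole lattice.  At Δμ = 0 there is no
    driving force: the walls only roughen diffusively and the net occupancy
    does not grow.
    """
    if config.chemical_potential < 0:
        raise DomainError("healing requires Δμ >= 0")
    start = np.asarray(lattice, dtype=np.uint8)
    etched = int((start == 0).sum())
    if etched == 0:
        raise DomainError("lattice has no vacancies to heal")
    res = simulate_surface(config, initial_occupancy=start, n_snapshots=n_snapshots)
    occ = res.occupancy
    never_refilled = (start == 0) & (occ == 0)
    still_vacant = int(never_refilled.sum())
    healed_fraction = (etched - still_vacant) / etched
    _, void_count = ndimage.label(never_refilled.astype(np.uint8))
    unlike = int(np.sum(occ != np.roll(occ, 1, axis=0))) + int(
        np.sum(occ != np.roll(occ, 1, axis=1))
    )
    return HealResult(
        healed_fraction=float(healed_fraction),
        void_count=int(void_count),
        interface_roughness=float(unlike),
        n_etched=etched,
        result=res,
    )
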