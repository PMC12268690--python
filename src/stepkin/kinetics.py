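"""Step-kinetics laws on v(C) data and a solution-speciation screen.

Step velocity versus concentration distinguishes two growth regimes on the
(200) face:

* a quasi-first-order law v = β·(C/Ce − 1): the kink density is already at
  its thermodynamic ceiling in equilibrium, so only the solute chemical
  potential drives the step ([010] steps), and
* a kink-limited superlinear regime: the equilibrium step is kink-poor and
  supersaturation generates kinks by 1D row nucleation, so the
  kink–solute bimolecular reaction appears as roughly second order in
  concentration ([001] steps).

The exact analytic v(C) of the row-nucleation models is not committed to
here; a free-exponent power law v = β·(C/Ce − 1)^m (m ≥ 1) and a fixed
quadratic serve as explicit surrogates, compared by small-sample AICc.
All laws pin v(Ce) = 0 by using (C/Ce − 1) as the regressor.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError, InsufficientDataError

__all__ = [
    "VCDataset",
    "KineticFit",
    "AbsorbanceSeries",
    "fit_linear_bcf",
    "fit_power_law",
    "fit_kink_limited",
    "select_model",
    "anisotropy_ratio",
    "absorbance_linearity",
    "SpeciationReport",
]


@dataclass(frozen=True)
class VCDataset:
    """Step velocity vs concentration for one crystallographic direction."""

    concentrations: tuple[float, ...]  # mol/L
    velocities: tuple[float, ...]  # nm/s
    Ce: float  # mol/L
    velocity_sds: tuple[float, ...] | None = None
    direction_label: str = ""

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.velocities):
            raise DomainError("concentrations and velocities must have equal length")
        if self.velocity_sds is not None and len(self.velocity_sds) != len(self.velocities):
            raise DomainError("velocity_sds length mismatch")
        if self.Ce <= 0:
            raise DomainError("Ce must be > 0")

    @classmethod
    def from_arrays(cls, concentrations, velocities, Ce, velocity_sds=None, direction_label=""):
        return cls(
            concentrations=tuple(float(c) for c in concentrations),
            velocities=tuple(float(v) for v in velocities),
            Ce=float(Ce),
            velocity_sds=None if velocity_sds is None else tuple(float(s) for s in velocity_sds),
            direction_label=direction_label,
        )

    def sigma(self) -> np.ndarray:
        """Regressor σ' = C/Ce − 1 (zero at equilibrium)."""
        return np.asarray(self.concentrations) / self.Ce - 1.0

    def _weights(self) -> np.ndarray | None:
        if self.velocity_sds is None:
            return None
        sds = np.asarray(self.velocity_sds)
        if np.any(sds <= 0):
            return None
        return 1.0 / sds


@dataclass(frozen=True)
class KineticFit:
    """A fitted kinetic law v = β·(C/Ce − 1)^m."""

    model: str  # linear_bcf | power_law | quadratic_kink_limited
    beta: float  # nm/s
    order_m: float  # 1 for linear, 2 for quadratic, free >= 1 for power_law
    beta_se: float
    order_se: float
    aicc: float
    residuals: tuple[float, ...]
    n_points: int
    dataset_id: int = 0  # id() of the dataset, used to guard model comparison

    def __post_init__(self) -> None:
        if self.order_m < 1:
            raise DomainError("order_m must be >= 1")
        if self.beta < 0:
            raise DomainError("beta must be >= 0")

    def predict(self, concentrations, Ce: float | None = None) -> np.ndarray:
        ce = self.Ce_hint if Ce is None else Ce
        sig = np.asarray(concentrations) / ce - 1.0
        return self.beta * np.power(np.clip(sig, 0.0, None), self.order_m)

    Ce_hint: float = float("nan")


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for Gaussian residuals."""
    if n <= k + 1:
        return float("inf")
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _supersaturated(data: VCDataset, minimum: int):
    sig = data.sigma()
    v = np.asarray(data.velocities)
    mask = sig > 0
    if mask.sum() < minimum:
        raise InsufficientDataError(
            f"need >= {minimum} points with C > Ce, got {int(mask.sum())}"
        )
    w = data._weights()
    return sig[mask], v[mask], (None if w is None else w[mask])


def _pinned_regression(data: VCDataset, exponent: float, model: str) -> KineticFit:
    """(W)LS of v on (C/Ce − 1)^exponent through the origin.

    With velocity uncertainties present the fit and the information
    criterion both use the inverse-variance-weighted residuals, so model
    comparison stays coherent under heteroscedastic (multiplicative) noise.
    """
    sig, v, w = _supersaturated(data, 2)
    x = np.power(sig, exponent)
    ww = np.ones_like(sig) if w is None else w**2
    beta = float((ww * x * v).sum() / (ww * x**2).sum())
    resid = v - beta * x
    n = sig.size
    wrss = float((ww * resid**2).sum())
    dof = n - 1
    beta_se = math.sqrt((wrss / dof) / float((ww * x**2).sum())) if dof > 0 else 0.0
    return KineticFit(
        model=model,
        beta=max(beta, 0.0),
        order_m=exponent,
        beta_se=beta_se,
        order_se=0.0,
        aicc=_aicc(wrss, n, 1),
        residuals=tuple(resid),
        n_points=n,
        dataset_id=id(data),
        Ce_hint=data.Ce,
    )


def fit_linear_bcf(data: VCDataset) -> KineticFit:
    """Least squares of v = β·(C/Ce − 1) with the intercept pinned at v(Ce)=0."""
    return _pinned_regression(data, 1.0, "linear_bcf")


def _power_residuals(params, sig, v, w):
    beta, m = params
    r = v - beta * np.power(sig, m)
    return r if w is None else w * r


def fit_power_law(data: VCDataset, starts: Sequence[float] = (1.0, 1.5, 2.0, 3.0)) -> KineticFit:
    """Nonlinear least squares of v = β·(C/Ce − 1)^m with m ≥ 1.

    Multi-start over ``starts`` for the exponent; β started at the linear
    estimate.  Raises :class:`FitError` if no start converges.
    """
    sig, v, w = _supersaturated(data, 3)
    beta0 = max(float(np.sum(sig * v) / np.sum(sig**2)), 1e-12)
    best = None
    for m0 in starts:
        try:
            sol = least_squares(
                _power_residuals,
                x0=[beta0, m0],
                bounds=([0.0, 1.0], [np.inf, 10.0]),
                args=(sig, v, w),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(
            f"power-law fit failed to converge from starts {list(starts)} "
            f"(n={sig.size}, sigma range {sig.min():.3g}..{sig.max():.3g})"
        )
    beta, m = best.x
    resid = v - beta * np.power(sig, m)
    n = sig.size
    wrss = 2.0 * float(best.cost)  # weighted when sds are present
    # covariance from the (weighted) Jacobian at the solution
    try:
        jtj_inv = np.linalg.pinv(best.jac.T @ best.jac)
        s2 = wrss / max(n - 2, 1)
        ses = np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.array([float("nan"), float("nan")])
    return KineticFit(
        model="power_law",
        beta=float(beta),
        order_m=float(m),
        beta_se=float(ses[0]),
        order_se=float(ses[1]),
        aicc=_aicc(wrss, n, 2),
        residuals=tuple(resid),
        n_points=n,
        dataset_id=id(data),
        Ce_hint=data.Ce,
    )


def fit_kink_limited(data: VCDataset) -> KineticFit:
    """v = β·(C/Ce − 1)² — the kink-limited second-order surrogate."""
    return _pinned_regression(data, 2.0, "quadratic_kink_limited")


def residual_runs_test(fit: KineticFit) -> dict:
    """Wald–Wolfowitz runs diagnostic on the residual signs.

    A systematic trend (e.g. a quadratic law forced onto linear data)
    produces fewer sign runs than expected under exchangeable residuals.
    """
    signs = np.sign(fit.residuals)
    signs = signs[signs != 0]
    n = signs.size
    if n < 3:
        return {"runs": n, "expected": float(n), "z": 0.0, "trend_flagged": False}
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return {"runs": runs, "expected": 1.0, "z": 0.0, "trend_flagged": True}
    mu = 2 * n_pos * n_neg / n + 1
    var = 2 * n_pos * n_neg * (2 * n_pos * n_neg - n) / (n**2 * (n - 1))
    z = (runs - mu) / math.sqrt(var) if var > 0 else 0.0
    return {"runs": runs, "expected": mu, "z": z, "trend_flagged": z < -1.64}


def select_model(fits: Sequence[KineticFit]) -> list[tuple[KineticFit, float]]:
    """Rank fits of one dataset by AICc; returns (fit, ΔAICc) pairs.

    Ties (ΔAICc < 1e-9) break toward the lower-order model.
    """
    if not fits:
        raise InsufficientDataError("no fits to rank")
    ids = {f.dataset_id for f in fits}
    if len(ids) > 1:
        raise DomainError("fits compare different datasets")
    best = min(f.aicc for f in fits)
    ranked = sorted(fits, key=lambda f: (round(f.aicc - best, 9), f.order_m))
    return [(f, f.aicc - best) for f in ranked]


def anisotropy_ratio(
    fit_fast: KineticFit, fit_slow: KineticFit, concentrations, Ce: float
) -> np.ndarray:
    """v_fast(C)/v_slow(C) on a grid above Ce; zero-velocity points → NaN.

    For a linear fast direction against a superlinear slow one the ratio
    decays as (C/Ce − 1)^(1−m): large near equilibrium, modest at high
    supersaturation — the supersaturation-dependent step anisotropy.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= Ce):
        raise DomainError("grid must lie strictly above Ce")
    vf = fit_fast.predict(conc, Ce)
    vs = fit_slow.predict(conc, Ce)
    out = np.full_like(vf, np.nan)
    ok = vs > 0
    out[ok] = vf[ok] / vs[ok]
    return out


@dataclass(frozen=True)
class AbsorbanceSeries:
    """UV absorbance at one wavelength over a concentration series."""

    concentrations: tuple[float, ...]  # mol/L
    absorbances: tuple[float, ...]  # AU
    wavelength: float = 270.0  # nm

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.absorbances):
            raise DomainError("length mismatch")
        if any(c < 0 for c in self.concentrations):
            raise DomainError("concentrations must be >= 0")


@dataclass(frozen=True)
class SpeciationReport:
    """Outcome of the Beer–Lambert linearity screen."""

    verdict: str  # "monomeric" | "nonlinear (dimerization suspected)"
    linear_aicc: float
    dimer_aicc: float
    epsilon_l: float  # AU per (mol/L), linear model
    dimer_K: float  # L/mol, dimer model (0 if linear preferred)
    dimer_fraction_at_max: float
    curvature_z: float  # significance of a quadratic term


def _monomer_concentration(c_tot: np.ndarray, K: float) -> np.ndarray:
    """Mass balance M + 2K·M² = C solved in closed form (positive root)."""
    if K <= 0:
        return c_tot
    return (-1.0 + np.sqrt(1.0 + 8.0 * K * c_tot)) / (4.0 * K)


def absorbance_linearity(series: AbsorbanceSeries) -> SpeciationReport:
    """Screen a concentration–absorbance series for solute dimerization.

    Fits (a) the linear Beer–Lambert law A = εl·C through the origin and
    (b) a monomer–dimer model A = εm·l·M + εd·l·D with the dimerization
    equilibrium K = D/M² solved by mass balance.  The verdict is
    "monomeric" when the linear model is preferred by AICc — the situation
    for theophylline in n-octanol over 1–20 mM, where the spectra scale
    linearly and no new bands appear.
    """
    c = np.asarray(series.concentrations, dtype=float)
    a = np.asarray(series.absorbances, dtype=float)
    if c.size < 4:
        raise InsufficientDataError(f"need >= 4 concentrations, got {c.size}")
    n = c.size

    eps_l = float(np.sum(c * a) / np.sum(c**2))
    rss_lin = float(np.sum((a - eps_l * c) ** 2))
    aicc_lin = _aicc(rss_lin, n, 1)

    def dimer_resid(params):
        em, ed, logk = params
        k = math.exp(logk)
        m = _monomer_concentration(c, k)
        d = k * m**2
        return a - (em * m + ed * d)

    best = None
    for logk0 in (math.log(1.0), math.log(10.0), math.log(100.0)):
        try:
            sol = least_squares(
                dimer_resid,
                x0=[eps_l, 0.5 * eps_l, logk0],
                bounds=([0.0, 0.0, -20.0], [np.inf, np.inf, 20.0]),
                xtol=1e-14,
                ftol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("dimer-model fit failed to converge")
    rss_dim = float(np.sum(dimer_resid(best.x) ** 2))
    aicc_dim = _aicc(rss_dim, n, 3)

    # curvature diagnostic: z-score of the quadratic coefficient of A(C)
    X = np.column_stack([c, c**2])
    coef, res_, rank_, sv_ = np.linalg.lstsq(X, a, rcond=None)
    resid_q = a - X @ coef
    dof = max(n - 2, 1)
    s2 = float(np.sum(resid_q**2)) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    z = float(coef[1] / math.sqrt(cov[1, 1])) if cov[1, 1] > 0 else 0.0

    linear_preferred = aicc_lin <= aicc_dim
    k_fit = 0.0 if linear_preferred else float(math.exp(best.x[2]))
    cmax = float(c.max()) if c.size else 0.0
    if k_fit > 0 and cmax > 0:
        m = _monomer_concentration(np.array([cmax]), k_fit)[0]
        dimer_frac = 2.0 * k_fit * m**2 / cmax
    else:
        dimer_frac = 0.0
    return SpeciationReport(
        verdict="monomeric" if linear_preferred else "nonlinear (dimerization suspected)",
        linear_aicc=aicc_lin,
        dimer_aicc=aicc_dim,
        epsilon_l=eps_l,
        dimer_K=k_fit,
        dimer_fraction_at_max=dimer_frac,
        curvature_z=z,
    )
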