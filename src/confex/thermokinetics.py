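"""Activation and equilibrium thermodynamics.

Transition-state (Eyring-Polanyi) analysis of temperature-dependent rate
constants, Gibbs-Helmholtz activation barriers, Michaelis-Menten enzyme
kinetics, two-state van't Hoff thermal melts and binding free energies --
the quantitative chain that lets a conformational-exchange barrier be
compared with a catalytic one.

Conventions
-----------
* Temperatures are absolute (K) inside the library; CLI/table readers accept
  degrees Celsius and convert with a 273.15 offset.
* Energies are J mol^-1, entropies J mol^-1 K^-1, rates s^-1.
* The Eyring regression is performed in the linearized form

      ln(k/T) = ln(k_B/h) + dS/R - (dH/R) * (1/T)

  optionally weighted by 1/se^2 of ln(k/T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import H_PLANCK, K_B, R_GAS
from .exceptions import DomainError, FitFailureError, InvalidInputError

__all__ = [
    "EyringParameters",
    "RateSeries",
    "MichaelisFit",
    "MeltFit",
    "Barrier",
    "BarrierComparison",
    "eyring_fit",
    "eyring_rate",
    "gibbs_activation",
    "binding_free_energy",
    "michaelis_menten_fit",
    "vant_hoff_melt_fit",
    "compare_barriers",
]

_LN_KB_OVER_H = np.log(K_B / H_PLANCK)


@dataclass(frozen=True)
class EyringParameters:
    """Activation enthalpy/entropy pair from an Eyring-Polanyi regression.

    Attributes
    ----------
    dH : float
        Activation enthalpy, J mol^-1.
    dS : float
        Activation entropy, J mol^-1 K^-1.
    dH_se, dS_se : float
        Standard errors (same units); zero for noise-free/underdetermined fits.
    cov_HS : float
        Covariance of (dH, dS), J^2 mol^-2 K^-1; used for barrier SE
        propagation.
    """

    dH: float
    dS: float
    dH_se: float = 0.0
    dS_se: float = 0.0
    cov_HS: float = 0.0

    def __post_init__(self):
        if self.dH_se < 0 or self.dS_se < 0:
            raise InvalidInputError("standard errors must be non-negative")


@dataclass(frozen=True)
class RateSeries:
    """First-order rate constants against absolute temperature."""

    temperatures: np.ndarray
    rates: np.ndarray
    rate_se: np.ndarray | None = None

    def __post_init__(self):
        T = np.asarray(self.temperatures, dtype=float)
        k = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "rates", k)
        if T.shape != k.shape:
            raise InvalidInputError("temperatures and rates must have equal length")
        if np.any(T <= 0):
            raise DomainError("absolute temperatures must be positive")
        if np.any(k <= 0):
            raise DomainError("rate constants must be positive")
        if self.rate_se is not None:
            se = np.asarray(self.rate_se, dtype=float)
            if se.shape != k.shape:
                raise InvalidInputError("rate_se length mismatch")
            object.__setattr__(self, "rate_se", se)


@dataclass(frozen=True)
class MichaelisFit:
    """Michaelis-Menten parameters: v = Vmax*c/(Km + c)."""

    kcat: float
    Km: float
    kcat_se: float
    Km_se: float
    Vmax: float
    Vmax_se: float

    def __post_init__(self):
        if self.kcat <= 0 or self.Km <= 0:
            raise InvalidInputError("kcat and Km must be positive")


@dataclass(frozen=True)
class MeltFit:
    """Two-state thermal unfolding fit with linear folded/unfolded baselines."""

    Tm: float
    dHvH: float
    m_f: float
    m_u: float
    Xi_f: float
    Xi_u: float
    Tm_se: float = 0.0
    dHvH_se: float = 0.0

    def unfolded_fraction(self, T):
        """f_u(T) = K_u/(1+K_u) with K_u = exp(-(dHvH/R)(1/T - 1/Tm))."""
        T = np.asarray(T, dtype=float)
        Ku = np.exp(-(self.dHvH / R_GAS) * (1.0 / T - 1.0 / self.Tm))
        return Ku / (1.0 + Ku)


@dataclass(frozen=True)
class Barrier:
    """An activation free energy with its standard error at a stated T."""

    value: float
    se: float
    temperature: float


@dataclass(frozen=True)
class BarrierComparison:
    """Agreement report between two barriers measured at the same temperature."""

    difference: float
    pooled_se: float
    z: float
    agree: bool
    temperature: float


def eyring_fit(series: RateSeries) -> EyringParameters:
    """Fit activation enthalpy and entropy to a rate-vs-temperature series.

    Weighted linear regression of ln(k/T) on 1/T: the slope is -dH/R and the
    intercept ln(k_B/h) + dS/R. When ``series.rate_se`` is present the points
    are weighted by 1/se(ln k)^2 with se(ln k) = rate_se/rate, and the
    parameter covariance assumes those errors are correct; otherwise the
    residual variance scales the covariance (and the SEs are zero when only
    two points leave no residual degrees of freedom).
    """
    T = series.temperatures
    if np.unique(T).size < 2:
        raise InvalidInputError("need at least 2 distinct temperatures for an Eyring fit")
    x = 1.0 / T
    y = np.log(series.rates / T)
    if series.rate_se is not None:
        sigma = series.rate_se / series.rates
        w = 1.0 / sigma**2
        known_sigma = True
    else:
        w = np.ones_like(y)
        known_sigma = False

    X = np.column_stack([x, np.ones_like(x)])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ beta
    cov = np.linalg.inv(XtWX)
    dof = y.size - 2
    if not known_sigma:
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = cov * s2

    slope, intercept = beta
    dH = -R_GAS * slope
    dS = R_GAS * (intercept - _LN_KB_OVER_H)
    dH_se = R_GAS * np.sqrt(max(cov[0, 0], 0.0))
    dS_se = R_GAS * np.sqrt(max(cov[1, 1], 0.0))
    cov_HS = -R_GAS**2 * cov[0, 1]
    return EyringParameters(float(dH), float(dS), float(dH_se), float(dS_se), float(cov_HS))


def eyring_rate(params: EyringParameters, T) -> np.ndarray | float:
    """Eyring-Polanyi rate k(T) = (k_B T/h) exp(-(dH - T dS)/(R T))."""
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0):
        raise DomainError("absolute temperature must be positive")
    k = (K_B * T_arr / H_PLANCK) * np.exp(-(params.dH - T_arr * params.dS) / (R_GAS * T_arr))
    return float(k) if np.isscalar(T) or T_arr.ndim == 0 else k


def gibbs_activation(params: EyringParameters, T: float, *,
                     propagate: str = "covariance") -> Barrier:
    """Activation free energy dG = dH - T*dS at temperature T.

    Parameters
    ----------
    propagate : {"covariance", "marginal"}
        SE propagation. ``"covariance"`` (default) uses the full (dH, dS)
        covariance: var = var_H + T^2 var_S - 2 T cov. ``"marginal"`` drops
        the covariance term, giving the conservative parameter-level
        uncertainty appropriate when comparing barriers between independent
        experiments whose systematic differences dominate.
    """
    if T <= 0:
        raise DomainError("absolute temperature must be positive")
    dG = params.dH - T * params.dS
    var = params.dH_se**2 + T**2 * params.dS_se**2
    if propagate == "covariance":
        var -= 2.0 * T * params.cov_HS
    elif propagate != "marginal":
        raise InvalidInputError(f"unknown propagation mode {propagate!r}")
    return Barrier(float(dG), float(np.sqrt(max(var, 0.0))), float(T))


def binding_free_energy(Kd: float, T: float) -> float:
    """Stabilization free energy R T ln(1 M / Kd), J mol^-1.

    Positive for sub-molar dissociation constants; reported as the magnitude
    by which ligand binding lowers the free energy of the system.
    """
    if Kd <= 0:
        raise DomainError("dissociation constant must be positive")
    if T <= 0:
        raise DomainError("absolute temperature must be positive")
    return R_GAS * T * np.log(1.0 / Kd)


def michaelis_menten_fit(concentrations, velocities,
                         enzyme_concentration: float = 1.0) -> MichaelisFit:
    """Nonlinear least-squares fit of v = Vmax*c/(Km + c).

    ``enzyme_concentration`` (same molarity unit as the velocities' implied
    enzyme normalization) converts Vmax into the turnover number
    kcat = Vmax/[E]. With the default of 1 the reported kcat equals Vmax.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if c.shape != v.shape:
        raise InvalidInputError("concentration and velocity arrays must match")
    if np.unique(c).size < 3:
        raise InvalidInputError("need >= 3 distinct substrate concentrations")
    if np.any(c < 0):
        raise DomainError("substrate concentrations must be non-negative")

    def model(cc, Vmax, Km):
        return Vmax * cc / (Km + cc)

    p0 = (float(v.max()) * 1.2, float(np.median(c)))
    try:
        popt, pcov = curve_fit(model, c, v, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitFailureError(f"Michaelis-Menten fit did not converge: {exc}")
    Vmax, Km = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if c.max() < Km:
        warnings.warn(
            "all substrate concentrations lie below the fitted Km; "
            "Vmax and Km are poorly conditioned (only Vmax/Km is determined)",
            stacklevel=2,
        )
    return MichaelisFit(
        kcat=float(Vmax / enzyme_concentration),
        Km=float(Km),
        kcat_se=float(se[0] / enzyme_concentration),
        Km_se=float(se[1]),
        Vmax=float(Vmax),
        Vmax_se=float(se[0]),
    )


def melt_signal(T, Tm, dHvH, m_f, m_u, Xi_f, Xi_u):
    """Observed ellipticity of the six-parameter two-state melt model."""
    T = np.asarray(T, dtype=float)
    Ku = np.exp(-(dHvH / R_GAS) * (1.0 / T - 1.0 / Tm))
    folded = Xi_f + m_f * T
    unfolded = Xi_u + m_u * T
    return (folded + unfolded * Ku) / (1.0 + Ku)


def vant_hoff_melt_fit(temperatures, ellipticities) -> MeltFit:
    """Fit a two-state thermal melt with linear baselines.

    The equilibrium constant toward unfolding is
    K_u(T) = exp(-(dHvH/R)(1/T - 1/Tm)), so the unfolded fraction is 0.5 at
    the midpoint Tm and its slope there is dHvH/(4 R Tm^2).
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(ellipticities, dtype=float)
    if T.shape != y.shape:
        raise InvalidInputError("temperature and ellipticity arrays must match")
    if np.any(np.diff(T) <= 0):
        raise InvalidInputError("temperature grid must be strictly increasing")

    # no transition => nothing to fit: compare total excursion with the
    # point-to-point noise estimated from second differences
    noise = np.std(np.diff(y, 2)) / np.sqrt(6.0) if y.size > 4 else 0.0
    if np.ptp(y) <= max(5.0 * noise, 1e-12 * max(1.0, np.abs(y).max())):
        raise FitFailureError("no sigmoidal transition detectable in melt data")

    # initial guesses: baselines from the ends, Tm where the signal crosses
    # the midpoint of the two baseline values
    n_edge = max(3, T.size // 10)
    m_f0, Xi_f0 = np.polyfit(T[:n_edge], y[:n_edge], 1)
    m_u0, Xi_u0 = np.polyfit(T[-n_edge:], y[-n_edge:], 1)
    mid = 0.5 * (y[0] + y[-1])
    Tm0 = float(T[np.argmin(np.abs(y - mid))])
    p0 = (Tm0, 250e3, m_f0, m_u0, Xi_f0, Xi_u0)
    try:
        popt, pcov = curve_fit(melt_signal, T, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"melt fit did not converge: {exc}")
    Tm, dHvH, m_f, m_u, Xi_f, Xi_u = popt
    if not (T[0] <= Tm <= T[-1]):
        raise FitFailureError(
            f"fitted midpoint {Tm:.1f} K lies outside the measured range; "
            "no transition is bracketed"
        )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return MeltFit(
        Tm=float(Tm), dHvH=float(dHvH), m_f=float(m_f), m_u=float(m_u),
        Xi_f=float(Xi_f), Xi_u=float(Xi_u),
        Tm_se=float(se[0]), dHvH_se=float(se[1]),
    )


def compare_barriers(dG_dynamics: Barrier, dG_catalysis: Barrier,
                     n_sigma: float = 2.0) -> BarrierComparison:
    """Test whether two activation barriers agree within pooled uncertainty.

    Returns the difference (dynamics - catalysis), the pooled standard error
    sqrt(se1^2 + se2^2), the z-score, and an agreement flag set when
    |difference| <= n_sigma * pooled SE. Both barriers must refer to the
    same temperature.
    """
    if abs(dG_dynamics.temperature - dG_catalysis.temperature) > 1e-9:
        raise InvalidInputError(
            "barriers must be evaluated at the same temperature "
            f"({dG_dynamics.temperature} K vs {dG_catalysis.temperature} K)"
        )
    diff = dG_dynamics.value - dG_catalysis.value
    pooled = float(np.hypot(dG_dynamics.se, dG_catalysis.se))
    z = diff / pooled if pooled > 0 else (0.0 if diff == 0 else np.inf)
    return BarrierComparison(
        difference=float(diff),
        pooled_se=pooled,
        z=float(z),
        agree=bool(abs(diff) <= n_sigma * pooled),
        temperature=dG_dynamics.temperature,
    )
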