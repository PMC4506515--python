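"""Ligand-binding and solvent-exchange observables.

Single-exponential stopped-flow fluorescence kinetics, single-site ITC
isotherm fitting with displaced-volume corrections, weighted amide
chemical-shift perturbations, and MEXICO-style water-magnetization
build-up fits for fast amide proton exchange.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .constants import J_PER_CAL
from .exceptions import DomainError, FitFailureError, InvalidInputError

__all__ = [
    "KineticTrace",
    "StoppedFlowFit",
    "BindingIsotherm",
    "ItcFit",
    "ShiftPair",
    "BuildupSeries",
    "MexicoFit",
    "fit_stopped_flow",
    "itc_injection_heats",
    "fit_itc_single_site",
    "csp",
    "mexico_buildup",
    "fit_mexico_buildup",
]

DEFAULT_CELL_WORKING_UL = 200.0
"""Working cell volume (μl) of an Auto-iTC200-class calorimeter."""


# ---------------------------------------------------------------------------
# stopped flow


@dataclass(frozen=True)
class KineticTrace:
    """A (possibly replicate-averaged) fluorescence-vs-time trace."""

    time: np.ndarray
    intensity: np.ndarray
    temperature_C: float
    ligand_concentration: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        I = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", I)
        if t.shape != I.shape:
            raise InvalidInputError("time and intensity must have equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must be non-negative and sorted")


@dataclass(frozen=True)
class StoppedFlowFit:
    k_app: float
    k_app_se: float
    amplitude: float
    amplitude_se: float
    offset: float
    offset_se: float


def average_traces(traces) -> KineticTrace:
    """Point-wise average of replicate traces sharing one time base."""
    t0 = traces[0].time
    for tr in traces[1:]:
        if tr.time.shape != t0.shape or not np.allclose(tr.time, t0):
            raise InvalidInputError("replicate traces must share a common time base")
    mean_I = np.mean([tr.intensity for tr in traces], axis=0)
    return KineticTrace(t0, mean_I, traces[0].temperature_C,
                        traces[0].ligand_concentration)


def fit_stopped_flow(trace, dead_time: float = 0.0) -> StoppedFlowFit:
    """Fit I(t) = I_inf + dI*exp(-k_app*t) to a stopped-flow trace.

    ``trace`` may be a single :class:`KineticTrace` or a sequence of
    replicates, which are averaged before fitting. Points earlier than
    ``dead_time`` (mixing dead time, s) are discarded. Warns when the trace
    is shorter than ~3/k_app (amplitude/offset then trade off) and when the
    residuals show non-exponential structure (sign-runs test).
    """
    if not isinstance(trace, KineticTrace):
        trace = average_traces(list(trace))
    keep = trace.time >= dead_time
    t = trace.time[keep]
    I = trace.intensity[keep]
    if t.size < 4:
        raise InvalidInputError("too few points after dead-time truncation")

    def model(tt, I_inf, dI, k):
        return I_inf + dI * np.exp(-k * tt)

    span = t[-1] - t[0]
    dI0 = I[0] - I[-1]
    p0 = (float(I[-1]), float(dI0), 3.0 / span)
    try:
        popt, pcov = curve_fit(model, t, I, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"stopped-flow fit did not converge: {exc}")
    I_inf, dI, k = popt
    if k <= 0:
        raise FitFailureError("stopped-flow fit returned a non-positive rate")
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if span < 3.0 / k:
        warnings.warn(
            f"trace duration {span:.3g} s is shorter than 3/k_app = {3.0 / k:.3g} s; "
            "amplitude and offset are weakly determined", stacklevel=2,
        )
    resid = I - model(t, *popt)
    _warn_if_structured(resid)
    return StoppedFlowFit(k_app=float(k), k_app_se=float(se[2]),
                          amplitude=float(dI), amplitude_se=float(se[1]),
                          offset=float(I_inf), offset_se=float(se[0]))


def _warn_if_structured(resid):
    """Runs test on residual signs; too few runs means systematic misfit."""
    s = np.sign(resid[resid != 0])
    if s.size < 20:
        return
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    n_pos = int(np.sum(s > 0))
    n_neg = s.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return
    mu = 1 + 2 * n_pos * n_neg / s.size
    var = (mu - 1) * (mu - 2) / (s.size - 1)
    if var > 0 and (runs - mu) / np.sqrt(var) < -4.0:
        warnings.warn(
            "stopped-flow residuals show non-exponential structure "
            "(sign-runs test)", stacklevel=3,
        )


# ---------------------------------------------------------------------------
# ITC


@dataclass(frozen=True)
class BindingIsotherm:
    """An ITC titration: injection volumes, integrated heats, concentrations.

    ``heats`` are per-injection integrated heats in μcal. ``cell_volume``
    is the working (detected) cell volume in μl. The first injection is a
    small discard shot excluded from fitting.
    """

    injection_volumes: np.ndarray
    heats: np.ndarray
    cell_concentration: float
    syringe_concentration: float
    temperature: float
    cell_volume: float = DEFAULT_CELL_WORKING_UL
    first_is_discard: bool = True

    def __post_init__(self):
        v = np.asarray(self.injection_volumes, dtype=float)
        q = np.asarray(self.heats, dtype=float)
        object.__setattr__(self, "injection_volumes", v)
        object.__setattr__(self, "heats", q)
        if v.shape != q.shape:
            raise InvalidInputError("volumes and heats must have equal length")
        if np.any(v <= 0):
            raise DomainError("injection volumes must be positive")
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise DomainError("concentrations must be positive")

    @property
    def molar_ratio(self) -> np.ndarray:
        """Approximate cumulative ligand:protein molar ratio per injection."""
        Xt, Mt = _cell_concentrations(self)
        return Xt / Mt


def _cell_concentrations(iso: BindingIsotherm):
    """Origin-style displaced-volume corrected cell concentrations.

    After a cumulative injected volume dV (μl) into a working volume V0:
        Mt = M0 * (1 - dV/2V0) / (1 + dV/2V0)
        Xt = X_syr * (dV/V0) / (1 + dV/2V0)
    """
    V0 = iso.cell_volume
    dV = np.cumsum(iso.injection_volumes)
    Mt = iso.cell_concentration * (1.0 - dV / (2 * V0)) / (1.0 + dV / (2 * V0))
    Xt = iso.syringe_concentration * (dV / V0) / (1.0 + dV / (2 * V0))
    return Xt, Mt


def itc_injection_heats(iso: BindingIsotherm, Kd: float, dH: float,
                        n: float) -> np.ndarray:
    """Per-injection heats (μcal) of the single-site Wiseman model.

    The bound fraction after each injection comes from the quadratic root
    of the 1:n mass balance; the differential heat includes the standard
    displaced-volume correction
        q_i = Q_i - Q_{i-1} + (dV_i/V0)*(Q_i + Q_{i-1})/2,
    with Q the cell heat content n*Theta*Mt*dH*V0.
    """
    if Kd < 0 or n <= 0:
        raise DomainError("Kd must be >= 0 and n > 0")
    Xt, Mt = _cell_concentrations(iso)
    V0_l = iso.cell_volume * 1e-6
    r = Kd / (n * Mt)
    x = Xt / (n * Mt)
    disc = (1.0 + x + r) ** 2 - 4.0 * x
    theta = 0.5 * (1.0 + x + r - np.sqrt(np.clip(disc, 0.0, None)))
    Q = n * theta * Mt * dH * V0_l  # J
    Q_prev = np.concatenate([[0.0], Q[:-1]])
    dV = iso.injection_volumes * 1e-6
    q = Q - Q_prev + (dV / V0_l) * (Q + Q_prev) / 2.0
    return q / J_PER_CAL * 1e6  # -> μcal


@dataclass(frozen=True)
class ItcFit:
    Kd: float
    Kd_se: float
    dH: float
    dH_se: float
    n: float
    n_se: float


def fit_itc_single_site(iso: BindingIsotherm) -> ItcFit:
    """Fit (K_D, binding enthalpy, stoichiometry) to an ITC isotherm.

    The first (discard) injection is excluded. Warns when the Wiseman
    c-value n*[P]/K_D falls outside [1, 1e4] (sigmoid too sharp or too
    shallow for all three parameters) or when the isotherm shows no
    curvature at all.
    """
    usable = np.ones(iso.heats.size, dtype=bool)
    if iso.first_is_discard:
        usable[0] = False
    if usable.sum() < 10:
        raise InvalidInputError("need >= 10 usable injections")
    q_obs = iso.heats[usable]
    if np.ptp(q_obs) < 0.05 * np.max(np.abs(q_obs)):
        warnings.warn("flat isotherm: binding parameters weakly identifiable",
                      stacklevel=2)

    dV_per_mol = iso.injection_volumes * 1e-6 * iso.syringe_concentration
    dH0 = q_obs[0] * J_PER_CAL * 1e-6 / dV_per_mol[usable][0]

    def resid(theta):
        logKd, dH, n = theta
        q = itc_injection_heats(iso, np.exp(logKd), dH, n)
        return q[usable] - q_obs

    x0 = np.array([np.log(iso.cell_concentration / 100.0), dH0, 1.0])
    sol = least_squares(resid, x0, method="lm", max_nfev=20000)
    if not sol.success:
        raise FitFailureError("ITC single-site fit did not converge",
                              residuals=sol.fun)
    logKd, dH, n = sol.x
    Kd = float(np.exp(logKd))
    dof = max(q_obs.size - 3, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        Kd_se = float(Kd * ses[0])
        dH_se = float(ses[1])
        n_se = float(ses[2])
    except np.linalg.LinAlgError:
        Kd_se = dH_se = n_se = float("nan")
    c = n * iso.cell_concentration / Kd if Kd > 0 else np.inf
    if not (1.0 <= c <= 1e4):
        warnings.warn(
            f"Wiseman c-value {c:.3g} outside [1, 1e4]; K_D weakly identifiable",
            stacklevel=2,
        )
    return ItcFit(Kd=Kd, Kd_se=Kd_se, dH=float(dH), dH_se=dH_se,
                  n=float(n), n_se=n_se)


# ---------------------------------------------------------------------------
# chemical shift perturbation


@dataclass(frozen=True)
class ShiftPair:
    """Amide 1H/15N chemical-shift differences (p.p.m.) for one residue."""

    dH_ppm: float
    dN_ppm: float
    residue: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.dH_ppm) and np.isfinite(self.dN_ppm)):
            raise InvalidInputError("shift differences must be finite")


def csp(pair: ShiftPair, alpha: float = 0.2) -> float:
    """Weighted shift perturbation sqrt(dH^2 + (alpha*dN)^2), p.p.m.

    ``alpha`` down-weights the 15N dimension for its larger shift range;
    0.2 is the common amide convention.
    """
    if alpha <= 0:
        raise DomainError("nitrogen weight alpha must be positive")
    return float(np.hypot(pair.dH_ppm, alpha * pair.dN_ppm))


# ---------------------------------------------------------------------------
# MEXICO amide solvent exchange


@dataclass(frozen=True)
class BuildupSeries:
    """Normalized water-transfer build-up intensities vs mixing delay."""

    delays: np.ndarray
    intensities: np.ndarray
    residue: str = ""

    def __post_init__(self):
        t = np.asarray(self.delays, dtype=float)
        I = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "delays", t)
        object.__setattr__(self, "intensities", I)
        if t.shape != I.shape:
            raise InvalidInputError("delays and intensities must match")
        if np.any(t < 0):
            raise DomainError("mixing delays must be >= 0")
        if np.any((I < -0.1) | (I > 1.5)):
            raise InvalidInputError(
                "normalized intensities outside the [-0.1, 1.5] sanity band"
            )


@dataclass(frozen=True)
class MexicoFit:
    k_hx: float
    k_hx_se: float
    amplitude: float
    initial_slope_fallback: bool = False


def mexico_buildup(t, A, k_hx, R1_water, R1_amide):
    """Two-exponential water->amide transfer build-up.

    I(t) = A*k_hx*(exp(-R1w*t) - exp(-(R1a+k_hx)*t))/(R1a + k_hx - R1w);
    zero at t=0, initial slope A*k_hx.
    """
    t = np.asarray(t, dtype=float)
    lam = R1_amide + k_hx
    sep = lam - R1_water
    if abs(sep) < 1e-10:
        return A * k_hx * t * np.exp(-R1_water * t)
    return A * k_hx * (np.exp(-R1_water * t) - np.exp(-lam * t)) / sep


def fit_mexico_buildup(series: BuildupSeries, R1_water: float,
                       R1_amide: float) -> MexicoFit:
    """Fit the solvent-exchange rate k_hx to a build-up series.

    The water and amide longitudinal relaxation rates are supplied
    (measured independently in practice). When the fitted rates become
    degenerate (|R1a + k_hx - R1w| ~ 0) the estimator falls back to the
    initial-slope construction I(t) ~ A*k_hx*t, flagged on the result.
    """
    t = series.delays
    I = series.intensities
    if np.unique(t[t > 0]).size < 4:
        raise InvalidInputError("need >= 4 non-zero mixing delays")

    slope0 = float(I[t > 0][0] / t[t > 0][0])

    def resid(theta):
        A, k = theta
        return mexico_buildup(t, A, k, R1_water, R1_amide) - I

    sol = least_squares(resid, x0=np.array([max(slope0, 0.1), 2.0]),
                        bounds=([0.0, 0.0], np.inf), method="trf",
                        max_nfev=10000)
    A, k = sol.x
    if abs(R1_amide + k - R1_water) < 1e-6 * max(R1_water, 1.0):
        # degenerate separation: initial slope only
        early = t <= (t[t > 0].min() * 2 + 1e-12)
        slope = float(np.sum(I[early] * t[early]) / np.sum(t[early] ** 2))
        return MexicoFit(k_hx=slope / max(A, 1e-12), k_hx_se=float("nan"),
                         amplitude=A, initial_slope_fallback=True)
    dof = max(t.size - 2, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        k_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        k_se = float("nan")
    return MexicoFit(k_hx=float(k), k_hx_se=k_se, amplitude=float(A))
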