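"""ZZ-exchange (EXSY) analysis of slow conformational interconversion.

Longitudinal magnetization prepared on either of two slowly exchanging
states redistributes during a mixing time, producing auto peaks (AA, BB)
and exchange cross peaks (AB, BA). Two estimators for the interconversion
rate k_conf = k_open + k_close are provided:

* the relaxation-compensated intensity ratio

      Xi = (I_AB * I_BA) / (I_AA * I_BB - I_AB * I_BA)
         = p_A * p_B * (1 - exp(-k*t))^2 / exp(-k*t)

  which cancels uniform longitudinal relaxation and any overall intensity
  scale, fitted per residue and pooled by inverse variance;

* a joint ("four-curve") fit of all auto/cross build-ups against the
  kinetic propagator with a shared R1 and overall scale.

:func:`propagate_two_state` is the independent matrix-exponential oracle for
both estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .exceptions import (
    DomainError,
    FitFailureError,
    InvalidInputError,
    OutOfRegimeError,
)

__all__ = [
    "IntensityQuartet",
    "ZZSeries",
    "KconfEstimate",
    "FarrowFit",
    "propagate_two_state",
    "xi_statistic",
    "xi_closed_form",
    "fit_kconf_xi",
    "fit_kconf_farrow",
]


@dataclass(frozen=True)
class IntensityQuartet:
    """Auto (AA, BB) and cross (AB, BA) peak intensities at one mixing time."""

    t_mix: float
    I_AA: float
    I_BB: float
    I_AB: float
    I_BA: float

    def __post_init__(self):
        if self.t_mix < 0:
            raise DomainError("mixing time must be >= 0")
        for v in (self.I_AA, self.I_BB, self.I_AB, self.I_BA):
            if not np.isfinite(v):
                raise InvalidInputError("intensities must be finite")


@dataclass(frozen=True)
class ZZSeries:
    """Quartets for one residue at >= 3 distinct, sorted mixing times."""

    residue: str
    quartets: tuple

    def __post_init__(self):
        q = tuple(self.quartets)
        object.__setattr__(self, "quartets", q)
        t = [qq.t_mix for qq in q]
        if len(t) < 3:
            raise InvalidInputError("need quartets at >= 3 mixing times")
        if len(set(t)) != len(t) or sorted(t) != t:
            raise InvalidInputError("mixing times must be distinct and sorted")

    @property
    def t_mix(self) -> np.ndarray:
        return np.array([q.t_mix for q in self.quartets])


@dataclass(frozen=True)
class KconfEstimate:
    """Pooled interconversion rate with per-residue detail."""

    k_conf: float
    se: float
    per_residue: dict


@dataclass(frozen=True)
class FarrowFit:
    """Joint four-curve fit result: exchange rate and shared R1."""

    k_conf: float
    k_conf_se: float
    R1: float
    R1_se: float
    scale: float


def propagate_two_state(k_conf: float, p_open: float, R1: float,
                        t: float) -> IntensityQuartet:
    """Matrix-exponential propagation of the two-state ZZ experiment.

    The rate matrix obeys detailed balance (k_AB = p_B*k_conf out of A,
    k_BA = p_A*k_conf out of B, with A the open state of population
    ``p_open``); relaxation is a uniform R1 decay superimposed on exchange.
    Auto peaks start at the equilibrium populations, cross peaks at zero.
    """
    if not (0.0 < p_open < 1.0):
        raise DomainError("p_open must lie strictly inside (0, 1)")
    if k_conf < 0 or R1 < 0 or t < 0:
        raise DomainError("rates and times must be >= 0")
    pA, pB = p_open, 1.0 - p_open
    L = np.array([[-pB * k_conf, pA * k_conf],
                  [pB * k_conf, -pA * k_conf]]) - R1 * np.eye(2)
    P = expm(L * t)
    # column j = fate of magnetization prepared on state j
    return IntensityQuartet(
        t_mix=t,
        I_AA=float(P[0, 0] * pA),
        I_BB=float(P[1, 1] * pB),
        I_BA=float(P[1, 0] * pA),   # prepared on A, detected on B
        I_AB=float(P[0, 1] * pB),
    )


def xi_statistic(q: IntensityQuartet) -> float:
    """Relaxation-compensated exchange ratio Xi of one quartet.

    Xi = (I_AB*I_BA)/(I_AA*I_BB - I_AB*I_BA). Valid in the slow-exchange,
    moderate-mixing regime where the auto-peak product exceeds the
    cross-peak product; outside it the denominator is non-positive.
    """
    num = q.I_AB * q.I_BA
    den = q.I_AA * q.I_BB - num
    if den <= 0:
        raise OutOfRegimeError(
            f"quartet at t_mix={q.t_mix!r} s outside the Xi regime "
            f"(I_AA*I_BB = {q.I_AA * q.I_BB:.4g} <= I_AB*I_BA = {num:.4g})"
        )
    return float(num / den)


def xi_closed_form(k_conf, t, p_open: float = 0.5):
    """Xi(t) = p_A*p_B*(1 - exp(-k t))^2 / exp(-k t) for uniform R1."""
    t = np.asarray(t, dtype=float)
    pA, pB = p_open, 1.0 - p_open
    E = np.exp(-k_conf * t)
    return pA * pB * (1.0 - E) ** 2 / E


def fit_kconf_xi(series_list, p_open: float = 0.5) -> KconfEstimate:
    """Exchange rate from the Xi build-up, pooled over residues.

    Each residue's usable quartets (those inside the Xi regime) are fitted
    by least squares to the closed form; residues with fewer than three
    usable mixing times are skipped. The global rate is the
    inverse-variance weighted mean of per-residue estimates (plain mean if
    no residue yields a finite SE, as happens on noise-free data).
    """
    if isinstance(series_list, ZZSeries):
        series_list = [series_list]
    per_residue = {}
    for series in series_list:
        t, xi = [], []
        for q in series.quartets:
            try:
                xi.append(xi_statistic(q))
                t.append(q.t_mix)
            except OutOfRegimeError:
                continue
        if len(t) < 3:
            continue
        t = np.asarray(t)
        xi = np.asarray(xi)
        # initialize from the small-t expansion Xi ~ pA*pB*k^2*t^2
        pApB = p_open * (1.0 - p_open)
        k0 = float(np.sqrt(np.median(xi / (pApB * t**2))))

        def resid(logk):
            return xi_closed_form(np.exp(logk[0]), t, p_open) - xi

        sol = least_squares(resid, np.array([np.log(max(k0, 1e-3))]),
                            method="lm", max_nfev=2000)
        k = float(np.exp(sol.x[0]))
        dof = max(t.size - 1, 1)
        s2 = 2.0 * sol.cost / dof
        JtJ = float((sol.jac.T @ sol.jac).reshape(()))
        se = k * np.sqrt(s2 / JtJ) if JtJ > 0 else np.nan
        per_residue[series.residue] = (k, float(se))
    if not per_residue:
        raise FitFailureError("no residue had >= 3 quartets inside the Xi regime")
    ks = np.array([v[0] for v in per_residue.values()])
    ses = np.array([v[1] for v in per_residue.values()])
    ok = np.isfinite(ses) & (ses > 0)
    if ok.any():
        w = 1.0 / ses[ok] ** 2
        k_glob = float(np.sum(w * ks[ok]) / np.sum(w))
        se_glob = float(np.sqrt(1.0 / np.sum(w)))
    else:
        k_glob = float(ks.mean())
        se_glob = float(ks.std(ddof=1) / np.sqrt(ks.size)) if ks.size > 1 else 0.0
    return KconfEstimate(k_conf=k_glob, se=se_glob, per_residue=per_residue)


def fit_kconf_farrow(series: ZZSeries, p_open: float = 0.5) -> FarrowFit:
    """Joint least-squares fit of all four intensity curves.

    Fits (k_conf, shared R1, overall scale) to the auto- and cross-peak
    build-ups predicted by :func:`propagate_two_state`. Requires >= 4
    mixing times for one residual degree of freedom beyond the three
    parameters.
    """
    if len(series.quartets) < 4:
        raise InvalidInputError("Farrow fit needs >= 4 mixing times")
    t = series.t_mix
    obs = np.array([[q.I_AA, q.I_BB, q.I_AB, q.I_BA] for q in series.quartets])

    pA, pB = p_open, 1.0 - p_open

    def model(k, R1, scale):
        E = np.exp(-k * t)
        decay = np.exp(-R1 * t)
        I_AA = pA * (pA + pB * E) * decay
        I_BB = pB * (pB + pA * E) * decay
        I_X = pA * pB * (1.0 - E) * decay
        return scale * np.column_stack([I_AA, I_BB, I_X, I_X])

    def resid(theta):
        k, R1, scale = theta
        return (model(k, R1, scale) - obs).ravel()

    scale0 = max(float(obs[0, 0] + obs[0, 1]), 1e-12)
    x0 = np.array([10.0, 1.0, scale0])
    sol = least_squares(resid, x0, bounds=([0.0, 0.0, 0.0], np.inf),
                        method="trf", max_nfev=5000,
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise FitFailureError("Farrow four-curve fit did not converge",
                              residuals=sol.fun)
    k, R1, scale = sol.x
    dof = max(obs.size - 3, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        k_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        R1_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        k_se = R1_se = float("nan")
    return FarrowFit(k_conf=float(k), k_conf_se=k_se,
                     R1=float(R1), R1_se=R1_se, scale=float(scale))
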