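"""PFG-NMR diffusion analysis.

Stejskal-Tanner fitting of stimulated-echo signal attenuation,

    I(G) = I0 * exp(-D * gamma^2 * delta^2 * G^2 * (Delta - delta/3)),

two-component open/closed mixture decomposition (the diffusion coefficient
of a species exchanging slowly between a compact closed and an expanded
open conformation is a population-weighted superposition of the two pure
decays), and Stokes-Einstein hydrodynamic radii.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .constants import GAMMA_1H, K_B
from .exceptions import DomainError, IdentifiabilityError, InvalidInputError

__all__ = [
    "DiffusionDecay",
    "MixtureWeights",
    "DiffusionFit",
    "MixtureFit",
    "stejskal_tanner_fit",
    "mixture_decompose",
    "hydrodynamic_radius",
    "b_factor",
]


@dataclass(frozen=True)
class DiffusionDecay:
    """Signal integrals versus gradient strength for one diffusion profile.

    ``gradients`` are absolute (T m^-1) unless ``max_gradient`` is given,
    in which case they are fractions (0..1 or percent if >1.5) of it.
    ``delta`` is the gradient pulse length and ``Delta`` the diffusion time
    (both s). An optional ``correction`` is subtracted from the effective
    diffusion time (hook for bipolar-pulse timing terms).
    """

    gradients: np.ndarray
    integrals: np.ndarray
    delta: float
    Delta: float
    max_gradient: float | None = None
    gamma: float = GAMMA_1H
    correction: float = 0.0

    def __post_init__(self):
        g = np.asarray(self.gradients, dtype=float)
        I = np.asarray(self.integrals, dtype=float)
        object.__setattr__(self, "gradients", g)
        object.__setattr__(self, "integrals", I)
        if g.shape != I.shape:
            raise InvalidInputError("gradients and integrals must match in length")
        if np.unique(g).size < 5:
            raise InvalidInputError("need >= 5 distinct gradient strengths")
        if np.any(I <= 0):
            raise DomainError("signal integrals must be positive")
        if self.delta <= 0 or self.Delta <= 0:
            raise DomainError("gradient length and diffusion time must be positive")

    @property
    def gradients_T_per_m(self) -> np.ndarray:
        if self.max_gradient is None:
            return self.gradients
        g = self.gradients
        if g.max() > 1.5:  # percent convention
            g = g / 100.0
        return g * self.max_gradient

    @property
    def b_values(self) -> np.ndarray:
        """Attenuation exponents b(G) = gamma^2*delta^2*G^2*(Delta-delta/3)."""
        G = self.gradients_T_per_m
        return b_factor(G, self.delta, self.Delta, self.gamma, self.correction)


@dataclass(frozen=True)
class MixtureWeights:
    """Open-state weight plus the two reference diffusion coefficients.

    The open conformation is larger and therefore diffuses more slowly:
    D_open < D_closed.
    """

    w_open: float
    D_open: float
    D_closed: float

    def __post_init__(self):
        if not (0.0 <= self.w_open <= 1.0):
            raise DomainError("w_open must lie in [0, 1]")
        if self.D_open <= 0 or self.D_closed <= 0:
            raise DomainError("diffusion coefficients must be positive")
        if self.D_open >= self.D_closed:
            raise DomainError("expected D_open < D_closed (open state diffuses slower)")


@dataclass(frozen=True)
class DiffusionFit:
    D: float
    D_se: float
    I0: float
    I0_se: float


@dataclass(frozen=True)
class MixtureFit:
    w_open: float
    w_se: float
    I0: float
    D_effective: float
    refs: MixtureWeights


def b_factor(G, delta, Delta, gamma=GAMMA_1H, correction=0.0):
    """Stejskal-Tanner exponent per unit D, s m^-2."""
    return gamma**2 * delta**2 * np.asarray(G, dtype=float) ** 2 * (Delta - delta / 3.0 - correction)


def stejskal_tanner_fit(decay: DiffusionDecay) -> DiffusionFit:
    """Single-component Stejskal-Tanner fit, I(b) = I0*exp(-D*b).

    Replicated gradient strengths, when present, provide an empirical noise
    SD used as ``sigma`` (absolute) in the fit, so the reported SEs reflect
    replicate scatter. Attenuation of less than 20% at the strongest
    gradient triggers a conditioning warning (the SE is then dominated by
    the near-degeneracy of I0 and D).
    """
    b = decay.b_values
    I = decay.integrals

    order = np.argsort(b)
    b_sorted, I_sorted = b[order], I[order]
    # gross monotonicity check: a noise-free decay cannot end above its start
    if I_sorted[-1] > I_sorted[0]:
        raise InvalidInputError("signal does not decay with gradient strength")

    attenuation = 1.0 - I_sorted[-1] / I_sorted[0]
    if attenuation < 0.2:
        warnings.warn(
            f"only {100 * attenuation:.0f}% attenuation at maximum gradient; "
            "D is poorly determined and its SE inflated", stacklevel=2,
        )

    # replicate scatter -> absolute noise estimate
    sigma = None
    uniq, counts = np.unique(b, return_counts=True)
    if np.any(counts > 1):
        devs = []
        for bb in uniq[counts > 1]:
            vals = I[b == bb]
            devs.extend(vals - vals.mean())
        devs = np.asarray(devs)
        if devs.size > 1 and np.any(devs != 0):
            sigma = float(np.sqrt(np.sum(devs**2) / (devs.size - np.sum(counts > 1))))

    def model(bb, I0, D):
        return I0 * np.exp(-D * bb)

    # log-linear initial guess
    slope, logI0 = np.polyfit(b, np.log(I), 1)
    p0 = (float(np.exp(logI0)), float(max(-slope, 1e-14)))
    kwargs = {}
    if sigma is not None:
        kwargs = {"sigma": np.full_like(I, sigma), "absolute_sigma": True}
    popt, pcov = curve_fit(model, b, I, p0=p0, maxfev=10000, **kwargs)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return DiffusionFit(D=float(popt[1]), D_se=float(se[1]),
                        I0=float(popt[0]), I0_se=float(se[0]))


def mixture_decompose(decay: DiffusionDecay, refs: MixtureWeights) -> MixtureFit:
    """Two-component decomposition with reference D's fixed.

    Fits I(b) = I0*[w*exp(-D_open*b) + (1-w)*exp(-D_closed*b)] with a shared
    I0 and a single open-state weight w. Also reports the effective
    single-component D for comparison with the pure references. The
    references must differ by at least 5% for w to be identifiable.
    """
    if abs(refs.D_closed - refs.D_open) / (0.5 * (refs.D_closed + refs.D_open)) < 0.05:
        raise IdentifiabilityError(
            "reference diffusion coefficients differ by <5%; "
            "mixture weight is not identifiable"
        )
    b = decay.b_values
    I = decay.integrals

    def resid(theta):
        I0, w = theta
        pred = I0 * (w * np.exp(-refs.D_open * b) + (1 - w) * np.exp(-refs.D_closed * b))
        return pred - I

    sol = least_squares(resid, x0=np.array([float(I.max()), 0.5]),
                        bounds=([0.0, 0.0], [np.inf, 1.0]), method="trf",
                        max_nfev=5000, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    I0, w = sol.x
    dof = max(b.size - 2, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        w_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        w_se = float("nan")
    eff = stejskal_tanner_fit(decay)
    return MixtureFit(w_open=float(w), w_se=w_se, I0=float(I0),
                      D_effective=eff.D, refs=refs)


def hydrodynamic_radius(D: float, T: float, viscosity: float) -> float:
    """Stokes-Einstein radius R_h = k_B*T/(6*pi*eta*D), in metres."""
    if D <= 0 or T <= 0 or viscosity <= 0:
        raise DomainError("D, T and viscosity must all be positive")
    return K_B * T / (6.0 * np.pi * viscosity * D)
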