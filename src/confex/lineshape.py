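"""Two-state chemical-exchange NMR line shapes.

Simulation of one-dimensional spectra of a spin exchanging between two
environments via the Bloch-McConnell equations, two-component Lorentzian
regression of 15N slices, and exchange-rate estimation by least-squares
matching of simulated to observed line shapes with populations and shift
offsets held fixed from the Lorentzian fit.

The two-state magnetization evolves as dM/dt = A M with

    A = i * diag(2*pi*d1, 2*pi*d2) - diag(R2_1, R2_2) + K,
    K = [[-k12, k21], [k12, -k21]],  k12 = p2*k_ex,  k21 = p1*k_ex,

so the absorption spectrum is S(w) = Re[ 1^T (i*w*I - A)^-1 p ], a sum of
two Lorentzians of FWHM R2/pi Hz in the uncoupled limit that broaden,
approach and finally coalesce into a single averaged line as k_ex grows
past ~sqrt(2)*pi*dnu (equal populations; each jump rate is then
pi*dnu/sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.signal import find_peaks

from .constants import DEFAULT_N15_MHZ
from .exceptions import DomainError, FitFailureError, InvalidInputError
from .thermokinetics import RateSeries

__all__ = [
    "TwoStateExchangeModel",
    "Spectrum1D",
    "LorentzianPair",
    "simulate_two_state_spectrum",
    "fit_two_lorentzian",
    "estimate_kex_lineshape",
    "coalescence_rate",
]


@dataclass(frozen=True)
class TwoStateExchangeModel:
    """Populations, shifts, relaxation and exchange rate of a two-state spin.

    Offsets ``delta1``/``delta2`` are in Hz. Detailed balance fixes the
    microscopic rates to k12 = p2*k_ex and k21 = p1*k_ex, so k_ex = k12+k21.
    """

    p1: float
    p2: float
    delta1: float
    delta2: float
    R2_1: float
    R2_2: float
    k_ex: float

    def __post_init__(self):
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise DomainError("populations must lie in [0, 1]")
        if abs(self.p1 + self.p2 - 1.0) > 1e-9:
            raise DomainError("populations must sum to 1")
        if self.R2_1 < 0 or self.R2_2 < 0:
            raise DomainError("transverse relaxation rates must be >= 0")
        if self.k_ex < 0:
            raise DomainError("exchange rate must be >= 0")

    @property
    def k12(self) -> float:
        return self.p2 * self.k_ex

    @property
    def k21(self) -> float:
        return self.p1 * self.k_ex


@dataclass(frozen=True)
class Spectrum1D:
    """A 1D spectral slice: strictly monotone frequency axis + intensities."""

    frequency: np.ndarray
    intensity: np.ndarray
    unit: str = "Hz"
    spectrometer_mhz: float = DEFAULT_N15_MHZ

    def __post_init__(self):
        f = np.asarray(self.frequency, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "intensity", y)
        if f.shape != y.shape:
            raise InvalidInputError("frequency and intensity must have equal length")
        if f.size < 3:
            raise InvalidInputError("spectrum needs at least 3 points")
        d = np.diff(f)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("frequency axis must be strictly monotone")
        if self.unit not in ("Hz", "ppm"):
            raise InvalidInputError("axis unit must be 'Hz' or 'ppm'")

    @property
    def frequency_hz(self) -> np.ndarray:
        if self.unit == "Hz":
            return self.frequency
        return self.frequency * self.spectrometer_mhz


@dataclass(frozen=True)
class LorentzianPair:
    """Parameters of a two-component Lorentzian regression (axis units)."""

    y1: float
    y2: float
    delta1: float
    delta2: float
    A1: float
    A2: float
    w1: float
    w2: float
    degenerate: bool = False

    def __post_init__(self):
        if self.w1 <= 0 or self.w2 <= 0:
            raise InvalidInputError("full widths at half maximum must be positive")
        if self.A1 < 0 or self.A2 < 0:
            raise InvalidInputError("amplitudes must be non-negative")

    @property
    def populations(self) -> tuple[float, float]:
        """Area fractions A_i*w_i (Lorentzian area is proportional to A*w)."""
        a1, a2 = self.A1 * self.w1, self.A2 * self.w2
        tot = a1 + a2
        if tot <= 0:
            return (0.5, 0.5)
        return (a1 / tot, a2 / tot)


def simulate_two_state_spectrum(model: TwoStateExchangeModel, axis,
                                unit: str = "Hz",
                                spectrometer_mhz: float = DEFAULT_N15_MHZ) -> Spectrum1D:
    """Bloch-McConnell absorption spectrum of a two-state exchanging spin.

    ``axis`` is the frequency grid in ``unit``; the model offsets are always
    in Hz. The 2x2 resolvent is evaluated analytically for every grid point.
    The integrated area depends only on the total starting magnetization,
    not on k_ex.
    """
    f = np.asarray(axis, dtype=float)
    if f.size < 3 or np.unique(f).size != f.size:
        raise InvalidInputError("frequency grid must be non-degenerate")
    f_hz = f * spectrometer_mhz if unit == "ppm" else f

    w = 2.0 * np.pi * f_hz
    A11 = 1j * 2.0 * np.pi * model.delta1 - model.R2_1 - model.k12
    A22 = 1j * 2.0 * np.pi * model.delta2 - model.R2_2 - model.k21
    A12 = model.k21
    A21 = model.k12
    # solve (i*w*I - A) x = p for each w; 2x2 inverse in closed form
    d1 = 1j * w - A11
    d2 = 1j * w - A22
    det = d1 * d2 - A12 * A21
    x1 = (d2 * model.p1 + A12 * model.p2) / det
    x2 = (A21 * model.p1 + d1 * model.p2) / det
    intensity = np.real(x1 + x2)
    return Spectrum1D(f, intensity, unit=unit, spectrometer_mhz=spectrometer_mhz)


def lorentzian_pair_signal(x, y0, d1, d2, A1, A2, w1, w2):
    """Constant offset plus two Lorentzians parameterized by FWHM and height."""
    L1 = A1 * (w1 / 2.0) ** 2 / ((x - d1) ** 2 + (w1 / 2.0) ** 2)
    L2 = A2 * (w2 / 2.0) ** 2 / ((x - d2) ** 2 + (w2 / 2.0) ** 2)
    return y0 + L1 + L2


def fit_two_lorentzian(spectrum: Spectrum1D) -> LorentzianPair:
    """Least-squares regression of an offset plus two Lorentzian components.

    Initial centers come from the two most prominent local maxima (a single
    detectable maximum seeds two closely spaced components). A fit whose
    centers collapse onto each other or whose minor amplitude vanishes is
    returned with ``degenerate=True``; populations are area fractions.
    """
    x = spectrum.frequency
    y = spectrum.intensity
    span = abs(x[-1] - x[0])
    peaks, props = find_peaks(y, prominence=0.05 * np.ptp(y))
    if peaks.size >= 2:
        order = np.argsort(props["prominences"])[::-1]
        c1, c2 = np.sort(x[peaks[order[:2]]])
    elif peaks.size == 1:
        c0 = x[peaks[0]]
        c1, c2 = c0 - 0.02 * span, c0 + 0.02 * span
    else:
        c0 = x[np.argmax(y)]
        c1, c2 = c0 - 0.02 * span, c0 + 0.02 * span
    amp0 = float(np.ptp(y))
    w0 = 0.05 * span
    p0 = (float(y.min()), float(c1), float(c2), amp0, amp0, w0, w0)
    lo = [-np.inf, min(x[0], x[-1]), min(x[0], x[-1]), 0.0, 0.0, 1e-12, 1e-12]
    hi = [np.inf, max(x[0], x[-1]), max(x[0], x[-1]), np.inf, np.inf, span, span]
    try:
        popt, _ = curve_fit(lorentzian_pair_signal, x, y, p0=p0,
                            bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        resid = y - lorentzian_pair_signal(x, *p0)
        raise FitFailureError(f"two-Lorentzian fit did not converge: {exc}",
                              residuals=resid)
    y0, d1, d2, A1, A2, w1, w2 = popt
    wmax = max(w1, w2)
    degenerate = bool(abs(d1 - d2) < 0.25 * wmax
                      or min(A1, A2) < 1e-3 * max(A1, A2, 1e-300))
    # keep components ordered by center
    if d2 < d1:
        d1, d2, A1, A2, w1, w2 = d2, d1, A2, A1, w2, w1
    return LorentzianPair(y1=float(y0) / 2.0, y2=float(y0) / 2.0,
                          delta1=float(d1), delta2=float(d2),
                          A1=float(A1), A2=float(A2),
                          w1=float(w1), w2=float(w2),
                          degenerate=degenerate)


def _fit_kex_single(spectrum: Spectrum1D, seed: LorentzianPair,
                    shared_R2: bool = True):
    """Fit k_ex (plus R2, scale, offset) to one slice; returns (k_ex, se)."""
    f_hz = spectrum.frequency_hz
    y = spectrum.intensity
    scale_ppm = spectrum.spectrometer_mhz if spectrum.unit == "ppm" else 1.0
    d1 = seed.delta1 * scale_ppm
    d2 = seed.delta2 * scale_ppm
    p1, p2 = seed.populations
    # slow-exchange linewidth ~ (R2 + k_out)/pi: de-broadened R2 seed
    R2_seed = max(np.pi * 0.5 * (seed.w1 + seed.w2) * scale_ppm, 1.0)

    def predict(theta):
        log_k, log_R2, dd1, dd2, scale, offset = theta
        m = TwoStateExchangeModel(p1=p1, p2=p2, delta1=dd1, delta2=dd2,
                                  R2_1=np.exp(log_R2), R2_2=np.exp(log_R2),
                                  k_ex=np.exp(log_k))
        sim = simulate_two_state_spectrum(m, f_hz, unit="Hz")
        return scale * sim.intensity + offset

    def resid(theta):
        return predict(theta) - y

    # Coarse scan over k_ex to avoid local minima: exchange and relaxation
    # broadening are nearly degenerate (slow-exchange width ~ (R2+k_out)/pi),
    # so each grid value of k_ex is paired with the de-broadened
    # R2 ~ pi*w_obs - k_out implied by the Lorentzian seed widths; scale and
    # offset come from linear least squares at every grid point.
    best = None
    for log_k in np.log(np.logspace(-2, 4, 61)):
        k = np.exp(log_k)
        k_out = 0.5 * (p2 + p1) * k  # mean jump rate out of either state
        R2_k = max(R2_seed - k_out, 0.02 * R2_seed)
        m = TwoStateExchangeModel(p1=p1, p2=p2, delta1=d1, delta2=d2,
                                  R2_1=R2_k, R2_2=R2_k, k_ex=k)
        sim = simulate_two_state_spectrum(m, f_hz, unit="Hz").intensity
        G = np.column_stack([sim, np.ones_like(sim)])
        coef, rss, *_ = np.linalg.lstsq(G, y, rcond=None)
        cost = float(rss[0]) if rss.size else float(np.sum((G @ coef - y) ** 2))
        if best is None or cost < best[0]:
            best = (cost, log_k, R2_k, coef)
    _, log_k0, R2_0, coef0 = best
    x0 = np.array([log_k0, np.log(R2_0), d1, d2,
                   max(coef0[0], 1e-12), coef0[1]])
    sol = least_squares(resid, x0, method="lm", max_nfev=4000)
    if not sol.success:
        raise FitFailureError("line-shape k_ex fit did not converge",
                              residuals=sol.fun)
    log_k = sol.x[0]
    k_ex = float(np.exp(log_k))
    # SE of log k from the Gauss-Newton covariance, mapped to k
    m_pts, n_par = sol.jac.shape
    dof = max(m_pts - n_par, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        k_se = float(k_ex * np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        k_se = float("nan")
    return k_ex, k_se


def estimate_kex_lineshape(spectra: dict, seeds: dict) -> RateSeries:
    """Exchange rates from a temperature series of 1D slices.

    Parameters
    ----------
    spectra : dict
        Maps temperature in K to :class:`Spectrum1D`.
    seeds : dict
        Maps the same temperatures to :class:`LorentzianPair` regressions.
        Populations (area fractions) are held fixed from the regression;
        the shift offsets seed the fit but are refined locally, because
        exchange pulls the apparent Lorentzian maxima toward each other and
        clamping the centers at those pulled positions biases k_ex low.
        Per slice the optimized parameters are k_ex, a shared R2, the two
        centers and an intensity scale/offset.

    Returns
    -------
    RateSeries
        Temperatures (K) and fitted k_ex with standard errors, ready for
        :func:`confex.thermokinetics.eyring_fit`. Slices in fast exchange
        (degenerate Lorentzian seed) are still fitted but carry the wide SE
        the flat likelihood implies.
    """
    if set(spectra) != set(seeds):
        raise InvalidInputError("spectra and seeds must cover the same temperatures")
    temps = sorted(spectra)
    rates, ses = [], []
    for T in temps:
        k, se = _fit_kex_single(spectra[T], seeds[T])
        rates.append(k)
        ses.append(se)
    return RateSeries(np.asarray(temps, dtype=float), np.asarray(rates),
                      np.asarray(ses))


def coalescence_rate(delta_nu_hz: float) -> float:
    """Equal-population coalescence threshold of the total exchange rate.

    The classical condition for the merging of a symmetric doublet is that
    the per-direction jump rate reaches pi*dnu/sqrt(2). With
    k_ex = k12 + k21 and equal populations each jump rate is k_ex/2, so the
    doublet coalesces at k_ex = sqrt(2)*pi*dnu (verified against the
    matrix-resolvent simulator).
    """
    if delta_nu_hz <= 0:
        raise DomainError("peak separation must be positive")
    return np.sqrt(2.0) * np.pi * delta_nu_hz
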