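"""Delimited-table readers and writers for every modality.

All inputs are plain text tables (comma, tab or whitespace separated;
``#`` comments allowed). Column conventions follow the CLI documentation:
temperatures may be given as ``temperature_C`` or ``temperature_K``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binding_observables import BindingIsotherm, BuildupSeries, KineticTrace, ShiftPair
from .constants import celsius_to_kelvin
from .diffusion import DiffusionDecay
from .exceptions import InvalidInputError
from .lineshape import Spectrum1D
from .thermokinetics import RateSeries
from .zz_exchange import IntensityQuartet, ZZSeries

__all__ = [
    "read_table",
    "read_rate_series",
    "read_zz_series",
    "read_spectrum",
    "read_diffusion_decay",
    "read_kinetic_trace",
    "read_velocities",
    "read_melt",
    "read_isotherm",
    "read_shift_pairs",
    "read_buildups",
]


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table, sniffing the separator."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def _temperatures_kelvin(df: pd.DataFrame) -> np.ndarray:
    if "temperature_K" in df.columns:
        return df["temperature_K"].to_numpy(dtype=float)
    if "temperature_C" in df.columns:
        return celsius_to_kelvin(df["temperature_C"].to_numpy(dtype=float))
    raise InvalidInputError("table needs a temperature_C or temperature_K column")


def read_rate_series(path) -> RateSeries:
    """Columns: temperature_C|temperature_K, rate_s[, rate_se]."""
    df = read_table(path)
    T = _temperatures_kelvin(df)
    if "rate_s" not in df.columns:
        raise InvalidInputError("rate table needs a rate_s column")
    se = df["rate_se"].to_numpy(dtype=float) if "rate_se" in df.columns else None
    return RateSeries(T, df["rate_s"].to_numpy(dtype=float), se)


def read_zz_series(path) -> list[ZZSeries]:
    """Columns: residue, t_mix_s, I_AA, I_AB, I_BA, I_BB."""
    df = read_table(path)
    needed = {"residue", "t_mix_s", "I_AA", "I_AB", "I_BA", "I_BB"}
    if not needed.issubset(df.columns):
        raise InvalidInputError(f"ZZ table needs columns {sorted(needed)}")
    out = []
    for residue, grp in df.groupby("residue", sort=False):
        grp = grp.sort_values("t_mix_s")
        quartets = tuple(
            IntensityQuartet(t_mix=row.t_mix_s, I_AA=row.I_AA, I_BB=row.I_BB,
                             I_AB=row.I_AB, I_BA=row.I_BA)
            for row in grp.itertuples()
        )
        out.append(ZZSeries(residue=str(residue), quartets=quartets))
    return out


def read_spectrum(path, unit: str = "ppm", spectrometer_mhz: float = 86.2) -> Spectrum1D:
    """Two columns: frequency (declared unit), intensity."""
    df = read_table(path)
    cols = df.columns[:2]
    return Spectrum1D(df[cols[0]].to_numpy(dtype=float),
                      df[cols[1]].to_numpy(dtype=float),
                      unit=unit, spectrometer_mhz=spectrometer_mhz)


def read_diffusion_decay(path, delta: float, Delta: float,
                         max_gradient: float | None = None) -> DiffusionDecay:
    """Columns: gradient_frac|gradient_T_per_m, integral."""
    df = read_table(path)
    if "gradient_T_per_m" in df.columns:
        g = df["gradient_T_per_m"].to_numpy(dtype=float)
        max_g = None
    elif "gradient_frac" in df.columns:
        if max_gradient is None:
            raise InvalidInputError("fractional gradients need max_gradient")
        g = df["gradient_frac"].to_numpy(dtype=float)
        max_g = max_gradient
    else:
        raise InvalidInputError("diffusion table needs gradient_frac or gradient_T_per_m")
    return DiffusionDecay(g, df["integral"].to_numpy(dtype=float),
                          delta=delta, Delta=Delta, max_gradient=max_g)


def read_kinetic_trace(path, temperature_C: float = 25.0) -> KineticTrace:
    """Columns: time_s, intensity."""
    df = read_table(path)
    if not {"time_s", "intensity"}.issubset(df.columns):
        raise InvalidInputError("trace table needs time_s and intensity columns")
    return KineticTrace(df["time_s"].to_numpy(dtype=float),
                        df["intensity"].to_numpy(dtype=float),
                        temperature_C=temperature_C)


def read_velocities(path):
    """Columns: concentration_M, velocity[, temperature_C]; returns DataFrame."""
    df = read_table(path)
    if not {"concentration_M", "velocity"}.issubset(df.columns):
        raise InvalidInputError("velocity table needs concentration_M and velocity")
    return df


def read_melt(path):
    """Columns: temperature_C|temperature_K, ellipticity; returns (T_K, y)."""
    df = read_table(path)
    if "ellipticity" not in df.columns:
        raise InvalidInputError("melt table needs an ellipticity column")
    return _temperatures_kelvin(df), df["ellipticity"].to_numpy(dtype=float)


def read_isotherm(path, cell_concentration: float, syringe_concentration: float,
                  temperature: float = 298.15,
                  cell_volume: float = 200.0) -> BindingIsotherm:
    """Columns: injection_ul, heat_ucal (first row treated as discard)."""
    df = read_table(path)
    if not {"injection_ul", "heat_ucal"}.issubset(df.columns):
        raise InvalidInputError("ITC table needs injection_ul and heat_ucal")
    return BindingIsotherm(
        injection_volumes=df["injection_ul"].to_numpy(dtype=float),
        heats=df["heat_ucal"].to_numpy(dtype=float),
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        temperature=temperature, cell_volume=cell_volume)


def read_shift_pairs(path) -> list[ShiftPair]:
    """Columns: residue, dH_ppm, dN_ppm."""
    df = read_table(path)
    if not {"dH_ppm", "dN_ppm"}.issubset(df.columns):
        raise InvalidInputError("CSP table needs dH_ppm and dN_ppm columns")
    res = df["residue"] if "residue" in df.columns else [""] * len(df)
    return [ShiftPair(dH_ppm=h, dN_ppm=n, residue=str(r))
            for r, h, n in zip(res, df["dH_ppm"], df["dN_ppm"])]


def read_buildups(path) -> list[BuildupSeries]:
    """Columns: residue, delay_s, intensity."""
    df = read_table(path)
    if not {"residue", "delay_s", "intensity"}.issubset(df.columns):
        raise InvalidInputError("build-up table needs residue, delay_s, intensity")
    out = []
    for residue, grp in df.groupby("residue", sort=False):
        grp = grp.sort_values("delay_s")
        out.append(BuildupSeries(delays=grp["delay_s"].to_numpy(dtype=float),
                                 intensities=grp["intensity"].to_numpy(dtype=float),
                                 residue=str(residue)))
    return out
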