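"""End-to-end analysis pipeline.

Runs every modality fit, performs the Eyring analyses of the conformational
(stopped-flow + line-shape) and catalytic (activity-assay) rate constants,
and emits a barrier-convergence report: if catalytic turnover is limited by
the opening/closing conformational exchange, the activation free energy
from dynamics must match the one from catalysis at the same temperature.

Configuration is a single YAML/JSON document::

    scenario: paper          # bundled synthetic scenario
    seed: 1                  # mandatory; drives every stochastic stage
    temperature_C: 25        # temperature at which barriers are compared
    modalities: [...]        # optional subset
    inputs: {zz: file.tsv, ...}        # optional per-modality file overrides
    overrides: {k_conf: 30.0, ...}     # optional scenario-truth overrides

Barrier SEs fed to the convergence test use marginal (no-covariance)
propagation of the activation parameters: the comparison is between
independent experiments whose parameter-level uncertainties, not the tiny
interpolation error of a single fit, set the meaningful scale.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from . import io as cio
from .binding_observables import csp, fit_itc_single_site, fit_mexico_buildup, fit_stopped_flow
from .constants import celsius_to_kelvin
from .diffusion import MixtureWeights, mixture_decompose, stejskal_tanner_fit
from .exceptions import ConfigError, ConfexError
from .lineshape import estimate_kex_lineshape, fit_two_lorentzian
from .synthetic_data import generate_all, paper_scenario
from .thermokinetics import (
    Barrier,
    RateSeries,
    binding_free_energy,
    compare_barriers,
    eyring_fit,
    gibbs_activation,
    michaelis_menten_fit,
    vant_hoff_melt_fit,
)
from .zz_exchange import fit_kconf_farrow, fit_kconf_xi

__all__ = ["AnalysisReport", "run_pipeline", "validate_config", "ALL_MODALITIES"]

ALL_MODALITIES = ("zz", "lineshape", "diffusion", "stopped_flow",
                  "michaelis", "melt", "itc", "mexico", "csp")

_REQUIRED_KEYS = ("seed", "temperature_C")


@dataclass(frozen=True)
class AnalysisReport:
    """Machine-readable pipeline result.

    ``stages`` maps modality name to its fitted parameters (or an ``error``
    entry for a failed stage); ``barriers`` carries the dynamics/catalysis
    activation free energies and the convergence verdict; ``provenance``
    records the scenario, seed, input files and config hash.
    """

    stages: dict
    barriers: dict
    provenance: dict

    @property
    def ok(self) -> bool:
        return not any("error" in s for s in self.stages.values())

    def to_dict(self) -> dict:
        return {"stages": self.stages, "barriers": self.barriers,
                "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(_clean(self.to_dict()), indent=2, sort_keys=True,
                          allow_nan=False)

    def summary(self) -> str:
        lines = ["confex analysis report", "======================"]
        for name in sorted(self.stages):
            stage = self.stages[name]
            if "error" in stage:
                lines.append(f"{name:12s} FAILED: {stage['error']}")
                continue
            keys = ", ".join(f"{k}={_fmt(v)}" for k, v in sorted(stage.items())
                             if np.isscalar(v))
            lines.append(f"{name:12s} {keys}")
        b = self.barriers
        if b:
            lines.append("")
            lines.append(
                f"barriers at {b['temperature_K']:.2f} K: "
                f"dynamics {b['dG_dynamics_kJ']:.2f} +/- {b['dG_dynamics_se_kJ']:.2f} kJ/mol, "
                f"catalysis {b['dG_catalysis_kJ']:.2f} +/- {b['dG_catalysis_se_kJ']:.2f} kJ/mol"
            )
            lines.append(f"convergence verdict: {b['verdict']} (z = {b['z']:.2f})")
            if "dG_binding_kJ" in b:
                lines.append(f"binding stabilization: {b['dG_binding_kJ']:.1f} kJ/mol")
        return "\n".join(lines)


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _clean(obj):
    """JSON-safe copy: numpy scalars/arrays to builtins, non-finite to None."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_clean(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    return doc


def validate_config(config) -> list:
    """Schema and unit checks; returns a list of human-readable issues."""
    try:
        doc = _load_config(config)
    except ConfigError as exc:
        return [str(exc)]
    issues = []
    for key in _REQUIRED_KEYS:
        if key not in doc:
            issues.append(f"missing required key: {key}")
    if "seed" in doc and not isinstance(doc["seed"], int):
        issues.append("seed must be an integer")
    t = doc.get("temperature_C")
    if t is not None:
        if not isinstance(t, (int, float)):
            issues.append("temperature_C must be numeric")
        elif t > 150:
            issues.append(
                f"temperature_C = {t} looks like Kelvin mislabelled as Celsius")
    scen = doc.get("scenario", "paper")
    if scen != "paper":
        issues.append(f"unknown scenario {scen!r} (only 'paper' is bundled)")
    for m in doc.get("modalities", []):
        if m not in ALL_MODALITIES:
            issues.append(f"unknown modality {m!r}")
    inputs = doc.get("inputs", {})
    if not isinstance(inputs, dict):
        issues.append("inputs must be a mapping of modality -> file path")
        inputs = {}
    for m, path in inputs.items():
        if m not in ALL_MODALITIES:
            issues.append(f"inputs refers to unknown modality {m!r}")
        elif not os.path.exists(path):
            issues.append(f"input file for {m} not found: {path}")
    for key, val in doc.get("overrides", {}).items():
        if isinstance(val, (int, float)) and "concentration" in key and val <= 0:
            issues.append(f"override {key} must be positive, got {val}")
    return issues


def run_pipeline(config, out_path=None) -> AnalysisReport:
    """Execute every requested modality and assemble the report.

    A stage that raises records its error in the report instead of aborting
    the run; the report's ``ok`` property (and the CLI exit status) reflect
    whether all stages succeeded. With ``out_path`` the JSON report is
    written atomically; the same config and seed always produce
    byte-identical output.
    """
    doc = _load_config(config)
    issues = validate_config(doc)
    if issues:
        raise ConfigError("invalid config: " + "; ".join(issues))

    seed = doc["seed"]
    temp_C = float(doc["temperature_C"])
    T0 = celsius_to_kelvin(temp_C)
    modalities = tuple(doc.get("modalities", ALL_MODALITIES))
    overrides = doc.get("overrides", {})
    inputs = doc.get("inputs", {})

    scenario = paper_scenario(seed=seed, **overrides)
    data = generate_all(scenario)
    stages = {}

    def run_stage(name, fn):
        if name not in modalities:
            return
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stages[name] = fn()
        except (ConfexError, np.linalg.LinAlgError, ValueError) as exc:
            stages[name] = {"error": f"{type(exc).__name__}: {exc}"}

    # --- ZZ exchange ---
    def stage_zz():
        series = (cio.read_zz_series(inputs["zz"]) if "zz" in inputs
                  else data["zz"])
        est = fit_kconf_xi(series, p_open=scenario.p_open)
        far = fit_kconf_farrow(series[0], p_open=scenario.p_open)
        return {"k_conf_xi": est.k_conf, "k_conf_xi_se": est.se,
                "k_conf_farrow": far.k_conf, "k_conf_farrow_se": far.k_conf_se,
                "R1_farrow": far.R1, "n_residues": len(est.per_residue)}

    # --- line shape ---
    def stage_lineshape():
        spectra = data["lineshape"]
        seeds = {T: fit_two_lorentzian(s) for T, s in spectra.items()}
        resolved = {T: s for T, s in spectra.items() if not seeds[T].degenerate}
        rates = estimate_kex_lineshape(resolved, {T: seeds[T] for T in resolved})
        pars = eyring_fit(rates)
        barrier = gibbs_activation(pars, T0, propagate="marginal")
        return {"temperatures_K": rates.temperatures, "k_ex": rates.rates,
                "dH_J": pars.dH, "dH_se_J": pars.dH_se,
                "dS_J_K": pars.dS, "dS_se_J_K": pars.dS_se,
                "dG_kJ": barrier.value / 1e3, "dG_se_kJ": barrier.se / 1e3}

    # --- diffusion ---
    def stage_diffusion():
        if "diffusion" in inputs:
            raise ConfigError("diffusion file override needs the two reference "
                              "decays; supply them via the library API")
        d = data["diffusion"]
        open_fit = stejskal_tanner_fit(d["open"])
        closed_fit = stejskal_tanner_fit(d["closed"])
        refs = MixtureWeights(w_open=0.5, D_open=min(open_fit.D, closed_fit.D),
                              D_closed=max(open_fit.D, closed_fit.D))
        mix = mixture_decompose(d["mixture"], refs)
        return {"D_open": open_fit.D, "D_closed": closed_fit.D,
                "w_open": mix.w_open, "w_open_se": mix.w_se,
                "D_effective": mix.D_effective}

    # --- stopped flow ---
    def stage_sf():
        trace = (cio.read_kinetic_trace(inputs["stopped_flow"])
                 if "stopped_flow" in inputs else data["reference_trace"])
        ref = fit_stopped_flow(trace)
        rates = RateSeries(
            celsius_to_kelvin(data["rate_table"]["temperature_C"].to_numpy()),
            data["rate_table"]["rate_s"].to_numpy(),
            data["rate_table"]["rate_se"].to_numpy())
        pars = eyring_fit(rates)
        barrier = gibbs_activation(pars, T0, propagate="marginal")
        return {"k_app": ref.k_app, "k_app_se": ref.k_app_se,
                "dH_J": pars.dH, "dH_se_J": pars.dH_se,
                "dS_J_K": pars.dS, "dS_se_J_K": pars.dS_se,
                "dG_kJ": barrier.value / 1e3, "dG_se_kJ": barrier.se / 1e3}

    # --- Michaelis-Menten / catalysis Eyring ---
    def stage_mm():
        vel = (cio.read_velocities(inputs["michaelis"]) if "michaelis" in inputs
               else data["velocities"])
        if "temperature_C" not in vel.columns:
            vel = vel.assign(temperature_C=temp_C)
        temps, kcats, kses = [], [], []
        per_T = {}
        for t_c, grp in vel.groupby("temperature_C"):
            fit = michaelis_menten_fit(grp["concentration_M"], grp["velocity"],
                                       scenario.assay_enzyme_concentration)
            temps.append(celsius_to_kelvin(float(t_c)))
            kcats.append(fit.kcat)
            kses.append(fit.kcat_se if fit.kcat_se > 0 else 0.05 * fit.kcat)
            per_T[float(t_c)] = {"kcat": fit.kcat, "Km": fit.Km}
        result = {"per_temperature": per_T}
        if len(temps) >= 2:
            pars = eyring_fit(RateSeries(np.array(temps), np.array(kcats),
                                         np.array(kses)))
            barrier = gibbs_activation(pars, T0, propagate="marginal")
            result.update({"dH_J": pars.dH, "dH_se_J": pars.dH_se,
                           "dS_J_K": pars.dS, "dS_se_J_K": pars.dS_se,
                           "dG_kJ": barrier.value / 1e3,
                           "dG_se_kJ": barrier.se / 1e3})
        return result

    # --- melt ---
    def stage_melt():
        if "melt" in inputs:
            T, y = cio.read_melt(inputs["melt"])
        else:
            T = data["melt"]["temperature_K"].to_numpy()
            y = data["melt"]["ellipticity"].to_numpy()
        fit = vant_hoff_melt_fit(T, y)
        return {"Tm_K": fit.Tm, "Tm_se_K": fit.Tm_se,
                "dHvH_J": fit.dHvH, "dHvH_se_J": fit.dHvH_se}

    # --- ITC ---
    def stage_itc():
        iso = (cio.read_isotherm(inputs["itc"], scenario.itc_cell_concentration,
                                 scenario.itc_syringe_concentration)
               if "itc" in inputs else data["isotherm"])
        fit = fit_itc_single_site(iso)
        return {"Kd_M": fit.Kd, "Kd_se_M": fit.Kd_se,
                "dH_J": fit.dH, "dH_se_J": fit.dH_se,
                "n": fit.n, "n_se": fit.n_se,
                "dG_binding_kJ": binding_free_energy(fit.Kd, T0) / 1e3}

    # --- MEXICO ---
    def stage_mexico():
        buildups = (cio.read_buildups(inputs["mexico"]) if "mexico" in inputs
                    else data["buildups"])
        out = {}
        for series in buildups:
            fit = fit_mexico_buildup(series, scenario.mexico_R1_water,
                                     scenario.mexico_R1_amide)
            out[series.residue] = {"k_hx": fit.k_hx, "k_hx_se": fit.k_hx_se}
        return {"per_residue": out}

    # --- CSP ---
    def stage_csp():
        pairs = (cio.read_shift_pairs(inputs["csp"]) if "csp" in inputs
                 else data["csp"])
        return {"per_residue": {p.residue: csp(p) for p in pairs}}

    run_stage("zz", stage_zz)
    run_stage("lineshape", stage_lineshape)
    run_stage("diffusion", stage_diffusion)
    run_stage("stopped_flow", stage_sf)
    run_stage("michaelis", stage_mm)
    run_stage("melt", stage_melt)
    run_stage("itc", stage_itc)
    run_stage("mexico", stage_mexico)
    run_stage("csp", stage_csp)

    barriers = _barrier_report(stages, T0)

    provenance = {
        "scenario": doc.get("scenario", "paper"),
        "seed": seed,
        "temperature_C": temp_C,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config_hash": _config_hash(doc),
        "package": "confex",
    }
    report = AnalysisReport(stages=stages, barriers=barriers,
                            provenance=provenance)
    if out_path is not None:
        _atomic_write(out_path, report.to_json())
    return report


def _barrier_report(stages: dict, T0: float) -> dict:
    """Combine per-modality barriers into the convergence verdict.

    The dynamics barrier averages the stopped-flow and line-shape
    determinations; its SE combines their fit SEs with half their spread
    (the between-method scatter is real information about reproducibility).
    """
    sf = stages.get("stopped_flow", {})
    ls = stages.get("lineshape", {})
    mm = stages.get("michaelis", {})
    if "dG_kJ" not in sf or "dG_kJ" not in ls or "dG_kJ" not in mm:
        return {}
    vals = np.array([sf["dG_kJ"], ls["dG_kJ"]])
    ses = np.array([sf["dG_se_kJ"], ls["dG_se_kJ"]])
    dyn_val = float(vals.mean())
    dyn_se = float(np.sqrt(np.sum(ses**2) / 4.0 + (np.ptp(vals) / 2.0) ** 2))
    dyn = Barrier(dyn_val * 1e3, dyn_se * 1e3, T0)
    cat = Barrier(mm["dG_kJ"] * 1e3, mm["dG_se_kJ"] * 1e3, T0)
    cmp_ = compare_barriers(dyn, cat)
    out = {
        "temperature_K": T0,
        "dG_dynamics_kJ": dyn_val, "dG_dynamics_se_kJ": dyn_se,
        "dG_catalysis_kJ": mm["dG_kJ"], "dG_catalysis_se_kJ": mm["dG_se_kJ"],
        "difference_kJ": cmp_.difference / 1e3,
        "pooled_se_kJ": cmp_.pooled_se / 1e3,
        "z": cmp_.z,
        "verdict": "consistent" if cmp_.agree else "inconsistent",
    }
    itc = stages.get("itc", {})
    if "dG_binding_kJ" in itc:
        out["dG_binding_kJ"] = itc["dG_binding_kJ"]
    return out


def _config_hash(doc: dict) -> str:
    import hashlib
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _atomic_write(path, text: str):
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise
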