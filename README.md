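# confex

Quantitative analysis of slow two-state conformational exchange in proteins,
and of whether that exchange limits enzymatic turnover.

## The problem

Enzymes such as adenylate kinase (AdK) transiently visit high-energy
conformations — here, an *open yet substrate-bound* state — whose dynamics
can rate-limit catalysis. When a mutation slows the open/closed
interconversion into the slow-exchange NMR regime, the high-energy state
becomes directly observable: amide resonances split into two sets, ZZ-exchange
cross peaks report the interconversion rate k_conf = k_open + k_close, PFG
diffusion reveals the mixture of compact and expanded topologies, and
temperature series of line shapes, stopped-flow binding kinetics and enzyme
activity yield Eyring activation parameters. The decisive test is barrier
convergence: the activation free energy

ΔG‡(T) = ΔH‡ − TΔS‡

obtained from conformational dynamics must match the one obtained from
catalytic turnover if the conformational step is rate-limiting.

`confex` implements that full analysis chain as a tested library plus CLI:

| module | contents |
| --- | --- |
| `confex.lineshape` | Bloch–McConnell two-state spectra S(ω) = Re[1ᵀ(iωI−A)⁻¹p], two-Lorentzian regression, k_ex estimation per temperature |
| `confex.zz_exchange` | matrix-exponential ZZ propagation oracle, the relaxation-compensated ratio Ξ = I_AB·I_BA/(I_AA·I_BB − I_AB·I_BA) = p_A p_B(1−e^{−kt})²/e^{−kt}, and the joint four-curve fit |
| `confex.diffusion` | Stejskal–Tanner fits I(G) = I₀e^{−Dγ²δ²G²(Δ−δ/3)}, open/closed mixture decomposition, Stokes–Einstein radii |
| `confex.thermokinetics` | Eyring–Polanyi regression ln(k/T) vs 1/T, Gibbs–Helmholtz barriers, Michaelis–Menten, two-state van't Hoff melts, K_D → ΔG_bind, barrier comparison |
| `confex.binding_observables` | stopped-flow exponentials, single-site ITC (Wiseman) isotherms, weighted ¹H/¹⁵N shift perturbations, MEXICO amide-exchange build-ups |
| `confex.synthetic_data` | seeded generators for all modalities with the study conditions as defaults |
| `confex.pipeline` / `confex.cli` | orchestration, config validation, the barrier-convergence report |

## Worked example

Generate the bundled synthetic scenario (an AdK-variant-like system with
k_conf = 25 s⁻¹ at 15 °C, K_D = 250 nM, and the published activation
parameters as truths), then run the full pipeline:

```sh
confex simulate --seed 1 --out sim/
printf 'scenario: paper\nseed: 1\ntemperature_C: 25\n' > cfg.yaml
confex run --config cfg.yaml --out report.json
```

which prints (abridged):

```
itc          Kd_M=2.641e-07, ... dG_binding_kJ=37.55, n=1.001
lineshape    dG_kJ=64.1, dH_J=6.893e+04, dS_J_K=16.19
michaelis    dG_kJ=62.46, dH_J=2.533e+04, dS_J_K=-124.5
stopped_flow dG_kJ=63.41, dH_J=6.43e+04, k_app=23.97
zz           k_conf_farrow=24.82, k_conf_xi=25.17

barriers at 298.15 K: dynamics 63.75 +/- 1.79 kJ/mol, catalysis 62.46 +/- 1.54 kJ/mol
convergence verdict: consistent (z = 0.55)
binding stabilization: 37.5 kJ/mol
```

Reading: the interconversion rate fitted from ZZ-exchange intensities
(~25 s⁻¹) matches the stopped-flow apparent binding rate (~24 s⁻¹); the
activation barrier from conformational dynamics (mean of the stopped-flow
and line-shape Eyring analyses, ≈63.8 kJ/mol) agrees with the catalytic
barrier from Michaelis–Menten turnover rates (≈62.4 kJ/mol) within the
pooled uncertainty, and sub-μM binding stabilizes the complex by
≈37.7 kJ/mol (RT ln(1 M/K_D)).

Individual fits are available as subcommands (`confex zz`, `confex itc`,
`confex eyring`, `confex diffusion`, ...) or directly from Python:

```python
from confex import EyringParameters, gibbs_activation, binding_free_energy
b = gibbs_activation(EyringParameters(26.6e3, -120.0, 3.3e3, 20.0),
                     298.15, propagate="marginal")
# -> 62.4 +/- 6.8 kJ/mol
binding_free_energy(250e-9, 298.15)  # -> 37.7 kJ/mol
```

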