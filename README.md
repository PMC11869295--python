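# sookit

Desk-scale mechanism analysis of **superoxide oxidase (SOO)** — the minimal
membrane oxidoreductase that detoxifies superoxide by running its electron
onto the quinone pool (O₂•⁻ → heme 2 → heme 1 → Q → QH₂).

The package re-implements the computational layer of that analysis as a
tested pipeline:

* a **finite-temperature string method** that locates minimum free-energy
  pathways on 2D proton-transfer energy landscapes by iterating restrained
  sampling → drift estimation → curve refitting → equal-arclength
  reparameterization, with the convergence rule
  ΔSSQ < 0.008 Å² and max node deviation < 0.05 Å² for ≥ 3 iterations;
* **free-energy reconstruction** from umbrella windows by three estimators —
  2D WHAM, MBAR, and a variational maximum-likelihood profile — with block
  bootstrap uncertainties and path-barrier extraction;
* **electron-transfer rates** from the Moser–Dutton ruler

  log₁₀ k = 13 − (1.2 − 0.8ρ)(R − 3.6) − 3.1(ΔG + λ)²/λ

  (R in Å, ΔG and λ in eV), transition-state-theory conversion
  k = (k_BT/h)·e^(−ΔG‡/k_BT) with k_BT/h = 6 ps⁻¹, and Nernst
  concentration corrections E = E_m − 59 mV·log₁₀([red]/[ox]);
* a **kinetic master equation** dP_i/dt = Σ_j (k_ji P_j − k_ij P_i) of the
  full two-electron cycle, with detailed-balance reverse rates, an
  irreversible final proton-coupled electron transfer (PCET), and turnover
  k = ln 2 / t_½ of quinol formation;
* **trajectory-ensemble statistics** (axial membrane densities with
  core/bulk partition ratios, radial distributions, binding-site
  occupancies, center-of-mass distance series, concentration-shifted
  potential profiles) on standard-format or synthetic trajectories.

Real electronic-structure or MD data are not required: the
`surfaces` module generates analytic double-well landscapes with *known*
barriers, saddles and reaction free energies (plus the Müller–Brown
benchmark), and `fixtures` generates trajectories with planted statistics,
so every stage is validated against exact ground truth.

## Worked example

The end-to-end pipeline (surface → string → landscapes → barrier → rates →
master equation) with default settings:

```python
from sookit.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=1), "run1")
print(manifest["stages"]["fes"]["wham"])
print(manifest["stages"]["kinetics"])
```

prints (seed 1):

```
{'barrier_kcal': 12.099778616783063, 'delta_g_kcal': 7.041986481369155}
{'pcet_rate_per_s': 17681.65305909787, 't_half_s': 4.2280253940236604e-05,
 'turnover_per_s': 16394.111103015442}
```

Reading: the string converged in 3 iterations on the double-well surface
whose planted PCET barrier is 12 kcal/mol and reaction free energy
+7.5 kcal/mol; WHAM recovers a 12.10 kcal/mol barrier (MBAR 12.14, the
variational profile 12.10). Transition-state theory converts the barrier
into a PCET rate of ~1.8×10⁴ s⁻¹; fed into the master-equation model of
the full cycle together with the tunneling rates (superoxide→heme 2 at
9 Å, heme 2→heme 1 at 11 Å, heme 1→Q at 6 Å; λ = 0.7 eV, ρ = 0.76),
quinol forms with t_½ ≈ 42 μs, i.e. a turnover of ~1.6×10⁴ s⁻¹ — the
final PCET step is rate-limiting, two orders of magnitude slower than the
interheme electron transfer.

The same stages are exposed on the command line:

```bash
sookit rates --out rates.csv
sookit run-string --nodes 19 --kforce 200 --seed 1 --out run/
sookit kinetics --pcet-barrier 12 --out run/
sookit run-all --seed 1 --out run/
```

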