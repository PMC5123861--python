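# membind

Quantitative analysis of peripheral protein–membrane binding, built around
the experiment chain used to characterise Ca²⁺-sensor C2 domains (such as
the synaptotagmin-1 C2AB fragment) binding to anionic membranes containing
phosphatidylserine (PtdSer) and PtdIns(4,5)P₂:

- **Stopped-flow kinetics** — monoexponential trace fitting
  `F(t) = F₀ + A·e^(−k_obs·t)` and the pseudo-first-order rate law
  `k_obs = k_on[v] + k_off`, with `K_d = k_off/k_on` and the 90,000
  lipids-per-vesicle concentration conversion.
- **ITC thermodynamics** — the exact finite-concentration single-site
  isotherm with overflow-cell dilution bookkeeping; fits of (n, K_d, ΔH)
  and the decomposition ΔG = RT ln K_d, −TΔS = ΔG − ΔH.
- **Equilibrium partitioning** — sedimentation-assay fits of
  `f_b = K[L]/(1 + K[L])`, free-energy differences RT ln(K_a/K_b), and the
  effective lipid concentration felt by a membrane-tethered domain.
- **EPR power-saturation depth analysis** — P½ fits per relaxant condition,
  the depth parameter Φ = ln(ΔP½^O₂/ΔP½^NiEDDA), and a monotone tanh
  calibration mapping Φ to signed distance from the lipid phosphate plane.
- **Depth-restrained membrane docking** — rigid-body pose search against
  the plane z = 0 with flat-bottom point-to-plane restraints over the three
  observable degrees of freedom (tilt, azimuth, z-offset).
- **NMR chemical-shift perturbation** — weighted amide CSPs
  `√(ΔδH² + (0.2·ΔδN)²)` and binding-surface ranking.

Every stage has a paired synthetic-data generator that inverts the analysis
model exactly, so the whole pipeline is testable end-to-end with known
ground truth and no external data.

Intended users: biophysicists and structural biologists analysing
protein–lipid binding data (or teaching/validating such analyses), from
Python. A thin `membind` CLI wraps the same functions for shell use.

## Worked example

```python
import numpy as np
from membind import (TitrationProtocol, predict_heats, simulate_itc,
                     fit_isotherm)
from membind.composition import NoiseModel

protocol = TitrationProtocol.uniform(25, 10e-6, cell_volume_L=1.4e-3,
                                     cell_conc_M=50e-6, syringe_conc_M=1e-3,
                                     temperature_K=298.15)
sigma = 0.02 * np.max(np.abs(predict_heats(1.0, 14e-6, -30.0, protocol).q_kJ))
heats = simulate_itc(1.0, 14e-6, -30.0, protocol, noise=NoiseModel(sigma, seed=1))
fit = fit_isotherm(heats)
print(f"n = {fit.n:.3f}, K_d = {fit.K_d*1e6:.1f} uM, dH = {fit.dH:.1f} kJ/mol")
```

prints

```
n = 0.997, K_d = 12.8 uM, dH = -28.8 kJ/mol
```

— a 1 mM ligand titration into a 50 µM protein cell (25 × 10 µL injections,
25 °C, 2% heat noise) generated at a 1:1 site with K_d = 14 µM and
ΔH = −30 kJ/mol, refit blind. The stoichiometry comes back at 1, the
affinity within the noise-limited uncertainty of the generating value, and
ΔG (−27.9 kJ/mol) splits into its enthalpic and entropic parts.

The `examples/` directory has one narrative script per capability
(kinetics, ITC, partitioning, EPR depth, docking, CSP); each builds a small
input, runs the analysis, and explains the printed numbers.

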