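"""Single-site ITC: simulate an InsP3-into-C2AB titration and refit it.

50 uM protein cell, 25 x 10 uL injections of 1 mM ligand head group at
25 C - conditions where a 14 uM dissociation constant gives a c-value of
~3.6, low but fittable.
"""

import numpy as np

from membind import TitrationProtocol, fit_isotherm, predict_heats, simulate_itc
from membind.composition import NoiseModel

protocol = TitrationProtocol.uniform(25, 10e-6, cell_volume_L=1.4e-3,
                                     cell_conc_M=50e-6, syringe_conc_M=1e-3,
                                     temperature_K=298.15)
truth = dict(n=1.0, K_d=14e-6, dH=-30.0)
sigma = 0.02 * np.max(np.abs(predict_heats(**truth, protocol=protocol).q_kJ))
heats = simulate_itc(**truth, protocol=protocol, noise=NoiseModel(sigma, seed=1))

fit = fit_isotherm(heats)
print(f"n      = {fit.n:.3f} sites      (1:1 binding)")
print(f"K_d    = {fit.K_d*1e6:.1f} uM      (truth 14; exothermic head-group binding)")
print(f"dH     = {fit.dH:.1f} kJ/mol")
print(f"dG     = {fit.dG:.1f} kJ/mol    (RT ln K_d)")
print(f"-TdS   = {fit.minus_TdS:.1f} kJ/mol    (dG - dH: entropic penalty if positive)")
print(f"c-value = {fit.c_value:.1f}" + ("  (warning: outside [1, 1000])" if fit.c_warning else ""))
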