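"""EPR power saturation: from saturation curves to membrane immersion depth.

Simulates 12-step progressive power-saturation curves for a spin-labeled
site under nitrogen, air (O2) and NiEDDA, fits P_half per condition, forms
the depth parameter Phi, and converts it to a distance from the lipid
phosphate plane with the packaged reference calibration.
"""

from membind import (depth_from_phi, depth_parameter, fit_saturation,
                     reference_calibration, simulate_power_saturation)
from membind.composition import NoiseModel

curves = simulate_power_saturation({"N2": 4.0, "O2": 16.0, "NiEDDA": 8.5},
                                   eps=1.2, noise=NoiseModel(sigma=0.002, seed=0))
fits = {cond: fit_saturation(cv) for cond, cv in curves.items()}
for cond, f in fits.items():
    print(f"  {cond:7s} P_half = {f.P_half:5.2f} +/- {f.P_half_se:.2f} mW")

phi, phi_err = depth_parameter(
    fits["O2"].P_half, fits["NiEDDA"].P_half, fits["N2"].P_half,
    fits["O2"].P_half_se, fits["NiEDDA"].P_half_se, fits["N2"].P_half_se)
print(f"\nPhi = {phi:+.2f} +/- {phi_err:.2f}   (ln of the O2/NiEDDA accessibility ratio)")

cal = reference_calibration()
x, x_err, clamped = depth_from_phi(phi, cal, phi_err)
print(f"depth = {x:+.1f} +/- {x_err:.1f} A from the phosphate plane"
      + ("  [clamped]" if clamped else ""))
print("positive = buried in the hydrocarbon; negative = aqueous side.")
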