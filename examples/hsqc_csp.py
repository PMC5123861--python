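"""Chemical-shift perturbation mapping of a ligand binding site.

Simulates an HSQC peak list for a 40-residue stretch of a C2 domain,
plants dominant perturbations on the polybasic-patch lysines (K325-K327,
the phosphoinositide binding site), and recovers them by CSP ranking.
"""

from membind import csp_profile, rank_perturbed, simulate_hsqc_shifts
from membind.composition import NoiseModel

base = {r: (8.0 + 0.005 * (r - 300), 112.0 + 0.2 * (r - 300)) for r in range(300, 340)}
planted = {325: (0.10, 0.50), 326: (0.12, 0.60), 327: (0.09, 0.45)}

reference, titrated = simulate_hsqc_shifts(base, planted,
                                           noise=NoiseModel(sigma=0.002, seed=0))
records = csp_profile(reference, titrated, alpha=0.2)
top = rank_perturbed(records, method="threshold", n_sd=1.0)

print("residues above mean + 1 SD (candidate binding surface):")
for rec in top:
    print(f"  residue {rec.residue}: CSP = {rec.csp:.3f} ppm "
          f"(dH {rec.dH:+.3f}, dN {rec.dN:+.3f})")
print("\nCSP = sqrt(dH^2 + (0.2 dN)^2); the largest shifts localise the")
print("ligand to the polybasic lysine patch.")
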