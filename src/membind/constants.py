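"""Physical constants and unit conventions.

Internal units throughout the package: concentrations in molar, time in
seconds, energies in kJ/mol, distances in angstroms unless a function's
docstring says otherwise. Conversions happen only at the I/O layer.
"""

#: Gas constant in kJ/(mol K).
R_KJ = 8.314e-3

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Room temperature default for equilibrium assays, K.
ROOM_TEMPERATURE_K = 298.15

#: Phospholipids per ~100 nm large unilamellar vesicle, used to convert
#: total lipid concentration to vesicle concentration.
LIPIDS_PER_VESICLE = 90_000

#: Fraction of total lipid on the outer (solvent-accessible) leaflet of a LUV.
OUTER_LEAFLET_FRACTION = 0.5

#: Typical area per phospholipid in a fluid bilayer, nm^2.
AREA_PER_LIPID_NM2 = 0.65
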