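# Methods

This note records the models implemented in `membind`, the assumptions and
numerical choices behind them, and what the synthetic-data tests do and do
not establish about real instrument data.

## Units and conventions

Concentrations are molar, time seconds, energies kJ/mol (R = 8.314×10⁻³
kJ/mol/K), distances ångströms. Conversions (µL, µJ, nM, ppm) happen only
in the I/O layer. The membrane is always the plane z = 0 with +z pointing
into the hydrocarbon core; immersion depths, docking targets and reported
Cα depths all share this sign convention.

## Stopped-flow kinetics

Under pseudo-first-order conditions (vesicles in large excess over bound
protein) a binding relaxation is monoexponential,
F(t) = F₀ + A·e^(−k_obs t), with k_obs = k_on[v] + k_off linear in vesicle
concentration. Vesicle concentration is total lipid divided by a
lipids-per-vesicle count (default 90,000, appropriate for ~100 nm LUVs);
this conversion is the single sanctioned path from lipid to particle
concentration, and the rate-law regression is always on vesicle, not
lipid, concentration.

Numerical choices: the exponential fit is initialised from a log-linear
fit of |F − F(end)| (rate), the last-decile mean (offset) and the first
point (amplitude), with five multiplicative restarts of the rate guess
before declaring failure. Standard errors come from the least-squares
covariance. The k_obs–[v] regression is unweighted by default (weights of
1/SE² are available); with two points it returns the interpolating line
with zero residual variance. A negative fitted intercept (k_off) is
physically suspect but is reported unclamped with a warning flag so that
the error propagated to K_d = k_off/k_on remains honest; K_d's variance
uses the full slope–intercept covariance.

Group comparisons use one-way ANOVA followed by Fisher's least significant
difference on the pooled within-group variance, protected: pairwise flags
are set only when the omnibus test is itself significant at α = 0.05.

## ITC

The single-site isotherm is evaluated exactly at finite concentrations:
bound ligand solves the mass-action quadratic
B = ½[(nP_t + L_t + K_d) − √((nP_t + L_t + K_d)² − 4nP_tL_t)], and the
heat of injection i is ΔH·V₀·(B_i − B_{i−1}·d_i), where d_i = 1 − ΔV_i/V₀
is the dilution factor of the overflow (perfusion) cell model: each
injection displaces cell contents, so both total protein and total ligand
are diluted stepwise. This is the standard fixed-volume-cell treatment.

The fit optimises (n, K_d, ΔH) — K_d and n on log scale to stay positive —
plus, by default, a constant per-injection heat-of-dilution offset;
control-subtracted data can disable it. Optionally n is fixed (the usual
recourse when cell concentration, and hence the c-value n·P_cell/K_d, is
too low to determine stoichiometry) and the first injection can be
excluded. A c-value outside [1, 1000] raises a warning flag on the result.
ΔG = RT ln K_d and −TΔS = ΔG − ΔH are maintained as exact identities on
the result object.

The default synthetic titration — 50 µM cell protein, 25 × 10 µL
injections of 1 mM ligand, 25 °C, 1:1 site with K_d = 14 µM — mirrors a
realistic head-group titration of a C2 domain; ΔH = −30 kJ/mol is a
plausible exothermic enthalpy chosen once for the generator (the
corresponding published values are figure-only, so this number is a
package default, not a literature value). Noise is 2% of the largest
injection heat unless stated otherwise.

## Partitioning

The sedimentation observable is the fraction of protein co-pelleting with
sucrose-loaded vesicles, f_b = K[L]/(1 + K[L]) in accessible lipid [L].
K is fitted on log scale by nonlinear least squares; datasets that are
saturated (all f_b ≈ 1) or empty (≈ 0) are rejected as uninformative.
Accessible lipid defaults to half the total (outer leaflet of a LUV);
tabulated partition coefficients are treated as already expressed in
accessible lipid, so no second correction is applied when fitting
table-style data. ΔΔG = RT ln(K_a/K_b) at 298.15 K by default (room-
temperature assay), positive when a binds tighter.

The tethered-domain estimate treats the outer-leaflet lipids (surface
density 1/0.65 nm²) as spread through a slab of the tether range (default
4 nm) above the bilayer: c = 1/(N_A·t·a) ≈ 0.64 M, an order-of-magnitude
argument only — it ignores excluded volume, tether entropy and lipid
demixing.

## EPR depth analysis

Progressive power saturation follows
A(P) = I·√P·[1 + (2^(1/ε) − 1)·P/P½]^(−ε) with ε ∈ [0.5, 1.5] free by
default (fixable at 1.5). A curve with no rollover inside the scanned
range yields only a lower bound on P½ and is flagged. The depth parameter
is Φ = ln(ΔP½^O₂/ΔP½^NiEDDA) with the nitrogen-purged P½ as the common
baseline — the standard site-directed spin-labeling definition — with
first-order error propagation from the three P½ uncertainties.

The Φ→distance calibration is fitted, not hard-coded: the package ships a
15-pair reference table of (Φ, distance) values for spin-labeled C2-domain
sites on PtdSer/PtdIns(4,5)P₂ membranes and fits Φ(x) = A·tanh(B(x−C)) + D
with A, B > 0 (strictly increasing, hence invertible). If any tanh
residual exceeds 0.15 Φ-units the module falls back to a monotone PCHIP
interpolant. Inversion clamps Φ near the tanh asymptotes (at 99.99% of the
amplitude) with a flag; the distance error is the Φ error divided by the
local slope. Leave-one-out prediction over the reference table has median
absolute error ≈ 0.02 Å, so the calibration is effectively interpolation-
limited on these data.

## Membrane docking

The spin-label side chain is replaced by a geometric surrogate: a point at
Cβ + 7.0 Å along the Cα→Cβ direction (configurable). This fixed-offset
approximation is the dominant systematic term in the docking geometry; it
ignores rotamer distributions entirely.

Only tilt θ, azimuth ψ and vertical offset z are searched — rotation about
the membrane normal and in-plane translation are unobservable from depths
alone. The objective is a flat-bottom harmonic per restraint (zero within
the stated range, quadratic outside, unit weights). A coarse 5° × 5° ×
0.5 Å grid is scanned exhaustively, the best nodes are polished with
Nelder–Mead, and every pose within 10⁻³ of the optimum is returned, sorted
by tilt — the degeneracy is reported, never silently resolved. The
returned objective provably never exceeds the best grid node. With
restraints generated from a pose at zero noise the minimised objective
is 0 and the pose is recovered to well within the restraint windows
(tests assert 2° / 0.2 Å with 0.1 Å windows).

## Chemical-shift perturbation

CSP = √(ΔδH² + (α·ΔδN)²) with α = 0.2, the common ¹⁵N down-weighting; α is
a parameter because conventions vary. Peaks are matched by assignment id,
never by proximity in ppm space; residues missing from one list are
flagged (candidate exchange broadening) rather than dropped. The
binding-surface cut is mean + 1 SD of measured CSPs (or top-k); ties keep
input order.

## Synthetic data: what it shows and what it does not

Every generator inverts its analysis model exactly, so zero-noise
round-trips are machine-precision identities — these tests verify the
fitters, not the models. Noise is additive Gaussian on the measured
quantity with a seeded generator (identical parameters + seed ⇒ bitwise
identical data); recovery error grows monotonically over a σ ladder.
What the generators deliberately omit: instrument dead time and mixing
artefacts, baseline drift, FRET spectral physics, micelle/aggregation
artefacts in titrations, spectral lineshape effects in EPR, and resonance
assignment errors in NMR. Passing round-trip tests therefore certifies the
estimators under the stated noise model, not robustness to systematic
instrument error.

Problem sizes used in tests and in the acceptance script (chosen as
typical desk-scale analyses): 6-point kinetic series at 400 samples/trace;
25-injection titrations with 50 replicates; 10-point partition datasets
with 20 replicates; 12-step saturation curves; 20-residue toy domains with
3–4 restraints.

## Known limitations

- Single-exponential kinetics only; no double-exponential or global fits.
- Single-site ITC only; no competitive or sequential models, and inputs
  are integrated heats (no thermogram baseline integration).
- No electrostatic (Gouy–Chapman) modelling of partitioning.
- The docking surrogate fixes the label geometry; flexible side chains,
  membrane deformation and ensemble weighting are out of scope.
- The depth calibration is only as good as the supplied reference pairs;
  extrapolation beyond their Φ range is clamped, not trusted.
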