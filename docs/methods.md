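# Methods

This note records the models behind each component, the defaults that matter,
the numerical choices, and what the synthetic fixtures do and do not emulate.

## Composition and hydrogen classes

An RNA chain is assembled as Σ nucleoside formulas with each internal
phosphodiester contributing +P +2O and consuming the two bridging hydroxyl
protons. Phosphates are treated as ionized (no P–OH proton), so the molecular
weight is the polyanion mass; the free-acid convention would add ~1 Da per
linkage, well inside the ±0.1 kDa resolution at which sequence MWs are quoted.
Hydrogens are classed by exchange chemistry: **non-exchangeable** = C-bound
(ribose C–H and base C–H; per internal residue A 8, G 7, C 8, U 8), these are
the sites replaced by ²H when transcribing with deuterated rNTPs;
**exchangeable** = N/O-bound (base NH/NH₂ plus every 2′-OH; per internal
residue A 3, G 4, C 3, U 2), these equilibrate with the solvent. Free termini
add their hydroxyl protons (one each for 5′-OH and 3′-OH); terminal phosphates
replace them. Termini default to 5′-OH/3′-OH — the convention that best
reproduces sequence MWs as usually quoted — with the transcript-native
5′-triphosphate available through `TerminiSpec`.

The unit tests verify the class totals against an independent per-residue
formula oracle (Σ nucleoside formulas + (n−1)·(PO₂ − 2H)) across random
sequences.

## SLD model and its calibrated defaults

The molecule SLD is affine in both the non-exchangeable ²H fraction `d` and
the solvent D₂O fraction `x`; the excluded volume `V = MW_protiated·v̄/N_A` is
held fixed under deuteration (isotope substitution changes mass, not volume).
Scattering lengths live in one constants module (b_H −3.7406 fm, b_D 6.671,
b_C 6.6511, b_N 9.36, b_O 5.803, b_P 5.13); solvent SLDs follow from the
20 °C densities of H₂O (0.99707 g/cm³) and D₂O (1.1044 g/cm³) with ideal
volume mixing (excess-volume corrections < 0.3% are ignored).

Two defaults are calibrated jointly against published SLD and match-point
values for protiated, 42%-deuterated and perdeuterated RNA:

* **v̄ = 0.548 cm³/g** — within the 0.53–0.57 range quoted for RNA partial
  specific volumes;
* **f_exch = 0.85** — the effective completeness of labile-H exchange. Full
  equilibration (f = 1) over-steepens the SLD-vs-x slope relative to the
  published 0%→100% D₂O values; structured RNA protects a fraction of its
  imino/amino protons on experimental timescales, and 85% effective exchange
  reproduces the published slope. Both parameters are per-molecule arguments,
  not hidden constants.

With these defaults the model reproduces, for the stand-in constructs: SLDs
4.68/5.72 (42% d, 0%/100% D₂O) and 7.31 (perdeuterated, 100% D₂O) ×10⁻⁶ Å⁻²;
match points 0.688 (protiated, equimolar composition), 0.891 (42% d) and none
for perdeuterated RNA; and the inverse problem `required_deuteration(x*=0.90)`
= 0.44. Match points and required deuterations are closed-form solutions of
the affine system, with a bisection oracle cross-checking the tests.

The stand-in sequences themselves (`nucsolv.sequences`) are synthetic: they
are reconstructed from the published construct *description* (hairpin lengths
fixed by the loop residue numbers 13–18 and 32–37, all-C / all-G apical
palindromes, UCU bulge and 16-bp elongation in the larger hairpin) and
reproduce the published sequence MWs (9.2/20.9/30.1 kDa) to ±0.1 kDa. They are
not the deposited sequences.

## Debye simulation

Particles carry a heavy-atom (or bead) scattering length, implicit riding
hydrogens split by exchange class, a displaced-solvent volume (Fraser-style
atomic volumes; bead volumes from MW·v̄/N_A), and a chain id; chains carry the
deuteration label. The per-particle excess scattering length is
`f_i = b_i(effective) − ρ_solv·v_i`, and the orientationally averaged
intensity is the Debye double sum with `sinc` handled analytically at q→0.
Above 800 particles a weighted pair-distance histogram (default bin 0.1 Å)
replaces the exact O(n²) sum; the tests pin the two routes together at 0.5%.

Notable conventions:

* No hydration-shell term (the contrast argument is bulk-solvent level) and no
  instrumental smearing; both are documented limitations, not options.
* A bead model of a *continuum* body carries an O(1/N) incoherent self-term
  floor, `I(q) ≥ Σf²`. When a bead sphere is compared against the closed-form
  sphere form factor, the unbiased continuum estimate is
  `(I − Σf²)/((Σf)² − Σf²)`; the lattice generator also rescales coordinates
  so the coordinate R_g matches √(3/5)·R exactly (boundary voxelization
  otherwise biases the effective radius by ~0.1%, which is fatal near the
  form-factor zero). Even so, no finite bead model resolves the deep
  interference minimum itself: the comparison is conditioned on the form
  factor exceeding 0.5% of its forward value, which on a 0.01 Å⁻¹-step grid
  up to 0.3 Å⁻¹ excludes five points bracketing the zero at qR ≈ 4.49.

The CM-SANS simulator returns the full-complex profile plus each chain alone
at the same contrast: at the protiated chain's match point the cross- and
self-terms of that chain vanish and the complex profile collapses onto the
labelled chain's, which is the masking diagnostic the tests assert (≤5%
deviation across the Guinier region; recovered R_g within 5% of the visible
chain's coordinate R_g).

## Guinier analysis

Weighted least squares of ln I vs q² with weights (I/σ)². The automatic window
search scans start points, grows each window to the self-consistent ceiling
q_max·R_g ≤ 1.3 (1.0 with the elongated-particle flag), and keeps the longest
window with r² ≥ 0.99. This mirrors experimental practice and therefore
inherits its known property: for a homogeneous sphere, ln I(q²) is concave
(ln P(u) = −u²/5 − u⁴/350 + …), so a qR_g ≤ 1.3 window *overestimates* R_g by
≈1.6%. The tests document this bias explicitly; accuracy checks against
√(3/5)·R use a caller-fixed low-q window (qR_g ≤ 0.7) where the approximation
is exact to < 1%. Downstream, the dimensionless Kratky transform of a sphere
profile peaks at ≈1.06 with the convention-fitted R_g — printing as the
classic ≈1.1 globular signature — while the exact Guinier (Gaussian) curve
peaks at 3/e = 1.1036 at qR_g = √3 with the fitted parameters exact.

Non-positive intensities are excluded from the log-space fit but retained in
linear-space integrals (SANS background subtraction legitimately produces
negatives). Kratky peaks are refined by three-point parabolic interpolation.

## Porod volume

Q = ∫₀^cutoff q²I dq by the trapezoid rule, the 0→q_min gap filled with the
fitted Guinier model; V_p = 2π²I(0)/Q and MW = V_p × 0.00054 kDa/Å³ with the
biological default cutoff 0.15 Å⁻¹. Note that the invariant of a
sharp-interface sphere converges slowly (the tail carries ~1/u of the
integral); the geometric self-check against (4/3)πR³ therefore integrates to
qR = 20, and the default cutoff is meaningful only for data whose high-q decay
is faster than the ideal sphere's — as real (disordered-surface) biomolecular
data are. No tail extrapolation beyond the cutoff is applied, matching the
plain-cutoff convention.

## Indirect Fourier transform

P(r) on a 101-point grid over [0, D_max] minimises
‖(A·P − I)/σ‖² + α‖Δ²P‖², A_kj = 4πΔr·sinc(q_k r_j), with P(0) = P(D_max) = 0
built into the unknowns. α="auto" walks a 29-point logarithmic α grid scaled
by ‖A‖²/‖D‖², locates the L-curve corner by maximum Menger curvature, and
falls back to the largest α within 2× of the best residual when the L-curve is
flat (noiseless data). Positivity defaults to a soft penalty (iteratively
reweighted on negative nodes); `positivity="hard"` switches to non-negative
least squares and `"none"` to the unconstrained solve. Derived quantities:
R_g² = ∫r²P dr / 2∫P dr, I(0) = 4π∫P dr, and the back-transformed reduced χ².

`scan_dmax` inverts every candidate and accepts those whose P(r) stays above
−1%·max P, whose endpoint approaches zero without a truncation spike
(|P(D−Δr)| ≤ 5% of max), and whose χ² sits on the plateau (≤ 5% above the
best, with an absolute slack of 0.05 so machine-precision jitter on noiseless
data cannot break the plateau test); the smallest acceptable D_max is reported
(parsimony), with the full diagnostics table returned for inspection. On the
noiseless sphere this recovers 2R to the grid step; on rod-like fixtures the
distribution shows the expected early cross-section peak (~20 Å for the
coarse A-form helix) and long tail.

## χ² fitting

The theoretical curve is linearly interpolated onto the experimental grid (no
extrapolation); scale — and optionally a flat background, the residual
incoherent term of SANS — minimise the weighted SSR in closed form. χ² is
reduced by N − p with p the number of fitted parameters; values below 1 are
expected for data with generous error bars, which is why the ranking table
also carries Δχ² relative to the best model. Background fitting defaults off
and should be enabled for SANS comparisons.

## Synthetic fixtures and noise

Shapes: uniform random or symmetric-lattice spheres, random cylinders, and
coarse two-strand A-form helices (1 bead/nt, rise 2.81 Å/bp, twist 32.7°/bp,
backbone radius 9 Å ⇒ ~20 Å cross-section, strand phase offset 165°), with
hairpins capped by a 5-bead loop arc and two-hairpin complexes joined
end-to-end with a configurable bend. The average-nucleotide bead is built from
the equimolar internal-residue composition, so bead models and sequence-level
contrast calculations share one parameterisation (the tests pin the bead mass
and exchangeable-H count to the sequence module).

The noise model reflects *reduced* SANS data: I = Debye + flat background
proportional to the solvent ¹H incoherent weight ((1−x)·40 + x)/40, and
Gaussian heteroscedastic noise with σ = √((I+bg)·I₀/exposure) — Gaussian, not
Poisson, because reduced data are already averages of many frames.
Quadrupling the exposure halves every error bar; the background at 65% D₂O
exceeds that at 90% D₂O, which is the experimental reason to prefer
high-%D₂O match points. A seed is mandatory; identical seeds give identical
profiles.

What the fixtures do **not** emulate: real per-residue mass distribution,
sequence-specific structure, hydration shells, instrumental smearing
(wavelength spread), inter-particle structure factors, or radiation-damage and
aggregation artefacts. Passing the in-silico contrast-match test shows the
bookkeeping and estimators are correct, not that any particular experimental
sample will behave ideally.

## Problem sizes used in the self-checks

The bundled checks are sized for a single-CPU desk run: the bead-sphere
Debye-vs-analytic comparison uses a 32 000-bead lattice (the O(1/N) floor must
sit below the 1% band at the conditioned grid points); the statistical checks
use 200 replicates (χ² calibration) and 100 replicates (Guinier recovery) on
3 000-bead spheres; IFT checks run on 320-point profiles with a 101-point
real-space grid.

## Known limitations

* Buffer components (salts, phosphate) are not included in solvent SLDs.
* No X-ray contrast-variation support; the X-ray route is sequence-independent
  here only through the Porod MW estimate.
* The IFT's α policy is an L-curve heuristic, not a perceptual-criteria
  engine; for pathological data inspect the `scan_dmax` diagnostics table
  rather than trusting the point estimate.
* DNA, modified nucleotides and proteins are out of scope for the composition
  module.
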