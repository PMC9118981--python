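# Methods

This note records the models implemented in cyaclear, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests
do and do not demonstrate.

## Isotopomer model of N–N bond formation

A 1:1 molar mixture of ¹⁴N- and ¹⁵N-labeled substrate (urea or biuret) is
oxidized by excess hypochlorite and the evolved N₂ is measured at m/z 28
(¹⁴N¹⁴N), 29 (¹⁴N¹⁵N) and 30 (¹⁵N¹⁵N). Two limiting mechanisms predict
different isotopomer patterns:

- **Intermolecular**: nitrogen is released (via chloramine-type
  intermediates) into a fully scrambled pool before pairing. With heavy
  fraction *p*, N₂ assembles binomially — (1−p)² : 2p(1−p) : p², i.e.
  1:2:1 at p = ½ and a 29/30 ratio x = 2.
- **Intramolecular**: both atoms of an N₂ come from one molecule. Urea
  (two N) gives only 28 and 30 (1:0:1 at p = ½). Biuret (three N) gives
  one intramolecular N₂ per molecule plus half an intermolecular N₂ from
  the leftover atom, 5:2:5 overall at p = ½.

For a fraction *f* of molecules reacting intramolecularly the 29/30 ratio
is x = 2(1−f)/(1+f) for urea and x = (6−4f)/(3+2f) for biuret; the
estimators invert these as %intra = 100(2−x)/(2+x) and 150(2−x)/(2+x),
clamping to [0, 100] with a flag (ratios slightly above 2 are ordinary
measurement noise). The forward mixture model and the closed-form inverse
are derived independently and bound together by a round-trip identity test
(1e−9 over a 101-point grid). Note that *f* counts molecules, not N₂:
for biuret even f = 1 yields one intermolecular N₂ per two molecules
(x = 0.4, not 0).

**Background correction.** Air N₂ leaks into headspace measurements and
contributes to m/z 28 and, via natural ¹⁵N abundance (≈0.36%), to m/z 29.
The default `symmetric_excess` mode estimates the air-derived 28 signal as
max(area28 − area30, 0) — under a 1:1 label mix the reaction contributes
28 and 30 in equal measure, so the excess is air — and removes
air28 · 2(1−q)/q from channel 29 (q = ¹⁴N fraction of the light material,
default 0.9963). A `total_28` mode treats the whole 28 channel as air
(an upper bound, appropriate when reaction-derived 28 is negligible).
Which 28-quantity to use is a genuine modeling choice; both are reported
in the correction metadata. With q = 1 the correction is the identity, and
corrected areas are never negative.

**Labeling non-idealities.** The estimators assume ideal labeling
(p = 0.5, pure isotopes), as the closed forms require; the configured
purities enter only the background correction and the Monte-Carlo
generator. With the tracer purities as supplied (light 99.63% ¹⁴N, heavy
≥99% ¹⁵N) the residual ~1% ¹⁴N in the heavy material adds m/z 29 signal
that the ideal-label inverse attributes to the intermolecular route,
giving a systematic *underestimate* of f that grows with f and reaches
about 2 percentage points at f = 0.5 for biuret. The test suite pins this
bias (direction and magnitude) and performs estimator-recovery checks
under matched labeling, where the quantity being stressed is the air
correction (recovery within ±2 points up to 30% air contamination).

**N₂O.** Trace N₂O from the same scrambled pool assembles binomially as
well, predicting a 45/46 ratio of 2. It is reported separately and never
folded into the N₂ mechanism estimate.

**Peak integration** is a plain trapezoid above a straight baseline drawn
between the window edges (windows centered at 1.84 / 2.62 / 2.88 min for
N₂, CO₂ and N₂O by default); negative net areas are clipped to zero with
a flag. No peak deconvolution is attempted.

## Sequence mining

The diagnostic motif `S-G-G-X-E-X-Q-G-P-X-G-G-G-P` (wildcards at
positions 4, 6, 10) sits in the C-terminal metal-binding region of known
CAHs. "Near the C-terminus" is made operational as: the hit must start in
the final quarter of the chain (`c_term_threshold = 0.75`, configurable).
Anchor conservation (R194/R324 in reference numbering) is decided by
global alignment of the candidate to a reference sequence using BLOSUM62
with affine gaps (open 11, extend 1; a gap of length L costs 11 + (L−1)).
The alignment parameters used originally for the anchor mapping are not
published, so these standard values are a package choice and are recorded
in output metadata. Traceback ties are broken deterministically
(diagonal, then up, then left), so identical inputs give identical
alignments; the aligner's scores are cross-checked against Biopython's
`PairwiseAligner` in the tests. The classification rule is: motif in the
C-terminal quarter *and* all anchors conserved → CAH candidate; motif but
a failed anchor → barbiturase-like; otherwise negative (anchors are not
evaluated without a qualifying motif).

PFM columns count residues only (gaps excluded); information content is
log₂20 minus the column's Shannon entropy, in bits.

The bundled reference for anchor checking is *synthetic* (generated with
arginines planted at 194/324): the real reference protein sequence is not
shipped. Any real reference can be supplied as a single-record FASTA.

## Chlorine chemistry

- ppm means mg/L at unit water density; no density or activity
  corrections.
- Free-chlorine speciation uses the two-species acid/base model
  fraction(HOCl) = 1/(1+10^(pH−pKa(T))) with the empirical
  pKa(T) = 3000/T − 10.0686 + 0.0253·T (T in kelvin; pKa ≈ 7.54 at
  25 °C). Molecular Cl₂ (relevant below pH ≈ 4) is out of scope, as are
  chloramine equilibria and carbonate buffering.
- Electron balance: amide nitrogen starts at oxidation state −3; each
  ClO⁻ accepts 2 electrons. Hence biuret (3 N) → N₂ costs 4.5 ClO⁻
  equivalents, urea (2 N) → N₂ costs 3.0, and driving nitrogen to +5
  (nitrate) costs strictly more (12.0 for biuret).
- Reductant dosing is exact molar-mass arithmetic on an explicit basis
  species ("ppm hypochlorite" depends on the standard; the default basis
  is ClO⁻, 51.45 g/mol, and the basis is echoed in every result). The
  package ships the empirically observed full-neutralization ratios
  (~1:1 for thiosulfate, ~2:1 for sulfite against ClO⁻) as documented
  presets rather than hard-coded stoichiometric truth: the corresponding
  doses (17.6 / 28.0 ppm against 5.72 ppm ClO⁻) sit within ~1–2% of the
  observed endpoints (17.4 / 27.7 ppm), and no single clean stoichiometry
  reproduces both exactly.
- The soluble-nitrogen model for biuret oxidation is piecewise linear:
  100% at 0 equivalents, declining to a terminal 10% at 6 equivalents and
  flat beyond — an empirical summary, not a kinetic model.

## Assay calibration

Standard curves are ordinary least squares on (concentration, response)
pairs, refit per plate because temperature and matrix shift the response;
the 0-concentration standard is included in the fit (the intercept
absorbs the blank) rather than subtracted. R² < 0.98 raises a
quality flag only. Inversion preserves negative concentrations (a
total-chlorine reading below the deionized-water blank indicates a net
reducing matrix — exactly the signal that confirms neutralization);
clipping is available but off by default. Combined chlorine is computed
bit-exactly as total − free. Stability/aging panels are normalized to a
designated reference condition (= 100%).

## Kinetics and planning

The rate law is v = k_cat·E₀·S/(K_m+S) with no product inhibition and an
effectively irreversible forward reaction (CO₂ loss). Fitting uses
initial-rate data only: Hanes–Woolf linearization seeds a positive-
constrained nonlinear least squares (`scipy.optimize.curve_fit`), with
standard errors from the Jacobian; designs that cannot bracket K_m are
rejected. Progress curves integrate the ODE with LSODA at rtol/atol
1e−10 and are cross-checked in the tests against the implicit integrated
rate law K_m·ln(S₀/S) + (S₀−S) = k_cat·E₀·t. Hypochlorite inactivation
is modeled as an instantaneous step to zero activity at the first event
time (complete inactivation is observed at even trace free chlorine over
hours; no rate constant is resolvable), freezing the concentration
thereafter.

Converting enzyme loadings (mg/L) to molar concentration requires a
subunit molar mass that is not published for these enzymes; the default
is 40,000 g/mol and is an explicit assumption carried in
`KineticParams.enzyme_molar_mass`. Consequently absolute depletion slopes
(ppm/h per mg/L) are simulation capabilities, not reproducible claims;
the property the tests check is zero-order (linear) depletion while
S ≫ K_m, which is molar-mass independent in shape. Published parameter
sets are bundled (`CAH_PR`: k_cat 10.1 s⁻¹, K_m 115 μM; `CAH_BD`:
10.6 s⁻¹, 103 μM).

The remediation planner composes the three stages from the public
primitives: reductant dose (stage 1), hydrolysis time-to-target from the
implicit rate law (stage 2), and a hypochlorite shock sized at 4.5 ClO⁻
per biuret produced, 1:1 molar with CYA consumed (stage 3).

## Synthetic data: what it does and does not show

Generators are pure functions of their arguments (bit-identical output
per seed) and ship ground truth with every artifact.

- Protein backgrounds are uniform over the 20 residues — deliberately
  unrealistic, so the motif false-positive probability per window is
  exactly 20⁻¹¹ and zero hits are expected in any test-sized sample.
  Positives/barbiturase-like records are substitution-mutated copies of
  the synthetic reference (2% point mutations, anchors and motif window
  protected, no indels), so classification truth is guaranteed by
  construction; passing says nothing about remote homologs or gapped
  alignments of real families.
- Ion tables are atom-level Monte Carlo: molecules are assigned labels
  and isotopes per atom (honoring purities), intramolecular pairs stay
  within molecules, everything else is shuffled into a pool and paired.
  This generator is deliberately independent of the closed-form
  distributions, so the two act as mutual oracles (agreement within 3σ
  multinomial at 10⁶ molecules). Air is added at natural ¹⁵N abundance to
  a stated fraction of total N₂. Real GC/MS artifacts (detector
  nonlinearity, CO₂ tailing into the N₂O window, inlet fractionation)
  are not modeled.
- Plates are linear response + i.i.d. Gaussian read noise; rate tables
  apply multiplicative Gaussian noise to the exact rate law;
  chromatograms are Gaussian peaks on a flat baseline. Problem sizes in
  the test suite (10⁶ molecules per ion table, 50-seed kinetics recovery,
  1000-sequence scanner comparison) were chosen so the whole suite runs
  in well under a minute while keeping multinomial/fit noise far inside
  the asserted bands.

## Numerical conventions

Residue coordinates are 1-based inclusive everywhere (matching the
R194/R324 convention). Percentages are reported on the 0–100 scale.
Estimated percentages outside [0, 100] are clamped with an explicit flag
rather than raised, except where a ratio is genuinely undefined
(corrected area30 = 0), which is an error. Ion areas, rates and
concentrations are validated non-negative at construction.
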