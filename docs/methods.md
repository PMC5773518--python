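# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, and what the synthetic-data generator does and
does not emulate.

## Three-state equilibrium and ΔC

Cells without aggregates are modelled with three biosensor states: folded
N, free unfolded U, chaperone-bound unfolded UC. Folding equilibrates much
faster than synthesis, degradation or aggregation, so [N]/[U] = K_f =
exp(−ΔG_F/RT) always holds, while holdase binding (dissociation constant
K_d, treated as one effective constant for the whole QC network) drains U.
With total biosensor B and total latent chaperone C conserved (free
chaperone depletion modelled exactly; no competing clients), mass action
gives a closed form for the chaperone needed to hold the fraction folded
f at a given value, and its inverse — the fraction folded at given C — is
the positive root of a quadratic. `thermo.solve_equilibrium` instead
brackets the root and solves by Brent iteration to relative tolerance
1e-12; the closed-form quadratic (`fraction_folded_closed_form`,
vectorised, used per cell by the generator) is an independent route, and
the test-suite asserts the two agree to 1e-9. ΔC between two conditions is
the difference of the two C values and is computed directly from the two
fractions folded; it is exactly antisymmetric and positive when the
treatment leaves the biosensor less folded.

Temperatures: in-cell conversions of ΔG_F to K_f use 310 K (culture at
37 °C); denaturation fits use 296 K (assay at 23 °C). Both are arguments,
not constants. Concentrations are µM throughout; ΔC is reported in the
units of the user-supplied K_d and B, and ΔC/K_d is reported alongside
because the leading term of ΔC is proportional to K_d, which must come
from configuration (it is not identifiable from the cytometry itself).

## Gating and the Lower-slope gradient

Per sample, classification proceeds as in the assay's analysis protocol:

1. *Pre-gate*: cells with a FRET/donor ratio above the maximum ratio of
   the batch's wild-type* reference (which contains no aggregates) are
   set aside and later counted as Upper-slope.
2. *Scatter scale*: the wild-type* residual SD around its own robust
   origin-line is the expected scatter of aggregate-free cells; it is
   treated as intensity-independent.
3. *Iterative fit*: four rounds of a robust line through the origin
   (IRLS with Tukey bisquare weights, c = 4.685, MAD scale) on the
   retained cells, each round excluding cells more than 2 wild-type SDs
   *above* the line. Exclusion is one-sided because only aggregation
   pushes FRET up; low outliers are kept. Cells exactly on the boundary
   stay Lower.
4. *Reported gradient*: refit on Lower-labelled cells inside the acceptor
   analysis window — the lowest-expression slice covering 0.2 of the
   instrument dynamic range (default full scale 10^4.5 AFU), where
   chaperone engagement is most pronounced and the model's
   low-concentration assumptions hold best; explicit AFU bounds may
   override it.

The line is through the origin because compensated channels are
proportional; a free intercept exists only as a diagnostic. All steps are
deterministic: identical events and configuration give identical labels.

Two structural consequences are worth knowing. First, a strict 2-SD
one-sided band labels ~2.3% of genuinely soluble cells Upper (the Gaussian
tail); this is the classifier's false-positive floor and sets the baseline
of the binned aggregation percentages. Second, because the one-sided
exclusion trims the upper tail of the soluble scatter, the fitted gradient
carries a small negative bias (≈0.1–0.3% at default noise), which the
affine calibration absorbs.

## Slope-to-fraction calibration and B

Control-condition gradients of the panel are regressed on the fraction
folded predicted from each mutant's ΔG_F (affine: gradient = a·f + b).
Affine rather than one-parameter scaling was chosen because the unfolded
state has non-zero FRET, so the gradient at f = 0 is a genuine offset.
Because both the gradients and the calibration share the instrument's
arbitrary-unit scale, ΔC is invariant under any common rescaling of the
two. Inverted fractions are clipped into (1e-6, K_f/(1+K_f)]; mutant point
estimates invert *replicate-mean* gradients because clipping per replicate
truncates symmetric noise one-sidedly at the control boundary (control
cells sit at the intrinsic fraction) and would bias the panel mean low by
~0.01 µM at default noise. Per-replicate ΔC values are retained as spread.

The scalar B entering ΔC is the donor²-weighted mean biosensor
concentration over Lower-slope cells in the analysis window
(× the configured AFU→µM factor). The donor² weighting matches the
weighting the origin-constrained slope fit gives each cell, so the
gradient-derived f and B describe the same effective cell population;
pairing the gradient with an unweighted geometric-mean B (available via
`B_estimator: geometric`) understates ΔC by ~7% under the default
conditions because the equilibrium is nonlinear in B. B estimation from
fluorescence requires a volume/brightness calibration upstream; the
AFU→µM factor is configuration.

## Denaturation fits

Curves are fit by unweighted global least squares (lmfit
Levenberg–Marquardt, xtol = ftol = 1e-12) with m and the four baseline
parameters shared across all mutants and one D50 per mutant; replicate
experiment sets are fit independently and stabilities averaged afterwards.
Shared baselines are what keep destabilised mutants — partially unfolded
at 0 M urea, midpoint possibly extrapolating below 0 M — identifiable.
Starting values: m = 8 kJ/(mol·M) (barnase-scale cooperativity), D50 at
the steepest local FRET drop. Curves whose FRET never spans 0.08 show no
transition; they are flagged unidentifiable and contribute only to the
native baseline. The exponent is evaluated as a logistic mixture
(scipy expit), so extreme urea or midpoints cannot overflow.

Sign convention: the fit reports m·D50, the *unfolding* stability at 0 M
urea (positive = stable). The folding free energy used everywhere else in
the package is its negative.

## Aggregation analysis

Cells are binned by log10 acceptor intensity into 9 bins whose midpoints
evenly span the configured bounds (default 2.5–4.5, giving midpoints
10^2.5 … 10^4.5 spaced 0.25); intervals are half-open with edge values
going to the higher bin, and bins under 20 cells are dropped from fitting.
The per-bin percent of Upper-slope cells is fit with a count-weighted
Boltzmann sigmoid with plateaus fixed at 0 and 100, making the midpoint
x50 both half-maximal and 50%-absolute; A50% = 10^x50. Mutants whose
aggregation never reaches 20% in any bin (or spans less than 20 points)
are excluded as low-aggregators — their midpoint lies beyond the measured
range and the fit is ill-conditioned; an explicit exclusion list can
reproduce any fixed choice of excluded variants.

The landscape regression fits log10(A50%) = s·ΔG_F + c_condition with a
common slope and per-condition intercepts; ΔA50% is the intercept
difference (log10 scale; the linear fold-change is 10^offset). The
extra-sum-of-squares F-test compares this against per-condition slopes,
and per-mutant offsets feed the exact Wilcoxon signed-rank test.

## Panel statistics

The Wilcoxon signed-rank test is two-sided, drops zero differences,
mid-ranks ties, and enumerates the exact null by dynamic programming over
doubled ranks for n ≤ 25 (exact also under ties); larger samples use the
normal approximation with continuity and tie corrections. Twelve
same-direction mutants give the exact extreme p = 2/4096 ≈ 4.9e-4.
Reports carry star coding but always include raw p-values.

## The synthetic-data generator

`simulate` emulates exactly the structure the analysis assumes: per-cell
expression T log10-normal (mean 3.5, SD 0.5 decades) truncated to
[10^2.5, 10^4.5] AFU (upstream gating removes untransfected cells below
and off-scale events above); acceptor = T + noise and donor = d·T + noise
with independent Gaussian channel noise (60 AFU, giving a wild-type
residual CV of ~5% at typical intensities; channels pre-compensated);
fraction folded per cell from the three-state equilibrium at that cell's
B = T·(AFU→µM) and the condition's C; FRET emission from the observed
donor times slope_U + f·(slope_F − slope_U) for soluble cells (0.2/0.6
defaults) or slope_A = 1.2 for aggregated cells. Aggregation is a per-cell
Bernoulli draw from a Boltzmann sigmoid of log10 T whose midpoint is
linear in ΔG_F (slope −0.07 decades per kJ/mol, intercept 3.6, width 0.2)
plus a 0.3-decade offset under treatment, with a 2% nucleation floor:
below that probability the sigmoid tail is not populated within the
expression time window, which is what keeps the hyperstable wild-type*
(ΔG_F = −25 kJ/mol) genuinely aggregate-free — the premise on which the
2-SD gating band rests. Sub-seeds per sample spawn deterministically from
the master seed, so identical seeds give bit-identical tables on any
platform.

The default study design — 12 included mutants with ΔG_F evenly spanning
−6…+1 kJ/mol plus wild-type*, two conditions, three replicates, 5000
cells per sample, K_d = 2 µM, AFU→µM = 3e-4 (B ≈ 1 µM at median
expression), C_control = 0 — was chosen once to mirror a realistic
destabilised-mutant panel in which every included mutant's aggregation
midpoint stays inside the binned expression range under both conditions
and the Lower-slope gradient remains informative about f. The ΔA50%
validation scenario holds C equal between conditions to isolate the
translational offset (see limitations).

What the generator does *not* emulate: photophysics (spectral cross-talk,
donor bleed-through — inputs are assumed compensated), autofluorescence
and cell-cycle structure, partial within-cell aggregation (aggregation is
binary per cell), intensity-dependent noise, and instrument drift between
acquisitions. Passing tests therefore demonstrate that the estimators
recover truth when the assay's stated assumptions hold, not that those
assumptions hold in any particular experiment.

## Known limitations

- **K_d and AFU→µM are inputs.** ΔC scales with K_d in its leading term;
  misspecifying K_d rescales ΔC nearly proportionally. ΔC/K_d is reported
  for transparency.
- **Chaperone engagement curves the soluble population.** Under a
  treatment that raises C, high-expression cells (B ≫ K_d) are
  proportionally less affected than the low-expression cells the gradient
  window targets, so the soluble cloud bends above the fitted line and
  inflates Upper-slope false positives in the top expression bins. This
  is the same concentration dependence the ΔC measurement exploits, but
  it degrades A50% midpoints measured *under* strong holdase shifts;
  aggregation offsets are best quantified between conditions of
  comparable holdase activity, and the ~2.3% false-positive floor of the
  2-SD band sets the resolution of the low-aggregation plateau either
  way.
- **One effective K_d.** Heterogeneous chaperone families with different
  affinities are collapsed into a single binding constant; ΔC is then the
  K_d-weighted effective pool change, not a molecule count.
- **Equilibrium only.** Folding/unfolding kinetics, synthesis and
  degradation fluxes, and aggregation kinetics are outside the model; the
  aggregation readout is a fixed-time snapshot.
- **Analysis window heuristics.** The 0.2-of-dynamic-range window and the
  10^4.5 AFU full scale are instrument conventions; explicit acceptor
  bounds should be set per instrument.
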