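# Methods

This note records the models implemented in `stoichlab`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generators do and do not emulate.

## Molecular-weight arithmetic

All species are treated as sums of a DNA mass and zero or more protein
oligomer masses. dsDNA mass uses 0.650 kD/bp, the standard sodium-salt
average for double-stranded DNA; the ~0.6 kD biotin end label is ignored as
negligible at gel resolution. Both choices are configurable
(`dna_mw(..., kd_per_bp=...)`). Construct monomer masses are inputs taken
from the experimental design, never predicted from sequence — sequence-based
MW or isoelectric-point prediction is explicitly out of scope (pI is carried
as metadata only). Because the migration assays anchor everything to
internal standards, the inferred *unit counts* are insensitive to the exact
Da/bp constant; absolute complex masses are not, and may differ slightly
from values computed with other conventions.

## Migration model and normalization

The reptation regime for long, linear, uniformly charged chains gives
migration distance linear in `log10(MW)`, independent of protein charge or
conformation (the DNA overhang drives the migration). Each lane carries two
non-interacting reference DNAs; the normalized lag of a band is
`d_ref_fast − d_band`, which cancels per-lane electrophoresis offsets
exactly (the slow reference cancels algebraically; both are validated
against each other in tests). All distances are in arbitrary units
(pixels); every inference is unit-free by construction.

The standard curve regresses `log10(MW/MW_anchor)` on `d − d_anchor` by
ordinary least squares. The migration convention is a signed *difference*
of normalized lags anchored at the first standard (not a ratio): with a
log-mass response this reduces to the classical reptation law and makes the
two-point case exact. The intercept is fitted rather than forced through
the anchor; for clean data it is ≈0. Extrapolation beyond the standard
range is permitted but flagged in result warnings, because heavier
complexes resolve worse and extrapolated masses are noisier.

## Assay I (supershift differencing)

Every lower shift carries exactly one oligomer, so all assay-I standards
share one unknown protein mass `S` on top of their known DNA mass. The
implementation profiles `S` out by nonlinear least squares: for fixed `S`
the curve parameters are the inner OLS solution of
`d = a + b·log10(MW_DNA + S)`; `S` is located by a coarse geometric scan,
bounded minimization, and a full least-squares polish. This keeps the
estimator exactly self-consistent with the forward model — a noise-free
simulated gel returns the generating unit count to numerical precision —
while preserving the defining supershift-minus-lowershift logic: the unit
count is `(MW(supershift) − MW(lowershift)) / MW_monomer` per tandem lane.
A variant that regresses on bare DNA mass and relies on the subtraction to
absorb `S` is *not* exactly self-consistent under the log-linear law and
was rejected for that reason. The joint fit needs at least three
lower-shift standards; the default design has ten.

## Assay II (free-DNA ladder)

Free DNA of known sizes calibrates the curve; the probe's lower-shift
migration gives the complex mass and
`units = (MW_complex − MW_DNA,probe) / MW_monomer`. Replicate gels each
contribute one measurement per probe lane. The ladder's largest size is
chosen slightly above the heaviest shifted band so no estimate requires
extrapolation.

## Summaries, hypothesis fits, ANOVA

Unit counts are summarized as the arithmetic mean with a two-sided 95%
Student-t half-width, `t(0.975, n−1)·sd/√n`; this convention exactly
reproduces the reference half-widths 0.41 (n=5) and 0.66 (n=3) of the
denaturation-ratio table at 2-decimal rounding. Reported counts are
rounded to two decimals; raw values are retained. A single measurement
yields an undefined CI and a warning, never a silent zero.

The hypothesis fit compares observed band lags with the lags expected under
each candidate oligomer size (the candidate fixes all complex masses, so
the standard curve can be built per hypothesis) and scores each regression
by its squared deviation from the identity line (slope 1, intercept 0);
the generating size scores exactly zero on clean data. Differences between
construct groups are tested with one-way fixed-effects ANOVA
(`scipy.stats.f_oneway`); the degenerate all-groups-equal case is reported
as F=0, p=1. Multi-factor analysis (size, tag, expression system) is a
documented extension point, not implemented.

## Equilibrium binding

The single-site model is the exact two-component equilibrium with ligand
depletion (quadratic isotherm), evaluated in the algebraically stable form
`FB = 2P₀ / (b + √(b² − 4P₀D₀))`, `b = P₀+D₀+K_D`, which avoids
cancellation over concentrations spanning 10⁻³–10⁵ nM and degrades
gracefully to the hyperbola as D₀→0. Fits minimize untransformed residuals
of fraction bound over a log-spaced concentration grid, matching how such
titrations are recorded; the initial K_D guess is the concentration at
half-response. For lysate titrations the nominal concentration can be
rescaled by an `active_fraction` parameter (default 1).

Two-site fragments are treated as independent, identical sites (the digest
experiment shows the two complexes separate cleanly); no cooperativity
parameter is offered. Two analyses are provided without asserting which is
mechanistically correct: the independent-sites occupancy model, and an
*effective* single-species K_D fit on the summed shift fractions
(`mode="tandem_sum"`), which is how tandem titrations are commonly
summarized. Note the independent model predicts free DNA decaying as
(1−θ)² versus (1−θ) for a one-site fragment; an observed equal decay rate
is not reconciled by this model. Kinetics (on/off rates, slow equilibrium
drift over long incubations) and nonspecific-competitor partitioning are
out of scope.

## Band-pattern predictions

For a mixture of one or two distinct one-site fragments, the
one-DNA-per-oligomer topology predicts `2 × #fragments` bands (each free
fragment plus one shifted complex per fragment); the DNA-bridging topology
predicts `#fragments + 3` bands for two fragments (free fragments plus the
three unordered fragment pairs). Cutting a doubly occupied two-site
fragment at its internal restriction site converts the supershift into two
single complexes, one per product, migrating as the corresponding one-site
shifts; a singly occupied fragment yields a mixture of free and bound
products (four bands), since the single oligomer sits on either site.

## FCS

The autocorrelation model is the standard single-component 3-D diffusion
form with structure parameter κ = z₀/r₀. κ is fixed from a calibration
with rhodamine 6G (D = 426 µm²/s; `r₀ = √(4·D·τ_d)`) rather than co-fitted,
because a single curve constrains κ poorly. There is no triplet-state
term; lags below ~10 µs can be trimmed via `min_lag` to avoid triplet
contamination. Fits are unweighted by default (no weighting scheme is
assumed for the input data) with optional per-point weights. Initial
values are `N₀ = 1/G(first lag)` and τ_d,0 at the half-amplitude lag.

The oligomer order is the per-replicate-pair ratio `N_denatured/N_native`,
summarized with the same Student-t convention as the gel assays. The
denatured τ_d is fitted independently — urea changes viscosity and particle
size — and only amplitudes enter the ratio. Fluorophore brightness can
differ between native and denaturing conditions, which biases monomer
counts slightly upward; no correction is applied by default, but a
`brightness_correction` multiplier (default 1) is exposed. The simulator
takes the monomerizing effect of the denaturant as ground-truth input
(particle number multiplied by the oligomer order).

## Peptide mass fingerprinting

Trypsin cleavage follows the Keil rule (C-terminal to K/R, never before P);
peptides with 0..k missed cleavages are enumerated with 1-based positions.
Masses are monoisotopic (IUPAC residue masses embedded to five decimals),
singly protonated only, with fixed carbamidomethylation of cysteine
(+57.02146 Da, iodoacetamide alkylation); other modifications are omitted
by default and pluggable at the digest level. Matching takes the nearest
theoretical mass within a tolerance (ties: smaller |Δ|, then fewer missed
cleavages), reports Δ signed (observed − theoretical), and computes
coverage as the union of matched peptide spans. The default tolerance of
0.25 Da absorbs MALDI calibration offsets of up to ~0.1 Da.

One caveat worth recording: of the four MS/MS-confirmed reference peptides
used as mass anchors, three have measured values 0.06–0.08 Da *below* the
theoretical `[M+H]⁺`, consistent with a small one-sided calibration bias,
but the measured value for HQRTHTGEKPYVCR lies 1.03 Da below theory while
agreeing with the *neutral* monoisotopic mass M to 0.02 Da — consistent
with a neutral-mass printout or a one-isotope mis-assignment in the source
measurement. The implementation computes `[M+H]⁺` uniformly (validated
against pyteomics); the corresponding anchor test documents the
discrepancy rather than switching mass conventions per peptide. Raw
spectrum processing, database searching, and scoring schemes are out of
scope.

## Synthetic data generators

Every generator is a pure function of its config including an integer seed
(`numpy.random.default_rng`), with documented draw order, so identical
configs give byte-identical outputs.

* **Gels.** Forward model: `d = intercept − slope·log10(MW) + offset_lane +
  ε_band`, clipped at zero — the minimal model consistent with the
  log-linear migration law; band-compression and gel-percentage effects are
  not modelled. Default geometry (intercept 430, slope 120 gel units per
  decade) spans the 75–1460 bp fragment range over ~150 units, i.e. ~100 bp
  resolvable steps. Designs mirror the study layouts: assay I uses six
  one-site standards (75–1460 bp), four tandem fragments (114–468 bp) and
  4368/220 bp references; assay II uses the 75/114/273/543/740 bp ladder
  with a 75 bp probe. Default band noise is 1% of the standard span and
  the lane offset SD is 5 gel units — calibration choices (true
  experimental migration noise is not recoverable from the printed data),
  both config-exposed; lane offsets cancel under normalization regardless.
* **Titrations.** Depletion-aware fractions (per-site occupancy for tandem
  fragments, treating the site pool as 2×molecule concentration) with
  multiplicative lognormal noise of CV 5% (default), renormalized to sum
  to one. Default series: 12 log-spaced protein concentrations from 2.3 to
  1500 nM over 5 nM DNA with K_D 48 nM, emulating a serial-dilution
  titration.
* **FCS.** Model curves on a 120-point log lag grid (1 µs–1 s) with
  additive Gaussian noise of SD 2% of G(τ); denatured particle number =
  order × native. Photon-level trace simulation and photophysics are not
  emulated.
* **Peak lists.** Theoretical digest masses in the instrument window
  perturbed by Gaussian mass error (default SD 0.05 Da) plus uniform
  contaminant peaks.

Passing round-trip tests therefore demonstrates estimator correctness and
noise robustness *under these generative assumptions* — log-linear
migration, single-species diffusion, independent sites — not robustness to
real-data pathologies (band smearing, aggregates retained in wells,
multi-component diffusion, matrix clusters), which the generators do not
produce.

## Problem sizes and numerics

Round-trip benchmarks use 50 simulated gels per assay, 100 titrations, and
50 FCS replicate pairs — sizes at which the Monte-Carlo summaries are
stable to well under the tolerances tested. Nonlinear fits use
`scipy.optimize.least_squares`/`curve_fit` with tight tolerances (1e-15)
so noise-free round trips recover parameters to ≲1e-8; parameters are
bounded positive, and fits that pin at a bound or fail to converge raise
`FitError` with diagnostics rather than returning garbage. Degenerate
inputs (flat titrations, non-decaying correlation curves, duplicate
standard distances, empty groups) raise typed errors naming the offending
lane/row where applicable.
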