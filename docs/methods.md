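# Methods

This note documents the models implemented in `titinmech`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions applied where more than
one reasonable choice existed.

## Exon usage and PSI

Percent spliced in for exon *i* is computed from inclusion reads (IR,
reads overlapping the exon) and exclusion reads (ER, junction reads
supporting skipping), each normalized by the number of read start
positions that can generate them at read length *L*:

    IR_n = IR / (l_exon + L − 1),   ER_n = ER / (L − 1),
    PSI  = 100 · IR_n / (IR_n + ER_n).

PSI is a ratio of rates, so it is invariant under common scaling of IR
and ER. Exons with zero informative coverage get NaN, never a silent 0;
PSI-weighted size summaries refuse to run over undefined values and name
the offending exon. Group PSI defaults to the mean of per-sample PSI
values (consistent with per-sample error bars); a pooled-counts mode is
available via `group_psi(..., pooled=True)`.

Before between-group testing, each sample's exon counts are adjusted to
the mean total gene count, `E^A = E · Ḡ / G_sample`, which removes
library-size differences while preserving within-sample exon ratios.

**Per-exon test.** The default (`method="pooled"`) forms, per exon, the
2×2 table of adjusted inclusion/exclusion counts pooled within each group
and tests equal inclusion proportion — chi-square without continuity
correction when all expected counts are ≥ 5, Fisher's exact test
otherwise. This count-level test is in the spirit of the exact tests used
by differential-expression packages and has the resolution to flag
complete inclusion/exclusion reversals at small replicate numbers. A
sample-label permutation test on per-sample PSI (`method="permutation"`,
exact enumeration up to 10 samples, otherwise 10,000 seeded draws) is
provided as an assumption-light alternative; note that with 4 + 4 samples
its two-sided p-value cannot fall below 2/70 ≈ 0.029 by construction,
which is why it is not the default. `ΔPSI` is group A minus group B in
percentage points; −log10(p) display values are capped at 6.

## PEVK sizing and the wormlike chain

The PEVK transcript size of a genotype/muscle is
`Σ_PEVK (PSI_i/100) · n_residues,i`. Contour length assumes an unfolded
chain at the maximal residue spacing, `CL = n_residues · 0.38 nm`.

Force per titin molecule follows the wormlike-chain interpolation
formula, with fractional extension `x = z/CL`:

    F(x) = (k_B T / PL) · [ x + 1/(4(1 − x)²) − ¼ ].

Defaults: persistence length `PL = 1.4 nm` (PEVK), thermal energy
`k_B T = 4.11 pN·nm`. The temperature behind `k_B T` is taken as 298 K;
it only scales the force axis and is configurable through `WlcParams`.
`F(0) = 0`, the small-extension limit is `F → (3/2)(k_B T/PL)·x` (the
entropic linear spring), and F diverges as `x → 1`; extensions at or
beyond CL raise a domain error listing the offending points.

PEVK extension z comes from the separation of fluorescence epitopes
flanking the segment. Because the antibodies bind ~4 Ig domains away from
the PEVK ends, 15 nm is subtracted from measured separations; corrected
values below zero are flagged and excluded from fits (with a count kept).
Epitope positions are the centers of a sum-of-Gaussians nonlinear
least-squares fit to the intensity line profile, initialized from local
maxima with randomized restarts; non-convergence raises with diagnostics.

**Force curves and stiffness.** `titin_force_curve` fits z linearly on SL
(group-mean mode available; the two agree for the linear generators used
here) and maps the fitted z through the WLC. "Average stiffness" over an
SL window (default 2.45–2.75 µm, capturing most of the physiological
range) is everywhere the least-squares slope of the curve interpolated
onto a 0.01 µm grid within the window — identical estimator for
per-titin force, whole-muscle tension and ECM curves; for linear curves
it equals the endpoint finite difference.

## Force–sarcomere-length relation

From thin filament length TFL, thick filament length 1.6 µm and bare
zone 0.15 µm: plateau `[2·TFL − bare, 2·TFL + bare]` (force 1), zero
overlap at `2·TFL + thick` (force 0), limbs with slope magnitude
`1/(thick − bare) ≈ 0.6897 /µm`, clamped to [0, 1]. The plateau's lower
edge at `2·TFL − bare` encodes the convention that the ascending limb
begins where thin filament tips cross into the adjacent half-sarcomere's
bare zone; the alternative convention (ascending limb from `2·TFL`) is
available via `plateau_convention="tfl"` and lowers the short-range
average by a few points. Thick-filament compression effects below
~1.65 µm are not modelled; forces there are simply clamped at zero.

Working-range averages evaluate the relation at 0.05 µm increments
anchored at the range minimum, appending the maximum when off-grid, and
report the mean as percent of maximal force. A trapezoidal-integral
oracle agrees within 2 percentage points for all tested geometries; the
grid convention (anchoring, endpoint inclusion) is responsible for
differences of that order, which is also the tolerance used for the
headline 91%/96% working-range values.

Auxiliary conversions: TFL = half the Tmod–Tmod distance across a Z-disk
(the half Z-disk width is included by construction); end-inspiration
SL = arrest SL × (1 − ε) with ε the inspiratory strain amplitude; serial
sarcomere count = fiber length / SL (real-valued); SL during a
whole-muscle stretch = slack SL × (1 + (%stretch/100)/(FL:ML ratio)).

## Whole-muscle mechanics

PCSA = muscle mass · cos θ / (ρ · fiber length), with muscle density
ρ = 1.0597 g/cm³ by default (the conventional mammalian value; the
density is configurable since it is not otherwise pinned down).

The force–frequency relation is the sigmoid
`P0(F) = P0min + (P0max − P0min)/(1 + exp((F_half − F)/k))`; the sign in
the exponent is chosen so tension rises with frequency and `F_half` is
the half-maximal frequency. Fitting is multi-start Levenberg–Marquardt
least squares; flat data raise a non-identifiability error. Curves are
compared with the extra-sum-of-squares F-test,
`F = ((SS_shared − SS_separate)/Δdf) / (SS_separate/df_sep)`, where the
shared fit forces one parameter set on both datasets. Passive curves can
be compared the same way under a logarithmic model
`tension = a + b·ln(SL − c)` (c constrained below the smallest SL); the
log model is used only for curve comparison, never for stiffness.

Passive tension decomposition: titin-based tension is the
extraction-sensitive part, `titin(SL) = skinned(SL) − extracted(SL)` on
the common SL support (linear interpolation, no extrapolation), floored
at 0 with negatives counted; ECM tension is the extracted curve. The
titin fraction is `100 · mean(titin)/mean(skinned)` over a configurable
SL range (the analysis uses 2.2–3.2 µm). Additivity
titin + ECM = skinned holds exactly on the evaluation grid by
construction and is asserted in tests.

## Synthetic-data generators

All generators are pure functions of (spec, seed) via an explicit
`numpy` Generator; no global random state.

* **Exon reads** — per exon, `depth` informative reads (uniform
  per-locus allocation; real coverage profiles are irrelevant to formula
  testing) with inclusion drawn Bernoulli(π). Raw inclusion counts are
  scaled by `(l_exon + L − 1)/(L − 1)` so the length-normalized PSI
  estimate has expectation 100π. Default depth 10,000 and read length
  100 nt (paired-end-like). Not emulated: positional coverage bias,
  junction-read ambiguity, overdispersion between biological replicates
  — so passing recovery tests demonstrates estimator correctness, not
  robustness to real-library artifacts.
* **Synthetic annotation** (`titinmech.annotation`) — a 216-exon
  titin-like transcript across all five region labels with 47 PEVK exons
  flagged deleted. Exon boundaries and per-exon residue counts are
  invented, constrained to the published region-level totals (deleted
  exons encode 1586 residues; PSI-weighted PEVK sizes 1611 (WT) and 421
  (deletion) residues; exon 159 at 28 residues; Z-repeat upregulation in
  the deletion genotype). It is a stand-in for a real annotation table,
  which users supply as TSV.
* **Passive curves** — titin tension = WLC force at
  `z(SL) = 100 nm/µm · (SL − 2.0 µm)` scaled by 3×10⁹ titin molecules
  per mm² (chosen to put tensions on the tens-of-mN/mm² scale of
  measured specific tensions); ECM tension
  `0.2 · (exp(2.5·(SL − 2.2)) − 1) mN/mm²` clamped at 0, which makes
  titin carry ~70% of WT skinned tension over 2.2–3.2 µm — the
  titin-dominant regime observed in skeletal muscle. Intact and skinned
  states share the same true tension (skinning leaves passive tension
  unchanged); extracted is ECM only; independent Gaussian noise
  (default sd 0.2 mN/mm²) per point and state, floored at zero. Not
  emulated: viscoelastic relaxation, genotype-dependent ECM remodelling,
  tandem-Ig unfolding.
* **Force–frequency** — sigmoid plus Gaussian noise at the standard
  stimulation frequencies {1, 10, 20, 40, 60, 80, 100, 120, 150, 200} Hz.
* **Epitope profiles** — sums of Gaussians plus non-negative-clipped
  noise; warns when the sampling step exceeds the narrowest peak width.
  The WLC analysis driver uses σ = 15 nm peaks so that the smallest
  simulated separations (~55 nm) remain resolvable by a two-Gaussian fit;
  closely spaced epitopes at short SL merge optically, a real limitation
  the generator reproduces and the driver avoids by starting at 2.4 µm.

## Units

Sarcomere lengths and filament lengths are carried in µm; molecular
quantities (extensions, contour lengths, epitope positions/separations,
Tmod distances) in nm; forces in pN per molecule and mN/mm² for specific
tension. Conversions happen once at module boundaries
(`tfl_from_tmod_distance` returns nm; geometry consumes µm).

## Problem sizes

The test suite and the analysis drivers use deliberately modest problem
sizes — 200 seeded replicates for PSI recovery, 500 replicates/exons for
the null-calibration KS checks, 4 replicates per genotype at depth 10⁴
for the transcript simulation — sizes at which the asserted tolerances
(2 PSI points, KS p > 0.01, 2 percentage points on range averages) are
comfortably resolvable.

## Known limitations

* The per-exon test models read-level sampling only; with strong
  biological replicate variability its pooled p-values are anti-
  conservative, and the permutation variant (with more samples) is the
  safer choice.
* The WLC treats the PEVK as the only extensible element; tandem-Ig
  straightening, Ig unfolding and calcium effects on persistence length
  are out of scope, so absolute forces below ~2.3 µm SL are
  underconstrained.
* The force–SL relation ignores cross-bridge kinetics and non-uniform
  half-sarcomeres; it is a geometric overlap model.
* Titin fractions depend on the chosen SL range and the generator's ECM
  parameters; they are reported as descriptive outputs, not calibrated
  targets.
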