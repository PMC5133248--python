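# Methods

## The enrichment-detection procedure

For one OTU in one gradient, let r₁…r_F be its read counts over the F
sequenced fractions and ρᵢ = rᵢ / maxⱼ rⱼ the normalized profile ("ratio of
quantities"). Normalizing within each gradient removes per-gradient
sequencing depth, so any per-gradient rescaling of counts leaves the whole
analysis unchanged (this is a tested invariant).

**Peak calling.** The primary peak is the global-maximum fraction (ties are
resolved by the read-weighted mean density of the tied fractions). Its
*support* is the maximal contiguous run of fractions with ρ ≥ 0.5 that
contains the mode — the half-maximum band width. A peak is valid only when
the support holds at least `min_support = 3` fractions; a DNA band spread by
diffusion across a real gradient cannot occupy a single fraction, so
single-point spikes are treated as banding artifacts. For invalid peaks the
read-weighted centroid of the entire distribution is used instead, and any
comparison involving a centroid is made centroid-vs-centroid so both sides
are measured the same way. Local maxima outside the primary support with
ρ ≥ 0.25 and their own half-height support of ≥ 3 fractions are reported as
secondary peaks; these capture bimodal bands produced when only a subset of
an OTU's population assimilates the substrate. The support threshold is
applied relative to each peak's own height (0.5 × local maximum), which is
what makes the half-maximum notion well defined for secondary bands.

**Shift.** Δρ = labeled mode density − control mode density, differenced at
full floating precision and rounded to 4 decimals only in reports. By
default the primary peaks are compared; `use_secondary` switches the
labeled side to its densest supported peak, for subpopulation analysis of
bimodal labeled profiles. OTUs with zero reads on either side are excluded
from calling.

**Limit of detection.** A null treatment — an incubation designed so that
labeling stays below detectability — yields a set of shifts that measure
pure methodological banding variability. The cutoff is
`factor × max |null shift|` with `factor = 1.5`; the calibration reports n,
mean, the n−1 standard deviation of the signed shifts, a magnitude
histogram, and the cutoff's distance from the mean in SD units. Requiring
1.5 × the worst observed null excursion is deliberately conservative: it
trades sensitivity for a low false-positive rate, which matters because a
single false enrichment call changes a clade's uptake percentage. The
signed (not absolute) null distribution is used for the mean/SD summary.
An all-zero null set raises an error rather than producing a zero cutoff;
fewer than `lod_min_n = 10` null shifts proceeds with a small-n flag and
warning. Enrichment is Δρ ≥ cutoff, inclusive. Negative shifts are
physically unexpected (they would mean banding position is not a function
of density) and are flagged for inspection.

## Input selection rules

* **Fraction window.** Gradients are collected densest-first (fraction 1 =
  bottom of the gradient), validated as strictly decreasing density. Of the
  ~50 collected fractions, the contiguous window of `n_select_fractions =
  20` fractions maximizing summed DNA quantity is sequenced; contiguity
  mirrors a physical DNA band and the rule is deterministic (ties go to the
  lowest starting index). Selection is invariant to uniform rescaling of
  DNA quantities, so the quantification unit (ng vs ng μl⁻¹) is irrelevant.
* **OTU filter.** An OTU is analyzed when it ranks in the global top
  `top_n = 100` by total reads (ties broken lexicographically) and its mean
  reads per sequenced fraction reaches `min_mean_reads = 400` in at least
  one gradient of each analyzed pair. The depth rule suppresses random
  banding artifacts of very rare OTUs. "Mean over fractions, in at least
  one gradient" is one of several defensible readings of a per-fraction
  depth requirement; the statistic (`mean`/`min`) and the quantifier
  (`any`/`all`) are exposed as configuration (`read_stat`,
  `read_quantifier`) rather than hard-coded. The filter is idempotent.

## Isotope calculators

* **Pool mixing.** atom% = 100·(x_label·Cs + x_nat·Ca)/(Cs + Ca), with
  Cs the added labeled substrate and Ca the ambient unlabeled pool (μM).
  The labeled-stock purity defaults to x_label = 0.98 — commercial ¹⁵N
  stocks are typically 98–99 atom% — and natural abundance to
  x_nat = 0.003663. Both are configurable.
* **Semiconservative ceiling.** After g doublings with the substrate as the
  sole N source, DNA atom% = pool·(1 − 2⁻ᵍ) + 100·x_nat·2⁻ᵍ: each daughter
  duplex keeps one parental strand, so one doubling averages the pool with
  natural abundance exactly. This is an upper bound on real labeling (real
  cells draw on unlabeled N sources too).
* **Density gain.** Predicted Δρ = excess × Δρ_max with full-label maxima
  0.016 g ml⁻¹ (¹⁵N) and 0.036 g ml⁻¹ (¹³C) by default (ratio 0.44 — the
  reason ¹⁵N SIP needs per-taxon resolution).
* **Cross-feeding budget.** Primary uptake U (μmol N L⁻¹ h⁻¹) over duration
  t into a PON stock P (μM N) gives a PON label fraction min(1, U·t/P);
  each release pathway s with rate R_s contributes R_s·t·(label fraction)
  μM of labeled N; the secondary fraction is that total as a percentage of
  a competing consumer's uptake C·t. The label fraction deliberately does
  not multiply in the substrate pool's atom% purity — the budget is an
  upper bound, and keeping the arithmetic linear in measured rates keeps it
  transparent. The PON cap never binds at realistic coastal rates.

## The gradient simulator

The simulator exists so the full pipeline can be validated against known
truth without any sequencing data. Each OTU (or subpopulation) bands as a
Gaussian in density with center
`1.660 + 0.098·GC + excess·0.016` g ml⁻¹ — the classical linear GC–density
relation plus the linear isotope term — and SD `band_sd`. Fractions are 50
equal-width density bins over 1.66–1.77 g ml⁻¹ (an idealization of
equal-volume fractions), collected densest-first. DNA per fraction is the
community-weighted band mass with lognormal quantification noise
(σ = 0.1). After window selection, reads are drawn from a single
multinomial over (OTU × sequenced fraction) cells with probabilities ∝
relative abundance × band mass, so per-gradient read totals are conserved
exactly. One seed sequence per experiment derives independent per-gradient
substreams, so adding a treatment never perturbs earlier gradients and
fixed seeds give byte-identical output files.

Parameter choices that matter:

* `band_sd = 0.004` g ml⁻¹: chosen so that simulated profiles have
  half-maximum widths of ~4 fractions, matching typical per-OTU amplicon
  SIP profiles; it is the least constrained knob and is exposed in config.
  Much smaller values make bands fail the 3-fraction support rule; much
  larger ones blur adjacent bands together.
* `reads_per_gradient = 4×10⁶` (2×10⁵ per sequenced fraction): set by a
  design power analysis run before the pipeline was assembled. Peak
  positions are discretized to the fraction spacing (0.0022 g ml⁻¹ here),
  and the mode of a multinomially sampled band flips to a neighboring
  fraction with probability that falls with depth; at ≥ 4×10⁴ reads per
  OTU the flip rate drops below the ~10% nonzero-shift level a credible
  null treatment exhibits. Shallower simulations remain useful but show a
  noisier null.
* Null-treatment labeling: atom-fraction excess ~ Exponential(mean 0.005)
  capped at 0.12, i.e. imposed shifts < 0.002 g ml⁻¹ and mostly ≈ 0 —
  an incubation whose labeling is real but below detectability.
* Community GC ~ Normal(0.5, 0.05) clipped to [0.3, 0.7], even abundances:
  keeps all bands inside the 20-fraction window so recovery statistics
  measure the method, not window truncation.

What the simulator does **not** emulate: ultracentrifugation physics (rotor
speed/time enter only through `band_sd`), PCR and primer bias, 16S
copy-number variation, chimeras, compositional abundance noise between
gradients, and refractometer measurement error on fraction densities
(fraction densities are exact bin midpoints). Passing recovery tests
therefore shows the *inference* is correct under the banding model, not
that every wet-lab artifact is survivable.

## Numerical choices and degenerate inputs

* Recovered shifts from peak comparisons are integer multiples of the
  fraction spacing; tests of recovery accuracy are therefore stated as
  "within one fraction spacing".
* Ties at the profile maximum use the read-weighted mean of the tied
  fractions; an all-zero profile is a "no-signal" case excluded from
  shifts; a centroid over zero total reads never occurs (no-signal is
  caught first).
* SD uses the n−1 estimator throughout.
* Density differencing happens at full precision; reports round densities
  to 4 decimals and percentages to 1 decimal.
* Analysis is fully deterministic; the only randomness in the package is
  the simulator's, all of it seeded.

## Validation summary

The test suite checks: exact reproduction of the calculator examples above;
the peak-support rules (3-fraction acceptance, spike rejection, secondary
detection); the normalization/scale, reversal, identity-pair and
LOD-linearity invariants; simulator determinism and read conservation; and
a 10-seed recovery study (100 OTUs/seed, 50 labeled at excess ≥ 0.3 vs 50
unlabeled, analyzed at depth 4×10⁶ with the LOD calibrated from a simulated
null pair) requiring median sensitivity and specificity ≥ 0.95 and ≥ 90% of
null-pair shifts ≤ 0.001 g ml⁻¹. Problem sizes were chosen so the whole
suite runs in seconds on one CPU.
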