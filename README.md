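# tagsip

Per-OTU detection of stable-isotope enrichment from CsCl density-gradient
amplicon profiles (Tag-SIP), with a null-calibrated limit of detection,
isotope mass-balance calculators, and a gradient simulator for end-to-end
validation.

## The problem

DNA stable isotope probing (SIP) identifies which microbes assimilated an
isotopically labeled substrate: organisms that incorporate ¹⁵N (or ¹³C)
into new DNA band at a higher buoyant density in a CsCl gradient. For ¹⁵N
the signal is weak — full labeling raises DNA density by only ~0.016 g ml⁻¹,
about half of what ¹³C achieves — and inter-taxon GC variation spreads
unlabeled DNA over a wider density range than the labeling signal itself.
Tag-SIP resolves this by 16S amplicon ("tag") sequencing **every gradient
fraction**, so each OTU's own DNA density distribution is observed directly
and compared between a labeled incubation and its unlabeled control.

`tagsip` implements the analysis side of that design for microbial
ecologists running ¹⁵N (or ¹³C) SIP incubations:

1. **Profiles.** For each OTU and gradient, per-fraction read counts are
   normalized to the gradient-wise maximum (the *ratio of quantities*
   ρᵢ = rᵢ / max rᵢ ∈ [0, 1]), removing sequencing-depth differences.
2. **Peaks.** The OTU's band peak is the global-maximum fraction; it is
   accepted only if supported by ≥ 3 contiguous fractions at half maximum.
   Single-point spikes are rejected; for them the read-weighted centroid of
   the whole distribution is compared instead. Supported secondary peaks
   (bimodal bands from partially active subpopulations) are reported.
3. **Shifts.** Δρ = labeled peak density − control peak density (g ml⁻¹),
   per OTU. Negative shifts are preserved and flagged.
4. **Limit of detection.** A null treatment — an incubation whose labeling
   is expected to be undetectable — provides an empirical distribution of
   banding variability. The enrichment cutoff is 1.5 × the largest null
   shift magnitude; an OTU is *enriched* iff Δρ ≥ cutoff.
5. **Clade summaries.** Percent of enriched OTUs per taxonomic clade.

The package also ships closed-form calculators for experiment planning:
two-pool mixing (atom% ¹⁵N of amendment + ambient pool), the
semiconservative labeling ceiling (DNA atom% after g doublings:
`pool·(1−2⁻ᵍ) + 100·x_nat·2⁻ᵍ`), expected density shift per atom-fraction
excess, and a cross-feeding mass-balance budget — plus a simulator that
generates complete synthetic experiments with known ground truth.

## Worked example

Simulate a paired experiment (a labeled treatment plus an LNT-like null
treatment, each with control and labeled gradients) and analyze it:

```bash
cat > sim.yaml <<'YAML'
gradient:
  seed: 4
design:
  n_otus: 40
YAML
tagsip simulate --config sim.yaml --out-dir sim
tagsip analyze --metadata sim/fractions.csv --counts sim/otu_counts.tsv \
               --taxonomy sim/taxonomy.tsv --manifest sim/manifest.yaml \
               --out-dir out
```

prints

```
LOD cutoff: 0.0033 g/ml (n_null=40)
80 OTU comparisons, 20 enriched
```

The null pair's 40 shifts never exceeded one fraction spacing
(0.0022 g ml⁻¹), so the cutoff calibrated to 1.5 × 0.0022 = 0.0033 g ml⁻¹;
of the 80 OTU comparisons (40 per treatment), exactly the 20 OTUs simulated
with atom-fraction excess ≥ 0.3 were called enriched. `out/shifts.tsv`
holds per-OTU densities, Δρ, support sizes and calls; `out/clade_summary.tsv`
aggregates per family:

```
treatment  rank    clade              n_otus  n_enriched  percent_enriched
Nitrate    family  FamilyI            11      6           54.5
Nitrate    family  Flavobacteriaceae  6       3           50.0
...
Nitrate    family  (all)              40      20          50.0
```

The calculators work standalone:

```bash
$ tagsip atom-percent --cs 2.0 --ca 0.47
treatment     Cs [uM]  Ca [uM]   Cs:Ca  atom% 15N
pool             2.00     0.47    4.26      79.4%

$ tagsip labeling --pool 39.4 --doublings 1
pool 39.4 atom% 15N, 1 doubling(s) -> DNA 19.9 atom% 15N (substrate assumed sole N source)

$ tagsip crossfeed --uptake 0.01 --pon 1.25 --duration 24 \
    --don-release 0.002 --nh4-release 0.028 --competing-uptake 0.072
PON label fraction : 0.192
labeled DON  release : 0.0092 uM
labeled NH4  release : 0.1290 uM
secondary fraction : 8.0% of competing N uptake
secondary label is 8.0% of competing N uptake (negligible at the 10% threshold)
```

So a 2 μM ¹⁵N-nitrate amendment over a 0.47 μM ambient pool yields a
79.4 atom% ¹⁵N substrate pool; one semiconservative doubling on a 39.4%
pool labels bulk DNA at most 19.9%; and plausible cross-feeding fluxes
amount to ~8% of competing ammonium uptake — too dilute to register above
the detection limit.

## Input formats

* fraction metadata: CSV/TSV with `gradient_id, fraction_index,
  density_g_ml, dna_quantity, sequenced` (fraction 1 = densest; density
  strictly decreasing in index);
* OTU counts: TSV, first column `otu_id`, remaining columns
  `<gradient_id>:<fraction_index>`;
* taxonomy: TSV `otu_id, lineage` (semicolon-delimited domain…genus);
* manifest: YAML listing `pairs:` (`labeled`, `control`, `treatment`) and
  the `null_treatment` used for LOD calibration.

See `docs/methods.md` for the model, parameter meanings and limitations.
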