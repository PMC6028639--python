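# Methods

This document records the statistical model, the default parameters and why
they were chosen, the scope and limitations of the synthetic-data
generator, and the numerical design decisions.

## 1. Model

### 1.1 Experimental design

The unit of replication is a pooled same-sex, same-litter cage sample
(an *experimental unit*), not an individual animal. The full design is
2 × 2 × 2: group (SAL control vs POL immune-activated) × maternal diet
(n-6 vs n-3 PUFA) × sex (M/F), with 3 units per cell → 24 units, each
pooling 2–6 animals. Three planned contrasts are analysed:

| name | question |
|---|---|
| n-6-SAL vs n-6-POL | MIA effect on the control diet |
| n-3-POL vs n-6-POL | diet effect within the MIA group |
| n-3-SAL vs n-6-SAL | negative control (diet effect without MIA) |

Δ-methylation is always second-listed minus first-listed group, in
percentage points.

### 1.2 Per-CpG differential methylation

At each CpG, unit-level methylated/unmethylated read counts are pooled
within each contrast group and modelled as binomial with
`logit(π) = β0 + β1·treatment`. With a single binary covariate the MLE is
closed-form (group-pooled proportions, by sufficiency), so the 1-df
likelihood-ratio test reduces to a 2×2 binomial G-test, vectorised over
all sites. Separated tables (a zero margin) receive a Haldane–Anscombe
+0.5 correction, flagged in the output. P-values are converted to
q-values by an authored Benjamini–Hochberg step-up; sites with q < 0.01
are significant. Significant sites within 250 bp are grouped into regions
(single-linkage), annotated with nearest gene (signed TSS distance in
gene orientation, promoter/exon/intron) and CpG-island context
(island / shore within 2 kb / open sea), and ranked by |Δ| then q.
Genes with any site at |Δ| > 3% feed the pathway-gene list.

Eligibility requires depth ≥ 10 in **every** unit of both groups, after
quantile normalisation (below).

### 1.3 Global CCGG methylation

Directional RRBS reads begin at an MspI cut, so base 1–3 of a read is
`CGG` when the cut-site CpG was methylated and `TGG` when it was
bisulfite-converted. The global estimate is `100·C/(C+T)` over read
starts; reads starting with neither are counted separately and excluded.
The estimator is invariant to 3'-adapter trimming (tested). Unit-level
estimates enter an OLS GLM `percent ~ C(group) + C(diet) + C(sex)` with
all two-way interactions, a type-II ANOVA, and nine stratified Welch
comparisons (3 planned contrasts × {all, M, F}).

### 1.4 Regulatory integration

Tag tracks (DHS, MECP2) are single-position tag lists. For each eligible
CpG the tag count in ±`window` bp is normalised per million track tags.
A site "passes" when its density exceeds a cutoff; over-representation of
DMRs among passing sites is a hypergeometric tail test
(population = eligible sites, successes = passing sites, draws = DMRs).
Venn counts over DMR ∩ DHS ∩ MECP2 are reported.

### 1.5 Stabilisation

MIA-significant sites are inner-joined with the diet-contrast table at the
same (contig, pos). A site is *stabilised* when

1. `sign(Δ_diet) == sign(Δ_mia)` (the diet moves methylation back toward
   control: both contrasts are oriented so a rescue is sign-concordant),
2. `p_diet < 0.05` (configurable to q-values), and
3. `|Δ_diet| ≥ magnitude_ratio · |Δ_mia|` with `magnitude_ratio = 0.5`.

A gene is stabilised when at least half of its MIA-significant sites are.
The rescue fraction is `100 · stabilised / MIA-altered genes`. The
distributions of per-gene mean Δ_mia among stabilised vs non-stabilised
genes are compared by a two-sample KS test; the paired per-gene
(Δ_mia, Δ_diet) differences by a Wilcoxon signed-rank test.

## 2. Parameter defaults and rationale

### Simulation (`SimulationConfig`)

| parameter | default | rationale |
|---|---|---|
| n_contigs × contig_length | 2 × 50 kb | smallest genome where ~1000 eligible CpGs and ~250 kept fragments exist; seconds-scale runtime |
| ccgg_rate | 5 /kb | realistic MspI-site density for CpG-rich material; gives ~500 planted CCGGs |
| n_islands × island_length | 8 × 1 kb | islands cover ~8% of the genome, enough for island/shore/open-sea annotation classes |
| baseline_meth / island_meth | 75 / 20 | typical somatic open-sea vs island methylation |
| mia_global_shift | −5 | small global hypomethylation, detectable by the GLM but not per site |
| n_dmr_sites / dmr_delta | 100 / −20 | focal strong effects; −20 points is recoverable at the default coverage |
| rescue_fraction | 0.8 | the study condition of interest: ~80% of DMR sites restored by the n-3 diet |
| unit_dispersion | 200 | beta precision; unit-level SD ≈ 3 points at p = 0.5, matching biological replicate scatter |
| coverage | 20 reads/fragment/unit | per-CpG depths of ~15–40 after alignment, RRBS-like |
| read_length | 51 | single-end 51-bp protocol |
| conversion_rate | 0.995 | typical bisulfite conversion efficiency |
| size_range | (40, 220) | typical RRBS size selection (protocol value unstated upstream; documented choice) |
| error_rate | 0 | sequencing error off by default; optional for robustness tests |
| tag_background_rate | 0.02 /bp | ~2000 background tags per contig: dense enough for stable per-million densities |
| tag_enrichment_fold | 10 | clearly separated enriched windows |
| tag_window | ±50 bp | **deliberately narrow.** Eligible CpGs cluster in 51-bp "tufts" at fragment 5' ends spaced 40–220 bp apart; wide peaks bleed into neighbouring tufts and destroy the enriched/background contrast. ±50 bp keeps a planted peak on its own site. |
| dhs/mecp2_dmr_fraction | 0.6 | a majority, not all, DMRs carry each mark, so Venn regions are all populated |

### Processing

| parameter | default | rationale |
|---|---|---|
| adapter | AGATCGGAAGAGC | standard sequencing adapter stem |
| trim min_overlap / max_mismatches / min_keep | 12 / 2 / 22 | the protocol's stated trimming parameters |
| quality cutoff | mean Phred ≥ 20 | the protocol's stated screen (boundary inclusive) |
| aligner k / max_mismatches | 12 / 2 | pigeonhole: 3 seeds of ≥12 bases guarantee one exact seed at ≤2 mismatches for 51-bp reads; unique-best-hit or rejection |

### Differential methylation & downstream

| parameter | default | rationale |
|---|---|---|
| min_depth | 10 | stable per-unit percentages; matches common RRBS practice |
| q_cut | 0.01 | the study's significance level |
| region_gap | 250 bp | the study's region window |
| promoter_window | (−2000, +500) around TSS | conventional promoter definition |
| shore_width | 2 kb | conventional island-shore definition |
| delta_cut_pathway | 3 % | the study's gene-mapping threshold |
| regulatory window (pipeline) | ±100 bp | matched to the tag geometry above: background windows hold ≈ 0.02·201 ≈ 4 tags, enriched windows ≈ 4 + 9·0.02·101 ≈ 22, cleanly separable |
| density cutoff | "auto" = 3 × 25th percentile of eligible-site densities | on a miniature genome a fixed "density > 5" is scale-dependent; anchoring at a low quantile estimates the background level robustly even when many sites are enriched, and the ×3 margin sits between the ≈4-tag background and ≈22-tag enriched expectations. A fixed cutoff (e.g. 5) remains available. |
| stabilisation p_threshold / magnitude_ratio | 0.05 / 0.5 | nominal diet significance; "at least half the MIA effect reversed" operationalises rescue |

### A scenario property worth knowing

With the defaults, the **global** read-start estimator contrast
(POL − SAL on the n-6 diet) is ≈ −13 points, not the configured −5.
The global shift (−5) applies to every CpG, but the 100 DMR sites
(−20 each) sit by construction at fragment-start CCGGs — exactly the
sites the read-start estimator samples — so they contribute
disproportionately. This is a property of RRBS itself (the global
estimator sees only MspI cut sites), reproduced faithfully by the
simulator.

## 3. Generator scope and limitations

- **Directional, top-strand only.** Reads are 5' prefixes of the original
  top strand of size-selected fragments; the bottom-strand CpG is never
  sampled. This keeps the read-start CGG/TGG assumption exactly true.
- **Only the 5' CGG end is sequenced.** Real RRBS fills in both MspI ends;
  sampling only the 5' end is a documented simplification.
- **Unit-level methylation.** Beta-distributed unit probabilities around
  cell means model pooled samples; individual animals are not simulated.
- **No PCR duplicates, chimeras, or CpH methylation.** Sequencing error is
  optional and off by default.
- **Planted CCGGs.** CCGG sites follow a Poisson process at `ccgg_rate`;
  accidental CCGGs arising from the background sequence are scrubbed so
  the realised density matches the configured rate and fragment
  boundaries are exactly known.
- The per-CpG test models binomial counts; under beta-binomial
  overdispersion it is anticonservative. The type-I calibration criterion
  is therefore run under the binomial null; unit_dispersion is the knob
  for robustness studies.

## 4. Numerical choices

- **Closed-form logistic MLE + LRT** instead of iterative GLM fits: with
  one binary covariate the pooled proportions are the exact MLE, making
  20k-site tables vectorisable and removing convergence failure modes.
  Degenerate (separated) tables get +0.5 Haldane–Anscombe smoothing and a
  `corrected` flag; the LR statistic is clamped at 0.
- **Authored BH step-up** (cumulative-minimum over the sorted p-values,
  capped at 1), cross-checked in tests against both the direct step-up
  formula and `statsmodels.stats.multitest`.
- **Quantile normalisation of depths**: complete-case sites only; the
  reference distribution is the mean of per-unit order statistics; ties
  within a unit receive the average reference value of their rank range;
  new methylated counts are `round_half_away(percent/100 × new_depth)`
  so percentages are preserved to within half a count and counts stay
  integral and non-negative. With ties the identical-sorted-depth
  invariant holds only approximately (documented in tests).
- **Wilcoxon signed-rank**: exact p by dynamic programming over doubled
  midranks for n ≤ 25 (ties allowed, zeros dropped); otherwise a normal
  approximation with tie correction and continuity correction, matching
  `scipy.stats.wilcoxon(method="approx", correction=True)` to 1e-9
  (asserted in tests). Authored because scipy's exact mode rejects ties.
- **KS two-sample**: authored D statistic (sup over ECDF differences),
  asymptotic p via scipy.
- **Hypergeometric tail** via `scipy.stats.hypergeom.sf(k−1, …)`;
  cross-checked against direct binomial-coefficient enumeration and
  1e6-draw resampling.
- **Seeding**: every stochastic stage derives an independent
  `numpy.random.SeedSequence([seed, k])` stream, so stages are
  reproducible independently and two runs with the same config are
  byte-identical (checksummed in the manifest and asserted in tests).

## 5. Design decisions

- The synthetic module is the test bed: acceptance-style properties
  (calibration, sensitivity/FDR, estimator recovery, rescue recovery,
  determinism) are all asserted against planted ground truth.
- Two-route checks: authored statistics are verified against independent
  oracles (likelihood grid search, exhaustive sign enumeration, set
  algebra, naive pileup/scan/trim/align implementations) rather than the
  same library call that produced them.
- Loaders for standard formats (FASTA/FASTQ via Biopython, BED/TSV via
  pandas, Bismark-style coverage) allow user-supplied real data to enter
  at any stage; nothing in the analysis depends on the simulator.
- The pipeline writes a manifest with parameter echo, stage summaries,
  negative-control count, and SHA-256 checksums of every output, plus a
  human-readable report.
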