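# Methods

This note documents the statistical models implemented in `panelprofiler`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical and design decisions a
maintainer would want recorded.

## Somatic SNV detection

The caller treats the alt-read count at a site as Binomial(depth,
error_rate) under the null of pure sequencing error and computes the exact
upper-tail probability P(X ≥ alt_reads). The tail is evaluated through the
regularized incomplete beta function (`scipy.stats.binom.sf`), which is
exact to double precision; the test suite verifies agreement with direct
log-space pmf summation to relative error ≤ 1e-10 for all depths up to 500.

The filter cascade and its defaults:

| parameter | default | rationale |
|---|---|---|
| `error_rate` | 0.01 | typical post-dedup per-base error for hybrid-capture panels; configurable, and a per-site rate can be passed by re-running the tail test |
| `alpha_call` | 1e-6 | panel-wide Bonferroni-style control: a ~2 Mb panel tests ~2×10⁶ sites, so 1e-6 keeps the expected false-call count per sample near 2 |
| `min_af` | 0.05 | the assay's stated reporting floor; inclusive (AF = 5% is kept) |
| `min_alt_reads` | 5 | guards low-depth sites where the binomial test alone is unstable |
| strand rule | Fisher p < 0.01 **and** all alt reads on one strand | the named filter is "strand bias" without a stated threshold; requiring complete one-sidedness avoids discarding genuine high-AF variants with mild imbalance |
| `min_base_quality` | Q25 | conventional floor for Illumina substitution calls |
| `max_popfreq` | 0.015 | population-frequency ceiling; *strictly greater* removes, so popfreq = 0.015 is kept. Missing popfreq counts as 0: exclusion requires evidence of commonness |
| `tumor_content_min` | 0.20 | sample-eligibility floor, inclusive |

Pileup records carry the alt-read strand split but not the reference split;
the strand 2×2 table therefore splits reference reads evenly. Because the
rule only fires when one strand has *zero* alt reads, the reference split
has negligible influence on the decision.

The landscape (reporting) filter keeps missense, stopgain, frameshift-indel
and non-frameshift-indel calls with popfreq ≤ 0.015. It is idempotent and
order-preserving. Indels are not discovered from pileups (local realignment
is out of scope); they enter the pipeline as annotated rows of the MAF-like
table.

Coordinates are 1-based, fully closed, VCF-style. All stated thresholds are
inclusive on the keep side (≥ 5% AF keeps, > 0.015 popfreq removes,
≥ 20% tumor content passes, tail p ≤ alpha calls).

## MSI scoring

For locus *i* the MSS baseline provides the cut-point repeat length C_i and
p_i, the cumulative fraction of MSS reads at lengths beyond C_i. A tumor
profile contributes N_i total reads with n_i beyond the cut-point; the
locus is unstable when the exact binomial tail P(X ≥ n_i) under
Binomial(N_i, p_i) is ≤ 0.001 (inclusive). The sample's MSI score is the
unstable fraction of the 30 best-covered loci (largest N_i; ties broken by
ascending locus id; zero-coverage loci excluded before ranking; fewer than
30 covered loci triggers a warning and all are used). Score ≥ 0.4
(inclusive) classifies MSI-H. The score is stored on the fraction scale —
"percentage of unstable loci" with a 0.4 cutoff is only coherent as a
fraction.

"Unstable reads" are those at repeat lengths **strictly greater** than C_i.
The direction is a design choice made explicit here: the locus test only
assumes *some* tail direction, and the generator and scorer agree on it.
Counting both sides of the cut-point is available via `both_sided=True`.
Exact tail summation is used rather than a normal approximation because
N_i can be small and the 0.001 boundary must be decided exactly.

Construction of the MSS baseline panel (how C_i and p_i are estimated from
a normal cohort) is out of scope; baselines are inputs. The bundled default
panel (100 loci, C_i spanning 12–25 repeat units, p_i spanning 0.01–0.05)
is synthetic and exists so the pipeline runs end-to-end.

## TMB

TMB counts missense, silent, stopgain, stoploss, in-frame-indel and
frameshift calls with `is_driver = false`, divided by the examined coding
footprint in Mb. Two wiring rules matter:

* TMB consumes calls **before** the landscape class reduction (silent and
  stoploss count toward TMB but are not reported as landscape alterations)
  and **after** the population-frequency exclusion, which is this
  pipeline's stand-in for germline removal.
* `region_size_mb` has no default anywhere in the core API: a panel's
  coding footprint must be supplied explicitly (the simulator uses 2.2 Mb,
  a realistic footprint for a ~733-gene panel at ~3 kb CDS per gene). The
  driver catalogue is likewise the caller's responsibility: `is_driver` is
  an input annotation.

TMB ≥ 10 mut/Mb (inclusive) is flagged TMB-high, the pan-tumor
immunotherapy cutoff.

## Cohort statistics

* 2×2 proportion contrasts: Pearson chi-square without continuity
  correction, computed as Σ(O−E)²/E with 1 df; if any expected cell is
  below 5, the two-sided Fisher exact test is used instead, and the choice
  is recorded in `test_used`.
* Group means: Welch's t-test by default for two groups (the
  pooled-variance Student t behind `welch=False`), one-way ANOVA beyond
  two. Summaries are mean ± SEM with the n−1 standard deviation.
  Identical two-group samples return t = 0, p = 1 (scipy yields NaN at
  zero variance).
* Multiple testing: Benjamini–Hochberg step-up, emitted alongside raw
  p-values; no correction is silently applied.
* PD-L1 TPS is categorized at < 1 / 1–49 / ≥ 50 (conventional 22C3 bins,
  configurable) and compared across sites by chi-square/Fisher.
* Jejunum and ileum are kept distinct in the data model and merged on
  demand (`merge_jejunum_ileum=True`), since cohort summaries typically
  pool them while site-level analyses may split them.
* Significance is p < 0.05, strict.

## The synthetic-cohort generator

The generator's defaults are the study conditions the analyses are
validated under:

* **Cohort structure** — 298 patients; site probabilities 268:15:15
  (duodenum : jejunum : ileum); 60% male; ages uniform 40–80 (cosmetic
  metadata).
* **Gene alterations** — per-(gene, site) Bernoulli draws. Overall
  frequencies follow the published landscape of the motivating cohort
  (TP53 0.53, KRAS 0.51, APC ≈ 0.31, SMAD4 ≈ 0.19, …) with site effects in
  the reported directions (APC, LRP1B, PIK3CA, POLE, MSH6, MTOR higher in
  jejunum/ileum; SMAD4, CDKN2A, VEGFA, CTNNB1, ERBB2 higher in duodenum).
  Each altered gene yields one variant with AF uniform on [0.10, 0.50],
  marked `is_driver = true`.
* **MSI** — MSI-H prior 0.05 in duodenum and 0.30 in jejunum and ileum.
  Read-length histograms are multinomial draws over integer repeat
  lengths: an MSS locus places exactly p_i mass beyond C_i (so the
  generated tail fraction is unbiased for the quantity the locus test
  uses); an MSI-H sample shifts a per-sample fraction of loci, uniform on
  [0.5, 0.9], to a distribution with 0.35 tail mass. Per-locus coverage is
  Poisson(300).
* **TMB** — background (non-driver) coding mutations per sample are
  Poisson with mean 9 (MSS) or 50 (MSI-H); over 2.2 Mb this yields ≈ 4 vs
  ≈ 23 mut/Mb, i.e. clearly hypermutated MSI-H tumors.
* **Pileups** — depth Poisson(500) in cohort simulation (200 in the
  caller's operating-characteristics experiments); alt reads
  Binomial(depth, AF) at variant sites and Binomial(depth, 0.01) at
  reference sites; strands split Binomial(alt, ½); base quality Gaussian
  around Q32. Each patient also receives ~3 common polymorphisms
  (popfreq uniform on [0.02, 0.5]) so the population-frequency filter has
  real work in end-to-end runs.
* **PD-L1** — 45% TPS = 0, 35% uniform 1–49, 20% uniform 50–100,
  independent of site (no site effect is simulated).

Randomness is counter-based: the global seed expands to per-patient
sub-streams via `SeedSequence(entropy=seed, spawn_key=(i,))`, so enlarging
a cohort never changes patients already generated.

**What passing tests do and do not show.** The generator draws read counts
from exactly the distributions the models assume — binomial errors,
multinomial repeat-length histograms, independent loci and sites. Recovery
results (≥ 95% MSI classification accuracy, ≥ 99% caller sensitivity at
AF ≥ 10%) therefore validate the *implementation* of the models, not their
adequacy on real data, which carries FFPE deamination artifacts, mapping
errors, PCR stutter correlated across loci, GC-dependent coverage and
germline contamination that the generator deliberately omits. Read-level
(FASTQ/BAM) simulation, CNVs and fusions are out of scope.

## Problem sizes in the validation experiments

The bundled experiments use 200 synthetic MSI samples (100 per class) at
100 loci × depth 300; 3 000 variant sites and 50 000 reference-only sites
at depth 200 for the caller; all 135 751 2×2 tables with total ≤ 40 for the
Fisher cross-check; 1 000 null replicates for the Welch/ANOVA type-I
experiments; and a full 298-patient cohort for the end-to-end pipeline run.
These sizes give Monte-Carlo error comfortably below the margins being
tested while keeping the whole suite fast.

## Known limitations

* The binomial error model is global per run; site-specific error rates
  must be handled by the caller of the API.
* No matched-normal subtraction beyond the population-frequency filter.
* Indel discovery, CNV and rearrangement detection are out of scope.
* The MSS baseline panel bundled for simulation is synthetic; real use
  requires locus baselines estimated from a stable-tumor cohort.
* PD-L1 TPS is consumed as a numeric input; the IHC assay itself is out of
  scope, as are survival analyses and co-mutation/mutual-exclusivity
  testing.
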