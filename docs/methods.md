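# Methods

This note documents the models, defaults and design choices behind
`niptpool`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Simulation model

### Truth allele frequencies

Sites are placed uniformly without collision on non-Y chromosomes of a
synthetic genome (variants are never simulated on the Y, mirroring the
exclusion of Y from calling in ultra-low-coverage pooled data). Each site
receives an ancestral alt frequency drawn from a truncated Beta(0.5, 0.5)
on [0.01, 0.99] — a U-shaped site-frequency spectrum with the excess of
low-frequency alleles characteristic of human polymorphism; both shape and
bounds are configurable. Per-population frequencies follow the
Balding–Nichols model: AF ~ Beta(p(1−F)/F, (1−p)(1−F)/F), with mean p and
variance F·p(1−p). F = 0 reproduces the ancestral frequency exactly; F = 1
is rejected as degenerate. This is the minimal standard model that yields
FST-style divergence and PCA-separable populations. Alt alleles are drawn
as transitions with probability R/(1+R) (default R = 2.0, the genome-wide
Ti/Tv expected of true human SNPs) and otherwise as one of the two
transversions uniformly.

### Genotypes and pregnancies

Individuals receive Hardy–Weinberg genotypes: two independent Bernoulli(p)
haplotypes on autosomes and the female X, one on the male X. For each
pregnancy a mother and a father are drawn from the population; the fetus
receives one maternal gamete (a per-site coin flip between the mother's
copies — no recombination map or linkage is modelled) and one paternal
gamete; a male fetus has no paternal X and contributes a variant-free Y.
Fathers are discarded after meiosis. Fetal sex is Bernoulli(p_male = 0.5).

The fetal fraction defaults to a constant 0.084 — the centre of the 8–10%
range typical of maternal plasma — and accepts a constant, a uniform range
or a callable, since the cohort-level distribution of fetal fraction is not
well standardised. Per-sample depth defaults to a constant 0.17×
(configurable the same way).

### Reads

Each sample's target depth fixes its fragment count,
n_pairs = depth × genome / (2 × read_len), with 2 × 75 bp mates. A fragment
originates from one chromosome copy chosen with probability proportional to
length × mixture weight (maternal copies 1−ff, fetal copies ff); its
midpoint is uniform along the copy; its length is Normal(166, 40) truncated
to [read_len+1, 500] — the modal cfDNA plasma fragment is ≈166 bp, so a
substantial fraction of inserts is shorter than 150 bp and mates overlap,
reproducing the per-sample depth-2 positions that motivate the overlap
filter. Covered truth sites emit the copy's haplotype allele; every emitted
base is then substituted to one of the three other bases uniformly with
probability 0.003 (the error rate reported for this kind of data by
alignment QC). MAPQ is 60 everywhere except reads overlapping designated
low-mappability intervals, which receive MAPQ 20 (probability configurable)
— the analysis only ever uses MAPQ as a threshold, so a binary high/low
model suffices. Base-quality strings are constant; PCR duplicates,
indels/CNVs and aneuploidy (the clinical target of NIPT itself) are not
modelled.

### What the generator does not emulate

Real cfDNA has GC and mappability coverage biases, position-dependent error
profiles, correlated errors, linkage disequilibrium, and maternal/fetal
fragment-length differences. Passing tests therefore demonstrate that the
*pipeline logic and estimators* behave as specified under the stated
statistical model, not that the caller is robust to every artefact of real
plasma sequencing.

## Preprocessing

Pooled AF estimation assumes each sample contributes ≤1 allele per
position. Alignments with MAPQ < 30 are discarded first (threshold
inclusive: MAPQ = 30 is kept), then overlapping reads within a sample are
reduced by a greedy sweep: reads sorted by (start, end, read id), a read is
kept iff it starts after the last kept read ends. The sweep is
deterministic, order-independent after sorting, idempotent, and treats
overlapping mates of one pair like any other overlap (the depth-2 positions
arise precisely from overlapping mates). Which overlapping read survives is
not specified by the underlying analyses; the greedy rule was chosen for
reproducibility. Coverage summaries count depth exactly per position,
report per-sample and pooled coverage, mean depth and a depth histogram
with a configurable overflow bin, and can exclude a BED mask from all
numerators and denominators.

## Pooled calling

All filtered reads are pooled; after preprocessing every read at a position
comes from a different sample, so the column depth n equals the number of
distinct samples. For each non-reference base b with count k ≥ 1 the caller
computes the binomial tail p = P(X ≥ k), X ~ Binomial(n, e/3), under the
uniform error model (e/3 per specific alt base), and emits a call when
p ≤ α. This explicit error-vs-signal test replaces the black-box somatic
caller used on real pooled data with a minimal, fully specified model of
the same decision. Defaults and rationale:

* **α = 0.05 / genome length** — Bonferroni over positions; with a 1 Mb toy
  genome α = 5×10⁻⁸, which admits essentially no false calls at ~100×
  pooled depth (verified by the type-I property test).
* **e = 0.003** — matches the simulator's error rate; a configurable
  parameter, not an estimate.
* **min_alt = 3** — calls with fewer alt reads are flagged `weak_evidence`
  (the filter's name is standard; its rule here is a stated stand-in).
* **strand bias** — a call is flagged when the two-sided Fisher exact test
  on [[ref_fwd, ref_rev], [alt_fwd, alt_rev]] gives p < 10⁻³ *and* ≥90% of
  alt reads sit on one strand; the compound condition avoids flagging
  strong balanced signals at high depth.
* **contamination** — no contamination model exists in the simulator, so no
  contamination filter is implemented; the flag name is reserved.
* Multi-allelic sites are tested per alt and written VCF split-style (one
  ALT per line). The AF estimate is k/n; no individual genotypes or
  genotype likelihoods are produced, by design.

## Validation analyses

* **Partition** — sites keyed strictly by (chrom, pos, ref, alt); ordered
  panels with first-match precedence and a terminal `novel` category;
  percentages relative to the query call set. Exact-key matching is the
  strictest choice and cannot inflate overlap.
* **Sensitivity** — common truth sites are those carried by ≥ min_carriers
  (default 2) individuals; sensitivity is the fraction present in the call
  set.
* **AF correlation** — Pearson correlation on the inner join of call-set
  and panel sites (only matched sites enter, with no frequency
  restriction).
* **PCA** — dosage columns centered by 2p̂ and scaled by √(2p̂(1−p̂)) with
  p̂ pooled across all individuals in the combined matrix, monomorphic
  sites dropped; coordinates are SVD projections. Pseudo-individuals are
  simulated from the pooled AF estimates (default 100, a conventional
  panel size) and concatenated with the real-genotype panels before one
  joint PCA, mirroring how a pooled call set without individual genotypes
  is projected with reference populations.
* **Sex-chromosome dosage** — the male data fraction is ff × p_male; the
  predicted Y:genome depth ratio is ff × p_male / 2 (one fetal Y copy
  against two autosomal copies). The empirical ratio is computed on the raw
  pooled reads: the overlap filter thins high-per-sample-depth regions
  (autosomes) slightly more than the nearly empty Y and would bias the
  ratio upward. The simulated ratio sits ~2–3% relative above ff·p_male/2
  because the X carries (2−ff) copies rather than 2, shrinking the
  normaliser; with human-like chromosome shares the effect is well inside
  the acceptance tolerance.
* **Carrier frequency** — 2p(1−p), the Hardy–Weinberg heterozygote
  frequency for a recessive allele.

## Pipeline and reproducibility

Every stochastic operation takes an explicit seed; the pipeline derives
stage seeds from the global seed by fixed counters and per-sample read
seeds by a counter below the cohort seed, so reruns are byte-identical and
changing the seed changes outputs but never schemas. The YAML config
rejects unknown keys and the fully resolved config is written next to the
outputs. Synthetic reference panels are generated with the truth: a
99-individual panel from the cohort's own population (the size of the
smallest real reference panel this design emulates), a second panel from
the diverged population, and a site-only "database" panel holding a random
95% of truth sites.

## Problem sizes used in the test suite

Tests run on three profiles: tiny (3 samples, 10 kb), small (50 samples,
100 kb) and paper_like_scaled (500 samples, 1 Mb at 0.15×, 5000 sites —
pooled depth ~60× after filtering, the same per-sample regime as a real
cohort at ~1/3000 of the genome). The acceptance chrY experiment uses 1000
samples on a 2.5 Mb genome with human-like chromosome shares (X 5%, Y 2%)
so that Monte-Carlo error on the depth ratio is ~0.1 percentage point.
These scales were chosen so the full statistical behaviour (AF recovery
r ≥ 0.95, type-I control, PCA separation) is measurable on one CPU in
minutes.

## Known limitations

* The depth-2 fraction and post-filter depth depend on the empirical insert
  distribution of real cfDNA; the truncated-normal default reproduces the
  phenomenon qualitatively, not numerically.
* The caller's error model is exchangeable across positions and strands;
  no contamination, mapping-bias or overdispersion component.
* Genome scales are ~10³ smaller than a real genome; absolute call counts
  are not comparable to a real cohort, only rates and correlations.
* `n_samples` distinct-sample counting in the pileup defaults to the
  preprocessing contract (n_samples = n) rather than an exact recount;
  an exact mode exists for verification on small data.
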