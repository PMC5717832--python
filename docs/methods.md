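# Methods

This note records the models, parameter choices, and numerical
conventions behind `poolscreen`, and what the simulation-based tests do
and do not establish about real data.

## The screen being modelled

A three-stage pooled targeted-sequencing case–control screen. Stage 1
sequences one sub-cohort (cases and controls) in phenotype-homogeneous
pools of 20; stage 2 an independent sub-cohort in pools of 24. Stage 3
re-sequences a subset of the cases in pools *orthogonal* to the earlier
stages — any stage-3 pool shares at most `max_overlap` (1–2) members
with any stage-1/2 pool — so each carrier of a rare variant is observed
in two different pools and the intersection structure identifies them.
Association is then assessed at the carrier level (2×2 tables) and at
the gene level (rare-allele burden).

## Pooled read-count model

A pool of N individuals holding `c` alt alleles among its `2N`
chromosomes yields alt-supporting reads as

    alt ~ Binomial(depth, p_c),
    p_c = (c/2N)(1−e) + (1−c/2N)(e/3)

where `e` is the per-base miscall probability (default 0.005, contract
range [0, 0.01]). Miscalls are spread evenly over the three
non-reference bases, hence the `e/3` toward the specific alt — the
standard substitution-error convention.

The caller maximises this likelihood over `c ∈ {0..2N}` with a uniform
prior (MAP = MLE). Ties break toward the smaller count, which is
conservative for rare variants. Two confidences are reported:

- `quality` — log10 LR of the best count against `c = 0` (is the
  variant present in this pool at all);
- `margin` — log10 LR of the best count against the runner-up (is the
  *count itself* resolved). At 600× a pool of 20 resolves c=1 vs c=2
  with a boundary near 23 alt reads; a true singleton (mean ≈ 16 alt
  reads) is mis-resolved upward in roughly 2% of pools, which is why
  cross-stage consistency (below) matters.

Defaults: `min_quality = 2.0` (log10 LR) and depth ≥ 10× per pool
member for a call to count. The quality threshold was calibrated on
simulation so that single-pool discovery meets a ≤7% false-negative /
≤3% false-positive envelope at 600× median coverage; at threshold 5 the
singleton FN rate alone exceeds that envelope once per-site depth
dispersion is accounted for, while false positives remain ≈0 at
threshold 2 because a c=0 pool needs ~8 alt reads at 600× (Poisson mean
1) to clear it. Joint cross-pool modelling of the kind dedicated pooled
callers perform is intentionally out of scope; the per-pool MAP count
is the quantity all downstream stages consume.

Cohort allele counts sum per-pool MAP counts over depth-passing pools,
with nonzero counts contributing only when their quality clears the
threshold — otherwise sub-threshold noise in the ~185 negative pools
would inflate singleton counts into doubletons about 10% of the time.
AN sums the chromosomes of depth-passing pools; AF = AC/AN.

## Synthetic cohort

- **Phenotypes.** Configured numbers of cases and controls; a fixed
  fraction of cases (default 1346/4016) is early onset, with ages drawn
  uniformly on [12, 39.9) years (early) and [40, 75] (late); controls
  carry no age at diagnosis. Diagnosis at exactly 40 counts as late.
- **Site-frequency spectrum.** True AFs follow a truncated power law
  `f(x) ∝ x^−1.87` on [1e−5, 0.01], mixed with probability 0.04 with a
  log-uniform "common" component on [0.001, 0.05]. These defaults were
  calibrated once, by simulation, so that a ~3720-individual cohort
  discovers variants of which ~54% are singletons and ~81% sit at
  cohort AF ≤ 0.001 — the spectrum a rare-variant targeted screen
  observes — and then frozen. A pure power law cannot hit both numbers
  (pushing singletons to 54% starves the 0.001–0.01 band), hence the
  mixture.
- **Genotypes.** Neutral sites: Binomial(2, AF) per individual.
  Pathogenic sites: carrier probabilities (q₀, q₁) for controls/cases
  are solved (Brent's method) so that the carrier odds ratio equals the
  configured effect size exactly while the mixture carrier frequency
  matches Hardy–Weinberg at the site's AF; carriers are heterozygous
  unless the Hardy–Weinberg conditional says homozygous. This is the
  retrospective-sampling equivalent of a calibrated logistic penetrance
  (the screen itself is observational; no generative model is implied).
- **Coverage.** Each pool draws a median depth uniformly from
  [600, 970]× (the per-base medians typical of such captures); per-site
  depth is the median times a Gamma(shape 10, mean 1) multiplier. The
  default ~25 kb synthetic target (17 genes × 10 exons × 150 bp) flags
  7 exons, spread over distinct genes, as hard to capture; their depth
  is scaled by 0.05, emulating the handful of GC-rich exons real
  captures under-sequence. These exons dominate the simulated
  false-negative rate, as low coverage does in real screens.

What the generator does **not** emulate: read-level artefacts (FASTQ,
alignment, duplicates), indel-specific error processes, capture bias
beyond the low-coverage-exon scalar, linkage between sites, and
relatedness. Passing tests therefore demonstrate the pipeline's
statistical machinery under its stated error model, not robustness to
alignment or library artefacts.

## Pool design

Stratified pools shuffle each stratum under the seed (after canonical
sorting, so input order is irrelevant) and chunk; a stratum of size not
divisible by the pool size leaves one short final pool, with a warning.
The orthogonal construction groups the re-sequenced subset by base
pool, deals largest groups first into the most-open new pool subject to
a per-base-pool quota of `max_overlap`, and backtracks (bounded at 10⁴
steps, ≤5 seeded restarts) on dead ends; infeasibility by pigeonhole
(one base pool contributing more than `max_overlap ×` the number of new
pools) is reported naming the blocking pool. Every returned design is
re-verified with the overlap checker rather than trusted. Orthogonal
pools come out balanced (sizes within one of each other) because the
greedy fills the most open pool; ragged sizes are recorded per pool and
used downstream, never assumed global. Stage-3 stratum purity is
optional (off by default), since validation pools need not be
phenotype-homogeneous.

## Carrier decoding

"Parsimonious" is operationalised as: minimise the number of carrier
individuals, then the total allele count. The search is exact
(depth-first over the union of positive-pool members with residual
feasibility and objective bounds) and returns *all* minimal
assignments; a homozygous single carrier therefore beats two
heterozygotes where both fit, and genuine ties surface as `ambiguous`
rather than being silently resolved. Confidently negative pools (depth
≥ 10×/individual, count 0) exclude their members outright; low-coverage
negative pools impose no constraint, mirroring how real screens explain
count discrepancies by missing coverage.

Cross-stage consistency treats each stage-1/2 positive pool with count
`c` over members `M` as contributing between `max(0, c − 2|M∖S|)` and
`min(c, 2|M∩S|)` alleles to the re-sequenced subset `S`; the observed
stage-3 total must land in the summed interval. Outside it, the verdict
is `discrepant` unless a relevant pool had low coverage
(`unresolvable`). Carrier identification is meaningful for
consistency-passing variants — in end-to-end simulation, true
singletons detected in both stages with consistent counts decode
uniquely and correctly >95% of the time, and the dominant failure mode
(a one-step upward count mis-resolution in one stage) is exactly what
the consistency check intercepts.

## Classification and tallies

Consequence strings map to synonymous / missense-group (missense plus
in-frame indels) / PTV (nonsense, canonical splice, frameshift);
unrecognised consequences return `unclassified`, never a silent drop.
Rarity filters use strict inequality (AF 0.002 is *excluded* at the
0.2% threshold) and treat missing population AF as unobserved (kept),
matching absent-from-database entries. The candidate-deleterious filter
is the conjunction PolyPhen2 ≠ benign ∧ SIFT deleterious ∧ population
MAF < 0.05%; the expected side condition (MutationTaster
disease-causing, scaled CADD > 20) is verified and violations reported
for review rather than acted on. Carrier tallies count distinct
individuals (an individual with two registry variants counts once),
split early/late by the age-40 cutoff. ACMG 5-tier labels are input
data: re-deriving the 28 ACMG criteria is out of scope, and the
packaged registry fixtures store the published classifications
verbatim.

## Association statistics

Carrier 2×2 tables use unexposed = group size − carriers. The odds
ratio is the sample cross-product ad/bc; the CI is Woolf's
`exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`, which reproduces the published
interval for the screen's headline table from its printed counts
(Haldane +0.5 on all cells when any cell is zero, flagged); the p-value
is the two-sided Fisher exact test (point-probability method, matching
full hypergeometric enumeration).

The gene burden test aggregates rare (MAF < 0.2%) missense-group
allele counts per pool and compares rare-allele rates per chromosome
between case and control pools. Because the pool — not the individual —
is the unit of library preparation and sequencing, the pool label is
the exchangeable unit: significance is a one-sided permutation tail
over label reassignments (stratified by stage when both stages are
present), with p = (r+1)/(n_perm+1). The exact form of burden tests
differs between screens; this pool-permutation rate statistic is this
package's declared operationalisation. Permutation p-values are
conservative under ties, which matters when all pools are the same
size (the statistic then depends only on the case allele count);
calibration simulations therefore use mixed pool sizes, as any
two-stage screen naturally has. Bonferroni-corrected p-values can be
derived from the per-gene outputs; the pipeline reports nominal values.

## Reproducibility and problem sizes

All randomness descends from explicit seeds via `numpy` seed
sequences; no global state. Pipeline runs write a manifest of seeds and
SHA-256 output hashes, and a rerun with the same configuration is
bit-identical. Simulation-based tests use deliberately reduced problem
sizes chosen to keep the suite quick while leaving comfortable
statistical margins: 20 replicate pools (~50 true variants each) for
caller fidelity, a 480-individual cohort over three seeds (~250
consistency-passing singletons) for end-to-end decoding, 1000 null
genes × 999 permutations for burden calibration, and 10⁴ simulated
tables for CI coverage. The acceptance script
(`scripts/acceptance.py --seed N --out results/acceptance.json`)
recomputes the pooled-caller false-negative rate at the screen's
single-pool validation conditions and writes it as JSON.

## Known limitations

- The binomial caller ignores cross-pool information; its count
  resolution at 30× per chromosome is the limiting factor for carrier
  decoding, mitigated by (not solved by) cross-stage consistency.
- Decoding is combinatorial, not probabilistic: count uncertainty is
  handled by hard confident/unconfident thresholds rather than
  likelihood-weighted solutions.
- The generator's effect model ties case status to single sites
  independently; no polygenic background, no gene–gene structure.
- Indels share the SNV error model; real frameshift calling has its own
  error processes.
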