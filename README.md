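# poolscreen

Tools for designing and analysing **pooled DNA sequencing case–control
screens**, of the kind used to hunt for rare monogenic-diabetes (MODY)
mutations in thousands of individuals: DNA from 20–24 individuals is
sequenced as a single library, genotypes are observed only as per-pool
allele counts, and rare-variant carriers are pinned down by re-pooling
the same individuals *orthogonally* and intersecting the
variant-positive pools (combinatorial group testing).

The package covers the full computational arc of such a screen:

- **Pool design** — phenotype-homogeneous pools (stage 1: pools of 20;
  stage 2: pools of 24), and orthogonal stage-3 validation pools in
  which any new/old pool pair shares at most 1–2 individuals, built by a
  quota-constrained greedy with backtracking and certified by an
  overlap verifier.
- **Pooled allele-count calling** — with `c` alt alleles among the
  pool's `2N` chromosomes and per-base miscall rate `e`, alt reads are
  `Binomial(depth, p_c)` with `p_c = (c/2N)(1−e) + (1−c/2N)·e/3`; the
  caller reports the maximum-likelihood count, a log10 likelihood-ratio
  quality against `c = 0`, and a count-resolution margin, plus coverage
  QC (fraction of bases at ≥10× per individual, flagged low-coverage
  exons).
- **Carrier decoding** — exact branch-and-bound search for all
  *parsimonious* carrier assignments (fewest carriers, then fewest
  alleles) explaining every variant-positive pool and contradicting no
  confidently-negative pool, with cross-stage expected-vs-observed
  consistency checks and partial-attribute summaries (e.g. the age at
  diagnosis of an as-yet-ambiguous carrier).
- **Variant classification** — protein-truncating vs missense-group
  consequences, strict rarity filters (MAF < 0.2% for burden tests,
  < 0.05% for candidate-deleterious flagging), in-silico prediction
  conjunctions, and distinct-carrier tallies by onset subgroup
  (early onset = diagnosed before age 40). Registry fixtures transcribe
  published MODY mutation tables (PTVs, GCK missense, and previously
  reported pathogenic missense variants).
- **Association statistics** — sample odds ratio, Woolf CI, two-sided
  Fisher exact test on carrier 2×2 tables; a one-sided pool-label
  permutation burden test on rare-allele rates per chromosome, with
  stage-stratified permutation.
- **Synthetic cohort generator** — singleton-dominated rare-variant
  site-frequency spectrum (a truncated power law mixed with a small
  common-variant component), pathogenic sites with configurable carrier
  odds ratios, and a per-pool Gamma-dispersed coverage model with
  hard-to-capture exons, so the entire pipeline runs and is tested with
  no external data.

## Worked example

The headline carrier-level statistic of such a screen — 26 of 4016
cases versus 3 of 2872 controls carrying a previously reported
pathogenic missense mutation — from the command line:

```console
$ poolscreen associate --table 26 3990 3 2869
OR=6.23 CI=(1.9, 20.6) P=0.00044
```

i.e. carriers are 6.2× over-represented in cases (Woolf 95% CI
1.9–20.6), and the two-sided Fisher exact test puts the null of equal
carrier odds at P ≈ 4×10⁻⁴.

Decoding a singleton carrier from the Python API — a variant seen once
in stage-1 pool `P7` and once in orthogonal stage-3 pool `Q3` is forced
onto their single shared member:

```python
>>> from poolscreen import decode_carriers
>>> membership = {"P7": ["i01", "i02", "i42"], "Q3": ["i42", "i77", "i90"]}
>>> sol = decode_carriers({"P7": 1, "Q3": 1}, membership)
>>> sol.status, sol.solutions
('unique', [{'i42': 1}])
```

A full simulated screen (cohort → pools → read counts → calls → carrier
decoding → tallies → association), written as TSV/VCF artifacts with a
hash manifest so reruns are bit-identical:

```bash
poolscreen run-all --small --seed 3 --out out/
```

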