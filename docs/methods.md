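# Methods

This package implements a genome-resolved analysis of gut-microbiome change
after fecal microbiota transplantation (FMT): (i) compositional convergence
of recipient taxon profiles toward the donor, (ii) a balance-dendrogram
model of community succession, and (iii) an engraftment caller that decides,
per donor genome bin (MAG) and recipient, whether a donor strain colonised
the recipient — evidenced by marker-protein identity, average nucleotide
identity (ANI) and breadth-of-coverage detection over the sampling time
course, with SNV major-allele distances as confirmation. Every stage runs on
synthetic data with planted ground truth; this note records the models,
parameter choices and their limits.

## Compositional analysis

Taxon count tables carry only relative information, so all geometry is
Aitchison: a sample composition `x` (strictly positive, closed to 1) is
mapped by the centred log-ratio transform `clr(x)_i = ln(x_i / g(x))`
(`g` = geometric mean) and compared by the Euclidean norm of clr
differences (the Aitchison distance). Before transformation:

* **Rare-taxon filter** — keep taxa reaching relative abundance
  `min_prop` (default 0.001) in at least `min_samples` (default 2) samples.
  The thresholds are conventional, not estimated, and are configurable.
* **Zero replacement** — Bayesian-multiplicative: a zero cell in a sample
  with total count `N` over `D` parts becomes the posterior expectation
  `s/(N + s·D)` under a uniform Dirichlet prior of strength `s` per part
  (default `s = 0.5`); non-zero cells are rescaled multiplicatively, which
  provably preserves all ratios among originally observed parts.

**Total (metric) variance** is the mean squared Aitchison distance to the
clr-mean composition. The divisor is `n` (not `n−1`), chosen for
consistency with the per-balance variances below; the two-point closed form
under this convention is `d²/4`.

Ordination for trajectory figures uses non-metric MDS on the Aitchison
distance matrix. The original analysis used a robust-PCA ordination
(DEICODE); we deliberately compute classical Aitchison distance after zero
replacement instead, because the target quantity here is the monotone decay
of distance-to-donor, not ordination loadings.

## Balance dendrogram

A sequential binary partition (SBP) of `D` taxa is a hierarchy of `D−1`
binary splits; each split with numerator group `R` (size `r`) and
denominator group `S` (size `s`) defines the ilr balance

```
b = sqrt(rs/(r+s)) · ln( g(x_R) / g(x_S) ).
```

The full balance set is an orthonormal (isometric) coordinate system, so
the total variance decomposes exactly into per-balance variances — the
vertical bars of a CoDa dendrogram — and per-group (per-day) mean balances
describe succession.

How the partition is built is genuinely open; we construct it from the data
by Ward agglomeration on the log-ratio variation matrix
`t_ij = var(ln(x_i/x_j))`, so taxa that covary proportionally merge first
and the top splits separate the groups that move most relative to each
other. Determinism: merge-cost ties break by the lexicographically smallest
involved part label, and each node's `R` is the child containing the
smallest label. The implementation is a direct Lance–Williams recursion
(the part count is small), which keeps the tie-break and sign conventions
explicit.

## Strain identity

* **Quality gate** — completeness > 70%, contamination < 10%, length
  > 2,000,000 bp, all strict. Synthetic genomes are desk-scale stand-ins
  (default 50 kb), so synthetic runs scale the length gate proportionally;
  the published thresholds remain the defaults.
* **Marker identity** — up to 43 universal single-copy marker proteins per
  MAG are compared by global (Needleman–Wunsch) alignment; per-marker
  identity is matches / alignment columns, and the aggregate pools matches
  and columns over shared markers, so aggregate 1.0 requires every shared
  marker to align without mismatch or gap. Pairs sharing no markers are
  reported as incomparable, never as identity 0. MAGs are clustered by
  single linkage at aggregate identity ≥ 1.0 (configurable).
* **ANI** — orthologous-fragment style: genomes are cut into consecutive
  1020 bp fragments (per-contig remainders discarded), candidate partners
  are seeded by shared 15-mers, the best partner per fragment is chosen by
  global alignment identity, and only reciprocal best pairs whose alignment
  covers ≥ 35% of the fragment enter the mean (× 100 → percent). Fragment
  alignment uses edlib's global aligner (banded Myers bit-vector); identity
  is counted from the extended CIGAR. Pairs with no reciprocal fragments
  are a distinguished "no signal" outcome. Planted-rate tests bound the
  estimator's bias at ≤ 0.01 ANI points for substitution-only divergence.
* **Same-strain threshold** — ANI ≥ 99.90, boundary inclusive: the
  published exclusion criterion puts "< 99.90%" on the failing side. The
  threshold is configurable.

## Engraftment decision

Per (donor MAG, recipient), first match wins:

1. `no_marker_match` — no recipient MAG co-clusters at 100% aggregate
   marker identity;
2. `excluded_low_ani` — the best co-clustered recipient MAG (highest ANI)
   fails the strain threshold;
3. `excluded_pre_fmt_presence` — the donor MAG is already detected in the
   recipient before the transplant, so donor origin is uncertain;
4. `engrafted` — detection reaches `presence_threshold` in ≥ 1
   post-transplant sample;
5. `no_coverage_support` otherwise.

**Detection** is the fraction of the MAG's nucleotides covered ≥ 1×,
aggregated over contigs by length. `presence_threshold` defaults to 0.25, a
widely used heuristic for "present" with this metric (no cutoff is
published); the calls in the planted test regime are insensitive to it over
a broad range because planted detections are ≈ 0 or ≈ 1. Exclusion rule 3
is stated ambiguously in prose ("covered by reads after FMT" with a
donor-origin rationale); we implement pre-FMT presence as the intended
meaning and expose `exclude_on_pre_fmt=False` to flip the convention.

**Major-allele distance** between two samples' SNV profiles is the fraction
of shared positions — with depth ≥ `min_depth` (default 5, metaSNV-like
practice) in both samples — where the most frequent allele differs; ties
break by fixed allele order A<C<G<T; positions failing depth are excluded
from numerator and denominator, and zero qualifying positions is a
distinguished incomparable outcome.

## Synthetic cohort

The generator plants the structure each stage is supposed to recover; the
defaults are the study conditions for all tests.

* **Abundance time series** — per recipient, the expected clr vector at
  post-FMT day `t` is `(1−w_t)·baseline + w_t·donor` with
  `w_t = 1−exp(−λt)` (default λ = 0.05/day, so half-convergence by ~2
  weeks); pre-FMT samples sit at baseline. Baseline and donor clr vectors
  are standard normal (typical inter-individual Aitchison distances ≈ 10
  at 50 taxa), isotropic clr noise has SD 0.3 (keeps distances analytically
  predictable), and counts are multinomial at 10⁵ reads/sample. Exponential
  approach along the clr geodesic is the simplest dynamic consistent with a
  monotone shift toward the donor; no dynamic model is published.
* **Genomes** — 20 donor strains (10 shared, 10 distinct) × 3 recipients,
  50 kb each, 43 marker proteins of 100 aa at fixed non-overlapping offsets
  at the genome start (determinism and easy truth bookkeeping). Marker
  codons are four-fold degenerate at the third position, so shared-strain
  mutations (rate `(100−99.95)/100`, snapped to third positions inside
  markers) are synonymous by construction and marker proteins stay
  identical, while distinct-strain mutations (rate `(100−99.0)/100`,
  unrestricted) diverge the markers too. The planted ANI values straddle
  the 99.90 threshold by ≥ 5 estimator SDs at 50 kb.
* **Coverage** — present strains get per-position Poisson(depth) coverage
  (default 10×), absent strains all zeros; expected detection is the
  Poisson zero-class complement `1−e^(−depth)`.
* **SNV profiles** — paired allele-count tables whose major alleles differ
  at exactly `⌊q·n⌋` positions; the time-series variant decays `q` as
  `q₀·exp(−λ·day)` with nested disagreement sets, so planted distances are
  exact.

What the generator does **not** emulate: read-level errors, assembly
chimeras and contamination, strain mixtures within a sample, indels and
rearrangements between strain pairs, compositional count overdispersion
beyond multinomial, and donor-independent expansion of recipient strains.
Passing tests therefore demonstrate correctness of the inference machinery
under its stated model, not robustness to those real-data artefacts — the
false-negative modes the original analysis itself reports (chimeric bins,
incomplete assemblies) are out of reach of this generator by design.

## Numerical choices and degenerate inputs

Problem sizes in tests and the acceptance script are chosen for single-CPU
desk-scale runs: 2 Mb genome pairs for ANI recovery, 1 Mb contigs for the
detection closed form, 50 kb cohort genomes, 100 replicate seeds for the
Monte-Carlo claims. All randomness flows through `numpy` Generators seeded
from explicit configuration; identical config + seed reproduces outputs
byte-identically (manifest checksums). Degenerate cases are explicit
errors: all-zero samples (zero replacement), < 2 compositions (variance),
filtering away every taxon, missing detection days, missing quality
metrics, genomes shorter than one ANI fragment. Ties everywhere break by
fixed lexicographic or allele order, never by hash or insertion order.
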