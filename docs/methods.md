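# Methods

`finescale` quantifies fine-scale beta diversity among replicate amplicon
samples — seemingly identical samples taken millimetres apart — and asks how
much of the between-sample variation is carried by the rare biosphere, and
how much of it could be explained away by incomplete sampling.  This note
documents the models, estimators, and design choices, and what the synthetic
benchmarks do and do not demonstrate.

## Read quality control (`read_qc`)

Five filters are applied to each read in a fixed order so that per-filter
attrition is deterministic under first-failure attribution:

1. mean Phred quality ≥ 25 (arithmetic mean over all bases of the raw read);
2. exact forward-primer match at position 0 (zero mismatches, no IUPAC
   expansion — the 16S 27F primer is unambiguous as printed);
3. no ambiguous base (N);
4. no homopolymer run longer than 8 bases;
5. length ≥ 80 bp.

Conventions differ on whether the length minimum applies before or after
primer trimming; both are supported (`length_after_trim`, default: after,
i.e. on the biological insert).  The reverse primer is not searched for:
single-ended pyrosequencing-style reads start at the forward adaptor and no
trimming beyond the forward primer is performed.  Retained reads are emitted
primer-trimmed, in input order.

## Count tables and taxonomy (`otu_io`)

The canonical container is an OTU-by-sample integer matrix with validated
invariants (unique ids, non-negative counts, no all-zero rows).  The mothur
"shared" dialect (sample-rows) is transposed at the I/O boundary so every
downstream module sees one orientation.  OTU ids are opaque strings; tables
compared against each other must come from a joint clustering — the package
does not attempt to reconcile independently clustered label spaces.  Phylum
binning uses the taxonomy table's stored percent identity with a conservative
85% floor below which an OTU is pooled as "unclassified".

## Similarity indices (`beta_indices`)

For presence pairs (a = shared OTUs, b and c = unique to either sample):
Jaccard J = a/(a+b+c), Sorensen = 2a/(2a+b+c), Ochiai = a/√((a+b)(a+c)),
Anderberg = a/(a+2(b+c)).  The Anderberg form is chosen because it is the
form algebraically consistent with the companion identities
S = 2J/(1+J) and A = J/(2−J) that tie the three set-overlap indices
together; these identities are enforced as test invariants.

Quantitative indices on columns x, y with totals n, m:

* Bray-Curtis similarity 2·Σ min(xᵢ,yᵢ)/(n+m) on raw counts (the common
  count-level convention; relative-abundance inputs give the same value
  when depths are equal).
* Chao abundance-based Jaccard UV/(U+V−UV) and Sorensen 2UV/(U+V), where
  U, V are the estimated total relative abundances of shared OTUs with the
  Chao bias correction: Û = Σ_shared xᵢ/n + ((m−1)/m)·(f₊₁/2f₊₂)·Σ_{shared, yᵢ=1} xᵢ/n,
  with f₊₁/f₊₂ the shared OTUs that are singletons/doubletons in the other
  sample and the standard continuity substitution f₊₂ ← 1 when zero.  The
  raw (uncorrected) estimator is available via a flag; at two printed
  decimals the two are rarely distinguishable.
* Smith's theta: the plug-in estimator Σpq/(Σp²+Σq²−Σpq) on relative
  abundances.
* Yue–Clayton theta: the same estimand with unbiased moment estimators
  Σ̂p² = Σxᵢ(xᵢ−1)/(n(n−1)), Σ̂pq = Σxᵢyᵢ/(nm).  The debiased denominator
  can undershoot the numerator (or go non-positive) on sparse columns —
  e.g. two identical all-singleton columns — in which case the estimand is
  at its ceiling and the index is reported as 1.  All indices are clamped
  to [0, 1]; they are symmetric, equal 1 on identical columns and 0 on
  disjoint supports (Ochiai and the thetas by convention).

Treating the two thetas as estimator-level rather than estimand-level
variants reflects that they converge to each other as depth grows, which is
tested by scaling counts.

### Venn accounting

`venn_summary` partitions OTUs by their exact sample-occupancy subset and
reports inclusive shared percentages: an OTU shared by a given pair counts
toward that pair regardless of additional occupancy.  Two denominator
conventions are provided because published summaries mix them: per-subset
(shared OTUs of the x samples / distinct OTUs observed in those x samples;
a sample's own richness for its unshared class) and global (denominator =
distinct OTUs across all samples considered).  A clone-weighted variant
repeats the accounting over read counts.

## Rarity and the NUNN/UNN/UN sub-classification (`rarity`)

Rarity cutoffs are counts (n = 1, n ≤ 2, n ≤ 5, n ≤ 10) or proportions
(a ≤ 0.004%); abundance uses strict complements (n > 10, a > 1%).  A
proportion p converts to the count cutoff ⌊p·N⌋ for an N-read sample, so a
0.004% cutoff means n ≤ 3 at ~77k reads and n ≤ 2 at ~52k reads.  The n ≤ 10
/ n > 10 pair partitions every observed OTU.

Rare OTUs (pooled at n ≤ 5 by default) are classified by a two-stage rule:

* **NUNN** (non-unique, non-novel): best hit against the abundant
  representative set has identity strictly > 85% over ≥ 100 aligned columns;
* **UNN** (unique, non-novel): otherwise, best reference identity > 85%;
* **UN** (unique, novel): neither.

Identity comes from exact Smith–Waterman local alignment with match +1,
mismatch −1, gap open −2, gap extension −1.  Because multiple alignments can
attain the optimal score, the implementation canonicalizes: among
optimal-score alignments it maximizes matched columns, then minimizes total
columns, and reports identity = matches/columns × 100.  This favors
full-length alignments between genuinely homologous sequences (the relevant
case for the > 85%/≥ 100 bp gate) and makes the computation exactly
reproducible and testable against an independent dynamic-programming oracle.
Internally the three objectives are packed into one additive 64-bit integer
per alignment column, which caps supported sequence length at 1,000 bp —
ample for 16S variable-region amplicons.  The aligner is exact and therefore
desk-scale (~4 ms per 250-bp pair); for large studies a precomputed tabular
hit file (e.g. BLAST output or classifier identities) can be supplied via
`reference_identity`, and those values are used as-is.

The reference (UNN) gate applies the same ≥ 100 bp alignment-length
requirement as the NUNN gate when a reference FASTA is aligned directly:
short spurious local hits between unrelated sequences routinely exceed 85%
identity over 10–30 bp, and without the length gate the UN category would be
empty by artifact.  Precomputed classifier identities bypass alignment and
carry no length gate.

Classification operates on OTU representatives and weights categories by
reads; per-read classification inside a heterogeneous OTU could differ, a
known approximation.

## Richness model and the shared-singleton null (`richness_null`)

Counts follow a mixed Poisson whose rate distribution is a two-component
exponential mixture; integrating gives the geometric mixture
P(k) = w·g(k;μ₁) + (1−w)·g(k;μ₂), g(k;μ) = (1/(1+μ))(μ/(1+μ))^k.
Parameters maximize the zero-truncated multinomial likelihood of
f(1),…,f(τ) with counts above τ pooled into a tail category, on transformed
parameters (logit w, log μ) via L-BFGS-B from 10 deterministic starts
(likelihood tolerance 10⁻⁸).  Degenerate fits (w at a boundary or μ₁ ≈ μ₂)
fall back to a single zero-truncated geometric with a warning.  The
truncation point is scanned over {10, 25, 50, 100, k_max} and the highest τ
with goodness-of-fit p ≥ 0.05 is kept (best p as fallback); goodness of fit
is a chi-square on expected-vs-observed frequencies with bins pooled from
the right to expected counts ≥ 5.  Total richness is
Ŝ = D_τ/(1−P(0)) + n_{>τ} and a delta-method standard error is derived from
the observed information.

The expected-singleton pool defaults to **N_pool = Ŝ − (D − f₁)** — the
estimated number of species not yet observed at least twice (undetected
species plus observed singletons).  This is the only simple identity
consistent with a pool of 38,834 for a sample with D = 18,265 observed OTUs,
f₁ = 12,140 singletons and Ŝ ≈ 44,959.  The alternative reading, the model's
expected singleton count Ŝ·P(X=1), is available via `definition="model_f1"`.

The sharing null draws, independently for each of R replicates, n tokens
with replacement from a pool of N species; the per-replicate detection
probability is p = 1 − (1 − 1/N)ⁿ and E[species in exactly k of R] =
N·C(R,k)·pᵏ(1−p)^{R−k}.  Percentages follow either denominator convention.
A literal Monte Carlo mode performs the draws and must agree with the closed
form within Monte Carlo error (a standing test).  An alternative semantics —
drawing n *distinct* species per replicate (p = n/N) — is available via
`replacement=False`.  Whether published predicted percentages used the
closed form or simulation is unknowable from outside; the two agree within
simulation error, so the distinction is immaterial.

Observed and predicted occupancy-class percentages are compared by
two-sample Student t-tests per class; classes with a single data point on
either side are reported without a test.

## Resampling tests (`resample_tests`)

**Subsampling** treats reads as exchangeable OTU-labeled tokens:
a subsample is a multivariate hypergeometric draw (without replacement
within the subsample) from the sample's count vector.

**Spatial-separation test.**  Three subsamples of one source sample are
compared against one subsample from each of three other samples; per-class
shared/unshared percentages (global denominator within each 3-subsample
group) are compared by Student t-tests with the data-point bookkeeping of
the replicate design: 3 pairs for the shared-by-2 class, 3 subsamples for
the unshared class, one point (no test) for shared-by-3.  The three
within-source subsamples are drawn **jointly without replacement** (disjoint
reads) by default.  This choice is load-bearing: independent (overlapping)
within-source subsamples share their source's single realized OTU pool and
are therefore systematically more similar to each other than three
subsamples of independent replicate samples *even when no spatial structure
exists*.  At the reduced benchmark scale that bias is about −3.9 percentage
points on the unshared class and drives the t-test to reject a true null in
~90% of runs, whereas the disjoint partition is unbiased (+0.1 pp, observed
type-I ≈ 0 at nominal 0.05, i.e. mildly conservative due to the negative
token-level correlation).  Independent draws remain available via
`joint_partition=False`.  The default subsample size in the pipeline is
capped at a third of the source sample so the partition exists.

**G test.**  Likelihood-ratio chi-squared G = 2·Σ O·ln(O/E) on a
phylum-by-sample table, zero cells contributing zero (x ln x → 0), empty
rows/columns dropped with a warning; df = (rows−1)(cols−1), compared to the
upper-α chi-square quantile (α = 0.008 for a Bonferroni-corrected family of
six pairwise comparisons at 0.05; the corresponding critical value at
df = 177 is 225.5).

**Rarefaction** resamples without replacement at a depth grid and averages
observed richness; the exact hypergeometric expectation
Σᵢ [1 − C(N−nᵢ, d)/C(N, d)] serves as the test oracle.

**Ordination regression.**  `embedding_r2` regresses pairwise Euclidean
distances of externally supplied 2-D ordination coordinates on pairwise
similarities (OLS; r² = squared Pearson correlation).  The NMDS optimization
itself is deliberately out of scope — any standard implementation can
produce the coordinates — which keeps the module testable without an
optimizer.

## Synthetic data (`synthetic_data`)

`generate_community` draws metacommunity abundances from the same
two-exponential mixture the richness module fits (w = 0.7, μ₁ = 0.5,
μ₂ = 50 by default; a lognormal alternative exercises misspecification),
designates the top `core_fraction` (2%) of species as a shared abundant
core, and rebuilds the rare tail independently per replicate: each non-core
species is replaced by a replicate-private species of equal abundance with
probability ρ (default 0.8).  Reads are multinomial per replicate.  The
study-scale preset uses S = 45,000 and the four observed study depths
(77,361 / 86,240 / 76,693 / 51,836 reads); the reduced preset used
throughout the test suite is S = 2,000 at 5,000 reads per replicate, and the
spatial-test benchmarks subsample 1,650 of those 5,000 reads (~the 28,000 /
86,240 ratio of the study design).  Richness-recovery benchmarks simulate
from the count law directly (Poisson counts on exponential-mixture rates)
with w = 0.7, μ₁ = 0.5, μ₂ = 7.0, giving ≈ 4,900 expected reads over
S = 2,000 species.

Independent per-species replacement is the simplest mechanism that produces
rare-driven beta diversity against a conserved abundant core; it is not a
spatial field, carries no phylogenetic signal, no sequencing error model
beyond the planted QC defects, no chimeras, and no abundance correlation
between a replaced species and its replacement beyond equal abundance.
Passing the synthetic benchmarks therefore demonstrates correctness of the
estimators and calibration of the tests under the assumed sampling laws —
not robustness to real-data artifacts such as PCR bias or clustering error.

`generate_sequences` plants NUNN children as mutated copies of abundant
representatives, UNN children as mutated copies of reference-only parents,
and UN members as unrelated random sequences; achieved identities are
verified internally to land within 2 points of the targets (default 95%,
ten points above the 85% gate, so recovery is unambiguous).
`generate_reads_with_quality` plants at most one QC defect per read so each
filter's expected attrition is a known binomial.

## Numerical conventions and degenerate inputs

* Strict ">" at the 85% identity gates, consistently for NUNN and UNN.
* Abundant-hit ties broken by higher identity, then longer alignment, then
  lexicographic subject id; OTUs iterated in sorted order.
* Empty read → length failure; quality/sequence length mismatch → input
  error; empty QC batch → retention defined as 1.
* U + V = 0 → abundance-based indices 0; empty sample → Ochiai undefined
  (error); constant similarity vector → r² undefined (error).
* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds reproduce byte-identical outputs end to end.

## Known limitations

* The pipeline requires jointly clustered OTU labels; it does not align or
  re-cluster sequences across tables.
* The exact aligner is quadratic per pair; large rare pools should supply
  precomputed identities.
* Ŝ from the truncated fit slightly undercounts when both P(0) and the
  above-τ tail mass are large simultaneously (the pooled-tail species are
  added back as observed, not inflated); at the benchmark scales the
  recovery error is within ±15%.
* The unshared/shared t-tests inherit the small-n (3 points per side)
  fragility of the replicate design; the calibration benchmark covers the
  null, not heavy-tailed alternatives.
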