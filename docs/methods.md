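# Methods

## Scope and data model

`coexrif` analyses a gene × sample expression matrix (assumed normalized, on
a log-intensity scale) split into two conditions with at least three samples
each. All statistics consume only per-condition Pearson correlations and
per-condition mean expression, so the package is agnostic to the platform
that produced the matrix. Condition names are mapped to the codes {1, 2} in
lexicographic order (overridable), which fixes the orientation of the one
asymmetric statistic, RIF.

Duplicate gene rows are collapsed by averaging at load time: averaging is
order-independent and makes no assumption about which probe is "best".
Identifier aliasing and probe annotation are out of scope; gene ids are
compared case-sensitively.

## Differential coexpression

Within each condition we compute the full Pearson correlation matrix.
Zero-variance genes get correlation 0 (with a warning) rather than NaN so
that downstream sums stay finite; their diagonal stays 1.

**Link filter.** A link (unordered gene pair) is retained when
`max(|r1|, |r2|) ≥ t`, where `t` is the `(1 − q)`-quantile of the pooled
`|r|` values of both conditions (default `q = 0.25`). The comparison is `≥`,
so ties at the threshold are kept and `q = 1` keeps everything. This
half-thresholding keeps any pair that is strongly coexpressed in *at least
one* condition — precisely the pairs able to show a correlation change.

**Gene statistic.** Each gene is scored by the root-mean-square correlation
change over its retained links, `dC = sqrt(Σ (r1 − r2)² / n_links)`, bounded
by 2 and invariant under swapping the two conditions. Genes with no retained
links score 0.

**Permutation null.** Condition labels are permuted across all samples
(group sizes preserved) and the *entire* statistic — correlations, link
filter, dC — is recomputed per permutation. Re-applying the filter inside
each permutation keeps the observed and permuted statistics exchangeable, so
the per-gene p-values are uniform under the null; reusing the observed link
set would break exchangeability. The null is per-gene, not pooled across
genes, because genes differ in retained-link counts and hence in the null
scale of dC. P-values use the add-one estimator
`p = (1 + #{dC* ≥ dC}) / (1 + n_perm)`, so the smallest attainable p is
`1/(1 + n_perm)`; default `n_perm = 1000`. Permutations are drawn over the
sorted column index set, which makes equal-sized condition swaps exactly
invariant. A permutation count too coarse for the requested FDR cutoff
triggers a warning.

**Multiple testing.** Benjamini–Hochberg step-up adjustment, implemented
directly (`fdr_i = min_{k: p_(k) ≥ p_(i)} p_(k)·m/k`, clipped at 1) and
cross-checked in the tests against both an explicit min-over-suffix oracle
and `statsmodels.stats.multitest.multipletests`. Genes with `FDR < 0.25`
(strict inequality) are called DCGs; retained links with both endpoints DCGs
are reported as DC-links.

At the default permutation depth the smallest FDR any gene can reach is
`m/(m · (1 + n_perm)) · m/k`; with hundreds of genes and 1000 permutations
the floor is comfortably below the 0.25 cutoff, but users raising the gene
count into the tens of thousands should raise `n_perm` accordingly.

## Pathway enrichment

The DCG list is tested for over-representation in each gene set with the
hypergeometric upper tail, `p = Σ_{x≥k} C(K,x) C(N−K,n−x) / C(N,n)`
(scipy's `hypergeom.sf`, evaluated in log-space internally), equivalent to a
one-sided Fisher exact test. The universe is the set of genes present in the
expression matrix — the population actually measured — not the union of the
gene-set file. Sets are intersected with the universe and empty intersections
dropped. No multiple-testing correction is applied across pathways; a set is
"significant" at raw `p < 0.05` (strict). Rows are sorted by p, ties broken
by set name for determinism.

## Regulatory network

Known TF→target pairs (deduplicated, self-loops rejected) are overlaid on the
DCG calls. The default retention rule keeps a pair when *either* endpoint is
a DCG: this admits non-DCG TFs whose targets are differentially coexpressed,
which is exactly the interesting case of a regulator whose own level does not
move. The stricter rule (`retention="dc-link"`), keeping only pairs that are
themselves DC-links, is available behind a flag. Each retained edge records
which endpoint carries the DCG evidence; when both endpoints are DCGs the TF
takes precedence, treating regulatory direction as primary. TFs are
classified `DCG-TF` (the TF itself is a DCG) or `TF-of-DCGs`. The network is
exported as node/edge TSVs plus GraphML (via networkx) for graph tools.

## Regulatory impact factor

For TF *i* with eligible target set of size `n_de`:

    RIF_i = (1/n_de) · Σ_j [ (e1_j · r1_ij)² − (e2_j · r2_ij)² ]

with `e` the per-condition target means and `r` the per-condition TF–target
correlations. Analytic properties, asserted exactly in the tests: RIF is 0
when the conditions agree elementwise, antisymmetric under swapping
conditions, scales as c² when expression is scaled by c, and is invariant
under permuting the target set. Because correlations enter squared, RIF
responds to changes in correlation *magnitude* weighted by expression level;
a pure sign flip at constant |r| contributes only through the difference of
squares.

Eligible targets default to the TF's DCG targets in the regulatory network
(`targets="network-dcg"`); `targets="all-dcg"` scores against the full DCG
list. The TF itself is never its own target. TFs with no eligible measured
target are omitted with a warning. Ranking is by descending |RIF| with ties
broken by TF name; signed values are reported alongside the rank.

## Synthetic data generator

Each planted module follows a single-factor Gaussian model per condition: one
latent N(0,1) factor per sample, gene `g` generated as
`sign_g·sqrt(|rho_c|)·factor + sqrt(1−|rho_c|)·noise`, then scaled to
`sd_log_expr` and shifted by `mean_log_expr`. Pairwise population correlation
is `sign_g·sign_h·|rho_c|`. When the target correlation `rho_c` is negative,
loading signs are negated for a designated subset of non-anchor genes; the
first gene of each module (the *anchor*) keeps a positive loading and doubles
as the module's planted TF.

Two sign layouts are provided. The default, `flip_design="half"`, negates
every other non-anchor gene, so roughly half of each gene's within-module
links flip sign between conditions — every module gene then carries a strong
differential signal, not just the anchor. `flip_design="anchor"` negates all
non-anchors, which concentrates the flips on anchor–gene pairs; a non-anchor
gene then has a single flipping link, diluted in the RMS statistic by its
many retained background links, and per-gene power is materially lower. The
half layout was chosen from this power analysis; both preserve the anchor's
TF–target sign flips. Ground truth records all module genes as DC genes and
all sign-flipping pairs as DC-links.

Non-planted genes are independent noise (optionally equicorrelated through a
shared background factor, `baseline_rho ∈ [0, 1)`; a common *negative*
pairwise correlation across many genes is not a valid covariance structure
and is rejected). Defaults mirror the small two-condition microarray design
the pipeline targets: 2000 genes, 6 samples per condition, log2-like values
(mean 8, sd 2), and module correlations +0.95 / −0.85 — the magnitude of
sign flip seen in strongly differentially coexpressed TF–target pairs.

Companion files make the fixture self-contained: a GMT with one set per
planted module plus size-matched random decoy sets, and a TF→target table
wiring each anchor to its module plus decoy TFs targeting random non-planted
genes. Decoy targets deliberately exclude planted genes — a decoy regulating
a planted DC gene would be a genuine regulator of DCGs, not a negative
control.

**What the generator does not emulate:** probe-level artefacts, batch
effects, covariates such as age or postmortem delay, differential *expression*
(condition means are equal by construction), heavy-tailed noise, and the
dense correlation background of real transcriptomes. Passing the recovery
benchmarks therefore demonstrates that the statistics detect controlled
correlation rewiring at realistic sample sizes, not that any particular
biological dataset would yield comparable sensitivity.

## Benchmarks and problem sizes

The packaged recovery benchmark (`benchmark_spec`) uses 200 genes, two
planted 10-gene modules, 20 samples per condition, 2 planted + 20 decoy TFs
and 1000 permutations. Twenty samples per condition is the regime in which
sample correlations resolve a ±0.9 flip reliably (at n = 6 the null sd of r
is ≈ 0.45 and per-gene power collapses); 200 genes keeps a 50-replicate
benchmark run in the low minutes on one CPU while preserving a realistic
19 900-pair background for the link filter.

Measured on the benchmark (all recomputed by `scripts/acceptance.py`):
sensitivity 1.0 and empirical FDR ≈ 0.26–0.29 at the 0.25 cutoff under a
±0.9 flip; permutation p-values uniform under `rho1 = rho2` (KS ≈ 0.05–0.08
over 200 genes); planted pathway first in enrichment at p ≈ 6×10⁻¹⁰.

Regulator recovery deserves a caveat. On the fixed seed-1 fixture a planted
TF tops the |RIF| ranking in 50/50 analysis-seed replicates. Across fully
re-simulated fixtures the fraction is ≈ 0.8: because RIF squares the
correlations, the planted +0.95 → −0.85 sign flip contributes only
`E[r1² − r2²] ≈ 0.18` per target, while a decoy TF that acquires a single
false-positive DCG target carries a null `r1² − r2²` with sd ≈ 0.10 at
n = 20 — so an unlucky draw can put a decoy on top. This is an intrinsic
property of the squared RIF form under sign-flipping (rather than
magnitude-changing) rewiring, and both fractions are reported by the
acceptance script.

## Numerical and design choices

- Pearson, not Spearman: with a handful of samples per condition rank
  correlation is extremely coarse.
- Strict inequalities at both cutoffs (`FDR < 0.25`, `p < 0.05`).
- Ties at the link-filter threshold are retained (`≥`).
- All output tables use fixed column orders and 6-decimal floats; every
  stage's randomness derives from one master seed via SHA-256 of
  `"{seed}:{stage}"`, so identical config + seed reproduces byte-identical
  outputs and stages are independently reproducible.
- `bh_adjust` uses a stable mergesort so equal p-values always receive equal
  adjusted values regardless of input order.
- Degenerate inputs: zero-variance genes (correlation 0 + warning), empty DCG
  sets (header-only downstream tables), empty networks (valid empty GraphML),
  TFs without targets (omitted + warning), `fdr_cutoff = 0` (pipeline
  completes with empty results).

## Known limitations

- The permutation test recomputes a full correlation matrix per permutation;
  cost grows as `n_perm · n_genes² · n_samples`. Tens of thousands of genes
  call for blocked or approximate strategies not implemented here.
- The enrichment stage applies no correction across pathways by design;
  treat its p-values as exploratory.
- RIF orientation depends on which group is condition 1; ranking by |RIF|
  makes the ranking orientation-invariant, but signed values flip.
- The generator's equal condition means make the expression weights in RIF
  uninformative; real data with differential expression would sharpen RIF's
  contrast beyond what the benchmark exercises.
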