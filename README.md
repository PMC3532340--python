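# coexrif

Differential coexpression analysis, regulatory-network overlay and regulatory
impact factor (RIF) ranking for two-condition gene-expression studies.

## The problem

In small case/control expression studies (classically a handful of microarray
samples per group), single-gene differential expression is underpowered and
often uninformative about regulation. An alternative is to ask which genes
*change their correlation structure* between conditions: a gene pair that is
strongly positively coexpressed in controls and strongly negatively
coexpressed in cases points at rewired regulation even when neither gene's
mean level moves. `coexrif` implements that workflow as a reusable library
for transcriptomics and systems-biology analysts:

1. **DCG detection** — per-condition Pearson correlation matrices; links kept
   by half-thresholding (a pair survives when `max(|r1|, |r2|)` reaches the
   `(1−q)`-quantile of the pooled `|r|` distribution, default `q = 0.25`);
   each gene scored by the RMS correlation change over its retained links,

   `dC_g = sqrt( Σ_links (r1 − r2)² / n_links )  ∈ [0, 2]`;

   significance by sample-label permutation (the whole statistic, including
   the link filter, is recomputed inside every permutation), add-one p-values,
   Benjamini–Hochberg FDR, and a strict `FDR < 0.25` call for differentially
   coexpressed genes (DCGs). Links between two DCGs are reported as DC-links.
2. **Pathway enrichment** — hypergeometric upper-tail test of the DCG list
   against GMT gene sets, with the measured genes as the universe;
   `p < 0.05` flags a set as significant.
3. **Regulatory network** — known TF→target pairs are retained when an
   endpoint is a DCG (or, behind a flag, only when the pair is itself a
   DC-link); TFs are classified as `DCG-TF` versus `TF-of-DCGs`.
4. **RIF ranking** — each TF *i* with `n_de` eligible targets is scored by

   `RIF_i = (1/n_de) Σ_j [ (e1_j · r1_ij)² − (e2_j · r2_ij)² ]`

   where `e1_j, e2_j` are the target's mean expression per condition and
   `r1_ij, r2_ij` the TF–target correlations per condition; TFs are ranked by
   `|RIF|` (the sign only encodes which group is condition 1).

A synthetic-data module (`coexrif.simulate`) plants sign-flipping
coexpression modules with known ground truth — including matching GMT and
TF→target files — so the entire pipeline is exercisable and testable without
any external download.

## Worked example

```sh
python examples/02_dcg_detection.py
```

```
detected 28 DCGs at FDR < 0.25 (256 DC-links among them)
sensitivity = 1.00  (planted genes recovered: 20/20)
empirical FDR = 0.29  (false DCGs: 8)

top of the gene table (dC = RMS correlation change over retained links):
 gene       dC        p     fdr  is_dcg
G0003 0.629134 0.000999 0.00999    True
G0007 0.602558 0.000999 0.00999    True
G0005 0.596419 0.000999 0.00999    True
G0001 0.590040 0.000999 0.00999    True
G0014 0.589970 0.000999 0.00999    True
```

The benchmark plants two 10-gene modules (within-module correlation +0.95 in
condition 1, −0.85 in condition 2) among 200 genes with 20 samples per
condition. All 20 planted genes reach the smallest attainable permutation
p-value (1/1001 ≈ 0.000999) and are called DCGs; 8 background genes slip in,
an empirical FDR of 0.29 at the nominal 0.25 cutoff. Continuing with
`examples/04_network_and_rif.py`:

```
RIF ranking (|RIF| descending):
   tf  n_de       rif  abs_rank
G0011     9 21.061332         1
G0077     2  7.425178         2
G0001     9 -4.670796         3
```

`G0011` and `G0001` are the two planted regulators (each wired to its
9 module partners); the planted regulator `G0011` outranks all 20 decoy TFs.
`examples/03_pathway_enrichment.py` shows both planted module sets leading
the enrichment table at p ≈ 5.8×10⁻¹⁰ while all decoy sets sit near p = 1.

Every stage is also available from the shell:

```sh
coexrif simulate --out-dir fixture --seed 1
coexrif run --expression fixture/expression.tsv --labels fixture/labels.tsv \
    --gmt fixture/gene_sets.gmt --pairs fixture/regulatory_pairs.tsv \
    --out-dir results --seed 1
```

## Layout

- `src/coexrif/io.py` — TSV/GMT readers and writers with strict validation
- `src/coexrif/simulate.py` — planted-module generator and fixture bundles
- `src/coexrif/dcg.py` — correlations, link filter, dC, permutation FDR
- `src/coexrif/enrichment.py` — hypergeometric over-representation
- `src/coexrif/regnet.py` — network construction, TF classes, GraphML export
- `src/coexrif/rif.py` — RIF scores and TF ranking
- `src/coexrif/pipeline.py`, `src/coexrif/cli.py` — orchestration and CLI
- `docs/methods.md` — the statistical model, defaults and limitations
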