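"""Synthetic two-condition expression data with planted differential-coexpression modules.

The generator emulates the data model the downstream analysis assumes: a
normalized log-scale expression matrix over two sample groups in which a few
gene modules change their coexpression structure between conditions while
everything else is condition-independent noise.

Each planted module follows a single-factor Gaussian model per condition:
one latent standard-normal factor per sample, and module gene ``g`` generated
as ``sign_g * sqrt(|rho_c|) * factor + sqrt(1 - |rho_c|) * noise``, then
scaled to ``sd_log_expr`` and shifted by ``mean_log_expr``. With unit-variance
factor and noise the population correlation between genes ``g`` and ``h`` is
``sign_g * sign_h * |rho_c|``. In a condition with negative target
correlation, loading signs are negated for a designated subset of non-anchor
genes (``flip_design="half"`` negates every other non-anchor gene;
``"anchor"`` negates all non-anchors), so anchor–gene correlations equal
``rho_c`` exactly and sign-flipping links appear between conditions. The
module's anchor gene doubles as the module's planted transcription factor.

The companion builders emit a matching GMT file (planted module sets plus
size-matched decoy sets) and a TF→target pair table (planted anchors wired to
their module plus decoy TFs wired to random non-planted genes), so the whole
pipeline is exercisable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    ExpressionDataset,
    GeneSetCollection,
    RegulatoryPairs,
    write_expression,
    write_gmt,
    write_regulatory_pairs,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate",
    "build_companions",
    "write_fixture_bundle",
    "benchmark_spec",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the planted-module generator.

    Defaults mirror the two-condition microarray design the pipeline targets:
    six samples per condition, log2-intensity-like values (mean 8, sd 2), and
    a within-module correlation of +0.95 in condition 1 flipping to −0.85 in
    condition 2 — the magnitude of sign flip reported for strongly
    differentially coexpressed TF–target pairs.
    """

    n_genes: int = 2000
    n_samples_per_condition: int = 6
    n_modules: int = 2
    module_size: int = 10
    rho1: float = 0.95
    rho2: float = -0.85
    baseline_rho: float = 0.0
    mean_log_expr: float = 8.0
    sd_log_expr: float = 2.0
    seed: int = 0
    flip_design: str = "half"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_samples_per_condition < 3:
            raise ValueError("need >= 3 samples per condition")
        if self.n_modules < 0 or (self.n_modules > 0 and self.module_size < 2):
            raise ValueError("n_modules >= 0 and module_size >= 2 required")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("planted modules do not fit into n_genes")
        for rho in (self.rho1, self.rho2):
            if not -1.0 < rho < 1.0:
                raise ValueError("rho1/rho2 must be in (-1, 1)")
        if not 0.0 <= self.baseline_rho < 1.0:
            # a common negative pairwise correlation across many genes is not a
            # valid covariance structure, and the shared-factor construction
            # cannot produce it
            raise ValueError("baseline_rho must be in [0, 1)")
        if self.sd_log_expr <= 0:
            raise ValueError("sd_log_expr must be positive")
        if self.flip_design not in ("half", "anchor"):
            raise ValueError("flip_design must be 'half' or 'anchor'")


@dataclass
class GroundTruth:
    """What was planted: DC genes, per-module TF (the anchor), and flipped links."""

    dc_genes: set[str]
    planted_tf_of_module: dict[int, str]
    dc_links: set[frozenset[str]]
    module_genes: dict[int, list[str]] = field(default_factory=dict)

    def planted_tfs(self) -> set[str]:
        return set(self.planted_tf_of_module.values())


def _loading_signs(rho: float, size: int, flip_design: str) -> np.ndarray:
    """Per-gene loading signs; index 0 is the anchor and always +1."""
    signs = np.ones(size)
    if rho < 0:
        if flip_design == "anchor":
            signs[1:] = -1.0
        else:  # "half": negate every other non-anchor gene
            signs[1::2] = -1.0
    return signs


def simulate(spec: SimulationSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a two-condition dataset with planted sign-flipping modules.

    Identical ``spec`` (including seed) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, ns, sz = spec.n_genes, spec.n_samples_per_condition, spec.module_size
    width = max(4, len(str(n)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n + 1)]
    sample_ids = [f"c{c}_s{k:02d}" for c in (1, 2) for k in range(1, ns + 1)]
    condition_of = {s: (1 if s.startswith("c1_") else 2) for s in sample_ids}

    values = np.empty((n, 2 * ns))
    n_planted = spec.n_modules * sz
    signs_by_condition: list[list[np.ndarray]] = []
    for c, rho in ((0, spec.rho1), (1, spec.rho2)):
        cols = slice(c * ns, (c + 1) * ns)
        cond_signs = []
        for m in range(spec.n_modules):
            factor = rng.standard_normal(ns)
            noise = rng.standard_normal((sz, ns))
            signs = _loading_signs(rho, sz, spec.flip_design)
            cond_signs.append(signs)
            loadings = signs * np.sqrt(abs(rho))
            block = loadings[:, None] * factor[None, :] + np.sqrt(1.0 - abs(rho)) * noise
            values[m * sz : (m + 1) * sz, cols] = block
        signs_by_condition.append(cond_signs)
        n_bg = n - n_planted
        if n_bg:
            noise = rng.standard_normal((n_bg, ns))
            if spec.baseline_rho > 0:
                bg = rng.standard_normal(ns)
                b = spec.baseline_rho
                block = np.sqrt(b) * bg[None, :] + np.sqrt(1.0 - b) * noise
            else:
                block = noise
            values[n_planted:, cols] = block
    values = spec.mean_log_expr + spec.sd_log_expr * values

    module_genes = {
        m: gene_ids[m * sz : (m + 1) * sz] for m in range(spec.n_modules)
    }
    dc_links: set[frozenset[str]] = set()
    for m, genes in module_genes.items():
        # population correlation of pair (i, j) in condition c is
        # signs_c[i] * signs_c[j] * |rho_c|; a link is planted-DC when the
        # pairwise correlation changes sign between conditions
        s1, s2 = signs_by_condition[0][m], signs_by_condition[1][m]
        for i in range(sz):
            for j in range(i + 1, sz):
                pop1 = s1[i] * s1[j] * abs(spec.rho1)
                pop2 = s2[i] * s2[j] * abs(spec.rho2)
                if pop1 * pop2 < 0:
                    dc_links.add(frozenset((genes[i], genes[j])))
    truth = GroundTruth(
        dc_genes=set(g for genes in module_genes.values() for g in genes),
        planted_tf_of_module={m: genes[0] for m, genes in module_genes.items()},
        dc_links=dc_links,
        module_genes=module_genes,
    )
    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        condition_of=condition_of,
    )
    return dataset, truth


def build_companions(
    dataset: ExpressionDataset,
    truth: GroundTruth,
    n_decoy_sets: int = 8,
    n_decoy_tfs: int = 20,
    targets_per_decoy: int = 5,
    seed: int = 0,
) -> tuple[GeneSetCollection, RegulatoryPairs]:
    """Build the matching gene-set collection and TF→target pair table.

    One GMT set per planted module plus ``n_decoy_sets`` size-matched decoy
    sets of non-planted genes; pairs wire each planted TF (module anchor) to
    the rest of its module, plus ``n_decoy_tfs`` decoy TFs each targeting
    ``targets_per_decoy`` random non-planted genes. Decoy targets are drawn
    from non-planted genes only: a decoy regulating a planted DC gene would
    genuinely be a regulator of DCGs, not a negative control.
    """
    rng = np.random.default_rng(seed)
    others = [g for g in dataset.gene_ids if g not in truth.dc_genes]

    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    module_size = None
    for m, genes in truth.module_genes.items():
        sets[f"MODULE_{m + 1}"] = set(genes)
        descriptions[f"MODULE_{m + 1}"] = "planted differential-coexpression module"
        module_size = len(genes)
    if module_size is None:
        module_size = min(10, max(2, len(others) // 2))
    if n_decoy_sets and len(others) < module_size:
        raise ValueError("not enough non-planted genes for decoy sets")
    for d in range(n_decoy_sets):
        idx = rng.choice(len(others), size=module_size, replace=False)
        sets[f"DECOY_SET_{d + 1}"] = {others[i] for i in idx}
        descriptions[f"DECOY_SET_{d + 1}"] = "random non-planted gene set"

    pairs: list[tuple[str, str]] = []
    for m in sorted(truth.module_genes):
        anchor = truth.planted_tf_of_module[m]
        for g in truth.module_genes[m]:
            if g != anchor:
                pairs.append((anchor, g))
    if n_decoy_tfs:
        if len(others) < n_decoy_tfs + targets_per_decoy:
            raise ValueError("not enough non-planted genes for decoy TFs")
        tf_idx = rng.choice(len(others), size=n_decoy_tfs, replace=False)
        for i in tf_idx:
            tf = others[i]
            candidates = [j for j in range(len(others)) if j != i]
            t_idx = rng.choice(len(candidates), size=targets_per_decoy, replace=False)
            for j in t_idx:
                pairs.append((tf, others[candidates[j]]))
    gene_sets = GeneSetCollection(
        sets=sets, descriptions=descriptions, universe_hint=set(dataset.gene_ids)
    )
    return gene_sets, RegulatoryPairs(pairs=pairs)


def write_fixture_bundle(
    dataset: ExpressionDataset,
    truth: GroundTruth,
    out_dir: str | Path,
    n_decoy_sets: int = 8,
    n_decoy_tfs: int = 20,
    targets_per_decoy: int = 5,
    seed: int = 0,
) -> dict[str, Path]:
    """Write the full fixture: expression, labels, GMT, pairs and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_sets, pairs = build_companions(
        dataset,
        truth,
        n_decoy_sets=n_decoy_sets,
        n_decoy_tfs=n_decoy_tfs,
        targets_per_decoy=targets_per_decoy,
        seed=seed,
    )
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "regulatory_pairs": out / "regulatory_pairs.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_expression(
        dataset, paths["expression"], paths["labels"], condition_names=("control", "disease")
    )
    write_gmt(gene_sets, paths["gene_sets"])
    write_regulatory_pairs(pairs, paths["regulatory_pairs"])
    module_of = {g: m for m, genes in truth.module_genes.items() for g in genes}
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\tis_dc\tmodule\n")
        for g in dataset.gene_ids:
            is_dc = int(g in truth.dc_genes)
            module = str(module_of[g] + 1) if g in module_of else "NA"
            fh.write(f"{g}\t{is_dc}\t{module}\n")
    return paths


def benchmark_spec(seed: int = 1) -> SimulationSpec:
    """Simulation settings for the packaged end-to-end recovery benchmark.

    200 genes, two planted 10-gene modules and 20 samples per condition: large
    enough that sample correlations resolve the planted ±rho sign flips, small
    enough that a full permutation analysis runs in seconds.
    """
    return SimulationSpec(
        n_genes=200,
        n_samples_per_condition=20,
        n_modules=2,
        module_size=10,
        seed=seed,
    )
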