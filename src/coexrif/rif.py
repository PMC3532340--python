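"""Regulatory impact factor (RIF): rank TFs by expression-weighted coexpression change.

For TF *i* with a target set of ``n_de`` differentially (co)expressed genes,
let ``e1_j``/``e2_j`` be target *j*'s mean expression in conditions 1 and 2
and ``r1_ij``/``r2_ij`` the TF–target Pearson correlations per condition.
The score is the average squared expression-weighted correlation difference

    RIF_i = (1 / n_de) * sum_j [ (e1_j * r1_ij)^2 - (e2_j * r2_ij)^2 ].

It is zero when the two conditions agree, antisymmetric under swapping the
conditions, and scales as c^2 when all expression values are scaled by c.
TFs are ranked by descending |RIF| (the sign only encodes condition
orientation), ties broken by TF name; signed values are still reported.

By default a TF's target set is its DCG targets in the regulatory network
(``targets="network-dcg"``); ``targets="all-dcg"`` scores every TF against
the full DCG list instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dcg import correlation_matrix
from .io import ExpressionDataset
from .regnet import RegulatoryNetwork

__all__ = ["RIFInput", "condition_means", "rif_score", "build_rif_input", "rank_tfs"]


@dataclass
class RIFInput:
    """Per-TF inputs to the RIF score: target means and correlations per condition."""

    tf: str
    target_set: list[str]
    e1: np.ndarray
    e2: np.ndarray
    r1: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.e1 = np.asarray(self.e1, dtype=float)
        self.e2 = np.asarray(self.e2, dtype=float)
        self.r1 = np.asarray(self.r1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.target_set)
        if n < 1:
            raise ValueError("target set must contain at least one gene")
        for name, v in (("e1", self.e1), ("e2", self.e2), ("r1", self.r1), ("r2", self.r2)):
            if v.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if self.tf in self.target_set:
            raise ValueError("TF cannot be a member of its own target set")
        for name, v in (("r1", self.r1), ("r2", self.r2)):
            if np.any(np.abs(v) > 1.0 + 1e-12):
                raise ValueError(f"{name} entries must lie in [-1, 1]")

    @property
    def n_de(self) -> int:
        return len(self.target_set)


def condition_means(dataset: ExpressionDataset, gene: str) -> tuple[float, float]:
    """Arithmetic mean of a gene's expression over the samples of each condition."""
    idx = dataset.gene_index()
    if gene not in idx:
        raise KeyError(f"gene {gene!r} not in dataset")
    row = dataset.values[idx[gene]]
    m1 = float(row[dataset.condition_columns(1)].mean())
    m2 = float(row[dataset.condition_columns(2)].mean())
    return m1, m2


def rif_score(inp: RIFInput) -> float:
    """Evaluate the RIF formula for one TF."""
    terms = (inp.e1 * inp.r1) ** 2 - (inp.e2 * inp.r2) ** 2
    return float(terms.mean())


def build_rif_input(dataset: ExpressionDataset, tf: str, targets: list[str]) -> RIFInput:
    """Assemble means and per-condition TF–target correlations from the dataset."""
    idx = dataset.gene_index()
    if tf not in idx:
        raise KeyError(f"TF {tf!r} not in dataset")
    missing = [t for t in targets if t not in idx]
    if missing:
        raise KeyError(f"targets not in dataset: {missing}")
    rows = [idx[tf]] + [idx[t] for t in targets]
    sub = dataset.values[rows, :]
    cors = []
    for c in (1, 2):
        R, _ = correlation_matrix(sub[:, dataset.condition_columns(c)])
        cors.append(R[0, 1:])
    e1 = np.array([condition_means(dataset, t)[0] for t in targets])
    e2 = np.array([condition_means(dataset, t)[1] for t in targets])
    return RIFInput(tf=tf, target_set=list(targets), e1=e1, e2=e2, r1=cors[0], r2=cors[1])


def rank_tfs(
    dataset: ExpressionDataset,
    network: RegulatoryNetwork,
    dcgs: set[str],
    targets: str = "network-dcg",
) -> pd.DataFrame:
    """Score and rank every rankable TF in the network.

    A TF is rankable when it is measured in the expression matrix and has at
    least one eligible target (its DCG targets for ``"network-dcg"``, the
    whole DCG list for ``"all-dcg"``, always intersected with the measured
    genes and excluding the TF itself). Unrankable TFs are omitted with a
    warning. Columns: ``tf, n_de, rif, abs_rank``.
    """
    if targets not in ("network-dcg", "all-dcg"):
        raise ValueError("targets must be 'network-dcg' or 'all-dcg'")
    measured = set(dataset.gene_ids)
    rows = []
    skipped = []
    for tf in sorted(network.tfs()):
        if tf not in measured:
            skipped.append(tf)
            continue
        if targets == "network-dcg":
            candidate = network.targets_of(tf) & dcgs
        else:
            candidate = set(dcgs)
        eligible = sorted((candidate & measured) - {tf})
        if not eligible:
            skipped.append(tf)
            continue
        inp = build_rif_input(dataset, tf, eligible)
        rows.append((tf, inp.n_de, rif_score(inp)))
    if skipped:
        warnings.warn(
            f"omitted {len(skipped)} TF(s) with no eligible targets or no "
            f"expression data: {skipped[:5]}...",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no rankable TF: every TF lacks eligible targets")
    table = pd.DataFrame(rows, columns=["tf", "n_de", "rif"])
    table = table.sort_values(
        by=["rif", "tf"],
        key=lambda col: -col.abs() if col.name == "rif" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    table["abs_rank"] = np.arange(1, len(table) + 1)
    return table
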