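"""Readers and writers for the pipeline's on-disk formats.

All inputs are plain text: a gene-by-sample expression TSV (log-intensity
scale) plus a two-column sample→condition label TSV, gene sets in standard
GMT, and transcription-factor→target pairs as a two-column TSV. Loading is
strict: duplicate gene rows are collapsed by averaging, non-numeric cells
raise with the offending gene and sample named, and each condition must have
at least three samples (Pearson correlation needs three points).

Condition names are mapped to the integer codes {1, 2} in lexicographic
order of the names, so "condition 1" in downstream, orientation-sensitive
statistics is reproducible; pass ``condition1=`` to override which label is
condition 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "RegulatoryPairs",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_regulatory_pairs",
    "write_regulatory_pairs",
]


@dataclass
class ExpressionDataset:
    """Gene × sample real-valued expression matrix with a two-level condition design.

    Parameters
    ----------
    gene_ids : list of str
        Unique, non-empty gene identifiers (row order of ``values``).
    sample_ids : list of str
        Unique sample identifiers (column order of ``values``).
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values, assumed normalized and on a log scale.
    condition_of : dict mapping sample_id -> {1, 2}
        Two-group assignment; each condition needs >= 3 samples.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_of: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if any((not isinstance(g, str)) or g == "" for g in self.gene_ids):
            raise ValueError("gene ids must be non-empty strings")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids after loading")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        missing = [s for s in self.sample_ids if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples missing a condition label: {missing}")
        codes = {self.condition_of[s] for s in self.sample_ids}
        if codes != {1, 2}:
            raise ValueError(f"condition codes must be exactly {{1, 2}}, got {sorted(codes)}")
        for c in (1, 2):
            n_c = sum(1 for s in self.sample_ids if self.condition_of[s] == c)
            if n_c < 3:
                raise ValueError(
                    f"condition {c} has {n_c} samples; at least 3 are required "
                    "for Pearson correlation"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condition_columns(self, condition: int) -> np.ndarray:
        """Column indices of samples assigned to ``condition`` (1 or 2)."""
        return np.array(
            [j for j, s in enumerate(self.sample_ids) if self.condition_of[s] == condition],
            dtype=int,
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways), as read from a GMT file."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe_hint: set[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class RegulatoryPairs:
    """Deduplicated TF→target pairs in first-seen order; self-loops are rejected."""

    pairs: list[tuple[str, str]]
    n_self_loops_dropped: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for tf, target in self.pairs:
            if tf == target:
                raise ValueError(f"self-loop pair ({tf}, {target}) not allowed")
            if (tf, target) in seen:
                raise ValueError(f"duplicate pair ({tf}, {target})")
            seen.add((tf, target))

    def __len__(self) -> int:
        return len(self.pairs)

    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.pairs}

    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}


def _read_labels(labels_path: str | Path) -> dict[str, str]:
    lab = pd.read_csv(labels_path, sep="\t", header=None, dtype=str)
    if lab.shape[1] < 2:
        raise ValueError(f"labels file {labels_path} needs two tab-separated columns")
    rows = list(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
    if rows and rows[0] == ("sample_id", "condition"):
        rows = rows[1:]
    mapping: dict[str, str] = {}
    for sample, cond in rows:
        if sample in mapping and mapping[sample] != cond:
            raise ValueError(f"sample {sample!r} labelled with conflicting conditions")
        mapping[sample] = cond
    return mapping


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    condition1: str | None = None,
) -> ExpressionDataset:
    """Load an expression TSV plus condition labels into an :class:`ExpressionDataset`.

    The matrix file has a header row (first field is the gene-id column name,
    remaining fields are sample ids) and one gene per row. The labels file
    maps ``sample_id<TAB>condition`` with exactly two condition names among
    the matrix's samples; names are mapped to codes {1, 2} in sorted order
    unless ``condition1`` names the label that should be condition 1.

    Duplicate gene rows are collapsed by averaging (order-independent).
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise ValueError(f"expression matrix {matrix_path} has no sample columns")
    num = raw.apply(pd.to_numeric, errors="coerce")
    if num.isna().to_numpy().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing expression value for gene {num.index[r]!r} "
            f"in sample {num.columns[c]!r}"
        )
    if any((not isinstance(g, str)) or g == "" for g in num.index):
        raise ValueError("empty gene id in expression matrix")
    if num.index.duplicated().any():
        first_seen = list(dict.fromkeys(num.index))
        if len(first_seen) < 2:
            raise ValueError("all gene ids are duplicates of a single id")
        num = num.groupby(level=0, sort=False).mean()
        num = num.loc[first_seen]

    mapping = _read_labels(labels_path)
    missing = [s for s in num.columns if s not in mapping]
    if missing:
        raise ValueError(f"samples missing from labels file: {missing}")
    used = {s: mapping[s] for s in num.columns}
    names = sorted(set(used.values()))
    if len(names) != 2:
        raise ValueError(f"exactly two condition names required, got {names}")
    if condition1 is not None:
        if condition1 not in names:
            raise ValueError(f"condition1={condition1!r} not among labels {names}")
        names = [condition1] + [n for n in names if n != condition1]
    code = {names[0]: 1, names[1]: 2}
    condition_of = {s: code[used[s]] for s in num.columns}
    return ExpressionDataset(
        gene_ids=list(num.index),
        sample_ids=list(num.columns),
        values=num.to_numpy(dtype=float),
        condition_of=condition_of,
    )


def write_expression(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
    condition_names: tuple[str, str] = ("condition1", "condition2"),
) -> None:
    """Write the matrix and labels TSVs; inverse of :func:`read_expression`.

    ``condition_names`` must sort so that the first entry maps back to
    condition 1 on re-reading (the defaults do).
    """
    if sorted(condition_names) != list(condition_names):
        raise ValueError("condition_names must be in lexicographic order for round-trips")
    dataset.to_frame().rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    with open(labels_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\n")
        for s in dataset.sample_ids:
            fh.write(f"{s}\t{condition_names[dataset.condition_of[s] - 1]}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            genes = {g for g in fields[2:] if g != ""}
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_regulatory_pairs(path: str | Path) -> RegulatoryPairs:
    """Read a two-column ``tf<TAB>target`` TSV (optional header row).

    Duplicate pairs are dropped (first-seen order kept); self-loop rows are
    rejected with a warning and counted in ``n_self_loops_dropped``.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            tf, target = fields[0], fields[1]
            if lineno == 1 and (tf.lower(), target.lower()) == ("tf", "target"):
                continue
            if tf == target:
                n_self += 1
                continue
            if (tf, target) in seen:
                continue
            seen.add((tf, target))
            pairs.append((tf, target))
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop TF-target row(s) from {path}", stacklevel=2)
    return RegulatoryPairs(pairs=pairs, n_self_loops_dropped=n_self)


def write_regulatory_pairs(pairs: RegulatoryPairs, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\ttarget\n")
        for tf, target in pairs.pairs:
            fh.write(f"{tf}\t{target}\n")
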