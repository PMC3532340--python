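"""End-to-end orchestration: DCG detection → enrichment → network → RIF ranking.

A single :class:`PipelineConfig` names the four inputs (expression matrix,
condition labels, GMT gene sets, TF→target pairs), an output directory and
every threshold the stages apply. All randomness flows from one seed, split
per stage by hashing the stage name, so each stage is independently
reproducible and an identical config + seed reproduces byte-identical output
tables. Float columns are written with six decimals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dcg import dcg_analysis
from .enrichment import enrich
from .io import read_expression, read_gmt, read_regulatory_pairs
from .regnet import build_network, classify_tfs, export_network
from .rif import rank_tfs

__all__ = ["PipelineConfig", "stage_seed", "run_all"]

logger = logging.getLogger("coexrif")

_DCG_COLUMNS = ["gene", "dC", "p", "fdr", "is_dcg"]
_LINK_COLUMNS = ["gene_a", "gene_b", "r1", "r2", "d"]
_ENRICH_COLUMNS = ["set_name", "count", "size", "p", "significant"]
_RIF_COLUMNS = ["tf", "n_de", "rif", "abs_rank"]


@dataclass
class PipelineConfig:
    expression: Path
    labels: Path
    gene_sets: Path
    regulatory_pairs: Path
    out_dir: Path
    fdr_cutoff: float = 0.25
    alpha: float = 0.05
    q_filter: float = 0.25
    n_perm: int = 1000
    seed: int = 0
    retention: str = "either-endpoint"
    rif_targets: str = "network-dcg"
    condition1: str | None = None

    def __post_init__(self) -> None:
        for name in ("expression", "labels", "gene_sets", "regulatory_pairs", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if not 0.0 <= self.fdr_cutoff <= 1.0:
            raise ValueError("fdr_cutoff must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.q_filter <= 1.0:
            raise ValueError("q_filter must be in (0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        out = self.out_dir.resolve()
        for name in ("expression", "labels", "gene_sets", "regulatory_pairs"):
            p = Path(getattr(self, name))
            if p.resolve().parent == out:
                raise ValueError(f"output directory must be distinct from input file {p}")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write(df: pd.DataFrame, columns: list[str], path: Path) -> int:
    df = df.loc[:, columns] if len(df) else pd.DataFrame(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return len(df)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run manifest.

    Any stage failure is re-raised annotated with the stage name. Degenerate
    configurations (e.g. ``fdr_cutoff=0`` giving zero DCGs) complete with
    header-only downstream tables.
    """
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    row_counts: dict[str, int] = {}

    stage = "load"
    try:
        dataset = read_expression(config.expression, config.labels, condition1=config.condition1)
        gene_sets = read_gmt(config.gene_sets)
        reg_pairs = read_regulatory_pairs(config.regulatory_pairs)
        logger.info(
            "loaded %d genes x %d samples, %d gene sets, %d regulatory pairs",
            dataset.n_genes, dataset.n_samples, len(gene_sets), len(reg_pairs),
        )

        stage = "dcg"
        logger.info(
            "dcg: q_filter=%s n_perm=%d fdr_cutoff=%s seed=%d",
            config.q_filter, config.n_perm, config.fdr_cutoff, stage_seed(config.seed, "dcg"),
        )
        result = dcg_analysis(
            dataset,
            q=config.q_filter,
            n_perm=config.n_perm,
            fdr_cutoff=config.fdr_cutoff,
            seed=stage_seed(config.seed, "dcg"),
        )
        row_counts["dcg_table"] = _write(result.table, _DCG_COLUMNS, out / "dcg_table.tsv")
        row_counts["dc_links"] = _write(result.dc_links, _LINK_COLUMNS, out / "dc_links.tsv")
        logger.info("dcg: %d DCGs, %d DC-links", len(result.dcgs), len(result.dc_links))

        stage = "enrichment"
        universe = set(dataset.gene_ids)
        if result.dcgs:
            enrichment = enrich(result.dcgs, gene_sets, universe, alpha=config.alpha)
        else:
            enrichment = pd.DataFrame(columns=_ENRICH_COLUMNS)
        row_counts["enrichment"] = _write(enrichment, _ENRICH_COLUMNS, out / "enrichment.tsv")

        stage = "network"
        dc_link_set = {
            frozenset((a, b)) for a, b in zip(result.dc_links["gene_a"], result.dc_links["gene_b"])
        }
        network = build_network(
            result.dcgs,
            dc_link_set,
            reg_pairs,
            corr1=result.corr1,
            corr2=result.corr2,
            gene_index=dataset.gene_index(),
            retention=config.retention,
        )
        export_network(network, out)
        row_counts["edges"] = len(network.edges)
        row_counts["nodes"] = len(network.nodes)
        tf_classes = classify_tfs(network)
        tf_classes.to_csv(out / "tf_classes.tsv", sep="\t", index=False)
        row_counts["tf_classes"] = len(tf_classes)

        stage = "rif"
        try:
            rif_table = rank_tfs(dataset, network, result.dcgs, targets=config.rif_targets)
        except ValueError:
            rif_table = pd.DataFrame(columns=_RIF_COLUMNS)
        row_counts["rif_table"] = _write(rif_table, _RIF_COLUMNS, out / "rif_table.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "coexrif",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "fdr_cutoff": config.fdr_cutoff,
            "alpha": config.alpha,
            "q_filter": config.q_filter,
            "n_perm": config.n_perm,
            "retention": config.retention,
            "rif_targets": config.rif_targets,
            "condition1": config.condition1,
        },
        "row_counts": row_counts,
        "outputs": [
            "dcg_table.tsv",
            "dc_links.tsv",
            "enrichment.tsv",
            "nodes.tsv",
            "edges.tsv",
            "network.graphml",
            "tf_classes.tsv",
            "rif_table.tsv",
        ],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
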