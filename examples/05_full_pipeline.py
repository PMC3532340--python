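"""Run the whole pipeline end to end from files on disk.

Writes a fixture bundle (expression, labels, GMT, TF->target pairs), runs all
stages through one PipelineConfig, and prints the manifest's row counts. The
same thing is available from the shell:

    coexrif simulate --out-dir fixture --seed 1
    coexrif run --expression fixture/expression.tsv --labels fixture/labels.tsv \
        --gmt fixture/gene_sets.gmt --pairs fixture/regulatory_pairs.tsv \
        --out-dir results --seed 1
"""

import json
import tempfile
from pathlib import Path

from coexrif import PipelineConfig, run_all, simulate, write_fixture_bundle
from coexrif.simulate import benchmark_spec

workdir = Path(tempfile.mkdtemp(prefix="coexrif_"))
dataset, truth = simulate(benchmark_spec(seed=1))
paths = write_fixture_bundle(dataset, truth, workdir / "fixture", seed=1)

config = PipelineConfig(
    expression=paths["expression"],
    labels=paths["labels"],
    gene_sets=paths["gene_sets"],
    regulatory_pairs=paths["regulatory_pairs"],
    out_dir=workdir / "results",
    n_perm=1000,
    seed=1,
)
manifest = run_all(config)
print(json.dumps(manifest["row_counts"], indent=2))
print(f"outputs in {config.out_dir}")
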