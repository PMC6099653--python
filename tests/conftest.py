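import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports

from modnet import Config, NGParams, SimConfig, generate_dataset


@pytest.fixture
def params() -> NGParams:
    return NGParams(alpha=2.0, lam=0.1)


@pytest.fixture
def small_sim():
    """Small planted dataset: 2 subtypes, 2 modulators x 8 targets, fast."""
    cfg = SimConfig(
        n_subtypes=2,
        samples_per_subtype=30,
        n_modulators_per_subtype=2,
        targets_per_modulator=8,
        n_background_genes=40,
        decoys_per_subtype=1,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture
def fast_cfg() -> Config:
    """Pipeline config scaled for unit tests (fewer permutations/runs)."""
    return Config(n_permutations=100, n_ensemble_runs=10)


def write_tsv_triplet(tmp_path, expression: pd.DataFrame, cnv: pd.DataFrame, labels: pd.Series):
    expr_path = tmp_path / "expr.tsv"
    cnv_path = tmp_path / "cnv.tsv"
    labels_path = tmp_path / "labels.tsv"
    expression.to_csv(expr_path, sep="\t", index_label="gene")
    cnv.to_csv(cnv_path, sep="\t", index_label="gene")
    labels.rename_axis("sample").rename("subtype").reset_index().to_csv(
        labels_path, sep="\t", index=False
    )
    return str(expr_path), str(cnv_path), str(labels_path)
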