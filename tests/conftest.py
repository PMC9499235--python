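"""Shared fixtures: tiny tables and a fast training configuration."""

import numpy as np
import pytest

from cebp import (
    CausalSimConfig,
    ExpressionTable,
    MutationTable,
    RunConfig,
    simulate_confounded,
)


@pytest.fixture
def expr_3x2(tmp_path):
    """3-sample x 2-gene expression TSV (samples in rows)."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "sample_id\tGENE1\tGENE2\n"
        "S1\t1.0\t4.0\n"
        "S2\t2.0\t5.0\n"
        "S3\t3.0\t6.0\n"
    )
    return path


@pytest.fixture
def mut_4x3(tmp_path):
    path = tmp_path / "mut.tsv"
    path.write_text(
        "sample_id\tGA\tGB\tGC\n"
        "S1\t0\t1\t0\n"
        "S2\t1\t0\t0\n"
        "S3\t0\t0\t1\n"
        "S4\t1\t1\t0\n"
    )
    return path


@pytest.fixture
def tiny_cfg():
    """Training configuration small enough for sub-second unit tests."""
    return RunConfig(
        latent_dim=3,
        hidden_width=8,
        hidden_depth=2,
        epochs=8,
        patience=8,
        batch_size=64,
        n_replicates=2,
        n_mc_samples=20,
        n_confounders=10,
    )


@pytest.fixture
def tiny_sim():
    """A small confounded cohort for structural (non-recovery) tests."""
    cfg = CausalSimConfig(
        n_samples=120, n_confounder_genes=8, latent_dim=2, tau=0.5, seed=7
    )
    return simulate_confounded(cfg)
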