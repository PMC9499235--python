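"""Synthetic cohorts with known causal ground truth.

Two generators cover the two halves of the workflow:

* :func:`simulate_confounded` draws (X, M, Y) from the structural model the
  causal estimator assumes — a d-dimensional standard-normal latent
  confounder z drives the binary mutation background X (per-gene logistic
  links), the binary treatment M (a logistic link on a linear score of z),
  and a linear-Gaussian outcome Y = tau*M + w.z + noise.  The true average
  treatment effect is exactly ``tau`` by construction, and the naive
  difference-in-means bias implied by the configuration is measured by a
  large Monte Carlo evaluation of the generative law.

* :func:`simulate_pathway` plants a block of mutually correlated "core"
  genes in an otherwise-noise expression matrix: core genes share a common
  per-sample factor t ~ N(0,1) with a configurable loading, so the core set
  and the per-sample activity both have a known ground truth.

* :func:`simulate_mutation_cohort` composes the confounded generator into a
  full end-to-end cohort: several candidate treatment genes (one carrying a
  real effect) plus a block of background mutation genes, with the activity
  vector as outcome — written in the exact formats :mod:`cebp.io` reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .activity import PathwayExpression
from .cevae import CausalDataset
from .io import ExpressionTable, MutationTable


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# confounded causal data


@dataclass
class CausalSimConfig:
    """Settings of the confounded (X, M, Y) generator.

    ``confounder_to_treatment`` (c) and ``confounder_to_outcome`` (w_scale)
    control how strongly the latent z pushes on treatment and outcome — both
    act along the same direction of z, so raising them together raises the
    naive difference-in-means bias.  ``confounder_to_x`` (b_scale) sets how
    informative the proxy genes are about z.  Per-gene baseline logits are
    drawn once from a seeded spread so mutation rates land in a realistic
    1%-40% band.
    """

    n_samples: int = 2000
    n_confounder_genes: int = 50
    latent_dim: int = 5
    tau: float = 0.5
    confounder_to_treatment: float = 1.0
    confounder_to_outcome: float = 1.0
    confounder_to_x: float = 3.0
    treatment_baseline: float = 0.0
    outcome_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_noise_sd <= 0:
            raise ValueError("outcome_noise_sd must be positive")
        if self.n_samples < 50:
            raise ValueError("n_samples must be at least 50")
        if abs(self.treatment_baseline) > 3.0:
            raise ValueError(
                "treatment_baseline too extreme: a treatment arm would be "
                "empty in expectation"
            )


@dataclass
class SimulatedCausalData:
    """A drawn cohort plus its generative ground truth."""

    dataset: CausalDataset
    z_true: np.ndarray
    tau_true: float
    naive_bias_oracle: float
    config: CausalSimConfig


def _gene_params(cfg: CausalSimConfig, rng: np.random.Generator):
    """Per-gene baseline logits and loadings, drawn once per config."""
    d = cfg.latent_dim
    # baselines spread so sigmoid-integrated rates span roughly 1%-40%
    a = rng.uniform(-4.5, -0.5, size=cfg.n_confounder_genes)
    b = rng.normal(0.0, cfg.confounder_to_x / np.sqrt(d), size=(d, cfg.n_confounder_genes))
    # treatment and outcome act along a shared unit direction of z so that
    # confounding is real (not orthogonal by chance)
    direction = np.ones(d) / np.sqrt(d)
    c_vec = cfg.confounder_to_treatment * direction
    w_vec = cfg.confounder_to_outcome * direction
    return a, b, c_vec, w_vec


def naive_bias_oracle(cfg: CausalSimConfig, n_oracle: int = 1_000_000) -> float:
    """Monte Carlo evaluation of E[Y|M=1] - E[Y|M=0] - tau under the law.

    Uses an independent large draw of the generative model (not a dataset),
    so it measures the bias a difference-in-means estimator converges to.
    """
    rng = np.random.default_rng(cfg.seed + 999_983)
    _, _, c_vec, w_vec = _gene_params(cfg, np.random.default_rng(cfg.seed))
    z = rng.standard_normal((n_oracle, cfg.latent_dim))
    p_m = _sigmoid(cfg.treatment_baseline + z @ c_vec)
    m = rng.random(n_oracle) < p_m
    wz = z @ w_vec
    # outcome noise is mean-zero and independent of m: it drops from the contrast
    return float(wz[m].mean() - wz[~m].mean())


def simulate_confounded(cfg: CausalSimConfig) -> SimulatedCausalData:
    """Draw one cohort from the structural model; true ATE is ``cfg.tau``."""
    rng = np.random.default_rng(cfg.seed)
    a, b, c_vec, w_vec = _gene_params(cfg, np.random.default_rng(cfg.seed))
    z = rng.standard_normal((cfg.n_samples, cfg.latent_dim))
    X = (rng.random((cfg.n_samples, cfg.n_confounder_genes)) < _sigmoid(a + z @ b)).astype(
        np.int8
    )
    m = (rng.random(cfg.n_samples) < _sigmoid(cfg.treatment_baseline + z @ c_vec)).astype(
        np.int8
    )
    if m.sum() == 0 or m.sum() == cfg.n_samples:
        raise ValueError(
            "realized treatment has a single arm; change the seed or reduce "
            "confounder_to_treatment / treatment_baseline"
        )
    y = cfg.tau * m + z @ w_vec + rng.normal(0.0, cfg.outcome_noise_sd, cfg.n_samples)
    ds = CausalDataset(
        X=X, M=m, Y=y, sample_ids=[f"S{i:05d}" for i in range(cfg.n_samples)]
    )
    bias = naive_bias_oracle(cfg, n_oracle=200_000)
    return SimulatedCausalData(
        dataset=ds, z_true=z, tau_true=cfg.tau, naive_bias_oracle=bias, config=cfg
    )


def naive_ate(ds: CausalDataset) -> float:
    """Unadjusted difference in mean outcome: mean(Y|M=1) - mean(Y|M=0)."""
    m = ds.M.astype(bool)
    if m.sum() == 0 or (~m).sum() == 0:
        raise ValueError("both treatment arms must be nonempty")
    return float(ds.Y[m].mean() - ds.Y[~m].mean())


# ---------------------------------------------------------------------------
# planted-core pathway expression


@dataclass
class PathwaySimConfig:
    """Settings of the planted-core-gene expression generator."""

    n_samples: int = 100
    n_genes: int = 40
    core_size: Optional[int] = None  # default floor(P/2)
    loading: float = 4.5
    noise_sd: float = 0.5
    baseline: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_size is None:
            self.core_size = self.n_genes // 2
        if not 0 < self.core_size <= self.n_genes:
            raise ValueError("core_size must be in 1..n_genes")
        if self.loading < 0 or self.noise_sd <= 0:
            raise ValueError("loading must be >= 0 and noise_sd > 0")


def simulate_pathway(
    cfg: PathwaySimConfig,
) -> Tuple[PathwayExpression, np.ndarray, np.ndarray]:
    """Expression with a planted block of co-expressed core genes.

    Returns the pathway matrix, the planted core gene indices, and the
    planted per-sample factor.  Core genes are ``baseline + loading * t_i +
    noise``; the rest are independent noise around the same baseline.  The
    whole matrix is shifted by a constant (never truncated) to stay
    nonnegative, which preserves all correlations exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    N, P, k = cfg.n_samples, cfg.n_genes, cfg.core_size
    core = np.arange(k)  # planted block occupies the first k columns
    t = rng.standard_normal(N)
    U = cfg.baseline + rng.normal(0.0, cfg.noise_sd, size=(N, P))
    U[:, core] += cfg.loading * t[:, None]
    lo = U.min()
    if lo < 0:
        U = U - lo
    px = PathwayExpression(
        U=U,
        gene_ids=[f"G{j:03d}" for j in range(P)],
        sample_ids=[f"S{i:04d}" for i in range(N)],
    )
    return px, core, t


# ---------------------------------------------------------------------------
# end-to-end mutation cohort


@dataclass
class SimulatedCohort:
    """Mutation table + activity outcome + causal ground truth."""

    mutation: MutationTable
    activity: np.ndarray
    candidate_genes: List[str]
    taus: np.ndarray
    z_true: np.ndarray
    config: CausalSimConfig


def simulate_mutation_cohort(
    cfg: CausalSimConfig,
    candidate_taus: Sequence[float] = (0.5, 0.0, 0.0),
) -> SimulatedCohort:
    """A cohort with several candidate treatment genes and a background block.

    Each candidate gene is a confounded binary treatment (same latent z);
    the outcome sums every candidate's effect plus the confounder term.
    Background genes are the proxy block.  The mutation table holds the
    candidates first, then the background genes, so pipeline code can
    rediscover which candidate carries the planted effect.
    """
    rng = np.random.default_rng(cfg.seed)
    a, b, c_vec, w_vec = _gene_params(cfg, np.random.default_rng(cfg.seed))
    n, d = cfg.n_samples, cfg.latent_dim
    z = rng.standard_normal((n, d))
    X = (rng.random((n, cfg.n_confounder_genes)) < _sigmoid(a + z @ b)).astype(np.int8)

    taus = np.asarray(candidate_taus, dtype=float)
    n_cand = taus.size
    M = np.empty((n, n_cand), dtype=np.int8)
    for j in range(n_cand):
        M[:, j] = rng.random(n) < _sigmoid(cfg.treatment_baseline + z @ c_vec)
        if M[:, j].sum() in (0, n):
            raise ValueError(f"candidate {j} realized a single arm; re-seed")
    y = M @ taus + z @ w_vec + rng.normal(0.0, cfg.outcome_noise_sd, n)

    sample_ids = [f"S{i:05d}" for i in range(n)]
    cand_ids = [f"CAND{j}" for j in range(n_cand)]
    bg_ids = [f"BG{j:03d}" for j in range(cfg.n_confounder_genes)]
    table = MutationTable(
        sample_ids, cand_ids + bg_ids, np.concatenate([M, X], axis=1)
    )
    return SimulatedCohort(
        mutation=table,
        activity=y,
        candidate_genes=cand_ids,
        taus=taus,
        z_true=z,
        config=cfg,
    )


def write_cohort(
    cohort: SimulatedCohort, outdir: str | Path, prefix: str = "sim"
) -> None:
    """Write mutation TSV, activity TSV and a truth sidecar JSON."""
    import pandas as pd

    from .io import write_mutation_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mutation_matrix(cohort.mutation, outdir / f"{prefix}_mutations.tsv")
    pd.DataFrame(
        {"sample_id": cohort.mutation.sample_ids, "activity": cohort.activity}
    ).to_csv(outdir / f"{prefix}_activity.tsv", sep="\t", index=False)
    truth = {
        "candidate_genes": cohort.candidate_genes,
        "taus": cohort.taus.tolist(),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cohort.config).items()
        },
    }
    (outdir / f"{prefix}_truth.json").write_text(json.dumps(truth, indent=2))
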