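"""Study orchestration: candidate selection, per-gene causal datasets,
replicate-aggregated ATE ranking, and the mutated-vs-non-mutated group test.

For each candidate gene g the treatment vector M is g's mutation column,
the observed-confounder block X holds the ``n_confounders`` highest-
mutation-rate genes other than g (all with rate at or above the 1% floor),
and the outcome Y is the per-sample pathway activity.  Candidates are
ranked by the replicate mean ATE; each row also carries the gene's mutation
rate and a Mann-Whitney U comparison of activity between its mutated and
non-mutated groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .activity import ActivityVector
from .cevae import ATEEstimate, CausalDataset, run_replicates
from .config import RunConfig
from .io import MutationTable

logger = logging.getLogger(__name__)


@dataclass
class CandidateRule:
    """How the candidate gene list is cut from the mutation-rate ranking.

    ``top_k_by_rate`` keeps the k highest-rate genes; ``rate_at_least``
    keeps every gene whose rate meets the threshold.  Different cohorts call
    for different rules (large cohorts: top-200; smaller ones: rate >= 7% or
    >= 1%).
    """

    kind: str
    k: Optional[int] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "top_k_by_rate":
            if self.k is None or self.k < 1:
                raise ValueError("top_k_by_rate requires k >= 1")
        elif self.kind == "rate_at_least":
            if self.threshold is None or not 0.0 < self.threshold < 1.0:
                raise ValueError("rate_at_least requires threshold in (0, 1)")
        else:
            raise ValueError(f"unknown rule kind {self.kind!r}")


@dataclass
class RankingRow:
    gene: str
    ate_mean: float
    ate_std: float
    mutation_rate: float
    mw_u: float
    mw_p: float
    rank: int


def mutation_rates(mut: MutationTable) -> pd.Series:
    """Fraction of samples mutated, per gene."""
    if mut.n_samples == 0 or mut.n_genes == 0:
        raise ValueError("mutation table is empty")
    rates = mut.calls.mean(axis=0)
    return pd.Series(rates, index=mut.gene_ids, name="mutation_rate")


def select_candidates(rates: pd.Series, rule: CandidateRule) -> List[str]:
    """Apply a candidate rule to the per-gene rate vector.

    Ordering is rate-descending with ties broken by ascending gene id, so
    the result is deterministic regardless of input order.
    """
    df = rates.rename("rate").rename_axis("gene").reset_index()
    df = df.sort_values(["rate", "gene"], ascending=[False, True])
    if rule.kind == "top_k_by_rate":
        chosen = df.head(rule.k)
    else:
        chosen = df[df["rate"] >= rule.threshold]
    if chosen.empty:
        raise ValueError(
            "candidate rule selected no genes; lower the threshold or raise k"
        )
    return chosen["gene"].tolist()


def build_causal_dataset(
    mut: MutationTable,
    y: ActivityVector | np.ndarray,
    target_gene: str,
    cfg: RunConfig,
) -> CausalDataset:
    """Assemble (X, M, Y) for one target gene.

    M is the target's column; X holds the ``cfg.n_confounders`` highest-rate
    genes excluding the target, all with rate >= ``cfg.min_mutation_rate``
    (fewer, with a warning, when the table is smaller).  Sample order is
    preserved from the mutation table, which must already be aligned with
    the activity vector.
    """
    yv = y.y if isinstance(y, ActivityVector) else np.asarray(y, dtype=float)
    if yv.shape[0] != mut.n_samples:
        raise ValueError("activity vector and mutation table sample counts differ")
    if target_gene not in mut.gene_ids:
        raise KeyError(f"target gene {target_gene!r} not in mutation table")
    rates = mutation_rates(mut)
    if rates[target_gene] < cfg.min_mutation_rate:
        raise ValueError(
            f"target gene {target_gene!r} has mutation rate "
            f"{rates[target_gene]:.4f}, below the floor {cfg.min_mutation_rate}"
        )
    eligible = rates.drop(target_gene)
    eligible = eligible[eligible >= cfg.min_mutation_rate]
    ordered = (
        eligible.rename("rate")
        .rename_axis("gene")
        .reset_index()
        .sort_values(["rate", "gene"], ascending=[False, True])
    )
    chosen = ordered.head(cfg.n_confounders)["gene"].tolist()
    if len(chosen) < cfg.n_confounders:
        logger.warning(
            "only %d eligible confounder genes available (requested %d)",
            len(chosen),
            cfg.n_confounders,
        )
    if not chosen:
        raise ValueError("no eligible confounder genes above the rate floor")
    col = {g: j for j, g in enumerate(mut.gene_ids)}
    X = mut.calls[:, [col[g] for g in chosen]]
    M = mut.gene_column(target_gene)
    return CausalDataset(
        X=X, M=M, Y=yv, sample_ids=list(mut.sample_ids), confounder_genes=chosen
    )


def mann_whitney_u(
    y: ActivityVector | np.ndarray, m: np.ndarray
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test of activity between the two groups.

    Returns (U for the mutated group, two-sided p).  Small no-tie problems
    (min group size <= 8) are solved by exact enumeration of the rank-sum
    distribution; larger or tied ones use the normal approximation with
    midranks, tie correction and continuity correction.
    """
    yv = y.y if isinstance(y, ActivityVector) else np.asarray(y, dtype=float)
    m = np.asarray(m).astype(bool).ravel()
    if m.shape[0] != yv.shape[0]:
        raise ValueError("length mismatch between activity and group vector")
    if m.sum() == 0 or (~m).sum() == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(yv[m], yv[~m], alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def rank_mutations(
    mut: MutationTable,
    y: ActivityVector | np.ndarray,
    candidates: Sequence[str],
    cfg: RunConfig,
) -> List[RankingRow]:
    """Replicate-aggregated ATE for every candidate, ranked by mean ATE.

    Each candidate's replicates use seeds ``base_seed + candidate_index *
    n_replicates + r`` so different genes never share an initialization.
    Per-gene failures (e.g. a split with a single treatment arm) are logged
    and skipped rather than aborting the ranking.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    yv = y.y if isinstance(y, ActivityVector) else np.asarray(y, dtype=float)
    rates = mutation_rates(mut)
    rows: List[dict] = []
    for gi, gene in enumerate(candidates):
        try:
            ds = build_causal_dataset(mut, yv, gene, cfg)
            gene_cfg = RunConfig(
                **{**cfg.to_dict(), "split_fractions": cfg.split_fractions,
                   "base_seed": cfg.base_seed + gi * cfg.n_replicates}
            )
            est: ATEEstimate = run_replicates(ds, gene_cfg)
            u, p = mann_whitney_u(yv, mut.gene_column(gene))
        except (ValueError, KeyError) as exc:
            logger.warning("skipping gene %s: %s", gene, exc)
            continue
        rows.append(
            {
                "gene": gene,
                "ate_mean": est.ate_mean,
                "ate_std": est.ate_std,
                "mutation_rate": float(rates[gene]),
                "mw_u": u,
                "mw_p": p,
            }
        )
        logger.info(
            "gene %s (%d/%d): ATE %.4f +/- %.4f",
            gene, gi + 1, len(candidates), est.ate_mean, est.ate_std,
        )
    rows.sort(key=lambda r: -r["ate_mean"])
    ranked = [RankingRow(rank=i + 1, **r) for i, r in enumerate(rows)]
    top = ranked[:10]
    logger.info(
        "top %d by ATE: %s", len(top), ", ".join(f"{r.gene}:{r.ate_mean:.3f}" for r in top)
    )
    return ranked


def ranking_to_frame(rows: Sequence[RankingRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "ate_mean": r.ate_mean,
                "ate_std": r.ate_std,
                "mutation_rate": r.mutation_rate,
                "mw_u": r.mw_u,
                "mw_p": r.mw_p,
                "rank": r.rank,
            }
            for r in rows
        ]
    )


def write_ranking(rows: Sequence[RankingRow], path, bh_column: bool = False) -> None:
    """Write the ranking TSV; ``bh_column`` adds a Benjamini-Hochberg column
    (clearly an extension: the core report carries raw p-values)."""
    df = ranking_to_frame(rows)
    if bh_column:
        p = df["mw_p"].to_numpy()
        order = np.argsort(p)
        q = np.empty_like(p)
        ranked_p = p[order] * len(p) / (np.arange(len(p)) + 1)
        q[order] = np.minimum.accumulate(ranked_p[::-1])[::-1]
        df["mw_p_bh"] = np.clip(q, 0, 1)
    df.to_csv(path, sep="\t", index=False)
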