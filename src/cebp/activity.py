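"""Per-sample biological-process activity via core-gene regression.

For a pathway of P genes measured on N samples the outcome of the causal
model — the activity of the process in each sample — is built in four steps:

1. Pairwise Pearson correlation of the P gene vectors, with two-sided
   p-values from the exact t transform ``r * sqrt((N-2) / (1-r^2))`` on
   N-2 degrees of freedom.
2. A per-gene "co-expression information" score: the signed sum of that
   gene's correlations to all other genes, keeping only pairs whose
   p-value clears a significance cutoff alpha (default 1e-3),

       score_j = sum_{i != j} r_ij * 1[s_ij < alpha].

3. Core-gene selection: the floor(P/2) genes with the highest scores
   (ties broken by ascending gene index) become the core set, and their
   cohort-mean expression forms the reference profile K.
4. Per-sample regression of the core expression vector u against K.  The
   literal objective min_y ||y*u - K||^2 gives y = <u,K>/<u,u>
   ("as_printed"); the more conventional orientation min_y ||u - y*K||^2
   gives y = <u,K>/<K,K> ("reversed").  Both are available and the choice
   is recorded on the result.

The ``CoreGeneActivity`` estimator wraps the whole procedure with an
sklearn-style fit/transform surface; the module-level functions expose each
step individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_DIRECTIONS = ("as_printed", "reversed")


@dataclass
class PathwayExpression:
    """Expression of one pathway: N samples x P genes."""

    U: np.ndarray
    gene_ids: List[str]
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("U shape does not match id lists")
        if len(self.gene_ids) < 4:
            raise ValueError("pathway needs at least 4 genes for core selection")
        zero_var = np.flatnonzero(self.U.std(axis=0) == 0)
        if zero_var.size:
            logger.warning(
                "pathway contains %d zero-variance gene(s): %s",
                zero_var.size,
                ", ".join(self.gene_ids[j] for j in zero_var[:5]),
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class CorrelationResult:
    """Pairwise Pearson coefficients R and two-sided p-values S (both P x P)."""

    R: np.ndarray
    S: np.ndarray


@dataclass
class CoreGeneSelection:
    """Outcome of core-gene scoring and selection."""

    scores: np.ndarray
    mean_expr: np.ndarray
    core_indices: List[int]
    alpha: float


@dataclass
class ReferenceProfile:
    """Cohort-mean expression of each core gene (length floor(P/2))."""

    values: np.ndarray


@dataclass
class ActivityVector:
    """Per-sample activity coefficients plus provenance."""

    y: np.ndarray
    direction: str
    core_genes: List[str] = field(default_factory=list)
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("activity values must be finite")


def correlation_with_pvalues(px: PathwayExpression) -> CorrelationResult:
    """All-pairs Pearson r with two-sided p-values over the pathway genes.

    Zero-variance genes get r = 0, p = 1 against every partner so that they
    can never pass the significance gate; the diagonal is r = 1, p = 0.
    """
    n = px.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples for p-values, got {n}")
    U = px.U
    sd = U.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(U, rowvar=False)
    R = np.where(np.isnan(R), 0.0, R)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    # two-sided p from t = r * sqrt((n-2)/(1-r^2)), df = n-2
    r2 = np.clip(R**2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(R) * np.sqrt((n - 2) / np.maximum(1.0 - r2, 1e-300))
    S = 2.0 * stats.t.sf(t, df=n - 2)
    S = np.clip(S, 0.0, 1.0)
    S[degenerate, :] = 1.0
    S[:, degenerate] = 1.0
    np.fill_diagonal(S, 0.0)
    return CorrelationResult(R=R, S=S)


def core_scores(corr: CorrelationResult, alpha: float = 1e-3) -> np.ndarray:
    """Signed sum of significant correlations for each gene, diagonal excluded."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    gate = (corr.S < alpha).astype(float)
    np.fill_diagonal(gate, 0.0)
    return (corr.R * gate).sum(axis=1)


def select_core_genes(
    scores: np.ndarray, mean_expr: np.ndarray, alpha: float
) -> CoreGeneSelection:
    """Pick the floor(P/2) genes with the highest scores.

    Ties are broken by ascending gene index (stable sort on descending
    score), so the selection is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    P = scores.size
    k = P // 2
    if k < 2:
        raise ValueError(f"P={P} would select {k} core genes; need at least 2")
    order = np.argsort(-scores, kind="stable")
    core = sorted(order[:k].tolist())
    return CoreGeneSelection(
        scores=scores, mean_expr=np.asarray(mean_expr, float),
        core_indices=core, alpha=alpha,
    )


def reference_profile(
    px: PathwayExpression, sel: CoreGeneSelection
) -> ReferenceProfile:
    """Cohort-mean expression of each selected core gene."""
    return ReferenceProfile(values=px.U[:, sel.core_indices].mean(axis=0))


def sample_activity(
    u_core: np.ndarray, profile: ReferenceProfile, direction: str = "as_printed"
) -> float:
    """Closed-form regression coefficient of one sample against the profile.

    ``as_printed``: y = argmin ||y*u - K||^2 = <u,K>/<u,u>.
    ``reversed``:   y = argmin ||u - y*K||^2 = <u,K>/<K,K>.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    u = np.asarray(u_core, dtype=float)
    K = np.asarray(profile.values, dtype=float)
    if u.shape != K.shape:
        raise ValueError(f"length mismatch: sample {u.shape} vs profile {K.shape}")
    if direction == "as_printed":
        denom = float(u @ u)
        if denom == 0.0:
            raise ZeroDivisionError(
                "sample core-gene vector is all zero; activity undefined"
            )
    else:
        denom = float(K @ K)
        if denom == 0.0:
            raise ZeroDivisionError(
                "reference profile is all zero; activity undefined"
            )
    return float(u @ K) / denom


class CoreGeneActivity:
    """Estimator scoring per-sample pathway activity by core-gene regression.

    Parameters
    ----------
    alpha : float, default 1e-3
        Significance cutoff on pairwise correlation p-values.
    direction : {"as_printed", "reversed"}, default "as_printed"
        Orientation of the per-sample regression (see module docstring).

    Attributes
    ----------
    core_indices_ : list of int
        Column indices of the selected core genes (floor(P/2) of them).
    core_genes_ : list of str
        Their identifiers.
    scores_ : ndarray of shape (P,)
        Per-gene significance-gated correlation sums.
    reference_profile_ : ndarray of shape (floor(P/2),)
        Cohort-mean expression of the core genes.
    """

    def __init__(self, alpha: float = 1e-3, direction: str = "as_printed"):
        self.alpha = alpha
        self.direction = direction

    # minimal sklearn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "direction": self.direction}

    def set_params(self, **params) -> "CoreGeneActivity":
        for k, v in params.items():
            if k not in ("alpha", "direction"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _as_pathway(self, X) -> PathwayExpression:
        if isinstance(X, PathwayExpression):
            return X
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        return PathwayExpression(
            U=X,
            gene_ids=[f"g{j}" for j in range(p)],
            sample_ids=[f"s{i}" for i in range(n)],
        )

    def fit(self, X, y=None) -> "CoreGeneActivity":
        """Select core genes and the reference profile from a pathway matrix."""
        px = self._as_pathway(X)
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        corr = correlation_with_pvalues(px)
        scores = core_scores(corr, self.alpha)
        sel = select_core_genes(scores, px.U.mean(axis=0), self.alpha)
        self.n_features_in_ = px.n_genes
        self.scores_ = scores
        self.core_indices_ = sel.core_indices
        self.core_genes_ = [px.gene_ids[j] for j in sel.core_indices]
        self.reference_profile_ = reference_profile(px, sel).values
        return self

    def transform(self, X) -> np.ndarray:
        """Per-sample activity coefficients for a (new) pathway matrix."""
        if not hasattr(self, "core_indices_"):
            raise RuntimeError("CoreGeneActivity is not fitted")
        px = self._as_pathway(X)
        if px.n_genes != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} genes, got {px.n_genes}"
            )
        profile = ReferenceProfile(values=self.reference_profile_)
        core = px.U[:, self.core_indices_]
        out = np.empty(px.n_samples)
        for i in range(px.n_samples):
            try:
                out[i] = sample_activity(core[i], profile, self.direction)
            except ZeroDivisionError as exc:
                raise ZeroDivisionError(
                    f"sample {px.sample_ids[i]!r}: {exc}"
                ) from None
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def estimate_activity(px: PathwayExpression, cfg=None) -> ActivityVector:
    """One-call pipeline: correlation -> scores -> core set -> regression.

    Returns the per-sample activity with the selected core genes, cutoff
    and regression direction recorded as provenance.
    """
    alpha = cfg.alpha if cfg is not None else 1e-3
    direction = cfg.activity_direction if cfg is not None else "as_printed"
    est = CoreGeneActivity(alpha=alpha, direction=direction)
    y = est.fit_transform(px)
    return ActivityVector(
        y=y, direction=direction, core_genes=est.core_genes_, alpha=alpha
    )


def write_activity(av: ActivityVector, sample_ids: Sequence[str], path) -> None:
    import pandas as pd

    pd.DataFrame({"sample_id": list(sample_ids), "activity": av.y}).to_csv(
        path, sep="\t", index=False
    )
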