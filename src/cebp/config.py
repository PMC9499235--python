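"""Run configuration shared across the pipeline.

A single dataclass holds every tunable the workflow exposes: the
correlation-significance cutoff used for core-gene selection, the size of the
observed-confounder block, the latent dimension and network shape of the
causal model, optimizer settings, and replicate/seed bookkeeping.  Values
default to the settings used throughout the analyses this package implements.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class RunConfig:
    """Configuration for activity scoring, causal-model training and ranking.

    Parameters
    ----------
    alpha:
        Two-sided significance cutoff on pairwise Pearson correlation
        p-values when accumulating core-gene scores.
    n_confounders:
        Number of highest-mutation-rate genes used as the observed
        confounder block ``X`` for each target gene.
    min_mutation_rate:
        Rate floor for both the treatment gene and every confounder gene
        (fraction of samples mutated).
    latent_dim:
        Dimension of the latent confounder ``z``.
    hidden_width, hidden_depth:
        Width and number of hidden layers of the main ELU networks.
    learning_rate, weight_decay:
        Adam settings; weight decay is an L2 penalty on all parameters.
    split_fractions:
        Train/validation/test fractions.
    n_replicates:
        Independent training runs aggregated into each ATE estimate.
    outcome_sd:
        Fixed standard deviation of the Gaussian outcome decoder: a positive
        float, or ``"auto"`` (default) to estimate it as the residual
        standard deviation of an ordinary least-squares fit of the outcome
        on the treatment and observed confounders.  The fixed variance acts
        as an inverse weight on the outcome-reconstruction term, so it must
        live on the scale of the activity values.
    n_mc_samples:
        Posterior draws per sample when predicting counterfactuals.
    activity_direction:
        ``"as_printed"`` regresses the reference profile on the sample
        (the literal objective), ``"reversed"`` regresses the sample on
        the reference profile.  See :mod:`cebp.activity`.
    """

    alpha: float = 1e-3
    n_confounders: int = 200
    min_mutation_rate: float = 0.01
    latent_dim: int = 20
    hidden_width: int = 200
    hidden_depth: int = 3
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    split_fractions: Tuple[float, float, float] = (0.7, 0.1, 0.2)
    n_replicates: int = 10
    outcome_sd: float | str = "auto"
    n_mc_samples: int = 100
    epochs: int = 300
    batch_size: int = 128
    patience: int = 30
    base_seed: int = 0
    activity_direction: str = "as_printed"
    standardize_outcome: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"split_fractions must sum to 1, got {self.split_fractions}"
            )
        for name in (
            "n_confounders",
            "latent_dim",
            "hidden_width",
            "hidden_depth",
            "n_replicates",
            "n_mc_samples",
            "epochs",
            "batch_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if isinstance(self.outcome_sd, str):
            if self.outcome_sd != "auto":
                raise ValueError("outcome_sd must be positive or 'auto'")
        elif self.outcome_sd <= 0:
            raise ValueError("outcome_sd must be positive")
        if self.activity_direction not in ("as_printed", "reversed"):
            raise ValueError(
                "activity_direction must be 'as_printed' or 'reversed'"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def write_provenance(self, path: str | Path, **extra) -> None:
        """Write a provenance JSON (config plus run metadata) next to results."""
        payload = {"config": self.to_dict(), **extra}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))
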