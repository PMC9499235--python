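"""Causal-effect variational autoencoder (CEVAE) for mutation effects.

The structural model assumes a latent confounder ``z`` that drives the
observed mutation background ``x`` (a binary proxy vector per sample), the
binary treatment ``m`` (whether the target gene is mutated), and — together
with ``m`` — the continuous outcome ``y`` (the biological-process activity).
Estimating the average treatment effect

    ATE = E[Y(m=1) - Y(m=0)]

then requires integrating out ``z``, which is recovered variationally:

* an inference network ``q(z | x, m, y)`` — a shared ELU trunk ``g(x, y)``
  feeding two arm-specific heads ``f0``/``f1`` that emit per-dimension
  posterior means and standard deviations;
* a generative network ``p(x|z) p(m|z) p(y|z, m)`` with Bernoulli decoders
  for ``x`` and ``m`` (logits through a final sigmoid) and a Gaussian
  outcome whose mean is arm-gated, ``m*f_y1(z) + (1-m)*f_y0(z)``, with
  fixed standard deviation;
* auxiliary networks ``q(m|x)`` and ``q(y|x, m)`` trained jointly so the
  posterior can also be evaluated when the outcome or treatment of a new
  sample is unknown.

Training maximizes the ELBO (reconstruction terms minus the closed-form
Gaussian KL to the standard-normal prior) plus the auxiliary
log-likelihoods, with Adam.  Counterfactual outcomes are posterior
expectations of the two outcome heads, and the ATE is their mean contrast
over all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._autodiff import Tensor
from ._nn import MLP, Adam
from .config import RunConfig

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
_SD_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# data container


@dataclass
class CausalDataset:
    """Aligned (X, M, Y) triple for one target gene."""

    X: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    sample_ids: Optional[List[str]] = None
    confounder_genes: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.M = np.asarray(self.M).ravel()
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = self.X.shape[0]
        if self.M.shape[0] != n or self.Y.shape[0] != n:
            raise ValueError("X, M, Y must agree on sample count")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("X must be binary")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("M must be binary")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("Y must be finite")
        if self.M.sum() == 0 or self.M.sum() == n:
            raise ValueError("both treatment arms must be nonempty")
        self.X = self.X.astype(float)
        self.M = self.M.astype(float)
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_confounders(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "CausalDataset":
        ids = [self.sample_ids[i] for i in idx] if self.sample_ids else None
        return CausalDataset(
            self.X[idx], self.M[idx], self.Y[idx], ids, self.confounder_genes
        )


@dataclass
class TrainTrace:
    """Per-epoch objective values and split bookkeeping for one training run."""

    train_loss: List[float]
    val_loss: List[float]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    best_epoch: int


@dataclass
class ATEEstimate:
    """Replicate-aggregated average treatment effect."""

    ate_mean: float
    ate_std: float
    per_replicate: np.ndarray
    n_mc: int


# ---------------------------------------------------------------------------
# parameters


class ModelParams:
    """All networks of one CEVAE instance.

    ``hidden_depth`` counts hidden ELU layers on the deep paths
    (q(z|x,m,y), q(y|x,m), p(x|z), p(y|z,m)); the treatment networks
    q(m|x) and p(m|z) always use a single hidden layer.
    """

    def __init__(self, n_confounders: int, latent_dim: int, cfg: RunConfig, seed: int):
        if latent_dim < 1 or n_confounders < 1:
            raise ValueError("latent_dim and n_confounders must be positive")
        if cfg.hidden_depth < 2:
            raise ValueError("hidden_depth must be at least 2 (trunk + head)")
        self.n_confounders = n_confounders
        self.latent_dim = latent_dim
        # "auto" is resolved from data by train(); standalone bundles fall
        # back to unit variance
        self.outcome_sd = 1.0 if cfg.outcome_sd == "auto" else float(cfg.outcome_sd)
        self.seed = seed
        W, D = cfg.hidden_width, cfg.hidden_depth
        K, d = n_confounders, latent_dim
        rng = np.random.default_rng(seed)

        # inference side ------------------------------------------------
        # shared trunk g(x, y): D-1 ELU layers (D-2 hidden + activated out)
        self.g_net = MLP(K + 1, W, W, D - 2, rng)
        # arm heads f0/f1: one hidden layer, emit (mu, raw-sd) per dim
        self.f0_net = MLP(W, 2 * d, W, 1, rng)
        self.f1_net = MLP(W, 2 * d, W, 1, rng)
        # auxiliary q(m|x): single hidden layer
        self.qm_net = MLP(K, 1, W, 1, rng)
        # auxiliary q(y|x, m): shared trunk + arm-specific linear heads
        self.qy_trunk = MLP(K, W, W, D - 2, rng)
        self.qy_h0 = MLP(W, 1, W, 1, rng)
        self.qy_h1 = MLP(W, 1, W, 1, rng)

        # generative side -----------------------------------------------
        self.px_net = MLP(d, K, W, D, rng)  # Bernoulli logits per proxy gene
        self.pm_net = MLP(d, 1, W, 1, rng)  # Bernoulli logit for treatment
        self.py0_net = MLP(d, 1, W, D, rng)  # outcome mean, untreated arm
        self.py1_net = MLP(d, 1, W, D, rng)  # outcome mean, treated arm

    @property
    def networks(self) -> Dict[str, MLP]:
        return {
            "g": self.g_net,
            "f0": self.f0_net,
            "f1": self.f1_net,
            "qm": self.qm_net,
            "qy_trunk": self.qy_trunk,
            "qy_h0": self.qy_h0,
            "qy_h1": self.qy_h1,
            "px": self.px_net,
            "pm": self.pm_net,
            "py0": self.py0_net,
            "py1": self.py1_net,
        }

    @property
    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for net in self.networks.values():
            out.extend(net.parameters)
        return out

    def state(self) -> Dict[str, List[np.ndarray]]:
        return {name: net.state() for name, net in self.networks.items()}

    def load_state(self, state: Dict[str, List[np.ndarray]]) -> None:
        for name, net in self.networks.items():
            net.load_state(state[name])

    def tie_outcome_arms(self) -> None:
        """Copy the untreated outcome head into the treated one (testing aid)."""
        self.py1_net.copy_from(self.py0_net)


def init_model(
    dims: Tuple[int, int], cfg: RunConfig, seed: int = 0
) -> ModelParams:
    """Build a CEVAE parameter bundle for (n_confounders, latent_dim)."""
    K, d = dims
    return ModelParams(K, d, cfg, seed)


# ---------------------------------------------------------------------------
# forward passes


def _elu_trunk(net: MLP, x: Tensor) -> Tensor:
    return net(x).elu()


def infer_posterior(
    x: np.ndarray, y: np.ndarray, m: np.ndarray, params: ModelParams
) -> Tuple[Tensor, Tensor]:
    """Per-sample posterior q(z | x, m, y) as a diagonal Gaussian (mu, sd).

    The shared trunk sees (x, y); samples are routed to the arm head
    matching their observed treatment.  Standard deviations go through a
    softplus with a small positive floor.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float).reshape(-1, 1)
    m = np.asarray(m, float).reshape(-1, 1)
    rep = _elu_trunk(params.g_net, Tensor(np.concatenate([x, y], axis=1)))
    out0 = params.f0_net(rep)
    out1 = params.f1_net(rep)
    gated = Tensor(m) * out1 + Tensor(1.0 - m) * out0
    d = params.latent_dim
    mu = _take_half(gated, d, 0)
    raw = _take_half(gated, d, 1)
    sd = raw.softplus() + _SD_FLOOR
    return mu, sd


def _take_half(t: Tensor, d: int, half: int) -> Tensor:
    """Slice columns [half*d, (half+1)*d) out of a (N, 2d) tensor."""
    sel = np.zeros((2 * d, d))
    sel[half * d : (half + 1) * d, :] = np.eye(d)
    return t @ Tensor(sel)


def decode(
    z: Tensor | np.ndarray, m: np.ndarray, params: ModelParams
) -> Tuple[Tensor, Tensor, Tensor]:
    """Generative heads at latent z: (x-logits, m-probability, y-mean).

    The treatment decoder ends in a sigmoid so its output is a valid
    Bernoulli probability; the outcome mean is arm-gated between the two
    outcome heads with fixed standard deviation ``params.outcome_sd``.
    """
    if not isinstance(z, Tensor):
        z = Tensor(np.atleast_2d(np.asarray(z, float)))
    m = np.asarray(m, float).reshape(-1, 1)
    x_logits = params.px_net(z)
    m_prob = params.pm_net(z).sigmoid()
    y0 = params.py0_net(z)
    y1 = params.py1_net(z)
    y_mean = Tensor(m) * y1 + Tensor(1.0 - m) * y0
    return x_logits, m_prob, y_mean


def _bernoulli_loglik(target: np.ndarray, logits: Tensor) -> Tensor:
    """Stable sum_j [t*logit - softplus(logit)] per row."""
    t = Tensor(target)
    return (t * logits - logits.softplus()).sum(axis=1)


def _gaussian_loglik(target: np.ndarray, mean: Tensor, sd: float) -> Tensor:
    diff = mean - Tensor(np.asarray(target, float).reshape(-1, 1))
    const = -0.5 * _LOG_2PI - float(np.log(sd))
    return ((diff * diff) * (-0.5 / sd**2) + const).sum(axis=1)


def gaussian_kl(mu: Tensor, sd: Tensor) -> Tensor:
    """Closed-form KL( N(mu, diag sd^2) || N(0, I) ) per sample."""
    var = sd * sd
    return ((mu * mu + var - sd.log() * 2.0 - 1.0) * 0.5).sum(axis=1)


def elbo(
    batch: CausalDataset | Tuple[np.ndarray, np.ndarray, np.ndarray],
    params: ModelParams,
    n_mc: int = 1,
    seed: int | np.random.Generator = 0,
) -> Tuple[Tensor, Dict[str, float]]:
    """Negative per-sample training objective on a batch, with term breakdown.

    The objective is the ELBO — reparameterized expectation of
    ``log p(x|z) + log p(m|z) + log p(y|m,z)`` minus the closed-form
    Gaussian KL to the standard-normal prior — plus the auxiliary
    log-likelihoods ``log q(m|x)`` and ``log q(y|x,m)``.  Returns the loss
    (negative mean objective) as a graph tensor plus a float breakdown.
    """
    if isinstance(batch, CausalDataset):
        x, m, y = batch.X, batch.M, batch.Y
    else:
        x, m, y = batch
    x = np.atleast_2d(np.asarray(x, float))
    m = np.asarray(m, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    mu, sd = infer_posterior(x, y, m, params)
    kl = gaussian_kl(mu, sd)

    m_col = m.reshape(-1, 1)
    rec_x = rec_m = rec_y = None
    for _ in range(n_mc):
        eta = rng.standard_normal(mu.shape)
        z = mu + sd * Tensor(eta)
        x_logits = params.px_net(z)
        m_logit = params.pm_net(z)
        y_mean = Tensor(m_col) * params.py1_net(z) + Tensor(1.0 - m_col) * params.py0_net(z)
        lx = _bernoulli_loglik(x, x_logits)
        lm = _bernoulli_loglik(m_col, m_logit)
        ly = _gaussian_loglik(y, y_mean, params.outcome_sd)
        rec_x = lx if rec_x is None else rec_x + lx
        rec_m = lm if rec_m is None else rec_m + lm
        rec_y = ly if rec_y is None else rec_y + ly
    inv = 1.0 / n_mc
    rec_x, rec_m, rec_y = rec_x * inv, rec_m * inv, rec_y * inv

    # auxiliary heads
    qm_logit = params.qm_net(Tensor(x))
    aux_m = _bernoulli_loglik(m.reshape(-1, 1), qm_logit)
    rep = _elu_trunk(params.qy_trunk, Tensor(x))
    qy_mean = Tensor(m.reshape(-1, 1)) * params.qy_h1(rep) + Tensor(
        1.0 - m.reshape(-1, 1)
    ) * params.qy_h0(rep)
    aux_y = _gaussian_loglik(y, qy_mean, params.outcome_sd)

    objective = rec_x + rec_m + rec_y - kl + aux_m + aux_y
    loss = -objective.mean()
    breakdown = {
        "rec_x": float(rec_x.data.mean()),
        "rec_m": float(rec_m.data.mean()),
        "rec_y": float(rec_y.data.mean()),
        "kl": float(kl.data.mean()),
        "aux_m": float(aux_m.data.mean()),
        "aux_y": float(aux_y.data.mean()),
        "loss": float(loss.data),
    }
    return loss, breakdown


# ---------------------------------------------------------------------------
# training


def _split_indices(
    n: int, fractions: Tuple[float, float, float], rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def train(
    ds: CausalDataset, cfg: RunConfig, seed: int = 0
) -> Tuple[ModelParams, TrainTrace]:
    """Fit the model with Adam and early stopping on the validation objective.

    The cohort is shuffled into train/validation/test splits by the seeded
    generator; parameters at the best validation epoch are returned.  If the
    validation split is empty (tiny cohorts) the training loss is monitored
    instead.
    """
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = _split_indices(
        ds.n_samples, cfg.split_fractions, rng
    )
    m_train = ds.M[train_idx]
    if m_train.sum() == 0 or m_train.sum() == m_train.size:
        raise ValueError(
            "training split contains a single treatment arm; re-seed or "
            "use a larger cohort"
        )

    y_mean, y_sd = 0.0, 1.0
    Y = ds.Y
    if cfg.standardize_outcome:
        y_mean, y_sd = float(Y.mean()), float(Y.std()) or 1.0
        Y = (Y - y_mean) / y_sd

    params = ModelParams(ds.n_confounders, cfg.latent_dim, cfg, seed=int(rng.integers(2**31)))
    params._y_scale = (y_mean, y_sd)  # provenance for prediction-time rescale
    opt = Adam(params.parameters, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    Xtr, Mtr, Ytr = ds.X[train_idx], ds.M[train_idx], Y[train_idx]
    Xva, Mva, Yva = ds.X[val_idx], ds.M[val_idx], Y[val_idx]
    if cfg.outcome_sd == "auto":
        # decoder variance on the outcome's own scale: residual sd of an
        # OLS fit of y on (1, m, X) over the training split
        A = np.column_stack([np.ones(len(train_idx)), Mtr, Xtr])
        beta, *_ = np.linalg.lstsq(A, Ytr, rcond=None)
        params.outcome_sd = max(float((Ytr - A @ beta).std()), 0.05)
    monitor_val = len(val_idx) > 0

    train_losses: List[float] = []
    val_losses: List[float] = []
    best_loss = np.inf
    best_state = params.state()
    best_epoch = 0
    patience_left = cfg.patience

    n_train = len(train_idx)
    bs = min(cfg.batch_size, n_train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, bs):
            idx = order[start : start + bs]
            opt.zero_grad()
            loss, _ = elbo((Xtr[idx], Mtr[idx], Ytr[idx]), params, n_mc=1, seed=rng)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        train_losses.append(epoch_loss / n_train)

        if monitor_val:
            vloss, _ = elbo((Xva, Mva, Yva), params, n_mc=1, seed=rng)
            monitored = float(vloss.data)
        else:
            monitored = train_losses[-1]
        val_losses.append(monitored)

        if monitored < best_loss - 1e-6:
            best_loss = monitored
            best_state = params.state()
            best_epoch = epoch
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    params.load_state(best_state)
    trace = TrainTrace(
        train_loss=train_losses,
        val_loss=val_losses,
        train_idx=train_idx,
        val_idx=val_idx,
        test_idx=test_idx,
        seed=seed,
        best_epoch=best_epoch,
    )
    return params, trace


# ---------------------------------------------------------------------------
# prediction

def _np_mlp(net: MLP, x: np.ndarray) -> np.ndarray:
    """Plain-numpy forward pass (no graph) for prediction-time speed."""
    h = x
    last = len(net.weights) - 1
    for k, (W, b) in enumerate(zip(net.weights, net.biases)):
        h = h @ W.data + b.data
        if k < last:
            h = np.where(h > 0, h, np.expm1(np.minimum(h, 0.0)))
    return h


def _np_posterior(
    params: ModelParams, x: np.ndarray, y: np.ndarray, m: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    d = params.latent_dim
    rep = _np_mlp(params.g_net, np.concatenate([x, y.reshape(-1, 1)], axis=1))
    rep = np.where(rep > 0, rep, np.expm1(np.minimum(rep, 0.0)))
    out0 = _np_mlp(params.f0_net, rep)
    out1 = _np_mlp(params.f1_net, rep)
    gated = m.reshape(-1, 1) * out1 + (1.0 - m.reshape(-1, 1)) * out0
    mu, raw = gated[:, :d], gated[:, d:]
    sd = np.logaddexp(0.0, raw) + _SD_FLOOR
    return mu, sd


def predict_counterfactuals(
    ds: CausalDataset,
    params: ModelParams,
    n_mc: int = 100,
    seed: int = 0,
    infer_from: str = "xym",
) -> Tuple[np.ndarray, np.ndarray]:
    """Posterior-mean outcomes under both arms for every sample.

    ``infer_from="xym"`` (default) conditions the posterior on each sample's
    observed (x, y, m).  ``infer_from="x"`` instead imputes the outcome with
    the auxiliary head q(y|x, m) before encoding, the route used when the
    outcome of a new sample is not yet measured.
    """
    rng = np.random.default_rng(seed)
    x, m, y = ds.X, ds.M, ds.Y
    y_mean, y_sd = getattr(params, "_y_scale", (0.0, 1.0))
    y_model = (y - y_mean) / y_sd

    if infer_from == "x":
        rep = _np_mlp(params.qy_trunk, x)
        rep = np.where(rep > 0, rep, np.expm1(np.minimum(rep, 0.0)))
        qy = m.reshape(-1, 1) * _np_mlp(params.qy_h1, rep) + (
            1.0 - m.reshape(-1, 1)
        ) * _np_mlp(params.qy_h0, rep)
        y_model = qy.ravel()
    elif infer_from != "xym":
        raise ValueError("infer_from must be 'xym' or 'x'")

    mu, sd = _np_posterior(params, x, y_model, m)
    acc0 = np.zeros(ds.n_samples)
    acc1 = np.zeros(ds.n_samples)
    for _ in range(n_mc):
        z = mu + sd * rng.standard_normal(mu.shape)
        acc0 += _np_mlp(params.py0_net, z).ravel()
        acc1 += _np_mlp(params.py1_net, z).ravel()
    y0 = acc0 / n_mc * y_sd + y_mean
    y1 = acc1 / n_mc * y_sd + y_mean
    return y0, y1


def estimate_ate(
    ds: CausalDataset,
    params: ModelParams,
    n_mc: int = 100,
    seed: int = 0,
    subset: Optional[np.ndarray] = None,
) -> float:
    """ATE = mean over samples of [ y-hat(m=1) - y-hat(m=0) ].

    Computed over all N samples by default; pass ``subset`` (e.g. the test
    split from the training trace) to restrict the population.
    """
    y0, y1 = predict_counterfactuals(ds, params, n_mc=n_mc, seed=seed)
    diff = y1 - y0
    if subset is not None:
        diff = diff[subset]
    return float(diff.mean())


def run_replicates(ds: CausalDataset, cfg: RunConfig) -> ATEEstimate:
    """Train-and-estimate ``cfg.n_replicates`` times; report mean and std.

    Replicate r uses seed ``base_seed + r`` for its split, initialization
    and Monte Carlo draws.  The std is the sample standard deviation of the
    per-replicate ATEs (0 with a warning when only one replicate is run).
    """
    if cfg.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ates = []
    for r in range(cfg.n_replicates):
        seed = cfg.base_seed + r
        params, _ = train(ds, cfg, seed=seed)
        ates.append(estimate_ate(ds, params, n_mc=cfg.n_mc_samples, seed=seed))
    per = np.asarray(ates)
    if len(per) == 1:
        logger.warning("single replicate: reporting std of 0")
        std = 0.0
    else:
        std = float(per.std(ddof=1))
    return ATEEstimate(
        ate_mean=float(per.mean()), ate_std=std, per_replicate=per, n_mc=cfg.n_mc_samples
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator wrapper


class CEVAE:
    """Sklearn-style estimator around :func:`train` / :func:`estimate_ate`.

    Parameters mirror :class:`cebp.config.RunConfig`; fitted attributes are
    ``params_`` (the network bundle), ``trace_`` (the training trace) and
    ``ate_`` (the post-fit ATE over all samples).

    Examples
    --------
    >>> est = CEVAE(latent_dim=5, hidden_width=32, epochs=50, random_state=0)
    >>> est.fit(X, m, y)                      # doctest: +SKIP
    >>> est.ate_                              # doctest: +SKIP
    """

    _PARAM_NAMES = (
        "latent_dim",
        "hidden_width",
        "hidden_depth",
        "learning_rate",
        "weight_decay",
        "outcome_sd",
        "epochs",
        "batch_size",
        "patience",
        "split_fractions",
        "n_mc_samples",
        "standardize_outcome",
        "random_state",
    )

    def __init__(
        self,
        latent_dim: int = 20,
        hidden_width: int = 200,
        hidden_depth: int = 3,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-4,
        outcome_sd: float = 1.0,
        epochs: int = 300,
        batch_size: int = 128,
        patience: int = 30,
        split_fractions: Tuple[float, float, float] = (0.7, 0.1, 0.2),
        n_mc_samples: int = 100,
        standardize_outcome: bool = False,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden_width = hidden_width
        self.hidden_depth = hidden_depth
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.outcome_sd = outcome_sd
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.split_fractions = split_fractions
        self.n_mc_samples = n_mc_samples
        self.standardize_outcome = standardize_outcome
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAM_NAMES}

    def set_params(self, **params) -> "CEVAE":
        for k, v in params.items():
            if k not in self._PARAM_NAMES:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> RunConfig:
        return RunConfig(
            latent_dim=self.latent_dim,
            hidden_width=self.hidden_width,
            hidden_depth=self.hidden_depth,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            outcome_sd=self.outcome_sd,
            epochs=self.epochs,
            batch_size=self.batch_size,
            patience=self.patience,
            split_fractions=self.split_fractions,
            n_mc_samples=self.n_mc_samples,
            standardize_outcome=self.standardize_outcome,
            base_seed=self.random_state,
        )

    @staticmethod
    def _as_dataset(X, m=None, y=None) -> CausalDataset:
        if isinstance(X, CausalDataset):
            return X
        return CausalDataset(X, m, y)

    def fit(self, X, m=None, y=None) -> "CEVAE":
        """Train on (X, m, y) or a :class:`CausalDataset`."""
        ds = self._as_dataset(X, m, y)
        self.params_, self.trace_ = train(ds, self._config(), seed=self.random_state)
        self.n_features_in_ = ds.n_confounders
        self.ate_ = estimate_ate(
            ds, self.params_, n_mc=self.n_mc_samples, seed=self.random_state
        )
        return self

    def predict_counterfactuals(self, X, m=None, y=None, **kw):
        self._check_fitted()
        ds = self._as_dataset(X, m, y)
        kw.setdefault("n_mc", self.n_mc_samples)
        kw.setdefault("seed", self.random_state)
        return predict_counterfactuals(ds, self.params_, **kw)

    def estimate_ate(self, X, m=None, y=None, **kw) -> float:
        self._check_fitted()
        ds = self._as_dataset(X, m, y)
        kw.setdefault("n_mc", self.n_mc_samples)
        kw.setdefault("seed", self.random_state)
        return estimate_ate(ds, self.params_, **kw)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("CEVAE is not fitted")
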