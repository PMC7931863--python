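"""Variational autoencoder for heterogeneous, incomplete tabular data.

One model is trained per variable module. Each variable gets a
type-specific likelihood head (Gaussian, log-normal, Poisson, multinomial,
cumulative-link ordinal), the latent prior is a mixture of Gaussians with
``K`` components (a categorical code ``s`` selects the component; ``K=1``
reduces exactly to a standard-normal prior), and the reconstruction term of
the ELBO sums only over observed cells, so unobserved values never
influence the fit (input-dropout handling of missing data).

Training runs on a small numpy autodiff engine and keeps *per-example*
gradients throughout, which lets the differentially private variant
(:mod:`vambn.privacy`) reuse the identical loop with gradient clipping and
noise in place of plain averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln
from sklearn.model_selection import KFold

from ._autodiff import Var, concat, logsumexp
from .data_io import VariableSpec

_VAR_EPS = 1e-4   # variance floor inside softplus heads
_SD_FLOOR = 1e-8  # floor for observed standard deviations
SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# configuration & model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HivaeConfig:
    """Hyperparameters of one per-module VAE.

    latent_dim defaults to 1: module embeddings must stay low-dimensional
    so that each module contributes a single Gaussian node to the Bayesian
    network layer.
    """

    latent_dim: int = 1
    n_components: int = 1
    hidden_dim: int = 16
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if (min(self.latent_dim, self.n_components, self.hidden_dim,
                self.batch_size) < 1 or self.learning_rate <= 0
                or self.epochs < 0):
            raise ValueError("HivaeConfig fields out of range")


@dataclass(frozen=True)
class LatentCode:
    """Posterior code of one row: continuous z and 1-based component s."""

    z: np.ndarray
    s: int


@dataclass
class HivaeModel:
    config: HivaeConfig
    specs: list  # list[VariableSpec], column order of the training slice
    params: dict  # name -> ndarray
    norm_stats: list  # per-column dict with keys depending on vtype
    loss_trace_: list = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return len(self.specs)


# ---------------------------------------------------------------------------
# preprocessing: raw object cells -> numeric arrays
# ---------------------------------------------------------------------------

def _observed_stats(X: np.ndarray, mask: np.ndarray, specs) -> list:
    """Per-variable normalization statistics from observed cells only."""
    stats = []
    for j, sp in enumerate(specs):
        obs = mask[:, j]
        if not obs.any():
            raise ValueError(f"variable {sp.name!r} has zero observed cells")
        vals = X[obs, j]
        st = {"vtype": sp.vtype}
        if sp.vtype == "real":
            v = vals.astype(np.float64)
            st["mean"], st["sd"] = float(v.mean()), max(float(v.std()), _SD_FLOOR)
        elif sp.vtype == "positive":
            v = np.log(vals.astype(np.float64))
            st["mean"], st["sd"] = float(v.mean()), max(float(v.std()), _SD_FLOOR)
        elif sp.vtype == "count":
            v = np.log1p(vals.astype(np.float64))
            st["mean"], st["sd"] = float(v.mean()), max(float(v.std()), _SD_FLOOR)
            st["log_rate0"] = float(np.log(vals.astype(np.float64).mean() + 0.1))
        else:
            st["levels"] = list(sp.levels)
        stats.append(st)
    return stats


def _numeric_views(X: np.ndarray, mask: np.ndarray, specs, stats):
    """Encoder input and likelihood-target arrays.

    Masked cells are filled with zeros (or level index 0) *after*
    normalization; since every loss term is multiplied by the mask, the
    fill value provably never reaches a gradient or an output.
    """
    n = X.shape[0]
    xin_cols, targets = [], []
    for j, (sp, st) in enumerate(zip(specs, stats)):
        obs = mask[:, j]
        if sp.vtype in ("real", "positive", "count"):
            raw = np.zeros(n)
            raw[obs] = X[obs, j].astype(np.float64)
            if sp.vtype == "real":
                z = (raw - st["mean"]) / st["sd"]
                tgt = z.copy()
            elif sp.vtype == "positive":
                lg = np.zeros(n)
                lg[obs] = np.log(raw[obs])
                z = (lg - st["mean"]) / st["sd"]
                tgt = z.copy()
            else:  # count
                z = (np.log1p(raw) - st["mean"]) / st["sd"]
                tgt = raw.copy()
            z[~obs] = 0.0
            tgt[~obs] = 0.0
            xin_cols.append(z[:, None])
            targets.append(tgt)
        else:
            L = len(st["levels"])
            idx = np.zeros(n, dtype=np.int64)
            lut = {lab: k for k, lab in enumerate(st["levels"])}
            for i in np.nonzero(obs)[0]:
                idx[i] = lut[X[i, j]]
            onehot = np.zeros((n, L))
            onehot[np.arange(n), idx] = 1.0
            onehot[~obs] = 0.0
            xin_cols.append(onehot)
            targets.append(idx)
    return np.concatenate(xin_cols, axis=1), targets


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _input_dim(specs, stats) -> int:
    return sum(
        len(st["levels"]) if sp.vtype in ("categorical", "ordinal") else 1
        for sp, st in zip(specs, stats)
    )


def _softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


def _init_params(specs, stats, cfg: HivaeConfig, rng) -> dict:
    Din, H, L, K = _input_dim(specs, stats), cfg.hidden_dim, cfg.latent_dim, cfg.n_components

    def w(a, b):
        return rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b))

    p = {
        "enc_W1": w(Din, H), "enc_b1": np.zeros((1, H)),
        "enc_Ws": w(H, K), "enc_bs": np.zeros((1, K)),
        "enc_Wm": w(H, L), "enc_bm": np.zeros((1, L)),
        "enc_Wv": w(H, L), "enc_bv": np.zeros((1, L)),
        "dec_V1": w(L + K, H), "dec_c1": np.zeros((1, H)),
    }
    if K > 1:
        p["prior_mu"] = rng.normal(0.0, 1.0, size=(K, L))
    for j, (sp, st) in enumerate(zip(specs, stats)):
        if sp.vtype in ("real", "positive"):
            p[f"head_W{j}"] = w(H, 2)
            p[f"head_b{j}"] = np.zeros((1, 2))
        elif sp.vtype == "count":
            p[f"head_W{j}"] = w(H, 1)
            p[f"head_b{j}"] = np.array([[st["log_rate0"]]])
        elif sp.vtype == "categorical":
            Lj = len(st["levels"])
            p[f"head_W{j}"] = w(H, Lj)
            p[f"head_b{j}"] = np.zeros((1, Lj))
        else:  # ordinal
            Lj = len(st["levels"])
            p[f"head_W{j}"] = w(H, 1)
            p[f"head_b{j}"] = np.zeros((1, 1))
            thr = np.full((1, Lj - 1), _softplus_inv(2.0 / max(Lj - 1, 1)))
            thr[0, 0] = -1.0
            p[f"head_t{j}"] = thr
    return p


# ---------------------------------------------------------------------------
# tape forward: per-row ELBO with per-example parameter replicas
# ---------------------------------------------------------------------------

def _replicate(params: dict, n: int) -> dict:
    """Wrap each parameter as a Var broadcast to a leading batch axis.

    After backward(), ``var.grad[i]`` is the gradient of row i's loss
    contribution — per-example gradients for free.
    """
    out = {}
    for k, v in params.items():
        out[k] = Var(np.broadcast_to(v, (n,) + v.shape))
    return out


_LOG2PI = float(np.log(2.0 * np.pi))


def _head_loglik(j, sp, st, g, targets, n):
    """Log-likelihood column (n,1) of variable j under its head, via tape Vars."""
    pv = _head_loglik.params
    W, b = pv[f"head_W{j}"], pv[f"head_b{j}"]
    if sp.vtype in ("real", "positive"):
        out = g @ W + b  # (n,1,2)
        mu = out[:, :, 0:1]
        var = out[:, :, 1:2].softplus() + _VAR_EPS
        x = targets[j].reshape(n, 1, 1)
        ll = (var.log() + (mu - x) ** 2 / var + _LOG2PI) * (-0.5)
        return ll.reshape(n, 1)
    if sp.vtype == "count":
        eta = (g @ W + b).clip(-15.0, 15.0).reshape(n, 1)
        x = targets[j].reshape(n, 1)
        const = -gammaln(targets[j] + 1.0).reshape(n, 1)
        return eta * x - eta.exp() + const
    if sp.vtype == "categorical":
        Lj = len(st["levels"])
        logits = (g @ W + b).reshape(n, Lj)
        ll = logits[(np.arange(n), targets[j])] - logsumexp(logits, axis=1)
        return ll.reshape(n, 1)
    # ordinal: cumulative-link with ordered thresholds
    Lj = len(st["levels"])
    thr = pv[f"head_t{j}"]  # (n,1,Lj-1)
    pieces = [thr[:, :, 0:1]]
    for k in range(1, Lj - 1):
        pieces.append(pieces[-1] + thr[:, :, k : k + 1].softplus())
    theta = concat(pieces, axis=2) if Lj > 2 else pieces[0]  # (n,1,Lj-1)
    eta = (g @ W + b).clip(-30.0, 30.0)  # (n,1,1)
    cdf = (theta - eta).sigmoid().reshape(n, Lj - 1)
    ones = Var(np.ones((n, 1)))
    zeros = Var(np.zeros((n, 1)))
    upper = concat([cdf, ones], axis=1)
    lower = concat([zeros, cdf], axis=1)
    probs = upper - lower  # (n,Lj)
    ll = (probs[(np.arange(n), targets[j])] + 1e-12).log()
    return ll.reshape(n, 1)


def _elbo_rows(params_np: dict, xin, targets, mask, specs, stats,
               cfg: HivaeConfig, eps: np.ndarray, kl_weight: float = 1.0):
    """Per-row ELBO as a Var vector (n,), plus the replicated param Vars."""
    n = xin.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    K, L = cfg.n_components, cfg.latent_dim
    pv = _replicate(params_np, n)
    _head_loglik.params = pv

    x3 = xin.reshape(n, 1, -1)
    h = (Var(x3) @ pv["enc_W1"] + pv["enc_b1"]).tanh()  # (n,1,H)
    s_logits = (h @ pv["enc_Ws"] + pv["enc_bs"]).reshape(n, K)
    log_qs = s_logits - logsumexp(s_logits, axis=1, keepdims=True)
    qs = log_qs.exp()
    mu = h @ pv["enc_Wm"] + pv["enc_bm"]  # (n,1,L)
    logvar = (h @ pv["enc_Wv"] + pv["enc_bv"]).clip(-10.0, 10.0)
    sd = (logvar * 0.5).exp()
    z = mu + sd * eps.reshape(n, 1, L)

    # KL(q(s|x) || Uniform(K))
    kl_s = (qs * (log_qs + np.log(K))).sum(axis=1) if K > 1 else Var(np.zeros(n))

    total = None
    for k in range(K):
        onehot = np.zeros((n, 1, K))
        onehot[:, :, k] = 1.0
        g = (concat([z, Var(onehot)], axis=2) @ pv["dec_V1"] + pv["dec_c1"]).tanh()
        rec = None
        for j, sp in enumerate(specs):
            ll = _head_loglik(j, sp, stats[j], g, targets, n)
            ll = ll * mask[:, j : j + 1].astype(np.float64)
            rec = ll if rec is None else rec + ll
        rec = rec.reshape(n)
        if K > 1:
            pm = pv["prior_mu"][:, k : k + 1, :]  # (n,1,L)
        else:
            pm = Var(np.zeros((n, 1, L)))
        kl_z = ((logvar.exp() + (mu - pm) ** 2 - 1.0 - logvar) * 0.5).sum(axis=2)
        kl_z = kl_z.reshape(n)
        term = (rec - kl_z * kl_weight) * qs[(np.arange(n), np.full(n, k))]
        total = term if total is None else total + term
    rows = total - kl_s * kl_weight
    _head_loglik.params = None
    return rows, pv


def elbo(model: HivaeModel, X: np.ndarray, mask: np.ndarray,
         n_samples: int = 1, seed: int | None = None) -> float:
    """Evidence lower bound of a slice, summed over rows.

    The reconstruction term uses ``n_samples`` reparameterized draws whose
    noise is seeded (default: the model's own seed), so repeated calls on
    identical inputs agree bit-for-bit. Masked cells are excluded from the
    reconstruction term by construction; rows with no observed cell
    contribute only their KL terms.
    """
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    xin, targets = _numeric_views(X, mask, model.specs, model.norm_stats)
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    total = 0.0
    for _ in range(n_samples):
        eps = rng.standard_normal((X.shape[0], model.config.latent_dim))
        rows, _ = _elbo_rows(model.params, xin, targets, mask, model.specs,
                             model.norm_stats, model.config, eps)
        total += float(rows.data.sum())
    return total / n_samples


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam on a dict of arrays."""

    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _mean_aggregator(per_ex: dict, batch_size: int) -> dict:
    """Average per-example gradients (the non-private step)."""
    return {k: g.sum(axis=0) / batch_size for k, g in per_ex.items()}


def fit_hivae(X: np.ndarray, mask: np.ndarray, specs, cfg: HivaeConfig,
              aggregator=None, step_hook=None) -> HivaeModel:
    """Train a VAE on an object-array slice by stochastic gradient ascent.

    ``aggregator(per_example_grads, batch_size) -> grads`` turns the
    per-example gradient set of a minibatch into one update; the default
    averages them, and the differentially private trainer substitutes
    clipping plus noise. Deterministic given ``cfg.seed``.
    """
    X = np.asarray(X, dtype=object)
    mask = np.asarray(mask, dtype=bool)
    specs = list(specs)
    stats = _observed_stats(X, mask, specs)
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(specs, stats, cfg, rng)
    xin, targets = _numeric_views(X, mask, specs, stats)
    n = X.shape[0]
    opt = Adam(params, cfg.learning_rate)
    agg = aggregator or _mean_aggregator
    trace = []
    warmup = max(cfg.epochs // 4, 1)
    for epoch in range(cfg.epochs):
        # KL warm-up: ramp the KL weight to 1 over the first quarter of
        # training so the codes stay informative (guards against collapse)
        kl_w = min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for a in range(0, n, cfg.batch_size):
            idx = order[a : a + cfg.batch_size]
            eps = rng.standard_normal((len(idx), cfg.latent_dim))
            rows, pv = _elbo_rows(
                params, xin[idx], [t[idx] for t in targets], mask[idx],
                specs, stats, cfg, eps, kl_weight=kl_w,
            )
            loss = -rows.sum()  # total negative ELBO of the minibatch
            loss.backward()
            # pv[k].grad[i] is the gradient of row i's loss contribution
            per_ex = {k: pv[k].grad for k in params}
            grads = agg(per_ex, len(idx))
            opt.step(params, grads)
            ep_loss += float(loss.data) / len(idx)
            n_batches += 1
            if step_hook is not None:
                step_hook()
        trace.append(ep_loss / n_batches)
    return HivaeModel(cfg, specs, params, stats, trace)


# ---------------------------------------------------------------------------
# numpy (tape-free) forward passes for evaluation, encoding and decoding
# ---------------------------------------------------------------------------

def _np_softplus(x):
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _np_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _encoder_np(model: HivaeModel, xin: np.ndarray):
    p = model.params
    h = np.tanh(xin @ p["enc_W1"] + p["enc_b1"])
    s_logits = h @ p["enc_Ws"] + p["enc_bs"]
    s_logits = s_logits - s_logits.max(axis=1, keepdims=True)
    qs = np.exp(s_logits)
    qs /= qs.sum(axis=1, keepdims=True)
    mu = h @ p["enc_Wm"] + p["enc_bm"]
    logvar = np.clip(h @ p["enc_Wv"] + p["enc_bv"], -10, 10)
    return qs, mu, logvar


def _decoder_hidden(model: HivaeModel, z: np.ndarray, s_idx: np.ndarray):
    p = model.params
    K = model.config.n_components
    onehot = np.zeros((z.shape[0], K))
    onehot[np.arange(z.shape[0]), s_idx] = 1.0
    return np.tanh(np.concatenate([z, onehot], axis=1) @ p["dec_V1"] + p["dec_c1"])


def _head_params_np(model: HivaeModel, j: int, g: np.ndarray):
    p, sp, st = model.params, model.specs[j], model.norm_stats[j]
    W, b = p[f"head_W{j}"], p[f"head_b{j}"]
    out = g @ W + b
    if sp.vtype in ("real", "positive"):
        return out[:, 0], _np_softplus(out[:, 1]) + _VAR_EPS
    if sp.vtype == "count":
        return (np.exp(np.clip(out[:, 0], -15, 15)),)
    if sp.vtype == "categorical":
        logits = out - out.max(axis=1, keepdims=True)
        pr = np.exp(logits)
        return (pr / pr.sum(axis=1, keepdims=True),)
    Lj = len(st["levels"])
    thr = p[f"head_t{j}"][0]
    theta = np.concatenate([[thr[0]], thr[0] + np.cumsum(_np_softplus(thr[1:]))])
    eta = np.clip(out[:, 0], -30, 30)
    cdf = _np_sigmoid(theta[None, :] - eta[:, None])
    upper = np.concatenate([cdf, np.ones((g.shape[0], 1))], axis=1)
    lower = np.concatenate([np.zeros((g.shape[0], 1)), cdf], axis=1)
    return (np.maximum(upper - lower, 1e-12),)


def encode(model: HivaeModel, X: np.ndarray, mask: np.ndarray) -> list[LatentCode]:
    """Deterministic posterior codes: z = posterior mean, s = argmax component."""
    X = np.asarray(X, dtype=object)
    xin, _ = _numeric_views(X, mask, model.specs, model.norm_stats)
    qs, mu, _ = _encoder_np(model, xin)
    s = qs.argmax(axis=1)
    return [LatentCode(mu[i].copy(), int(s[i]) + 1) for i in range(X.shape[0])]


def decode(model: HivaeModel, codes: list[LatentCode], mode: str = "sample",
           rng=None) -> np.ndarray:
    """Map latent codes back to the original variable space.

    mode="sample" draws from each head distribution; mode="expectation"
    returns its mean (continuous; the log-normal head returns its median so
    the output stays on the data scale), rounded mean (counts) or mode
    (discrete). Numeric outputs are de-normalized to original units.
    """
    if mode not in ("sample", "expectation"):
        raise ValueError(f"unknown decode mode {mode!r}")
    K = model.config.n_components
    for c in codes:
        if not 1 <= c.s <= K:
            raise ValueError(f"component label {c.s} outside [1..{K}]")
    if rng is None:
        rng = np.random.default_rng(model.config.seed)
    z = np.stack([c.z for c in codes])
    s_idx = np.array([c.s - 1 for c in codes])
    g = _decoder_hidden(model, z, s_idx)
    n = z.shape[0]
    out = np.empty((n, model.n_variables), dtype=object)
    for j, (sp, st) in enumerate(zip(model.specs, model.norm_stats)):
        hp = _head_params_np(model, j, g)
        if sp.vtype in ("real", "positive"):
            mu, var = hp
            x = rng.normal(mu, np.sqrt(var)) if mode == "sample" else mu
            x = x * st["sd"] + st["mean"]
            vals = np.exp(x) if sp.vtype == "positive" else x
            out[:, j] = [float(v) for v in vals]
        elif sp.vtype == "count":
            lam = hp[0]
            vals = rng.poisson(lam) if mode == "sample" else np.rint(lam)
            out[:, j] = [int(max(v, 0)) for v in vals]
        else:
            probs = hp[0]
            if mode == "sample":
                cum = probs.cumsum(axis=1)
                u = rng.random((n, 1))
                idx = (u > cum).sum(axis=1)
            else:
                idx = probs.argmax(axis=1)
            labels = st["levels"]
            out[:, j] = [labels[int(i)] for i in idx]
    return out


def reconstruction_loglik(model: HivaeModel, X: np.ndarray,
                          mask: np.ndarray) -> np.ndarray:
    """Per-row masked log-likelihood at the deterministic code (z=mu, hard s)."""
    X = np.asarray(X, dtype=object)
    xin, targets = _numeric_views(X, mask, model.specs, model.norm_stats)
    qs, mu, _ = _encoder_np(model, xin)
    g = _decoder_hidden(model, mu, qs.argmax(axis=1))
    n = X.shape[0]
    total = np.zeros(n)
    for j, (sp, st) in enumerate(zip(model.specs, model.norm_stats)):
        hp = _head_params_np(model, j, g)
        if sp.vtype in ("real", "positive"):
            m_, v_ = hp
            ll = -0.5 * (np.log(v_) + (targets[j] - m_) ** 2 / v_ + _LOG2PI)
        elif sp.vtype == "count":
            lam = hp[0]
            ll = targets[j] * np.log(lam) - lam - gammaln(targets[j] + 1.0)
        else:
            ll = np.log(hp[0][np.arange(n), targets[j]])
        total += ll * mask[:, j]
    return total


# ---------------------------------------------------------------------------
# hyperparameter selection
# ---------------------------------------------------------------------------

def select_hyperparameters(X: np.ndarray, mask: np.ndarray, specs,
                           grid: list[HivaeConfig], n_folds: int = 3,
                           seed: int = 0) -> HivaeConfig:
    """Pick the grid entry with lowest mean held-out reconstruction loss.

    Fold assignment is seeded and shared across grid entries; ties break by
    grid order. The default grid of the training pipeline crosses learning
    rate {0.01, 0.001} with minibatch size {16, 32}.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    X = np.asarray(X, dtype=object)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    losses = []
    for cfg in grid:
        fold_losses = []
        for tr, te in kf.split(X):
            model = fit_hivae(X[tr], mask[tr], specs, cfg)
            ll = reconstruction_loglik(model, X[te], mask[te])
            n_obs = mask[te].sum()
            fold_losses.append(-ll.sum() / max(n_obs, 1))
        losses.append(float(np.mean(fold_losses)))
    return grid[int(np.argmin(losses))]


DEFAULT_GRID = [
    replace(HivaeConfig(), learning_rate=lr, batch_size=bs)
    for lr in (0.01, 0.001)
    for bs in (16, 32)
]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: HivaeModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config": model.config.__dict__,
        "specs": [
            {
                "name": s.name, "vtype": s.vtype, "module": s.module,
                "visits": list(s.visits), "levels": list(s.levels),
            }
            for s in model.specs
        ],
        "norm_stats": model.norm_stats,
        "params": {k: v.tolist() for k, v in model.params.items()},
        "loss_trace": model.loss_trace_,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> HivaeModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported model schema version")
    specs = [
        VariableSpec(
            name=s["name"], vtype=s["vtype"], module=s["module"],
            visits=tuple(s["visits"]), levels=tuple(s["levels"]),
        )
        for s in doc["specs"]
    ]
    params = {k: np.asarray(v, dtype=np.float64) for k, v in doc["params"].items()}
    return HivaeModel(HivaeConfig(**doc["config"]), specs, params,
                      doc["norm_stats"], doc["loss_trace"])
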