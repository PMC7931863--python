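"""Differentially private VAE training and (epsilon, delta) accounting.

Per-example gradients are rescaled to a global-norm bound C, summed, and
perturbed with isotropic Gaussian noise of sd = noise_multiplier * C
before averaging — the gradient-perturbation recipe of DP-SGD. Privacy is
tracked with a Renyi-DP accountant for the subsampled Gaussian mechanism
(exact integer-order moments, converted to (epsilon, delta)); for full
batches (sampling rate 1) the tight analytic Gaussian-mechanism bound is
used instead. Guarantees compose across the per-module models: basic
composition adds the (epsilon, delta) budgets.

The MBN stage consumes only codes produced by DP-trained encoders; its own
released parameters are NOT separately privatized — the guarantee reported
here covers the VAE training step, and whole-model claims rest on the
composition over those components only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .hivae import HivaeConfig, HivaeModel, fit_hivae

_RDP_ORDERS = tuple(range(2, 129))


@dataclass(frozen=True)
class DpConfig:
    noise_multiplier: float
    clip_norm: float
    delta: float
    sampling_rate: float
    epochs: int = 1

    def __post_init__(self):
        if self.noise_multiplier < 0 or self.clip_norm <= 0:
            raise ValueError("noise_multiplier >= 0 and clip_norm > 0 required")
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if not 0 < self.sampling_rate <= 1:
            raise ValueError("sampling_rate must lie in (0, 1]")


# ---------------------------------------------------------------------------
# the noisy aggregation step
# ---------------------------------------------------------------------------

def _as_dict(per_example):
    if isinstance(per_example, dict):
        return per_example
    return {"_g": np.asarray(per_example, dtype=np.float64)}


def clip_factors(per_example: dict, clip_norm: float) -> np.ndarray:
    """Per-example rescale factors min(1, C / ||g_i||) over the global norm."""
    sq = None
    for g in per_example.values():
        s = (g**2).reshape(g.shape[0], -1).sum(axis=1)
        sq = s if sq is None else sq + s
    norms = np.sqrt(sq)
    return np.minimum(1.0, clip_norm / np.maximum(norms, 1e-30))


def dp_step(per_example, config: DpConfig, rng) -> dict | np.ndarray:
    """Clip, sum, noise and average one batch of per-example gradients.

    Each per-example gradient is rescaled to global norm <= clip_norm; the
    clipped gradients are summed, isotropic Gaussian noise with
    sd = noise_multiplier * clip_norm is added (none when the multiplier is
    zero), and the result is divided by the batch size. With multiplier 0
    and a clip bound above every norm this reduces exactly to the plain
    mean gradient.
    """
    gd = _as_dict(per_example)
    b = next(iter(gd.values())).shape[0]
    if b == 0:
        raise ValueError("empty batch")
    factors = clip_factors(gd, config.clip_norm)
    out = {}
    sd = config.noise_multiplier * config.clip_norm
    for k, g in gd.items():
        f = factors.reshape((b,) + (1,) * (g.ndim - 1))
        total = (g * f).sum(axis=0)
        if config.noise_multiplier > 0:
            total = total + rng.normal(0.0, sd, size=total.shape)
        out[k] = total / b
    if not isinstance(per_example, dict):
        return out["_g"]
    return out


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def _rdp_subsampled_gaussian(q: float, sigma: float, order: int) -> float:
    """Renyi divergence bound of one subsampled-Gaussian step at integer order.

    Exact binomial moment expansion: the order-a moment of the privacy loss
    is sum_k C(a,k) (1-q)^(a-k) q^k exp(k(k-1) / (2 sigma^2)).
    """
    if q == 1.0:
        return order / (2.0 * sigma**2)
    terms = []
    for k in range(order + 1):
        log_binom = (gammaln(order + 1) - gammaln(k + 1)
                     - gammaln(order - k + 1))
        terms.append(
            log_binom + k * math.log(q) + (order - k) * math.log1p(-q)
            + k * (k - 1) / (2.0 * sigma**2)
        )
    m = max(terms)
    log_a = m + math.log(sum(math.exp(t - m) for t in terms))
    return log_a / (order - 1)


def analytic_gaussian_epsilon(sigma: float, delta: float) -> float:
    """Tight (epsilon, delta) of the Gaussian mechanism at sensitivity 1.

    Solves delta = Phi(1/(2 sigma) - eps sigma)
                   - e^eps Phi(-1/(2 sigma) - eps sigma) for eps by
    bisection (the left side is strictly decreasing in eps).
    """

    def delta_of(eps: float) -> float:
        return float(
            norm.cdf(1.0 / (2 * sigma) - eps * sigma)
            - math.exp(eps) * norm.cdf(-1.0 / (2 * sigma) - eps * sigma)
        )

    if delta_of(0.0) <= delta:
        return 0.0
    lo, hi = 0.0, 1.0
    while delta_of(hi) > delta:
        hi *= 2.0
        if hi > 1e6:
            return float("inf")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if delta_of(mid) > delta:
            lo = mid
        else:
            hi = mid
    return hi


def epsilon_for(config: DpConfig, steps: int) -> float:
    """Privacy budget epsilon at the configured delta after `steps` steps.

    Full-batch training composes Gaussian mechanisms exactly (equivalent
    noise sigma / sqrt(steps)), evaluated with the analytic Gaussian bound;
    subsampled training uses the Renyi accountant over integer orders
    2..128. Returns infinity when no noise is added.
    """
    if config.noise_multiplier == 0:
        return float("inf")
    if steps <= 0:
        return 0.0
    sigma = config.noise_multiplier
    if config.sampling_rate == 1.0:
        return analytic_gaussian_epsilon(sigma / math.sqrt(steps), config.delta)
    best = float("inf")
    for a in _RDP_ORDERS:
        rdp = steps * _rdp_subsampled_gaussian(config.sampling_rate, sigma, a)
        eps = rdp + math.log(1.0 / config.delta) / (a - 1)
        best = min(best, eps)
    return best


def basic_composition(budgets: list[tuple[float, float]]) -> tuple[float, float]:
    """(sum eps_i, sum delta_i) — the basic composition bound."""
    return (sum(e for e, _ in budgets), sum(d for _, d in budgets))


# ---------------------------------------------------------------------------
# DP training loop
# ---------------------------------------------------------------------------

def dp_fit_hivae(
    X: np.ndarray, mask: np.ndarray, specs, cfg: HivaeConfig, dp: DpConfig,
) -> tuple[HivaeModel, float]:
    """Train a module VAE with DP-SGD and report the resulting epsilon.

    Identical to the non-private trainer except that the per-example
    gradient aggregation runs through :func:`dp_step`; with noise
    multiplier 0 and a clip bound above every gradient norm, the training
    trace matches non-private training bit-for-bit at the same seed. The
    accountant uses the realized sampling rate batch_size / n.
    """
    n = np.asarray(X, dtype=object).shape[0]
    dp = replace(dp, sampling_rate=min(cfg.batch_size, n) / n)
    noise_rng = np.random.default_rng([cfg.seed, 900_913])
    steps = 0

    def agg(per_ex, batch_size):
        return dp_step(per_ex, dp, noise_rng)

    def hook():
        nonlocal steps
        steps += 1

    model = fit_hivae(X, mask, specs, cfg, aggregator=agg, step_hook=hook)
    return model, epsilon_for(dp, steps)
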