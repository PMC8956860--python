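"""Metropolis-within-Gibbs machinery, diagnostics, and brute-force oracles.

The occupancy likelihood is a two-state Markov chain on each substrate
series: an empty unit is colonized with probability theta, an occupied unit
persists with probability theta + psi * delta under the literal transition
rule (clamped into (0, 1)), or psi * delta under the standard complementary
dynamic-occupancy parametrization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import CredibleSummary, credible_interval

__all__ = [
    "PROB_FLOOR",
    "MCMCConfig",
    "PosteriorDraws",
    "transition_probability",
    "series_loglik",
    "mwg_sample",
    "gelman_rubin",
    "grid_posterior_oracle",
]

PROB_FLOOR = 1e-6
RHAT_INF = np.inf


def _clamp(p):
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain configuration for all samplers.

    Defaults follow the analysis protocol of the field study: 5 parallel
    chains of 5000 steps, the first 1000 discarded as burn-in, retaining
    every 50th step.  Proposals are random walks on the logit scale for
    probabilities, the log scale for positive parameters, and the identity
    scale for permanence deviations.
    """

    n_chains: int = 5
    total_steps: int = 5000
    burn_in: int = 1000
    thin: int = 50
    seed: int = 0
    step_logit: float = 0.8
    step_log: float = 0.5
    step_identity: float = 0.3
    link: str = "literal"
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.total_steps <= self.burn_in:
            raise ValueError("total_steps must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.link not in ("literal", "complementary"):
            raise ValueError("link must be 'literal' or 'complementary'")

    @property
    def draws_per_chain(self) -> int:
        return (self.total_steps - self.burn_in) // self.thin

    def replace(self, **kwargs) -> "MCMCConfig":
        params = asdict(self)
        params.update(kwargs)
        return MCMCConfig(**params)


class PosteriorDraws:
    """Named posterior draws organized (chain, draw), with run metadata."""

    def __init__(
        self,
        draws: Mapping[str, np.ndarray],
        config: MCMCConfig,
        acceptance: Mapping[str, float] | None = None,
    ):
        shapes = {np.asarray(v).shape for v in draws.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent draw shapes: {shapes}")
        self.draws = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in draws.items()}
        self.config = config
        self.acceptance = dict(acceptance or {})

    def __contains__(self, name: str) -> bool:
        return name in self.draws

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self.draws[name].ravel()

    def interval(self, name: str, level: float = 0.95) -> CredibleSummary:
        return credible_interval(self.pooled(name), level)

    def rhat(self) -> dict[str, float]:
        return {k: gelman_rubin(v) for k, v in self.draws.items()}

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean/median and equal-tailed interval per parameter."""
        rows = []
        rhats = self.rhat() if self.config.n_chains > 1 else {}
        for name in self.draws:
            ci = self.interval(name, level)
            rows.append(
                {
                    "parameter": name,
                    "mean": ci.mean,
                    "median": ci.median,
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "rhat": rhats.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # -- serialization -------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        frames = []
        for name, arr in self.draws.items():
            n_chains, n_draws = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": np.repeat(np.arange(n_chains), n_draws),
                        "draw": np.tile(np.arange(n_draws), n_chains),
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, config: MCMCConfig | None = None) -> "PosteriorDraws":
        df = pd.read_csv(path)
        draws = {}
        for name, sub in df.groupby("parameter", sort=False):
            piv = sub.pivot(index="chain", columns="draw", values="value")
            draws[name] = piv.to_numpy()
        return cls(draws, config or MCMCConfig())

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "acceptance": self.acceptance,
            "rhat": {k: (None if not np.isfinite(v) else v) for k, v in self.rhat().items()}
            if self.config.n_chains > 1
            else {},
            "n_parameters": len(self.draws),
        }

    def write_manifest(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


# ---------------------------------------------------------------------------
# Likelihood primitives


def transition_probability(theta, psi, delta=1.0, o_prev=0, link: str = "literal"):
    """Occurrence probability at time t given occupancy at t-1.

    literal:        clamp(theta + o_prev * psi * delta)
    complementary:  clamp(theta * (1 - o_prev) + psi * delta * o_prev)

    The literal rule is the printed model; it can exceed 1 for large
    theta + psi and is therefore hard-clamped into (0, 1).
    """
    theta = np.asarray(theta, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if link == "literal":
        p = theta + np.asarray(o_prev) * psi * np.asarray(delta)
    elif link == "complementary":
        o = np.asarray(o_prev)
        p = theta * (1 - o) + psi * np.asarray(delta) * o
    else:
        raise ValueError(f"unknown link {link!r}")
    return _clamp(p)


def series_loglik(theta, psi, delta, series: Sequence[int], link: str = "literal"):
    """Log-likelihood of one occupancy series, first occasion conditioned on.

    Sums Bernoulli log-densities of O_t given O_{t-1} for t = 2..T.  theta
    and psi may be arrays (e.g. a parameter grid); the series contributes
    one factor per transition.
    """
    obs = np.asarray(series)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    if not np.isin(obs, (0, 1)).all():
        raise ValueError("series values must be 0 or 1")
    theta = np.asarray(theta, dtype=float)
    total = np.zeros(np.broadcast(theta, np.asarray(psi, dtype=float)).shape)
    for prev, cur in zip(obs[:-1], obs[1:]):
        p = transition_probability(theta, psi, delta, prev, link)
        total = total + (np.log(p) if cur else np.log1p(-p))
    return total if total.shape else float(total)


# ---------------------------------------------------------------------------
# Generic one-parameter-at-a-time sampler

_TRANSFORMS = {
    "logit": (
        lambda x: np.log(x / (1.0 - x)),
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z: z - 2.0 * np.log1p(np.exp(z)) if z < 30 else -z,  # log|dx/dz|
    ),
    "log": (np.log, np.exp, lambda z: z),
    "identity": (lambda x: x, lambda z: z, lambda z: 0.0),
}


def mwg_sample(
    log_posterior: Callable[[dict[str, float]], float],
    init: Mapping[str, float],
    config: MCMCConfig | None = None,
    transforms: Mapping[str, str] | None = None,
    step_sizes: Mapping[str, float] | None = None,
) -> PosteriorDraws:
    """Random-walk Metropolis-within-Gibbs over a scalar parameter map.

    Each chain sweeps the parameters in a fixed order, proposing a random
    walk on the transformed scale (default: logit) and accepting by the
    Metropolis rule on ``log_posterior`` plus the transform Jacobian.
    Proposal scales are tuned toward 20-50% acceptance during burn-in only,
    then frozen.  Deterministic under a fixed config seed.
    """
    config = config or MCMCConfig()
    transforms = dict(transforms or {})
    names = list(init)
    for name in names:
        transforms.setdefault(name, "logit")

    default_step = {"logit": config.step_logit, "log": config.step_log, "identity": config.step_identity}
    steps0 = {
        name: float((step_sizes or {}).get(name, default_step[transforms[name]]))
        for name in names
    }

    # validate init
    z_init = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name in names:
            fwd, _, _ = _TRANSFORMS[transforms[name]]
            z = fwd(float(init[name]))
            if not np.isfinite(z):
                raise ValueError(f"initial value of {name!r} not in the transform's domain")
            z_init[name] = float(z)
    lp0 = float(log_posterior(dict(init)))
    if not np.isfinite(lp0):
        raise ValueError("log-posterior is not finite at the initial values")

    ss = np.random.SeedSequence(config.seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(config.n_chains)]

    kept = {name: np.empty((config.n_chains, config.draws_per_chain)) for name in names}
    accepts = {name: 0 for name in names}
    proposals = {name: 0 for name in names}

    for c, rng in enumerate(chain_rngs):
        z = dict(z_init)
        x = dict(init)
        steps = dict(steps0)
        lp = lp0 + sum(_TRANSFORMS[transforms[n]][2](z[n]) for n in names)
        acc_win = {name: 0 for name in names}
        n_win = 0
        k = 0
        for it in range(config.total_steps):
            for name in names:
                fwd, inv, ljac = _TRANSFORMS[transforms[name]]
                z_new = z[name] + steps[name] * rng.standard_normal()
                x_new = dict(x)
                x_new[name] = float(inv(z_new))
                lp_new = float(log_posterior(x_new)) + sum(
                    _TRANSFORMS[transforms[n]][2](z_new if n == name else z[n]) for n in names
                )
                if np.log(rng.random()) < lp_new - lp:
                    z[name], x, lp = z_new, x_new, lp_new
                    acc_win[name] += 1
                    if it >= config.burn_in:
                        accepts[name] += 1
                if it >= config.burn_in:
                    proposals[name] += 1
            n_win += 1
            if config.adapt and it < config.burn_in and n_win == 50:
                for name in names:
                    rate = acc_win[name] / n_win
                    if rate < 0.20:
                        steps[name] *= 0.7
                    elif rate > 0.50:
                        steps[name] *= 1.4
                    acc_win[name] = 0
                n_win = 0
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and k < config.draws_per_chain:
                for name in names:
                    kept[name][c, k] = x[name]
                k += 1

    acc_rate = {
        name: (accepts[name] / proposals[name]) if proposals[name] else np.nan for name in names
    }
    return PosteriorDraws(kept, config, acc_rate)


# ---------------------------------------------------------------------------
# Diagnostics


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor of one parameter across chains.

    PSRF = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of the chain means.  Returns
    +inf when the chains have zero within-chain variance but distinct means,
    and 1.0 when all draws are identical.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = arr.shape
    if m < 2:
        raise ValueError("need at least two chains")
    if n < 2:
        raise ValueError("need at least two draws per chain")
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else RHAT_INF
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# Brute-force oracle


def grid_posterior_oracle(
    series_set: Sequence[Sequence[int]],
    prior: str = "uniform",
    resolution: int = 2001,
) -> tuple[float, float]:
    """Posterior means of (theta, psi) by quadrature on the unit square.

    Midpoint-rule integration of the single-genus likelihood (literal link,
    no treatment deviation) under a uniform prior.  Used as an independent
    check of the samplers; an empty series set returns the prior means.
    """
    if prior != "uniform":
        raise ValueError("only the uniform prior is supported")
    if resolution < 10:
        raise ValueError("resolution must be >= 10")
    mid = (np.arange(resolution) + 0.5) / resolution
    th = mid[:, None]
    ps = mid[None, :]
    ll = np.zeros((resolution, resolution))
    for series in series_set:
        ll = ll + series_loglik(th, ps, 1.0, series, link="literal")
    ll -= ll.max()
    w = np.exp(ll)
    z = w.sum()
    e_theta = float((w * th).sum() / z)
    e_psi = float((w * ps).sum() / z)
    return e_theta, e_psi
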