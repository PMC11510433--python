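"""A small, seeded tree-structured Parzen estimator for hyperparameter search.

Univariate TPE: past trials are split at a loss quantile into "good" and
"bad" groups; per parameter, one-dimensional Parzen (Gaussian-kernel)
densities l(x) and g(x) are built over the two groups, candidates are drawn
from l and the candidate maximizing l(x)/g(x) is proposed.  Categorical
parameters use smoothed empirical frequencies instead of kernels.  The first
``n_startup`` trials are sampled uniformly at random.

Self-contained replacement for an external TPE optimizer so that searches
are reproducible offline; deliberately minimal (no pruning, no multivariate
kernels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

__all__ = ["FloatParam", "IntParam", "CatParam", "TPESampler", "minimize"]


@dataclass(frozen=True)
class FloatParam:
    low: float
    high: float
    log: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"low must be < high, got [{self.low}, {self.high}]")
        if self.log and self.low <= 0:
            raise ValueError("log-scaled parameter requires low > 0")

    def to_internal(self, x: float) -> float:
        return float(np.log(x)) if self.log else float(x)

    def from_internal(self, u: float) -> float:
        lo, hi = self.to_internal(self.low), self.to_internal(self.high)
        u = min(max(u, lo), hi)
        return float(np.exp(u)) if self.log else float(u)

    def sample_uniform(self, rng: np.random.Generator) -> float:
        u = rng.uniform(self.to_internal(self.low), self.to_internal(self.high))
        return self.from_internal(u)


@dataclass(frozen=True)
class IntParam:
    low: int
    high: int
    log: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"low must be < high, got [{self.low}, {self.high}]")
        if self.log and self.low <= 0:
            raise ValueError("log-scaled parameter requires low > 0")

    def to_internal(self, x: int) -> float:
        return float(np.log(x)) if self.log else float(x)

    def from_internal(self, u: float) -> int:
        if self.log:
            u = float(np.exp(u))
        return int(min(max(int(round(u)), self.low), self.high))

    def sample_uniform(self, rng: np.random.Generator) -> int:
        u = rng.uniform(self.to_internal(self.low), self.to_internal(self.high))
        return self.from_internal(u)


@dataclass(frozen=True)
class CatParam:
    choices: tuple

    def __init__(self, choices: Sequence) -> None:
        object.__setattr__(self, "choices", tuple(choices))
        if len(self.choices) < 1:
            raise ValueError("categorical parameter needs at least one choice")

    def sample_uniform(self, rng: np.random.Generator):
        return self.choices[rng.integers(len(self.choices))]


def _parzen_logpdf(x: np.ndarray, centers: np.ndarray, bw: float, lo: float, hi: float) -> np.ndarray:
    """Log density of a Gaussian mixture over centers plus a uniform prior component."""
    # prior component guards against zero density away from observations
    prior = 1.0 / (hi - lo)
    if centers.size == 0:
        return np.full_like(x, np.log(prior))
    z = (x[:, None] - centers[None, :]) / bw
    kernel = np.exp(-0.5 * z**2) / (bw * np.sqrt(2 * np.pi))
    dens = (kernel.sum(axis=1) + prior) / (centers.size + 1)
    return np.log(dens)


class TPESampler:
    """Sequential proposer over a dict of parameter definitions."""

    def __init__(
        self,
        space: dict[str, FloatParam | IntParam | CatParam],
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ) -> None:
        if not space:
            raise ValueError("empty search space")
        self.space = dict(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.trials: list[tuple[dict[str, Any], float]] = []

    def tell(self, params: dict[str, Any], loss: float) -> None:
        self.trials.append((dict(params), float(loss)))

    def _split(self) -> tuple[list[dict], list[dict]]:
        done = [t for t in self.trials if np.isfinite(t[1])]
        done.sort(key=lambda t: t[1])
        n_good = max(1, int(np.ceil(self.gamma * len(done))))
        return [p for p, _ in done[:n_good]], [p for p, _ in done[n_good:]]

    def _propose_numeric(self, name: str, param, good: list[dict], bad: list[dict]):
        lo, hi = param.to_internal(param.low), param.to_internal(param.high)
        g_obs = np.array([param.to_internal(p[name]) for p in good])
        b_obs = np.array([param.to_internal(p[name]) for p in bad])
        width = hi - lo
        bw_g = max(width / max(np.sqrt(g_obs.size), 1.0), 1e-3 * width)
        bw_b = max(width / max(np.sqrt(b_obs.size), 1.0), 1e-3 * width)
        # draw candidates from the good mixture (plus a uniform exploration draw)
        cands = []
        for _ in range(self.n_candidates):
            if g_obs.size and self.rng.random() > 1.0 / (g_obs.size + 1):
                c = self.rng.normal(self.rng.choice(g_obs), bw_g)
            else:
                c = self.rng.uniform(lo, hi)
            cands.append(min(max(c, lo), hi))
        cands = np.array(cands)
        score = _parzen_logpdf(cands, g_obs, bw_g, lo, hi) - _parzen_logpdf(
            cands, b_obs, bw_b, lo, hi
        )
        return param.from_internal(float(cands[int(np.argmax(score))]))

    def _propose_categorical(self, name: str, param: CatParam, good: list[dict], bad: list[dict]):
        k = len(param.choices)
        g_counts = np.ones(k)
        b_counts = np.ones(k)
        index = {c: i for i, c in enumerate(param.choices)}
        for p in good:
            g_counts[index[p[name]]] += 1
        for p in bad:
            b_counts[index[p[name]]] += 1
        score = np.log(g_counts / g_counts.sum()) - np.log(b_counts / b_counts.sum())
        return param.choices[int(np.argmax(score))]

    def ask(self) -> dict[str, Any]:
        if len(self.trials) < self.n_startup:
            return {k: p.sample_uniform(self.rng) for k, p in self.space.items()}
        good, bad = self._split()
        if not good or not bad:
            return {k: p.sample_uniform(self.rng) for k, p in self.space.items()}
        out: dict[str, Any] = {}
        for name, param in self.space.items():
            if isinstance(param, CatParam):
                out[name] = self._propose_categorical(name, param, good, bad)
            else:
                out[name] = self._propose_numeric(name, param, good, bad)
        return out


def minimize(
    objective,
    space: dict[str, FloatParam | IntParam | CatParam],
    n_trials: int,
    seed: int = 0,
    **sampler_kwargs,
) -> tuple[dict[str, Any], float, list[tuple[dict[str, Any], float]]]:
    """Run ``n_trials`` of TPE minimization; returns (best_params, best_loss, trace).

    Failing objective evaluations record an infinite loss and the search
    continues.  Deterministic for a fixed seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sampler = TPESampler(space, seed=seed, **sampler_kwargs)
    best_params, best_loss = None, np.inf
    for _ in range(n_trials):
        params = sampler.ask()
        try:
            loss = float(objective(params))
        except Exception:
            loss = np.inf
        sampler.tell(params, loss)
        if loss < best_loss:
            best_params, best_loss = dict(params), loss
    if best_params is None:
        best_params = sampler.trials[0][0]
    return best_params, float(best_loss), list(sampler.trials)
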