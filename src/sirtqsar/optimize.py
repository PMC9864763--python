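"""Sequential model-based (Bayesian) optimization over hyperparameter spaces.

A Gaussian-process surrogate (Matérn 5/2 + white noise) is fitted to the
evaluated configurations, and the next configuration maximizes expected
improvement over a pool of random candidates.  Dimensions may be uniform or
log-uniform reals, integers, or categoricals; everything is encoded into the
unit cube for the surrogate.  The loop is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["Real", "Integer", "Categorical", "bayes_search", "sample_space"]


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    log: bool = False

    def decode(self, u: float):
        if self.log:
            return math.exp(
                math.log(self.low) + u * (math.log(self.high) - math.log(self.low))
            )
        return self.low + u * (self.high - self.low)


@dataclass(frozen=True)
class Integer:
    low: int
    high: int
    log: bool = False

    def decode(self, u: float):
        if self.log:
            v = math.exp(
                math.log(self.low) + u * (math.log(self.high) - math.log(self.low))
            )
        else:
            v = self.low + u * (self.high - self.low)
        return int(min(self.high, max(self.low, round(v))))


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def decode(self, u: float):
        i = int(min(len(self.choices) - 1, math.floor(u * len(self.choices))))
        return self.choices[i]


def _decode(space: dict, u: np.ndarray) -> dict:
    return {name: dim.decode(float(u[i])) for i, (name, dim) in enumerate(space.items())}


def sample_space(space: dict, rng: np.random.Generator) -> dict:
    """One random configuration from the space."""
    return _decode(space, rng.uniform(size=len(space)))


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_search(
    objective: Callable[[dict], float],
    space: dict,
    n_calls: int,
    seed: int,
    n_initial: int | None = None,
    n_candidates: int = 512,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Maximize ``objective`` over ``space`` with ``n_calls`` evaluations.

    Returns ``(best_params, history)``; history preserves evaluation order.
    With ``n_calls == 1`` this degenerates to evaluating a single random
    configuration.
    """
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    rng = np.random.default_rng(seed)
    d = len(space)
    if n_initial is None:
        n_initial = min(n_calls, max(3, d + 1))
    U: list[np.ndarray] = []
    scores: list[float] = []
    history: list[tuple[dict, float]] = []

    def evaluate(u: np.ndarray):
        params = _decode(space, u)
        try:
            score = float(objective(params))
        except Exception as exc:  # fall back to space midpoint, per contract
            warnings.warn(f"objective failed for {params!r} ({exc}); "
                          "falling back to space midpoint")
            u = np.full(d, 0.5)
            params = _decode(space, u)
            score = float(objective(params))
        U.append(u)
        scores.append(score)
        history.append((params, score))

    for _ in range(min(n_initial, n_calls)):
        evaluate(rng.uniform(size=d))

    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.full(d, 0.5), length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(1e-6, (1e-10, 1e-1))
    )
    while len(scores) < n_calls:
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.vstack(U), np.asarray(scores))
        cand = rng.uniform(size=(n_candidates, d))
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, max(scores))
        evaluate(cand[int(np.argmax(ei))])

    best = int(np.argmax(scores))
    return history[best][0], history
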