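"""Sequential model-based hyperparameter search.

A compact Bayesian optimizer: random initial design in the unit cube,
then a Gaussian-process surrogate (Matern 5/2) ranks candidate points
by expected improvement.  Dimensions may be linear or log-scaled,
continuous or integer.  Deterministic given the generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
import warnings

__all__ = ["Dimension", "bayes_search"]


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def from_unit(self, u: float):
        if self.log:
            val = np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
        else:
            val = self.low + u * (self.high - self.low)
        return int(round(val)) if self.integer else float(val)


def _decode(space: list[Dimension], u: np.ndarray) -> dict:
    return {d.name: d.from_unit(ui) for d, ui in zip(space, u)}


def bayes_search(objective: Callable[[dict], float], space: list[Dimension],
                 n_calls: int, rng: np.random.Generator,
                 n_initial: int | None = None, n_candidates: int = 256):
    """Maximize ``objective`` over ``space`` in ``n_calls`` evaluations.

    Returns ``(best_params, best_value, history)`` where history is the
    list of (params, value) pairs in evaluation order.
    """
    if n_calls < 1:
        raise ValueError("search budget must be at least 1")
    ndim = len(space)
    if n_initial is None:
        n_initial = max(min(n_calls, 2 * ndim + 1), 1)
    X: list[np.ndarray] = []
    y: list[float] = []
    history: list[tuple[dict, float]] = []

    def evaluate(u: np.ndarray) -> None:
        params = _decode(space, u)
        val = float(objective(params))
        X.append(u)
        y.append(val)
        history.append((params, val))

    for _ in range(min(n_initial, n_calls)):
        evaluate(rng.random(ndim))

    kernel = Matern(length_scale=np.ones(ndim), nu=2.5) if ndim else None
    for _ in range(n_calls - len(y)):
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6, normalize_y=True,
                                      random_state=int(rng.integers(2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.array(X), np.array(y))
        cand = rng.random((n_candidates, ndim))
        mu, sd = gp.predict(cand, return_std=True)
        best = max(y)
        sd = np.maximum(sd, 1e-12)
        z = (mu - best) / sd
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])

    i_best = int(np.argmax(y))
    return history[i_best][0], y[i_best], history
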