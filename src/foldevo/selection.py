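"""Survivor selection from the mixed 2N pool.

Three modes: strong (deterministic top half), fitness-proportional
(with-replacement draws weighted by score), and Gibbs (softmax with inverse
temperature beta; beta = 0 is neutral drift, large beta approaches strong
selection).  Stochastic modes can also sample without replacement, which is
the variant whose large-beta limit reproduces strong selection's survivor
set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class SelectionMode(Enum):
    STRONG = "strong"
    PROPORTIONAL = "proportional"
    GIBBS = "gibbs"


@dataclass(frozen=True)
class SelectionConfig:
    mode: SelectionMode = SelectionMode.PROPORTIONAL
    beta: float = 1.0
    replace: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


def _check_pool(scores: np.ndarray, n: int) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if len(scores) != 2 * n:
        raise ValueError(f"pool size {len(scores)} != 2n = {2 * n}")
    return scores


def proportional_probabilities(scores) -> np.ndarray:
    """P(i) = s_i / sum(s); uniform fallback when every score is zero."""
    s = np.asarray(scores, dtype=float)
    if np.any(s < 0):
        raise ValueError("scores must be non-negative")
    total = s.sum()
    if total == 0:
        return np.full(len(s), 1.0 / len(s))
    return s / total


def gibbs_probabilities(scores, beta: float) -> np.ndarray:
    """Softmax P(i) = e^{beta s_i} / sum e^{beta s_k}, max-shifted for safety."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x = beta * np.asarray(scores, dtype=float)
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def select_strong(scores, n: int) -> np.ndarray:
    """Indices of the n highest-scoring pool members (stable on ties)."""
    s = _check_pool(scores, n)
    # stable sort descending: sort ascending on -score keeps insertion order on ties
    order = np.argsort(-s, kind="stable")
    return np.sort(order[:n])


def _draw(p: np.ndarray, n: int, rng: np.random.Generator, replace: bool) -> np.ndarray:
    if replace:
        return rng.choice(len(p), size=n, replace=True, p=p)
    # sequential renormalised draws (weighted sampling without replacement)
    out = np.empty(n, dtype=int)
    p = p.copy()
    remaining = np.ones(len(p), dtype=bool)
    for k in range(n):
        total = p.sum()
        p_norm = p / total if total > 0 else remaining / remaining.sum()
        out[k] = rng.choice(len(p), p=p_norm)
        p[out[k]] = 0.0
        remaining[out[k]] = False
    return out


def select_proportional(
    scores, n: int, rng: np.random.Generator, replace: bool = True
) -> np.ndarray:
    """n fitness-proportional draws (with replacement by default)."""
    s = _check_pool(scores, n)
    return _draw(proportional_probabilities(s), n, rng, replace)


def select_gibbs(
    scores, n: int, beta: float, rng: np.random.Generator, replace: bool = True
) -> np.ndarray:
    """n softmax draws at inverse temperature beta.

    With ``replace=False`` the draws are sequential without replacement; in
    the beta -> infinity limit that variant returns exactly the strong-
    selection survivor set.
    """
    s = _check_pool(scores, n)
    return _draw(gibbs_probabilities(s, beta), n, rng, replace)


def select(
    scores, n: int, config: SelectionConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dispatch on the configured mode; returns pool indices (may repeat)."""
    if config.mode is SelectionMode.STRONG:
        return select_strong(scores, n)
    if config.mode is SelectionMode.PROPORTIONAL:
        return select_proportional(scores, n, rng, config.replace)
    return select_gibbs(scores, n, config.beta, rng, config.replace)
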