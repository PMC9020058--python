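"""Bernoulli generative model for deregulated subgraphs.

Binary node labels ``S_v`` (1 = deregulated) are assumed independent given a
subgraph ``V'``: inside the subgraph ``S_v ~ Ber(p')``, outside
``S_v ~ Ber(p)``, with ``p' > p`` encoding elevated deregulation inside.
Under this model, maximizing the average node score over the feasible
subgraph family is maximum-likelihood estimation of ``V'``; this module
provides the likelihood surface that the optimizer implicitly climbs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "DeregulationModel",
    "log_likelihood",
    "fit_rates",
    "profile_log_likelihood",
]


@dataclass(frozen=True)
class DeregulationModel:
    """Background (p) and in-subgraph (p_prime) deregulation probabilities."""

    p: float
    p_prime: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < self.p_prime < 1.0):
            raise ValueError("require 0 < p < p_prime < 1")


def _xlogy(x: float, y: float) -> float:
    """x * log(y) with the profile-likelihood convention 0 * log 0 = 0."""
    if x == 0.0:
        return 0.0
    if y == 0.0:
        return -math.inf
    return x * math.log(y)


def _check_binary(scores: Mapping[str, float]) -> None:
    for v, s in scores.items():
        if s not in (0, 1, 0.0, 1.0):
            raise ValueError(f"non-binary score for node {v!r}: {s}")


def log_likelihood(
    scores: Mapping[str, float],
    subgraph: Iterable[str],
    model: DeregulationModel,
) -> float:
    """Log-likelihood of binary scores given a subgraph and fixed rates.

    Sum over inside nodes of ``s ln p' + (1-s) ln(1-p')`` plus the analogous
    background terms outside.
    """
    _check_binary(scores)
    inside = frozenset(subgraph)
    if not inside <= set(scores):
        raise ValueError("subgraph contains nodes without scores")
    ll = 0.0
    for v, s in scores.items():
        rate = model.p_prime if v in inside else model.p
        ll += _xlogy(s, rate) + _xlogy(1 - s, 1 - rate)
    return ll


def fit_rates(
    scores: Mapping[str, float], subgraph: Iterable[str]
) -> tuple[float, float]:
    """MLE of (p, p') for a given subgraph: the in/out sample deregulation
    fractions.  Boundary values 0 and 1 are permitted in the estimate."""
    _check_binary(scores)
    inside = frozenset(subgraph)
    if not inside:
        raise ValueError("subgraph must be non-empty")
    if inside >= set(scores):
        raise ValueError("subgraph must be a proper subset of the nodes")
    n_in = sum(1 for v in scores if v in inside)
    n_out = len(scores) - n_in
    k_in = sum(scores[v] for v in inside)
    k_out = sum(s for v, s in scores.items() if v not in inside)
    return k_out / n_out, k_in / n_in


def profile_log_likelihood(
    scores: Mapping[str, float], subgraph: Iterable[str]
) -> float:
    """Log-likelihood profiled over (p, p').

    Evaluated at the per-subgraph MLE rates with ``0 ln 0 = 0``.  When the
    estimated ordering violates ``p' > p`` the model is degenerate and the
    constrained supremum is attained at the pooled rate ``p = p'``.
    """
    p_hat, pp_hat = fit_rates(scores, subgraph)
    inside = frozenset(subgraph)
    if pp_hat < p_hat:
        pooled = sum(scores.values()) / len(scores)
        p_hat = pp_hat = pooled
    ll = 0.0
    for v, s in scores.items():
        rate = pp_hat if v in inside else p_hat
        ll += _xlogy(s, rate) + _xlogy(1 - s, 1 - rate)
    return ll
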