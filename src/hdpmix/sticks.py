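"""Truncated stick-breaking posteriors for the global and local processes.

A truncation at K represents K - 1 free Beta-distributed stick fractions
v_1..v_{K-1}; the final fraction is fixed at 1 so the mixture weights
Psi_k = v_k * prod_{k'<k} (1 - v_k') sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .datatypes import ValidationError


@dataclass
class StickPosterior:
    """Beta(a_k, b_k) posteriors for the K-1 free sticks of a truncated DP."""

    a: np.ndarray  # (K-1,)
    b: np.ndarray  # (K-1,)
    concentration: float  # prior Beta(1, concentration)

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ValidationError("stick parameter vectors must match in length")
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValidationError("stick Beta parameters must be positive")
        if self.concentration <= 0:
            raise ValidationError("stick concentration must be positive")

    @property
    def K(self) -> int:
        return len(self.a) + 1

    def expected_weights(self) -> np.ndarray:
        """Point estimate E[Psi_k] from E[v_k] = a/(a+b); sums to exactly 1."""
        v = np.concatenate([self.a / (self.a + self.b), [1.0]])
        log1mv = np.log1p(-np.concatenate([v[:-1], [0.0]]))
        return v * np.exp(np.concatenate([[0.0], np.cumsum(log1mv[:-1])]))


def expected_log_sticks(s: StickPosterior) -> tuple[np.ndarray, np.ndarray]:
    """(E[log v_k], E[log(1 - v_k)]) for k = 1..K; the fixed final stick
    contributes (0, -inf)."""
    dg = digamma(s.a + s.b)
    e_log_v = np.concatenate([digamma(s.a) - dg, [0.0]])
    e_log_1mv = np.concatenate([digamma(s.b) - dg, [-np.inf]])
    return e_log_v, e_log_1mv


def mixture_log_weights(logs: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """E[log Psi_k] = E[log v_k] + sum_{k'<k} E[log(1 - v_k')].

    The -inf of the fixed final stick never enters (it would belong to
    component K + 1).
    """
    e_log_v, e_log_1mv = logs
    if e_log_v.shape != e_log_1mv.shape:
        raise ValidationError("stick expectation vectors must match in length")
    prefix = np.concatenate([[0.0], np.cumsum(e_log_1mv[:-1])])
    return e_log_v + prefix


def update_global_sticks(
    resp: np.ndarray, gamma: float, scale: float = 1.0
) -> StickPosterior:
    """Hat update from global responsibilities: a_k = 1 + scale*sum_i r_ik,
    b_k = gamma + scale*sum_i sum_{k'>k} r_ik'."""
    resp = np.asarray(resp, dtype=float)
    counts = scale * resp.sum(axis=0)  # (K,)
    tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
    return StickPosterior(a=1.0 + counts[:-1], b=gamma + tail[:-1], concentration=gamma)


def update_local_sticks(linkage: np.ndarray, lam: float) -> StickPosterior:
    """As the global update, with sums over global clusters k of q(Z_kt).

    The linkage is a global variable (one row per global cluster), so no
    minibatch scaling applies.
    """
    linkage = np.asarray(linkage, dtype=float)
    counts = linkage.sum(axis=0)  # (T,)
    tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
    return StickPosterior(a=1.0 + counts[:-1], b=lam + tail[:-1], concentration=lam)
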