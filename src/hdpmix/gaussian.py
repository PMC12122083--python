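"""Gaussian metabolome components with per-observation selection.

Each local cluster of the continuous layer carries, per feature, a
Normal-Gamma variational posterior over (mean mu, precision delta); a single
background component carries one per feature. The likelihood factorises over
features with scalar precisions, so the precision posteriors are per-feature
Gamma distributions (the diagonal specialisation of a Wishart).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit

from .datatypes import MetabolomeMatrix, ValidationError

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class NormalGammaPosterior:
    """Per-feature posterior: mu | delta ~ N(mean, (scale_count*delta)^-1),
    delta ~ Gamma(shape, rate). Fields may be vectors (one entry per feature).
    """

    mean: np.ndarray
    scale_count: np.ndarray  # kappa
    shape: np.ndarray  # a
    rate: np.ndarray  # b

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.scale_count = np.atleast_1d(np.asarray(self.scale_count, dtype=float))
        self.shape = np.atleast_1d(np.asarray(self.shape, dtype=float))
        self.rate = np.atleast_1d(np.asarray(self.rate, dtype=float))
        for name in ("scale_count", "shape", "rate"):
            v = getattr(self, name)
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} must be positive and finite")

    @property
    def e_precision(self) -> np.ndarray:
        return self.shape / self.rate

    @property
    def e_log_precision(self) -> np.ndarray:
        return digamma(self.shape) - np.log(self.rate)


@dataclass
class GaussComponentPosterior:
    """T_max cluster posteriors (each vectorised over D' features) + background."""

    clusters: list[NormalGammaPosterior]
    background: NormalGammaPosterior

    @property
    def T(self) -> int:
        return len(self.clusters)


def log_normal_pdf(x, mean, precision):
    """log N(x | mean, precision^-1); vectorised over broadcastable inputs."""
    precision = np.asarray(precision, dtype=float)
    if np.any(precision <= 0):
        raise ValidationError("precision must be positive")
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    out = 0.5 * (np.log(precision) - _LOG_2PI - precision * (x - mean) ** 2)
    return float(out) if out.ndim == 0 else out


def expected_log_normal(x, q: NormalGammaPosterior):
    """Closed-form E_q[log N(x | mu, delta^-1)] under the Normal-Gamma posterior:

    0.5 * ( E[log delta] - log 2 pi - E[delta] (x - m)^2 - 1/kappa ).
    """
    x = np.asarray(x, dtype=float)
    out = 0.5 * (
        q.e_log_precision
        - _LOG_2PI
        - q.e_precision * (x - q.mean) ** 2
        - 1.0 / q.scale_count
    )
    return float(out) if out.ndim == 0 else out


def expected_loglik_matrix(q: NormalGammaPosterior, values: np.ndarray) -> np.ndarray:
    """(N, D') matrix of expected per-observation Gaussian log-densities."""
    return 0.5 * (
        q.e_log_precision[None, :]
        - _LOG_2PI
        - q.e_precision[None, :] * (values - q.mean[None, :]) ** 2
        - 1.0 / q.scale_count[None, :]
    )


def _weighted_ng_update(
    w: np.ndarray, values: np.ndarray, prior: NormalGammaPosterior
) -> NormalGammaPosterior:
    """Normal-Gamma conjugate update with per-observation weights w (N, D')."""
    sw = w.sum(axis=0)
    swx = (w * values).sum(axis=0)
    swx2 = (w * values**2).sum(axis=0)
    kappa = prior.scale_count + sw
    m = (prior.scale_count * prior.mean + swx) / kappa
    a = prior.shape + 0.5 * sw
    b = prior.rate + 0.5 * (
        swx2 + prior.scale_count * prior.mean**2 - kappa * m**2
    )
    # b is positive analytically; guard against roundoff at zero weight
    b = np.maximum(b, 1e-12)
    return NormalGammaPosterior(mean=m, scale_count=kappa, shape=a, rate=b)


def gauss_update_cluster(
    t: int,
    resp: np.ndarray,
    phi: np.ndarray,
    data: MetabolomeMatrix,
    prior: NormalGammaPosterior,
    scale: float = 1.0,
) -> NormalGammaPosterior:
    """Hat update for local cluster ``t`` with weights scale*resp_i*phi_ij."""
    resp = np.asarray(resp, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if resp.shape[0] != data.n_samples or phi.shape != data.values.shape:
        raise ValidationError("resp/phi dimensions do not match the data matrix")
    if scale < 1.0 - 1e-12:
        raise ValidationError("scale must be >= 1")
    w = scale * resp[:, None] * phi
    return _weighted_ng_update(w, data.values, prior)


def gauss_update_background(
    phi: np.ndarray,
    data: MetabolomeMatrix,
    prior: NormalGammaPosterior,
    scale: float = 1.0,
) -> NormalGammaPosterior:
    """Background update with weights scale*(1 - phi), cluster-independent."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != data.values.shape:
        raise ValidationError("phi dimensions do not match the data matrix")
    if scale < 1.0 - 1e-12:
        raise ValidationError("scale must be >= 1")
    w = scale * (1.0 - phi)
    return _weighted_ng_update(w, data.values, prior)


def phi_from_terms(
    sel_terms: np.ndarray,  # (T, N, D')
    bg_terms: np.ndarray,  # (N, D')
    cluster_weights: np.ndarray,  # (N, T)
    prior_logodds: float,
) -> np.ndarray:
    sel = np.einsum("nt,tnd->nd", cluster_weights, sel_terms)
    return expit(prior_logodds + sel - bg_terms)


def update_phi_metabolome(
    data: MetabolomeMatrix,
    resp: np.ndarray,
    linkage: np.ndarray,
    comp: GaussComponentPosterior,
    prior_logodds: float,
) -> np.ndarray:
    """Posterior selection probabilities for every (sample, metabolite)."""
    resp = np.asarray(resp, dtype=float)
    linkage = np.asarray(linkage, dtype=float)
    if resp.shape[0] != data.n_samples or resp.shape[1] != linkage.shape[0]:
        raise ValidationError("responsibility/linkage dimensions are inconsistent")
    r = resp @ linkage
    sel = np.stack([expected_loglik_matrix(q, data.values) for q in comp.clusters])
    bg = expected_loglik_matrix(comp.background, data.values)
    return phi_from_terms(sel, bg, r, prior_logodds)
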