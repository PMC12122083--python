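"""Dirichlet-multinomial count components with per-observation selection.

Each local cluster t of the count layer carries a variational Dirichlet
posterior over its concentration vector alpha_t; a single shared background
component carries one over beta. Because a Dirichlet-distributed concentration
vector lies on the simplex, sum(alpha) = 1 almost surely, so the shared
normalising term logGamma(sum alpha) - logGamma(sum alpha + J) of the
Dirichlet-multinomial log-pmf is the deterministic constant -logGamma(J + 1)
and exactly cancels the J! of the multinomial coefficient. What remains of the
log-likelihood decomposes feature by feature,

    log p(x_i | alpha) = sum_j [ lgamma(alpha_j + x_ij) - lgamma(alpha_j)
                                 - lgamma(x_ij + 1) ],

which is the decomposition the selection indicators Phi_1ij act on: feature j
of sample i contributes its cluster term when selected and the background term
otherwise.

The expectations E[lgamma(alpha_j + x) - lgamma(alpha_j)] under the Dirichlet
posterior have no closed form; they are approximated by a second-order delta
method around the posterior mean (the marginal of one coordinate is Beta, so
mean and variance are available exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit, gammaln, polygamma

from .datatypes import MicrobiomeCounts, ValidationError


@dataclass
class DirichletPosterior:
    """Variational Dirichlet over one concentration vector (alpha_t or beta)."""

    shape: np.ndarray  # (D,) positive

    def __post_init__(self) -> None:
        self.shape = np.asarray(self.shape, dtype=float)
        if self.shape.ndim != 1:
            raise ValidationError("Dirichlet shape must be a vector")
        if not np.all(np.isfinite(self.shape)) or np.any(self.shape <= 0):
            raise ValidationError("Dirichlet shapes must be positive and finite")

    @property
    def mean(self) -> np.ndarray:
        return self.shape / self.shape.sum()

    @property
    def coordinate_variance(self) -> np.ndarray:
        """Var of each coordinate under its Beta(u_j, U - u_j) marginal."""
        total = self.shape.sum()
        m = self.shape / total
        return m * (1.0 - m) / (total + 1.0)


@dataclass
class DMComponentPosterior:
    """T_max cluster posteriors plus the shared background posterior."""

    clusters: list[DirichletPosterior]
    background: DirichletPosterior

    @property
    def T(self) -> int:
        return len(self.clusters)


def log_dm_pmf(x: np.ndarray, alpha: np.ndarray) -> float:
    """Log pmf of the Dirichlet-multinomial at count vector ``x``.

    Computed entirely in log-Gamma space:
    log C(J; x) + lgamma(S) - lgamma(S + J) + sum_j [lgamma(a_j + x_j) -
    lgamma(a_j)], with S = sum(alpha), J = sum(x).
    """
    x = np.asarray(x)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise ValidationError("x and alpha must have the same length")
    if np.any(x < 0) or not np.allclose(x, np.rint(x)):
        raise ValidationError("counts must be non-negative integers")
    if np.any(alpha <= 0):
        raise ValidationError("alpha must be strictly positive")
    x = np.rint(x).astype(np.int64)
    total = int(x.sum())
    s = alpha.sum()
    coeff = gammaln(total + 1) - gammaln(x + 1).sum()
    return float(
        coeff
        + gammaln(s)
        - gammaln(s + total)
        + (gammaln(alpha + x) - gammaln(alpha)).sum()
    )


def expected_feature_terms(q: DirichletPosterior, counts: np.ndarray) -> np.ndarray:
    """E[lgamma(alpha_j + x_ij) - lgamma(alpha_j)] for every sample/feature.

    Split as log(alpha_j) + [lgamma(alpha_j + x) - lgamma(alpha_j + 1)] for
    x >= 1 (zero for x = 0). The singular first piece has the exact Dirichlet
    expectation digamma(u_j) - digamma(U); the smooth remainder is
    delta-approximated to second order around the posterior mean m_j, where
    its curvature is bounded (trigamma at arguments >= 1). Exact for x = 0
    and in the concentrated-posterior limit. Returns an (N, D) array.
    """
    X = np.asarray(counts)
    u = q.shape
    total = u.sum()
    m = q.mean  # (D,)
    var = q.coordinate_variance  # (D,)
    e_log_alpha = digamma(u) - digamma(total)  # exact E[log alpha_j]
    out = e_log_alpha[None, :] + gammaln(m[None, :] + X) - gammaln(m + 1.0)[None, :]
    # curvature correction; |0.5 var curv| <= 0.5 var trigamma(1), so skip
    # features whose posterior variance makes it numerically irrelevant
    active = var > 1e-8
    if active.any():
        ma = m[active]
        curv = polygamma(1, ma[None, :] + X[:, active]) - polygamma(1, ma + 1.0)[None, :]
        out[:, active] += 0.5 * var[active][None, :] * curv
    return np.where(X > 0, out, 0.0)


def expected_log_dm(x: np.ndarray, q_alpha: DirichletPosterior) -> float:
    """Delta-method approximation of E_q[log DM(x | alpha)].

    Uses the simplex constraint of the Dirichlet posterior (see module
    docstring), so the value is -sum_j lgamma(x_j + 1) plus the per-feature
    expected Gamma-ratio terms.
    """
    x = np.asarray(x)
    if x.shape != q_alpha.shape.shape:
        raise ValidationError("x and posterior must have the same length")
    if np.any(x < 0) or not np.allclose(x, np.rint(x)):
        raise ValidationError("counts must be non-negative integers")
    x = np.rint(x).astype(np.int64)
    terms = expected_feature_terms(q_alpha, x[None, :])[0]
    return float(terms.sum() - gammaln(x + 1).sum())


def dm_update_cluster(
    t: int,
    resp: np.ndarray,
    phi: np.ndarray,
    counts: MicrobiomeCounts,
    prior: DirichletPosterior,
    scale: float = 1.0,
) -> DirichletPosterior:
    """Intermediate ("hat") Dirichlet parameter for local cluster ``t``.

    ``resp`` is the per-sample weight of local cluster t (already combining
    global responsibilities with the global-to-local linkage); ``phi`` the
    selection probabilities. Shape update:
    prior + scale * sum_i resp_i * phi_ij * x_ij.
    """
    resp = np.asarray(resp, dtype=float)
    phi = np.asarray(phi, dtype=float)
    X = counts.values
    if resp.shape[0] != X.shape[0] or phi.shape != X.shape:
        raise ValidationError("resp/phi dimensions do not match the count matrix")
    if scale < 1.0 - 1e-12:
        raise ValidationError("scale must be >= 1")
    acc = (resp[:, None] * phi * X).sum(axis=0)
    return DirichletPosterior(shape=prior.shape + scale * acc)


def dm_update_background(
    phi: np.ndarray,
    counts: MicrobiomeCounts,
    prior: DirichletPosterior,
    scale: float = 1.0,
) -> DirichletPosterior:
    """Background update: weights (1 - phi), independent of cluster labels."""
    phi = np.asarray(phi, dtype=float)
    X = counts.values
    if phi.shape != X.shape:
        raise ValidationError("phi dimensions do not match the count matrix")
    if scale < 1.0 - 1e-12:
        raise ValidationError("scale must be >= 1")
    acc = ((1.0 - phi) * X).sum(axis=0)
    return DirichletPosterior(shape=prior.shape + scale * acc)


def phi_from_terms(
    sel_terms: np.ndarray,  # (T, N, D) stacked cluster expectations
    bg_terms: np.ndarray,  # (N, D)
    cluster_weights: np.ndarray,  # (N, T) = resp @ linkage
    prior_logodds: float,
) -> np.ndarray:
    """Selection posterior sigma(prior_logodds + E[selected] - E[background])."""
    sel = np.einsum("nt,tnd->nd", cluster_weights, sel_terms)
    return expit(prior_logodds + sel - bg_terms)


def update_phi_microbiome(
    counts: MicrobiomeCounts,
    resp: np.ndarray,
    linkage: np.ndarray,
    comp: DMComponentPosterior,
    prior_logodds: float,
) -> np.ndarray:
    """Posterior selection probabilities for every (sample, taxon) observation.

    ``resp`` is the N x K global responsibility matrix, ``linkage`` the K x T
    global-to-local linkage of the count layer. The multinomial-coefficient
    constants cancel between the selected and background terms.
    """
    resp = np.asarray(resp, dtype=float)
    linkage = np.asarray(linkage, dtype=float)
    if resp.shape[0] != counts.n_samples or resp.shape[1] != linkage.shape[0]:
        raise ValidationError("responsibility/linkage dimensions are inconsistent")
    r = resp @ linkage  # (N, T)
    sel = np.stack(
        [expected_feature_terms(q, counts.values) for q in comp.clusters]
    )
    bg = expected_feature_terms(comp.background, counts.values)
    return phi_from_terms(sel, bg, r, prior_logodds)
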