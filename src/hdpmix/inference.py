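"""Variational inference for the integrative hierarchical mixture.

Model summary. Samples are assigned to global clusters k through a truncated
stick-breaking process (weights Psi, concentration gamma). Each global
cluster is linked, per omics layer m, to a local mixture component t through
a second truncated stick-breaking process (weights Pi_m, concentration
lambda). The count layer uses Dirichlet-multinomial components, the
continuous layer Gaussian components; in both layers a per-observation binary
indicator Phi_mij switches feature j of sample i between its cluster-specific
component and a layer-wide shared background component. The selection rate of
each layer carries a symmetric Beta prior.

Inference is mean-field variational: q factorises over W (global
responsibilities), the sticks, Z (global-to-local linkage), Phi, the
component parameters and the selection rates. W and Phi are local (per
sample) variables; everything else is global and, in minibatch mode, is
updated by blending the natural parameters of the full-data "hat" update with
a Robbins-Monro step size. In the default full-batch mode the step size is 1
and the algorithm is deterministic coordinate ascent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import betaln, digamma, gammaln, xlogy
from sklearn.cluster import KMeans

from . import dmm, gaussian
from .datatypes import (
    FitConfig,
    FitResult,
    MultiOmicsDataset,
    ValidationError,
)
from .io import standardize_metabolome
from .sticks import (
    StickPosterior,
    expected_log_sticks,
    mixture_log_weights,
    update_global_sticks,
    update_local_sticks,
)

logger = logging.getLogger(__name__)

_RESP_FLOOR = 1e-12


@dataclass
class BetaPosterior:
    """Beta posterior over one layer's feature-selection rate epsilon."""

    c: float
    d: float
    prior_shape: float

    def prior_logodds(self) -> float:
        return float(digamma(self.c) - digamma(self.d))


@dataclass
class ModelState:
    """All variational posteriors of one fit, plus the configuration."""

    config: FitConfig
    global_sticks: StickPosterior
    qW: np.ndarray  # (N, K)
    local_sticks: dict[str, StickPosterior]
    qZ: dict[str, np.ndarray]  # layer -> (K, T)
    qPhi: dict[str, np.ndarray]  # layer -> (N, D_m)
    eps: dict[str, BetaPosterior]
    dm: dmm.DMComponentPosterior
    gauss: Optional[gaussian.GaussComponentPosterior]
    iteration: int = 0

    @property
    def layers(self) -> list[str]:
        return list(self.qZ.keys())

    def selection_logodds(self, layer: str) -> float:
        """Prior log-odds used in the Phi updates.

        The symmetric Beta(s0, s0) hyperprior on a layer's selection rate is
        bimodal for s0 < 1, and under mean field its posterior tracks the
        mean of Phi, creating a positive feedback that drives the whole
        layer to all-selected or all-rejected. By default the log-odds are
        therefore held at the prior's symmetric centre (0) and q(epsilon)
        is tracked for reporting and the ELBO only; set
        ``adapt_selection_rate`` to recover the full coordinate update.
        """
        if self.config.adapt_selection_rate:
            return self.eps[layer].prior_logodds()
        return 0.0


def learning_rate(t: int, tau0: float, kappa: float) -> float:
    """Robbins-Monro schedule (tau0 + t)^(-kappa)."""
    if tau0 < 0 or not (0.5 < kappa <= 1.0):
        raise ValidationError("need tau0 >= 0 and 0.5 < kappa <= 1")
    return float((tau0 + t) ** (-kappa))


def natural_gradient_step(old, hat, rho: float):
    """(1 - rho) * old + rho * hat on the natural parameters of each factor.

    Accepts the posterior types used by the model, plain arrays/floats, and
    (recursively) lists and dicts of them. Probability tables (rows on the
    simplex) are blended in log space and renormalised.
    """
    if not (0.0 < rho <= 1.0):
        raise ValidationError("rho must lie in (0, 1]")
    if type(old) is not type(hat) and not (
        np.isscalar(old) and np.isscalar(hat)
    ):
        raise ValidationError("old and hat bundles must be structurally identical")
    if isinstance(old, StickPosterior):
        return StickPosterior(
            a=(1 - rho) * old.a + rho * hat.a,
            b=(1 - rho) * old.b + rho * hat.b,
            concentration=old.concentration,
        )
    if isinstance(old, dmm.DirichletPosterior):
        return dmm.DirichletPosterior(shape=(1 - rho) * old.shape + rho * hat.shape)
    if isinstance(old, gaussian.NormalGammaPosterior):
        # natural coordinates: (kappa, kappa*m, a, b + kappa*m^2/2)
        kappa = (1 - rho) * old.scale_count + rho * hat.scale_count
        km = (1 - rho) * old.scale_count * old.mean + rho * hat.scale_count * hat.mean
        a = (1 - rho) * old.shape + rho * hat.shape
        bh = (1 - rho) * (old.rate + 0.5 * old.scale_count * old.mean**2) + rho * (
            hat.rate + 0.5 * hat.scale_count * hat.mean**2
        )
        m = km / kappa
        return gaussian.NormalGammaPosterior(
            mean=m, scale_count=kappa, shape=a, rate=bh - 0.5 * kappa * m**2
        )
    if isinstance(old, BetaPosterior):
        return BetaPosterior(
            c=(1 - rho) * old.c + rho * hat.c,
            d=(1 - rho) * old.d + rho * hat.d,
            prior_shape=old.prior_shape,
        )
    if isinstance(old, dmm.DMComponentPosterior):
        return dmm.DMComponentPosterior(
            clusters=[
                natural_gradient_step(o, h, rho)
                for o, h in zip(old.clusters, hat.clusters)
            ],
            background=natural_gradient_step(old.background, hat.background, rho),
        )
    if isinstance(old, gaussian.GaussComponentPosterior):
        return gaussian.GaussComponentPosterior(
            clusters=[
                natural_gradient_step(o, h, rho)
                for o, h in zip(old.clusters, hat.clusters)
            ],
            background=natural_gradient_step(old.background, hat.background, rho),
        )
    if isinstance(old, dict):
        return {k: natural_gradient_step(old[k], hat[k], rho) for k in old}
    if isinstance(old, list):
        return [natural_gradient_step(o, h, rho) for o, h in zip(old, hat)]
    return (1 - rho) * np.asarray(old, dtype=float) + rho * np.asarray(
        hat, dtype=float
    )


def blend_categorical(old: np.ndarray, hat: np.ndarray, rho: float) -> np.ndarray:
    """Blend row-simplex tables in log space and renormalise."""
    log_mix = (1 - rho) * np.log(np.clip(old, _RESP_FLOOR, None)) + rho * np.log(
        np.clip(hat, _RESP_FLOOR, None)
    )
    return _row_softmax(log_mix)


def _row_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    p = np.exp(logits - m)
    p /= p.sum(axis=-1, keepdims=True)
    return p


# ---------------------------------------------------------------------------
# expected data log-likelihood assembly
# ---------------------------------------------------------------------------


def _dm_stacks(state: ModelState, X: np.ndarray):
    return _dm_stacks_of(state.dm, X)


def _dm_stacks_of(comp: dmm.DMComponentPosterior, X: np.ndarray):
    # deduplicate identical posteriors: empty truncation slots all sit at the
    # prior, so their (N, D) expectation arrays are shared, not recomputed
    cache: dict[bytes, np.ndarray] = {}

    def terms(q: dmm.DirichletPosterior) -> np.ndarray:
        key = q.shape.tobytes()
        if key not in cache:
            cache[key] = dmm.expected_feature_terms(q, X)
        return cache[key]

    sel = np.stack([terms(q) for q in comp.clusters])
    bg = terms(comp.background)
    return sel, bg


def _gauss_stacks(state: ModelState, V: np.ndarray):
    sel = np.stack(
        [gaussian.expected_loglik_matrix(q, V) for q in state.gauss.clusters]
    )
    bg = gaussian.expected_loglik_matrix(state.gauss.background, V)
    return sel, bg


def _layer_loglik(
    sel: np.ndarray, bg: np.ndarray, phi: np.ndarray, const: np.ndarray | float = 0.0
) -> np.ndarray:
    """(N, T) expected log-likelihood of each sample under each local cluster,
    with the background contribution (shared across t) folded in."""
    L = np.einsum("nd,tnd->nt", phi, sel)
    L += (((1.0 - phi) * bg).sum(axis=1) + const)[:, None]
    return L


def _count_constants(X: np.ndarray) -> np.ndarray:
    """Per-sample -sum_j lgamma(x_ij + 1); the depth terms cancel exactly."""
    return -gammaln(X + 1.0).sum(axis=1)


def update_responsibilities_W(
    state: ModelState, logliks: dict[str, np.ndarray]
) -> np.ndarray:
    """q(W_ik) proportional to exp(E[log Psi_k] + sum_m sum_t q(Z_mkt) L_mit)."""
    log_psi = mixture_log_weights(expected_log_sticks(state.global_sticks))
    logits = np.tile(log_psi, (logliks[next(iter(logliks))].shape[0], 1))
    for layer, L in logliks.items():
        logits = logits + L @ state.qZ[layer].T
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite responsibility logits")
    return _row_softmax(logits)


def update_linkage_Z(
    state: ModelState, logliks: dict[str, np.ndarray], scale: float = 1.0
) -> dict[str, np.ndarray]:
    """q(Z_mkt) proportional to exp(E[log Pi_mt] + scale*sum_i q(W_ik) L_mit)."""
    out = {}
    for layer, L in logliks.items():
        log_pi = mixture_log_weights(expected_log_sticks(state.local_sticks[layer]))
        logits = log_pi[None, :] + scale * (state.qW.T @ L)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError(f"non-finite linkage logits in layer {layer}")
        out[layer] = _row_softmax(logits)
    return out


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------


def _beta_entropy(a, b):
    return (
        betaln(a, b)
        - (a - 1) * digamma(a)
        - (b - 1) * digamma(b)
        + (a + b - 2) * digamma(a + b)
    )


def _stick_block(s: StickPosterior) -> float:
    """E[log p(v)] + H(q(v)) for the K-1 free Beta(1, c) sticks."""
    c = s.concentration
    e_log_1mv = digamma(s.b) - digamma(s.a + s.b)
    prior = np.log(c) + (c - 1.0) * e_log_1mv
    return float((prior + _beta_entropy(s.a, s.b)).sum())


def _categorical_block(q: np.ndarray, e_log_w: np.ndarray) -> float:
    """sum rows of q . E[log weights] + entropy of each row."""
    cross = float((q * e_log_w[None, :]).sum())
    ent = -float(xlogy(q, np.clip(q, _RESP_FLOOR, None)).sum())
    return cross + ent


def _dirichlet_kl(u: np.ndarray, u0: np.ndarray) -> float:
    su, su0 = u.sum(), u0.sum()
    return float(
        gammaln(su)
        - gammaln(su0)
        - (gammaln(u) - gammaln(u0)).sum()
        + ((u - u0) * (digamma(u) - digamma(su))).sum()
    )


def _normal_gamma_block(
    q: gaussian.NormalGammaPosterior, p: gaussian.NormalGammaPosterior
) -> float:
    """E_q[log p(mu, delta)] + H(q) for vectorised Normal-Gamma factors."""
    e_log_d = q.e_log_precision
    e_d = q.e_precision
    log_2pi = np.log(2 * np.pi)
    e_log_p_delta = (
        p.shape * np.log(p.rate) - gammaln(p.shape) + (p.shape - 1) * e_log_d - p.rate * e_d
    )
    e_d_mu_dev = e_d * (q.mean - p.mean) ** 2 + 1.0 / q.scale_count
    e_log_p_mu = 0.5 * (
        np.log(p.scale_count) - log_2pi + e_log_d - p.scale_count * e_d_mu_dev
    )
    h_gamma = q.shape - np.log(q.rate) + gammaln(q.shape) + (1 - q.shape) * digamma(q.shape)
    h_mu = 0.5 * (np.log(2 * np.pi * np.e) - np.log(q.scale_count) - e_log_d)
    return float((e_log_p_delta + e_log_p_mu + h_gamma + h_mu).sum())


def _beta_kl(c, d, c0, d0) -> float:
    return float(
        betaln(c0, d0)
        - betaln(c, d)
        + (c - c0) * digamma(c)
        + (d - d0) * digamma(d)
        - (c + d - c0 - d0) * digamma(c + d)
    )


def compute_elbo(state: ModelState, data: MultiOmicsDataset) -> float:
    """Evidence lower bound of the current variational state on ``data``.

    Count-layer data expectations use the delta approximation of the
    Dirichlet-multinomial terms; every other term is exact.
    """
    cfg = state.config
    elbo = 0.0
    pieces: dict[str, float] = {}

    # data terms
    X = data.counts.values
    sel, bg = _dm_stacks(state, X)
    L1 = _layer_loglik(sel, bg, state.qPhi["microbiome"], _count_constants(X))
    r1 = state.qW @ state.qZ["microbiome"]
    pieces["data_microbiome"] = float((r1 * L1).sum())

    if data.continuous is not None:
        V = data.continuous.values
        sel2, bg2 = _gauss_stacks(state, V)
        L2 = _layer_loglik(sel2, bg2, state.qPhi["metabolome"])
        r2 = state.qW @ state.qZ["metabolome"]
        pieces["data_metabolome"] = float((r2 * L2).sum())

    # global sticks and W
    log_psi = mixture_log_weights(expected_log_sticks(state.global_sticks))
    pieces["W"] = _categorical_block(state.qW, log_psi)
    pieces["global_sticks"] = _stick_block(state.global_sticks)

    # local sticks and Z
    for layer in state.layers:
        log_pi = mixture_log_weights(expected_log_sticks(state.local_sticks[layer]))
        pieces[f"Z_{layer}"] = _categorical_block(state.qZ[layer], log_pi)
        pieces[f"local_sticks_{layer}"] = _stick_block(state.local_sticks[layer])

    # selection indicators and rates. With the selection rate pinned at the
    # symmetric prior centre (the default), epsilon is a fixed model
    # constant of 1/2, so its cross term is flat and it contributes no KL;
    # with adapt_selection_rate the full hierarchical terms appear.
    for layer in state.layers:
        phi = state.qPhi[layer]
        ep = state.eps[layer]
        if cfg.adapt_selection_rate:
            e_log_e = digamma(ep.c) - digamma(ep.c + ep.d)
            e_log_1me = digamma(ep.d) - digamma(ep.c + ep.d)
            cross = float((phi * e_log_e + (1 - phi) * e_log_1me).sum())
            pieces[f"eps_{layer}"] = -_beta_kl(
                ep.c, ep.d, ep.prior_shape, ep.prior_shape
            )
        else:
            cross = float(phi.size * np.log(0.5))
        ent = -float(
            (
                xlogy(phi, np.clip(phi, _RESP_FLOOR, None))
                + xlogy(1 - phi, np.clip(1 - phi, _RESP_FLOOR, None))
            ).sum()
        )
        pieces[f"phi_{layer}"] = cross + ent

    # component parameters
    d = data.counts.n_features
    u0 = np.full(d, cfg.dm_prior_shape)
    kl = sum(_dirichlet_kl(q.shape, u0) for q in state.dm.clusters)
    kl += _dirichlet_kl(state.dm.background.shape, u0)
    pieces["dm_components"] = -kl

    if state.gauss is not None:
        dp = data.continuous.n_features
        prior = gaussian.NormalGammaPosterior(
            mean=np.full(dp, cfg.gauss_prior_mean),
            scale_count=np.full(dp, cfg.gauss_prior_scale_count),
            shape=np.full(dp, cfg.gauss_prior_shape),
            rate=np.full(dp, cfg.gauss_prior_rate),
        )
        ng = sum(_normal_gamma_block(q, prior) for q in state.gauss.clusters)
        ng += _normal_gamma_block(state.gauss.background, prior)
        pieces["gauss_components"] = ng

    elbo = sum(pieces.values())
    if not np.isfinite(elbo):
        raise FloatingPointError(f"non-finite ELBO; term breakdown: {pieces}")
    return float(elbo)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def _clr(X: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    logx = np.log(X + pseudocount)
    return logx - logx.mean(axis=1, keepdims=True)


def _init_state(data: MultiOmicsDataset, cfg: FitConfig) -> ModelState:
    n = data.n_samples
    K, T = cfg.K_max, cfg.T_max
    rng = np.random.default_rng(cfg.seed)

    feats = _clr(data.counts.values)
    if data.continuous is not None:
        feats = np.hstack([feats, data.continuous.values])
    k_eff = min(K, n)
    km = KMeans(n_clusters=k_eff, n_init=4, random_state=int(rng.integers(2**31)))
    hard = km.fit_predict(feats)

    qW = np.full((n, K), 0.1 / max(K - 1, 1))
    qW[np.arange(n), hard] = 0.9 if K > 1 else 1.0
    qW /= qW.sum(axis=1, keepdims=True)

    layers = ["microbiome"] + (["metabolome"] if data.continuous is not None else [])
    qZ = {}
    for layer in layers:
        z = np.full((K, T), 0.1 / max(T - 1, 1))
        z[np.arange(K), np.arange(K) % T] = 0.9 if T > 1 else 1.0
        z /= z.sum(axis=1, keepdims=True)
        qZ[layer] = z

    qPhi = {"microbiome": np.full((n, data.counts.n_features), 0.5)}
    if data.continuous is not None:
        qPhi["metabolome"] = np.full((n, data.continuous.n_features), 0.5)

    global_sticks = update_global_sticks(qW, cfg.gamma)
    local_sticks = {layer: update_local_sticks(qZ[layer], cfg.lam) for layer in layers}

    s0 = cfg.phi_beta_shape
    eps = {
        layer: BetaPosterior(
            c=s0 + float(qPhi[layer].sum()),
            d=s0 + float((1 - qPhi[layer]).sum()),
            prior_shape=s0,
        )
        for layer in layers
    }

    d = data.counts.n_features
    dm_prior = dmm.DirichletPosterior(shape=np.full(d, cfg.dm_prior_shape))
    r1 = qW @ qZ["microbiome"]
    dm_comp = dmm.DMComponentPosterior(
        clusters=[
            dmm.dm_update_cluster(t, r1[:, t], qPhi["microbiome"], data.counts, dm_prior)
            for t in range(T)
        ],
        background=dmm.dm_update_background(qPhi["microbiome"], data.counts, dm_prior),
    )

    gauss_comp = None
    if data.continuous is not None:
        dp = data.continuous.n_features
        ng_prior = gaussian.NormalGammaPosterior(
            mean=np.full(dp, cfg.gauss_prior_mean),
            scale_count=np.full(dp, cfg.gauss_prior_scale_count),
            shape=np.full(dp, cfg.gauss_prior_shape),
            rate=np.full(dp, cfg.gauss_prior_rate),
        )
        r2 = qW @ qZ["metabolome"]
        gauss_comp = gaussian.GaussComponentPosterior(
            clusters=[
                gaussian.gauss_update_cluster(
                    t, r2[:, t], qPhi["metabolome"], data.continuous, ng_prior
                )
                for t in range(T)
            ],
            background=gaussian.gauss_update_background(
                qPhi["metabolome"], data.continuous, ng_prior
            ),
        )

    return ModelState(
        config=cfg,
        global_sticks=global_sticks,
        qW=qW,
        local_sticks=local_sticks,
        qZ=qZ,
        qPhi=qPhi,
        eps=eps,
        dm=dm_comp,
        gauss=gauss_comp,
    )


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def _compute_stacks(state: ModelState, data: MultiOmicsDataset, rows: np.ndarray):
    """Per-epoch expected log-density arrays for the batch rows."""
    X = data.counts.values[rows]
    sel1, bg1 = _dm_stacks(state, X)
    stacks = {"sel1": sel1, "bg1": bg1, "const1": _count_constants(X)}
    if data.continuous is not None:
        sel2, bg2 = _gauss_stacks(state, data.continuous.values[rows])
        stacks["sel2"], stacks["bg2"] = sel2, bg2
    return stacks


def _batch_logliks(state: ModelState, stacks, rows: np.ndarray):
    logliks = {
        "microbiome": _layer_loglik(
            stacks["sel1"], stacks["bg1"], state.qPhi["microbiome"][rows], stacks["const1"]
        )
    }
    if "sel2" in stacks:
        logliks["metabolome"] = _layer_loglik(
            stacks["sel2"], stacks["bg2"], state.qPhi["metabolome"][rows]
        )
    return logliks


def _local_updates(state: ModelState, stacks, rows: np.ndarray) -> None:
    """Per-sample updates for the batch: W, then Phi."""
    state.qW[rows] = update_responsibilities_W(state, _batch_logliks(state, stacks, rows))
    wr = state.qW[rows]
    r1 = wr @ state.qZ["microbiome"]
    state.qPhi["microbiome"][rows] = dmm.phi_from_terms(
        stacks["sel1"], stacks["bg1"], r1, state.selection_logodds("microbiome")
    )
    if "sel2" in stacks:
        r2 = wr @ state.qZ["metabolome"]
        state.qPhi["metabolome"][rows] = gaussian.phi_from_terms(
            stacks["sel2"], stacks["bg2"], r2, state.selection_logodds("metabolome")
        )


def _global_updates(
    state: ModelState, data: MultiOmicsDataset, stacks, rows: np.ndarray, rho: float
) -> None:
    """Shared-parameter updates: Z, sticks, components, selection rates."""
    cfg = state.config
    n = data.n_samples
    scale = n / len(rows)
    has_metab = "sel2" in stacks
    sel1, bg1, const1 = stacks["sel1"], stacks["bg1"], stacks["const1"]
    if has_metab:
        sel2, bg2 = stacks["sel2"], stacks["bg2"]

    logliks = _batch_logliks(state, stacks, rows)
    if scale == 1.0:
        hat_qZ = update_linkage_Z(state, logliks)
    else:
        sub = ModelState(
            config=cfg,
            global_sticks=state.global_sticks,
            qW=state.qW[rows],
            local_sticks=state.local_sticks,
            qZ=state.qZ,
            qPhi=state.qPhi,
            eps=state.eps,
            dm=state.dm,
            gauss=state.gauss,
        )
        hat_qZ = update_linkage_Z(sub, logliks, scale=scale)
    for layer in state.layers:
        state.qZ[layer] = blend_categorical(state.qZ[layer], hat_qZ[layer], rho)

    # --- global: sticks ---
    hat_gs = update_global_sticks(state.qW[rows], cfg.gamma, scale=scale)
    state.global_sticks = natural_gradient_step(state.global_sticks, hat_gs, rho)
    for layer in state.layers:
        hat_ls = update_local_sticks(state.qZ[layer], cfg.lam)
        state.local_sticks[layer] = natural_gradient_step(
            state.local_sticks[layer], hat_ls, rho
        )

    # --- global: components and selection rates ---
    phi1 = state.qPhi["microbiome"][rows]
    counts_rows = data.counts if scale == 1.0 else _subset_counts(data, rows)
    r1 = state.qW[rows] @ state.qZ["microbiome"]
    d = data.counts.n_features
    dm_prior = dmm.DirichletPosterior(shape=np.full(d, cfg.dm_prior_shape))
    hat_dm = dmm.DMComponentPosterior(
        clusters=[
            dmm.dm_update_cluster(t, r1[:, t], phi1, counts_rows, dm_prior, scale)
            for t in range(cfg.T_max)
        ],
        background=dmm.dm_update_background(phi1, counts_rows, dm_prior, scale),
    )
    if scale == 1.0 and rho == 1.0:
        # The conjugate count accumulation is a natural-gradient direction,
        # not an exact coordinate maximiser of the delta-approximated bound
        # (the expectations weight features by presence, the accumulation by
        # counts). In deterministic full-batch mode, backtrack the step until
        # the count-component block of the bound does not decrease; every
        # other update ascends exactly, so each epoch is then monotone.
        X_rows = counts_rows.values
        u0 = dm_prior.shape

        def dm_block(comp: dmm.DMComponentPosterior) -> float:
            sel, bg = _dm_stacks_of(comp, X_rows)
            sel_part = np.einsum("it,tij,ij->", r1, sel, phi1)
            data_part = sel_part + ((1 - phi1) * bg).sum()
            kl = sum(_dirichlet_kl(q.shape, u0) for q in comp.clusters)
            kl += _dirichlet_kl(comp.background.shape, u0)
            return float(data_part - kl)

        current = dm_block(state.dm)
        step = 1.0
        for _ in range(6):
            cand = natural_gradient_step(state.dm, hat_dm, step)
            if dm_block(cand) >= current - 1e-9:
                state.dm = cand
                break
            step *= 0.5
        # if no step helps, the components stay put this epoch
    else:
        state.dm = natural_gradient_step(state.dm, hat_dm, rho)

    s0 = cfg.phi_beta_shape
    hat_eps1 = BetaPosterior(
        c=s0 + scale * float(phi1.sum()),
        d=s0 + scale * float((1 - phi1).sum()),
        prior_shape=s0,
    )
    state.eps["microbiome"] = natural_gradient_step(
        state.eps["microbiome"], hat_eps1, rho
    )

    if has_metab:
        phi2 = state.qPhi["metabolome"][rows]
        metab_rows = (
            data.continuous if scale == 1.0 else _subset_metab(data, rows)
        )
        r2 = state.qW[rows] @ state.qZ["metabolome"]
        dp = data.continuous.n_features
        ng_prior = gaussian.NormalGammaPosterior(
            mean=np.full(dp, cfg.gauss_prior_mean),
            scale_count=np.full(dp, cfg.gauss_prior_scale_count),
            shape=np.full(dp, cfg.gauss_prior_shape),
            rate=np.full(dp, cfg.gauss_prior_rate),
        )
        hat_g = gaussian.GaussComponentPosterior(
            clusters=[
                gaussian.gauss_update_cluster(
                    t, r2[:, t], phi2, metab_rows, ng_prior, scale
                )
                for t in range(cfg.T_max)
            ],
            background=gaussian.gauss_update_background(
                phi2, metab_rows, ng_prior, scale
            ),
        )
        state.gauss = natural_gradient_step(state.gauss, hat_g, rho)
        hat_eps2 = BetaPosterior(
            c=s0 + scale * float(phi2.sum()),
            d=s0 + scale * float((1 - phi2).sum()),
            prior_shape=s0,
        )
        state.eps["metabolome"] = natural_gradient_step(
            state.eps["metabolome"], hat_eps2, rho
        )


def _epoch(
    state: ModelState, data: MultiOmicsDataset, rows: np.ndarray, rho: float
) -> None:
    """One update sweep (W -> Phi -> Z -> sticks -> components) in place.

    ``rows`` is the minibatch (all rows in full-batch mode); global hats are
    scaled by N/|rows| before the natural-gradient blend with step ``rho``.
    """
    stacks = _compute_stacks(state, data, rows)
    _local_updates(state, stacks, rows)
    _global_updates(state, data, stacks, rows, rho)


def _cluster_signatures(state: ModelState) -> np.ndarray:
    """Per-global-cluster signature used to rank merge candidates: the
    linkage-weighted expected log-compositions (plus Gaussian means)."""
    e1 = np.stack(
        [digamma(q.shape) - digamma(q.shape.sum()) for q in state.dm.clusters]
    )
    sigs = []
    for k in range(state.qW.shape[1]):
        s = state.qZ["microbiome"][k] @ e1
        if state.gauss is not None:
            mg = np.stack([q.mean for q in state.gauss.clusters])
            s = np.concatenate([s, state.qZ["metabolome"][k] @ mg])
        sigs.append(s)
    return np.stack(sigs)


def _merge_sweep(
    state: ModelState,
    data: MultiOmicsDataset,
    elbo: float,
    rows: np.ndarray,
) -> tuple[ModelState, float, int]:
    """Propose cluster merges and keep those that raise the ELBO.

    Coordinate ascent cannot merge redundant global clusters on its own:
    each fragment's components overfit its own samples, so no single-sample
    move improves the bound even when the merged configuration is far
    better. A merge move transplants one cluster's responsibility mass into
    another, refreshes the shared parameters so the absorbed component
    cannot recapture its samples, relaxes for a couple of sweeps, and is
    accepted only if the bound improves — the procedure is therefore
    monotone in the ELBO. Candidate pairs are ranked by distance between
    cluster signatures; the ``merge_candidates`` closest pairs are tried.
    """
    import copy

    cfg = state.config
    occ = state.qW.sum(axis=0)
    sigs = _cluster_signatures(state)
    pairs = []
    K = state.qW.shape[1]
    for a in range(K):
        for b in range(a + 1, K):
            if occ[a] < 0.5 or occ[b] < 0.5:
                continue
            pairs.append((float(np.linalg.norm(sigs[a] - sigs[b])), a, b))
    pairs.sort()
    accepted = 0
    for _, a, b in pairs[: cfg.merge_candidates]:
        if state.qW[:, a].sum() < 0.5 or state.qW[:, b].sum() < 0.5:
            continue  # already absorbed earlier in this sweep
        trial = copy.deepcopy(state)
        if trial.qW[:, a].sum() < trial.qW[:, b].sum():
            a, b = b, a
        trial.qW[:, a] += trial.qW[:, b]
        trial.qW[:, b] = 0.0
        stacks = _compute_stacks(trial, data, rows)
        _global_updates(trial, data, stacks, rows, 1.0)
        for _ in range(cfg.merge_inner_epochs):
            _epoch(trial, data, rows, 1.0)
        trial_elbo = compute_elbo(trial, data)
        if trial_elbo > elbo + 1e-9:
            state, elbo = trial, trial_elbo
            accepted += 1
    return state, elbo, accepted


def _subset_counts(data: MultiOmicsDataset, rows: np.ndarray):
    from .datatypes import MicrobiomeCounts

    return MicrobiomeCounts(
        sample_ids=[data.counts.sample_ids[i] for i in rows],
        feature_ids=list(data.counts.feature_ids),
        values=data.counts.values[rows],
    )


def _subset_metab(data: MultiOmicsDataset, rows: np.ndarray):
    from .datatypes import MetabolomeMatrix

    return MetabolomeMatrix(
        sample_ids=[data.continuous.sample_ids[i] for i in rows],
        feature_ids=list(data.continuous.feature_ids),
        values=data.continuous.values[rows],
        standardized=data.continuous.standardized,
    )


def estimate_num_clusters(mixing: np.ndarray, threshold: float = 0.01) -> int:
    """Count mixture weights above ``threshold``; the largest weight always
    counts, so the result is at least 1."""
    mixing = np.asarray(mixing, dtype=float)
    if mixing.size == 0:
        raise ValidationError("empty mixing-weight vector")
    if np.any(mixing < 0):
        raise ValidationError("mixing weights must be non-negative")
    return max(int((mixing > threshold).sum()), 1)


def hard_labels(resp: np.ndarray) -> np.ndarray:
    """Row argmax (ties to the lowest index), re-indexed to consecutive
    integers ordered by descending cluster size."""
    raw = np.argmax(resp, axis=1)
    uniq, counts = np.unique(raw, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {int(c): i for i, c in enumerate(order)}
    return np.array([remap[int(c)] for c in raw], dtype=np.int64)


def fit(data: MultiOmicsDataset, config: Optional[FitConfig] = None) -> FitResult:
    """Run the variational fit and summarise it as a FitResult.

    The metabolome layer is z-scored first unless the config disables it or
    the matrix is already standardized. Every ``merge_every`` epochs,
    ELBO-guided merge moves try to absorb redundant global clusters (see
    ``_merge_sweep``); they are accepted only when the bound improves. Stops
    when the relative ELBO change drops below ``config.elbo_tol`` after a
    ``min_iter`` burn-in, or at ``config.max_iter`` epochs (non-convergence
    is flagged on the result, not raised).
    """
    cfg = config or FitConfig()
    if (
        data.continuous is not None
        and cfg.standardize_metabolome
        and not data.continuous.standardized
    ):
        data = MultiOmicsDataset(
            counts=data.counts, continuous=standardize_metabolome(data.continuous)
        )
    n = data.n_samples
    full_batch = cfg.batch_size == "full" or int(cfg.batch_size) >= n
    if not full_batch and int(cfg.batch_size) > n:
        raise ValidationError("batch_size exceeds the number of samples")

    state = _init_state(data, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    all_rows = np.arange(n)

    trace: list[float] = []
    converged = False
    for epoch in range(1, cfg.max_iter + 1):
        state.iteration = epoch
        if full_batch:
            rows, rho = all_rows, 1.0
        else:
            rows = rng.choice(n, size=int(cfg.batch_size), replace=False)
            rho = learning_rate(epoch, cfg.lr_tau0, cfg.lr_kappa)
        _epoch(state, data, rows, rho)
        elbo = compute_elbo(state, data)
        trace.append(elbo)
        mixing = state.global_sticks.expected_weights()
        logger.info(
            "epoch %d: elbo=%.4f, active clusters=%d",
            epoch,
            elbo,
            estimate_num_clusters(mixing, cfg.prune_threshold),
        )
        if len(trace) >= 2 and epoch >= cfg.min_iter:
            rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1e-12)
            if rel < cfg.elbo_tol:
                # at a fixed point of coordinate ascent; try merge moves.
                # Merging only makes sense here: away from convergence the
                # trial's relaxation epochs would bias the ELBO comparison.
                if cfg.merge_moves and cfg.merge_candidates > 0:
                    state, merged_elbo, n_merged = _merge_sweep(
                        state, data, elbo, all_rows
                    )
                    if n_merged:
                        logger.info(
                            "epoch %d: accepted %d merge move(s)", epoch, n_merged
                        )
                        trace[-1] = merged_elbo
                        continue  # re-converge after the merges
                converged = True
                break
    if not converged:
        logger.warning("fit did not converge within %d epochs", cfg.max_iter)

    mixing = state.global_sticks.expected_weights()
    return FitResult(
        labels=hard_labels(state.qW),
        responsibilities=state.qW,
        mixing=mixing,
        elbo_trace=np.asarray(trace),
        n_clusters=estimate_num_clusters(mixing, cfg.prune_threshold),
        phi_avg_microbiome=state.qPhi["microbiome"].mean(axis=0),
        phi_avg_metabolome=(
            state.qPhi["metabolome"].mean(axis=0) if "metabolome" in state.qPhi else None
        ),
        converged=converged,
        state=state,
    )
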