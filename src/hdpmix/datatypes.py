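"""Core data containers for paired microbiome/metabolome clustering.

The package operates on two sample-aligned matrices: a table of taxonomic-unit
counts (each row sums to that sample's sequencing depth) and a table of
continuous metabolite measurements. Both are carried around together with
their identifiers so that validation and alignment errors can name the
offending sample/feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class MicrobiomeCounts:
    """Taxonomic-unit count table: N samples x D features of non-negative ints.

    ``depths[i]`` is the sequencing depth J_i = sum_j values[i, j].
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (N, D) integer counts
    depths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, d = self.values.shape
        if n < 1 or d < 2:
            raise ValidationError(f"count matrix needs N >= 1, D >= 2; got {n} x {d}")
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValidationError("identifier lengths do not match matrix shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.issubdtype(self.values.dtype, np.integer):
            # accept float input only if every entry is an exact integer
            rounded = np.rint(self.values)
            bad = np.argwhere(~np.isclose(self.values, rounded, atol=0.0))
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count {self.values[i, j]!r} at sample "
                    f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )
            self.values = rounded.astype(np.int64)
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        self.depths = self.values.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class MetabolomeMatrix:
    """Continuous metabolite table: N samples x D' features of finite reals."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (N, D') floats
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("metabolome values must be a 2-D matrix")
        n, d = self.values.shape
        if d < 1:
            raise ValidationError("metabolome matrix needs D' >= 1")
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValidationError("identifier lengths do not match matrix shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class MultiOmicsDataset:
    """Paired omics layers sharing one sample order.

    ``continuous`` may be ``None`` for a counts-only (single-omics) analysis;
    ``M`` is then 1.
    """

    counts: MicrobiomeCounts
    continuous: Optional[MetabolomeMatrix] = None

    def __post_init__(self) -> None:
        if self.continuous is not None:
            if self.counts.sample_ids != self.continuous.sample_ids:
                raise ValidationError(
                    "sample identifiers differ between omics layers; "
                    "use align_samples() first"
                )

    @property
    def M(self) -> int:
        return 1 if self.continuous is None else 2

    @property
    def n_samples(self) -> int:
        return self.counts.n_samples

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.sample_ids


@dataclass
class FitConfig:
    """Tunables of the variational fit.

    K_max / T_max truncate the global and per-omics local stick-breaking
    representations; gamma / lam are the corresponding Beta(1, .)
    concentrations. phi_beta_shape parameterises the symmetric Beta prior on
    the per-layer feature-selection rate; dm_prior_shape is the symmetric
    Dirichlet prior shape on the count-component concentration vectors.
    Convergence tests start after ``min_iter`` epochs; once they fire,
    ELBO-guided merge moves may absorb redundant clusters (``merge_*``
    fields) before the run is declared converged. ``adapt_selection_rate``
    re-enables the coordinate update of the selection-rate log-odds (off by
    default; see ModelState.selection_logodds).
    """

    K_max: int = 10
    T_max: int = 10
    gamma: float = 0.1
    lam: float = 0.1
    phi_beta_shape: float = 0.1
    dm_prior_shape: float = 1.0
    gauss_prior_mean: float = 0.0
    gauss_prior_scale_count: float = 1.0
    gauss_prior_shape: float = 1.0
    gauss_prior_rate: float = 1.0
    elbo_tol: float = 1e-3
    min_iter: int = 30
    max_iter: int = 1000
    merge_moves: bool = True
    merge_every: int = 5
    merge_candidates: int = 8
    merge_inner_epochs: int = 2
    adapt_selection_rate: bool = False
    batch_size: int | str = "full"
    lr_tau0: float = 64.0
    lr_kappa: float = 0.6
    seed: int = 0
    prune_threshold: float = 0.01
    standardize_metabolome: bool = True

    def __post_init__(self) -> None:
        if self.K_max < 1 or self.T_max < 1:
            raise ValidationError("K_max and T_max must be >= 1")
        if self.gamma <= 0 or self.lam <= 0:
            raise ValidationError("stick concentrations must be > 0")
        if self.elbo_tol <= 0:
            raise ValidationError("elbo_tol must be > 0")
        if not (0.5 < self.lr_kappa <= 1.0):
            raise ValidationError("lr_kappa must lie in (0.5, 1]")
        if self.merge_every < 1 or self.merge_candidates < 0 or self.merge_inner_epochs < 1:
            raise ValidationError("invalid merge-move settings")
        if self.batch_size != "full" and (
            not isinstance(self.batch_size, (int, np.integer)) or self.batch_size < 1
        ):
            raise ValidationError("batch_size must be 'full' or a positive integer")

    def with_overrides(self, **kwargs) -> "FitConfig":
        return replace(self, **kwargs)


@dataclass
class FitResult:
    """Outcome of one variational fit.

    ``labels`` are hard assignments re-indexed to consecutive integers ordered
    by descending cluster size; ``mixing`` are the expected global
    stick-breaking weights E[Psi_k] in the model's own (truncation) order;
    ``phi_avg_*`` are the per-feature selection probabilities averaged over
    samples.
    """

    labels: np.ndarray
    responsibilities: np.ndarray
    mixing: np.ndarray
    elbo_trace: np.ndarray
    n_clusters: int
    phi_avg_microbiome: np.ndarray
    phi_avg_metabolome: Optional[np.ndarray]
    converged: bool
    state: object  # ModelState; kept loose to avoid an import cycle

    def __post_init__(self) -> None:
        rows = self.responsibilities.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValidationError("responsibility rows must sum to 1")
        if np.any(self.mixing < -1e-12) or self.mixing.sum() > 1 + 1e-8:
            raise ValidationError("mixing weights must be a sub-probability vector")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        for scores in (self.phi_avg_microbiome, self.phi_avg_metabolome):
            if scores is not None and (
                np.any(scores < -1e-12) or np.any(scores > 1 + 1e-12)
            ):
                raise ValidationError("phi averages must lie in [0, 1]")
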