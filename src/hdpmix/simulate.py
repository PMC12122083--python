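"""Synthetic paired count/continuous datasets with known cluster structure.

Counts are Dirichlet-multinomial draws: each sample's latent composition is a
Dirichlet draw around its cluster's concentration vector, followed by a
multinomial at that sample's sequencing depth. Metabolite vectors are
independent Gaussians. A configurable fraction of features is "informative"
(cluster-specific parameters); the rest share one parameter set across
clusters, which is exactly the structure the fitted model's background
component is meant to absorb.

Five scenario presets mirror common study designs: a single cluster of 500
samples (false-positive control), two balanced clusters of 200 subsampled
from a 1000-sample pool, an unbalanced 100 + 300 split of the same pool
design, two small clusters of 50, and three clusters of 200 subsampled from
a 1500-sample pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .datatypes import (
    MetabolomeMatrix,
    MicrobiomeCounts,
    MultiOmicsDataset,
    ValidationError,
)

#: full-scale feature dimensions of the scenario presets
DEFAULT_N_TAXA = 614
DEFAULT_N_METAB = 161


@dataclass
class ScenarioConfig:
    """Generating design of one synthetic dataset.

    ``separation`` scales the cluster-specific signal: informative taxa get
    log-normal multiplicative perturbations of the shared concentration with
    log-sd ``separation``; informative metabolites get cluster means spaced
    ``separation`` standard deviations apart. ``sizes`` are the retained
    per-cluster sample counts; ``pool_sizes``, when given, are the per-cluster
    sizes of the larger pool the retained samples are drawn from.
    """

    n_clusters: int
    sizes: list[int]
    n_taxa: int = DEFAULT_N_TAXA
    n_metab: int = DEFAULT_N_METAB
    depth_range: tuple[int, int] = (5000, 50000)
    dm_base_concentration: float = 20.0
    dm_lognormal_sigma: float = 2.0
    informative_fraction: float = 0.3
    separation: float = 3.0
    seed: int = 0
    pool_sizes: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or len(self.sizes) != self.n_clusters:
            raise ValidationError("sizes must list one sample count per cluster")
        if not (0.0 < self.informative_fraction <= 1.0):
            raise ValidationError("informative_fraction must lie in (0, 1]")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValidationError("invalid depth_range")
        if self.pool_sizes is not None:
            if len(self.pool_sizes) != self.n_clusters or any(
                p < s for p, s in zip(self.pool_sizes, self.sizes)
            ):
                raise ValidationError("pool_sizes must cover the retained sizes")


@dataclass
class GroundTruth:
    """Generating parameters and true labels for evaluating a fit."""

    labels: np.ndarray
    dm_params: np.ndarray  # (K, D) cluster concentration vectors
    gauss_means: np.ndarray  # (K, D')
    gauss_precisions: np.ndarray  # (K, D')
    informative_mask_taxa: np.ndarray
    informative_mask_metab: np.ndarray


def make_cluster_params(cfg: ScenarioConfig, rng: Optional[np.random.Generator] = None):
    """Draw cluster parameters: shared background plus informative deviations.

    Returns a GroundTruth with empty labels (filled when samples are drawn).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    d, dp, k = cfg.n_taxa, cfg.n_metab, cfg.n_clusters

    # shared concentration: log-normal magnitudes scaled to the target total.
    # The heavy log-normal tail gives the steep rank-abundance curve (and the
    # zero fraction) typical of species-level 16S tables.
    w = rng.lognormal(0.0, cfg.dm_lognormal_sigma, size=d)
    base = cfg.dm_base_concentration * w / w.sum()

    n_inf_taxa = int(round(cfg.informative_fraction * d))
    mask_taxa = np.zeros(d, dtype=bool)
    mask_taxa[rng.choice(d, size=n_inf_taxa, replace=False)] = True
    dm_params = np.tile(base, (k, 1))
    if n_inf_taxa:
        # balanced multiplicative perturbation: per informative taxon the
        # clusters take a random permutation of log-multipliers spaced
        # `separation` apart and centred at 0, so no cluster is systematically
        # more concentrated than another
        levels = np.arange(k) - (k - 1) / 2.0
        perm = np.array([rng.permutation(levels) for _ in range(n_inf_taxa)]).T
        dm_params[:, mask_taxa] = base[mask_taxa][None, :] * np.exp(
            cfg.separation * perm
        )

    n_inf_metab = int(round(cfg.informative_fraction * dp))
    mask_metab = np.zeros(dp, dtype=bool)
    mask_metab[rng.choice(dp, size=n_inf_metab, replace=False)] = True
    means = np.zeros((k, dp))
    if n_inf_metab:
        levels = np.arange(k) - (k - 1) / 2.0
        # per feature, clusters take a random permutation of the spaced levels;
        # the metabolome spacing is half the count-layer log-scale separation,
        # which keeps the two layers' per-sample evidence comparable
        perm = np.array([rng.permutation(levels) for _ in range(n_inf_metab)]).T
        means[:, mask_metab] = 0.5 * cfg.separation * perm
    precisions = np.ones((k, dp))

    return GroundTruth(
        labels=np.empty(0, dtype=np.int64),
        dm_params=dm_params,
        gauss_means=means,
        gauss_precisions=precisions,
        informative_mask_taxa=mask_taxa,
        informative_mask_metab=mask_metab,
    )


def sample_dm_counts(
    alpha: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """One Dirichlet-multinomial draw: p ~ Dir(alpha), counts ~ Mult(depth, p)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValidationError("alpha must be strictly positive")
    if depth <= 0:
        raise ValidationError("depth must be a positive integer")
    p = rng.dirichlet(alpha)
    return rng.multinomial(int(depth), p)


def sample_gaussian_features(
    means: np.ndarray, precisions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independent normal draws per feature with the given precisions."""
    means = np.asarray(means, dtype=float)
    precisions = np.asarray(precisions, dtype=float)
    if np.any(precisions <= 0) or not np.all(np.isfinite(precisions)):
        raise ValidationError("precisions must be positive and finite")
    return means + rng.standard_normal(means.shape) / np.sqrt(precisions)


SCENARIOS = {
    "I": dict(n_clusters=1, sizes=[500], pool_sizes=None),
    "II": dict(n_clusters=2, sizes=[200, 200], pool_sizes=[500, 500]),
    "III": dict(n_clusters=2, sizes=[100, 300], pool_sizes=[500, 500]),
    "IV": dict(n_clusters=2, sizes=[50, 50], pool_sizes=None),
    "V": dict(n_clusters=3, sizes=[200, 200, 200], pool_sizes=[500, 500, 500]),
}


def scenario_config(which: str, **overrides) -> ScenarioConfig:
    """Preset ScenarioConfig for scenario I..V with optional field overrides."""
    if which not in SCENARIOS:
        raise ValidationError(f"unknown scenario {which!r}; choose from {list(SCENARIOS)}")
    kwargs = dict(SCENARIOS[which])
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def simulate_scenario(
    which: str | ScenarioConfig, **overrides
) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Generate one paired dataset from a preset name or a custom config."""
    cfg = which if isinstance(which, ScenarioConfig) else scenario_config(which, **overrides)
    rng = np.random.default_rng(cfg.seed)
    truth = make_cluster_params(cfg, rng)

    pool_sizes = cfg.pool_sizes or cfg.sizes
    counts_rows, metab_rows, labels = [], [], []
    for k, (pool, keep) in enumerate(zip(pool_sizes, cfg.sizes)):
        depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=pool)
        x = np.stack(
            [sample_dm_counts(truth.dm_params[k], depths[i], rng) for i in range(pool)]
        )
        v = np.stack(
            [
                sample_gaussian_features(
                    truth.gauss_means[k], truth.gauss_precisions[k], rng
                )
                for _ in range(pool)
            ]
        )
        kept = rng.choice(pool, size=keep, replace=False)
        counts_rows.append(x[kept])
        metab_rows.append(v[kept])
        labels.extend([k] * keep)

    counts = np.vstack(counts_rows)
    metab = np.vstack(metab_rows)
    labels = np.asarray(labels, dtype=np.int64)
    perm = rng.permutation(len(labels))
    counts, metab, labels = counts[perm], metab[perm], labels[perm]

    n = len(labels)
    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    taxa_ids = [f"taxon_{j + 1:04d}" for j in range(cfg.n_taxa)]
    metab_ids = [f"metab_{j + 1:04d}" for j in range(cfg.n_metab)]
    dataset = MultiOmicsDataset(
        counts=MicrobiomeCounts(sample_ids, taxa_ids, counts),
        continuous=MetabolomeMatrix(sample_ids, metab_ids, metab),
    )
    truth.labels = labels
    return dataset, truth


def write_dataset(
    dataset: MultiOmicsDataset, truth: GroundTruth, out_dir: str | Path
) -> list[Path]:
    """Write counts, metabolome, truth labels and informative-feature masks."""
    import pandas as pd

    from .io import write_continuous_matrix, write_count_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / "counts.csv", out / "metabolome.csv", out / "truth.csv",
             out / "mask_taxa.csv", out / "mask_metabolites.csv"]
    write_count_matrix(dataset.counts, paths[0])
    write_continuous_matrix(dataset.continuous, paths[1])
    pd.DataFrame(
        {"sample_id": dataset.sample_ids, "label": truth.labels}
    ).to_csv(paths[2], index=False)
    pd.DataFrame(
        {
            "feature_id": dataset.counts.feature_ids,
            "informative": truth.informative_mask_taxa.astype(int),
        }
    ).to_csv(paths[3], index=False)
    pd.DataFrame(
        {
            "feature_id": dataset.continuous.feature_ids,
            "informative": truth.informative_mask_metab.astype(int),
        }
    ).to_csv(paths[4], index=False)
    return paths
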