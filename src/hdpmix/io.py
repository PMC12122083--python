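"""CSV input/output and sample alignment.

Conventions: comma-separated, UTF-8, header row of feature identifiers,
first column of sample identifiers. These match the most common export format
of 16S count tables and metabolite panels.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FitConfig,
    FitResult,
    MetabolomeMatrix,
    MicrobiomeCounts,
    MultiOmicsDataset,
    ValidationError,
)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_count_matrix(path: str | Path) -> MicrobiomeCounts:
    """Read a samples x taxa count table from CSV and validate it."""
    df = _read_table(path)
    values = df.to_numpy()
    if values.dtype == object:
        raise ValidationError(f"{path}: count table contains non-numeric entries")
    return MicrobiomeCounts(
        sample_ids=list(df.index), feature_ids=list(df.columns), values=values
    )


def read_continuous_matrix(path: str | Path) -> MetabolomeMatrix:
    """Read a samples x metabolites table of finite reals from CSV."""
    df = _read_table(path)
    values = df.to_numpy()
    if values.dtype == object:
        raise ValidationError(f"{path}: metabolome table contains non-numeric entries")
    return MetabolomeMatrix(
        sample_ids=list(df.index),
        feature_ids=list(df.columns),
        values=values.astype(float),
        standardized=False,
    )


def write_count_matrix(counts: MicrobiomeCounts, path: str | Path) -> None:
    pd.DataFrame(
        counts.values, index=counts.sample_ids, columns=counts.feature_ids
    ).to_csv(path)


def write_continuous_matrix(m: MetabolomeMatrix, path: str | Path) -> None:
    pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_ids).to_csv(path)


def align_samples(
    counts: MicrobiomeCounts, continuous: MetabolomeMatrix
) -> MultiOmicsDataset:
    """Restrict both layers to shared samples, ordered as in the count layer.

    Samples present in only one layer are dropped with a warning; an empty
    intersection is an error.
    """
    shared = set(counts.sample_ids) & set(continuous.sample_ids)
    if not shared:
        raise ValidationError("no sample identifiers shared between the two layers")
    order = [s for s in counts.sample_ids if s in shared]
    dropped = [s for s in counts.sample_ids if s not in shared] + [
        s for s in continuous.sample_ids if s not in shared
    ]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} unmatched sample(s): {sorted(dropped)}",
            stacklevel=2,
        )
    c_idx = {s: i for i, s in enumerate(counts.sample_ids)}
    m_idx = {s: i for i, s in enumerate(continuous.sample_ids)}
    new_counts = MicrobiomeCounts(
        sample_ids=order,
        feature_ids=list(counts.feature_ids),
        values=counts.values[[c_idx[s] for s in order]],
    )
    new_cont = MetabolomeMatrix(
        sample_ids=order,
        feature_ids=list(continuous.feature_ids),
        values=continuous.values[[m_idx[s] for s in order]],
        standardized=continuous.standardized,
    )
    return MultiOmicsDataset(counts=new_counts, continuous=new_cont)


def standardize_metabolome(m: MetabolomeMatrix) -> MetabolomeMatrix:
    """z-score each feature (n-1 denominator); constant features become zeros."""
    if m.n_samples < 2:
        raise ValidationError("standardization needs at least 2 samples")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    constant = sd < 1e-300
    if constant.any():
        names = [m.feature_ids[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"constant feature(s) mapped to zeros: {names}", stacklevel=2)
    safe_sd = np.where(constant, 1.0, sd)
    z = (m.values - mean) / safe_sd
    z[:, constant] = 0.0
    return MetabolomeMatrix(
        sample_ids=list(m.sample_ids),
        feature_ids=list(m.feature_ids),
        values=z,
        standardized=True,
    )


def load_config(path: str | Path) -> FitConfig:
    """Load a FitConfig from a YAML or JSON file of field overrides."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping of FitConfig fields")
    unknown = set(data) - set(FitConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"{path}: unknown config fields {sorted(unknown)}")
    return FitConfig(**data)


def write_result(
    result: FitResult,
    out_dir: str | Path,
    dataset: Optional[MultiOmicsDataset] = None,
) -> list[Path]:
    """Write assignments, mixing weights, ELBO trace and ranked feature tables.

    Returns the list of paths written. ``dataset`` supplies feature
    identifiers; without it features are named by index.
    """
    from .features import rank_features  # local import: avoid cycle

    if not str(out_dir):
        raise ValidationError("output directory must be a non-empty path")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    n = len(result.labels)
    sample_ids = dataset.sample_ids if dataset is not None else [str(i) for i in range(n)]
    p = out / "assignments.csv"
    pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": result.labels,
            "max_responsibility": result.responsibilities.max(axis=1),
        }
    ).to_csv(p, index=False)
    written.append(p)

    p = out / "mixing.csv"
    pd.DataFrame(
        {"cluster": np.arange(len(result.mixing)), "weight": result.mixing}
    ).to_csv(p, index=False)
    written.append(p)

    p = out / "elbo_trace.csv"
    pd.DataFrame(
        {"epoch": np.arange(1, len(result.elbo_trace) + 1), "elbo": result.elbo_trace}
    ).to_csv(p, index=False)
    written.append(p)

    taxa_ids = (
        dataset.counts.feature_ids
        if dataset is not None
        else [f"taxon_{j}" for j in range(len(result.phi_avg_microbiome))]
    )
    p = out / "ranked_taxa.csv"
    rank_features(result.phi_avg_microbiome, taxa_ids, layer="microbiome").to_csv(
        p, index=False
    )
    written.append(p)

    if result.phi_avg_metabolome is not None:
        metab_ids = (
            dataset.continuous.feature_ids
            if dataset is not None and dataset.continuous is not None
            else [f"metab_{j}" for j in range(len(result.phi_avg_metabolome))]
        )
        p = out / "ranked_metabolites.csv"
        rank_features(result.phi_avg_metabolome, metab_ids, layer="metabolome").to_csv(
            p, index=False
        )
        written.append(p)
    return written
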