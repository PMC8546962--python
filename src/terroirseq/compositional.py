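"""Compositional transforms, alpha diversity, and core-microbiome detection.

Marker-gene and tag counts are compositional: library size is an artifact,
so analyses work on relative abundances or on the centered log-ratio (CLR)
scale, where Euclidean geometry is meaningful (Aitchison distance).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datamodel import CountTable, DistanceMatrix, ValidationError


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Normalize counts to per-sample relative abundances.

    Returns a features x samples frame whose columns each sum to 1.
    Samples with zero total are rejected by name.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {list(zero[:5])}")
    return counts / totals


def clr_transform(
    table: CountTable | pd.DataFrame, pseudocount: str = "half-min"
) -> pd.DataFrame:
    """Centered log-ratio transform, samples in rows.

    Zeros are replaced before the log according to ``pseudocount``:

    * ``"half-min"`` (default): work on relative abundances and replace
      zeros with half the smallest nonzero relative abundance in the whole
      table, then re-close each sample.
    * ``"add-one"``: add 1 to every raw count.

    Each returned row sums to 0 and is invariant to scaling a sample's
    counts by any positive constant.
    """
    if isinstance(table, CountTable):
        counts = table.counts
    else:
        counts = pd.DataFrame(table)
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("CLR requires non-negative counts")
    if values.size == 0:
        return pd.DataFrame(index=counts.columns, columns=counts.index, dtype=float)
    totals = values.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[totals == 0]
        raise ValidationError(f"zero-total sample(s): {list(bad[:5])}")
    if pseudocount == "half-min":
        rel = values / totals
        nonzero = rel[rel > 0]
        eps = 0.5 * nonzero.min()
        rel = np.where(rel == 0, eps, rel)
        comp = rel / rel.sum(axis=0)
    elif pseudocount == "add-one":
        comp = values + 1.0
    else:
        raise ValueError(f"unknown pseudocount policy {pseudocount!r}")
    logs = np.log(comp)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr.T, index=counts.columns, columns=counts.index)


def aitchison_distance(clr_matrix: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples (rows)."""
    values = np.asarray(clr_matrix, dtype=float)
    if values.ndim != 2:
        raise ValidationError("CLR matrix must be 2-dimensional")
    dist = squareform(pdist(values, metric="euclidean"))
    ids = (
        list(clr_matrix.index)
        if isinstance(clr_matrix, pd.DataFrame)
        else [str(i) for i in range(values.shape[0])]
    )
    return DistanceMatrix(ids, dist, metric_name="aitchison")


def euclidean_distance(matrix: pd.DataFrame, metric_name: str = "euclidean") -> DistanceMatrix:
    """Plain Euclidean distance between rows of a numeric matrix."""
    values = np.asarray(matrix, dtype=float)
    dist = squareform(pdist(values, metric="euclidean"))
    ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else [
        str(i) for i in range(values.shape[0])
    ]
    return DistanceMatrix(ids, dist, metric_name=metric_name)


def core_microbiome(
    table: CountTable, prevalence: float = 0.90, abundance: float = 0.01
) -> list[str]:
    """Features at >= ``abundance`` relative abundance in >= ``prevalence``
    of samples.

    Defaults (1% abundance in 90% of samples) follow the conventional
    core-microbiome definition for grape musts.  Abundance is assessed per
    sample.  Raising either threshold never adds features.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    if table.n_features == 0 or table.n_samples == 0:
        return []
    rel = relative_abundance(table)
    frac = (rel >= abundance).mean(axis=1)
    return list(frac.index[frac >= prevalence])


def shannon_index(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i over nonzero proportions (nats)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValidationError("Shannon diversity undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1_index(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 / F2 are the singleton and doubleton counts; the bias-corrected form
    is finite when no doubletons are observed.
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise ValidationError("Chao1 undefined for an all-zero sample")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: CountTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity (``shannon`` in nats, or ``chao1``)."""
    funcs = {"shannon": shannon_index, "chao1": chao1_index}
    if metric not in funcs:
        raise ValueError(f"unknown alpha-diversity metric {metric!r}")
    fn = funcs[metric]
    return pd.Series(
        {s: fn(table.counts[s].to_numpy()) for s in table.sample_ids},
        name=metric,
    )
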