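"""Consensus clustering over resampled probe subsets and plain hierarchical
clustering of samples.

Each resampling step draws a probe subset (without replacement, default 80%
of probes), computes the sample-sample Pearson dissimilarity 1 - r over it,
and cuts a Ward dendrogram at each requested k.  Co-clustering indicators
are averaged over resamples into a per-k consensus matrix; with probe-level
resampling every sample pair is co-sampled in every step, so the divisor is
simply the number of resamples.  The final per-k assignment reclusters
1 - consensus; per-k diagnostics are the consensus CDF area and the mean
silhouette width, and ``chosen_k`` maximizes the latter (advisory only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "ConsensusResult",
    "select_consensus_probes",
    "pearson_dissimilarity",
    "consensus_cluster",
    "hierarchical_cluster",
]


def select_consensus_probes(
    dhmr_probes: set[str], top1_mt: set[str], top1_wt: set[str]
) -> set[str]:
    """DHMR probes that are in exactly one cohort's top fraction
    (the symmetric difference of the two top sets)."""
    if not dhmr_probes or not top1_mt or not top1_wt:
        raise ValueError("probe sets must be nonempty")
    return set(dhmr_probes) & (set(top1_mt) ^ set(top1_wt))


def pearson_dissimilarity(matrix: np.ndarray) -> np.ndarray:
    """1 - Pearson r between columns (samples) of a probe x sample matrix."""
    m = np.asarray(matrix, dtype=float)
    sd = m.std(axis=0)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"sample at column {bad} has zero variance; Pearson undefined")
    d = 1.0 - np.corrcoef(m.T)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


@dataclass
class ConsensusResult:
    k_values: list[int]
    consensus_matrices: dict[int, pd.DataFrame]
    assignments: dict[int, pd.Series]
    cdf_summaries: dict[int, dict[str, float]]
    silhouette: dict[int, float]
    chosen_k: int
    n_resample: int
    subsample_fraction: float


def _cut(linkage: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.fcluster(linkage, t=k, criterion="maxclust")


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range: list[int] | range = range(2, 6),
    n_resample: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of the samples (columns) of a probe x sample
    beta matrix with Pearson dissimilarity and Ward linkage."""
    values = matrix.to_numpy(dtype=float)
    n_probes, n_samples = values.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    k_values = sorted(k_range)
    if max(k_values) > n_samples:
        raise ValueError(f"k={max(k_values)} exceeds {n_samples} samples")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    n_draw = int(np.ceil(subsample_fraction * n_probes))
    co = {k: np.zeros((n_samples, n_samples)) for k in k_values}
    for _ in range(n_resample):
        idx = rng.choice(n_probes, size=n_draw, replace=False)
        d = pearson_dissimilarity(values[idx])
        link = hierarchy.linkage(squareform(d, checks=False), method="ward")
        for k in k_values:
            labels = _cut(link, k)
            co[k] += labels[:, None] == labels[None, :]

    sample_ids = list(matrix.columns)
    consensus, assignments, cdfs, sils = {}, {}, {}, {}
    for k in k_values:
        m = co[k] / n_resample
        np.fill_diagonal(m, 1.0)
        consensus[k] = pd.DataFrame(m, index=sample_ids, columns=sample_ids)
        d_cons = 1.0 - m
        np.fill_diagonal(d_cons, 0.0)
        link = hierarchy.linkage(squareform(d_cons, checks=False), method="ward")
        labels = _cut(link, k)
        assignments[k] = pd.Series(labels, index=sample_ids, name=f"k{k}")
        tri = m[np.triu_indices(n_samples, 1)]
        grid = np.linspace(0, 1, 101)
        cdf = np.searchsorted(np.sort(tri), grid, side="right") / tri.size
        cdfs[k] = {"auc": float(np.trapezoid(cdf, grid))}
        if len(set(labels)) > 1:
            sils[k] = float(
                silhouette_score(d_cons, labels, metric="precomputed")
            )
        else:
            sils[k] = float("nan")
    finite = {k: s for k, s in sils.items() if np.isfinite(s)}
    chosen = max(finite, key=finite.get) if finite else k_values[0]
    return ConsensusResult(
        k_values, consensus, assignments, cdfs, sils, chosen,
        n_resample, subsample_fraction,
    )


def hierarchical_cluster(
    matrix: pd.DataFrame,
    k: int,
    distance: str = "pearson_dissimilarity",
) -> tuple[np.ndarray, pd.Series]:
    """Ward hierarchical clustering of samples; returns (linkage, labels)."""
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if distance == "pearson_dissimilarity":
        sd = values.std(axis=0)
        if (sd == 0).any():
            bad = matrix.columns[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"sample {bad!r} has constant profile; Pearson undefined")
        d = pearson_dissimilarity(values)
    elif distance == "euclidean":
        diff = values.T[:, None, :] - values.T[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    link = hierarchy.linkage(squareform(d, checks=False), method="ward")
    labels = _cut(link, k)
    return link, pd.Series(labels, index=matrix.columns, name=f"k{k}")
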