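"""Temporal co-expression clustering of circadian genes by consensus NMF.

Gene-by-time profiles are median-normalized and shifted to be nonnegative,
factorized repeatedly by KL-divergence multiplicative-update NMF from random
starts, and the run-to-run co-assignment frequencies form a consensus matrix.
Average-linkage hierarchical grouping of 1 - consensus, cut at the smallest
number of clusters where every cluster's mean within-cluster consensus
exceeds the threshold, yields the co-expression clusters; small clusters are
discarded.  (Cutting the consensus matrix can legitimately yield more
clusters than the factorization rank: a rank-3 consensus over four phase
archetypes resolves all four when runs disagree about which pair to merge.)

Phases are normalized by their period onto the 24-h circadian-time scale and
assigned to the four temporal windows dawn [CT22,2), day [2,10), dusk
[10,14), night [14,22).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .utils import circular_mean

__all__ = [
    "ConsensusMatrix",
    "ConsensusCluster",
    "prepare_nonnegative",
    "nmf_factorize",
    "kl_divergence",
    "consensus_matrix",
    "select_coexpression_clusters",
    "normalize_phase",
    "assign_phase_window",
    "phase_histogram",
    "PHASE_WINDOWS",
]

PHASE_WINDOWS = {
    "dawn": ((22.0, 24.0), (0.0, 2.0)),
    "day": ((2.0, 10.0),),
    "dusk": ((10.0, 14.0),),
    "night": ((14.0, 22.0),),
}


@dataclass
class ConsensusMatrix:
    gene_ids: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]
    k: int
    n_runs: int


@dataclass
class ConsensusCluster:
    member_gene_ids: list[str]
    mean_phase: float | None = None
    window: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def prepare_nonnegative(values: np.ndarray) -> np.ndarray:
    """Median-normalize each row and shift it by its minimum to >= 0.

    Subtracting the row median on the log scale removes the baseline while
    preserving temporal shape; the minimum shift makes the matrix admissible
    for NMF.
    """
    v = np.asarray(values, dtype=float)
    v = v - np.median(v, axis=1, keepdims=True)
    return v - v.min(axis=1, keepdims=True)


def nmf_factorize(
    matrix: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """KL-divergence multiplicative-update NMF from a random start."""
    v = np.asarray(matrix, dtype=float)
    if (v < 0).any():
        raise ValueError("NMF input must be nonnegative")
    if k < 1:
        raise ValueError("rank k must be >= 1")
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        w = model.fit_transform(v)
    return w, model.components_


def kl_divergence(v: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH), the NMF objective."""
    v = np.asarray(v, dtype=float)
    wh = np.maximum(w @ h, 1e-12)
    vs = np.maximum(v, 1e-12)
    return float(np.sum(v * np.log(vs / wh) - v + wh))


def consensus_matrix(
    matrix: np.ndarray,
    gene_ids: Sequence[str],
    k: int = 3,
    n_runs: int = 20,
    master_seed: int = 0,
) -> ConsensusMatrix:
    """Mean connectivity over repeated NMF runs with derived seeds.

    Each run assigns genes to their argmax factor; the connectivity matrix
    marks co-assigned pairs; the consensus is the mean over runs.  A run in
    which some factor is empty is retained (it still defines a partition).
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs for a consensus")
    v = np.asarray(matrix, dtype=float)
    n = v.shape[0]
    consensus = np.zeros((n, n))
    for run in range(n_runs):
        w, _ = nmf_factorize(v, k=k, seed=master_seed + run)
        labels = w.argmax(axis=1)
        conn = (labels[:, None] == labels[None, :]).astype(float)
        consensus += conn
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    return ConsensusMatrix(list(gene_ids), consensus, k=k, n_runs=n_runs)


def _mean_within(values: np.ndarray, idx: np.ndarray) -> float:
    if idx.size < 2:
        return 1.0
    sub = values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def select_coexpression_clusters(
    consensus: ConsensusMatrix,
    threshold: float = 0.8,
    min_size: int = 100,
    phases: Mapping[str, float] | None = None,
    max_clusters: int = 12,
    profiles: np.ndarray | None = None,
) -> list[ConsensusCluster]:
    """Cut the consensus matrix into co-expression clusters.

    Average-linkage grouping on 1 - consensus, flat-cut at the smallest
    number of clusters for which every cluster's mean within-cluster
    consensus exceeds the threshold; clusters below ``min_size`` are dropped
    and their members excluded.  With per-gene phases, each cluster gets the
    circular mean phase of its members and the matching temporal window.

    With ``profiles`` (rows aligned to the consensus gene ids), each
    consensus cluster is additionally required to be pairwise co-expressed:
    clusters are split by complete linkage on 1 - Pearson correlation at
    distance 1 - threshold, so every retained gene pair correlates above the
    threshold.  This is what lets a rank-k consensus resolve more than k
    phase groups when the factorization stably merges the two closest ones.
    """
    c = consensus.values
    n = c.shape[0]
    if not np.allclose(c, c.T, atol=1e-9):
        raise ValueError("consensus matrix must be symmetric")
    dist = squareform(np.clip(1.0 - c, 0.0, None), checks=False)
    z = linkage(dist, method="average")
    chosen = None
    best_fallback: list[np.ndarray] = []
    for n_clust in range(1, min(max_clusters, n) + 1):
        labels = fcluster(z, t=n_clust, criterion="maxclust")
        groups = [np.flatnonzero(labels == l) for l in np.unique(labels)]
        if all(_mean_within(c, g) > threshold for g in groups):
            chosen = groups
            break
        passing = [g for g in groups if _mean_within(c, g) > threshold and g.size >= min_size]
        if len(passing) > len(best_fallback):
            best_fallback = passing
    if chosen is None:
        # no cut makes every cluster cohesive: retain only the passing ones
        chosen = best_fallback
    if profiles is not None:
        profiles = np.asarray(profiles, dtype=float)
        refined = []
        for g in chosen:
            parts = _split_by_pairwise_correlation(profiles, g, threshold)
            # accept the split only where it reveals real substructure: at
            # least two co-expression groups of the minimum size; a coherent
            # phase continuum that would merely shatter stays whole
            if sum(p.size >= min_size for p in parts) >= 2:
                refined.extend(parts)
            else:
                refined.append(g)
        chosen = refined
    clusters = []
    for g in chosen:
        if g.size < min_size:
            continue
        members = [consensus.gene_ids[i] for i in g]
        mean_phase = window = None
        if phases is not None:
            mean_phase = circular_mean([phases[m] for m in members])
            window = assign_phase_window(mean_phase)
        clusters.append(ConsensusCluster(members, mean_phase=mean_phase, window=window))
    if not clusters:
        warnings.warn("no cluster passed the consensus threshold and size filter")
    clusters.sort(key=lambda cl: (-cl.size, cl.member_gene_ids[0]))
    return clusters


def _split_by_pairwise_correlation(
    profiles: np.ndarray, idx: np.ndarray, threshold: float
) -> list[np.ndarray]:
    """Split a gene group whose profiles are not mutually correlated.

    Average linkage on 1 - Pearson correlation, cut at distance
    1 - threshold: two phase groups whose average cross-correlation falls
    below the threshold separate, while a coherent group (average within-
    correlation above it) survives individual noisy pairs intact.
    """
    if idx.size < 2:
        return [idx]
    sub = profiles[idx]
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    z = linkage(dist, method="average")
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    return [idx[np.flatnonzero(labels == l)] for l in np.unique(labels)]


def normalize_phase(phase: float, period: float) -> float:
    """Map a phase in hours of an arbitrary period onto CT hours in [0, 24)."""
    if period <= 0:
        raise ValueError("period must be positive")
    return (phase % period) * 24.0 / period


def assign_phase_window(ct: float) -> str:
    """The temporal window containing a CT phase; boundaries are half-open."""
    if not 0.0 <= ct < 24.0:
        raise ValueError(f"CT phase must lie in [0, 24), got {ct}")
    for window, spans in PHASE_WINDOWS.items():
        for lo, hi in spans:
            if lo <= ct < hi:
                return window
    raise AssertionError("unreachable: windows cover [0, 24)")


def phase_histogram(phases: Sequence[float]) -> np.ndarray:
    """Counts of phases per one-hour bin [h, h+1) over [0, 24)."""
    counts, _ = np.histogram(list(phases), bins=np.arange(25))
    return counts
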