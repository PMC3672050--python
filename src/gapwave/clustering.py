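"""Correlation-distance PAM clustering of selected transcript profiles.

Profiles are z-scaled per transcript (shape matters, not level), pairwise
dissimilarity is the correlation distance d = 1 - r: uncorrelated pairs sit
at 1, identical shapes at 0, opposite shapes at 2.  Clustering is k-medoids
(partitioning around medoids): greedy BUILD initialisation followed by SWAP
passes until no single medoid/non-medoid exchange lowers the total cost.
The number of clusters is chosen as the largest k whose cluster median
profiles are pairwise "unique" (Pearson correlation below ``rho_max``).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def zscale(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Row-wise z-scaling (mean 0, SD 1 across days)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant profile cannot be z-scaled")
    return (v - v.mean(axis=1, keepdims=True)) / sd


def correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - Pearson r over rows; symmetric, zero diagonal, [0, 2]."""
    v = np.asarray(profiles, dtype=float)
    if np.any(v.std(axis=1) == 0):
        raise ValueError("constant profiles have undefined correlation")
    d = 1.0 - np.corrcoef(v)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclasses.dataclass
class PAMResult:
    k: int
    medoids: np.ndarray        # point indices of the medoids
    labels: np.ndarray         # cluster index (0..k-1) per point
    total_cost: float          # sum of distances to the assigned medoid


def _assign(d: np.ndarray, medoids: np.ndarray):
    sub = d[medoids]                       # (k, n)
    labels = sub.argmin(axis=0)            # ties -> lowest medoid position
    d1 = sub[labels, np.arange(d.shape[1])]
    if len(medoids) > 1:
        part = np.partition(sub, 1, axis=0)
        d2 = part[1]
    else:
        d2 = np.full(d.shape[1], np.inf)
    return labels, d1, d2


def pam_cluster(d: np.ndarray, k: int, rng_seed: int = 0) -> PAMResult:
    """Partitioning around medoids on a precomputed distance matrix.

    BUILD: start from the point minimising total distance, then greedily add
    the medoid giving the largest cost reduction.  SWAP: repeatedly apply the
    single best medoid/non-medoid exchange while it strictly lowers the total
    cost.  Ties are broken by the lowest point index, so the result is fully
    deterministic; ``rng_seed`` is accepted for interface stability but the
    algorithm draws no random numbers.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    dn = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dn[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        dn = np.minimum(dn, d[best])
    medoids = np.array(sorted(medoids))

    # SWAP
    labels, d1, d2 = _assign(d, medoids)
    while True:
        best_delta, best_pair = -1e-12, None
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        for h in np.flatnonzero(~in_medoids):
            dh = d[h]
            base = np.minimum(dh - d1, 0.0)
            shared = base.sum()
            # removing medoid j: its members re-attach to min(dh, second-best)
            contrib = np.minimum(dh, d2) - d1 - base
            per_medoid = np.bincount(labels, weights=contrib, minlength=len(medoids))
            deltas = shared + per_medoid
            j = int(np.argmin(deltas))
            if deltas[j] < best_delta:
                best_delta, best_pair = float(deltas[j]), (j, h)
        if best_pair is None:
            break
        j, h = best_pair
        medoids = np.array(sorted(np.r_[np.delete(medoids, j), h]))
        labels, d1, d2 = _assign(d, medoids)

    return PAMResult(k=k, medoids=medoids, labels=labels, total_cost=float(d1.sum()))


def median_z_profiles(m: ExpressionMatrix, labels) -> pd.DataFrame:
    """Per-cluster, per-day median of the members' z-scaled profiles.

    ``labels`` maps each row of ``m`` to a cluster id; empty clusters raise.
    Returns a DataFrame indexed by cluster id, columns = days.
    """
    labels = np.asarray(labels)
    if len(labels) != m.n_features:
        raise ValueError("labels length does not match matrix")
    z = zscale(m.values)
    out = {}
    for c in np.unique(labels):
        members = z[labels == c]
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        out[c] = np.median(members, axis=0)
    df = pd.DataFrame(out).T
    df.columns = list(m.col_days)
    df.index.name = "cluster"
    return df


def choose_k(d: np.ndarray, z_profiles: np.ndarray,
             k_range: tuple = (2, 10), rho_max: float = 0.8,
             col_days=None) -> int:
    """Largest k whose PAM clusters have pairwise-unique median profiles.

    A k is admissible if every pair of cluster median z-profiles has Pearson
    correlation below ``rho_max``; beyond the true structure, splitting a
    cluster yields two near-identical medians and the k becomes inadmissible.
    If no k in the range is admissible, returns 2 with a warning.
    """
    z = np.asarray(z_profiles, dtype=float)
    n = d.shape[0]
    lo, hi = k_range
    lo = max(2, lo)
    hi = min(hi, n - 1)
    admissible = []
    for k in range(lo, hi + 1):
        labels = pam_cluster(d, k).labels
        meds = np.vstack([np.median(z[labels == c], axis=0) for c in range(k)])
        if np.any(meds.std(axis=1) == 0):
            continue
        r = np.corrcoef(meds)
        iu = np.triu_indices(k, 1)
        if np.all(r[iu] < rho_max):
            admissible.append(k)
    if not admissible:
        warnings.warn("no k in range gives pairwise-unique clusters; falling back to k=2")
        return 2
    return max(admissible)


@dataclasses.dataclass
class ClusterResult:
    """PAM clustering outcome over the selected transcripts.

    Cluster ids are 1-based.  ``labels`` maps transcript id -> cluster id;
    ``median_z_profiles`` is indexed by cluster id with day columns.
    """

    k: int
    medoid_ids: list
    labels: pd.Series
    median_z_profiles: pd.DataFrame
    total_cost: float
    distance: np.ndarray

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def write_tsv(self, path) -> None:
        self.labels.rename("cluster").rename_axis("transcript_id").to_csv(path, sep="\t")


def cluster_transcripts(m: ExpressionMatrix, k="auto",
                        k_range: tuple = (2, 10), rho_max: float = 0.8,
                        rng_seed: int = 0) -> ClusterResult:
    """Distance + PAM + (optionally automatic) k, on a transcript matrix.

    ``m`` should hold the selected transcripts on log2 scale; profiles are
    z-scaled internally before the correlation distance is computed.
    """
    z = zscale(m.values)
    d = correlation_distance(z)
    if k == "auto":
        k = choose_k(d, z, k_range=k_range, rho_max=rho_max)
    res = pam_cluster(d, int(k), rng_seed=rng_seed)
    labels = pd.Series(res.labels + 1, index=m.row_ids, name="cluster")
    profiles = median_z_profiles(m, res.labels)
    profiles.index = profiles.index + 1
    return ClusterResult(
        k=res.k,
        medoid_ids=[m.row_ids[i] for i in res.medoids],
        labels=labels,
        median_z_profiles=profiles,
        total_cost=res.total_cost,
        distance=d,
    )
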