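"""Consensus clustering of response profiles (Monti resampling).

Samples (cell lines) are clustered repeatedly on random subsets of the
data; the consensus matrix records how often each sample pair lands in
the same cluster among the resamples where both were drawn.  Stable
structure shows up as near-0/1 consensus values.  The cluster number is
chosen by the largest relative gain in the area under the consensus CDF
(the delta-area criterion).  Feature selection beforehand keeps the top
fraction of features by median absolute deviation (MAD) across samples,
restricted to features measured in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ConsensusConfig:
    mad_fraction: float = 0.30
    k_range: tuple = (2, 3, 4, 5, 6)
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    subsample_features: bool = False
    linkage_method: str = "average"
    distance: str = "one_minus_pearson"  # or "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if not 0 < self.mad_fraction <= 1:
            raise ValueError("mad_fraction must lie in (0, 1]")


@dataclass
class ConsensusResult:
    consensus: dict            # k -> sample x sample DataFrame
    assignments: dict          # k -> Series of cluster labels
    cdf_area: dict             # k -> area under consensus CDF
    delta_area: dict           # k -> relative change in area
    chosen_k: int


def mad_select(matrix: pd.DataFrame, fraction: float = 0.30) -> pd.DataFrame:
    """Top ``ceil(fraction * n)`` complete features by MAD across samples.

    Features with any missing value are excluded before ranking, so the
    variability ranking is not driven by differing coverage.
    """
    complete = matrix.dropna(axis=0)
    if len(complete) == 0:
        raise ValueError("no features with complete values")
    med = complete.median(axis=1)
    mad = (complete.sub(med, axis=0)).abs().median(axis=1)
    n_keep = int(np.ceil(fraction * len(complete)))
    order = mad.sort_values(ascending=False, kind="mergesort")
    return complete.loc[order.index[:n_keep]]


def _distance_condensed(data: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance over columns (samples) of ``data``."""
    if metric == "one_minus_pearson":
        corr = np.corrcoef(data.T)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        return squareform(dist, checks=False)
    if metric == "euclidean":
        from scipy.spatial.distance import pdist
        return pdist(data.T)
    raise ValueError(f"unknown distance {metric!r}")


def _cut(condensed: np.ndarray, k: int, method: str) -> np.ndarray:
    z = linkage(condensed, method=method)
    return fcluster(z, k, criterion="maxclust")


def consensus_cluster(matrix: pd.DataFrame,
                      config: ConsensusConfig | None = None
                      ) -> ConsensusResult:
    """Monti-style consensus clustering of the matrix's samples.

    For each k in ``config.k_range``: ``n_resamples`` times, subsample
    ``subsample_fraction`` of the samples (and optionally of the
    features), hierarchically cluster the subsample at k, and count
    co-clustering per co-sampled pair.  Final assignments at each k come
    from clustering 1 - consensus; the chosen k maximizes the relative
    change of the area under the consensus CDF.
    """
    config = config or ConsensusConfig()
    n = matrix.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples")
    ks = [k for k in config.k_range]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range {ks} infeasible for {n} samples")
    data = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    n_sub = max(2, int(round(config.subsample_fraction * n)))
    consensus, assignments, areas = {}, {}, {}
    for k in ks:
        together = np.zeros((n, n))
        both = np.zeros((n, n))
        rng_k = np.random.default_rng(rng.integers(2 ** 31))
        for _ in range(config.n_resamples):
            cols = rng_k.choice(n, size=n_sub, replace=False)
            sub = data[:, cols]
            if config.subsample_features:
                nfeat = max(2, int(round(config.subsample_fraction
                                         * data.shape[0])))
                rows = rng_k.choice(data.shape[0], size=nfeat,
                                    replace=False)
                sub = sub[rows]
            labels = _cut(_distance_condensed(sub, config.distance), k,
                          config.linkage_method)
            for i_pos, i in enumerate(cols):
                for j_pos, j in enumerate(cols):
                    if i < j:
                        both[i, j] += 1
                        if labels[i_pos] == labels[j_pos]:
                            together[i, j] += 1
        with np.errstate(invalid="ignore"):
            cons = np.where(both > 0, together / np.maximum(both, 1), 0.0)
        cons = cons + cons.T
        np.fill_diagonal(cons, 1.0)
        cons_df = pd.DataFrame(cons, index=matrix.columns,
                               columns=matrix.columns)
        consensus[k] = cons_df
        final = _cut(squareform(np.clip(1.0 - cons, 0.0, None),
                                checks=False), k, config.linkage_method)
        assignments[k] = pd.Series(final, index=matrix.columns)
        vals = cons[np.triu_indices(n, k=1)]
        # area under the empirical CDF of consensus entries over [0, 1]
        # equals 1 - mean(vals) exactly for a step CDF
        areas[k] = float(1.0 - vals.mean())
    delta = {}
    prev = None
    for k in sorted(ks):
        if prev is None:
            delta[k] = areas[k]
        else:
            delta[k] = (areas[k] - prev) / prev if prev > 0 else areas[k]
        prev = areas[k]
    chosen_k = _choose_k(delta)
    return ConsensusResult(consensus, assignments, areas, delta, chosen_k)


def _choose_k(delta: dict, threshold: float = 0.1) -> int:
    """Elbow rule on the relative CDF-area gain.

    The area gain stays substantial while increasing k still separates
    real structure and collapses once genuine clusters start being
    split, so the chosen k is the largest one whose relative gain is at
    least ``threshold``; if none qualifies beyond the smallest k, that
    smallest k is returned.
    """
    ks = sorted(delta)
    eligible = [k for k in ks if delta[k] >= threshold]
    return eligible[-1] if eligible else ks[0]
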