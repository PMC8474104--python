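"""Callers and group statistics operating directly on summed probe
intensities: kernel-density cut-offs, hierarchical clustering, and
Kruskal-Wallis / Dunn / effect-size comparisons between genotype groups."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks

GENOTYPE_LABELS = {0: "WT", 1: "het", 2: "hom-del"}


class CutoffsNotFound(RuntimeError):
    """Fewer than two troughs/shoulders in the intensity density."""


@dataclass
class DensityCutoffs:
    probe_id: str
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if not self.c1 < self.c2:
            raise ValueError("require c1 < c2")


def density_cutoffs(s_values: np.ndarray, probe_id: str = "",
                    bandwidth_rule: str | float = "silverman",
                    grid_size: int = 512) -> DensityCutoffs:
    """Two intensity cut-offs from the density of summed intensities.

    Fits a Gaussian KDE (Silverman bandwidth by default), takes the two most
    prominent local minima of the density as (C1, C2); if fewer than two
    minima exist, falls back to shoulder detection via sign changes of the
    smoothed second derivative. Raises CutoffsNotFound otherwise.
    """
    s = np.asarray(s_values, dtype=float)
    if len(s) < 50:
        raise ValueError("need at least 50 samples for density cut-offs")
    if np.ptp(s) == 0:
        raise CutoffsNotFound("constant intensities")
    kde = stats.gaussian_kde(s, bw_method=bandwidth_rule)
    grid = np.linspace(s.min(), s.max(), grid_size)
    dens = kde(grid)

    minima, props = find_peaks(-dens, prominence=0.0)
    candidates = sorted(zip(props["prominences"], grid[minima]), reverse=True)
    points = sorted(v for _, v in candidates[:2])
    if len(points) < 2:
        # shoulder fallback: local minima of |slope| that are not density
        # extrema (a single Gaussian has none, a shoulder produces one)
        d1 = np.gradient(dens, grid)
        flat_idx, _ = find_peaks(-np.abs(d1))
        maxima, _ = find_peaks(dens)
        extrema = set(minima) | set(maxima)
        shoulders = [float(grid[i]) for i in flat_idx
                     if all(abs(i - e) > 2 for e in extrema)]
        pool = sorted(set(points) | set(shoulders))
        mode = grid[np.argmax(dens)]
        left = [p for p in pool if p < mode]
        right = [p for p in pool if p > mode]
        if left and right:
            points = [max(left), min(right)]
        elif len(pool) >= 2:
            points = pool[:2]
        else:
            raise CutoffsNotFound("could not locate two troughs or shoulders")
    return DensityCutoffs(probe_id=probe_id, c1=float(points[0]), c2=float(points[1]))


def call_by_cutoffs(s: np.ndarray, cutoffs: DensityCutoffs) -> np.ndarray:
    """Genotype from summed intensity: s <= C1 -> hom-del (2);
    C1 < s < C2 -> het (1); s >= C2 -> WT (0)."""
    s = np.asarray(s, dtype=float)
    calls = np.ones(s.shape, dtype=np.int8)
    calls[s <= cutoffs.c1] = 2
    calls[s >= cutoffs.c2] = 0
    return calls


@dataclass
class HierarchicalCallResult:
    calls: np.ndarray
    linkage_matrix: np.ndarray
    cluster_labels: np.ndarray          # raw cluster index per sample
    cluster_mean_s: np.ndarray          # mean summed intensity per cluster
    linkage_method: str = "complete"
    metric: str = "euclidean"


def hierarchical_call(intensity_matrix: np.ndarray, n_clusters: int = 3,
                      linkage_method: str = "complete") -> HierarchicalCallResult:
    """Cluster samples on standardized per-probe intensities and label the
    clusters hom-del/het/WT by ascending cluster-mean summed intensity.

    intensity_matrix: samples x probes summed intensities (k >= 2 probes).
    """
    X = np.asarray(intensity_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a samples x probes matrix with >= 2 probes")
    if X.shape[0] < n_clusters:
        raise ValueError(f"need at least {n_clusters} samples")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    link = linkage(Z, method=linkage_method, metric="euclidean")
    labels = fcluster(link, t=n_clusters, criterion="maxclust")
    s_total = X.sum(axis=1)
    uniq = np.unique(labels)
    means = np.array([s_total[labels == u].mean() for u in uniq])
    order = np.argsort(means)  # lowest summed intensity -> hom-del (2)
    geno_of_cluster = {uniq[order[k]]: genotype
                       for k, genotype in zip(range(len(uniq)), (2, 1, 0))}
    calls = np.array([geno_of_cluster.get(l, 1) for l in labels], dtype=np.int8)
    return HierarchicalCallResult(calls=calls, linkage_matrix=link,
                                  cluster_labels=labels, cluster_mean_s=means[order],
                                  linkage_method=linkage_method)


@dataclass
class IntensityGroupStats:
    probe_id: str
    kw_h: float
    kw_p: float
    pairs: list[tuple[int, int]]
    dunn_z: dict = field(default_factory=dict)
    dunn_p: dict = field(default_factory=dict)
    dunn_p_bonferroni: dict = field(default_factory=dict)
    cohens_d: dict = field(default_factory=dict)
    hedges_g: dict = field(default_factory=dict)


def _effect_sizes(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n1, n2 = len(a), len(b)
    s_pooled = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    d = (a.mean() - b.mean()) / s_pooled
    g = d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0))
    return float(d), float(g)


def group_difference_tests(s_values: np.ndarray, true_genotypes: np.ndarray,
                           probe_id: str = "") -> IntensityGroupStats:
    """Kruskal-Wallis across genotype groups, Dunn pairwise z with tie
    correction, plus Cohen's d and Hedges' g per pair."""
    s = np.asarray(s_values, dtype=float)
    g = np.asarray(true_genotypes, dtype=int)
    groups = {}
    for label in np.unique(g):
        vals = s[g == label]
        if len(vals) == 0:
            warnings.warn(f"dropping empty genotype group {label}", stacklevel=2)
            continue
        groups[int(label)] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    kw_h, kw_p = stats.kruskal(*groups.values())

    all_vals = np.concatenate(list(groups.values()))
    N = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks, sizes, offset = {}, {}, 0
    for label, vals in groups.items():
        mean_ranks[label] = ranks[offset:offset + len(vals)].mean()
        sizes[label] = len(vals)
        offset += len(vals)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))

    result = IntensityGroupStats(probe_id=probe_id, kw_h=float(kw_h), kw_p=float(kw_p),
                                 pairs=list(combinations(sorted(groups), 2)))
    m = len(result.pairs)
    for (i, j) in result.pairs:
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        result.dunn_z[(i, j)] = float(z)
        result.dunn_p[(i, j)] = float(p)
        result.dunn_p_bonferroni[(i, j)] = float(min(1.0, p * m))
        d, hg = _effect_sizes(groups[i], groups[j])
        result.cohens_d[(i, j)] = d
        result.hedges_g[(i, j)] = hg
    return result
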