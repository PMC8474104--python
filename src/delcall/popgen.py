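"""LD, extended haplotype homozygosity, haplotype spectra and Tajima's D
over phased panels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .panel import HaplotypePanel


class UndefinedStatistic(ValueError):
    """A statistic is undefined for the given input (e.g. monomorphic site)."""


@dataclass
class LDResult:
    r: float
    r2: float
    dprime: float


def pairwise_ld(panel: HaplotypePanel, i: int, j: int) -> LDResult:
    """Signed r, r-squared and D' from phased two-locus haplotype counts.

    D = p11 - pA*pB over haplotype frequencies of the '1' alleles;
    r = D / sqrt(pA qA pB qB); D' = D/Dmax with Dmax = min(pA qB, qA pB) for
    D > 0 and min(pA pB, qA qB) otherwise.
    """
    if i == j:
        raise ValueError("need two distinct variants")
    a = panel.alleles[:, i].astype(float)
    b = panel.alleles[:, j].astype(float)
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0):
        raise UndefinedStatistic(f"variant {panel.variant_ids[i]} is monomorphic")
    if pB in (0.0, 1.0):
        raise UndefinedStatistic(f"variant {panel.variant_ids[j]} is monomorphic")
    qA, qB = 1.0 - pA, 1.0 - pB
    p11 = float((a * b).mean())
    D = p11 - pA * pB
    r = D / np.sqrt(pA * qA * pB * qB)
    if D > 0:
        dmax = min(pA * qB, qA * pB)
    else:
        dmax = min(pA * pB, qA * qB)
    dprime = 0.0 if dmax == 0 else D / dmax
    return LDResult(r=float(r), r2=float(r * r), dprime=float(dprime))


def ld_profile(panel: HaplotypePanel, focal_index: int) -> pd.DataFrame:
    """LD of every other variant against a focal variant, ordered by position.

    Undefined pairs (monomorphic partners) are retained with NaN metrics and
    a reason string rather than silently dropped.
    """
    af = panel.allele_frequency(focal_index)
    if af in (0.0, 1.0):
        raise UndefinedStatistic("focal variant is monomorphic")
    rows = []
    for j in range(panel.n_variants):
        if j == focal_index:
            continue
        row = {"variant_id": panel.variant_ids[j],
               "position_bp": int(panel.positions_bp[j]),
               "r": np.nan, "r2": np.nan, "dprime": np.nan, "reason": ""}
        try:
            ld = pairwise_ld(panel, focal_index, j)
            row.update(r=ld.r, r2=ld.r2, dprime=ld.dprime)
        except UndefinedStatistic as exc:
            row["reason"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("position_bp", ignore_index=True)


@dataclass
class EHHCurve:
    focal_index: int
    allele: int
    indices: np.ndarray     # variant column indices, ascending
    positions: np.ndarray
    ehh_values: np.ndarray  # aligned with indices; 1.0 at the focal variant


def _homozygosity(hashes: np.ndarray) -> float:
    """Probability two distinct chromosomes share a haplotype class."""
    n = len(hashes)
    _, counts = np.unique(hashes, return_counts=True)
    num = (counts * (counts - 1) // 2).sum()
    den = n * (n - 1) // 2
    return float(num / den)


def ehh(panel: HaplotypePanel, focal_index: int, allele: int) -> EHHCurve:
    """Extended haplotype homozygosity outward from a focal allele.

    EHH at distance x = sum over distinct extended haplotypes h of
    C(n_h, 2) / C(n_carriers, 2), computed separately leftward and rightward
    of the focal variant; EHH(focal) = 1 by construction.
    """
    carriers = panel.alleles[:, focal_index] == allele
    if carriers.sum() < 2:
        raise UndefinedStatistic("fewer than 2 chromosomes carry the focal allele")
    H = panel.alleles[carriers, :]
    n_var = panel.n_variants
    values = np.empty(n_var)
    values[focal_index] = 1.0
    # extend rightward, accumulating a haplotype-class id per chromosome
    classes = np.zeros(H.shape[0], dtype=np.int64)
    for j in range(focal_index + 1, n_var):
        keys = classes * 2 + H[:, j]
        _, classes = np.unique(keys, return_inverse=True)
        values[j] = _homozygosity(classes)
    classes = np.zeros(H.shape[0], dtype=np.int64)
    for j in range(focal_index - 1, -1, -1):
        keys = classes * 2 + H[:, j]
        _, classes = np.unique(keys, return_inverse=True)
        values[j] = _homozygosity(classes)
    idx = np.arange(n_var)
    return EHHCurve(focal_index=focal_index, allele=allele, indices=idx,
                    positions=panel.positions_bp.copy(), ehh_values=values)


@dataclass
class HaplotypeSpectrum:
    haplotypes: list[str]   # distinct 0/1 strings over the window
    counts: np.ndarray
    frequencies: np.ndarray
    n_chromosomes: int
    window: tuple[int, int]


def haplotype_spectrum(panel: HaplotypePanel, window: tuple[int, int] | None = None,
                       rows: np.ndarray | None = None) -> HaplotypeSpectrum:
    """Distinct haplotype strings and their frequencies over a column window.

    window is a half-open (start, stop) column range; rows optionally
    restricts to a subset of chromosomes (e.g. deletion carriers).
    """
    start, stop = window if window is not None else (0, panel.n_variants)
    if stop <= start:
        raise ValueError("empty window")
    sub = panel.alleles[:, start:stop]
    if rows is not None:
        sub = sub[np.asarray(rows)]
    strings = ["".join(map(str, row)) for row in sub]
    uniq, counts = np.unique(strings, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    uniq, counts = uniq[order], counts[order]
    return HaplotypeSpectrum(haplotypes=list(uniq), counts=counts,
                             frequencies=counts / counts.sum(),
                             n_chromosomes=int(counts.sum()), window=(start, stop))


def haplotype_diversity(spectrum: HaplotypeSpectrum) -> float:
    """Nei haplotype diversity Hd = n (1 - sum p_i^2) / (n - 1)."""
    n = spectrum.n_chromosomes
    if n < 2:
        raise UndefinedStatistic("need at least 2 chromosomes")
    return float(n * (1.0 - np.sum(spectrum.frequencies ** 2)) / (n - 1))


def tajimas_d(panel: HaplotypePanel, window: tuple[int, int] | None = None) -> float:
    """Tajima's D over the window from pairwise diversity and segregating sites."""
    start, stop = window if window is not None else (0, panel.n_variants)
    sub = panel.alleles[:, start:stop].astype(float)
    n = sub.shape[0]
    if n < 4:
        raise UndefinedStatistic("need at least 4 chromosomes")
    p = sub.mean(axis=0)
    seg = (p > 0) & (p < 1)
    S = int(seg.sum())
    if S == 0:
        raise UndefinedStatistic("no segregating sites in window")
    # mean pairwise differences: sum over sites of 2*count1*count0/(n choose 2)
    c1 = sub.sum(axis=0)
    pi = float(np.sum(c1 * (n - c1)) / (n * (n - 1) / 2.0))
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1_ = b1 - 1.0 / a1
    c2_ = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1_ / a1
    e2 = c2_ / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))


@dataclass
class HaplotypeDendrogram:
    linkage_matrix: np.ndarray        # scipy hierarchical-linkage encoding
    haplotypes: list[str]
    counts: np.ndarray
    carrier_fraction: np.ndarray      # per-leaf deletion-carrier fraction
    linkage_method: str


def cluster_haplotypes(spectrum: HaplotypeSpectrum,
                       linkage_method: str = "complete",
                       carrier_fraction: np.ndarray | None = None) -> HaplotypeDendrogram:
    """Agglomerative clustering of distinct haplotypes on Hamming distance.

    One distinct haplotype yields a single-leaf tree (empty linkage matrix).
    """
    k = len(spectrum.haplotypes)
    if carrier_fraction is None:
        carrier_fraction = np.zeros(k)
    if k < 2:
        return HaplotypeDendrogram(np.empty((0, 4)), list(spectrum.haplotypes),
                                   spectrum.counts.copy(), np.asarray(carrier_fraction, float),
                                   linkage_method)
    X = np.array([[int(c) for c in h] for h in spectrum.haplotypes], dtype=float)
    dist = pdist(X, metric="hamming") * X.shape[1]  # absolute mismatch counts
    Z = linkage(dist, method=linkage_method)
    return HaplotypeDendrogram(Z, list(spectrum.haplotypes), spectrum.counts.copy(),
                               np.asarray(carrier_fraction, float), linkage_method)


def carrier_subtree_count(panel: HaplotypePanel, window: tuple[int, int] | None = None,
                          min_hamming: int = 1) -> int:
    """Number of well-separated flanking-haplotype groups among deletion carriers.

    Counts connected components of carrier haplotypes linked at Hamming
    distance <= min_hamming — a proxy for the number of independent origins.
    """
    carriers = panel.alleles[:, panel.del_index] == 1
    spec = haplotype_spectrum(panel, window=window, rows=np.nonzero(carriers)[0])
    X = np.array([[int(c) for c in h] for h in spec.haplotypes], dtype=int)
    if len(X) == 1:
        return 1
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import squareform
    D = squareform(pdist(X, metric="hamming") * X.shape[1])
    n_comp, _ = connected_components(D <= min_hamming, directed=False)
    return int(n_comp)
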