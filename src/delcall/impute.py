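"""Haplotype-copying imputation of a masked deletion allele.

A Li-Stephens hidden Markov model: each test chromosome is modelled as an
imperfect mosaic of the reference haplotypes. Between adjacent markers the
copied haplotype switches with probability rho_j = 1 - exp(-4*Ne*c_j/H)
(c_j the map distance in Morgans, H the number of reference haplotypes),
the new template drawn uniformly; alleles are emitted with error theta.
The deletion-allele posterior is read off the copying-state posterior at the
deletion's position, smoothed by theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import PerformanceReport, performance_report
from .panel import HaplotypePanel

logger = logging.getLogger(__name__)

NO_CALL = -1
MIN_MORGANS = 1e-8


@dataclass
class ImputationConfig:
    n_ref_individuals: int = 100
    ne: float = 20_000.0
    theta: float = 1e-3
    thresholds: tuple[float, ...] = (0.7, 0.9)
    runs: int = 1000
    seed: int = 0

    def validate(self, n_total: int | None = None) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0,1)")
        if any(not (1.0 / 3.0 < t <= 1.0) for t in self.thresholds):
            raise ValueError("thresholds must lie in (1/3, 1]")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.ne <= 0:
            raise ValueError("Ne must be positive")
        if n_total is not None and self.n_ref_individuals >= n_total:
            raise ValueError("reference panel must be smaller than the cohort")


@dataclass
class ReferenceSplit:
    ref_indices: np.ndarray    # individual indices
    test_indices: np.ndarray
    ref_haplotypes: np.ndarray   # 2*n_ref x n_variants, deletion typed
    test_haplotypes: np.ndarray  # 2*n_test x n_variants, deletion column = -1
    truth_genotypes: np.ndarray  # deletion genotype per test individual


def split_reference(panel: HaplotypePanel, config: ImputationConfig,
                    rng: np.random.Generator | None = None) -> ReferenceSplit:
    """Random disjoint reference/test split; only the deletion column is
    masked (-1) in the test haplotypes."""
    if panel.del_index is None:
        raise ValueError("panel has no flagged deletion locus")
    config.validate(panel.n_individuals)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    perm = rng.permutation(panel.n_individuals)
    ref_ind = np.sort(perm[:config.n_ref_individuals])
    test_ind = np.sort(perm[config.n_ref_individuals:])
    if np.intersect1d(ref_ind, test_ind).size:
        raise ValueError("reference and test sets overlap")

    def hap_rows(ind):
        return np.ravel(np.column_stack([2 * ind, 2 * ind + 1]))

    ref_h = panel.alleles[hap_rows(ref_ind), :].astype(np.int8)
    test_h = panel.alleles[hap_rows(test_ind), :].astype(np.int8).copy()
    truth = (test_h[0::2, panel.del_index] + test_h[1::2, panel.del_index]).astype(np.int8)
    test_h[:, panel.del_index] = -1
    return ReferenceSplit(ref_indices=ref_ind, test_indices=test_ind,
                          ref_haplotypes=ref_h, test_haplotypes=test_h,
                          truth_genotypes=truth)


def _switch_probs(cum_morgans: np.ndarray, ne: float, n_ref_haps: int) -> np.ndarray:
    c = np.maximum(np.diff(cum_morgans), MIN_MORGANS)
    if np.all(np.diff(cum_morgans) <= 0):
        logger.warning("zero-width genetic map; using uniform recombination floor")
    return 1.0 - np.exp(-4.0 * ne * c / n_ref_haps)


def _emissions(obs_col: np.ndarray, ref_col: np.ndarray, theta: float) -> np.ndarray:
    """(T, H) emission probabilities; missing observations emit 1."""
    match = obs_col[:, None] == ref_col[None, :]
    e = np.where(match, 1.0 - theta, theta)
    e[obs_col < 0, :] = 1.0
    return e


def deletion_posteriors(test_haplotypes: np.ndarray, ref_haplotypes: np.ndarray,
                        cum_morgans: np.ndarray, del_index: int,
                        config: ImputationConfig) -> np.ndarray:
    """Per-test-chromosome posterior probability of the deletion allele.

    Scaled forward and backward passes meet at the deletion column; the
    posterior is theta-smoothed over the copied haplotypes' deletion alleles.
    """
    obs = np.asarray(test_haplotypes)
    ref = np.asarray(ref_haplotypes)
    T, M = obs.shape
    H = ref.shape[0]
    if ref.shape[1] != M:
        raise ValueError("test and reference marker grids differ")
    if len(cum_morgans) != M:
        raise ValueError("map length does not match marker count")
    rho = _switch_probs(cum_morgans, config.ne, H)
    theta = config.theta

    alpha = _emissions(obs[:, 0], ref[:, 0], theta) / H
    alpha /= alpha.sum(axis=1, keepdims=True)
    for j in range(1, del_index + 1):
        pre = (1.0 - rho[j - 1]) * alpha + rho[j - 1] / H
        alpha = pre * _emissions(obs[:, j], ref[:, j], theta)
        alpha /= alpha.sum(axis=1, keepdims=True)

    beta = np.ones((T, H))
    for j in range(M - 2, del_index - 1, -1):
        tmp = beta * _emissions(obs[:, j + 1], ref[:, j + 1], theta)
        beta = (1.0 - rho[j]) * tmp + rho[j] * tmp.mean(axis=1, keepdims=True)
        beta /= beta.sum(axis=1, keepdims=True)

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    copied = gamma @ (ref[:, del_index] == 1).astype(float)
    return theta + (1.0 - 2.0 * theta) * copied


def impute_deletion_haplotype(test_haplotype: np.ndarray, ref_haplotypes: np.ndarray,
                              cum_morgans: np.ndarray, del_index: int,
                              config: ImputationConfig) -> float:
    """Single-chromosome convenience wrapper around deletion_posteriors."""
    p = deletion_posteriors(np.asarray(test_haplotype)[None, :], ref_haplotypes,
                            cum_morgans, del_index, config)
    return float(p[0])


def impute_deletion_genotype(p1: float | np.ndarray, p2: float | np.ndarray) -> np.ndarray:
    """Genotype probability triple(s) (WT, het, hom) from two independent
    per-chromosome deletion posteriors."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("posteriors must lie in [0,1]")
    triple = np.stack([(1 - p1) * (1 - p2), p1 * (1 - p2) + p2 * (1 - p1), p1 * p2], axis=-1)
    return triple


def call_genotypes(prob_triples: np.ndarray, threshold: float) -> np.ndarray:
    """Argmax genotype if its probability reaches the threshold, else no-call.

    A probability exactly equal to the threshold is called."""
    if not 1.0 / 3.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (1/3, 1]")
    P = np.asarray(prob_triples, dtype=float)
    calls = np.argmax(P, axis=-1).astype(np.int8)
    calls[np.max(P, axis=-1) < threshold] = NO_CALL
    return calls


@dataclass
class CrossValidationResult:
    config: ImputationConfig
    per_run: dict[float, list[PerformanceReport]]   # threshold -> run reports
    failed_runs: int = 0
    summary_cache: dict = field(default_factory=dict)

    def summary(self, threshold: float) -> dict[str, dict[str, float]]:
        """Distribution summary (min/q1/median/mean/sd/max) of headline
        metrics across runs at one threshold."""
        key = round(threshold, 6)
        if key in self.summary_cache:
            return self.summary_cache[key]
        reports = self.per_run[threshold]

        def collect(fn):
            return np.array([fn(r) for r in reports], dtype=float)

        metrics = {
            "n_correct": collect(lambda r: r.n_correct),
            "n_total": collect(lambda r: r.n),
            "n_no_call": collect(lambda r: r.n_no_call),
            "correct_proportion": collect(lambda r: r.correct_proportion),
            "adjusted_correct_proportion": collect(lambda r: r.adjusted_correct_proportion),
            "no_call_proportion": collect(lambda r: r.no_call_proportion),
            "dosage_correlation": collect(lambda r: r.dosage_correlation),
        }
        for cls, name in ((0, "wt"), (1, "het"), (2, "hom")):
            for rate in ("sensitivity", "specificity", "accuracy", "ppv"):
                metrics[f"{name}_{rate}"] = collect(lambda r, c=cls, rt=rate:
                                                    getattr(r, rt)[c])
        out = {}
        for name, vals in metrics.items():
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                out[name] = {}
                continue
            out[name] = {
                "min": float(np.min(vals)),
                "q1": float(np.percentile(vals, 25)),
                "median": float(np.median(vals)),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "q3": float(np.percentile(vals, 75)),
                "max": float(np.max(vals)),
            }
        self.summary_cache[key] = out
        return out


def imputation_cross_validation(panel: HaplotypePanel, config: ImputationConfig,
                                cum_morgans: np.ndarray | None = None) -> CrossValidationResult:
    """Repeated random reference/test splits: impute the masked deletion in
    the test set and score calls against the held-back truth."""
    config.validate(panel.n_individuals)
    if cum_morgans is None:
        # default 1 cM/Mb physical -> genetic scaling
        cum_morgans = (panel.positions_bp - panel.positions_bp[0]) / 1e8
    rng = np.random.default_rng(config.seed)
    per_run: dict[float, list[PerformanceReport]] = {t: [] for t in config.thresholds}
    failed = 0
    for _ in range(config.runs):
        split = split_reference(panel, config, rng)
        p = deletion_posteriors(split.test_haplotypes, split.ref_haplotypes,
                                cum_morgans, panel.del_index, config)
        triples = impute_deletion_genotype(p[0::2], p[1::2])
        for t in config.thresholds:
            calls = call_genotypes(triples, t)
            if np.all(calls == NO_CALL):
                failed += 1
                logger.warning("run produced no calls at threshold %.2f", t)
                continue
            per_run[t].append(performance_report(split.truth_genotypes, calls))
    return CrossValidationResult(config=config, per_run=per_run, failed_runs=failed)
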