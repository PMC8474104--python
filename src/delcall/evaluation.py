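"""Performance metrics for inferred vs directly typed genotypes, and a
side-by-side harness running every caller plus association on one dataset."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NO_CALL = -1
CLASSES = (0, 1, 2)


@dataclass
class PerformanceReport:
    """3x(3+no-call) confusion table and derived rates.

    Per-class one-vs-rest rates are computed on called samples only;
    correct_proportion is over all samples while
    adjusted_correct_proportion = correct / (total - no-calls).
    Undefined rates (zero denominators) are NaN, never 0.
    """

    confusion: np.ndarray               # rows = truth 0/1/2; cols = call 0/1/2/no-call
    sensitivity: dict = field(default_factory=dict)
    specificity: dict = field(default_factory=dict)
    accuracy: dict = field(default_factory=dict)
    ppv: dict = field(default_factory=dict)
    npv: dict = field(default_factory=dict)
    correct_proportion: float = np.nan
    adjusted_correct_proportion: float = np.nan
    no_call_proportion: float = np.nan
    dosage_correlation: float = np.nan
    n: int = 0
    n_correct: int = 0
    n_no_call: int = 0


def performance_report(truth: np.ndarray, calls: np.ndarray) -> PerformanceReport:
    truth = np.asarray(truth, dtype=int)
    calls = np.asarray(calls, dtype=int)
    if truth.shape != calls.shape:
        raise ValueError("truth and calls must have equal length")
    n = len(truth)
    confusion = np.zeros((3, 4), dtype=int)
    for t, c in zip(truth, calls):
        confusion[t, 3 if c == NO_CALL else c] += 1

    called = calls != NO_CALL
    n_no_call = int((~called).sum())
    n_correct = int(np.sum(truth[called] == calls[called]))
    report = PerformanceReport(confusion=confusion, n=n, n_correct=n_correct,
                               n_no_call=n_no_call)
    report.correct_proportion = n_correct / n if n else np.nan
    n_called = n - n_no_call
    report.adjusted_correct_proportion = n_correct / n_called if n_called else np.nan
    report.no_call_proportion = n_no_call / n if n else np.nan

    t_c, c_c = truth[called], calls[called]
    for cls in CLASSES:
        tp = np.sum((t_c == cls) & (c_c == cls))
        fn = np.sum((t_c == cls) & (c_c != cls))
        fp = np.sum((t_c != cls) & (c_c == cls))
        tn = np.sum((t_c != cls) & (c_c != cls))
        report.sensitivity[cls] = tp / (tp + fn) if tp + fn else np.nan
        report.specificity[cls] = tn / (tn + fp) if tn + fp else np.nan
        report.ppv[cls] = tp / (tp + fp) if tp + fp else np.nan
        report.npv[cls] = tn / (tn + fn) if tn + fn else np.nan
        report.accuracy[cls] = (tp + tn) / n_called if n_called else np.nan
    if n_called >= 2 and np.std(t_c) > 0 and np.std(c_c) > 0:
        report.dosage_correlation = float(np.corrcoef(t_c, c_c)[0, 1])
    return report


def report_to_row(report: PerformanceReport, method: str = "") -> dict:
    row = {"method": method, "n": report.n, "n_correct": report.n_correct,
           "n_no_call": report.n_no_call,
           "correct_proportion": report.correct_proportion,
           "adjusted_correct_proportion": report.adjusted_correct_proportion,
           "no_call_proportion": report.no_call_proportion,
           "dosage_correlation": report.dosage_correlation}
    for cls, name in ((0, "wt"), (1, "het"), (2, "hom")):
        for rate in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            row[f"{name}_{rate}"] = getattr(report, rate).get(cls, np.nan)
    return row


def compare_methods(dataset, methods: list[str] | None = None, seed: int = 0,
                    assoc_models: tuple[str, ...] = ("additive", "genotypic"),
                    imputation_runs: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every caller plus the direct truth through performance and
    association scoring; failures are isolated per method.

    Returns (performance table, association table) in long format.
    """
    from . import association as assoc_mod
    from . import intensity as intensity_mod
    from . import models as models_mod
    from .impute import (ImputationConfig, NO_CALL, call_genotypes,
                         deletion_posteriors, impute_deletion_genotype,
                         split_reference)

    if methods is None:
        methods = ["truth", "cutoffs", "hclust", "mrm", "cart", "imputation"]
    rng = np.random.default_rng(seed)
    truth = dataset.panel.deletion_genotypes()
    n = len(truth)
    probes = dataset.intensities.deletion_probes or dataset.intensities.probes
    s_matrix = dataset.intensities.wide("s")[probes].to_numpy()

    calls_by_method: dict[str, np.ndarray] = {}
    perf_rows, assoc_rows = [], []
    for method in methods:
        try:
            if method == "truth":
                calls = truth.copy()
            elif method == "cutoffs":
                probe = probes[0]
                cuts = intensity_mod.density_cutoffs(s_matrix[:, 0], probe_id=probe)
                calls = intensity_mod.call_by_cutoffs(s_matrix[:, 0], cuts)
            elif method == "hclust":
                calls = intensity_mod.hierarchical_call(s_matrix).calls
            elif method in ("mrm", "cart"):
                X, names = dataset.intensities.feature_matrix(probes)
                for _ in range(50):
                    idx = rng.choice(n, size=min(100, max(30, n // 5)), replace=False)
                    if len(np.unique(truth[idx])) == 3:
                        break
                if method == "mrm":
                    model = models_mod.fit_mrm(X[idx], truth[idx], feature_names=names)
                    _, calls = models_mod.predict_mrm(model, X)
                else:
                    model = models_mod.fit_cart(X[idx], truth[idx], feature_names=names)
                    calls = models_mod.predict_cart(model, X)
            elif method == "imputation":
                cfg = ImputationConfig(n_ref_individuals=min(100, n // 3),
                                       runs=imputation_runs, seed=seed)
                cum_m = (dataset.panel.positions_bp - dataset.panel.positions_bp[0]) / 1e8
                split = split_reference(dataset.panel, cfg, rng)
                p = deletion_posteriors(split.test_haplotypes, split.ref_haplotypes,
                                        cum_m, dataset.panel.del_index, cfg)
                triples = impute_deletion_genotype(p[0::2], p[1::2])
                calls_test = call_genotypes(triples, cfg.thresholds[0])
                calls = np.full(n, NO_CALL, dtype=int)
                calls[split.test_indices] = calls_test
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as exc:  # noqa: BLE001 - isolate per-method failures
            logger.warning("method %s failed: %s", method, exc)
            perf_rows.append({"method": method, "failed": True, "error": str(exc)})
            continue
        calls_by_method[method] = np.asarray(calls, dtype=int)
        row = report_to_row(performance_report(truth, calls_by_method[method]), method)
        row["failed"] = False
        perf_rows.append(row)

    for method, calls in calls_by_method.items():
        for model in assoc_models:
            try:
                res = assoc_mod.genetic_association(calls, dataset.phenotypes,
                                                    model=model, no_call_code=NO_CALL)
                for term in res.terms:
                    assoc_rows.append({"method": method, "model": model, "term": term.name,
                                       "or": term.odds_ratio, "ci_low": term.ci_low,
                                       "ci_high": term.ci_high, "p": term.p,
                                       "n": res.n_used, "converged": res.converged})
            except Exception as exc:  # noqa: BLE001
                logger.warning("association for %s/%s failed: %s", method, model, exc)
                assoc_rows.append({"method": method, "model": model, "term": "FAILED",
                                   "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                   "p": np.nan, "n": 0, "converged": False})
    return pd.DataFrame(perf_rows), pd.DataFrame(assoc_rows)
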