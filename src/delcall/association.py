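"""Case-control association testing via fixed-effects logistic regression.

Genotypes enter under one of five encodings (additive dosage, two-indicator
genotypic, dominant, recessive, heterozygous); sex, ethnicity contrasts and
rs334 dosage are the standard adjustment set. Fitting is iteratively
reweighted least squares with Wald confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import PhenotypeTable

GENETIC_MODELS = ("additive", "genotypic", "dominant", "recessive", "heterozygous")
NO_CALL = -1


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable design matrix."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    column_names: list[str]


def fit_logistic(response: np.ndarray, design: np.ndarray,
                 column_names: list[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 50) -> LogisticFit:
    """IRLS logistic regression; flags separation (|beta| > 15) as
    non-converged rather than erroring."""
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    n, p = X.shape
    if column_names is None:
        column_names = [f"x{j}" for j in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns via pivoted QR
        _, R, piv = __import__("scipy").linalg.qr(X, pivoting=True)
        bad = sorted(column_names[j] for j in piv[rank:])
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if np.any(np.abs(beta) > 15):
        warnings.warn("possible separation: |beta| > 15; fit flagged non-converged",
                      stacklevel=2)
        converged = False

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, None))
                      + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None))))
    return LogisticFit(coef=beta, cov=cov, se=se, z=zstat, p=pvals, loglik=ll,
                       iterations=it, converged=converged, column_names=column_names)


@dataclass
class TermResult:
    name: str
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class AssociationResult:
    variant_id: str
    model: str
    terms: list[TermResult] = field(default_factory=list)
    n_used: int = 0
    n_dropped_no_call: int = 0
    converged: bool = True


def _encode_genotype(g: np.ndarray, model: str) -> tuple[np.ndarray, list[str]]:
    if model == "additive":
        return g[:, None].astype(float), ["dosage"]
    if model == "genotypic":
        cols, names = [], []
        for code, name in ((1, "het"), (2, "hom")):
            ind = (g == code).astype(float)
            if ind.sum() == 0:
                warnings.warn(f"empty genotype class '{name}' dropped from genotypic model",
                              stacklevel=3)
                continue
            cols.append(ind)
            names.append(name)
        if not cols:
            raise DesignError("no non-reference genotype classes present")
        return np.column_stack(cols), names
    if model == "dominant":
        return (g >= 1).astype(float)[:, None], ["dominant"]
    if model == "recessive":
        return (g == 2).astype(float)[:, None], ["recessive"]
    if model == "heterozygous":
        return (g == 1).astype(float)[:, None], ["heterozygous"]
    raise ValueError(f"unknown genetic model {model!r}; choose from {GENETIC_MODELS}")


def _covariate_design(pheno: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    if "sex" in covariates:
        cols.append(pheno["sex"].to_numpy(dtype=float))
        names.append("sex")
    if "ethnicity" in covariates:
        labels = list(pd.unique(pheno["ethnicity"]))
        for lab in labels[1:]:  # first observed label is the reference
            cols.append((pheno["ethnicity"] == lab).to_numpy(dtype=float))
            names.append(f"ethnicity[{lab}]")
    if "rs334" in covariates:
        cols.append(pheno["rs334_genotype"].to_numpy(dtype=float))
        names.append("rs334")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(pheno), 0)), names


def genetic_association(genotypes: np.ndarray, phenotypes: PhenotypeTable | pd.DataFrame,
                        covariates: tuple[str, ...] = ("sex", "ethnicity", "rs334"),
                        model: str = "additive", variant_id: str = "DEL",
                        no_call_code: int = NO_CALL) -> AssociationResult:
    """Adjusted odds ratios for one variant under a chosen genetic model.

    No-call genotypes are excluded (complete-case) with the count reported.
    """
    g = np.asarray(genotypes, dtype=int)
    pheno = phenotypes.df if isinstance(phenotypes, PhenotypeTable) else phenotypes
    if len(g) != len(pheno):
        raise ValueError("genotype and phenotype lengths differ")
    keep = g != no_call_code
    n_dropped = int((~keep).sum())
    g, pheno = g[keep], pheno.loc[keep].reset_index(drop=True)

    G, g_names = _encode_genotype(g, model)
    C, c_names = _covariate_design(pheno, covariates)
    X = np.column_stack([np.ones(len(g)), G, C])
    names = ["intercept"] + g_names + c_names
    fit = fit_logistic(pheno["status"].to_numpy(dtype=float), X, column_names=names)

    result = AssociationResult(variant_id=variant_id, model=model, n_used=len(g),
                               n_dropped_no_call=n_dropped, converged=fit.converged)
    for j, name in enumerate(names):
        if name == "intercept" or name in c_names:
            continue
        b, se = fit.coef[j], fit.se[j]
        result.terms.append(TermResult(
            name=name, beta=float(b), se=float(se), odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - 1.96 * se)), ci_high=float(np.exp(b + 1.96 * se)),
            p=float(fit.p[j])))
    return result


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("need at least one test")
    return alpha / n_tests


@dataclass
class RegionScanResult:
    table: pd.DataFrame
    threshold: float
    n_tested: int


def region_scan(panel, phenotypes: PhenotypeTable,
                covariates: tuple[str, ...] = ("sex", "ethnicity", "rs334"),
                model: str = "additive", alpha: float = 0.05) -> RegionScanResult:
    """Per-variant association across a panel with a Bonferroni threshold of
    alpha / (number of variants tested); monomorphic variants are skipped."""
    G = panel.genotypes()
    rows = []
    tested = 0
    for j in range(panel.n_variants):
        vid = panel.variant_ids[j]
        af = panel.allele_frequency(j)
        if af in (0.0, 1.0):
            rows.append({"variant_id": vid, "position_bp": int(panel.positions_bp[j]),
                         "term": "", "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "n": 0, "converged": False,
                         "skipped": "monomorphic"})
            continue
        try:
            res = genetic_association(G[:, j], phenotypes, covariates=covariates,
                                      model=model, variant_id=vid)
        except DesignError as exc:
            rows.append({"variant_id": vid, "position_bp": int(panel.positions_bp[j]),
                         "term": "", "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "n": 0, "converged": False,
                         "skipped": f"collinear: {exc}"})
            continue
        tested += 1
        for term in res.terms:
            rows.append({"variant_id": vid, "position_bp": int(panel.positions_bp[j]),
                         "term": term.name, "or": term.odds_ratio,
                         "ci_low": term.ci_low, "ci_high": term.ci_high,
                         "p": term.p, "n": res.n_used, "converged": res.converged,
                         "skipped": ""})
    if tested == 0:
        raise ValueError("no polymorphic variants to test")
    threshold = bonferroni_threshold(tested, alpha)
    df = pd.DataFrame(rows)
    df["significant"] = (df["p"] < threshold).fillna(False)
    return RegionScanResult(table=df, threshold=threshold, n_tested=tested)
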