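"""Single-SNP association scans and SNP-block construction.

Continuous traits are scanned with per-SNP linear regression (trait on
additive dosage plus covariates), binary diseases with per-SNP logistic
regression; both report per-allele Wald estimates.  SNPs passing the
significance threshold (default 1e-5) for a trait form that trait's "SNP
block", the unit on which factor analysis is run.  The linear scan uses
Frisch-Waugh residualization so the per-SNP slope, SE and p-value are
algebraically identical to the full OLS fit while the covariate
projection is computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "SNPBlock",
    "ScanResults",
    "SingleSNPScan",
    "linear_scan",
    "logistic_scan",
    "select_blocks",
    "ld_prune",
]


@dataclass
class AssociationResult:
    snp_id: str
    trait: str
    model: str                 # "linear" | "logistic"
    estimate: float
    se: float
    statistic: float
    p_value: float
    converged: bool = True
    note: str = ""


@dataclass
class SNPBlock:
    """Significant SNPs for one trait, ordered by ascending p-value."""

    block_id: str
    trait: str
    snp_ids: list = field(default_factory=list)

    def __len__(self):
        return len(self.snp_ids)


def _covariate_matrix(df, covariates, n):
    cols = [np.ones(n)]
    for c in covariates:
        cols.append(df[c].to_numpy(float))
    return np.column_stack(cols)


def linear_scan(cohort, trait, covariates=()):
    """Per-SNP least-squares scan of a continuous trait.

    Returns one :class:`AssociationResult` per SNP with the per-allele
    slope, its SE, the Wald t statistic and a two-sided p-value on the
    residual degrees of freedom.  Monomorphic SNPs are flagged with
    ``p_value = nan`` and excluded from blocks downstream.
    """
    X = cohort.X
    pheno = cohort.phenotype_frame()
    y_all = pheno[trait].to_numpy(float)
    mask = np.isfinite(y_all)
    for c in covariates:
        mask &= np.isfinite(pheno[c].to_numpy(float))
    df = pheno.loc[mask]
    G = X.loc[mask].to_numpy(float)
    y = y_all[mask]
    n = len(y)
    C = _covariate_matrix(df, covariates, n)
    kc = C.shape[1]
    dof = n - kc - 1
    if dof < 1:
        raise ValueError("not enough complete cases for the covariate model")
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    sxx = np.einsum("ij,ij->j", G_r, G_r)
    sxy = G_r.T @ y_r
    syy = float(y_r @ y_r)
    results = []
    for j, snp in enumerate(X.columns):
        col = G[:, j]
        if len(np.unique(col)) < 2 or sxx[j] <= 1e-12:
            results.append(AssociationResult(snp, trait, "linear", np.nan, np.nan,
                                             np.nan, np.nan, False, "monomorphic"))
            continue
        beta = sxy[j] / sxx[j]
        rss = max(syy - beta * sxy[j], 0.0)
        sigma2 = rss / dof
        if sigma2 <= 0:
            # perfect fit: infinite evidence, p underflows to 0
            results.append(AssociationResult(snp, trait, "linear", float(beta),
                                             0.0, np.inf, 0.0))
            continue
        se = float(np.sqrt(sigma2 / sxx[j]))
        t = beta / se
        p = 2 * stats.t.sf(abs(t), dof)
        results.append(AssociationResult(snp, trait, "linear", float(beta), se,
                                         float(t), float(p)))
    return results


def _irls_logistic(Xmat, y, tol=1e-8, max_iter=50):
    """IRLS for logistic regression; returns (beta, cov, converged)."""
    n, k = Xmat.shape
    beta = np.zeros(k)
    beta[0] = np.log(max(y.mean(), 1e-10) / max(1 - y.mean(), 1e-10))
    converged = False
    cov = np.full((k, k), np.nan)
    for _ in range(max_iter):
        eta = np.clip(Xmat @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if w.max() < 1e-12:
            break
        XtW = Xmat.T * w
        H = XtW @ Xmat
        g = Xmat.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            eta = np.clip(Xmat @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1 - mu)
            try:
                cov = np.linalg.inv((Xmat.T * w) @ Xmat)
            except np.linalg.LinAlgError:
                break
            converged = True
            break
    if converged and (np.max(np.abs(beta)) > 25 or not np.all(np.isfinite(cov))):
        converged = False  # quasi-separation: estimates diverging
    return beta, cov, converged


def logistic_scan(cohort, disease, covariates=(), tol=1e-8, max_iter=50):
    """Per-SNP logistic-regression scan of a binary disease.

    Wald log-odds per allele from IRLS (tolerance 1e-8, at most 50
    iterations); non-converged fits — e.g. perfect separation — are
    flagged and later excluded from blocks.
    """
    X = cohort.X
    pheno = cohort.phenotype_frame()
    y_all = pheno[disease].to_numpy(float)
    mask = np.isfinite(y_all)
    for c in covariates:
        mask &= np.isfinite(pheno[c].to_numpy(float))
    df = pheno.loc[mask]
    G = X.loc[mask].to_numpy(float)
    y = y_all[mask]
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError(f"{disease} must be coded 0/1")
    if classes.size < 2:
        raise ValueError(f"{disease} has a single class; cannot fit logistic models")
    n = len(y)
    C = _covariate_matrix(df, covariates, n)
    results = []
    for j, snp in enumerate(X.columns):
        col = G[:, j]
        if len(np.unique(col)) < 2:
            results.append(AssociationResult(snp, disease, "logistic", np.nan, np.nan,
                                             np.nan, np.nan, False, "monomorphic"))
            continue
        Xmat = np.column_stack([C, col])
        beta, cov, ok = _irls_logistic(Xmat, y, tol=tol, max_iter=max_iter)
        if not ok:
            results.append(AssociationResult(snp, disease, "logistic", np.nan, np.nan,
                                             np.nan, np.nan, False, "non-converged"))
            continue
        est = float(beta[-1])
        se = float(np.sqrt(cov[-1, -1]))
        z = est / se
        p = 2 * stats.norm.sf(abs(z))
        results.append(AssociationResult(snp, disease, "logistic", est, se,
                                         float(z), float(p)))
    return results


def select_blocks(results_by_trait, alpha=1e-5):
    """One SNPBlock per trait with exactly the SNPs at p < alpha.

    ``results_by_trait``: mapping trait -> list of AssociationResult.
    Flagged (non-converged / monomorphic) results never enter a block.
    Empty blocks are kept so the caller can see and report them.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    blocks = []
    for i, (trait, results) in enumerate(results_by_trait.items(), start=1):
        hits = [r for r in results
                if r.converged and np.isfinite(r.p_value) and r.p_value < alpha]
        hits.sort(key=lambda r: (r.p_value, r.snp_id))
        blocks.append(SNPBlock(f"block{i}", trait, [r.snp_id for r in hits]))
    return blocks


def ld_prune(X: pd.DataFrame, snp_order, r2_threshold=0.8):
    """Greedy LD pruning in the given (p-value) order.

    A SNP is kept iff its squared Pearson correlation with every
    already-kept SNP is below the threshold.  Off by default in the
    pipeline.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    kept = []
    for snp in snp_order:
        x = X[snp].to_numpy(float)
        ok = True
        for k in kept:
            r = np.corrcoef(x, X[k].to_numpy(float))[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(snp)
    return kept


class ScanResults:
    """All per-trait scan results plus block construction helpers."""

    def __init__(self, results_by_trait, alpha=1e-5):
        self.results_by_trait = dict(results_by_trait)
        self.alpha = alpha

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trait, results in self.results_by_trait.items():
            for r in results:
                rows.append({"snp": r.snp_id, "trait": trait, "model": r.model,
                             "beta": r.estimate, "se": r.se, "stat": r.statistic,
                             "p": r.p_value, "converged": r.converged, "note": r.note})
        return pd.DataFrame(rows)

    def blocks(self, alpha=None):
        return select_blocks(self.results_by_trait, alpha if alpha is not None else self.alpha)

    def summary(self):
        lines = ["Single-SNP association scan"]
        for b in self.blocks():
            lines.append(f"  {b.trait}: {len(b)} SNPs with p < {self.alpha:g}")
        return "\n".join(lines)


class SingleSNPScan:
    """Scan every SNP against each listed trait and disease.

    Statsmodels-style entry point: construct from a cohort, call
    :meth:`fit`, get a :class:`ScanResults`.
    """

    def __init__(self, cohort, traits=(), diseases=(), covariates=(), alpha=1e-5):
        self.cohort = cohort
        self.traits = list(traits)
        self.diseases = list(diseases)
        self.covariates = list(covariates)
        self.alpha = alpha

    def fit(self) -> ScanResults:
        out = {}
        for t in self.traits:
            out[t] = linear_scan(self.cohort, t, self.covariates)
        for d in self.diseases:
            out[d] = logistic_scan(self.cohort, d, self.covariates)
        return ScanResults(out, alpha=self.alpha)
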