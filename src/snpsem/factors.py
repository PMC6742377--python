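"""Per-block exploratory factor analysis of correlated SNPs.

Each block of trait-associated SNPs is summarised by a small number of
latent variables: loadings come from principal-component extraction of the
dosage correlation matrix (column j of the loading matrix is
sqrt(lambda_j) * v_j), the number of factors defaults to the Kaiser rule
(eigenvalues strictly greater than 1), the solution is varimax-rotated,
SNPs whose communality falls below a threshold (default 0.3) are dropped
with re-extraction, and per-subject factor scores are standardized
principal-component scores of the rotated solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorModel",
    "FactorResults",
    "SNPFactorModel",
    "extract_factors",
    "varimax",
    "varimax_criterion",
    "communality_filter",
    "factor_scores",
    "assign_snps",
]


class NoCommonFactorError(ValueError):
    """Raised when the retention rule keeps zero factors (e.g. identity R)."""


def _fix_signs(L):
    """Make each column's largest-|.| entry positive (deterministic signs)."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def extract_factors(R, k=None):
    """Unrotated principal-component loadings of a correlation matrix.

    Parameters
    ----------
    R : (m, m) array
        SNP correlation matrix — symmetric, unit diagonal, PSD.
    k : int, optional
        Number of factors; defaults to the Kaiser rule (eigenvalues > 1).

    Returns
    -------
    loadings : (m, k) array
    eigenvalues : (k,) array of the retained eigenvalues
    """
    R = np.asarray(R, float)
    m = R.shape[0]
    if R.shape != (m, m) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be a symmetric square matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("R must have unit diagonal (a correlation matrix)")
    w, v = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise ValueError("R is not positive semi-definite")
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if k is None:
        k = int(np.sum(w > 1.0))
        if k == 0 and m == 1:
            # a one-SNP block is its own factor (loading exactly 1)
            k = 1
        if k == 0:
            raise NoCommonFactorError(
                "no eigenvalue exceeds 1; the block has no common factor")
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}]")
    L = v[:, :k] * np.sqrt(w[:k])
    return _fix_signs(L), w[:k]


def varimax_criterion(L):
    """Raw varimax criterion: sum over columns of the variance of squared loadings."""
    sq = np.asarray(L, float) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax(L, normalize=True, tol=1e-9, max_iter=500):
    """Varimax rotation by pairwise planar rotations.

    Returns the rotated loadings and the accumulated orthogonal rotation
    matrix ``T`` with ``L_rot = L @ T``.  With ``normalize=True`` rows are
    Kaiser-normalized (divided by the square root of their communality)
    during rotation, the common convention.
    """
    L = np.asarray(L, float)
    m, k = L.shape
    T = np.eye(k)
    if k < 2:
        return _fix_signs(L), T
    h = np.sqrt(np.sum(L ** 2, axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    W = L / h_safe[:, None] if normalize else L.copy()
    last = varimax_criterion(W)
    for _ in range(max_iter):
        for p in range(k - 1):
            for q in range(p + 1, k):
                x, y = W[:, p], W[:, q]
                u = x ** 2 - y ** 2
                v = 2 * x * y
                num = 2 * (m * np.sum(u * v) - np.sum(u) * np.sum(v))
                den = m * (np.sum(u ** 2) - np.sum(v ** 2)) - (np.sum(u) ** 2 - np.sum(v) ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                W[:, [p, q]] = W[:, [p, q]] @ rot
                T[:, [p, q]] = T[:, [p, q]] @ rot
        crit = varimax_criterion(W)
        if crit - last < tol:
            break
        last = crit
    Lr = (W * h_safe[:, None]) if normalize else W
    # order columns by explained variance, then fix signs; fold both into T
    order = np.argsort(-np.sum(Lr ** 2, axis=0), kind="stable")
    Lr = Lr[:, order]
    T = T[:, order]
    for j in range(k):
        i = int(np.argmax(np.abs(Lr[:, j])))
        if Lr[i, j] < 0:
            Lr[:, j] = -Lr[:, j]
            T[:, j] = -T[:, j]
    return Lr, T


@dataclass
class FactorModel:
    """Rotated factor solution for one SNP block."""

    block_id: str
    snp_ids: list
    loadings: pd.DataFrame          # retained SNPs x factors, rotated
    communalities: pd.Series
    variance_explained: float       # fraction of total (retained-SNP) variance
    rotation: np.ndarray            # k x k orthogonal matrix
    score_coefficients: pd.DataFrame
    eigenvalues: np.ndarray
    excluded_snps: dict = field(default_factory=dict)  # snp -> final communality

    @property
    def n_factors(self):
        return self.loadings.shape[1]

    def factor_names(self):
        return list(self.loadings.columns)


# FactorResults is the statsmodels-flavoured alias used by SNPFactorModel.fit()
FactorResults = FactorModel


def _fit_once(R, snp_ids, block_id, k=None):
    L, w = extract_factors(R, k=k)
    Lr, T = varimax(L)
    kk = Lr.shape[1]
    names = [f"factor{j + 1}" for j in range(kk)]
    comm = pd.Series(np.sum(Lr ** 2, axis=1), index=snp_ids, name="communality")
    var_expl = float(np.sum(Lr ** 2) / len(snp_ids))
    # PC scores: Z V Lambda^{-1/2} T  (standardized, mutually orthogonal)
    wfull, vfull = np.linalg.eigh(np.asarray(R, float))
    order = np.argsort(wfull)[::-1]
    wfull, vfull = wfull[order], vfull[:, order]
    W = vfull[:, :kk] / np.sqrt(wfull[:kk])
    # align unrotated eigenvector signs with extract_factors' convention
    Lu = vfull[:, :kk] * np.sqrt(wfull[:kk])
    for j in range(kk):
        i = int(np.argmax(np.abs(Lu[:, j])))
        if Lu[i, j] < 0:
            W[:, j] = -W[:, j]
    score_coef = pd.DataFrame(W @ T, index=snp_ids, columns=names)
    return FactorModel(block_id, list(snp_ids),
                       pd.DataFrame(Lr, index=snp_ids, columns=names),
                       comm, var_expl, T, score_coef, w)


def communality_filter(R, snp_ids=None, threshold=0.3, k=None, block_id="block"):
    """Iterative low-communality exclusion with re-extraction.

    Repeatedly drops the lowest-communality SNP below ``threshold`` and
    refits (re-extraction + varimax) until every retained SNP has
    communality >= threshold.  Raises if the block empties out.
    """
    R = np.asarray(R, float)
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(R.shape[0])]
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    snp_ids = list(snp_ids)
    keep = list(range(len(snp_ids)))
    excluded = {}
    while True:
        if not keep:
            raise ValueError(f"{block_id}: every SNP excluded by the communality filter")
        sub = R[np.ix_(keep, keep)]
        ids = [snp_ids[i] for i in keep]
        try:
            model = _fit_once(sub, ids, block_id, k=k)
        except NoCommonFactorError:
            raise ValueError(f"{block_id}: no common factor among retained SNPs")
        comm = model.communalities
        below = comm[comm < threshold]
        if below.empty:
            model.excluded_snps = excluded
            return model
        worst = below.idxmin()
        excluded[worst] = float(comm[worst])
        keep = [i for i in keep if snp_ids[i] != worst]


def factor_scores(genotypes: pd.DataFrame, model: FactorModel) -> pd.DataFrame:
    """Standardized rotated principal-component scores for each subject.

    ``genotypes`` must contain every retained SNP of the model; dosages
    are standardized in-sample (ddof=1) so each score has mean 0 and
    variance 1 and scores of different factors are exactly orthogonal.
    """
    missing = [s for s in model.snp_ids if s not in genotypes.columns]
    if missing:
        raise ValueError(f"genotype data is missing SNPs {missing}")
    X = genotypes[model.snp_ids].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [model.snp_ids[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"monomorphic SNPs cannot be scored: {bad}")
    Z = (X - mu) / sd
    F = Z @ model.score_coefficients.to_numpy()
    return pd.DataFrame(F, index=genotypes.index, columns=model.factor_names())


def assign_snps(model: FactorModel, logger=None):
    """Assign each SNP to the factor with its maximum-|loading|.

    Ties go to the lower-indexed factor (and are logged).  The signed
    loading is retained so opposite-direction members stay visible.
    """
    groups = {f: [] for f in model.factor_names()}
    L = model.loadings
    for snp in L.index:
        row = L.loc[snp].to_numpy()
        a = np.abs(row)
        best = int(np.argmax(a))  # argmax takes the first (lowest) index on ties
        if np.sum(np.isclose(a, a[best], rtol=0, atol=1e-12)) > 1 and logger is not None:
            logger.warning("loading tie for %s; assigned to %s", snp, L.columns[best])
        groups[L.columns[best]].append((snp, float(row[best])))
    return groups


class SNPFactorModel:
    """Factor model for one SNP block, built from dosages or a correlation matrix.

    Examples
    --------
    >>> model = SNPFactorModel.from_genotypes(dosage_df, block_id="BMI")
    >>> res = model.fit()
    >>> res.loadings
    """

    def __init__(self, R, snp_ids=None, block_id="block", genotypes=None):
        self.R = np.asarray(R, float)
        self.snp_ids = list(snp_ids) if snp_ids is not None else \
            [f"snp{i + 1}" for i in range(self.R.shape[0])]
        self.block_id = block_id
        self.genotypes = genotypes

    @classmethod
    def from_genotypes(cls, genotypes: pd.DataFrame, snp_ids=None, block_id="block"):
        cols = list(snp_ids) if snp_ids is not None else list(genotypes.columns)
        sub = genotypes[cols]
        sd = sub.std(ddof=1)
        mono = list(sd.index[sd == 0])
        if mono:
            raise ValueError(f"monomorphic SNPs in block {block_id}: {mono}")
        R = np.corrcoef(sub.to_numpy(float), rowvar=False)
        if len(cols) == 1:
            R = np.array([[1.0]])
        return cls(R, cols, block_id, genotypes=sub)

    def fit(self, threshold=0.3, k=None) -> FactorResults:
        return communality_filter(self.R, self.snp_ids, threshold=threshold,
                                  k=k, block_id=self.block_id)
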