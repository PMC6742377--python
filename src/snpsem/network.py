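"""Covariate-adjusted partial correlations and recursive path analysis.

Step 3 of the modelling procedure: partial correlations among the
intermediate phenotypes and diseases given the demographic covariates
(Pearson correlation of least-squares residuals), then an exploratory
recursive path analysis whose ordering encodes the mediation hypothesis
(subcutaneous adiposity -> overall adiposity -> abdominal adiposity ->
T2D -> hypertension).  For a recursive system each endogenous variable's
standardized coefficients are the least-squares solution of the normal
equations on the correlation matrix, identical whether fitted from raw
data or from the correlation matrix itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .sem import Path, SEMSpec

__all__ = [
    "PartialCorrMatrix",
    "PathSpec",
    "PathModel",
    "PathResults",
    "partial_correlation",
    "default_disease_paths",
    "PHENOTYPE_ORDER",
]

#: mediation ordering of the phenotype/disease network
PHENOTYPE_ORDER = ("SUB", "BMI", "WC", "T2D", "HTN")


@dataclass
class PartialCorrMatrix:
    variables: list
    r: pd.DataFrame
    p_values: pd.DataFrame
    n_effective: int
    covariates: list = field(default_factory=list)


def partial_correlation(data: pd.DataFrame, variables, covariates=()) -> PartialCorrMatrix:
    """Partial correlations of ``variables`` given ``covariates``.

    Each variable is regressed (with intercept) on the covariates and the
    residuals are correlated; p-values use t on n - #covariates - 2 df.
    With an empty conditioning set this is the plain Pearson matrix.
    """
    variables = list(variables)
    covariates = list(covariates)
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    cols = variables + covariates
    df = data[cols].dropna()
    n = len(df)
    k = len(covariates)
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2 complete cases")
    for c in cols:
        if df[c].nunique() < 2:
            raise ValueError(f"column {c!r} is constant")
    V = df[variables].to_numpy(float)
    C = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in covariates])
    Q, _ = np.linalg.qr(C)
    resid = V - Q @ (Q.T @ V)
    R = np.corrcoef(resid, rowvar=False)
    dof = n - k - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt(dof / np.maximum(1 - R ** 2, 1e-300))
    P = 2 * stats.t.sf(np.abs(t), dof)
    np.fill_diagonal(P, 0.0)
    return PartialCorrMatrix(
        variables,
        pd.DataFrame(R, index=variables, columns=variables),
        pd.DataFrame(P, index=variables, columns=variables),
        n, covariates)


@dataclass
class PathSpec:
    """A recursive (acyclic) directed path diagram over named variables."""

    variables: list
    edges: list  # (source, target) pairs

    def __post_init__(self):
        declared = set(self.variables)
        for s, t in self.edges:
            if s not in declared or t not in declared:
                raise ValueError(f"edge {s}->{t} uses undeclared variables")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"edge set contains a cycle: {nx.find_cycle(g)}")

    def graph(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self):
        pos = {v: i for i, v in enumerate(self.variables)}
        return list(nx.lexicographical_topological_sort(self.graph(),
                                                        key=lambda v: pos[v]))

    def parents(self, v):
        return [s for s, t in self.edges if t == v]

    def to_sem_spec(self, **kwargs) -> SEMSpec:
        return SEMSpec([Path(s, t) for s, t in self.edges],
                       observed=self.variables, **kwargs)


def default_disease_paths() -> PathSpec:
    """The clinically ordered phenotype network:

    SUB -> BMI, {SUB, BMI} -> WC, {SUB, BMI, WC} -> T2D,
    {SUB, BMI, WC, T2D} -> HTN   (10 edges in total).
    """
    v = list(PHENOTYPE_ORDER)
    edges = []
    for i, t in enumerate(v):
        for s in v[:i]:
            edges.append((s, t))
    return PathSpec(v, edges)


@dataclass
class PathResults:
    """Standardized path coefficients of a recursive system."""

    spec: PathSpec
    coefficients: pd.DataFrame   # rows: source, target, estimate, se, t, p_value
    corr: pd.DataFrame
    nobs: int

    def coefficient(self, source, target):
        m = self.coefficients
        row = m[(m.source == source) & (m.target == target)]
        if row.empty:
            raise KeyError(f"no edge {source}->{target}")
        return float(row.estimate.iloc[0])

    def implied_correlation(self) -> pd.DataFrame:
        """Model-implied correlation matrix of the recursive system."""
        v = self.spec.variables
        idx = {x: i for i, x in enumerate(v)}
        nv = len(v)
        A = np.zeros((nv, nv))
        for _, row in self.coefficients.iterrows():
            A[idx[row.target], idx[row.source]] = row.estimate
        S = np.zeros((nv, nv))
        endo = {t for _, t in self.spec.edges}
        exog = [x for x in v if x not in endo]
        for a in exog:
            for b in exog:
                S[idx[a], idx[b]] = self.corr.loc[a, b]
        for t in endo:
            pa = self.spec.parents(t)
            beta = np.array([self.coefficient(s, t) for s in pa])
            rxy = self.corr.loc[pa, t].to_numpy()
            S[idx[t], idx[t]] = 1.0 - float(beta @ rxy)
        B = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
        C = B @ S @ B.T
        return pd.DataFrame(C, index=v, columns=v)

    def summary(self):
        lines = [f"Recursive path analysis (n = {self.nobs})"]
        for _, r in self.coefficients.iterrows():
            lines.append(f"  {r.source:>4} -> {r.target:<4} "
                         f"b = {r.estimate:7.3f}  se = {r.se:6.3f}  p = {r.p_value:.3g}")
        return "\n".join(lines)


class PathModel:
    """Recursive path model fitted by standardized least squares.

    Accepts raw data (``data=``) or a labeled correlation matrix plus n
    (matrix mode).  Each endogenous variable is solved from the normal
    equations on the correlation matrix, so raw-data and matrix-mode
    fits agree exactly.
    """

    def __init__(self, spec: PathSpec, data: pd.DataFrame | None = None,
                 corr: pd.DataFrame | None = None, n: int | None = None):
        self.spec = spec
        if data is not None:
            sub = data[spec.variables].dropna()
            self.corr = sub.corr()
            self.nobs = len(sub)
        elif corr is not None:
            if n is None:
                raise ValueError("matrix mode requires a sample size n")
            self.corr = corr.loc[spec.variables, spec.variables].astype(float)
            self.nobs = int(n)
            w = np.linalg.eigvalsh(self.corr.to_numpy())
            if w.min() < -1e-8:
                raise ValueError("correlation matrix is not positive semi-definite")
        else:
            raise ValueError("provide data= or corr= and n=")

    def fit(self) -> PathResults:
        rows = []
        for t in self.spec.variables:
            pa = self.spec.parents(t)
            if not pa:
                continue
            Rxx = self.corr.loc[pa, pa].to_numpy()
            rxy = self.corr.loc[pa, t].to_numpy()
            beta = np.linalg.solve(Rxx, rxy)
            r2 = float(beta @ rxy)
            dof = self.nobs - len(pa) - 1
            mse = max(1.0 - r2, 0.0) / dof
            Rinv = np.linalg.inv(Rxx)
            for j, s in enumerate(pa):
                se = float(np.sqrt(mse * Rinv[j, j]))
                if se > 0:
                    tval = beta[j] / se
                    p = 2 * stats.t.sf(abs(tval), dof)
                else:
                    tval, p = np.inf, 0.0
                rows.append({"source": s, "target": t, "estimate": float(beta[j]),
                             "se": se, "t": float(tval), "p_value": float(p)})
        return PathResults(self.spec, pd.DataFrame(rows), self.corr, self.nobs)
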