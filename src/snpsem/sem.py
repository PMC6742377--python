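"""Structural equation modelling by maximum-likelihood covariance-structure analysis.

The model is held in RAM form: a directed-path matrix ``A`` over all
variables (observed and latent), a symmetric matrix ``S`` of variances and
covariances of exogenous terms and residuals, and a selection matrix ``F``
mapping the full variable set onto the observed variables.  The implied
covariance of the observed variables is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

and the ML discrepancy minimised over the free parameters theta is

    F_ML = ln|Sigma| + tr(S_obs Sigma^-1) - ln|S_obs| - p,

whose optimum scaled by (n - 1) is the model chi-square.  Standard errors
come from the inverse expected information; standardized direct, indirect
and total effects are decomposed as B, (I-B)^-1 - I - B and (I-B)^-1 - I
with delta-method standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Path",
    "Covariance",
    "SEMSpec",
    "RAMMatrices",
    "SEModel",
    "SEMResults",
    "FitIndices",
    "implied_covariance",
    "fit_indices",
    "check_cutoffs",
    "independence_chi_square",
    "CUTOFFS",
]

#: conventional good-fit cutoffs used to judge a fitted model
CUTOFFS = {"nfi": 0.95, "cfi": 0.95, "gfi": 0.95, "agfi": 0.90, "rmsea": 0.07}


@dataclass(frozen=True)
class Path:
    """A directed path ``source -> target``; ``value=None`` means free."""

    source: str
    target: str
    value: float | None = None


@dataclass(frozen=True)
class Covariance:
    """A free (or fixed) covariance between two exogenous/residual terms."""

    a: str
    b: str
    value: float | None = None


class SEMSpec:
    """Declarative structural model.

    Parameters
    ----------
    paths
        Directed paths as :class:`Path` objects or ``(source, target)`` /
        ``(source, target, value)`` tuples.
    observed, latent
        Variable name lists; every path endpoint must be declared.
    covariances
        Extra free covariances between exogenous terms (beyond the
        automatic ones, see ``auto_exog_cov``).
    residual_covariances
        Pairs of endogenous variables whose *error terms* are allowed to
        covary (correlated measurement errors, e.g. duplicate SNP
        indicators appearing in two blocks).
    fixed_variances
        Mapping variable -> fixed (residual) variance.  Latent variables
        without a fixed loading get their variance fixed to 1 automatically
        so that each latent is scale-identified.
    auto_exog_cov
        If True (default), covariances among all pairs of exogenous
        *observed* variables are free, as in a standard path analysis.
    """

    def __init__(
        self,
        paths,
        observed,
        latent=(),
        covariances=(),
        residual_covariances=(),
        fixed_variances=None,
        auto_exog_cov=True,
    ):
        self.observed = list(observed)
        self.latent = list(latent)
        self.variables = self.observed + self.latent
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        self.paths = [p if isinstance(p, Path) else Path(*p) for p in paths]
        self.covariances = [c if isinstance(c, Covariance) else Covariance(*c) for c in covariances]
        self.residual_covariances = [tuple(rc) for rc in residual_covariances]
        self.fixed_variances = dict(fixed_variances or {})
        self.auto_exog_cov = bool(auto_exog_cov)
        self._validate()

    def _validate(self):
        declared = set(self.variables)
        for p in self.paths:
            undeclared = {p.source, p.target} - declared
            if undeclared:
                raise ValueError(f"path {p.source}->{p.target} uses undeclared variables {sorted(undeclared)}")
        import networkx as nx

        g = nx.DiGraph([(p.source, p.target) for p in self.paths])
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"structural paths contain a cycle: {cycle}")
        # scale identification for latents: fixed variance or one fixed loading
        for lv in self.latent:
            has_fixed_loading = any(p.source == lv and p.value is not None for p in self.paths)
            if not has_fixed_loading and lv not in self.fixed_variances:
                self.fixed_variances[lv] = 1.0

    @property
    def endogenous(self):
        return [v for v in self.variables if any(p.target == v for p in self.paths)]

    @property
    def exogenous(self):
        endo = set(self.endogenous)
        return [v for v in self.variables if v not in endo]

    def graph(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((p.source, p.target) for p in self.paths)
        return g


@dataclass
class RAMMatrices:
    """Numeric RAM template plus the map from theta into A and S."""

    variables: list
    observed: list
    A: np.ndarray
    S: np.ndarray
    F: np.ndarray
    param_names: list
    param_entries: list  # name -> list of ("A"|"S", i, j)

    def materialize(self, theta):
        A = self.A.copy()
        S = self.S.copy()
        for ent, value in zip(self.param_entries, theta):
            for mat, i, j in ent:
                tgt = A if mat == "A" else S
                tgt[i, j] = value
                if mat == "S" and i != j:
                    tgt[j, i] = value
        return A, S


def build_ram(spec: SEMSpec) -> RAMMatrices:
    var = spec.variables
    idx = {v: i for i, v in enumerate(var)}
    nv = len(var)
    A = np.zeros((nv, nv))
    S = np.zeros((nv, nv))
    F = np.zeros((len(spec.observed), nv))
    for r, v in enumerate(spec.observed):
        F[r, idx[v]] = 1.0

    names: list = []
    entries: dict = {}

    def add(name, mat, i, j):
        if name not in entries:
            names.append(name)
            entries[name] = []
        entries[name].append((mat, i, j))

    for p in spec.paths:
        i, j = idx[p.target], idx[p.source]
        if p.value is not None:
            A[i, j] = p.value
        else:
            add(f"{p.target}~{p.source}", "A", i, j)

    endo = set(spec.endogenous)
    for v in var:
        i = idx[v]
        if v in spec.fixed_variances:
            S[i, i] = spec.fixed_variances[v]
        else:
            add(f"var({v})", "S", i, i)

    if spec.auto_exog_cov:
        exog_obs = [v for v in spec.observed if v not in endo]
        for a_i, a in enumerate(exog_obs):
            for b in exog_obs[a_i + 1:]:
                add(f"cov({a},{b})", "S", idx[a], idx[b])
    for c in spec.covariances:
        if c.value is not None:
            S[idx[c.a], idx[c.b]] = S[idx[c.b], idx[c.a]] = c.value
        else:
            add(f"cov({c.a},{c.b})", "S", idx[c.a], idx[c.b])
    for a, b in spec.residual_covariances:
        add(f"rcov({a},{b})", "S", idx[a], idx[b])

    return RAMMatrices(var, list(spec.observed), A, S, F, names, [entries[n] for n in names])


def implied_covariance(ram: RAMMatrices, theta) -> np.ndarray:
    """Sigma(theta) = F (I-A)^-1 S (I-A)^-T F^T over the observed variables."""
    A, S = ram.materialize(np.asarray(theta, float))
    nv = A.shape[0]
    IA = np.eye(nv) - A
    try:
        B = np.linalg.solve(IA, np.eye(nv))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by DAG check
        raise ValueError("I - A is singular; check structural paths/parameters") from exc
    C = B @ S @ B.T
    return ram.F @ C @ ram.F.T


def _full_covariance(ram, theta):
    A, S = ram.materialize(np.asarray(theta, float))
    nv = A.shape[0]
    B = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
    return A, S, B @ S @ B.T


class SEModel:
    """Covariance-structure model ready for ML estimation.

    Accepts either raw data (``data=`` a DataFrame containing every
    observed variable) or matrix mode (``cov=`` a labeled covariance or
    correlation DataFrame plus ``n=``).
    """

    def __init__(self, spec: SEMSpec, data: pd.DataFrame | None = None,
                 cov: pd.DataFrame | None = None, n: int | None = None):
        self.spec = spec
        self.ram = build_ram(spec)
        self.data = None
        if data is not None:
            missing = [v for v in spec.observed if v not in data.columns]
            if missing:
                raise ValueError(f"data is missing observed variables {missing}")
            self.data = data[spec.observed].astype(float)
            self.sample_cov = self.data.cov().to_numpy()
            self.nobs = len(self.data)
        elif cov is not None:
            if n is None:
                raise ValueError("matrix mode requires a sample size n")
            if isinstance(cov, pd.DataFrame):
                cov = cov.loc[spec.observed, spec.observed].to_numpy()
            self.sample_cov = np.asarray(cov, float)
            self.nobs = int(n)
        else:
            raise ValueError("provide either data= or cov= and n=")
        p = len(spec.observed)
        if self.sample_cov.shape != (p, p):
            raise ValueError("covariance matrix shape does not match observed variables")
        if not np.allclose(self.sample_cov, self.sample_cov.T, atol=1e-10):
            raise ValueError("sample covariance is not symmetric")
        w = np.linalg.eigvalsh(self.sample_cov)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("sample covariance matrix is not positive semi-definite")
        if self.nobs <= p:
            raise ValueError("sample size must exceed the number of observed variables")

    def _is_scale_invariant(self):
        """True when rescaling observed variables maps the model onto itself:
        no fixed-value paths or covariances touching observed variables and
        no fixed observed variances."""
        obs = set(self.spec.observed)
        for p in self.spec.paths:
            if p.value is not None and (p.source in obs or p.target in obs):
                return False
        for c in self.spec.covariances:
            if c.value is not None and (c.a in obs or c.b in obs):
                return False
        return not (obs & set(self.spec.fixed_variances))

    # -- starting values -------------------------------------------------
    def _start_values(self, sample_cov=None):
        spec, ram = self.spec, self.ram
        Sc = pd.DataFrame(self.sample_cov if sample_cov is None else sample_cov,
                          index=spec.observed, columns=spec.observed)
        parents = {}
        for p in spec.paths:
            if p.value is None:
                parents.setdefault(p.target, []).append(p.source)
        start = {}
        resid_var = {}
        for tgt, srcs in parents.items():
            obs_srcs = [s for s in srcs if s in spec.observed]
            if tgt in spec.observed and obs_srcs:
                Rxx = Sc.loc[obs_srcs, obs_srcs].to_numpy()
                rxy = Sc.loc[obs_srcs, tgt].to_numpy()
                try:
                    beta = np.linalg.lstsq(Rxx, rxy, rcond=None)[0]
                except np.linalg.LinAlgError:
                    beta = np.full(len(obs_srcs), 0.1)
                for s, b in zip(obs_srcs, beta):
                    start[f"{tgt}~{s}"] = float(b)
                resid_var[tgt] = float(max(Sc.loc[tgt, tgt] - beta @ rxy,
                                           0.05 * Sc.loc[tgt, tgt]))
        theta0 = []
        for name in ram.param_names:
            if name in start:
                theta0.append(start[name])
            elif name.startswith("var("):
                v = name[4:-1]
                if v in resid_var:
                    theta0.append(resid_var[v])
                elif v in spec.observed:
                    sv = Sc.loc[v, v]
                    theta0.append(float(sv * (0.5 if v in spec.endogenous else 1.0)))
                else:
                    theta0.append(0.5 if v in spec.endogenous else 1.0)
            elif name.startswith("cov("):
                a, b = name[4:-1].split(",")
                if a in spec.observed and b in spec.observed:
                    theta0.append(float(Sc.loc[a, b]))
                else:
                    theta0.append(0.0)
            elif name.startswith("rcov("):
                theta0.append(0.0)
            else:  # free loading on a latent
                theta0.append(0.5)
        return np.asarray(theta0, float)

    # -- objective -------------------------------------------------------
    def _discrepancy(self, theta, S_obs=None):
        S_obs = self.sample_cov if S_obs is None else S_obs
        p = S_obs.shape[0]
        try:
            Sigma = implied_covariance(self.ram, theta)
        except ValueError:
            return 1e12
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e12
        sign_s, logdet_s = np.linalg.slogdet(S_obs)
        try:
            solve = np.linalg.solve(Sigma, S_obs)
        except np.linalg.LinAlgError:
            return 1e12
        f = logdet + np.trace(solve) - logdet_s - p
        if not np.isfinite(f):
            return 1e12
        return max(f, 0.0) if abs(f) < 1e-13 else f

    def _rescale_theta(self, theta, sd_full):
        """Map estimates from the correlation-scale fit back to raw scale."""
        out = np.asarray(theta, float).copy()
        for k, ent in enumerate(self.ram.param_entries):
            mat, i, j = ent[0]
            if mat == "A":
                out[k] *= sd_full[i] / sd_full[j]
            else:
                out[k] *= sd_full[i] * sd_full[j]
        return out

    def fit(self, gtol=1e-8, max_restarts=5) -> "SEMResults":
        """Minimise F_ML by quasi-Newton from OLS-derived starting values.

        When the model is scale-invariant (no fixed values attached to
        observed variables) the optimisation runs on the correlation
        rescaling of the sample matrix — far better conditioned when
        variances are heterogeneous (binary diseases next to standardized
        scores) — and the optimum is mapped back; the two problems have
        identical F_ML minima for such models.
        """
        p = len(self.spec.observed)
        standardized = self._is_scale_invariant()
        if standardized:
            sd = np.sqrt(np.diag(self.sample_cov))
            target = self.sample_cov / np.outer(sd, sd)
            sd_full = np.concatenate([sd, np.ones(len(self.spec.latent))])
        else:
            target = self.sample_cov
        theta0 = self._start_values(sample_cov=target)
        rng = np.random.default_rng(0)
        best = None
        attempts = 0
        for attempt in range(max_restarts + 1):
            x0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, size=theta0.size)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(self._discrepancy, x0, args=(target,),
                                        method="BFGS",
                                        options={"gtol": gtol, "maxiter": 2000})
            gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
            attempts = attempt + 1
            if best is None or res.fun < best[0].fun:
                best = (res, gnorm)
            if gnorm < 1e-5 and np.isfinite(res.fun) and res.fun < 1e11:
                break
        res, gnorm = best
        converged = np.isfinite(res.fun) and res.fun < 1e11 and gnorm < 1e-4
        if not converged:
            raise RuntimeError(
                f"ML estimation did not converge after {attempts} attempts "
                f"(F={res.fun:.4g}, |grad|={gnorm:.3g})")
        theta = self._rescale_theta(res.x, sd_full) if standardized else res.x
        return SEMResults(self, theta, float(self._discrepancy(theta)),
                          {"iterations": int(res.nit), "gradient_norm": gnorm,
                           "restarts": attempts - 1,
                           "standardized_optimization": standardized})


def _expected_information(model: SEModel, theta):
    """I_ij = (n-1)/2 * tr(Sigma^-1 dSigma_i Sigma^-1 dSigma_j)."""
    Sigma = implied_covariance(model.ram, theta)
    Sinv = np.linalg.inv(Sigma)
    k = len(theta)
    derivs = []
    for i in range(k):
        h = 1e-6 * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        derivs.append((implied_covariance(model.ram, tp) -
                       implied_covariance(model.ram, tm)) / (2 * h))
    info = np.empty((k, k))
    for i in range(k):
        Wi = Sinv @ derivs[i]
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * np.trace(Wi @ Sinv @ derivs[j])
    return (model.nobs - 1) * info


class SEMResults:
    """Fitted SEM: estimates, standard errors, fit statistics, effects."""

    def __init__(self, model: SEModel, theta, fmin, convergence):
        self.model = model
        self.spec = model.spec
        self.ram = model.ram
        self.theta = np.asarray(theta, float)
        self.fmin = fmin
        self.convergence = dict(convergence)
        self.nobs = model.nobs
        self.params = pd.Series(self.theta, index=self.ram.param_names)
        self.chi_square = (self.nobs - 1) * self.fmin
        p = len(self.spec.observed)
        self.df = p * (p + 1) // 2 - len(self.theta)
        if self.df < 0:
            raise ValueError("model has more free parameters than covariance moments")
        self.Sigma_hat = pd.DataFrame(implied_covariance(self.ram, self.theta),
                                      index=self.spec.observed, columns=self.spec.observed)
        self._cov_params = None

    # -- uncertainty -----------------------------------------------------
    @property
    def cov_params(self):
        if self._cov_params is None:
            info = _expected_information(self.model, self.theta)
            self._cov_params = pd.DataFrame(np.linalg.pinv(info),
                                            index=self.ram.param_names,
                                            columns=self.ram.param_names)
        return self._cov_params

    @property
    def bse(self):
        return pd.Series(np.sqrt(np.maximum(np.diag(self.cov_params.to_numpy()), 0.0)),
                         index=self.ram.param_names)

    @property
    def zvalues(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self):
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues.to_numpy())),
                         index=self.ram.param_names)

    # -- standardized solution -------------------------------------------
    def _standardized_A(self, theta=None):
        theta = self.theta if theta is None else theta
        A, S, C = _full_covariance(self.ram, theta)
        sd = np.sqrt(np.maximum(np.diag(C), 1e-300))
        return A * sd[np.newaxis, :] / sd[:, np.newaxis]

    @property
    def standardized_paths(self):
        """Standardized coefficient for every directed path in the model."""
        B = self._standardized_A()
        idx = {v: i for i, v in enumerate(self.spec.variables)}
        rows = []
        for pth in self.spec.paths:
            rows.append({"source": pth.source, "target": pth.target,
                         "estimate": B[idx[pth.target], idx[pth.source]],
                         "free": pth.value is None})
        return pd.DataFrame(rows)

    def standardized_path(self, source, target):
        B = self._standardized_A()
        idx = {v: i for i, v in enumerate(self.spec.variables)}
        return float(B[idx[target], idx[source]])

    # -- fit indices -----------------------------------------------------
    def fit_indices(self, baseline=None) -> "FitIndices":
        return fit_indices(self, baseline=baseline)

    # -- effect decomposition --------------------------------------------
    def _effect_pairs(self):
        g = self.spec.graph()
        import networkx as nx

        order = list(nx.topological_sort(g))
        pairs = []
        for tgt in order:
            if tgt not in set(self.spec.endogenous):
                continue
            for src in order:
                if src != tgt and nx.has_path(g, src, tgt):
                    pairs.append((src, tgt))
        return pairs

    def _effects_at(self, theta):
        B = self._standardized_A(theta)
        nv = B.shape[0]
        total = np.linalg.solve(np.eye(nv) - B, np.eye(nv)) - np.eye(nv)
        return B, total - B, total

    def effects(self, standard_errors=True) -> pd.DataFrame:
        """Standardized direct/indirect/total effects with delta-method SEs.

        One row per (source, target) pair connected by at least one
        directed path; stars follow * p<.10, ** p<.05, *** p<.01.
        """
        pairs = self._effect_pairs()
        idx = {v: i for i, v in enumerate(self.spec.variables)}
        direct, indirect, total = self._effects_at(self.theta)

        def flat(d, i, t):
            out = []
            for s, g in pairs:
                si, ti = idx[s], idx[g]
                out.extend([d[ti, si], i[ti, si], t[ti, si]])
            return np.asarray(out)

        est = flat(direct, indirect, total)
        ses = np.full(est.shape, np.nan)
        if standard_errors:
            k = len(self.theta)
            J = np.empty((est.size, k))
            for j in range(k):
                h = 1e-5 * (1.0 + abs(self.theta[j]))
                tp = self.theta.copy(); tp[j] += h
                tm = self.theta.copy(); tm[j] -= h
                J[:, j] = (flat(*self._effects_at(tp)) - flat(*self._effects_at(tm))) / (2 * h)
            covp = self.cov_params.to_numpy()
            ses = np.sqrt(np.maximum(np.einsum("ik,kl,il->i", J, covp, J), 0.0))

        rows = []
        for m, (s, t) in enumerate(pairs):
            for which, off in (("direct", 0), ("indirect", 1), ("total", 2)):
                e, se = est[3 * m + off], ses[3 * m + off]
                with np.errstate(divide="ignore", invalid="ignore"):
                    z = e / se if se and np.isfinite(se) and se > 0 else np.nan
                pv = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
                rows.append({"source": s, "target": t, "effect": which,
                             "estimate": e, "se": se, "z": z, "p_value": pv,
                             "stars": _stars(pv)})
        out = pd.DataFrame(rows)
        return out

    def effect(self, source, target, which="total"):
        idx = {v: i for i, v in enumerate(self.spec.variables)}
        d, i, t = self._effects_at(self.theta)
        mat = {"direct": d, "indirect": i, "total": t}[which]
        return float(mat[idx[target], idx[source]])

    # -- bootstrap --------------------------------------------------------
    def bootstrap_indirect(self, B=500, seed=0, alpha=0.05) -> pd.DataFrame:
        """Nonparametric case-resampling percentile CIs for indirect effects.

        Requires the model to have been fitted from raw data; matrix-mode
        fits carry no resampling units.
        """
        if self.model.data is None:
            raise ValueError("bootstrap requires raw-data input, not matrix mode")
        if B < 200:
            raise ValueError("use at least 200 bootstrap replicates")
        rng = np.random.default_rng(seed)
        data = self.model.data.reset_index(drop=True)
        n = len(data)
        pairs = self._effect_pairs()
        idx = {v: i for i, v in enumerate(self.spec.variables)}
        draws = np.empty((B, len(pairs)))
        for b in range(B):
            boot = data.iloc[rng.integers(0, n, size=n)]
            m = SEModel(self.spec, data=boot)
            try:
                r = m.fit()
            except RuntimeError:
                draws[b] = np.nan
                continue
            _, ind, _ = r._effects_at(r.theta)
            draws[b] = [ind[idx[t], idx[s]] for s, t in pairs]
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        rows = []
        _, ind_hat, _ = self._effects_at(self.theta)
        for j, (s, t) in enumerate(pairs):
            col = draws[:, j]
            col = col[np.isfinite(col)]
            rows.append({"source": s, "target": t,
                         "estimate": float(ind_hat[idx[t], idx[s]]),
                         "ci_low": float(np.percentile(col, lo)),
                         "ci_high": float(np.percentile(col, hi)),
                         "replicates": int(col.size)})
        return pd.DataFrame(rows)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = []
        lines.append("Structural equation model (ML covariance-structure fit)")
        lines.append(f"  observed variables: {len(self.spec.observed)}   "
                     f"latent: {len(self.spec.latent)}   n = {self.nobs}")
        lines.append(f"  chi-square = {self.chi_square:.4f} on {self.df} df   "
                     f"F_ML = {self.fmin:.6g}")
        try:
            fi = self.fit_indices()
            lines.append("  " + fi.one_line())
        except ValueError:
            pass
        lines.append("")
        lines.append(f"{'parameter':<28}{'estimate':>12}{'std err':>12}{'z':>10}{'P>|z|':>10}")
        bse, zv, pv = self.bse, self.zvalues, self.pvalues
        for name in self.ram.param_names:
            lines.append(f"{name:<28}{self.params[name]:>12.4f}{bse[name]:>12.4f}"
                         f"{zv[name]:>10.2f}{pv[name]:>10.3g}")
        return "\n".join(lines)


def _stars(p):
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


@dataclass
class FitIndices:
    chi_square: float
    df: int
    nfi: float
    cfi: float
    gfi: float
    agfi: float | None
    rmsea: float | None
    baseline_chi_square: float
    baseline_df: int
    passed: dict = field(default_factory=dict)

    def one_line(self):
        agfi = f"{self.agfi:.3f}" if self.agfi is not None else "n/a"
        rmsea = f"{self.rmsea:.3f}" if self.rmsea is not None else "n/a"
        return (f"NFI={self.nfi:.3f} CFI={self.cfi:.3f} GFI={self.gfi:.3f} "
                f"AGFI={agfi} RMSEA={rmsea}")

    @property
    def all_pass(self):
        return all(self.passed.values())


def independence_chi_square(sample_cov, n):
    """Closed-form chi-square of the independence (diagonal) model.

    With free variances the ML solution is Sigma = diag(S), giving
    F = sum(ln s_ii) - ln|S| and chi-square (n-1)F on p(p-1)/2 df.
    """
    S = np.asarray(sample_cov, float)
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance must be positive definite")
    f = float(np.sum(np.log(np.diag(S))) - logdet)
    return (n - 1) * f, p * (p - 1) // 2


def fit_indices(results: SEMResults, baseline: SEMResults | None = None,
                cutoffs=CUTOFFS) -> FitIndices:
    """NFI/CFI/GFI/AGFI/RMSEA for a fitted model against the independence baseline."""
    S = results.model.sample_cov
    n = results.nobs
    p = S.shape[0]
    chi2, df = results.chi_square, results.df
    if baseline is None:
        chi2_b, df_b = independence_chi_square(S, n)
    else:
        chi2_b, df_b = baseline.chi_square, baseline.df
    nfi = (chi2_b - chi2) / chi2_b if chi2_b > 0 else 1.0
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    Sigma_inv_S = np.linalg.solve(results.Sigma_hat.to_numpy(), S)
    resid = Sigma_inv_S - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(Sigma_inv_S @ Sigma_inv_S)
    if df > 0:
        agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    else:
        agfi = None
        rmsea = None
    fi = FitIndices(chi2, df, nfi, cfi, gfi, agfi, rmsea, chi2_b, df_b)
    fi.passed = check_cutoffs(fi, cutoffs)
    return fi


def check_cutoffs(indices, cutoffs=CUTOFFS) -> dict:
    """Judge fit indices against the conventional good-fit cutoffs.

    Accepts a :class:`FitIndices` or a mapping with keys nfi/cfi/gfi/
    agfi/rmsea.  AGFI and RMSEA that are undefined by saturation count
    as passing (a saturated model fits perfectly).
    """
    if isinstance(indices, FitIndices):
        vals = {"nfi": indices.nfi, "cfi": indices.cfi, "gfi": indices.gfi,
                "agfi": indices.agfi, "rmsea": indices.rmsea}
    else:
        vals = {k.lower(): v for k, v in dict(indices).items()}
    out = {}
    for key in ("nfi", "cfi", "gfi", "agfi"):
        v = vals.get(key)
        out[key] = True if v is None else bool(v >= cutoffs[key])
    v = vals.get("rmsea")
    out["rmsea"] = True if v is None else bool(v <= cutoffs["rmsea"])
    return out
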