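"""Synthetic cohort generator with the structure the analysis assumes.

Emulates a KARE-like cohort: Hardy-Weinberg genotypes in correlated SNP
clusters (Gaussian copula, then HWE-quantile discretization), one latent
genetic factor per cluster (the standardized weighted sum of its SNPs),
three continuous adiposity traits following the ordered cascade
SUB -> BMI -> WC on the standardized scale, binary T2D and hypertension
from Gaussian liability thresholds calibrated to configured prevalences,
and covariates sex/area (Bernoulli) and age (uniform on 39-70).

Every generating coefficient is specified on the standardized scale;
residual variances are solved so each trait and liability has unit
population variance, which keeps prevalence thresholds exact
(threshold = Phi^-1(1 - prevalence)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortData

__all__ = ["SNPGroup", "SimConfig", "SimulatedCohort", "generate_genotypes",
           "generate_cohort", "default_config"]

CASCADE_KEYS = ("sub_to_bmi", "sub_to_wc", "bmi_to_wc", "sub_to_t2d",
                "bmi_to_t2d", "wc_to_t2d", "sub_to_htn", "bmi_to_htn",
                "wc_to_htn", "t2d_to_htn")

TRAITS = ("SUB", "BMI", "WC")
DISEASES = ("T2D", "HTN")
AGE_RANGE = (39.0, 70.0)


@dataclass
class SNPGroup:
    group_id: str
    n_snps: int
    maf_range: tuple = (0.1, 0.5)
    within_group_r: float = 0.6

    def __post_init__(self):
        self.maf_range = tuple(self.maf_range)
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"{self.group_id}: maf_range must lie in (0, 0.5]")
        if not 0 <= self.within_group_r < 1:
            raise ValueError(f"{self.group_id}: within_group_r must be in [0, 1)")
        if self.n_snps < 1:
            raise ValueError(f"{self.group_id}: n_snps must be >= 1")


@dataclass
class SimConfig:
    """All generating parameters of a synthetic cohort (standardized scale)."""

    n_subjects: int = 8842
    seed: int = 0
    snp_groups: list = field(default_factory=lambda: [
        SNPGroup("SUBG", 5), SNPGroup("BMIG", 7), SNPGroup("WCG", 7),
        SNPGroup("T2DG", 1), SNPGroup("HTNG", 4)])
    # group_id -> (target trait/disease, standardized effect)
    factor_effects: dict = field(default_factory=lambda: {
        "SUBG": ("SUB", 0.08), "BMIG": ("BMI", 0.08), "WCG": ("WC", 0.05),
        "T2DG": ("T2D", 0.05), "HTNG": ("HTN", 0.05)})
    cascade: dict = field(default_factory=lambda: {
        "sub_to_bmi": 0.632, "sub_to_wc": 0.041, "bmi_to_wc": 0.797,
        "sub_to_t2d": 0.085, "bmi_to_t2d": -0.024, "wc_to_t2d": 0.097,
        "sub_to_htn": 0.005, "bmi_to_htn": 0.140, "wc_to_htn": 0.052,
        "t2d_to_htn": 0.079})
    prevalences: dict = field(default_factory=lambda: {"t2d": 0.0945, "htn": 0.2706})
    # per-trait standardized covariate coefficients (arbitrary small defaults;
    # the source cohort's covariate effect sizes are not public)
    covariate_effects: dict = field(default_factory=lambda: {
        "SUB": {"sex": -0.15, "area": 0.05, "age": 0.10},
        "BMI": {"sex": -0.05, "area": 0.05, "age": 0.05},
        "WC": {"sex": 0.10, "area": 0.05, "age": 0.10},
        "T2D": {"sex": 0.05, "area": 0.02, "age": 0.15},
        "HTN": {"sex": 0.05, "area": 0.02, "age": 0.25}})
    sex_p: float = 0.4731   # P(male), mirroring the cohort's composition
    area_p: float = 0.4756  # P(rural area)

    def __post_init__(self):
        self.snp_groups = [g if isinstance(g, SNPGroup) else SNPGroup(**g)
                           for g in self.snp_groups]
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        missing = set(CASCADE_KEYS) - set(self.cascade)
        if missing:
            raise ValueError(f"cascade is missing coefficients {sorted(missing)}")
        for k, v in self.prevalences.items():
            if not 0 < v < 1:
                raise ValueError(f"prevalence {k}={v} must be in (0, 1)")
        ids = [g.group_id for g in self.snp_groups]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate group ids")
        for gid, (target, _) in self.factor_effects.items():
            if gid not in ids:
                raise ValueError(f"factor effect references unknown group {gid}")
            if target not in TRAITS + DISEASES:
                raise ValueError(f"factor effect targets unknown variable {target}")

    def to_dict(self):
        d = asdict(self)
        d["snp_groups"] = [asdict(g) for g in self.snp_groups]
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    @classmethod
    def from_file(cls, path):
        """Load a SimConfig from YAML or JSON."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        d["factor_effects"] = {k: tuple(v) for k, v in d.get("factor_effects", {}).items()}
        return cls.from_dict(d)


@dataclass
class SimulatedCohort:
    cohort: CohortData
    truth: dict
    config: SimConfig

    def write(self, genotype_path, phenotype_path, truth_path=None):
        self.cohort.write(genotype_path, phenotype_path)
        if truth_path is not None:
            serializable = {k: v for k, v in self.truth.items()
                            if not isinstance(v, (pd.DataFrame, pd.Series))}
            with open(truth_path, "w") as fh:
                json.dump(serializable, fh, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"cannot serialize {type(x)}")


def generate_genotypes(mafs, n, within_group_r=0.0, seed=None, rng=None):
    """HWE genotypes for one correlated SNP cluster.

    A latent equicorrelated Gaussian (correlation ``within_group_r``) is
    thresholded at the HWE cumulative probabilities (1-p)^2 and
    (1-p)^2 + 2p(1-p) of each SNP's minor-allele frequency, yielding
    0/1/2 minor-allele counts whose margins satisfy HWE exactly.
    """
    mafs = np.asarray(mafs, float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        bad = mafs[(mafs <= 0) | (mafs > 0.5)]
        raise ValueError(f"minor-allele frequencies must be in (0, 0.5]; got {bad}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= within_group_r < 1:
        raise ValueError("within_group_r must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = mafs.size
    if within_group_r > 0:
        shared = rng.standard_normal((n, 1))
        Z = np.sqrt(within_group_r) * shared + \
            np.sqrt(1 - within_group_r) * rng.standard_normal((n, m))
    else:
        Z = rng.standard_normal((n, m))
    U = stats.norm.cdf(Z)
    p0 = (1 - mafs) ** 2
    p01 = p0 + 2 * mafs * (1 - mafs)
    G = (U > p0[np.newaxis, :]).astype(np.int64) + (U > p01[np.newaxis, :]).astype(np.int64)
    return G


def _standardize(x, ddof=1):
    x = np.asarray(x, float)
    return (x - x.mean()) / x.std(ddof=ddof)


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one cohort per the configuration; bit-identical under a fixed seed.

    The exogenous basis (group factors, standardized covariates, trait and
    liability residuals) is mutually independent with unit variance, so
    each trait's residual variance is solved from its coefficient vector
    over that basis; a systematic variance >= 1 is rejected with the
    offending equation named.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # genotypes and group factors
    geno_blocks = []
    factor_cols = {}
    truth_groups = {}
    for g in config.snp_groups:
        mafs = rng.uniform(g.maf_range[0], g.maf_range[1], size=g.n_snps)
        G = generate_genotypes(mafs, n, g.within_group_r, rng=rng)
        snp_names = [f"rs{g.group_id}_{j + 1}" for j in range(g.n_snps)]
        geno_blocks.append(pd.DataFrame(G, columns=snp_names))
        if n > 1 and np.all(G.std(axis=0) > 0):
            Zs = (G - G.mean(axis=0)) / G.std(axis=0, ddof=1)
            factor = _standardize(Zs.mean(axis=1))
        else:
            factor = np.zeros(n)
        factor_cols[g.group_id] = factor
        truth_groups[g.group_id] = {"mafs": mafs, "snp_ids": snp_names,
                                    "within_group_r": g.within_group_r}
    X = pd.concat(geno_blocks, axis=1)

    # covariates (standardized by population moments for the linear system)
    sex = (rng.random(n) < config.sex_p).astype(int)
    area = (rng.random(n) < config.area_p).astype(int)
    age = rng.uniform(AGE_RANGE[0], AGE_RANGE[1], size=n)
    cov_std = {
        "sex": (sex - config.sex_p) / np.sqrt(config.sex_p * (1 - config.sex_p)),
        "area": (area - config.area_p) / np.sqrt(config.area_p * (1 - config.area_p)),
        "age": (age - np.mean(AGE_RANGE)) / np.sqrt((AGE_RANGE[1] - AGE_RANGE[0]) ** 2 / 12.0),
    }

    # basis bookkeeping: factors + covariates + one residual per equation
    basis_names = ([f"factor:{g.group_id}" for g in config.snp_groups]
                   + ["cov:sex", "cov:area", "cov:age"]
                   + [f"resid:{v}" for v in TRAITS + DISEASES])
    bindex = {b: i for i, b in enumerate(basis_names)}
    nb = len(basis_names)
    basis = np.zeros((n, nb))
    for g in config.snp_groups:
        basis[:, bindex[f"factor:{g.group_id}"]] = factor_cols[g.group_id]
    for c in ("sex", "area", "age"):
        basis[:, bindex[f"cov:{c}"]] = cov_std[c]
    for v in TRAITS + DISEASES:
        basis[:, bindex[f"resid:{v}"]] = rng.standard_normal(n)

    cas = config.cascade
    parents = {
        "SUB": {},
        "BMI": {"SUB": cas["sub_to_bmi"]},
        "WC": {"SUB": cas["sub_to_wc"], "BMI": cas["bmi_to_wc"]},
        "T2D": {"SUB": cas["sub_to_t2d"], "BMI": cas["bmi_to_t2d"], "WC": cas["wc_to_t2d"]},
        "HTN": {"SUB": cas["sub_to_htn"], "BMI": cas["bmi_to_htn"],
                "WC": cas["wc_to_htn"], "T2D": cas["t2d_to_htn"]},
    }
    coef = {}          # variable -> coefficient vector over the basis
    residual_sd = {}
    for v in TRAITS + DISEASES:
        c = np.zeros(nb)
        for parent, beta in parents[v].items():
            c += beta * coef[parent]
        for gid, (target, eff) in config.factor_effects.items():
            if target == v:
                c[bindex[f"factor:{gid}"]] += eff
        for cname, eff in config.covariate_effects.get(v, {}).items():
            c[bindex[f"cov:{cname}"]] += eff
        var_sys = float(c @ c)
        if var_sys >= 1.0 - 1e-10:
            raise ValueError(
                f"equation for {v}: systematic variance {var_sys:.4f} >= 1; "
                "path/covariate coefficients admit no unit-variance solution")
        sd = float(np.sqrt(1.0 - var_sys))
        c[bindex[f"resid:{v}"]] = sd
        residual_sd[v] = sd
        coef[v] = c

    values = {v: basis @ coef[v] for v in TRAITS + DISEASES}
    thresholds = {"T2D": float(stats.norm.ppf(1 - config.prevalences["t2d"])),
                  "HTN": float(stats.norm.ppf(1 - config.prevalences["htn"]))}
    Y = pd.DataFrame({v: values[v] for v in TRAITS})
    Z = pd.DataFrame({d: (values[d] > thresholds[d]).astype(int) for d in DISEASES})
    covariates = pd.DataFrame({"SEX": sex, "AREA": area, "AGE": age})
    ids = pd.Index([f"S{i + 1:06d}" for i in range(n)], name="subject_id")
    for frame in (X, Y, Z, covariates):
        frame.index = ids

    truth = {
        "groups": truth_groups,
        "factor_effects": {k: list(v) for k, v in config.factor_effects.items()},
        "cascade": dict(cas),
        "covariate_effects": config.covariate_effects,
        "residual_sd": residual_sd,
        "thresholds": thresholds,
        "prevalences": dict(config.prevalences),
        "factors": pd.DataFrame(factor_cols, index=ids),
        "liabilities": pd.DataFrame({d: values[d] for d in DISEASES}, index=ids),
    }
    cohort = CohortData(X=X, Y=Y, Z=Z, covariates=covariates, subject_ids=ids)
    return SimulatedCohort(cohort=cohort, truth=truth, config=config)


def default_config(**overrides) -> SimConfig:
    """The study-scale default configuration (n = 8,842, prevalences
    9.45% / 27.06%, five SNP groups), with keyword overrides."""
    return SimConfig(**overrides)
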