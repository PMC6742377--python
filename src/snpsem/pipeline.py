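"""Orchestration of the four modelling steps from a single configuration.

Raw mode runs: (1) single-SNP scans and SNP-block selection, (2) per-block
factor analysis and factor scores, (3) partial correlations and the
recursive phenotype path analysis, (4) the full SEM with effect
decomposition.  Matrix mode (a labeled correlation matrix plus n) skips
steps 1-2 and fits the phenotype network and SEM directly — the published
summary matrix of the source cohort is runnable this way without any
genotype data.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortData, read_genotypes, read_phenotypes
from .factors import SNPFactorModel, factor_scores
from .network import PathModel, PathSpec, default_disease_paths, partial_correlation
from .scan import SingleSNPScan
from .sem import Path, SEModel, SEMSpec

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "export_diagram",
           "residualize"]

log = logging.getLogger("snpsem")


@dataclass
class PipelineConfig:
    # raw mode
    genotypes: str | None = None
    phenotypes: str | None = None
    # matrix mode
    corr_matrix: str | None = None
    n: int | None = None
    traits: list = field(default_factory=lambda: ["SUB", "BMI", "WC"])
    diseases: list = field(default_factory=lambda: ["T2D", "HTN"])
    covariates: list = field(default_factory=lambda: ["SEX", "AREA", "AGE"])
    alpha: float = 1e-5
    communality_threshold: float = 0.3
    k_overrides: dict = field(default_factory=dict)       # block trait -> k
    path_spec: str = "default"                            # "default" or JSON file
    residual_covariances: list = field(default_factory=list)
    ld_prune_r2: float | None = None
    seed: int = 0
    out_dir: str = "snpsem_out"

    def __post_init__(self):
        raw = self.genotypes is not None or self.phenotypes is not None
        matrix = self.corr_matrix is not None
        if raw == matrix:
            raise ValueError("configure exactly one input mode: "
                             "genotypes+phenotypes (raw) or corr_matrix+n (matrix)")
        if matrix and self.n is None:
            raise ValueError("matrix mode requires n")

    @property
    def matrix_mode(self):
        return self.corr_matrix is not None

    def to_dict(self):
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_file(cls, path):
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class PipelineReport:
    out_dir: str
    artifacts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add(self, key, path):
        self.artifacts[key] = str(path)

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"out_dir": self.out_dir, "artifacts": self.artifacts,
                       "warnings": self.warnings, "version": __version__}, fh, indent=2)


def residualize(frame: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Least-squares residuals of every column on the covariates (with intercept)."""
    n = len(frame)
    C = np.column_stack([np.ones(n)] + [covariates[c].to_numpy(float)
                                        for c in covariates.columns])
    Q, _ = np.linalg.qr(C)
    V = frame.to_numpy(float)
    R = V - Q @ (Q.T @ V)
    return pd.DataFrame(R, index=frame.index, columns=frame.columns)


def _load_path_spec(config, variables) -> PathSpec:
    if config.path_spec == "default":
        return default_disease_paths()
    with open(config.path_spec) as fh:
        d = json.load(fh)
    return PathSpec(d.get("variables", variables), [tuple(e) for e in d["edges"]])


def _build_sem_spec(path_spec: PathSpec, factor_cols_by_trait, residual_covariances):
    """Final-model spec: per-block factor scores regress on their trait, plus
    the phenotype/disease DAG."""
    paths = [Path(s, t) for s, t in path_spec.edges]
    observed = list(path_spec.variables)
    for trait, cols in factor_cols_by_trait.items():
        for c in cols:
            paths.append(Path(c, trait))
            observed.append(c)
    return SEMSpec(paths, observed=observed,
                   residual_covariances=residual_covariances)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = FilePath(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(str(out))
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="[snpsem] %(message)s")

    if config.matrix_mode:
        log.info("== matrix mode: steps 1-2 skipped ==")
        corr = pd.read_csv(config.corr_matrix, index_col=0)
        _steps_3_4(config, report, out, corr=corr, n=config.n)
        report.write(out / "report.json")
        return report

    log.info("== step 1: single-SNP association scan ==")
    X = read_genotypes(config.genotypes)
    pheno = read_phenotypes(config.phenotypes)
    pheno = pheno.loc[X.index]
    cohort = CohortData(X=X, Y=pheno[config.traits], Z=pheno[config.diseases],
                        covariates=pheno[config.covariates], subject_ids=X.index)
    scan_res = SingleSNPScan(cohort, config.traits, config.diseases,
                             config.covariates, alpha=config.alpha).fit()
    scan_frame = scan_res.to_frame()
    scan_frame.to_csv(out / "scan.tsv", sep="\t", index=False)
    report.add("scan", out / "scan.tsv")
    blocks = scan_res.blocks()
    if config.ld_prune_r2 is not None:
        from .scan import ld_prune

        for b in blocks:
            b.snp_ids = ld_prune(cohort.X, b.snp_ids, config.ld_prune_r2)
    with open(out / "blocks.json", "w") as fh:
        json.dump([{"block_id": b.block_id, "trait": b.trait, "snp_ids": b.snp_ids}
                   for b in blocks], fh, indent=2)
    report.add("blocks", out / "blocks.json")
    for b in blocks:
        log.info("  %s: %d significant SNPs", b.trait, len(b))

    log.info("== step 2: latent factors per SNP block ==")
    score_frames = []
    factor_cols_by_trait = {}
    loading_rows = []
    for b in blocks:
        if len(b) == 0:
            report.warnings.append(f"empty SNP block for {b.trait}; no factors built")
            continue
        model = SNPFactorModel.from_genotypes(cohort.X, b.snp_ids, block_id=b.trait)
        try:
            fr = model.fit(threshold=config.communality_threshold,
                           k=config.k_overrides.get(b.trait))
        except ValueError as exc:
            report.warnings.append(f"factor analysis failed for {b.trait}: {exc}")
            continue
        names = [f"{b.trait}_f{j + 1}" for j in range(fr.n_factors)]
        scores = factor_scores(cohort.X, fr)
        scores.columns = names
        score_frames.append(scores)
        factor_cols_by_trait[b.trait] = names
        tab = fr.loadings.copy()
        tab.columns = names
        tab["communality"] = fr.communalities
        tab.insert(0, "snp", tab.index)
        tab.insert(1, "block", b.trait)
        loading_rows.append(tab)
        log.info("  %s: %d factors (variance explained %.1f%%), excluded %s",
                 b.trait, fr.n_factors, 100 * fr.variance_explained,
                 list(fr.excluded_snps) or "none")
    if loading_rows:
        pd.concat(loading_rows).to_csv(out / "loadings.tsv", sep="\t", index=False)
        report.add("loadings", out / "loadings.tsv")
    if score_frames:
        all_scores = pd.concat(score_frames, axis=1)
        # multicollinearity guard: blocks can share SNPs, making scores from
        # different blocks near-duplicates; keep the first of any |r|>0.95 pair
        corr = all_scores.corr().abs().to_numpy()
        keep, drop = [], []
        for j, col in enumerate(all_scores.columns):
            if any(corr[j, all_scores.columns.get_loc(k)] > 0.95 for k in keep):
                drop.append(col)
            else:
                keep.append(col)
        if drop:
            report.warnings.append(
                f"dropped near-duplicate factor scores (|r|>0.95): {drop}")
            log.info("  dropping near-duplicate factor scores: %s", drop)
            all_scores = all_scores[keep]
            factor_cols_by_trait = {t: [c for c in cols if c in keep]
                                    for t, cols in factor_cols_by_trait.items()}
            factor_cols_by_trait = {t: cols for t, cols in factor_cols_by_trait.items()
                                    if cols}
        all_scores.to_csv(out / "factor_scores.csv")
        report.add("factor_scores", out / "factor_scores.csv")
    else:
        all_scores = None
        report.warnings.append("no SNP blocks produced factors; "
                               "continuing with a phenotype-only SEM")

    _steps_3_4(config, report, out, cohort=cohort, scores=all_scores,
               factor_cols_by_trait=factor_cols_by_trait)
    report.write(out / "report.json")
    return report


def _steps_3_4(config, report, out, cohort=None, scores=None,
               factor_cols_by_trait=None, corr=None, n=None):
    variables = list(config.traits) + list(config.diseases)
    path_spec = _load_path_spec(config, variables)

    log.info("== step 3: phenotype network ==")
    if corr is None:
        pheno = cohort.phenotype_frame()
        pc = partial_correlation(pheno, variables, config.covariates)
        pc.r.to_csv(out / "partial_correlations.csv")
        report.add("partial_correlations", out / "partial_correlations.csv")
        path_model = PathModel(path_spec, corr=pc.r, n=pc.n_effective)
    else:
        path_model = PathModel(path_spec, corr=corr, n=n)
    path_res = path_model.fit()
    path_res.coefficients.to_csv(out / "path_fit.tsv", sep="\t", index=False)
    report.add("path_fit", out / "path_fit.tsv")
    dot = export_diagram([(r.source, r.target, r.estimate, r.p_value)
                          for _, r in path_res.coefficients.iterrows()])
    (out / "path_diagram.dot").write_text(dot)
    report.add("path_diagram", out / "path_diagram.dot")

    log.info("== step 4: structural equation model ==")
    if corr is None:
        frames = [residualize(pd.concat([cohort.Y, cohort.Z.astype(float)], axis=1),
                              cohort.covariates)]
        if scores is not None:
            frames.append(residualize(scores, cohort.covariates))
        data = pd.concat(frames, axis=1)
        spec = _build_sem_spec(path_spec, factor_cols_by_trait or {},
                               config.residual_covariances)
        sem_model = SEModel(spec, data=data)
    else:
        spec = _build_sem_spec(path_spec, {}, config.residual_covariances)
        sem_model = SEModel(spec, cov=corr, n=n)
    fit = sem_model.fit()
    effects = fit.effects()
    effects.to_csv(out / "effects.tsv", sep="\t", index=False)
    report.add("effects", out / "effects.tsv")
    fi = fit.fit_indices()
    fit_report = {
        "n": fit.nobs, "chi_square": fit.chi_square, "df": fit.df,
        "f_ml": fit.fmin,
        "indices": {"nfi": fi.nfi, "cfi": fi.cfi, "gfi": fi.gfi,
                    "agfi": fi.agfi, "rmsea": fi.rmsea},
        "cutoffs_passed": fi.passed,
        "parameters": {k: float(v) for k, v in fit.params.items()},
        "standard_errors": {k: float(v) for k, v in fit.bse.items()},
        "convergence": fit.convergence,
        "seed": config.seed,
    }
    with open(out / "sem_fit.json", "w") as fh:
        json.dump(fit_report, fh, indent=2)
    report.add("sem_fit", out / "sem_fit.json")
    direct = effects[effects.effect == "direct"]
    dot = export_diagram([(r.source, r.target, r.estimate, r.p_value)
                          for _, r in direct.iterrows()
                          if (r.source, r.target) in {(p.source, p.target)
                                                      for p in spec.paths}])
    (out / "sem_diagram.dot").write_text(dot)
    report.add("sem_diagram", out / "sem_diagram.dot")
    log.info("  chi-square %.2f on %d df; %s", fit.chi_square, fit.df, fi.one_line())


def export_diagram(edges, name="model") -> str:
    """DOT digraph; edge labels are standardized estimates (3 decimals) and
    edges with p >= 0.05 are dashed (insignificant-path convention)."""
    lines = [f"digraph {name} {{", "  rankdir=LR;", "  node [shape=box];"]
    nodes = []
    for s, t, *_ in edges:
        for v in (s, t):
            if v not in nodes:
                nodes.append(v)
    for v in nodes:
        lines.append(f'  "{v}";')
    for s, t, est, p in edges:
        style = "dashed" if (p is None or not np.isfinite(p) or p >= 0.05) else "solid"
        lines.append(f'  "{s}" -> "{t}" [label="{est:.3f}", style={style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
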