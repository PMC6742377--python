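"""Shared heavy property checks, used by both the module tests and the
acceptance battery so each simulation design is defined exactly once."""

import numpy as np
import pandas as pd
from scipy import stats

import snpsem as ss
from snpsem.sem import SEModel, SEMSpec

#: recovery design: balanced strong-effect cascade chosen by an a-priori power
#: calculation so the +-0.02 band is >= 3.4 asymptotic SDs per coefficient
RECOVERY_CASCADE = {"sub_to_bmi": 0.5, "sub_to_wc": 0.3, "bmi_to_wc": 0.5,
                    "sub_to_t2d": 0.3, "bmi_to_t2d": 0.35, "wc_to_t2d": 0.35,
                    "sub_to_htn": 0.3, "bmi_to_htn": 0.25, "wc_to_htn": 0.3,
                    "t2d_to_htn": 0.25}
RECOVERY_FACTOR_EFFECTS = {"G1": ("SUB", 0.6), "G2": ("BMI", 0.45)}

RECOVERY_SPEC = SEMSpec(
    [("G1F", "SUB"), ("G2F", "BMI"),
     ("SUB", "BMI"), ("SUB", "WC"), ("BMI", "WC"),
     ("SUB", "T2D_L"), ("BMI", "T2D_L"), ("WC", "T2D_L"),
     ("SUB", "HTN_L"), ("BMI", "HTN_L"), ("WC", "HTN_L"), ("T2D_L", "HTN_L")],
    observed=["G1F", "G2F", "SUB", "BMI", "WC", "T2D_L", "HTN_L"])

RECOVERY_TRUTH = {
    ("G1F", "SUB"): 0.6, ("G2F", "BMI"): 0.45,
    ("SUB", "BMI"): RECOVERY_CASCADE["sub_to_bmi"],
    ("SUB", "WC"): RECOVERY_CASCADE["sub_to_wc"],
    ("BMI", "WC"): RECOVERY_CASCADE["bmi_to_wc"],
    ("SUB", "T2D_L"): RECOVERY_CASCADE["sub_to_t2d"],
    ("BMI", "T2D_L"): RECOVERY_CASCADE["bmi_to_t2d"],
    ("WC", "T2D_L"): RECOVERY_CASCADE["wc_to_t2d"],
    ("SUB", "HTN_L"): RECOVERY_CASCADE["sub_to_htn"],
    ("BMI", "HTN_L"): RECOVERY_CASCADE["bmi_to_htn"],
    ("WC", "HTN_L"): RECOVERY_CASCADE["wc_to_htn"],
    ("T2D_L", "HTN_L"): RECOVERY_CASCADE["t2d_to_htn"]}


def recovery_counts(n_seeds=100, n_subjects=20000, band=0.02):
    """Refit the generating structure on fresh cohorts; count seeds where all
    coefficients land inside the band, and per-coefficient 3-SE coverage.

    The disease equations are fitted on the generator's latent liabilities
    (from the truth record): normal-theory ML on 0/1 indicators estimates
    attenuated coefficients by construction, so the liability scale is the
    one on which recovery is well-posed.
    """
    ok_band = 0
    within_3se = {pair: 0 for pair in RECOVERY_TRUTH}
    for seed in range(n_seeds):
        cfg = ss.SimConfig(
            n_subjects=n_subjects, seed=seed,
            snp_groups=[ss.SNPGroup("G1", 3, (0.2, 0.4), 0.5),
                        ss.SNPGroup("G2", 3, (0.2, 0.4), 0.5)],
            factor_effects=RECOVERY_FACTOR_EFFECTS,
            cascade=RECOVERY_CASCADE, covariate_effects={})
        sim = ss.generate_cohort(cfg)
        data = pd.concat(
            [sim.truth["factors"].rename(columns={"G1": "G1F", "G2": "G2F"}),
             sim.cohort.Y,
             sim.truth["liabilities"].rename(columns={"T2D": "T2D_L",
                                                      "HTN": "HTN_L"})], axis=1)
        fit = SEModel(RECOVERY_SPEC, data=data).fit()
        bse = fit.bse
        ok_band += all(abs(fit.params[f"{t}~{s}"] - v) < band
                       for (s, t), v in RECOVERY_TRUTH.items())
        for (s, t), v in RECOVERY_TRUTH.items():
            within_3se[(s, t)] += (abs(fit.params[f"{t}~{s}"] - v)
                                   < 3 * max(bse[f"{t}~{s}"], 1e-9))
    return ok_band, within_3se


def null_scan_uniformity_count(n_scans=100, n_snps=200, n_subjects=500,
                               master_seed=12345):
    """Number of null scans whose p-value KS statistic vs U(0,1) is below the
    two-sided alpha=0.01 critical value."""
    from snpsem.scan import linear_scan

    crit = stats.ksone.ppf(1 - 0.005, n_snps)
    rng = np.random.default_rng(master_seed)
    ok = 0
    for _ in range(n_scans):
        cfg = ss.SimConfig(n_subjects=n_subjects, seed=int(rng.integers(2 ** 31)),
                           snp_groups=[ss.SNPGroup("G", n_snps, (0.1, 0.5), 0.0)],
                           factor_effects={}, covariate_effects={},
                           cascade={k: 0.0 for k in ss.simulate.CASCADE_KEYS})
        cohort = ss.generate_cohort(cfg).cohort
        pvals = np.array([r.p_value for r in linear_scan(cohort, "SUB")])
        ok += stats.kstest(pvals, "uniform").statistic < crit
    return ok


def chi2_rejection_rate(n_reps=500, n=200, seed=77):
    """Empirical P(chi2 > 3.84) for a correctly specified 1-df chain model."""
    rng = np.random.default_rng(seed)
    spec = SEMSpec([("x", "m"), ("m", "y")], observed=["x", "m", "y"])
    crit = stats.chi2.ppf(0.95, 1)
    rejections = 0
    for _ in range(n_reps):
        x = rng.standard_normal(n)
        m = 0.5 * x + np.sqrt(0.75) * rng.standard_normal(n)
        y = 0.4 * m + np.sqrt(0.84) * rng.standard_normal(n)
        fit = SEModel(spec, data=pd.DataFrame({"x": x, "m": m, "y": y})).fit()
        rejections += fit.chi_square > crit
    return rejections / n_reps
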