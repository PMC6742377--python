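"""Published summary statistics from the KARE cohort, usable as matrix-mode inputs.

The KARE (Korea Association Resource) individual-level data are access
restricted, but the published covariate-adjusted partial correlations
among the three adiposity traits and the two disease indicators
(n = 8,792 complete cases) are public summary statistics and suffice to
fit the recursive phenotype path model in matrix mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["kare_phenotype_correlations", "kare_reported_fit_indices",
            "KARE_N", "KARE_PREVALENCES"]

#: complete-case sample size the published partial correlations refer to
KARE_N = 8792

#: published cohort disease prevalences (T2D 9.45%, hypertension 27.06%)
KARE_PREVALENCES = {"t2d": 0.0945, "htn": 0.2706}

_VARS = ["SUB", "BMI", "WC", "T2D", "HTN"]
_LOWER = {
    ("BMI", "SUB"): 0.634,
    ("WC", "SUB"): 0.547, ("WC", "BMI"): 0.824,
    ("T2D", "SUB"): 0.121, ("T2D", "BMI"): 0.107, ("T2D", "WC"): 0.122,
    ("HTN", "SUB"): 0.135, ("HTN", "BMI"): 0.194, ("HTN", "WC"): 0.180,
    ("HTN", "T2D"): 0.102,
}


def kare_phenotype_correlations() -> pd.DataFrame:
    """5x5 covariate-adjusted partial-correlation matrix (SUB, BMI, WC, T2D, HTN)."""
    R = np.eye(len(_VARS))
    idx = {v: i for i, v in enumerate(_VARS)}
    for (a, b), r in _LOWER.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return pd.DataFrame(R, index=_VARS, columns=_VARS)


def kare_reported_fit_indices() -> dict:
    """Goodness-of-fit indices reported for the final full SEM on the KARE data.

    The underlying individual-level data are restricted, so these values
    cannot be recomputed here; they serve as inputs to the cutoff checker.
    """
    return {"chi_square": 536.52, "nfi": 0.997, "cfi": 0.998,
            "gfi": 0.995, "agfi": 0.993, "rmsea": 0.012}
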