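"""Cohort container: the n x c block matrix A = [X | Y | Z] plus covariates.

X holds additive genotype dosages (0/1/2 minor-allele counts), Y the
continuous intermediate phenotypes, Z the binary disease indicators;
covariates (sex, area, age) are carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortData", "read_genotypes", "read_phenotypes", "read_plink_raw"]

PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class CohortData:
    X: pd.DataFrame                      # n x p dosages
    Y: pd.DataFrame                      # n x q continuous phenotypes
    Z: pd.DataFrame                      # n x r binary diseases
    covariates: pd.DataFrame             # sex/area/age
    subject_ids: pd.Index = field(default=None)

    def __post_init__(self):
        if self.subject_ids is None:
            self.subject_ids = self.Y.index
        for name, block in (("X", self.X), ("Y", self.Y), ("Z", self.Z),
                            ("covariates", self.covariates)):
            if len(block) != len(self.subject_ids):
                raise ValueError(f"block {name} has {len(block)} rows, "
                                 f"expected {len(self.subject_ids)}")
        gx = self.X.to_numpy(float)
        finite = gx[np.isfinite(gx)]
        if finite.size and not np.all(np.isin(finite, [0.0, 1.0, 2.0])):
            raise ValueError("genotype dosages must be in {0, 1, 2}")
        dz = self.Z.to_numpy(float)
        finite = dz[np.isfinite(dz)]
        if finite.size and not np.all(np.isin(finite, [0.0, 1.0])):
            raise ValueError("disease indicators must be 0/1")

    @property
    def n(self):
        return len(self.subject_ids)

    @property
    def shape(self):
        """(n, p, q, r) with c = p + q + r columns in the block matrix."""
        return (self.n, self.X.shape[1], self.Y.shape[1], self.Z.shape[1])

    def phenotype_frame(self) -> pd.DataFrame:
        """Y, Z and covariates joined on subjects (for regression scans)."""
        return pd.concat([self.Y, self.Z, self.covariates], axis=1)

    def block_matrix(self) -> pd.DataFrame:
        """The full A = [X | Y | Z] matrix."""
        return pd.concat([self.X, self.Y, self.Z], axis=1)

    def write(self, genotype_path, phenotype_path):
        gx = self.X.copy()
        gx.index.name = "subject_id"
        gx.to_csv(genotype_path)
        ph = self.phenotype_frame().copy()
        ph.index.name = "subject_id"
        ph.to_csv(phenotype_path)


def read_genotypes(path) -> pd.DataFrame:
    """Dosage matrix from CSV/TSV (first column subject ID, header SNP IDs)
    or from the PLINK .raw dialect (detected by its FID/IID header)."""
    with open(path) as fh:
        header = fh.readline()
    if header.split()[:2] == ["FID", "IID"]:
        return read_plink_raw(path)
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df


def read_plink_raw(path) -> pd.DataFrame:
    """PLINK additive-recode file: FID IID PAT MAT SEX PHENOTYPE then SNP_allele
    columns; the trailing _allele suffix is stripped from SNP names."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in PLINK_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"not a PLINK .raw file; missing columns {missing}")
    df = df.set_index("IID")
    snp_cols = [c for c in df.columns if c not in PLINK_META_COLS]
    out = df[snp_cols].copy()
    out.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return out


def read_phenotypes(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, index_col=0)
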