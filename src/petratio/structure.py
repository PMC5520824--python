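"""Interregional correlation, within-genotype z-scoring, PCA and R² association.

These analyses probe *why* ratio outcomes behave as they do: if regional
binding across subjects is dominated by a single shared latent factor, all
regions are near-collinear, the first principal component of z-scored
regional values carries almost all variance, and dividing a target region
by a highly correlated denominator removes the between-subject signal —
leaving mostly noise in SUVR/DVR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionMatrix",
    "region_matrix",
    "interregional_correlation",
    "zscore_within_genotype",
    "pca_variance_explained",
    "association_r2",
]


@dataclass
class RegionMatrix:
    """Scans × ROIs matrix of one measure, with genotype/scan row labels."""

    data: pd.DataFrame  # index: (subject, scan), columns: ROI
    genotype: pd.Series  # aligned with data.index
    scan_index: pd.Series

    def __post_init__(self):
        if self.data.isna().any().any():
            missing = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing cells in ROI columns {missing}")
        counts = self.genotype.value_counts()
        if (counts < 2).any():
            raise ValueError("each genotype needs at least 2 scans for z-scoring")


def region_matrix(values: pd.DataFrame, value_col: str) -> RegionMatrix:
    """Pivot a long (subject, scan, genotype, roi, value) table to scans × ROIs."""
    wide = values.pivot_table(index=["subject", "scan"], columns="roi",
                              values=value_col)
    geno = values.drop_duplicates(["subject", "scan"]).set_index(["subject", "scan"])
    geno = geno.loc[wide.index]
    return RegionMatrix(data=wide,
                        genotype=geno["genotype"],
                        scan_index=wide.index.get_level_values("scan").to_series(index=wide.index))


def interregional_correlation(matrix: RegionMatrix) -> pd.DataFrame:
    """ROI × ROI Pearson correlation matrix (square r to obtain R²).

    Zero-variance columns yield NaN entries — flagged, never imputed.
    """
    if len(matrix.data) < 3:
        raise ValueError("need at least 3 scans for correlations")
    return matrix.data.corr(method="pearson")


def zscore_within_genotype(matrix: RegionMatrix) -> RegionMatrix:
    """Standardise each ROI column to mean 0, sample SD 1 within genotype."""
    out = matrix.data.copy()
    for group in matrix.genotype.unique():
        mask = (matrix.genotype == group).to_numpy()
        if mask.sum() < 2:
            raise ValueError(f"genotype {group} has fewer than 2 scans")
        block = out.loc[mask]
        out.loc[mask] = (block - block.mean()) / block.std(ddof=1)
    return RegionMatrix(data=out, genotype=matrix.genotype,
                        scan_index=matrix.scan_index)


def pca_variance_explained(matrix: RegionMatrix, scan_index: int | None = None) -> np.ndarray:
    """Fractions of variance per principal component, descending.

    Computed as eigenvalues of the column covariance of the (already
    z-scored) matrix, normalised to sum 1. With z-scored input this equals
    correlation-matrix PCA. ``scan_index`` restricts rows to one scan
    session, as when decomposing test and retest sessions independently.
    """
    data = matrix.data
    if scan_index is not None:
        data = data[matrix.scan_index == scan_index]
    X = data.to_numpy(float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows for PCA")
    if p > n:
        warnings.warn(f"PCA with more ROIs ({p}) than rows ({n}): small-sample "
                      "regime; fractions are still computed")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    return eig / eig.sum()


def association_r2(outcome_values: np.ndarray, vt_values: np.ndarray,
                   genotype: np.ndarray) -> dict[str, float]:
    """Squared Pearson correlation of an outcome with V_T, per genotype.

    Both scans of a subject enter as separate points. Zero variance in
    either variable gives NaN for that genotype (flagged undefined).
    """
    outcome_values = np.asarray(outcome_values, float)
    vt_values = np.asarray(vt_values, float)
    genotype = np.asarray(genotype)
    if not (len(outcome_values) == len(vt_values) == len(genotype)):
        raise ValueError("inputs must have equal length")
    result = {}
    for group in pd.unique(genotype):
        m = genotype == group
        if m.sum() < 3:
            raise ValueError(f"genotype {group} has fewer than 3 points")
        x, y = outcome_values[m], vt_values[m]
        if x.std() == 0 or y.std() == 0:
            result[str(group)] = float("nan")
            continue
        r = np.corrcoef(x, y)[0, 1]
        result[str(group)] = float(r * r)
    return result
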