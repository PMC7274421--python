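"""Quality control, imputation and transformation of genotypes & metabolites.

Marker QC follows the array-genotyping conventions of multi-family
populations: a marker is kept only if it is polymorphic in at least one
family, its missing-call fraction is strictly below 10% and its heterozygote
fraction strictly below 12.5% (residual heterozygosity in a BC1S3 population
is expected near 6.25%, so a grossly heterozygous marker indicates a
genotyping artefact). Missing genotype calls are mean-imputed per marker
(MNI) with the continuous column mean, since the downstream whole-genome
regressions accept real-valued dosages. Metabolites with more than 10%
missing values are dropped; remaining gaps are filled with the per-metabolite
observed minimum (missingness in GC-MS intensities is predominantly
left-censoring at the detection limit).

Array-shaped steps are also exposed as scikit-learn transformers so they
compose with pipelines.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import GenotypeMatrix

__all__ = [
    "qc_filter_snps",
    "impute_mni",
    "monomorphic_family_recode",
    "filter_metabolites",
    "impute_metabolite_min",
    "boxcox_transform",
    "DEFAULT_LAMBDA_GRID",
    "MeanDosageImputer",
    "MetaboliteMinImputer",
    "BoxCoxGridTransformer",
]

logger = logging.getLogger(__name__)

#: Box-Cox candidate exponents: -3 to 3 in steps of 0.25.
DEFAULT_LAMBDA_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.25), 2)


def _family_polymorphic(g: GenotypeMatrix) -> np.ndarray:
    """Boolean (families x markers): marker segregates within the family."""
    fams = pd.unique(g.family_ids)
    out = np.zeros((len(fams), g.n_markers), dtype=bool)
    for i, fam in enumerate(fams):
        sub = g.dosage[g.family_ids == fam]
        with np.errstate(invalid="ignore"):
            lo = np.nanmin(sub, axis=0)
            hi = np.nanmax(sub, axis=0)
        out[i] = hi > lo
    return out


def qc_filter_snps(
    raw: GenotypeMatrix, max_failure: float = 0.10, max_het: float = 0.125
) -> GenotypeMatrix:
    """Keep markers polymorphic in >=1 family, with missingness < `max_failure`
    and heterozygote fraction < `max_het` (both strict)."""
    if not (0 <= max_failure <= 1 and 0 <= max_het <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    d = raw.dosage
    miss_frac = np.isnan(d).mean(axis=0)
    with np.errstate(invalid="ignore"):
        het_frac = np.nansum(d == 1, axis=0) / np.maximum((~np.isnan(d)).sum(axis=0), 1)
    poly_any = _family_polymorphic(raw).any(axis=0)
    keep = poly_any & (miss_frac < max_failure) & (het_frac < max_het)
    logger.info("marker QC: %d of %d markers retained", int(keep.sum()), raw.n_markers)
    return raw.select_markers(keep)


def impute_mni(g: GenotypeMatrix) -> GenotypeMatrix:
    """Mean imputation (MNI): missing calls -> per-marker mean observed dosage.

    The continuous mean is used (not rounded); observed cells are untouched.
    """
    d = g.dosage.copy()
    miss = np.isnan(d)
    if not miss.any():
        return g.copy_with(dosage=d)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = g.marker_ids[all_missing][:5]
        raise ValueError(f"markers with no observed calls cannot be imputed: {list(bad)}")
    col_mean = np.nanmean(d, axis=0)
    d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return g.copy_with(dosage=d)


def monomorphic_family_recode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Set within-family-monomorphic markers to dosage 0 for that family.

    In a NAM design the donor allele is only defined where the family
    segregates; a family monomorphic at a marker is genetically identical to
    the recurrent parent there and is coded 0 regardless of the raw call.
    """
    d = g.dosage.copy()
    fams = pd.unique(g.family_ids)
    for fam in fams:
        rows = g.family_ids == fam
        sub = d[rows]
        with np.errstate(invalid="ignore"):
            lo = np.nanmin(sub, axis=0)
            hi = np.nanmax(sub, axis=0)
        mono = ~(hi > lo)  # all-NaN columns count as monomorphic
        sub[:, mono] = 0.0
        d[rows] = sub
    return g.copy_with(dosage=d)


def filter_metabolites(m: pd.DataFrame, max_missing: float = 0.10) -> pd.DataFrame:
    """Drop metabolites whose missing fraction strictly exceeds `max_missing`."""
    if not (0 <= max_missing < 1):
        raise ValueError("max_missing must lie in [0, 1)")
    miss_frac = m.isna().mean(axis=0)
    keep = miss_frac.to_numpy() <= max_missing
    logger.info("metabolite filter: %d of %d metabolites retained", int(keep.sum()), m.shape[1])
    return m.loc[:, keep]


def impute_metabolite_min(m: pd.DataFrame) -> pd.DataFrame:
    """Fill missing intensities with the per-metabolite observed minimum."""
    if (m.isna().all(axis=0)).any():
        bad = m.columns[m.isna().all(axis=0)][:5].tolist()
        raise ValueError(f"metabolites with no observed values: {bad}")
    return m.fillna(m.min(axis=0))


def boxcox_transform(
    x: np.ndarray, lambda_grid: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Box-Cox power transform with the exponent chosen from a grid.

    The exponent maximising the Box-Cox log-likelihood under normality is
    selected from `lambda_grid` (default -3..3 by 0.25). Non-positive inputs
    are first shifted by (1 - min). Transform: (x^l - 1)/l, or log x at l = 0.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")
    if x.size < 2:
        raise ValueError("need at least two values")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    xmin = x.min()
    shifted = x + (1.0 - xmin) if xmin <= 0 else x
    llf = np.array([stats.boxcox_llf(lam, shifted) for lam in grid])
    lam = float(grid[int(np.argmax(llf))])
    if lam == 0.0:
        return np.log(shifted), lam
    return (shifted**lam - 1.0) / lam, lam


class MeanDosageImputer(TransformerMixin, BaseEstimator):
    """Per-column mean imputation of a dosage array (MNI), sklearn-style."""

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan")
        if np.isnan(X).all(axis=0).any():
            raise ValueError("column with no observed values")
        self.col_mean_ = np.nanmean(X, axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "col_mean_")
        X = check_array(X, ensure_all_finite="allow-nan", copy=True)
        miss = np.isnan(X)
        X[miss] = np.broadcast_to(self.col_mean_, X.shape)[miss]
        return X


class MetaboliteMinImputer(TransformerMixin, BaseEstimator):
    """Per-column minimum imputation for left-censored intensity data."""

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan")
        if np.isnan(X).all(axis=0).any():
            raise ValueError("column with no observed values")
        self.col_min_ = np.nanmin(X, axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "col_min_")
        X = check_array(X, ensure_all_finite="allow-nan", copy=True)
        miss = np.isnan(X)
        X[miss] = np.broadcast_to(self.col_min_, X.shape)[miss]
        return X


class BoxCoxGridTransformer(TransformerMixin, BaseEstimator):
    """Column-wise Box-Cox transform with grid-selected exponents.

    Parameters
    ----------
    lambda_grid : array-like, default -3..3 by 0.25
        Candidate exponents; the per-column exponent maximises the Box-Cox
        log-likelihood on the training data.
    """

    def __init__(self, lambda_grid=None):
        self.lambda_grid = lambda_grid

    def fit(self, X, y=None):
        X = check_array(X)
        grid = (
            DEFAULT_LAMBDA_GRID
            if self.lambda_grid is None
            else np.asarray(self.lambda_grid, dtype=float)
        )
        self.shift_ = np.where(X.min(axis=0) <= 0, 1.0 - X.min(axis=0), 0.0)
        lambdas = []
        for j in range(X.shape[1]):
            col = X[:, j] + self.shift_[j]
            llf = [stats.boxcox_llf(lam, col) for lam in grid]
            lambdas.append(float(grid[int(np.argmax(llf))]))
        self.lambdas_ = np.array(lambdas)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "lambdas_")
        X = check_array(X, copy=True)
        out = np.empty_like(X, dtype=float)
        for j, lam in enumerate(self.lambdas_):
            col = X[:, j] + self.shift_[j]
            if (col <= 0).any():
                raise ValueError("non-positive values after training shift")
            out[:, j] = np.log(col) if lam == 0.0 else (col**lam - 1.0) / lam
        return out
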