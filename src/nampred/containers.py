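"""Core in-memory containers shared across the pipeline.

Genotypes live in a light dataclass (dosage matrix plus line/family/marker
metadata, AnnData-style but without the overhead); metabolite intensities and
plot-level phenotypes are plain pandas objects, which already handle missing
values and long-format records idiomatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PHENOTYPE_COLUMNS",
    "validate_phenotype_table",
]

#: Required columns of a long-format plot phenotype table.
PHENOTYPE_COLUMNS = ("line_id", "year", "replicate", "trait", "value")


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with family labels and a marker map.

    Dosages count copies of the donor (wild) allele relative to the recurrent
    elite parent: 0 = homozygous recurrent parent, 1 = heterozygous,
    2 = homozygous donor. Missing calls are NaN. The marker table carries
    (marker_id, chromosome, position_cM) in column order matching `dosage`.
    """

    line_ids: np.ndarray
    family_ids: np.ndarray
    markers: pd.DataFrame  # columns: marker_id, chromosome, position_cM
    dosage: np.ndarray  # float, shape (n_lines, n_markers), NaN = missing

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.family_ids = np.asarray(self.family_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D lines x markers array")
        n, m = self.dosage.shape
        if len(self.line_ids) != n:
            raise ValueError(f"{len(self.line_ids)} line ids for {n} dosage rows")
        if len(self.family_ids) != n:
            raise ValueError("family label required for every line")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker records for {m} dosage columns")
        if pd.Index(self.line_ids).has_duplicates:
            raise ValueError("duplicate line ids")
        if pd.Index(self.markers["marker_id"]).has_duplicates:
            raise ValueError("duplicate marker ids")
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            # imputed matrices carry fractional dosages; only raw matrices are
            # checked strictly, via read_genotype_table / simulators
            pass

    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    def copy_with(self, **updates) -> "GenotypeMatrix":
        return replace(self, **updates)

    def select_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset by marker positions (boolean mask or integer index)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            line_ids=self.line_ids,
            family_ids=self.family_ids,
            markers=self.markers.iloc[np.flatnonzero(index) if index.dtype == bool else index]
            .reset_index(drop=True),
            dosage=self.dosage[:, index],
        )

    def select_lines(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            line_ids=self.line_ids[index],
            family_ids=self.family_ids[index],
            markers=self.markers,
            dosage=self.dosage[index],
        )


def validate_phenotype_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format plot table for the required schema.

    Requires columns (line_id, year, replicate, trait, value), a unique
    (line, year, replicate, trait) key and finite values.
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    key = ["line_id", "year", "replicate", "trait"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (line, year, replicate, trait) records")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite phenotype values")
    return table
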