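"""Tab-separated readers/writers for every table the pipeline exchanges.

Genotypes travel as a wide TSV (line_id, family, one column per marker) with
an optional companion marker-map TSV (marker_id, chromosome, position_cM);
phenotypes as a long TSV (line_id, year, replicate, trait, value);
metabolites as a wide TSV indexed by line id. Simulation ground truth is
written both as TSV and as a key=value sidecar for quick inspection.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PHENOTYPE_COLUMNS, validate_phenotype_table
from .simulate import SimTruth

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_metabolite_table",
    "write_metabolite_table",
    "write_truth",
]

_VALID = {0.0, 1.0, 2.0}


def write_genotype_table(g: GenotypeMatrix, path: str, marker_map_path: str | None = None) -> None:
    df = pd.DataFrame(g.dosage, columns=g.marker_ids)
    df.insert(0, "family", g.family_ids)
    df.insert(0, "line_id", g.line_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    if marker_map_path:
        g.markers.to_csv(marker_map_path, sep="\t", index=False)


def read_genotype_table(path: str, marker_map_path: str | None = None) -> GenotypeMatrix:
    """Read a wide genotype TSV; cells must be 0/1/2 or missing (NA/empty).

    A malformed cell raises a format error naming the offending row and
    column. Fractional dosages (from a previously imputed matrix) are
    accepted when they lie in [0, 2].
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "family": str})
    for col in ("line_id", "family"):
        if col not in df.columns:
            raise ValueError(f"genotype table lacks required column {col!r}")
    marker_cols = [c for c in df.columns if c not in ("line_id", "family")]
    dosage = df[marker_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(dosage) | ((dosage >= 0) & (dosage <= 2)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid dosage {dosage[i, j]!r} at line {df['line_id'].iloc[i]!r}, "
            f"marker {marker_cols[j]!r}: expected 0/1/2 or missing"
        )
    if marker_map_path and os.path.exists(marker_map_path):
        markers = pd.read_csv(marker_map_path, sep="\t")
        if list(markers["marker_id"]) != marker_cols:
            raise ValueError("marker map does not match genotype columns")
    else:
        markers = pd.DataFrame(
            {
                "marker_id": marker_cols,
                "chromosome": "chr0",
                "position_cM": np.arange(len(marker_cols), dtype=float),
            }
        )
    return GenotypeMatrix(
        line_ids=df["line_id"].to_numpy(dtype=object),
        family_ids=df["family"].to_numpy(dtype=object),
        markers=markers,
        dosage=dosage,
    )


def write_phenotype_table(table: pd.DataFrame, path: str) -> None:
    validate_phenotype_table(table)
    table[list(PHENOTYPE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"line_id": str, "trait": str})
    return validate_phenotype_table(table)


def write_metabolite_table(m: pd.DataFrame, path: str) -> None:
    m.to_csv(path, sep="\t", index=True, index_label="line_id", na_rep="NA")


def read_metabolite_table(path: str) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col="line_id")
    vals = m.to_numpy(dtype=float)
    if np.isinf(vals).any():
        raise ValueError("non-finite metabolite intensities")
    return m


def write_truth(truth: SimTruth, tsv_path: str, sidecar_path: str | None = None) -> None:
    """Persist simulation ground truth as TSV plus a key=value sidecar."""
    pd.DataFrame(
        {"qtl_index": truth.qtl_indices, "qtl_effect": truth.qtl_effects}
    ).to_csv(tsv_path, sep="\t", index=False)
    if sidecar_path:
        scalars = {
            "target_h2": truth.target_h2,
            "gxy_variance_ratio": truth.gxy_variance_ratio,
            "v_g": truth.v_g,
            "v_gy": truth.v_gy,
            "v_r": truth.v_r,
            "n_years": truth.n_years,
            "n_reps": truth.n_reps,
            "n_qtl": len(truth.qtl_indices),
        }
        with open(sidecar_path, "w") as fh:
            for k, v in scalars.items():
                fh.write(f"{k}={v}\n")
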