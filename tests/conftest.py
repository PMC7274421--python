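"""Shared simulated fixtures. Session-scoped where generation is expensive."""

import numpy as np
import pandas as pd
import pytest

from nampred import (
    GenotypeMatrix,
    simulate_genetic_map,
    simulate_metabolites,
    simulate_nam_population,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def gmap_small():
    return simulate_genetic_map(4, 30, 100.0, seed=11)


@pytest.fixture(scope="session")
def geno_small(gmap_small):
    """60-line, 120-marker NAM population for fast unit tests."""
    return simulate_nam_population(gmap_small, 6, 10, selfing_generations=3, seed=11)


@pytest.fixture(scope="session")
def nam():
    """Mid-sized NAM data set (400 lines, 560 markers) with phenotypes,
    metabolites and ground truth, shared by the pheno/evaluation tests."""
    gmap = simulate_genetic_map(7, 80, 150.0, seed=1)
    geno = simulate_nam_population(gmap, 25, 16, selfing_generations=3, seed=7)
    phen, truth = simulate_phenotypes(
        geno, n_qtl=50, target_h2=0.9, n_years=8, n_reps=2, gxy_ratio=0.1, seed=3
    )
    mets, met_truth = simulate_metabolites(
        geno, n_metabolites=64, h2_snp_mean=0.10, h2_snp_max=0.50,
        missing_rate=0.0, trait_truth=truth, shared_qtl_fraction=0.5, seed=11,
    )
    return {"geno": geno, "phen": phen, "truth": truth, "mets": mets, "met_truth": met_truth}


@pytest.fixture()
def toy_geno():
    """Hand-built 6-line, 4-marker matrix over two families.

    M1: polymorphic in both families. M2: monomorphic 0 everywhere.
    M3: polymorphic in F1 only; F2 carries a constant non-zero call.
    M4: has a missing call.
    """
    markers = pd.DataFrame(
        {
            "marker_id": ["M1", "M2", "M3", "M4"],
            "chromosome": ["chr1"] * 4,
            "position_cM": [0.0, 10.0, 20.0, 30.0],
        }
    )
    dosage = np.array(
        [
            [0, 0, 0, 0],
            [2, 0, 2, 2],
            [1, 0, 0, np.nan],
            [0, 0, 2, 0],
            [2, 0, 2, 2],
            [1, 0, 2, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        line_ids=np.array([f"L{i}" for i in range(6)], dtype=object),
        family_ids=np.array(["F1", "F1", "F1", "F2", "F2", "F2"], dtype=object),
        markers=markers,
        dosage=dosage,
    )
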