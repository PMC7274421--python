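"""Synthetic nested-association-mapping (NAM) population generator.

Emulates a barley-style NAM design: 25 wild donors each crossed to one
recurrent elite parent, one backcross to the recurrent parent, then
single-seed-descent selfing (BC1S3 by default). Meiosis places crossovers as
a Poisson process at one event per 100 cM with no interference. On top of the
genotypes the module simulates multi-year replicated plot phenotypes with an
additive multi-QTL architecture calibrated to a target broad-sense
heritability, and a metabolite layer with low genomic heritability and
missing-at-random entries — every downstream stage of the pipeline can then
be tested against known ground truth.

Mendelian expectations for the default BC1S3 scheme (used as test oracles):
donor allele frequency 1/4 at donor-polymorphic loci, and expected
heterozygote fraction 1/2 * (1/2)^s after s selfing generations (1/16 at s=3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import GenotypeMatrix, PHENOTYPE_COLUMNS

__all__ = [
    "GeneticMap",
    "SimTruth",
    "simulate_genetic_map",
    "simulate_nam_population",
    "simulate_phenotypes",
    "simulate_metabolites",
]


@dataclass
class GeneticMap:
    """Chromosome lengths (cM) and an ordered marker map.

    `chromosomes` maps chromosome id -> length in cM; `markers` has columns
    (marker_id, chromosome, position_cM), ordered by chromosome then position.
    """

    chromosomes: dict[str, float]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        pos = self.markers["position_cM"].to_numpy(dtype=float)
        if (pos < 0).any():
            raise ValueError("negative marker position")
        for chrom, sub in self.markers.groupby("chromosome", sort=False):
            if chrom not in self.chromosomes:
                raise ValueError(f"marker on undeclared chromosome {chrom!r}")
            p = sub["position_cM"].to_numpy(dtype=float)
            if (np.diff(p) < 0).any():
                raise ValueError(f"marker positions not sorted on chromosome {chrom}")
            if p.size and p[-1] > self.chromosomes[chrom]:
                raise ValueError(f"marker beyond the end of chromosome {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        """Contiguous marker index range per chromosome, in map order."""
        out, start = [], 0
        for chrom, sub in self.markers.groupby("chromosome", sort=False):
            out.append((chrom, slice(start, start + len(sub))))
            start += len(sub)
        return out


@dataclass
class SimTruth:
    """Generating values recorded alongside a simulated data set.

    Used by parameter-recovery tests: QTL positions/effects, the variance
    components the phenotype generator solved for, per-line genotypic values
    and, when metabolites were simulated, their target genomic heritabilities
    and QTL overlap with the trait.
    """

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    target_h2: float
    gxy_variance_ratio: float
    v_g: float
    v_gy: float
    v_r: float
    n_years: int
    n_reps: int
    genotypic_values: np.ndarray
    metabolite_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0 < self.target_h2 <= 1):
            raise ValueError("target_h2 must lie in (0, 1]")


def simulate_genetic_map(
    n_chrom: int,
    markers_per_chrom: int,
    chrom_length_cM: float,
    seed: int,
) -> GeneticMap:
    """Uniformly spaced markers (with jitter) on equally sized chromosomes."""
    if n_chrom < 1 or markers_per_chrom < 1:
        raise ValueError("n_chrom and markers_per_chrom must be >= 1")
    if chrom_length_cM <= 0:
        raise ValueError("chrom_length_cM must be positive")
    rng = substream(seed, "genetic_map")
    records = []
    chromosomes = {}
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        chromosomes[chrom] = float(chrom_length_cM)
        grid = (np.arange(markers_per_chrom) + 0.5) / markers_per_chrom * chrom_length_cM
        jitter = rng.uniform(-0.4, 0.4, size=markers_per_chrom) * (
            chrom_length_cM / markers_per_chrom
        )
        pos = np.sort(np.clip(grid + jitter, 0.0, chrom_length_cM))
        for k, p in enumerate(pos):
            records.append((f"{chrom}_M{k + 1:05d}", chrom, float(p)))
    markers = pd.DataFrame(records, columns=["marker_id", "chromosome", "position_cM"])
    return GeneticMap(chromosomes=chromosomes, markers=markers)


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    chrom_bounds: list[tuple[slice, float]],
    positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product: crossovers Poisson(length/100), no interference."""
    out = np.empty_like(hap_a)
    for sl, length in chrom_bounds:
        n_co = rng.poisson(length / 100.0)
        phase0 = rng.integers(0, 2)
        if n_co == 0:
            src = hap_a if phase0 == 0 else hap_b
            out[sl] = src[sl]
            continue
        breaks = np.sort(rng.uniform(0.0, length, size=n_co))
        parity = (np.searchsorted(breaks, positions[sl], side="right") + phase0) % 2
        out[sl] = np.where(parity == 0, hap_a[sl], hap_b[sl])
    return out


def simulate_nam_population(
    gmap: GeneticMap,
    n_families: int,
    lines_per_family: int,
    selfing_generations: int = 3,
    seed: int = 0,
    donor_polymorphic_fraction: float = 0.5,
) -> GenotypeMatrix:
    """Breed a NAM population from one recurrent parent and `n_families` donors.

    The recurrent parent is homozygous 0 everywhere; each donor is homozygous
    2 at a family-specific random subset of markers (fraction
    `donor_polymorphic_fraction`), so families segregate only at their donor's
    subset. Scheme per line: F1 x recurrent parent (BC1), then
    `selfing_generations` rounds of single-seed descent. Dosage counts donor
    alleles (0/1/2).
    """
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    if n_families < 1 or lines_per_family < 1:
        raise ValueError("n_families and lines_per_family must be >= 1")
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    if not (0 < donor_polymorphic_fraction <= 1):
        raise ValueError("donor_polymorphic_fraction must lie in (0, 1]")

    rng = substream(seed, "meiosis")
    m = gmap.n_markers
    positions = gmap.markers["position_cM"].to_numpy(dtype=float)
    chrom_bounds = [(sl, gmap.chromosomes[chrom]) for chrom, sl in gmap.chromosome_slices()]
    n_poly = max(1, int(round(donor_polymorphic_fraction * m)))

    dosages = np.empty((n_families * lines_per_family, m), dtype=np.int8)
    line_ids, family_ids = [], []
    row = 0
    for fam in range(1, n_families + 1):
        fam_id = f"F{fam:02d}"
        donor = np.zeros(m, dtype=np.int8)
        donor[rng.choice(m, size=n_poly, replace=False)] = 1  # haplotype allele
        # F1 = donor x recurrent parent: one donor haplotype, one null haplotype
        f1 = (donor, np.zeros(m, dtype=np.int8))
        for k in range(1, lines_per_family + 1):
            # BC1: gamete from the F1 plus a null gamete from the recurrent parent
            hap_a = _gamete(f1[0], f1[1], chrom_bounds, positions, rng)
            hap_b = np.zeros(m, dtype=np.int8)
            for _ in range(selfing_generations):
                hap_a, hap_b = (
                    _gamete(hap_a, hap_b, chrom_bounds, positions, rng),
                    _gamete(hap_a, hap_b, chrom_bounds, positions, rng),
                )
            dosages[row] = hap_a + hap_b
            line_ids.append(f"{fam_id}_L{k:03d}")
            family_ids.append(fam_id)
            row += 1

    return GenotypeMatrix(
        line_ids=np.array(line_ids, dtype=object),
        family_ids=np.array(family_ids, dtype=object),
        markers=gmap.markers.copy(),
        dosage=dosages.astype(float),
    )


def _solve_residual_variance(
    v_g: float, v_gy: float, target_h2: float, n_years: int, n_reps: int
) -> float:
    """Residual variance making V_G/(V_G + V_GY/y + V_R/(y r)) hit target_h2."""
    v_r = n_years * n_reps * (v_g / target_h2 - v_g - v_gy / n_years)
    if v_r < -1e-9 * max(v_g, 1.0):
        raise ValueError(
            f"target_h2={target_h2} unreachable with gxy ratio giving V_GY={v_gy:.3g} "
            f"at y={n_years}: required residual variance is negative"
        )
    return max(v_r, 0.0)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    n_qtl: int,
    target_h2: float,
    n_years: int = 8,
    n_reps: int = 2,
    gxy_ratio: float = 0.1,
    seed: int = 0,
    trait: str = "TRAIT",
) -> tuple[pd.DataFrame, SimTruth]:
    """Additive multi-QTL plot phenotypes over a multi-year replicated trial.

    Genotypic value = sum of additive QTL dosage effects. Plot value adds a
    year main effect (wide normal, cancels in BLUEs), a genotype-by-year
    deviate with variance `gxy_ratio * V_G`, and a residual whose variance is
    solved so that h2 = V_G/(V_G + V_GY/y + V_R/(y r)) equals `target_h2`.
    """
    if not (0 < target_h2 <= 1):
        raise ValueError("target_h2 must lie in (0, 1]")
    if n_qtl < 1 or n_qtl > genotypes.n_markers:
        raise ValueError("n_qtl must lie in [1, n_markers]")
    if n_years < 1 or n_reps < 1:
        raise ValueError("n_years and n_reps must be >= 1")
    if gxy_ratio < 0:
        raise ValueError("gxy_ratio must be >= 0")

    rng = substream(seed, "phenotypes")
    X = genotypes.dosage
    polymorphic = np.flatnonzero(np.nanstd(X, axis=0) > 0)
    if polymorphic.size < n_qtl:
        raise ValueError("fewer polymorphic markers than requested QTL")
    qtl = np.sort(rng.choice(polymorphic, size=n_qtl, replace=False))
    effects = rng.normal(0.0, 1.0, size=n_qtl)
    gv = np.nan_to_num(X[:, qtl]) @ effects
    v_g = float(np.var(gv))
    if v_g == 0:
        raise ValueError("degenerate genotypes: zero genetic variance")
    v_gy = gxy_ratio * v_g
    v_r = _solve_residual_variance(v_g, v_gy, target_h2, n_years, n_reps)

    n = genotypes.n_lines
    year_effects = rng.normal(0.0, 2.0 * np.sqrt(v_g), size=n_years)
    gxy = rng.normal(0.0, np.sqrt(v_gy), size=(n, n_years)) if v_gy > 0 else np.zeros((n, n_years))
    records = []
    for j in range(n_years):
        for r in range(n_reps):
            noise = rng.normal(0.0, np.sqrt(v_r), size=n) if v_r > 0 else np.zeros(n)
            vals = gv + year_effects[j] + gxy[:, j] + noise
            records.append(
                pd.DataFrame(
                    {
                        "line_id": genotypes.line_ids,
                        "year": 2011 + j,
                        "replicate": r + 1,
                        "trait": trait,
                        "value": vals,
                    }
                )
            )
    table = pd.concat(records, ignore_index=True)[list(PHENOTYPE_COLUMNS)]
    truth = SimTruth(
        qtl_indices=qtl,
        qtl_effects=effects,
        target_h2=target_h2,
        gxy_variance_ratio=gxy_ratio,
        v_g=v_g,
        v_gy=v_gy,
        v_r=v_r,
        n_years=n_years,
        n_reps=n_reps,
        genotypic_values=gv,
    )
    return table, truth


def simulate_metabolites(
    genotypes: GenotypeMatrix,
    n_metabolites: int = 128,
    h2_snp_mean: float = 0.10,
    h2_snp_max: float = 0.50,
    missing_rate: float = 0.05,
    trait_truth: SimTruth | None = None,
    shared_qtl_fraction: float = 0.5,
    seed: int = 0,
    n_qtl_per_metabolite: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metabolite intensities with low genomic heritability and MCAR gaps.

    Per metabolite, a target genomic heritability is drawn from a Beta
    distribution with mean `h2_snp_mean`, truncated at `h2_snp_max` (matching
    the observed pattern that most metabolites carry little genomic signal and
    the best about half). The metabolite is an additive signal over its own
    small QTL set — a fraction `shared_qtl_fraction` drawn from the trait's
    QTL when `trait_truth` is given — plus Gaussian noise sized so the
    variance ratio hits the target, mapped to a positive intensity scale.

    Returns (intensity table indexed by line id, per-metabolite truth table).
    """
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0, 1)")
    if not (0 <= shared_qtl_fraction <= 1):
        raise ValueError("shared_qtl_fraction must lie in [0, 1]")
    if h2_snp_max < h2_snp_mean:
        raise ValueError("h2_snp_max must be >= h2_snp_mean")
    if not (0 < h2_snp_mean < 1) or h2_snp_max > 1:
        raise ValueError("heritability parameters must lie in (0, 1)")

    rng = substream(seed, "metabolites")
    X = np.nan_to_num(genotypes.dosage)
    polymorphic = np.flatnonzero(X.std(axis=0) > 0)
    beta_b = (1.0 - h2_snp_mean) / h2_snp_mean
    trait_qtl = (
        np.asarray(trait_truth.qtl_indices) if trait_truth is not None else np.empty(0, dtype=int)
    )
    if trait_qtl.size and trait_qtl.max() >= genotypes.n_markers:
        raise ValueError("trait_truth QTL indices exceed the genotype marker count")
    n_shared = int(round(shared_qtl_fraction * n_qtl_per_metabolite)) if trait_qtl.size else 0
    n_shared = min(n_shared, trait_qtl.size)

    n = genotypes.n_lines
    intensities = np.empty((n, n_metabolites))
    truth_rows = []
    for j in range(n_metabolites):
        h2_j = min(float(rng.beta(1.0, beta_b)), h2_snp_max)
        shared = rng.choice(trait_qtl, size=n_shared, replace=False) if n_shared else []
        own_pool = np.setdiff1d(polymorphic, shared)
        own = rng.choice(own_pool, size=n_qtl_per_metabolite - n_shared, replace=False)
        qtl = np.concatenate([np.asarray(shared, dtype=int), own])
        effects = rng.normal(0.0, 1.0, size=qtl.size)
        g = X[:, qtl] @ effects
        sd_g = g.std()
        if sd_g > 0 and h2_j > 0:
            g = (g - g.mean()) / sd_g * np.sqrt(h2_j)
        else:
            g = np.zeros(n)
            h2_j = 0.0
        e = rng.normal(0.0, np.sqrt(max(1.0 - h2_j, 0.0)), size=n)
        # positive intensity scale: mean 100, unit-variance signal scaled by 10
        intensities[:, j] = 100.0 + 10.0 * (g + e)
        truth_rows.append((f"MET{j + 1:03d}", h2_j, int(n_shared), qtl))

    table = pd.DataFrame(
        intensities,
        index=pd.Index(genotypes.line_ids, name="line_id"),
        columns=[r[0] for r in truth_rows],
    )
    if missing_rate > 0:
        mask = rng.random(table.shape) < missing_rate
        table = table.mask(mask)
    truth = pd.DataFrame(
        {
            "metabolite_id": [r[0] for r in truth_rows],
            "h2_snp_target": [r[1] for r in truth_rows],
            "n_shared_qtl": [r[2] for r in truth_rows],
            "qtl_indices": [r[3].tolist() for r in truth_rows],
        }
    )
    return table, truth
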