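"""Phenotype modelling: variance components, heritability, BLUEs.

The plot-level model is  value = mu + year_j + genotype_i + (gxy)_ij + e_ijk
with genotype, genotype-by-year and error random (year fixed, so year means
cancel). Because both random terms are genotype-specific, the marginal
covariance is block-diagonal by genotype; REML exploits this and never forms
the full N x N covariance. On balanced designs the REML solution coincides
with the classical ANOVA method-of-moments estimators, which serve as the
independent oracle in the test-suite.

Broad-sense heritability on an entry-mean basis:

    h2 = V_G / (V_G + V_GY / y + V_R / (y r))

with y years and r replicates. Repeatability is V_G / (V_G + V_R / r).

Genomic (SNP-based) heritability of a single-value-per-line trait is the
variance captured jointly by additive, dominance and additive-by-additive
epistasis genomic kernels:

    h2_SNP = (s2_A + s2_D + s2_I) / (s2_A + s2_D + s2_I + s2_R)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .containers import GenotypeMatrix, validate_phenotype_table

__all__ = [
    "VarianceComponents",
    "GenomicVarianceComponents",
    "TraitBLUEs",
    "estimate_variance_components",
    "broad_sense_heritability",
    "compute_blues",
    "repeatability",
    "genomic_kernels",
    "genomic_heritability",
    "genomic_heritability_batch",
]


@dataclass
class VarianceComponents:
    """REML estimates of the phenotypic variance decomposition."""

    v_g: float
    v_gy: float
    v_r: float
    n_years: int
    n_reps: float  # harmonic-mean replicates on unbalanced designs

    def __post_init__(self) -> None:
        if min(self.v_g, self.v_gy, self.v_r) < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class GenomicVarianceComponents:
    """Multi-kernel genomic variance decomposition of a line-level trait."""

    sigma2_a: float
    sigma2_d: float
    sigma2_i: float
    sigma2_r: float

    @property
    def h2_snp(self) -> float:
        genetic = self.sigma2_a + self.sigma2_d + self.sigma2_i
        total = genetic + self.sigma2_r
        if total <= 0:
            raise ValueError("all variance components are zero; h2 undefined")
        return genetic / total


@dataclass
class TraitBLUEs:
    """One adjusted entry mean (BLUE) per line for a trait."""

    values: pd.Series  # index: line_id
    trait: str
    h2: float | None = None


# ---------------------------------------------------------------------------
# REML for the plot-level model
# ---------------------------------------------------------------------------


def _line_blocks(table: pd.DataFrame) -> tuple[list, np.ndarray, list[str]]:
    """Group plot records by line: (per-line (y, year-codes) pairs, years)."""
    years = np.sort(table["year"].unique())
    year_code = {y: i for i, y in enumerate(years)}
    blocks = []
    for line, sub in table.groupby("line_id", sort=True):
        y = sub["value"].to_numpy(dtype=float)
        yc = sub["year"].map(year_code).to_numpy()
        order = np.argsort(yc, kind="stable")  # canonical order: replicates exchangeable
        blocks.append((line, y[order], yc[order]))
    return blocks, years, [b[0] for b in blocks]


def _block_design(yc: np.ndarray, n_years: int) -> np.ndarray:
    k = yc.size
    X = np.zeros((k, 1 + n_years - 1))
    X[:, 0] = 1.0
    for j in range(1, n_years):
        X[:, j] = (yc == j).astype(float)
    return X


def _neg2_restricted_ll(
    log_var: np.ndarray, blocks: list, n_years: int, uniform: tuple | None,
    floor: float = 0.0,
) -> float:
    """-2 x restricted log-likelihood (up to a constant) of (V_G, V_GY, V_R).

    `uniform` carries (Y, yc0, X_block) when every line shares the same
    (year, replicate) layout: the block covariance is then identical across
    lines and factorized once. `floor` is a small additive lower bound that
    keeps the covariance full-rank on degenerate (noise-free) data, where the
    unbounded likelihood would otherwise let the other components drift.
    """
    v_g, v_gy, v_r = floor + np.exp(np.clip(log_var, -30.0, 30.0))
    p = 1 + (n_years - 1)  # intercept + year contrasts
    if uniform is not None:
        Y, yc0, Xb = uniform  # Y: n x k stacked responses
        n, k = Y.shape
        same_year = (yc0[:, None] == yc0[None, :]).astype(float)
        V = v_g + v_gy * same_year + v_r * np.eye(k)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e30
        logdet = n * 2.0 * np.log(np.diag(L)).sum()
        Xs = np.linalg.solve(L, Xb)
        Ys = np.linalg.solve(L, Y.T)  # k x n
        xtvx = n * (Xs.T @ Xs)
        xtvy = Xs.T @ Ys.sum(axis=1)
        ytvy = float(np.sum(Ys * Ys))
    else:
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet = 0.0
        for _, y, yc in blocks:
            k = y.size
            same_year = (yc[:, None] == yc[None, :]).astype(float)
            V = v_g + v_gy * same_year + v_r * np.eye(k)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e30
            logdet += 2.0 * np.log(np.diag(L)).sum()
            A = np.linalg.solve(L, np.column_stack([_block_design(yc, n_years), y]))
            Xs, ys = A[:, :-1], A[:, -1]
            xtvx += Xs.T @ Xs
            xtvy += Xs.T @ ys
            ytvy += ys @ ys
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return 1e30
    beta = np.linalg.solve(xtvx, xtvy)
    ypy = ytvy - xtvy @ beta
    return logdet + logdet_x + ypy


def _anova_moments(blocks: list, n_years: int) -> tuple[float, float, float] | None:
    """Balanced two-way ANOVA method-of-moments start values (or None)."""
    reps = {tuple(sorted(yc.tolist())) for _, _, yc in blocks}
    if len(reps) != 1:
        return None
    yc0 = blocks[0][2]
    counts = np.bincount(yc0, minlength=n_years)
    if counts.min() == 0 or counts.min() != counts.max():
        return None
    r = int(counts[0])
    n = len(blocks)
    y_all = np.stack([b[1] for b in blocks])  # n x (years*reps), arbitrary cell order
    yc = blocks[0][2]
    cell_means = np.stack(
        [y_all[:, yc == j].mean(axis=1) for j in range(n_years)], axis=1
    )  # n x years
    line_means = cell_means.mean(axis=1)
    year_means = cell_means.mean(axis=0)
    grand = line_means.mean()
    ms_g = n_years * r * np.sum((line_means - grand) ** 2) / max(n - 1, 1)
    inter = cell_means - line_means[:, None] - year_means[None, :] + grand
    ms_gy = r * np.sum(inter**2) / max((n - 1) * (n_years - 1), 1)
    if r > 1:
        within = 0.0
        for j in range(n_years):
            cells = y_all[:, yc == j]
            within += np.sum((cells - cells.mean(axis=1, keepdims=True)) ** 2)
        ms_e = within / (n * n_years * (r - 1))
    else:
        ms_e = None
    if ms_e is None:
        return None
    v_r = ms_e
    v_gy = max((ms_gy - ms_e) / r, 0.0)
    v_g = max((ms_g - ms_gy) / (n_years * r), 0.0)
    return v_g, v_gy, v_r


def estimate_variance_components(table: pd.DataFrame, trait: str) -> VarianceComponents:
    """REML estimates of V_G, V_GY and V_R for one trait.

    Requires >= 2 years, >= 2 lines, and replicated plots somewhere in the
    design (with a single replicate everywhere, V_GY and V_R are confounded).
    Estimates are truncated at zero.
    """
    validate_phenotype_table(table)
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    blocks, years, _ = _line_blocks(sub)
    n_years = len(years)
    if n_years < 2:
        raise ValueError("need >= 2 years to separate V_GY from V_G")
    if len(blocks) < 2:
        raise ValueError("need >= 2 lines")
    max_reps = max(np.bincount(yc).max() for _, _, yc in blocks)
    if max_reps < 2:
        raise ValueError("V_R inestimable: no replicated (line, year) cells in the design")

    yc0 = blocks[0][2]
    uniform = None
    if all(np.array_equal(b[2], yc0) for b in blocks):
        Y = np.stack([b[1] for b in blocks])
        uniform = (Y, yc0, _block_design(yc0, n_years))

    var_y = float(np.var(np.concatenate([b[1] for b in blocks])))
    start_sets = []
    mom = _anova_moments(blocks, n_years)
    if mom is not None:
        start_sets.append(np.log(np.maximum(mom, 1e-8 * max(var_y, 1.0))))
    third = max(var_y / 3.0, 1e-8)
    start_sets.append(np.log([third, third, third]))
    start_sets.append(np.log([var_y * 0.8 + 1e-8, var_y * 0.05 + 1e-8, var_y * 0.15 + 1e-8]))

    best, best_val = None, np.inf
    for x0 in start_sets:
        res = optimize.minimize(
            _neg2_restricted_ll,
            x0,
            args=(blocks, n_years, uniform, 1e-8 * max(var_y, 1e-12)),
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 4000},
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    v_g, v_gy, v_r = np.exp(best)
    tiny = 1e-6 * max(var_y, 1.0)
    reps = np.concatenate([np.bincount(yc, minlength=n_years) for _, _, yc in blocks])
    reps = reps[reps > 0]
    harmonic_r = reps.size / np.sum(1.0 / reps)
    return VarianceComponents(
        v_g=0.0 if v_g < tiny else float(v_g),
        v_gy=0.0 if v_gy < tiny else float(v_gy),
        v_r=0.0 if v_r < tiny else float(v_r),
        n_years=n_years,
        n_reps=float(harmonic_r),
    )


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability h2 = V_G/(V_G + V_GY/y + V_R/(y r))."""
    if vc.n_years < 1 or vc.n_reps < 1:
        raise ValueError("n_years and n_reps must be >= 1")
    denom = vc.v_g + vc.v_gy / vc.n_years + vc.v_r / (vc.n_years * vc.n_reps)
    if denom <= 0:
        raise ValueError("all variance components zero; heritability undefined")
    return vc.v_g / denom


def repeatability(v_g: float, v_r: float, r: int) -> float:
    """Repeatability V_G/(V_G + V_R/r) of r repeated measurements."""
    if r < 1:
        raise ValueError("r must be >= 1")
    denom = v_g + v_r / r
    if denom <= 0:
        raise ValueError("zero denominator; repeatability undefined")
    return v_g / denom


# ---------------------------------------------------------------------------
# BLUEs
# ---------------------------------------------------------------------------


def compute_blues(
    table: pd.DataFrame, trait: str, year_effect: str = "fixed", h2: float | None = None
) -> TraitBLUEs:
    """Best linear unbiased estimates per line, adjusted for year effects.

    Fits value = mu + genotype (fixed) + year + error via sparse normal
    equations. `year_effect` is "fixed" (default), "random" (year ridge with a
    moments-estimated variance ratio) or "none". The BLUE reported for each
    line is its expected value averaged over the observed years, so values
    are comparable across lines whatever the year coding.
    """
    validate_phenotype_table(table)
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    lines = np.sort(sub["line_id"].unique())
    line_idx = {l: i for i, l in enumerate(lines)}
    years = np.sort(sub["year"].unique())
    year_idx = {y: i for i, y in enumerate(years)}
    n_obs, n_lines, n_years = len(sub), len(lines), len(years)

    li = sub["line_id"].map(line_idx).to_numpy()
    yi = sub["year"].map(year_idx).to_numpy()
    y = sub["value"].to_numpy(dtype=float)

    use_year = year_effect in ("fixed", "random") and n_years > 1
    # columns: lines, then (years - reference) when fixed, or all years when random
    if not use_year:
        Z = sparse.csr_matrix(
            (np.ones(n_obs), (np.arange(n_obs), li)), shape=(n_obs, n_lines)
        )
        beta, *_ = np.linalg.lstsq((Z.T @ Z).toarray(), Z.T @ y, rcond=None)
        values = pd.Series(beta, index=pd.Index(lines, name="line_id"))
        return TraitBLUEs(values=values, trait=trait, h2=h2)

    if year_effect == "fixed":
        keep = yi > 0  # first year is the reference level
        cols = np.concatenate([li, n_lines + yi[keep] - 1])
        rows = np.concatenate([np.arange(n_obs), np.flatnonzero(keep)])
        X = sparse.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n_obs, n_lines + n_years - 1)
        )
        xtx = (X.T @ X).toarray()
        beta, *_ = np.linalg.lstsq(xtx, X.T @ y, rcond=None)
        year_eff = np.concatenate([[0.0], beta[n_lines:]])
        blues = beta[:n_lines] + year_eff.mean()
    else:  # random year: Henderson MME with a moments ratio
        year_means = np.array([y[yi == j].mean() for j in range(n_years)])
        s2_year = max(np.var(year_means, ddof=1), 1e-12)
        s2_res = max(np.var(y - year_means[yi], ddof=1), 1e-12)
        k = s2_res / s2_year
        cols = np.concatenate([li, n_lines + yi])
        rows = np.concatenate([np.arange(n_obs), np.arange(n_obs)])
        X = sparse.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n_obs, n_lines + n_years)
        )
        lhs = (X.T @ X).toarray()
        lhs[n_lines:, n_lines:] += k * np.eye(n_years)
        beta = np.linalg.solve(lhs, X.T @ y)
        blues = beta[:n_lines] + beta[n_lines:].mean()

    values = pd.Series(blues, index=pd.Index(lines, name="line_id"))
    return TraitBLUEs(values=values, trait=trait, h2=h2)


# ---------------------------------------------------------------------------
# Genomic heritability (multi-kernel REML)
# ---------------------------------------------------------------------------


def genomic_kernels(
    g: GenotypeMatrix, which: tuple[str, ...] = ("additive", "dominance", "epistasis")
) -> dict[str, np.ndarray]:
    """Genomic relationship kernels from a dosage matrix.

    additive  : centered dosages, K = Xc Xc' scaled to mean diagonal 1
    dominance : centered heterozygosity indicators, scaled likewise
    epistasis : element-wise square of the additive kernel (additive x
                additive interactions under the Hadamard construction)
    """
    kernels: dict[str, np.ndarray] = {}
    X = np.nan_to_num(g.dosage)
    if "additive" in which or "epistasis" in which:
        Xc = X - X.mean(axis=0)
        K = Xc @ Xc.T
        d = np.trace(K) / K.shape[0]
        K = K / d if d > 0 else K
        if "additive" in which:
            kernels["additive"] = K
        if "epistasis" in which:
            kernels["epistasis"] = K * K
    if "dominance" in which:
        H = (X == 1).astype(float)
        Hc = H - H.mean(axis=0)
        KD = Hc @ Hc.T
        d = np.trace(KD) / KD.shape[0]
        kernels["dominance"] = KD / d if d > 0 else KD
    return kernels


def _neg2_reml_kernels(log_var: np.ndarray, Ks: list[np.ndarray], y: np.ndarray) -> float:
    v = np.exp(np.clip(log_var, -30.0, 30.0))
    n = y.size
    V = v[-1] * np.eye(n)
    for s, K in zip(v[:-1], Ks):
        V += s * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e30
    logdet = 2.0 * np.log(np.diag(L)).sum()
    A = np.linalg.solve(L, np.column_stack([np.ones(n), y]))
    one_s, ys = A[:, 0], A[:, 1]
    xtvx = one_s @ one_s
    if xtvx <= 0:
        return 1e30
    ypy = ys @ ys - (one_s @ ys) ** 2 / xtvx
    return logdet + np.log(xtvx) + ypy


def genomic_heritability(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    kernels: tuple[str, ...] = ("additive", "dominance", "epistasis"),
) -> GenomicVarianceComponents:
    """Multi-kernel REML estimate of SNP-based heritability of a line trait.

    Fits y = mu + u_A + u_D + u_I + e with u_k ~ N(0, s2_k K_k) and returns
    the components; `GenomicVarianceComponents.h2_snp` gives the ratio. When a
    trait is aligned by line id (pandas Series), lines are matched to `g`.
    """
    if isinstance(y, pd.Series):
        idx = pd.Index(g.line_ids)
        missing = y.index.difference(idx)
        if len(missing):
            raise ValueError(f"trait lines not in genotype matrix: {list(missing[:5])}")
        order = idx.get_indexer(y.index)
        g = g.select_lines(order)
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size != g.n_lines:
        raise ValueError("y length does not match genotype lines")

    Kd = genomic_kernels(g, which=kernels)
    Ks = [Kd[k] for k in kernels if k in Kd]
    var_y = max(float(np.var(y)), 1e-12)
    p = len(Ks) + 1
    starts = [
        np.log(np.full(p, var_y / p)),
        np.log(np.concatenate([np.full(p - 1, 0.05 * var_y), [0.9 * var_y]])),
        np.log(np.concatenate([np.full(p - 1, 0.3 * var_y), [0.3 * var_y]])),
    ]
    best, best_val = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            _neg2_reml_kernels,
            x0,
            args=(Ks, y),
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 6000},
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    if best is None or best_val >= 1e30:
        raise np.linalg.LinAlgError(
            "singular kernel system; consider dropping the epistasis kernel"
        )
    v = np.exp(best)
    tiny = 1e-6 * var_y
    v = np.where(v < tiny, 0.0, v)
    comp = dict.fromkeys(("additive", "dominance", "epistasis"), 0.0)
    for name, s in zip([k for k in kernels if k in Kd], v[:-1]):
        comp[name] = float(s)
    return GenomicVarianceComponents(
        sigma2_a=comp["additive"],
        sigma2_d=comp["dominance"],
        sigma2_i=comp["epistasis"],
        sigma2_r=float(v[-1]),
    )


def genomic_heritability_batch(Y: pd.DataFrame | np.ndarray, K: np.ndarray) -> np.ndarray:
    """Additive-kernel heritability for many traits sharing one kernel.

    Eigendecomposes K once and profiles each column's REML likelihood over the
    genetic-to-residual variance ratio (1-D bounded search), which makes
    scanning a full metabolite panel cheap. Returns h2 per column.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = K.shape[0]
    if Y.shape[0] != n:
        raise ValueError("rows of Y must match kernel dimension")
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    ones_r = U.T @ np.ones(n)
    Yr = U.T @ Y

    def neg2(log_ratio: float, yr: np.ndarray) -> float:
        ratio = np.exp(log_ratio)  # s2_g / s2_e
        d = ratio * lam + 1.0
        xtvx = np.sum(ones_r**2 / d)
        xtvy = np.sum(ones_r * yr / d)
        ypy = np.sum(yr**2 / d) - xtvy**2 / xtvx
        # profile out s2_e: REML scale estimate
        s2e = ypy / (n - 1)
        if s2e <= 0 or xtvx <= 0:
            return 1e30
        return np.sum(np.log(d)) + np.log(xtvx) + (n - 1) * np.log(s2e)

    h2 = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        yr = Yr[:, j]
        res = optimize.minimize_scalar(
            neg2, args=(yr,), bounds=(-12.0, 12.0), method="bounded",
            options={"xatol": 1e-8},
        )
        ratio = float(np.exp(res.x))
        mean_lam = lam.mean()
        h2[j] = ratio * mean_lam / (ratio * mean_lam + 1.0)
    return h2
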