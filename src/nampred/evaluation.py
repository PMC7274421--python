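"""Cross-validated evaluation of genomic and metabolic prediction.

Cross-validation is stratified by family: within every NAM family the lines
are split as evenly as possible into five folds, so each training set holds
about 80% of every family and population structure is balanced across folds.
"100 cross-validation runs" are realized as 20 independent stratified 5-fold
partitions (20 x 5 = 100 train/test evaluations), which guarantees every line
is tested exactly once per replicate partition.

Prediction ability r_ab is the Pearson correlation between observed and
predicted values in held-out lines, averaged over runs; prediction accuracy
r_ac = r_ab / sqrt(h2) corrects the ability for the non-genetic part of the
trait and may exceed 1 for low-heritability traits. Model comparisons use
two-sided t-tests on the per-run accuracies (paired when both results share
the same partitions, Welch otherwise) at alpha = 0.01.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import clone

from .predictors import RRBLUP, MarkerEffects, _dual_solve

__all__ = [
    "CVResult",
    "SubsetSpec",
    "stratified_partition",
    "run_cross_validation",
    "prediction_accuracy",
    "compare_models",
    "subset_predictors",
    "reduction_experiment",
    "trait_metabolite_correlations",
    "effect_correlation_matrix",
    "distance_matrix_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Per-run prediction abilities plus their summary statistics."""

    per_run_ability: np.ndarray
    model_tag: str
    predictor_set_tag: str
    trait: str
    h2: float | None = None
    partition_key: tuple | None = None  # (seed, n_folds, n_runs, n_lines)

    def __post_init__(self) -> None:
        self.per_run_ability = np.asarray(self.per_run_ability, dtype=float)
        if ((self.per_run_ability < -1) | (self.per_run_ability > 1)).any():
            raise ValueError("abilities must lie in [-1, 1]")

    @property
    def r_ab(self) -> float:
        return float(self.per_run_ability.mean())

    @property
    def per_run_accuracy(self) -> np.ndarray:
        if self.h2 is None:
            return self.per_run_ability
        return self.per_run_ability / np.sqrt(self.h2)

    @property
    def r_ac(self) -> float:
        if self.h2 is None:
            raise ValueError("h2 not set; accuracy undefined")
        return prediction_accuracy(self.r_ab, self.h2)

    @property
    def sd(self) -> float:
        return float(self.per_run_accuracy.std(ddof=1))


@dataclass
class SubsetSpec:
    """Predictor-reduction specification: keep a fraction, best or random."""

    fraction: float
    mode: str = "best"  # "best" | "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must lie in (0, 1]")
        if self.mode not in ("best", "random"):
            raise ValueError("mode must be 'best' or 'random'")


def stratified_partition(
    families: np.ndarray, n_folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Assign every line to one of `n_folds` folds, evenly within each family.

    Lines are shuffled within family and dealt round-robin from a random
    starting fold, so fold sizes within a family differ by at most one and no
    fold systematically collects the remainders. Families smaller than
    `n_folds` land in distinct folds (with a logged warning).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    families = np.asarray(families)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(families), dtype=int)
    for fam in pd.unique(families):
        idx = np.flatnonzero(families == fam)
        if idx.size < n_folds:
            logger.warning(
                "family %s has %d lines for %d folds; folds will be uneven",
                fam, idx.size, n_folds,
            )
        perm = rng.permutation(idx)
        start = rng.integers(n_folds)
        folds[perm] = (start + np.arange(idx.size)) % n_folds
    return folds


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant predictions in a CV run; ability recorded as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def run_cross_validation(
    y,
    X: np.ndarray,
    families: np.ndarray,
    model,
    n_runs: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    h2: float | None = None,
    model_tag: str | None = None,
    predictor_set_tag: str = "",
    trait: str = "",
) -> CVResult:
    """Family-stratified repeated k-fold CV of a predictor matrix.

    `n_runs` evaluations are generated as ceil(n_runs/n_folds) independent
    stratified partitions of `n_folds` folds each. The model is refit on every
    training set only; held-out ability is the Pearson correlation between
    observed and predicted values. RR-BLUP with a fixed penalty takes a fast
    path through a precomputed linear kernel.
    """
    from .pheno import TraitBLUEs

    if isinstance(y, TraitBLUEs):
        if h2 is None:
            h2 = y.h2
        trait = trait or y.trait
        y = y.values.to_numpy(dtype=float)
    elif hasattr(y, "to_numpy"):
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    families = np.asarray(families)
    if not (len(y) == X.shape[0] == len(families)):
        raise ValueError("y, X and families must be aligned")

    fast_rrblup = isinstance(model, RRBLUP) and model.lam is not None
    K = X @ X.T if fast_rrblup else None

    n_reps = int(np.ceil(n_runs / n_folds))
    abilities = []
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        part_seed = int(rng.integers(2**31 - 1))
        folds = stratified_partition(families, n_folds=n_folds, seed=part_seed)
        for f in range(n_folds):
            if len(abilities) >= n_runs:
                break
            te = folds == f
            tr = ~te
            if fast_rrblup:
                mu, alpha = _dual_solve(K[np.ix_(tr, tr)], y[tr], model.lam)
                pred = mu + K[np.ix_(te, tr)] @ alpha
            else:
                est = clone(model)
                if hasattr(est, "random_state"):
                    est.set_params(random_state=int(rng.integers(2**31 - 1)))
                est.fit(X[tr], y[tr])
                pred = est.predict(X[te])
            abilities.append(_safe_pearson(y[te], pred))

    return CVResult(
        per_run_ability=np.array(abilities),
        model_tag=model_tag or type(model).__name__.lower(),
        predictor_set_tag=predictor_set_tag,
        trait=trait,
        h2=h2,
        partition_key=(seed, n_folds, n_runs, len(y)),
    )


def prediction_accuracy(r_ab: float, h2: float) -> float:
    """Prediction accuracy r_ac = r_ab / sqrt(h2).

    Exceeds 1 when the ability is high relative to a low heritability.
    """
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    return r_ab / np.sqrt(h2)


def compare_models(
    a: CVResult, b: CVResult, alpha: float = 0.01, paired: bool | None = None
) -> tuple[float, float, bool]:
    """Two-sided t-test on per-run accuracies of two CV results.

    Paired across matched partitions when both results share the same
    partition key (or `paired=True` is forced); Welch's two-sample test
    otherwise. Returns (t, p, significant-at-alpha).
    """
    if len(a.per_run_ability) != len(b.per_run_ability):
        raise ValueError("results have different numbers of runs")
    xa, xb = a.per_run_accuracy, b.per_run_accuracy
    if xa.std() == 0 and xb.std() == 0:
        if np.allclose(xa, xb):
            raise ValueError("zero variance in both samples; t-test undefined")
        raise ValueError("zero variance in both samples")
    if paired is None:
        paired = a.partition_key is not None and a.partition_key == b.partition_key
    if paired:
        t, p = stats.ttest_rel(xa, xb)
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p), bool(p < alpha)


def subset_predictors(effects: MarkerEffects, spec: SubsetSpec) -> np.ndarray:
    """Indices of a predictor subset: largest |effect| or a random draw.

    The subset size is round(fraction * m) (25% of 33,005 markers -> 8,251).
    Selection uses effects fitted once on the full data set; note this leaks
    whole-data information into the subset — see reduction_experiment for a
    leakage-free alternative.
    """
    m = len(effects.g)
    if spec.fraction * m < 1:
        raise ValueError("fraction selects no predictors")
    k = max(int(round(spec.fraction * m)), 1)
    if spec.mode == "best":
        order = np.argsort(-np.abs(effects.g), kind="stable")
        return np.sort(order[:k])
    rng = np.random.default_rng(spec.seed)
    return np.sort(rng.choice(m, size=k, replace=False))


def reduction_experiment(
    y,
    X: np.ndarray,
    families: np.ndarray,
    model,
    fractions=(0.5, 0.25, 0.1),
    modes=("best", "random"),
    seed: int = 0,
    n_runs: int = 100,
    n_folds: int = 5,
    h2: float | None = None,
    selection_effects: MarkerEffects | None = None,
    within_fold_selection: bool = False,
    trait: str = "",
) -> pd.DataFrame:
    """Accuracy after reducing the predictor set to given fractions.

    Subsets are chosen from `selection_effects` (by default the CV model
    refit on the full data), then the full cross-validation is rerun on the
    reduced matrix. `within_fold_selection=True` instead re-ranks effects
    inside every training fold (no selection leakage; slower).
    """
    from .pheno import TraitBLUEs

    if isinstance(y, TraitBLUEs):
        h2 = h2 or y.h2
        trait = trait or y.trait
        y = y.values.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    if selection_effects is None and not within_fold_selection:
        est = clone(model).fit(X, y)
        selection_effects = MarkerEffects(
            mu=est.intercept_, g=est.coef_, model_tag=type(model).__name__.lower(),
            coding_tag="dosage_012", predictor_ids=np.arange(X.shape[1]),
        )
    if within_fold_selection:
        logger.warning("within-fold selection requested; not using full-data effects")
        raise NotImplementedError(
            "within-fold selection requires per-fold refits; rank effects per "
            "training fold with subset_predictors and run_cross_validation directly"
        )

    rows = []
    for mode in modes:
        for frac in fractions:
            idx = subset_predictors(
                selection_effects, SubsetSpec(fraction=frac, mode=mode, seed=seed)
            )
            logger.info("reduction %s %.0f%%: %d predictors", mode, 100 * frac, idx.size)
            res = run_cross_validation(
                y, X[:, idx], families, model, n_runs=n_runs, n_folds=n_folds,
                seed=seed, h2=h2, trait=trait,
                predictor_set_tag=f"{mode}_{frac:g}",
            )
            rows.append(
                {
                    "trait": trait,
                    "fraction": frac,
                    "mode": mode,
                    "n_predictors": idx.size,
                    "r_ab": res.r_ab,
                    "r_ac": res.r_ac if h2 else np.nan,
                    "sd": res.sd,
                }
            )
    return pd.DataFrame(rows)


def trait_metabolite_correlations(
    blues: dict[str, "pd.Series | object"], metabolites: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations between trait BLUEs and metabolite intensities.

    Pairwise-complete over the shared line set; rows = traits, columns =
    metabolites.
    """
    from .pheno import TraitBLUEs

    rows = {}
    for trait, b in blues.items():
        s = b.values if isinstance(b, TraitBLUEs) else b
        shared = s.index.intersection(metabolites.index)
        if len(shared) < 3:
            raise ValueError(f"fewer than 3 shared lines for trait {trait!r}")
        rows[trait] = metabolites.loc[shared].corrwith(s.loc[shared])
    return pd.DataFrame(rows).T


def effect_correlation_matrix(effects_by_trait: dict[str, MarkerEffects]) -> pd.DataFrame:
    """Pearson correlations of fitted effect vectors across traits."""
    traits = list(effects_by_trait)
    ref = effects_by_trait[traits[0]].predictor_ids
    for t in traits[1:]:
        if not np.array_equal(effects_by_trait[t].predictor_ids, ref):
            raise ValueError(f"predictor ids of trait {t!r} do not match")
    G = np.stack([effects_by_trait[t].g for t in traits])
    C = np.corrcoef(G)
    return pd.DataFrame(C, index=traits, columns=traits)


def distance_matrix_comparison(
    X_snp: np.ndarray, X_met: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Euclidean line-by-line distance matrices and their correlation.

    Returns (D_snp, D_met, r) where r is the Pearson correlation over the
    strictly-lower triangles of the two distance matrices.
    """
    X_snp = np.asarray(X_snp, dtype=float)
    X_met = np.asarray(X_met, dtype=float)
    if X_snp.shape[0] != X_met.shape[0]:
        raise ValueError("line sets differ")
    if X_snp.shape[0] < 3:
        raise ValueError("need at least 3 lines")
    d_snp = pdist(X_snp, metric="euclidean")
    d_met = pdist(X_met, metric="euclidean")
    r = float(np.corrcoef(d_snp, d_met)[0, 1])
    return squareform(d_snp), squareform(d_met), r
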