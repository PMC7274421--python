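"""Whole-genome regression: RR-BLUP and BayesB, written from scratch.

Both models share the linear form

    y = 1_n mu + X g + e

over n lines and m predictors (SNP dosages, metabolite intensities, or both).

RR-BLUP places a common normal prior g ~ N(0, s2_g I) and solves Henderson's
mixed-model equations with ridge penalty lambda = s2_e / s2_g. The paper-style
plug-in is lambda = (s2_R / l) / (s2_G / m) with s2_G, s2_R from the
phenotypic mixed model and l the number of trial years. The solver switches
between the primal (m+1 normal equations) and the dual/GBLUP form
g = X' (XX' + lambda I)^-1 (y - 1 mu), which are algebraically identical; the
test-suite asserts agreement to 1e-8.

BayesB is the spike-and-slab variant: each effect is exactly zero with
probability pi, otherwise drawn from N(0, s2_gi) with a scaled inverse
chi-squared prior on its own variance; pi gets a beta prior, mu a flat prior,
and the residual variance a scaled inverse chi-squared prior. All parameters
are sampled by Gibbs. The indicator update integrates the effect out
analytically given its variance, and an excluded effect's variance is
refreshed from its prior, which keeps the chain a valid Gibbs sampler on the
joint posterior. The sweep is JIT-compiled with numba when available.

Estimators follow the scikit-learn protocol (fit/predict, coef_, intercept_,
get_params), so they compose with sklearn model selection and pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "MarkerEffects",
    "rrblup_lambda",
    "RRBLUP",
    "BayesB",
    "fit_rrblup",
    "fit_bayesb",
    "predict_values",
    "combine_predictors",
]


@dataclass
class MarkerEffects:
    """Fitted intercept and per-predictor effects with model metadata."""

    mu: float
    g: np.ndarray
    model_tag: str  # "rr_blup" | "bayes_b"
    coding_tag: str
    predictor_ids: np.ndarray
    inclusion_prob: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.predictor_ids = np.asarray(self.predictor_ids, dtype=object)
        if len(self.g) != len(self.predictor_ids):
            raise ValueError("effect vector and predictor ids disagree in length")
        if not np.isfinite(self.g).all() or not np.isfinite(self.mu):
            raise ValueError("non-finite fitted effects")


def rrblup_lambda(sigma2_G: float, sigma2_R: float, m: int, l: int) -> float:
    """Ridge penalty lambda = (s2_R / l) / (s2_G / m).

    s2_G and s2_R are the genotypic and residual variance components from the
    phenotypic mixed model, m the number of predictors, l the number of years.
    """
    if sigma2_G <= 0:
        raise ValueError("sigma2_G must be positive; lambda undefined")
    if sigma2_R <= 0 or m < 1 or l < 1:
        raise ValueError("sigma2_R, m and l must be positive")
    return (sigma2_R / l) / (sigma2_G / m)


# ---------------------------------------------------------------------------
# RR-BLUP
# ---------------------------------------------------------------------------


class RRBLUP(RegressorMixin, BaseEstimator):
    """Ridge-regression BLUP of predictor effects with unpenalized intercept.

    Parameters
    ----------
    lam : float or None
        Ridge penalty. If None, it is estimated by REML on the training data
        (spectral parametrization of the ridge ratio).
    method : {"auto", "primal", "dual"}
        "primal" solves the (m+1) mixed-model equations, "dual" the n x n
        kernel system; "auto" picks whichever is smaller.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (m,)
    lam_ : float — the penalty actually used.
    """

    def __init__(self, lam: float | None = 1.0, method: str = "auto"):
        self.lam = lam
        self.method = method

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, m = X.shape
        lam = self.lam if self.lam is not None else self._reml_lambda(X, y)
        if lam <= 0:
            raise ValueError("lam must be positive")
        method = self.method
        if method == "auto":
            method = "primal" if m <= n else "dual"
        if method == "primal":
            C = np.empty((m + 1, m + 1))
            C[0, 0] = n
            C[0, 1:] = X.sum(axis=0)
            C[1:, 0] = C[0, 1:]
            C[1:, 1:] = X.T @ X + lam * np.eye(m)
            rhs = np.concatenate([[y.sum()], X.T @ y])
            sol = np.linalg.solve(C, rhs)
            self.intercept_, self.coef_ = float(sol[0]), sol[1:]
        elif method == "dual":
            K = X @ X.T
            mu, alpha = _dual_solve(K, y, lam)
            self.intercept_, self.coef_ = mu, X.T @ alpha
        else:
            raise ValueError(f"unknown method {method!r}")
        self.lam_ = float(lam)
        self.n_features_in_ = m
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_

    @staticmethod
    def _reml_lambda(X: np.ndarray, y: np.ndarray) -> float:
        """REML ridge ratio via eigendecomposition of the linear kernel."""
        from scipy import optimize

        n = X.shape[0]
        K = X @ X.T
        lam_k, U = np.linalg.eigh(K)
        lam_k = np.clip(lam_k, 0.0, None)
        ones_r = U.T @ np.ones(n)
        yr = U.T @ y

        def neg2(log_inv_lam: float) -> float:
            d = np.exp(log_inv_lam) * lam_k + 1.0
            xtvx = np.sum(ones_r**2 / d)
            xtvy = np.sum(ones_r * yr / d)
            ypy = np.sum(yr**2 / d) - xtvy**2 / xtvx
            s2e = ypy / (n - 1)
            if s2e <= 0 or xtvx <= 0:
                return 1e30
            return np.sum(np.log(d)) + np.log(xtvx) + (n - 1) * np.log(s2e)

        res = optimize.minimize_scalar(neg2, bounds=(-16.0, 16.0), method="bounded")
        return float(np.exp(-res.x))


def _dual_solve(K: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Solve the kernel form: returns (mu, alpha) with g = X' alpha.

    H = (K + lam I)^-1; mu = (1'H y)/(1'H 1); alpha = H (y - 1 mu).
    """
    n = K.shape[0]
    A = K + lam * np.eye(n)
    sol = np.linalg.solve(A, np.column_stack([y, np.ones(n)]))
    hy, h1 = sol[:, 0], sol[:, 1]
    mu = float(np.ones(n) @ hy / (np.ones(n) @ h1))
    alpha = hy - mu * h1
    return mu, alpha


# ---------------------------------------------------------------------------
# BayesB Gibbs sampler
# ---------------------------------------------------------------------------


def _gibbs_bayesb(
    X, y, pi_a, pi_b, pi_fixed, df0, scale0, dfe0, scale_e0,
    n_iter, burn_in, thin, seed,
):
    """One BayesB chain. Returns posterior means over retained sweeps.

    X must already be coded/shifted. The residual vector is updated in place
    after every effect move, so each predictor update costs O(n). Runs under
    numba's nopython mode when numba is installed (see module bottom).
    """
    np.random.seed(seed)
    n, m = X.shape
    xx = np.empty(m)
    for j in range(m):
        xx[j] = X[:, j] @ X[:, j]
    mu = y.mean()
    g = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    s2g = np.full(m, df0 * scale0 / (df0 + 2.0))
    s2e = max(y.var(), 1e-8)
    pi = 0.5 if pi_fixed < 0 else pi_fixed
    e = y - mu  # residual; g starts at zero

    n_keep = 0
    mu_sum = 0.0
    g_sum = np.zeros(m)
    pip_sum = np.zeros(m)
    pi_sum = 0.0
    s2e_sum = 0.0

    for it in range(n_iter):
        # intercept: flat prior, normal full conditional
        mu_new = mu + e.sum() / n + np.random.standard_normal() * np.sqrt(s2e / n)
        e += mu - mu_new
        mu = mu_new

        n_in = 0
        for j in range(m):
            if xx[j] <= 0.0:
                g[j] = 0.0
                delta[j] = 0
                continue
            if g[j] != 0.0:
                e += X[:, j] * g[j]
            rhs = X[:, j] @ e
            c = xx[j] / s2e + 1.0 / s2g[j]
            mean_j = rhs / (s2e * c)
            # log Bayes factor slab vs spike with g integrated out
            log_bf = -0.5 * (np.log(s2g[j]) + np.log(c)) + 0.5 * mean_j * mean_j * c
            if pi >= 1.0:
                p_in = 0.0
            elif pi <= 0.0:
                p_in = 1.0
            else:
                log_odds = log_bf + np.log(1.0 - pi) - np.log(pi)
                if log_odds > 35.0:
                    p_in = 1.0
                elif log_odds < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p_in:
                gj = mean_j + np.random.standard_normal() / np.sqrt(c)
                g[j] = gj
                delta[j] = 1
                e -= X[:, j] * gj
                n_in += 1
            else:
                g[j] = 0.0
                delta[j] = 0
            # per-effect variance: conditional if in the slab, prior draw if not
            if delta[j] == 1:
                s2g[j] = (g[j] * g[j] + df0 * scale0) / np.random.chisquare(df0 + 1.0)
            else:
                s2g[j] = df0 * scale0 / np.random.chisquare(df0)

        if pi_fixed < 0:
            pi = np.random.beta(pi_a + (m - n_in), pi_b + n_in)
        s2e = (e @ e + dfe0 * scale_e0) / np.random.chisquare(dfe0 + n)
        if not np.isfinite(s2e) or s2e > 1e12:
            raise ValueError(
                "residual variance diverged; standardize predictors/response"
            )

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
            mu_sum += mu
            g_sum += g
            pip_sum += delta
            pi_sum += pi
            s2e_sum += s2e

    return (
        mu_sum / n_keep,
        g_sum / n_keep,
        pip_sum / n_keep,
        pi_sum / n_keep,
        s2e_sum / n_keep,
    )


try:  # JIT-compile the sweep when numba is present; fall back to pure NumPy
    import numba

    _gibbs_bayesb_impl = numba.njit(_gibbs_bayesb, cache=True)
except ImportError:  # pragma: no cover - exercised only without numba
    _gibbs_bayesb_impl = _gibbs_bayesb


class BayesB(RegressorMixin, BaseEstimator):
    """BayesB whole-genome regression via Gibbs sampling.

    Parameters
    ----------
    pi_a, pi_b : float
        Beta prior shapes for pi, the prior probability that an effect is
        exactly zero.
    pi_fixed : float or None
        If set, pi is held at this value instead of being sampled
        (pi_fixed=1 gives the spike-only model).
    df0, scale0 : float
        Scaled inverse chi-squared prior of each slab variance. With
        scale0=None the scale is set so the slab explains half the response
        variance given the mean predictor variance and the prior inclusion
        rate.
    dfe0, scale_e0 : float
        Residual-variance prior; scale_e0=None targets half the response
        variance.
    n_iter, burn_in, thin : int
        Chain length, burn-in, and thinning of retained sweeps.
    shift : float
        Subtracted from X before sampling (1.0 turns 0/1/2 dosages into
        -1/0/1; predictions are invariant because the intercept absorbs it).
    random_state : int

    Attributes
    ----------
    intercept_, coef_ : posterior means (on the original X scale).
    inclusion_prob_ : posterior inclusion probability per predictor.
    pi_ : posterior mean of pi. sigma2_e_ : posterior mean residual variance.
    """

    def __init__(
        self,
        pi_a: float = 1.0,
        pi_b: float = 9.0,
        pi_fixed: float | None = None,
        df0: float = 5.0,
        scale0: float | None = None,
        dfe0: float = 5.0,
        scale_e0: float | None = None,
        n_iter: int = 12000,
        burn_in: int = 2000,
        thin: int = 5,
        shift: float = 1.0,
        random_state: int = 0,
    ):
        self.pi_a = pi_a
        self.pi_b = pi_b
        self.pi_fixed = pi_fixed
        self.df0 = df0
        self.scale0 = scale0
        self.dfe0 = dfe0
        self.scale_e0 = scale_e0
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.shift = shift
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.df0 <= 0 or self.dfe0 <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        Xs = np.asarray(X, dtype=np.float64) - self.shift
        y = np.asarray(y, dtype=np.float64)
        var_y = max(float(np.var(y)), 1e-12)
        mean_var_x = max(float(np.mean(np.var(Xs, axis=0))), 1e-12)
        m = Xs.shape[1]
        if self.pi_fixed is not None:
            prior_in = max(1.0 - self.pi_fixed, 1e-3)
        else:
            prior_in = max(1.0 - self.pi_a / (self.pi_a + self.pi_b), 1e-3)
        # slab explains ~half the response variance a priori
        scale0 = self.scale0
        if scale0 is None:
            e_s2g = 0.5 * var_y / (prior_in * m * mean_var_x)
            scale0 = e_s2g * (self.df0 - 2.0) / self.df0 if self.df0 > 2 else e_s2g
        scale_e0 = self.scale_e0
        if scale_e0 is None:
            scale_e0 = 0.5 * var_y * (self.dfe0 - 2.0) / self.dfe0 if self.dfe0 > 2 else 0.5 * var_y
        pi_fixed = -1.0 if self.pi_fixed is None else float(self.pi_fixed)

        mu, g, pip, pi, s2e = _gibbs_bayesb_impl(
            np.asfortranarray(Xs),  # column-contiguous: O(n) slices in the sweep
            y,
            float(self.pi_a),
            float(self.pi_b),
            pi_fixed,
            float(self.df0),
            float(scale0),
            float(self.dfe0),
            float(scale_e0),
            int(self.n_iter),
            int(self.burn_in),
            int(self.thin),
            int(self.random_state) & 0x7FFFFFFF,
        )
        # report on the original X scale: mu_orig = mu - shift * sum(g)
        self.coef_ = g
        self.intercept_ = float(mu - self.shift * g.sum())
        self.inclusion_prob_ = pip
        self.pi_ = float(pi)
        self.sigma2_e_ = float(s2e)
        self.n_features_in_ = m
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_


# ---------------------------------------------------------------------------
# Functional wrappers and predictor-set assembly
# ---------------------------------------------------------------------------


def _as_xy(y, X):
    """Accept TraitBLUEs, Series or array for y; return aligned arrays + ids."""
    from .pheno import TraitBLUEs

    if isinstance(y, TraitBLUEs):
        y = y.values
    if hasattr(y, "to_numpy"):
        y = y.to_numpy(dtype=float)
    return np.asarray(y, dtype=float), np.asarray(X, dtype=float)


def fit_rrblup(y, X, lam: float, predictor_ids=None) -> MarkerEffects:
    """Fit RR-BLUP and package the solution as MarkerEffects."""
    yv, Xv = _as_xy(y, X)
    est = RRBLUP(lam=lam).fit(Xv, yv)
    ids = np.arange(Xv.shape[1]) if predictor_ids is None else predictor_ids
    return MarkerEffects(
        mu=est.intercept_, g=est.coef_, model_tag="rr_blup",
        coding_tag="dosage_012", predictor_ids=np.asarray(ids, dtype=object),
    )


def fit_bayesb(y, X, predictor_ids=None, **prior_kwargs) -> MarkerEffects:
    """Fit BayesB and package posterior-mean effects as MarkerEffects."""
    yv, Xv = _as_xy(y, X)
    est = BayesB(**prior_kwargs).fit(Xv, yv)
    ids = np.arange(Xv.shape[1]) if predictor_ids is None else predictor_ids
    return MarkerEffects(
        mu=est.intercept_, g=est.coef_, model_tag="bayes_b",
        coding_tag="shifted_-101", predictor_ids=np.asarray(ids, dtype=object),
        inclusion_prob=est.inclusion_prob_,
    )


def predict_values(effects: MarkerEffects, X_new, predictor_ids=None) -> np.ndarray:
    """Estimated values mu + X_new . g for new lines.

    If `predictor_ids` is given, columns are checked against the fitted ids.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != len(effects.g):
        raise ValueError(
            f"X_new has {X_new.shape[1]} predictors, effects have {len(effects.g)}"
        )
    if predictor_ids is not None:
        got = np.asarray(predictor_ids, dtype=object)
        if not np.array_equal(got, effects.predictor_ids):
            missing = set(effects.predictor_ids) - set(got)
            raise ValueError(f"predictor id mismatch; missing: {sorted(missing)[:5]}")
    return effects.mu + X_new @ effects.g


def combine_predictors(
    X_snp: np.ndarray,
    X_met: np.ndarray,
    snp_ids=None,
    met_ids=None,
    standardize_metabolites: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Column-concatenate SNP and metabolite predictor blocks.

    Metabolite columns are standardized (zero mean, unit variance) by default
    so heterogeneous intensity scales do not dominate the common-variance
    prior. Returns (matrix, provenance-tagged predictor ids).
    """
    X_snp = np.asarray(X_snp, dtype=float)
    X_met = np.asarray(X_met, dtype=float)
    if X_met.size and X_snp.shape[0] != X_met.shape[0]:
        raise ValueError("SNP and metabolite blocks have different line counts")
    if X_met.size and standardize_metabolites:
        sd = X_met.std(axis=0)
        sd[sd == 0] = 1.0
        X_met = (X_met - X_met.mean(axis=0)) / sd
    snp_ids = (
        np.array([f"snp:{i}" for i in range(X_snp.shape[1])], dtype=object)
        if snp_ids is None
        else np.array([f"snp:{s}" for s in snp_ids], dtype=object)
    )
    met_ids = (
        np.array([f"met:{i}" for i in range(X_met.shape[1] if X_met.size else 0)], dtype=object)
        if met_ids is None
        else np.array([f"met:{s}" for s in met_ids], dtype=object)
    )
    if not X_met.size:
        return X_snp, snp_ids
    return np.hstack([X_snp, X_met]), np.concatenate([snp_ids, met_ids])
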