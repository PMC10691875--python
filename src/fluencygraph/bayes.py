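"""Bayesian logistic regression of frontal-lesion status.

Three nested feature sets are compared for predicting whether a participant
carries a frontal lesion (frontal = 1 versus posterior and healthy control
= 0): a *baseline* model (age, NART, fluency score), an *errors* model
(baseline plus rule-break percentage, low-frequency percentage, number of
switches, relative switches and mean cluster size) and a *full* model
(errors plus the sequence embeddings, reduced by Gaussian random projection).

Sampling is a Gibbs sampler with Polya-Gamma latent-variable augmentation.
The Polya-Gamma draws use the infinite-sum-of-exponentials representation
truncated at ``K`` terms with an analytic mean correction for the discarded
tail (see docs/methods.md). Priors: *ridge* places Normal(0, tau^2) on the
standardized coefficients with a half-Cauchy(0,1) hyperprior on tau;
*horseshoe* places Normal(0, lambda_j^2 tau^2) with half-Cauchy(0,1) local
and global scales (both via the inverse-gamma auxiliary representation).
The intercept is unpenalized.

Fit quality is summarized by McFadden's pseudo-R^2 computed from the mean
posterior log-likelihood, and by WAIC = -2 (lppd - p_waic); per-coefficient
effective sample sizes use the initial-positive-sequence autocorrelation
truncation and are reported as fractions of the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingMatrix

__all__ = [
    "ModelSpec",
    "FitResult",
    "random_project",
    "fit_bayes_logistic",
    "pseudo_r2",
    "waic",
    "waic_from_loglik",
    "ess_fractions",
    "compare_models",
    "canonical_specs",
    "BASELINE_FEATURES",
    "ERROR_FEATURES",
]

BASELINE_FEATURES = ("age", "nart", "fluency")
ERROR_FEATURES = BASELINE_FEATURES + (
    "pct_rulebreak", "pct_lowfreq", "n_switches", "relative_switches",
    "mean_cluster_size",
)

_PG_TERMS = 64  # truncation of the Polya-Gamma exponential-sum representation


@dataclass
class ModelSpec:
    """One predictive model: features, prior and MCMC schedule.

    ``mcmc = (n_burn, n_samples, thin)``: ``n_burn`` discarded iterations,
    then ``n_samples`` iterations of which every ``thin``-th is retained.
    """

    name: str
    features: tuple[str, ...]
    prior: str = "ridge"
    mcmc: tuple[int, int, int] = (10_000, 10_000, 5)
    seed: int = 0
    use_embeddings: bool = False

    def __post_init__(self) -> None:
        if self.prior not in ("ridge", "horseshoe"):
            raise ValueError(f"unknown prior {self.prior!r}")
        n_burn, n_samples, thin = self.mcmc
        if min(n_burn, n_samples, thin) < 1 or n_samples < thin:
            raise ValueError("invalid MCMC schedule")


def canonical_specs(mcmc: tuple[int, int, int] = (10_000, 10_000, 5),
                    seed: int = 0) -> list[ModelSpec]:
    """The baseline / errors / full model triple (ridge, ridge, horseshoe)."""
    return [
        ModelSpec("baseline", BASELINE_FEATURES, "ridge", mcmc, seed),
        ModelSpec("errors", ERROR_FEATURES, "ridge", mcmc, seed),
        ModelSpec("full", ERROR_FEATURES, "horseshoe", mcmc, seed,
                  use_embeddings=True),
    ]


@dataclass
class FitResult:
    """Posterior draws and fit summaries for one model."""

    spec: ModelSpec
    coef_names: list[str]
    draws: np.ndarray               # (n_retained, p + 1); column 0 = intercept
    x_mean: np.ndarray
    x_scale: np.ndarray
    pseudo_r2: float = math.nan
    waic: float = math.nan
    ess_fraction_min: float = math.nan

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        Xz = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.draws[:, :1] + self.draws[:, 1:] @ Xz.T

    def coef_posterior_mean(self) -> np.ndarray:
        """Posterior means of the non-intercept (standardized) coefficients."""
        return self.draws[:, 1:].mean(axis=0)


def random_project(E: EmbeddingMatrix | np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Gaussian random projection to ``k`` latent variables.

    The projection matrix has i.i.d. Normal(0, 1/k) entries, preserving
    squared distances in expectation (Johnson-Lindenstrauss style).
    """
    X = E.vectors if isinstance(E, EmbeddingMatrix) else np.asarray(E, dtype=float)
    d = X.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= d:
        raise ValueError(f"k={k} must be smaller than the input dimension {d}")
    rng = np.random.default_rng(seed)
    R = rng.normal(0.0, 1.0 / np.sqrt(k), size=(d, k))
    return X @ R


def _sample_pg(z: np.ndarray, rng: np.random.Generator,
               K: int = _PG_TERMS) -> np.ndarray:
    """Polya-Gamma PG(1, z) draws, one per element of ``z``.

    Truncated sum-of-exponentials representation with an exact mean
    correction for the discarded tail, vectorized over observations.
    """
    z = np.abs(np.asarray(z, dtype=float))
    ks = (np.arange(1, K + 1) - 0.5) ** 2            # (K,)
    denom = ks[None, :] + (z[:, None] / (2.0 * np.pi)) ** 2
    e = rng.standard_exponential((z.size, K))
    s = (e / denom).sum(axis=1) / (2.0 * np.pi ** 2)
    mean_full = np.where(z < 1e-8, 0.25, np.tanh(z / 2.0) / (2.0 * np.maximum(z, 1e-8)))
    mean_trunc = (1.0 / denom).sum(axis=1) / (2.0 * np.pi ** 2)
    return s + (mean_full - mean_trunc)


def _inv_gamma(rng: np.random.Generator, shape, scale):
    return scale / rng.gamma(shape, 1.0, size=np.shape(scale) or None)


def fit_bayes_logistic(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                       coef_names: Optional[Sequence[str]] = None,
                       intercept_var: float = 100.0) -> FitResult:
    """Polya-Gamma Gibbs sampler for Bayesian logistic regression.

    Columns of ``X`` are standardized internally (constant columns are left
    centred with unit scale); the intercept carries a fixed wide normal
    prior and is never shrunk. Deterministic under ``spec.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y are misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    p = X.shape[1]
    x_mean = X.mean(axis=0) if p else np.zeros(0)
    x_scale = X.std(axis=0, ddof=0) if p else np.zeros(0)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xz = (X - x_mean) / x_scale
    D = np.column_stack([np.ones(n), Xz]) if p else np.ones((n, 1))
    kappa = y - 0.5

    rng = np.random.default_rng(spec.seed)
    n_burn, n_samples, thin = spec.mcmc
    beta = np.zeros(p + 1)
    lam2 = np.ones(p)
    nu = np.ones(p)
    tau2, xi = 1.0, 1.0
    retained = []
    for it in range(n_burn + n_samples):
        omega = _sample_pg(D @ beta, rng)
        if spec.prior == "horseshoe":
            prior_prec = np.concatenate([[1.0 / intercept_var],
                                         1.0 / (lam2 * tau2)]) if p else \
                np.array([1.0 / intercept_var])
        else:
            prior_prec = np.concatenate([[1.0 / intercept_var],
                                         np.full(p, 1.0 / tau2)]) if p else \
                np.array([1.0 / intercept_var])
        A = D.T @ (D * omega[:, None])
        A[np.diag_indices_from(A)] += prior_prec
        L = np.linalg.cholesky(A)
        mu = np.linalg.solve(L.T, np.linalg.solve(L, D.T @ kappa))
        beta = mu + np.linalg.solve(L.T, rng.standard_normal(p + 1))
        if p:
            b2 = beta[1:] ** 2
            if spec.prior == "horseshoe":
                lam2 = _inv_gamma(rng, 1.0, 1.0 / nu + b2 / (2.0 * tau2))
                nu = _inv_gamma(rng, 1.0, 1.0 + 1.0 / lam2)
                tau2 = float(_inv_gamma(rng, (p + 1) / 2.0,
                                        1.0 / xi + float((b2 / lam2).sum()) / 2.0))
            else:
                tau2 = float(_inv_gamma(rng, (p + 1) / 2.0,
                                        1.0 / xi + float(b2.sum()) / 2.0))
            xi = float(_inv_gamma(rng, 1.0, 1.0 + 1.0 / tau2))
        if it >= n_burn and (it - n_burn) % thin == 0:
            retained.append(beta.copy())
    draws = np.asarray(retained)
    names = list(coef_names) if coef_names is not None else [
        f"x{j}" for j in range(p)
    ]
    fit = FitResult(spec=spec, coef_names=["intercept"] + names, draws=draws,
                    x_mean=x_mean, x_scale=x_scale)
    fit.ess_fraction_min = float(ess_fractions(draws).min())
    fit.pseudo_r2 = pseudo_r2(fit, X, y)
    fit.waic = waic(fit, X, y)
    if fit.ess_fraction_min < 0.1:
        import warnings
        warnings.warn("minimum effective sample size below 10% of draws",
                      stacklevel=2)
    return fit


def _loglik_matrix(fit: FitResult, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-draw, per-observation Bernoulli log-likelihoods (S x n)."""
    eta = fit.linear_predictor(X)
    sign = np.where(np.asarray(y, dtype=float) > 0.5, 1.0, -1.0)
    return -np.logaddexp(0.0, -sign[None, :] * eta)


def ess_fractions(draws: np.ndarray, max_lag: Optional[int] = None) -> np.ndarray:
    """Effective sample size of each column as a fraction of the draw count.

    Autocorrelations are summed in Geyer initial-positive-sequence pairs;
    constant chains report a fraction of 1.
    """
    S, p = draws.shape
    if S < 4:
        return np.ones(p)
    max_lag = max_lag or S - 2
    out = np.empty(p)
    for j in range(p):
        x = draws[:, j] - draws[:, j].mean()
        var = float(x @ x) / S
        if var <= 0:
            out[j] = 1.0
            continue
        nfft = 1 << (2 * S - 1).bit_length()
        f = np.fft.rfft(x, nfft)
        acov = np.fft.irfft(f * np.conj(f), nfft)[:S].real / S
        rho = acov / acov[0]
        ssum = 0.0
        t = 1
        while t + 1 <= min(max_lag, S - 2):
            pair = rho[t] + rho[t + 1]
            if pair <= 0:
                break
            ssum += pair
            t += 2
        ess = S / (1.0 + 2.0 * ssum)
        out[j] = min(ess / S, 1.0)
    return out


def pseudo_r2(fit: FitResult, X: np.ndarray, y: np.ndarray) -> float:
    """McFadden's pseudo-R^2 from the mean posterior log-likelihood.

    ``1 - E_post[log L] / log L0`` with ``L0`` the intercept-only likelihood
    at the empirical positive rate; an intercept-only model scores exactly 0
    by definition.
    """
    y = np.asarray(y, dtype=float).ravel()
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise ValueError("pseudo-R^2 undefined for constant y")
    if len(fit.coef_names) <= 1:
        return 0.0
    ll_mean = float(_loglik_matrix(fit, X, y).sum(axis=1).mean())
    ll0 = y.size * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    return 1.0 - ll_mean / ll0


def waic_from_loglik(loglik: np.ndarray) -> float:
    """WAIC from an (S draws x n observations) log-likelihood table.

    ``WAIC = -2 (lppd - p_waic)`` with ``lppd = sum_i log mean_s p(y_i|s)``
    and ``p_waic = sum_i var_s log p(y_i|s)`` (sample variance). Lower is
    better.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need at least two posterior draws")
    S = ll.shape[0]
    lppd = float((np.logaddexp.reduce(ll, axis=0) - np.log(S)).sum())
    p_waic = float(ll.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic)


def waic(fit: FitResult, X: np.ndarray, y: np.ndarray) -> float:
    """WAIC of a fitted model on its data."""
    return waic_from_loglik(_loglik_matrix(fit, X, y))


def compare_models(
    features: pd.DataFrame,
    y: np.ndarray,
    embeddings: Optional[EmbeddingMatrix | np.ndarray] = None,
    specs: Optional[Sequence[ModelSpec]] = None,
    seed: int = 0,
    k_project: int = 256,
    mcmc: tuple[int, int, int] = (10_000, 10_000, 5),
) -> pd.DataFrame:
    """Fit and compare the nested models on one cohort.

    ``features`` must contain every named feature column; models flagged
    ``use_embeddings`` append the random projection of ``embeddings`` to
    ``k_project`` latent variables. Per-model failures are recorded in the
    ``error`` column and the remaining models still run.
    """
    if specs is None:
        specs = canonical_specs(mcmc=mcmc, seed=seed)
    y = np.asarray(y, dtype=float).ravel()
    rows = []
    for spec in specs:
        try:
            cols = list(spec.features)
            missing = [c for c in cols if c not in features.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            X = features[cols].to_numpy(dtype=float)
            names = cols
            if spec.use_embeddings:
                if embeddings is None:
                    raise ValueError(f"model {spec.name!r} needs embeddings")
                Z = random_project(embeddings, k=k_project, seed=seed)
                X = np.column_stack([X, Z])
                names = cols + [f"emb{j}" for j in range(Z.shape[1])]
            fit = fit_bayes_logistic(X, y, spec, coef_names=names)
            rows.append(dict(model=spec.name, prior=spec.prior,
                             n_features=X.shape[1], pseudo_r2=fit.pseudo_r2,
                             waic=fit.waic,
                             ess_fraction_min=fit.ess_fraction_min, error=""))
        except Exception as exc:  # noqa: BLE001 - continue with other models
            rows.append(dict(model=spec.name, prior=spec.prior,
                             n_features=np.nan, pseudo_r2=np.nan, waic=np.nan,
                             ess_fraction_min=np.nan, error=str(exc)))
    return pd.DataFrame(rows)
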