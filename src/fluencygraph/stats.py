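"""Group-comparison battery: ANCOVA controlling for age and NART,
Bonferroni-corrected pairwise contrasts, and categorical demographics tests.

The ANCOVA is the extra-sum-of-squares F-test of the group factor: the full
linear model (group dummies + covariates) is compared with the
covariates-only model, ``F = ((RSS_reduced - RSS_full)/df_between) /
(RSS_full/df_within)`` and ``partial eta^2 = SS_group / (SS_group +
SS_residual)``. Adjusted group means are model predictions at the grand mean
of the covariates. Pairwise contrasts are covariate-adjusted two-group
models tested against a per-comparison threshold ``family_alpha /
n_comparisons`` (reported alongside each test).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AncovaResult",
    "CategoricalResult",
    "ancova",
    "bonferroni_pairwise",
    "categorical_tests",
]


@dataclass
class AncovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    partial_eta_sq: float
    adjusted_means: dict[str, float]


def _as_cov_matrix(covariates) -> np.ndarray:
    if covariates is None:
        return np.empty((0, 0))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return C


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular design matrix (collinear or constant column)")
    r = y - X @ coef
    return float(r @ r)


def ancova(y, group, covariates=None) -> AncovaResult:
    """Group effect on ``y`` adjusting for covariates (e.g. age and NART)."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    C = _as_cov_matrix(covariates)
    if C.size and C.shape[0] != y.size:
        raise ValueError("covariates misaligned with y")
    levels = sorted(pd.unique(group).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    counts = {g: int(np.sum(group == g)) for g in levels}
    if min(counts.values()) < 2:
        raise ValueError("each group needs n >= 2")
    n = y.size
    dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    ones = np.ones((n, 1))
    X_full = np.column_stack([ones, dummies] + ([C] if C.size else []))
    X_red = np.column_stack([ones] + ([C] if C.size else []))
    rss_full = _rss(X_full, y)
    rss_red = _rss(X_red, y)
    df_between = len(levels) - 1
    df_within = n - X_full.shape[1]
    ss_group = max(rss_red - rss_full, 0.0)
    F = (ss_group / df_between) / (rss_full / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    eta = ss_group / (ss_group + rss_full) if (ss_group + rss_full) > 0 else 1.0
    coef, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    cbar = C.mean(axis=0) if C.size else np.zeros(0)
    adj = {}
    for i, g in enumerate(levels):
        x = np.concatenate([[1.0],
                            np.eye(len(levels) - 1)[i - 1] if i > 0
                            else np.zeros(len(levels) - 1),
                            cbar])
        adj[str(g)] = float(x @ coef)
    return AncovaResult(float(F), df_between, df_within, p, float(eta), adj)


def bonferroni_pairwise(
    y, group, covariates=None, family_alpha: float = 0.05,
    n_comparisons: Optional[int] = None,
    pairs: Optional[Sequence[tuple]] = None,
) -> pd.DataFrame:
    """Covariate-adjusted pairwise contrasts at ``family_alpha / n`` each."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    C = _as_cov_matrix(covariates)
    if pairs is None:
        pairs = list(combinations(sorted(pd.unique(group).tolist()), 2))
    if n_comparisons is None:
        n_comparisons = len(pairs)
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    threshold = family_alpha / n_comparisons
    rows = []
    for a, b in pairs:
        mask = (group == a) | (group == b)
        ys = y[mask]
        ind = (group[mask] == b).astype(float)
        X = np.column_stack([np.ones(ys.size), ind]
                            + ([C[mask]] if C.size else []))
        coef, _, rank, _ = np.linalg.lstsq(X, ys, rcond=None)
        if rank < X.shape[1]:
            raise ValueError("singular design in pairwise contrast")
        resid = ys - X @ coef
        dof = ys.size - X.shape[1]
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        t = float(coef[1] / se)
        p = float(2.0 * sps.t.sf(abs(t), dof))
        rows.append(dict(group_a=str(a), group_b=str(b),
                         estimate=float(coef[1]), t=t, df=dof, p=p,
                         threshold=threshold, significant=bool(p < threshold)))
    return pd.DataFrame(rows)


@dataclass
class CategoricalResult:
    test: str                       # "chi2" or "fisher"
    statistic: float                # chi-square statistic (no continuity corr.)
    p: float
    phi: float                      # sqrt(chi2/n) for 2x2 tables, else NaN


def categorical_tests(counts, force_exact: Optional[bool] = None) -> CategoricalResult:
    """Chi-square test of independence on a contingency table.

    Continuity correction is off. For 2x2 tables the phi coefficient
    ``sqrt(chi2/n)`` is reported, and Fisher's exact test replaces the
    chi-square p-value when any expected count falls below 5 (or when
    ``force_exact`` is set).
    """
    table = np.asarray(counts, dtype=float)
    if table.size == 0 or table.sum() == 0:
        raise ValueError("empty contingency table")
    if np.any(table < 0) or np.any(table != np.rint(table)):
        raise ValueError("table must contain non-negative integers")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if np.any(expected == 0):
        raise ValueError("table has an empty row or column")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    is_2x2 = table.shape == (2, 2)
    phi = float(np.sqrt(chi2 / n)) if is_2x2 else float("nan")
    use_exact = force_exact if force_exact is not None else (
        is_2x2 and expected.min() < 5
    )
    if use_exact and is_2x2:
        _, p = sps.fisher_exact(table.astype(int))
        return CategoricalResult("fisher", chi2, float(p), phi)
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return CategoricalResult("chi2", chi2, p, phi)
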