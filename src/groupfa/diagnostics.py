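"""Descriptive and inferential diagnostics around a fitted group factor model.

Covers the choices and checks a morphometry analysis reports: a scree /
Kaiser criterion to pick the number of factors, per-feature one-way ANOVA
across diagnostic groups, Kolmogorov-Smirnov normality of the factor scores
(the model asserts f ~ N(0, I), so the null is the fixed standard normal),
distances and correlations between aligned per-group loading matrices,
soft reestimation of the group proportions, and per-group association of a
factor score with an external covariate (e.g. a cognitive test score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .em import MFAParams, responsibilities
from .preprocess import FeatureMatrix, GroupLabels

__all__ = [
    "ScreeResult",
    "LoadingComparison",
    "scree",
    "ks_normality",
    "anova_per_feature",
    "compare_loadings",
    "reestimate_proportions",
    "score_covariate_association",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreeResult:
    """Eigenvalue spectrum of the sample covariance, descending."""

    eigenvalues: np.ndarray
    cum_var_pct: np.ndarray
    kaiser_count: int

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "cum_var_pct": self.cum_var_pct.tolist(),
            "kaiser_count": self.kaiser_count,
        }


@dataclass
class LoadingComparison:
    """Pairwise distances and correlations between aligned loading matrices.

    ``pairwise_distance[a, b]`` is the Frobenius norm of L_a - L_b;
    ``aggregate_distance`` the mean over unordered pairs;
    ``pairwise_corr[a, b]`` the Pearson correlation of the vectorized
    matrices.
    """

    pairwise_distance: np.ndarray
    aggregate_distance: float
    pairwise_corr: np.ndarray

    def to_dict(self) -> dict:
        return {
            "pairwise_distance": self.pairwise_distance.tolist(),
            "aggregate_distance": self.aggregate_distance,
            "pairwise_corr": self.pairwise_corr.tolist(),
        }


def scree(X: FeatureMatrix) -> ScreeResult:
    """Eigenvalues of the sample covariance and cumulative variance percent.

    On standardized input the covariance equals the correlation matrix, so
    the Kaiser criterion (eigenvalues > 1) counts factors explaining more
    than one feature's worth of variance.
    """
    cov = np.cov(X.values, rowvar=False)
    cov = np.atleast_2d(cov)
    eig = np.linalg.eigvalsh(cov)[::-1]
    cum = 100.0 * np.cumsum(eig) / eig.sum()
    return ScreeResult(eig, cum, int(np.sum(eig > 1.0)))


def ks_normality(scores: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of scores against N(0, 1).

    The model takes the latent factors to be standard normal, so the null is
    the *fixed* standard normal, not one with estimated moments. Returns the
    KS statistic sup_x |F_N(x) - Phi(x)| and the two-sided p-value.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 5:
        raise ValueError("need a vector of at least 5 scores")
    if np.any(np.isnan(scores)):
        raise ValueError("scores contain NaN")
    res = stats.kstest(scores, "norm")
    return float(res.statistic), float(res.pvalue)


def anova_per_feature(
    X: FeatureMatrix, labels: GroupLabels
) -> list[tuple[str, float, float]]:
    """Classical one-way ANOVA of each feature across the M groups.

    Returns (feature_name, F, p) per column with (M-1, N-M) degrees of
    freedom. A feature that is constant everywhere (zero between- and
    within-group variance) is reported as F = 0, p = 1 by convention.
    """
    if labels.n_groups < 2:
        raise ValueError("ANOVA needs at least two groups")
    if np.any(labels.counts < 2):
        raise ValueError("every group needs at least two members for ANOVA")
    groups_rows = [X.values[labels.labels == j + 1] for j in range(labels.n_groups)]
    out = []
    for d, name in enumerate(X.feature_names):
        samples = [g[:, d] for g in groups_rows]
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(X.values[:, d]) == 0:
            logger.info("feature %s constant everywhere; ANOVA p set to 1", name)
            out.append((name, 0.0, 1.0))
            continue
        f, p = stats.f_oneway(*samples)
        out.append((name, float(f), float(p)))
    return out


def compare_loadings(L_list: list[np.ndarray]) -> LoadingComparison:
    """Distances and correlations between (already aligned) loading matrices."""
    m = len(L_list)
    dist = np.zeros((m, m))
    corr = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            dist[a, b] = dist[b, a] = float(
                np.linalg.norm(L_list[a] - L_list[b])
            )
            va = np.asarray(L_list[a]).ravel()
            vb = np.asarray(L_list[b]).ravel()
            corr[a, b] = corr[b, a] = float(np.corrcoef(va, vb)[0, 1])
    if m > 1:
        agg = float(dist[np.triu_indices(m, 1)].mean())
    else:
        agg = 0.0
    return LoadingComparison(dist, agg, corr)


def reestimate_proportions(X: FeatureMatrix, params: MFAParams) -> np.ndarray:
    """Soft reestimate of the group proportions from a fitted model.

    Column means of the posterior responsibility matrix: pi_hat_j =
    (1/N) sum_i h_ij. Unlike the diagnosis-derived proportions these account
    for subjects whose features resemble another group's model.
    """
    return responsibilities(X, params).mean(axis=0)


def score_covariate_association(
    scores: np.ndarray,
    covariate: np.ndarray,
    labels: GroupLabels,
) -> list[dict]:
    """Per-group OLS of a covariate on a factor score, plus Pearson r.

    Returns one dict per group with keys ``group``, ``slope``,
    ``intercept``, ``r``, ``n``. A group whose scores are constant has no
    defined correlation; its entries are NaN.
    """
    scores = np.asarray(scores, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    out = []
    for j in range(labels.n_groups):
        idx = labels.labels == j + 1
        s = scores[idx]
        c = covariate[idx]
        ok = np.isfinite(c)
        s, c = s[ok], c[ok]
        if s.size < 3:
            raise ValueError(
                f"group {labels.group_names[j]} has fewer than 3 subjects "
                "with a finite covariate"
            )
        if np.ptp(s) == 0:
            out.append({"group": labels.group_names[j], "slope": float("nan"),
                        "intercept": float("nan"), "r": float("nan"),
                        "n": int(s.size)})
            continue
        res = stats.linregress(s, c)
        out.append({
            "group": labels.group_names[j],
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r": float(res.rvalue),
            "n": int(s.size),
        })
    return out
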