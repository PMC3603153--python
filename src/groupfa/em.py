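"""EM estimation of the group factor analysis model.

The model: each subject belongs to one of M diagnostic groups. Within group
j the D-dimensional feature vector is

    x = mu_j + L_j f + u,      f ~ N(0, I_K),   u ~ N(0, Psi),

with a group-specific D x K loading matrix L_j and mean mu_j, but a single
diagonal noise covariance Psi shared by all groups — the measurement errors
come from a common acquisition pipeline, so the groups share them. The
marginal within-group covariance is L_j L_j^T + Psi.

Estimation is by EM. In the default *supervised* mode the group
responsibilities are fixed to the clinical labels (h_ij = 1 iff subject i
carries diagnosis j) for the whole run; in *soft* mode they are recomputed
each iteration from the current parameters with the label-derived prior pi.
The M-step uses the augmented-loading trick: appending a constant 1 to the
factor vector folds the group mean into an extra loading column, so loadings
and means are updated by one weighted least-squares solve per group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .preprocess import FeatureMatrix, GroupLabels

__all__ = [
    "MFAParams",
    "EStepResult",
    "FitResult",
    "init_params",
    "group_density",
    "responsibilities",
    "hard_responsibilities",
    "conditional_factor_mean",
    "conditional_factor_second_moment",
    "m_step_loadings",
    "m_step_psi",
    "log_likelihood",
    "factor_scores",
    "fit",
]

logger = logging.getLogger(__name__)

DEFAULT_PSI_FLOOR = 1e-6


@dataclass
class MFAParams:
    """Parameters of the group factor analysis model.

    Attributes
    ----------
    loadings : ndarray of shape (M, D, K)
        Per-group factor loading matrices L_j.
    means : ndarray of shape (M, D)
        Per-group mean vectors mu_j.
    psi : ndarray of shape (D,)
        Diagonal of the shared noise covariance, strictly positive.
    proportions : ndarray of shape (M,)
        Group prior probabilities pi_j on the simplex.
    group_names : list of str, optional
    """

    loadings: np.ndarray
    means: np.ndarray
    psi: np.ndarray
    proportions: np.ndarray
    group_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.loadings.ndim != 3:
            raise ValueError("loadings must have shape (M, D, K)")
        m, d, _ = self.loadings.shape
        if self.means.shape != (m, d):
            raise ValueError("means must have shape (M, D)")
        if self.psi.shape != (d,):
            raise ValueError("psi must have shape (D,)")
        if np.any(self.psi <= 0):
            raise ValueError("psi must be strictly positive")
        if self.proportions.shape != (m,):
            raise ValueError("proportions must have shape (M,)")
        if abs(self.proportions.sum() - 1.0) > 1e-8 or np.any(self.proportions < 0):
            raise ValueError("proportions must lie on the simplex")
        if self.group_names is None:
            self.group_names = [f"group{j + 1}" for j in range(m)]

    @property
    def n_groups(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_features(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[2]

    def group_covariance(self, j: int) -> np.ndarray:
        """Model covariance L_j L_j^T + Psi of group j."""
        L = self.loadings[j]
        return L @ L.T + np.diag(self.psi)

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "name": self.group_names[j],
                    "loading": self.loadings[j].tolist(),
                    "mean": self.means[j].tolist(),
                }
                for j in range(self.n_groups)
            ],
            "psi": self.psi.tolist(),
            "proportions": self.proportions.tolist(),
            "K": self.n_factors,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MFAParams":
        groups = d["groups"]
        return cls(
            loadings=np.asarray([g["loading"] for g in groups], dtype=float),
            means=np.asarray([g["mean"] for g in groups], dtype=float),
            psi=np.asarray(d["psi"], dtype=float),
            proportions=np.asarray(d["proportions"], dtype=float),
            group_names=[g["name"] for g in groups],
        )

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MFAParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class EStepResult:
    """Posterior quantities from one E-step.

    ``resp[i, j]`` is the responsibility h_ij; ``f_mean[i, j]`` the
    conditional factor mean E[f_i | w_j, x_i]; ``f_second[i, j]`` the
    conditional second moment E[f_i f_i^T | w_j, x_i].
    """

    resp: np.ndarray
    f_mean: np.ndarray
    f_second: np.ndarray


@dataclass
class FitResult:
    params: MFAParams
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    mode: str
    psi_floor_events: int = 0
    estep: EStepResult | None = field(default=None, repr=False)


def init_params(
    X: FeatureMatrix, labels: GroupLabels, K: int, seed: int
) -> MFAParams:
    """Label-informed starting point for EM.

    Group means start at the within-group sample means, Psi at the pooled
    within-group residual variances, pi at the observed label proportions,
    and the loadings at small seeded Gaussian noise (sd 0.1) to break the
    rotational symmetry of the flat L = 0 point.
    """
    d = X.n_features
    m = labels.n_groups
    if not 1 <= K < d:
        raise ValueError(f"need 1 <= K < D={d}; got K={K} (model not reduced)")
    rng = np.random.default_rng(seed)
    means = np.empty((m, d))
    resid_ss = np.zeros(d)
    for j in range(m):
        rows = X.values[labels.labels == j + 1]
        means[j] = rows.mean(axis=0)
        resid_ss += ((rows - means[j]) ** 2).sum(axis=0)
    psi = np.maximum(resid_ss / X.n_subjects, DEFAULT_PSI_FLOOR)
    loadings = rng.normal(scale=0.1, size=(m, d, K))
    return MFAParams(loadings, means, psi, labels.proportions.copy(),
                     group_names=list(labels.group_names))


def _log_densities(X: np.ndarray, params: MFAParams) -> np.ndarray:
    """N x M matrix of log N(x_i; mu_j, L_j L_j^T + Psi), via Cholesky."""
    n, d = X.shape
    out = np.empty((n, params.n_groups))
    for j in range(params.n_groups):
        cov = params.group_covariance(j)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"group {j + 1} covariance numerically singular"
            ) from exc
        z = solve_triangular(chol, (X - params.means[j]).T, lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, j] = -0.5 * (d * np.log(2.0 * np.pi) + logdet + (z ** 2).sum(axis=0))
    return out


def group_density(x: np.ndarray, L: np.ndarray, mu: np.ndarray, psi: np.ndarray) -> float:
    """Marginal density N(x; mu, L L^T + Psi) of one observation in one group."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    L = np.atleast_2d(np.asarray(L, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    if np.any(psi <= 0):
        raise ValueError("psi must be strictly positive")
    params = MFAParams(L[None], mu[None], psi, np.array([1.0]))
    return float(np.exp(_log_densities(x[None], params)[0, 0]))


def responsibilities(X: FeatureMatrix, params: MFAParams) -> np.ndarray:
    """Posterior group probabilities h_ij from the current parameters.

    h_ij is proportional to pi_j N(x_i; mu_j, L_j L_j^T + Psi), normalized
    over groups; computed in log space.
    """
    logd = _log_densities(X.values, params)
    with np.errstate(divide="ignore"):
        logw = logd + np.log(params.proportions)
    norm = logsumexp(logw, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = np.flatnonzero(~np.isfinite(norm))
        raise FloatingPointError(
            f"all group densities underflow for subjects {bad[:5].tolist()}; "
            "consider standardizing the features"
        )
    return np.exp(logw - norm[:, None])


def hard_responsibilities(labels: GroupLabels) -> np.ndarray:
    """Binary responsibility matrix encoding the clinical diagnosis."""
    h = np.zeros((labels.labels.size, labels.n_groups))
    h[np.arange(labels.labels.size), labels.labels - 1] = 1.0
    return h


def _posterior_precision(L: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """R = L^T Psi^{-1} L + I, the posterior precision of f given x."""
    return L.T @ (L / psi[:, None]) + np.eye(L.shape[1])


def conditional_factor_mean(
    x: np.ndarray, L: np.ndarray, mu: np.ndarray, psi: np.ndarray
) -> np.ndarray:
    """E[f | w_j, x] = R^{-1} L^T Psi^{-1} (x - mu) with R = L^T Psi^{-1} L + I."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    R = _posterior_precision(L, np.asarray(psi, dtype=float))
    rhs = L.T @ ((np.asarray(x, dtype=float) - np.asarray(mu, dtype=float))
                 / np.asarray(psi, dtype=float))
    return np.linalg.solve(R, rhs)


def conditional_factor_second_moment(
    x: np.ndarray, L: np.ndarray, mu: np.ndarray, psi: np.ndarray
) -> np.ndarray:
    """E[f f^T | w_j, x] = R^{-1} + m m^T where m is the conditional mean."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    R = _posterior_precision(L, np.asarray(psi, dtype=float))
    m = conditional_factor_mean(x, L, np.asarray(mu), np.asarray(psi))
    return np.linalg.inv(R) + np.outer(m, m)


def _e_step_moments(X: np.ndarray, params: MFAParams, resp: np.ndarray) -> EStepResult:
    """Conditional factor means and second moments for every subject/group."""
    n, _ = X.shape
    m, _, k = params.loadings.shape
    f_mean = np.empty((n, m, k))
    f_second = np.empty((n, m, k, k))
    for j in range(m):
        L = params.loadings[j]
        R = _posterior_precision(L, params.psi)
        Rinv = np.linalg.inv(R)
        # beta = R^{-1} L^T Psi^{-1}, the regression of f on (x - mu)
        beta = Rinv @ (L / params.psi[:, None]).T
        mj = (X - params.means[j]) @ beta.T
        f_mean[:, j] = mj
        f_second[:, j] = Rinv + mj[:, :, None] * mj[:, None, :]
    return EStepResult(resp, f_mean, f_second)


def _augmented_moments(estep: EStepResult) -> tuple[np.ndarray, np.ndarray]:
    """Moments of the augmented factor ftilde = [f, 1].

    Returns mean (N, M, K+1) and second moment (N, M, K+1, K+1) with blocks
    [[E[ff^T], E[f]], [E[f]^T, 1]].
    """
    n, m, k = estep.f_mean.shape
    mean = np.concatenate([estep.f_mean, np.ones((n, m, 1))], axis=2)
    second = np.empty((n, m, k + 1, k + 1))
    second[:, :, :k, :k] = estep.f_second
    second[:, :, :k, k] = estep.f_mean
    second[:, :, k, :k] = estep.f_mean
    second[:, :, k, k] = 1.0
    return mean, second


def m_step_loadings(X: FeatureMatrix, estep: EStepResult) -> np.ndarray:
    """Update the augmented loadings Ltilde_j = [L_j mu_j].

    Ltilde_j = (sum_i h_ij x_i E[ftilde_i]^T)(sum_s h_sj E[ftilde_s ftilde_s^T])^{-1}
    — a responsibility-weighted least-squares regression of x on the
    augmented factor, solved per group. Returns shape (M, D, K+1); the last
    column of each matrix is the updated group mean.
    """
    Xv = X.values
    aug_mean, aug_second = _augmented_moments(estep)
    m = estep.resp.shape[1]
    d = Xv.shape[1]
    k1 = aug_mean.shape[2]
    out = np.empty((m, d, k1))
    for j in range(m):
        h = estep.resp[:, j]
        if h.sum() <= 0:
            raise ValueError(f"group {j + 1} has zero total responsibility")
        A = (Xv * h[:, None]).T @ aug_mean[:, j]                # D x (K+1)
        G = np.einsum("i,iab->ab", h, aug_second[:, j])         # (K+1) x (K+1)
        try:
            out[j] = np.linalg.solve(G.T, A.T).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular Gram matrix in group {j + 1}; "
                "try a smaller K or more data"
            ) from exc
    return out


def m_step_psi(
    X: FeatureMatrix,
    estep: EStepResult,
    L_aug: np.ndarray,
    floor: float = DEFAULT_PSI_FLOOR,
) -> tuple[np.ndarray, int]:
    """Update the shared noise variances.

    Psi = (1/N) diag( sum_{i,j} h_ij (x_i - Ltilde_j E[ftilde_i]) x_i^T ),
    elementwise floored. Returns (psi, number of floored coordinates).
    """
    Xv = X.values
    n = Xv.shape[0]
    aug_mean, _ = _augmented_moments(estep)
    diag = np.zeros(Xv.shape[1])
    for j in range(estep.resp.shape[1]):
        h = estep.resp[:, j]
        pred = aug_mean[:, j] @ L_aug[j].T                      # N x D
        diag += np.einsum("i,id,id->d", h, Xv - pred, Xv)
    psi = diag / n
    floored = int(np.sum(psi < floor))
    if np.any(psi <= 0):
        logger.warning("non-positive noise variance before flooring (%d coords)",
                       int(np.sum(psi <= 0)))
    return np.maximum(psi, floor), floored


def log_likelihood(
    X: FeatureMatrix,
    params: MFAParams,
    mode: str = "supervised",
    labels: GroupLabels | None = None,
) -> float:
    """Observed-data log likelihood.

    supervised: sum_i log N(x_i; mu_{j(i)}, C_{j(i)}) with j(i) the subject's
    diagnosis. soft: sum_i log sum_j pi_j N(x_i; mu_j, C_j), the mixture
    marginal.
    """
    logd = _log_densities(X.values, params)
    if mode == "supervised":
        if labels is None:
            raise ValueError("supervised log likelihood requires labels")
        return float(logd[np.arange(X.n_subjects), labels.labels - 1].sum())
    if mode == "soft":
        with np.errstate(divide="ignore"):
            logw = logd + np.log(params.proportions)
        return float(logsumexp(logw, axis=1).sum())
    raise ValueError(f"unknown mode {mode!r}")


def factor_scores(
    X: FeatureMatrix, params: MFAParams, labels: GroupLabels | None = None
) -> np.ndarray:
    """Per-subject factor scores E[f_i | w_j, x_i], N x K.

    Scores are computed under each subject's assigned group when labels are
    given, otherwise under the maximum-responsibility group.
    """
    if labels is not None:
        assign = labels.labels - 1
    else:
        assign = responsibilities(X, params).argmax(axis=1)
    scores = np.empty((X.n_subjects, params.n_factors))
    for j in range(params.n_groups):
        idx = np.flatnonzero(assign == j)
        if idx.size == 0:
            continue
        L = params.loadings[j]
        R = _posterior_precision(L, params.psi)
        beta = np.linalg.inv(R) @ (L / params.psi[:, None]).T
        scores[idx] = (X.values[idx] - params.means[j]) @ beta.T
    return scores


def fit(
    X: FeatureMatrix,
    labels: GroupLabels,
    K: int,
    mode: str = "supervised",
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    psi_floor: float = DEFAULT_PSI_FLOOR,
    init: MFAParams | None = None,
) -> FitResult:
    """Fit the model by EM.

    Alternates an E-step (responsibilities fixed to the diagnosis in
    supervised mode, recomputed from the current parameters in soft mode;
    conditional factor moments in both) with an M-step (joint loading/mean
    update, then shared-Psi update). Stops when the relative log-likelihood
    change |dLL| / (|LL| + 1) drops below ``tol`` or after ``max_iter``
    iterations. The trace is non-decreasing up to floating-point noise.
    """
    if mode not in ("supervised", "soft"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = labels.counts
    if np.any(counts < 2):
        small = [labels.group_names[j] for j in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 members cannot be fit: {small}")
    params = init if init is not None else init_params(X, labels, K, seed)
    hard = hard_responsibilities(labels)
    floor_events = 0

    ll = log_likelihood(X, params, mode=mode, labels=labels)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        resp = hard if mode == "supervised" else responsibilities(X, params)
        estep = _e_step_moments(X.values, params, resp)
        L_aug = m_step_loadings(X, estep)
        psi, floored = m_step_psi(X, estep, L_aug, floor=psi_floor)
        floor_events += floored
        if floored:
            logger.info("iteration %d: floored %d noise variances", n_iter, floored)
        params = MFAParams(
            loadings=L_aug[:, :, :-1].copy(),
            means=L_aug[:, :, -1].copy(),
            psi=psi,
            proportions=params.proportions,
            group_names=params.group_names,
        )
        ll_new = log_likelihood(X, params, mode=mode, labels=labels)
        if not np.isfinite(ll_new):
            raise FloatingPointError(f"non-finite log likelihood at iteration {n_iter}")
        trace.append(ll_new)
        if abs(ll_new - ll) / (abs(ll_new) + 1.0) < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new

    resp = hard if mode == "supervised" else responsibilities(X, params)
    estep = _e_step_moments(X.values, params, resp)
    return FitResult(params, trace, n_iter, converged, mode, floor_events, estep)
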