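"""Varimax rotation and cross-group alignment of factor loadings.

A factor model is only identified up to an orthogonal rotation of the
loading columns: L H with H orthogonal gives the same model covariance
L L^T + Psi. Varimax picks the rotation that maximizes the variance of the
squared loadings per factor ("simple structure"). Even after rotation, each
column can still be reflected (multiplied by -1) and the columns permuted
without changing anything, so loadings fitted separately per group are not
directly comparable. This module matches columns across groups by absolute
Pearson correlation, solving the resulting assignment problem either with
the Hungarian algorithm or by exhaustive enumeration (the latter doubles as
a small-scale oracle: the enumeration space has 2^(KM) (K!)^M candidates).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "AlignmentMap",
    "varimax",
    "varimax_criterion",
    "alignment_cost",
    "align_hungarian",
    "align_exhaustive",
    "apply_alignment",
]


@dataclass
class AlignmentMap:
    """Per-group column permutation and sign flips making loadings comparable.

    ``permutations[m][k]`` is the source column of group m placed at aligned
    position k; ``signs[m][k]`` the factor in {-1, +1} applied to it. The
    reference group's entry is the identity with all +1 signs.
    """

    permutations: list[np.ndarray]
    signs: list[np.ndarray]
    reference_group: int

    def __post_init__(self) -> None:
        self.permutations = [np.asarray(p, dtype=int) for p in self.permutations]
        self.signs = [np.asarray(s, dtype=int) for s in self.signs]
        k = self.permutations[0].size
        for p, s in zip(self.permutations, self.signs):
            if sorted(p.tolist()) != list(range(k)):
                raise ValueError(f"not a permutation of 0..{k - 1}: {p.tolist()}")
            if not np.all(np.isin(s, (-1, 1))):
                raise ValueError("signs must be -1 or +1")
        ref = self.permutations[self.reference_group]
        if not np.array_equal(ref, np.arange(k)) or np.any(
            self.signs[self.reference_group] != 1
        ):
            raise ValueError("reference group map must be the identity")

    def to_dict(self) -> dict:
        return {
            "permutations": [p.tolist() for p in self.permutations],
            "signs": [s.tolist() for s in self.signs],
            "reference_group": self.reference_group,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentMap":
        return cls(
            [np.asarray(p) for p in d["permutations"]],
            [np.asarray(s) for s in d["signs"]],
            int(d["reference_group"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def varimax_criterion(L: np.ndarray) -> float:
    """Varimax objective: sum over columns of the variance of squared loadings."""
    L = np.asarray(L, dtype=float)
    d = L.shape[0]
    sq = L ** 2
    return float(np.sum((sq ** 2).sum(axis=0) / d - (sq.sum(axis=0) / d) ** 2))


def _varimax_once(A: np.ndarray, H0: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """SVD-based varimax iteration from a given starting rotation."""
    d = A.shape[0]
    H = H0
    crit = 0.0
    for _ in range(max_iter):
        B = A @ H
        grad = A.T @ (B ** 3 - B * ((B ** 2).sum(axis=0) / d))
        u, s, vt = np.linalg.svd(grad)
        H = u @ vt
        new = s.sum()
        if new <= crit * (1.0 + tol):
            break
        crit = new
    return H


def varimax(
    L: np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax-rotate a loading matrix.

    Parameters
    ----------
    L : ndarray of shape (D, K)
    kaiser : bool
        Normalize each row by its communality (root sum of squared
        loadings) before rotating and undo afterwards, so that every
        variable carries equal weight in the criterion.
    tol, max_iter :
        Convergence controls of the iterative rotation.

    Returns
    -------
    rotated : ndarray of shape (D, K), equal to ``L @ H``.
    H : ndarray of shape (K, K), orthogonal.

    Notes
    -----
    The standard iteration can stall in a non-global stationary point, so a
    fixed small set of deterministic random restarts is run and the rotation
    with the highest criterion kept.
    """
    L = np.asarray(L, dtype=float)
    d, k = L.shape
    if k < 1:
        raise ValueError("need at least one factor column")
    if k == 1:
        return L.copy(), np.eye(1)
    if kaiser:
        comm = np.sqrt((L ** 2).sum(axis=1))
        if np.any(comm <= 0):
            rows = np.flatnonzero(comm <= 0).tolist()
            raise ValueError(f"zero-communality rows {rows} with Kaiser normalization")
        A = L / comm[:, None]
    else:
        A = L

    starts = [np.eye(k)]
    rng = np.random.default_rng(k * 1000 + d)  # fixed: restarts, not data-dependent
    for _ in range(4):
        q, _ = np.linalg.qr(rng.standard_normal((k, k)))
        starts.append(q)
    best_H, best_crit = None, -np.inf
    for H0 in starts:
        H = _varimax_once(A, H0, tol, max_iter)
        c = varimax_criterion(A @ H)
        if c > best_crit:
            best_H, best_crit = H, c
    return L @ best_H, best_H


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two columns; 0 when either is constant."""
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0 or nb == 0:
        return 0.0
    return float(da @ db / (na * nb))


def alignment_cost(L_ref: np.ndarray, L_tgt: np.ndarray) -> np.ndarray:
    """K x K assignment cost: cost[a, b] = -|corr(L_ref[:, a], L_tgt[:, b])|."""
    L_ref = np.asarray(L_ref, dtype=float)
    L_tgt = np.asarray(L_tgt, dtype=float)
    if L_ref.shape != L_tgt.shape:
        raise ValueError("loading matrices must share shape")
    k = L_ref.shape[1]
    cost = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            cost[a, b] = -abs(_column_corr(L_ref[:, a], L_tgt[:, b]))
    return cost


def _signed_corr(L_ref: np.ndarray, L_tgt: np.ndarray) -> np.ndarray:
    k = L_ref.shape[1]
    c = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            c[a, b] = _column_corr(L_ref[:, a], L_tgt[:, b])
    return c


def align_hungarian(L_list: list[np.ndarray], reference: int = 0) -> AlignmentMap:
    """Align each group's columns to the reference group by optimal assignment.

    For every non-reference group the K x K problem of matching its columns
    to the reference columns — minimizing the summed :func:`alignment_cost`,
    i.e. maximizing total absolute correlation — is solved exactly with the
    Hungarian algorithm. The sign of each matched pair is the sign of the
    (raw) correlation; zero correlation resolves to +1.
    """
    k = L_list[reference].shape[1]
    perms, signs = [], []
    for m, L in enumerate(L_list):
        if m == reference:
            perms.append(np.arange(k))
            signs.append(np.ones(k, dtype=int))
            continue
        cost = alignment_cost(L_list[reference], L)
        row, col = linear_sum_assignment(cost)
        perm = np.empty(k, dtype=int)
        sign = np.empty(k, dtype=int)
        corr = _signed_corr(L_list[reference], L)
        for a, b in zip(row, col):
            perm[a] = b
            sign[a] = 1 if corr[a, b] >= 0 else -1
        perms.append(perm)
        signs.append(sign)
    return AlignmentMap(perms, signs, reference)


def alignment_similarity(L_list: list[np.ndarray], amap: AlignmentMap) -> float:
    """Total signed correlation to the reference after applying the map."""
    ref = L_list[amap.reference_group]
    total = 0.0
    for m, L in enumerate(L_list):
        if m == amap.reference_group:
            continue
        aligned = apply_alignment(L, None, (amap.permutations[m], amap.signs[m]))[0]
        for kk in range(ref.shape[1]):
            total += _column_corr(ref[:, kk], aligned[:, kk])
    return total


def align_exhaustive(L_list: list[np.ndarray], reference: int = 0) -> AlignmentMap:
    """Globally optimal alignment by enumerating all sign/permutation combos.

    Walks the full product space of per-group column permutations and sign
    vectors — 2^(KM) (K!)^M candidates — and returns the one with maximal
    total signed correlation to the reference. Guarded to K <= 4 and M <= 3;
    beyond that use :func:`align_hungarian`.
    """
    m_total = len(L_list)
    k = L_list[reference].shape[1]
    if k > 4 or m_total > 3:
        raise ValueError(
            f"enumeration of 2^(K*M) * (K!)^M candidates infeasible for "
            f"K={k}, M={m_total}; use align_hungarian"
        )
    perm_list = list(itertools.permutations(range(k)))
    sign_list = list(itertools.product((1, -1), repeat=k))  # +1 first: tie-break
    # Candidate score per group: total signed correlation to the reference
    # for each (perm, sign) pair. The reference group's own candidates score
    # zero, matching its fixed identity map in the returned AlignmentMap.
    group_scores = []
    for m, L in enumerate(L_list):
        scores = np.zeros((len(perm_list), len(sign_list)))
        if m != reference:
            corr = _signed_corr(L_list[reference], L)
            for pi, perm in enumerate(perm_list):
                for si, sign in enumerate(sign_list):
                    scores[pi, si] = sum(
                        sign[a] * corr[a, perm[a]] for a in range(k)
                    )
        group_scores.append(scores.ravel())
    # Full enumeration over the product space (vectorized outer sums).
    total = group_scores[0]
    for s in group_scores[1:]:
        total = np.add.outer(total, s).ravel()
    flat_best = int(np.argmax(total))
    # Decode the flat product-space index back to per-group candidates.
    n_cand = len(perm_list) * len(sign_list)
    idx = []
    for _ in range(m_total):
        idx.append(flat_best % n_cand)
        flat_best //= n_cand
    idx = idx[::-1]
    perms, signs = [], []
    for m in range(m_total):
        if m == reference:
            perms.append(np.arange(k))
            signs.append(np.ones(k, dtype=int))
            continue
        pi, si = divmod(idx[m], len(sign_list))
        perms.append(np.asarray(perm_list[pi], dtype=int))
        signs.append(np.asarray(sign_list[si], dtype=int))
    return AlignmentMap(perms, signs, reference)


def apply_alignment(
    L: np.ndarray,
    scores: np.ndarray | None,
    map_entry: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply one group's (permutation, signs) jointly to loadings and scores.

    Column k of the output is ``signs[k] * L[:, permutations[k]]`` (same for
    the score matrix), so the reconstruction L S^T is unchanged.
    """
    perm, sign = map_entry
    perm = np.asarray(perm, dtype=int)
    sign = np.asarray(sign, dtype=float)
    L_new = np.asarray(L, dtype=float)[:, perm] * sign
    s_new = None
    if scores is not None:
        s_new = np.asarray(scores, dtype=float)[:, perm] * sign
    return L_new, s_new
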