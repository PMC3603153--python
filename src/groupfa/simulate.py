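"""Seeded synthetic cohorts from the group factor analysis generative model.

Every subject draws a group label from the proportion vector, a standard
normal K-vector of factor scores, and shared diagonal Gaussian noise:
x = mu_j + L_j f + u. Ground truth (parameters, labels, scores) is retained
so that fitting, rotation and alignment can be tested end to end by
parameter recovery, without any external dataset.

:func:`make_ad_like_spec` builds a cohort shaped like a dementia
morphometry study: 15 subcortical volume-ratio features (7 bilateral pairs
plus a brainstem/ventricle measure), three diagnostic groups (healthy
controls, very mild and moderate disease) with proportions
(75.96, 16.83, 7.21)%, simple-structure loadings in which left/right
homologues load on the same factor, and patient group means shifted
downward on the structures that atrophy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .em import MFAParams
from .preprocess import FeatureMatrix, GroupLabels

__all__ = [
    "SyntheticSpec",
    "generate",
    "make_ad_like_spec",
    "make_recovery_spec",
    "AD_LIKE_FEATURES",
]

AD_LIKE_FEATURES = [
    "left_hippocampus", "right_hippocampus",
    "left_amygdala", "right_amygdala",
    "left_accumbens", "right_accumbens",
    "left_putamen", "right_putamen",
    "left_pallidum", "right_pallidum",
    "left_caudate", "right_caudate",
    "left_thalamus", "right_thalamus",
    "brainstem_ventricle",
]

# factor index per feature: 0 = limbic, 1 = basal ganglia, 2 = diencephalic
_AD_LIKE_FACTOR = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 2, 2, 2]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic cohort.

    ``fixed_sizes=False`` samples group sizes from a categorical label per
    subject (matching the generative model); ``True`` uses deterministic
    largest-remainder counts, handy for exactly reproducible fixtures.
    """

    n_subjects: int
    true_params: MFAParams
    seed: int
    label_names: list[str] = field(default_factory=list)
    fixed_sizes: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 2 * self.true_params.n_groups:
            raise ValueError("n_subjects too small for the number of groups")
        if not self.label_names:
            self.label_names = list(self.true_params.group_names)
        if len(self.label_names) != self.true_params.n_groups:
            raise ValueError("label_names length must match the number of groups")

    @property
    def proportions(self) -> np.ndarray:
        return self.true_params.proportions

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "label_names": self.label_names,
            "fixed_sizes": self.fixed_sizes,
            "true_params": self.true_params.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(
            n_subjects=int(d["n_subjects"]),
            true_params=MFAParams.from_dict(d["true_params"]),
            seed=int(d["seed"]),
            label_names=list(d["label_names"]),
            fixed_sizes=bool(d.get("fixed_sizes", False)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _fixed_counts(n: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n subjects to the groups."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate(
    spec: SyntheticSpec,
    feature_names: list[str] | None = None,
) -> tuple[FeatureMatrix, GroupLabels, np.ndarray]:
    """Draw one cohort; the same spec (incl. seed) gives identical output.

    Returns the feature matrix, the group labels, and the N x K matrix of
    true factor scores used to generate each subject.
    """
    params = spec.true_params
    m, d, k = params.loadings.shape
    rng = np.random.default_rng(spec.seed)
    if spec.fixed_sizes:
        counts = _fixed_counts(spec.n_subjects, params.proportions)
        labels = np.repeat(np.arange(1, m + 1), counts)
    else:
        labels = None
        for _ in range(10):
            cand = rng.choice(m, size=spec.n_subjects, p=params.proportions) + 1
            if np.all(np.bincount(cand, minlength=m + 1)[1:] > 0):
                labels = cand
                break
        if labels is None:
            raise RuntimeError(
                "a group came up empty in 10 consecutive label draws; "
                "increase n_subjects or the smallest proportion"
            )
    scores = rng.standard_normal((spec.n_subjects, k))
    noise = rng.standard_normal((spec.n_subjects, d)) * np.sqrt(params.psi)
    values = params.means[labels - 1] + np.einsum(
        "ndk,nk->nd", params.loadings[labels - 1], scores
    ) + noise
    if feature_names is None:
        feature_names = [f"feat{i + 1:02d}" for i in range(d)]
    X = FeatureMatrix(values, feature_names,
                      [f"S{i:05d}" for i in range(spec.n_subjects)])
    return X, GroupLabels(labels, spec.label_names), scores


def make_ad_like_spec(
    n_subjects: int = 416,
    seed: int = 0,
    fixed_sizes: bool = False,
) -> SyntheticSpec:
    """Cohort spec emulating a three-group dementia morphometry study.

    D = 15 features, K = 3 factors, M = 3 groups with proportions
    (75.96, 16.83, 7.21)%. Loadings have simple structure — one dominant
    entry per row, bilateral structures sharing a factor — with a dominant
    loading of 0.8 in controls, weakened to 0.7 on the limbic factor in the
    patient groups. Patient means are shifted downward (0.5-1 pooled SD) on
    the structures known to atrophy (hippocampus, thalamus, putamen most),
    so the groups overlap and posterior responsibilities stay non-binary.
    Noise variances span 0.30-0.45, giving communalities near 0.6 and total
    feature variances near 1.
    """
    d, k, m = 15, 3, 3
    proportions = np.array([0.7596, 0.1683, 0.0721])
    loadings = np.zeros((m, d, k))
    for row, fac in enumerate(_AD_LIKE_FACTOR):
        loadings[0, row, fac] = 0.8
        loadings[1, row, fac] = 0.7 if fac == 0 else 0.8
        loadings[2, row, fac] = 0.7 if fac == 0 else 0.8
    means = np.zeros((m, d))
    limbic = [i for i, f in enumerate(_AD_LIKE_FACTOR) if f == 0]
    means[1, limbic] = -0.5
    hippo_thal_put = [0, 1, 6, 7, 12, 13]
    other_limbic = [2, 3, 4, 5]
    means[2, hippo_thal_put] = -1.0
    means[2, other_limbic] = -0.6
    psi = np.linspace(0.30, 0.45, d)
    params = MFAParams(loadings, means, psi, proportions,
                       group_names=["NL", "vAD", "AD"])
    return SyntheticSpec(
        n_subjects=n_subjects,
        true_params=params,
        seed=seed,
        label_names=["NL", "vAD", "AD"],
        fixed_sizes=fixed_sizes,
    )


def make_recovery_spec(n_subjects: int = 2000, seed: int = 0) -> SyntheticSpec:
    """Balanced variant of the AD-like cohort for parameter-recovery studies.

    Same loadings, means and noise as :func:`make_ad_like_spec` but equal
    group proportions, the conventional design for measuring estimator
    error: every group's loadings are estimated from the same number of
    subjects, so recovery error reflects the estimator rather than the
    cohort's group imbalance.
    """
    base = make_ad_like_spec(n_subjects=n_subjects, seed=seed)
    p = base.true_params
    m = p.n_groups
    params = MFAParams(p.loadings.copy(), p.means.copy(), p.psi.copy(),
                       np.full(m, 1.0 / m), group_names=list(p.group_names))
    return SyntheticSpec(n_subjects, params, seed,
                         label_names=list(base.label_names))
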