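"""Latent-class structure, covariate regression of membership, scoring weights.

The canonical three-class structure mirrors the response strategies test-takers
may use in a high-stakes assessment:

* ``S&F``    -- categories chosen from substantive traits *and* faking
                (the reference class),
* ``S-only`` -- substantive traits only,
* ``F-only`` -- faking only.

A class is defined purely by the set of latent dimensions that are active in
its measurement model; slopes of inactive dimensions are fixed to 0 through a
binary mask, which makes class identity structural (no label switching).
Class membership can be predicted from person covariates with a latent
multinomial logistic regression whose reference-class coefficients are fixed
to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .model_core import ScoringWeights

SF, S_ONLY, F_ONLY = "S&F", "S-only", "F-only"
CANONICAL_LABELS = (SF, S_ONLY, F_ONLY)


@dataclass(frozen=True)
class LatentClass:
    label: str
    active_dims: tuple  # latent dimension indices entering this class's model

    def __post_init__(self):
        if len(self.active_dims) == 0:
            raise ValueError(f"class {self.label!r} has an empty active set")


@dataclass(frozen=True)
class ClassSpec:
    """Ordered latent classes with their active-dimension sets."""

    classes: tuple
    n_traits: int
    reference: str = SF

    def __post_init__(self):
        if len(self.classes) == 0:
            raise ValueError("need at least one class")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate class labels")
        if self.reference not in labels:
            # when the nominal reference is absent, the first class takes over
            object.__setattr__(self, "reference", labels[0])
        D = self.n_traits + 1
        for c in self.classes:
            if any(d < 0 or d >= D for d in c.active_dims):
                raise ValueError(f"class {c.label!r}: dimension index out of range")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def labels(self) -> list:
        return [c.label for c in self.classes]

    @property
    def faking_dim(self) -> int:
        return self.n_traits

    @property
    def reference_index(self) -> int:
        return self.labels.index(self.reference)

    def subset(self, labels) -> "ClassSpec":
        keep = tuple(c for c in self.classes if c.label in labels)
        ref = self.reference if self.reference in labels else keep[0].label
        return ClassSpec(keep, self.n_traits, ref)


def three_class_spec(n_traits: int = 3) -> ClassSpec:
    """The full mixture: S&F (reference), S-only, F-only."""
    traits = tuple(range(n_traits))
    fak = n_traits
    return ClassSpec(
        (
            LatentClass(SF, traits + (fak,)),
            LatentClass(S_ONLY, traits),
            LatentClass(F_ONLY, (fak,)),
        ),
        n_traits,
    )


def single_class_spec(kind: str, n_traits: int = 3) -> ClassSpec:
    """Non-mixture special cases: 'sf' (traits+faking), 's', or 'f'."""
    traits = tuple(range(n_traits))
    fak = n_traits
    active = {"sf": traits + (fak,), "s": traits, "f": (fak,)}
    if kind not in active:
        raise ValueError(f"unknown non-mixture model {kind!r}")
    label = {"sf": SF, "s": S_ONLY, "f": F_ONLY}[kind]
    return ClassSpec((LatentClass(label, active[kind]),), n_traits, label)


def model_spec(name: str, n_traits: int = 3) -> ClassSpec:
    """Registry of the four fitted models: mix | sf | s | f."""
    if name == "mix":
        return three_class_spec(n_traits)
    return single_class_spec(name, n_traits)


def build_class_masks(spec: ClassSpec, item_scale_map) -> np.ndarray:
    """Binary (C, I, D) mask: dimension d is active for item i in class c iff
    d belongs to the class's active set AND d is the item's measured trait or
    the faking dimension."""
    item_scale_map = np.asarray(item_scale_map, dtype=int)
    I = item_scale_map.shape[0]
    D = spec.n_traits + 1
    if np.any(item_scale_map < 0) or np.any(item_scale_map >= spec.n_traits):
        raise ValueError("item_scale_map refers to an unknown trait")
    mask = np.zeros((spec.n_classes, I, D))
    for c, cls in enumerate(spec.classes):
        for d in cls.active_dims:
            if d == spec.faking_dim:
                mask[c, :, d] = 1.0
            else:
                mask[c, item_scale_map == d, d] = 1.0
    return mask


# ---------------------------------------------------------------------------
# latent multinomial regression of class membership
# ---------------------------------------------------------------------------


@dataclass
class LatentRegression:
    """pi_nc = softmax_c(beta0_c + x_n' beta[:, c]); reference column fixed 0."""

    beta0: np.ndarray
    beta: np.ndarray
    reference_index: int = 0

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2 or self.beta.shape[1] != self.beta0.shape[0]:
            raise ValueError("beta must be (P, C) matching beta0 length C")
        if not np.all(np.isfinite(self.beta0)) or not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite regression coefficients")
        r = self.reference_index
        if self.beta0[r] != 0 or np.any(self.beta[:, r] != 0):
            raise ValueError("reference-class coefficients must be fixed to 0")

    @property
    def n_classes(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[0]


def class_probabilities(reg: LatentRegression, x) -> np.ndarray:
    """Multinomial-logit class probabilities for one person (P-vector input,
    C-vector output) or a whole sample ((N, P) input, (N, C) output)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    eta = reg.beta0[None, :] + X @ reg.beta
    p = softmax(eta, axis=1)  # max-subtraction inside scipy guards overflow
    return p[0] if squeeze else p


@dataclass
class ClassState:
    """Sampled memberships zeta (N,) and membership probabilities pi (N, C)."""

    zeta: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        self.zeta = np.asarray(self.zeta, dtype=int)
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.allclose(self.pi.sum(axis=1), 1.0):
            raise ValueError("pi rows must sum to 1")
        C = self.pi.shape[1]
        if np.any(self.zeta < 0) or np.any(self.zeta >= C):
            raise ValueError("zeta outside class range")


# ---------------------------------------------------------------------------
# scoring-weight construction
# ---------------------------------------------------------------------------


def build_trait_weights(K: int) -> np.ndarray:
    """Evenly spaced substantive-trait scoring weights (0, 1, ..., K)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return np.arange(K + 1, dtype=float)


def rescale_desirability(mean_ratings, rating_min: float, rating_max: float) -> np.ndarray:
    """Linearly map mean desirability ratings onto the common 0..6 metric.

    The *possible* range of the rating instrument (not the observed min/max)
    anchors the transform, so the instrument's endpoints map to exactly 0 and 6.
    """
    r = np.asarray(mean_ratings, dtype=float)
    if rating_min >= rating_max:
        raise ValueError("rating_min must be < rating_max")
    if np.any(r < rating_min) or np.any(r > rating_max):
        raise ValueError("ratings outside the declared instrument range")
    return 6.0 * (r - rating_min) / (rating_max - rating_min)


def build_scoring_weights(item_scale_map, faking_rows, K: int, n_traits: int) -> ScoringWeights:
    """Assemble per-item S_i matrices: trait row (0..K) on the measured trait,
    zeros elsewhere, and the given desirability row on the faking dimension."""
    item_scale_map = np.asarray(item_scale_map, dtype=int)
    faking_rows = np.asarray(faking_rows, dtype=float)
    I = item_scale_map.shape[0]
    if faking_rows.shape != (I, K + 1):
        raise ValueError("faking_rows must be (I, K+1)")
    S = np.zeros((I, n_traits + 1, K + 1))
    tw = build_trait_weights(K)
    for i in range(I):
        S[i, item_scale_map[i]] = tw
        S[i, n_traits] = faking_rows[i]
    return ScoringWeights(S, n_traits)
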