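"""Probability machinery for the (mixture) multidimensional nominal response model.

The multidimensional nominal response model (MNRM) describes the probability
that person ``n`` selects category ``k`` of item ``i`` by a softmax over
category logits

    logit_k = (alpha_i ∘ s_ik)' theta_n + gamma_ik

where ``alpha_i`` holds the item's slopes on ``D`` latent dimensions, ``s_ik``
are fixed scoring weights that link category ``k`` to each dimension,
``theta_n`` is the person's vector of latent scores and ``gamma_ik`` is an
item-category intercept.  Substantive trait dimensions use evenly spaced
scoring weights ``0..K`` (the partial credit pattern); a faking dimension uses
per-item category desirabilities on a 0..6 metric.

The mixture extension attaches one latent class per person.  A class
determines which dimensions enter the measurement model through a binary slope
mask (e.g. traits+faking, traits only, faking only) and carries its own
intercepts, while non-masked slopes are shared between classes.  The marginal
probability of a response vector is the class-probability-weighted average of
the class-conditional probabilities.

Everything here is pure computation in log space; it is consumed by the
estimation, simulator and fit-metric layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

MISSING = -1  # missing-response code inside ResponseMatrix.values


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ResponseMatrix:
    """N persons x I items of integer categories 0..K (``MISSING`` = absent).

    ``item_scale_map[i]`` gives the index of the substantive trait measured by
    item ``i``.
    """

    values: np.ndarray
    K: int
    item_scale_map: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        self.item_scale_map = np.asarray(self.item_scale_map, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("responses must be a 2-D person x item matrix")
        n, i = self.values.shape
        if n < 1 or i < 1 or self.K < 1:
            raise ValueError("need N >= 1, I >= 1, K >= 1")
        if self.item_scale_map.shape != (i,):
            raise ValueError("item_scale_map must have one entry per item")
        obs = self.values[self.values != MISSING]
        if obs.size and (obs.min() < 0 or obs.max() > self.K):
            raise ValueError(f"responses outside 0..{self.K}")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        return self.values != MISSING


@dataclass
class ScoringWeights:
    """Per-item D x (K+1) scoring-weight matrices ``S_i``, stacked as (I, D, K+1).

    Dimensions 0..n_traits-1 are substantive traits, dimension ``n_traits`` is
    faking.  Trait rows of traits an item does not measure are all zero; the
    measured trait's row is ``(0, 1, ..., K)`` unless explicitly overridden.
    """

    S: np.ndarray
    n_traits: int

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 3:
            raise ValueError("S must be (I, D, K+1)")
        if self.S.shape[1] != self.n_traits + 1:
            raise ValueError("S must have n_traits + 1 dimension rows")

    @property
    def n_items(self) -> int:
        return self.S.shape[0]

    @property
    def n_dims(self) -> int:
        return self.S.shape[1]

    @property
    def K(self) -> int:
        return self.S.shape[2] - 1

    @property
    def faking_dim(self) -> int:
        return self.n_traits

    @property
    def faking_rows(self) -> np.ndarray:
        """(I, K+1) desirability weights of the faking dimension."""
        return self.S[:, self.faking_dim, :]

    def validate_structure(self, item_scale_map: np.ndarray) -> None:
        """Check the zero-structure of trait rows against the item-trait map."""
        for i in range(self.n_items):
            for d in range(self.n_traits):
                if d != item_scale_map[i] and np.any(self.S[i, d] != 0):
                    raise ValueError(
                        f"item {i}: nonzero weights on trait {d} "
                        f"but item measures trait {item_scale_map[i]}"
                    )


@dataclass
class ItemSlopes:
    """I x D nonnegative slope matrix; class-specific views are mask * alpha."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha < 0):
            raise ValueError("slopes must be nonnegative")


@dataclass
class Intercepts:
    """Class-specific item-category intercepts, shape (C, I, K+1), gamma[...,0]=0."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim != 3:
            raise ValueError("gamma must be (C, I, K+1)")
        if np.any(self.gamma[:, :, 0] != 0):
            raise ValueError("first-category intercepts must be 0 (identification)")


@dataclass
class PersonParams:
    """theta (N, D) latent scores; Sigma correlation matrix; mu fixed at 0."""

    theta: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        d = self.Sigma.shape[0]
        if self.Sigma.shape != (d, d) or not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be square symmetric")
        if not np.allclose(np.diag(self.Sigma), 1.0):
            raise ValueError("Sigma must have unit diagonal")
        np.linalg.cholesky(self.Sigma)  # raises if not positive definite


@dataclass
class ModelParams:
    """Bundle of everything the likelihood needs.

    masks is the (C, I, D) binary active-dimension array; gamma is (C, I, K+1).
    """

    weights: ScoringWeights
    alpha: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    masks: np.ndarray
    Sigma: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.masks.shape[0]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def category_logit(alpha_i, s_ik, theta_n, gamma_ik: float) -> float:
    """Log-numerator of the softmax: (alpha_i ∘ s_ik)' theta_n + gamma_ik."""
    alpha_i = np.asarray(alpha_i, dtype=float)
    s_ik = np.asarray(s_ik, dtype=float)
    theta_n = np.asarray(theta_n, dtype=float)
    if not (alpha_i.shape == s_ik.shape == theta_n.shape):
        raise ValueError("alpha, s and theta must share length D")
    return float((alpha_i * s_ik) @ theta_n + gamma_ik)


def masked_slope_weights(alpha: np.ndarray, S: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Combine slopes, scoring weights and class masks: (C, I, D, K+1)."""
    # A[c,i,d,k] = mask[c,i,d] * alpha[i,d] * S[i,d,k]
    return masks[:, :, :, None] * (alpha[None, :, :, None] * S[None, :, :, :])


def category_logits(theta: np.ndarray, A: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """All category logits, shape (C, N, I, K+1)."""
    z = np.einsum("nd,cidk->cnik", theta, A)
    return z + gamma[:, None, :, :]


def _log_softmax(x: np.ndarray) -> np.ndarray:
    return x - logsumexp(x, axis=-1, keepdims=True)


def class_conditional_prob(item: int, person: int, cls: int, params: ModelParams) -> np.ndarray:
    """Category-probability vector p(Y_ni = k | zeta_n = c), length K+1."""
    S_i = params.weights.S[item]
    a = params.masks[cls, item] * params.alpha[item]
    logits = (a[:, None] * S_i).T @ params.theta[person] + params.gamma[cls, item]
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite category logits")
    return np.exp(_log_softmax(logits))


def mixture_prob(item: int, person: int, class_probs, params: ModelParams) -> np.ndarray:
    """Mixture category probabilities sum_c p(zeta=c) p(Y=k | c)."""
    class_probs = np.asarray(class_probs, dtype=float)
    if np.any(class_probs < 0):
        raise ValueError("class probabilities must be nonnegative")
    if not np.isclose(class_probs.sum(), 1.0):
        raise ValueError("class probabilities must sum to 1")
    out = np.zeros(params.weights.K + 1)
    for c in range(params.n_classes):
        if class_probs[c] > 0:
            out += class_probs[c] * class_conditional_prob(item, person, c, params)
    return out


# ---------------------------------------------------------------------------
# vectorized likelihood
# ---------------------------------------------------------------------------


def loglik_class_item(params: ModelParams, responses: ResponseMatrix) -> np.ndarray:
    """Log p(y_ni | zeta_n = c) for every class/person/item: shape (C, N, I).

    Missing responses contribute 0 (skipped under the missing-at-random
    contract).
    """
    A = masked_slope_weights(params.alpha, params.weights.S, params.masks)
    lp = _log_softmax(category_logits(params.theta, A, params.gamma))
    y = np.where(responses.observed_mask, responses.values, 0)
    C = params.n_classes
    idx = np.broadcast_to(y[None, :, :, None], (C,) + y.shape + (1,))
    ll = np.take_along_axis(lp, idx, axis=-1)[..., 0]
    ll = np.where(responses.observed_mask[None, :, :], ll, 0.0)
    return ll


def person_class_loglik(params: ModelParams, responses: ResponseMatrix) -> np.ndarray:
    """Log p(y_n | zeta_n = c), the within-class item product: shape (N, C)."""
    return loglik_class_item(params, responses).sum(axis=2).T


def marginal_person_loglik(L_nc: np.ndarray, log_pi: np.ndarray) -> np.ndarray:
    """Person-level mixture: logsumexp_c [log pi_nc + L_nc], shape (N,)."""
    return logsumexp(log_pi + L_nc, axis=1)


def responsibilities(L_nc: np.ndarray, log_pi: np.ndarray) -> np.ndarray:
    """Posterior class probabilities p(zeta_n = c | y_n), rows sum to 1."""
    w = log_pi + L_nc
    w = w - logsumexp(w, axis=1, keepdims=True)
    return np.exp(w)


def log_likelihood(
    responses: ResponseMatrix,
    params: ModelParams,
    mode: str = "marginal",
    class_probs=None,
    zeta: np.ndarray | None = None,
    per_person: bool = False,
):
    """Model log-likelihood of a response matrix.

    mode="marginal": one latent class per person, marginalized out -- the
    likelihood is the product over persons of
    sum_c pi_nc * prod_i p(y_ni | c).  ``class_probs`` is a C-vector shared by
    all persons or an (N, C) matrix of person-specific probabilities.

    mode="class_conditional": conditions on known memberships ``zeta``
    (scalar class index or N-vector).
    """
    L_nc = person_class_loglik(params, responses)
    n, C = L_nc.shape
    if mode == "marginal":
        if class_probs is None:
            class_probs = np.full(C, 1.0 / C)
        pi = np.asarray(class_probs, dtype=float)
        if np.any(pi < 0):
            raise ValueError("class probabilities must be nonnegative")
        if pi.ndim == 1:
            pi = np.broadcast_to(pi, (n, C))
        with np.errstate(divide="ignore"):
            log_pi = np.log(pi)
        out = marginal_person_loglik(L_nc, log_pi)
    elif mode == "class_conditional":
        if zeta is None:
            raise ValueError("class_conditional mode needs zeta")
        z = np.broadcast_to(np.asarray(zeta, dtype=int), (n,))
        out = L_nc[np.arange(n), z]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if per_person else float(out.sum())
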