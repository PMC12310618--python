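"""Synthetic-data generator for the mixture-model recovery study.

Emulates high-stakes personality-assessment data: by default 3 substantive
trait scales with 10 items each on a 7-point scale (categories 0..6), N=1500
test-takers, three latent response-strategy classes whose membership is driven
by three covariates (one null, one weak, one strong effect), under one of ten
class-proportion conditions.

Generation steps (per replication):

1. item slopes for the measured trait and faking drawn from U(0.5, 1);
2. trait scoring weights fixed at (0..6); faking scoring weights built from
   three shape families (monotone increasing, nonmonotone increasing with a
   peak at category 5, inverted-U with a peak at the midpoint), allocated
   round-robin within each trait scale, all spanning 0..6;
3. class-specific intercepts from sorted thresholds tau ~ U(-2, 2) accumulated
   as gamma_k = -(tau_1 + ... + tau_k), gamma_0 = 0, independently per class;
4. person parameters (3 traits + faking) from MVN(0, Sigma) with unit
   variances, trait-pair correlations {0.3, -0.3, 0} in randomized assignment
   and faking uncorrelated with the traits;
5. latent-regression slopes: null covariate 0, weak ~ N(1, 0.2^2), strong
   ~ N(2, 0.2^2), half of the nonzero slopes sign-flipped; intercepts solved
   so the expected class proportions match the condition;
6. covariates from independent standard normals;
7. class membership sampled from the person's multinomial-logit probabilities;
8. responses sampled from the class-conditional category distribution.

Classes with a target proportion of 0 are excluded from generation entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .model_core import (
    Intercepts,
    ItemSlopes,
    ModelParams,
    PersonParams,
    ResponseMatrix,
    ScoringWeights,
    category_logits,
    masked_slope_weights,
)
from .mixture_spec import (
    CANONICAL_LABELS,
    ClassSpec,
    ClassState,
    LatentRegression,
    build_class_masks,
    build_scoring_weights,
    class_probabilities,
    three_class_spec,
)

#: The ten class-proportion conditions (S&F, S-only, F-only).
CONDITIONS = {
    1: (1 / 3, 1 / 3, 1 / 3),
    2: (0.60, 0.20, 0.20),
    3: (0.20, 0.60, 0.20),
    4: (0.20, 0.20, 0.60),
    5: (0.00, 0.50, 0.50),
    6: (0.50, 0.00, 0.50),
    7: (0.50, 0.50, 0.00),
    8: (1.00, 0.00, 0.00),
    9: (0.00, 1.00, 0.00),
    10: (0.00, 0.00, 1.00),
}

#: covariate effect sizes: |slope| ~ N(mean, 0.2^2); None = exactly 0
EFFECT_MEANS = {"null": None, "weak": 1.0, "strong": 2.0}


@dataclass
class SimulationDesign:
    n_traits: int = 3
    items_per_trait: int = 10
    K: int = 6
    n_persons: int = 1500
    condition: int = 1
    covariate_effects: tuple = ("null", "weak", "strong")
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.proportions)
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")

    @property
    def proportions(self) -> tuple:
        if isinstance(self.condition, int):
            return CONDITIONS[self.condition]
        return tuple(self.condition)

    @property
    def n_items(self) -> int:
        return self.n_traits * self.items_per_trait

    @property
    def item_scale_map(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_traits), self.items_per_trait)


@dataclass
class GroundTruth:
    """Everything the generator drew, packaged for recovery scoring.

    ``zeta`` and ``present_classes`` index the canonical three-class order
    (S&F, S-only, F-only); ``gamma`` holds intercepts for present classes only.
    """

    design: SimulationDesign
    alpha: np.ndarray  # (I, D) slope draws (entries off the measured trait unused)
    weights: ScoringWeights
    gamma: np.ndarray  # (C_present, I, K+1)
    theta: np.ndarray  # (N, D)
    Sigma: np.ndarray  # (D, D)
    reg: LatentRegression | None  # over present classes; None if single class
    X: np.ndarray  # (N, P)
    zeta: np.ndarray  # (N,) canonical class index
    pi: np.ndarray  # (N, C_present)
    present_classes: tuple  # canonical indices of generated classes
    class_spec: ClassSpec  # spec restricted to present classes


@dataclass
class SimulatedData:
    truth: GroundTruth
    responses: ResponseMatrix

    @property
    def X(self) -> np.ndarray:
        return self.truth.X


# ---------------------------------------------------------------------------
# individual generation steps
# ---------------------------------------------------------------------------


def draw_item_slopes(rng: np.random.Generator, I: int, D: int) -> ItemSlopes:
    """Slopes of substantive traits and faking, all from U(0.5, 1)."""
    return ItemSlopes(rng.uniform(0.5, 1.0, size=(I, D)))


def _shape_families(K: int) -> list:
    """The three desirability trajectories, each spanning 0..6.

    monotone: equidistant rise over all categories; nonmonotone increasing:
    equidistant rise peaking one category before the maximum, then one step
    back down; inverted-U: rise to the midpoint, mirrored descent.
    """
    if K < 2:
        raise ValueError("canonical shape families need K >= 2")
    mono = np.linspace(0.0, 6.0, K + 1)
    up = np.linspace(0.0, 6.0, K)
    nonmono = np.append(up, up[-2])
    half = K // 2
    rise = np.linspace(0.0, 6.0, half + 1)
    fall = np.linspace(6.0, 0.0, K - half + 1)[1:]
    inv_u = np.concatenate([rise, fall])
    return [mono, nonmono, inv_u]


def build_faking_weights(rng: np.random.Generator, items_per_scale: int, K: int = 6) -> np.ndarray:
    """Faking scoring-weight vectors for one trait scale, (items_per_scale, K+1).

    Items are allocated to the three shape families round-robin, so with 10
    items the counts are 4/3/3.  The generator argument is accepted for
    interface symmetry; the trajectories themselves are deterministic.
    """
    if items_per_scale < 3:
        raise ValueError("need at least 3 items per scale to place all three shapes")
    fams = _shape_families(K)
    return np.stack([fams[j % 3] for j in range(items_per_scale)])


def thresholds_to_intercepts(tau: np.ndarray) -> np.ndarray:
    """gamma_0 = 0, gamma_k = -(tau_1 + ... + tau_k) along the last axis."""
    tau = np.asarray(tau, dtype=float)
    g = -np.cumsum(tau, axis=-1)
    zero = np.zeros(tau.shape[:-1] + (1,))
    return np.concatenate([zero, g], axis=-1)


def draw_intercepts(rng: np.random.Generator, I: int, K: int, C: int) -> Intercepts:
    """Class-specific intercepts from sorted U(-2, 2) thresholds."""
    tau = np.sort(rng.uniform(-2.0, 2.0, size=(C, I, K)), axis=-1)
    return Intercepts(thresholds_to_intercepts(tau))


def make_true_sigma(rng: np.random.Generator, n_traits: int = 3) -> np.ndarray:
    """Unit-variance latent covariance: trait pairs get {0.3, -0.3, 0} in
    randomized assignment; faking is uncorrelated with the traits."""
    D = n_traits + 1
    Sigma = np.eye(D)
    pairs = [(a, b) for a in range(n_traits) for b in range(a + 1, n_traits)]
    vals = [0.3, -0.3, 0.0]
    rho = [vals[j % 3] for j in range(len(pairs))]
    rho = rng.permutation(rho)
    for (a, b), r in zip(pairs, rho):
        Sigma[a, b] = Sigma[b, a] = r
    return Sigma


def draw_person_params(rng: np.random.Generator, N: int, Sigma_true: np.ndarray) -> PersonParams:
    Sigma_true = np.asarray(Sigma_true, dtype=float)
    L = np.linalg.cholesky(Sigma_true)  # raises on non-PD
    theta = rng.standard_normal((N, Sigma_true.shape[0])) @ L.T
    return PersonParams(theta, Sigma_true)


def draw_regression_coefficients(
    rng: np.random.Generator,
    n_present: int,
    effect_spec: tuple = ("null", "weak", "strong"),
    reference_index: int = 0,
) -> LatentRegression:
    """Covariate slopes per effect size; exactly half of the nonzero slopes are
    sign-flipped.  Intercepts are left at 0 (solved for afterwards)."""
    P = len(effect_spec)
    beta = np.zeros((P, n_present))
    free = [c for c in range(n_present) if c != reference_index]
    signed_positions = []
    for p, eff in enumerate(effect_spec):
        mean = EFFECT_MEANS[eff]
        if mean is None:
            continue
        for c in free:
            beta[p, c] = rng.normal(mean, 0.2)
            signed_positions.append((p, c))
    flip = rng.permutation(len(signed_positions))[: len(signed_positions) // 2]
    for j in flip:
        p, c = signed_positions[j]
        beta[p, c] *= -1.0
    return LatentRegression(np.zeros(n_present), beta, reference_index)


def solve_intercepts_for_proportions(
    target,
    reg: LatentRegression,
    rng: np.random.Generator | None = None,
    n_mc: int = 120_000,
    tol: float = 0.005,
    max_iter: int = 500,
) -> LatentRegression:
    """Choose beta0 so that E_X[pi_c(X)] matches the target proportions.

    With all slopes zero the solution is the closed-form logit
    beta0_c = log(target_c / target_ref).  Otherwise a damped fixed-point
    iteration on a fixed Monte-Carlo sample of the standard-normal covariate
    distribution is used and verified to ``tol``.
    """
    target = np.asarray(target, dtype=float)
    if not np.isclose(target.sum(), 1.0):
        raise ValueError("target proportions must sum to 1")
    if np.any(target <= 0):
        raise ValueError("absent classes must be excluded before solving")
    r = reg.reference_index
    if np.all(reg.beta == 0):
        beta0 = np.log(target / target[r])
        return LatentRegression(beta0, reg.beta, r)
    if rng is None:
        rng = np.random.default_rng(0)
    X = rng.standard_normal((n_mc, reg.n_covariates))
    eta_x = X @ reg.beta
    beta0 = np.log(target / target[r])
    for _ in range(max_iter):
        p = softmax(beta0[None, :] + eta_x, axis=1).mean(axis=0)
        err = np.max(np.abs(p - target))
        if err < tol / 2:
            break
        beta0 = beta0 + np.log(target) - np.log(p)
        beta0 = beta0 - beta0[r]
    else:
        raise RuntimeError(
            f"intercept solver did not converge: target={target}, reached={p}"
        )
    return LatentRegression(beta0, reg.beta, r)


def assign_classes(rng: np.random.Generator, reg: LatentRegression, X: np.ndarray) -> ClassState:
    """Sample memberships from Cat(pi_n) with pi from the latent regression."""
    pi = class_probabilities(reg, X)
    u = rng.uniform(size=pi.shape[0])
    zeta = (pi.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return ClassState(zeta, pi)


def generate_responses(rng: np.random.Generator, truth: GroundTruth) -> ResponseMatrix:
    """Draw each response from the class-conditional categorical distribution
    of the person's true class."""
    design = truth.design
    masks = build_class_masks(truth.class_spec, design.item_scale_map)
    A = masked_slope_weights(truth.alpha, truth.weights.S, masks)
    logits = category_logits(truth.theta, A, truth.gamma)  # (C_present, N, I, K+1)
    probs = softmax(logits, axis=-1)
    N, I = design.n_persons, design.n_items
    present = list(truth.present_classes)
    values = np.zeros((N, I), dtype=int)
    local = np.searchsorted(present, truth.zeta)  # canonical -> local class index
    u = rng.uniform(size=(N, I))
    for c in range(len(present)):
        sel = local == c
        if not np.any(sel):
            continue
        cdf = probs[c, sel].cumsum(axis=-1)
        values[sel] = (cdf < u[sel, :, None]).sum(axis=-1)
    return ResponseMatrix(values, design.K, design.item_scale_map)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def simulate(design: SimulationDesign) -> SimulatedData:
    """Run generation steps 1-8 for one replication, fully seeded."""
    rng = np.random.default_rng(design.seed)
    D = design.n_traits + 1
    I = design.n_items

    alpha = draw_item_slopes(rng, I, D).alpha
    fak = np.vstack(
        [build_faking_weights(rng, design.items_per_trait, design.K)] * design.n_traits
    )
    weights = build_scoring_weights(design.item_scale_map, fak, design.K, design.n_traits)

    props = np.asarray(design.proportions)
    present = tuple(int(c) for c in np.flatnonzero(props > 0))
    full_spec = three_class_spec(design.n_traits)
    spec = full_spec.subset([CANONICAL_LABELS[c] for c in present])

    gamma = draw_intercepts(rng, I, design.K, len(present)).gamma
    Sigma = make_true_sigma(rng, design.n_traits)
    theta = draw_person_params(rng, design.n_persons, Sigma).theta

    P = len(design.covariate_effects)
    X = rng.standard_normal((design.n_persons, P))
    if len(present) == 1:
        reg = None
        pi = np.ones((design.n_persons, 1))
        zeta = np.full(design.n_persons, present[0])
    else:
        reg = draw_regression_coefficients(
            rng, len(present), design.covariate_effects, spec.reference_index
        )
        reg = solve_intercepts_for_proportions(props[list(present)], reg, rng)
        state = assign_classes(rng, reg, X)
        pi = state.pi
        zeta = np.asarray(present)[state.zeta]

    truth = GroundTruth(
        design=design,
        alpha=alpha,
        weights=weights,
        gamma=gamma,
        theta=theta,
        Sigma=Sigma,
        reg=reg,
        X=X,
        zeta=zeta,
        pi=pi,
        present_classes=present,
        class_spec=spec,
    )
    responses = generate_responses(rng, truth)
    return SimulatedData(truth, responses)
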