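"""Bayesian estimation of the mixture MNRM and its non-mixture special cases.

The sampler is an adaptive Metropolis-within-Gibbs scheme on the *marginal*
likelihood in which the discrete class membership zeta_n is summed out of

    p(y_n) = sum_c pi_nc * prod_i p(y_ni | zeta_n = c),

so person parameters theta_n (block-updated per person, vectorized over
persons), latent correlations (drawn exactly from their griddy full
conditionals, uniform prior subject to positive definiteness) and
latent-regression coefficients (block per non-reference class) are updated
against this marginal.  Item slopes and the class-specific item-category
intercepts are updated after drawing the memberships from their exact full
conditional (the current responsibilities), which renders all (class, item)
parameter blocks conditionally independent and lets their scalar moves run
vectorized; the memberships are discarded again afterwards (a partially
collapsed Gibbs scheme, equivalent to the fully augmented sampler).
Per-person class responsibilities are recovered from Bayes' rule at every
retained draw.

Two likelihood-invariant interweaving moves (a slope/score rescaling and a
latent-mean/intercept shear per dimension) traverse the ridges that plain
random-walk updates cross only slowly, and the latent regression is frozen at
uniform class probabilities for the first half of burnin so that the class
measurement models separate on the likelihood alone before class-proportion
feedback can starve a class.

Priors follow the reference analysis: slopes ~ N+(0, 2^2), intercepts
~ N(0, 5^2) with the first category fixed at 0, theta ~ MVN(0, Sigma) with
unit variances and pairwise-uniform correlations, regression coefficients
~ N(0, 2^2) with the reference class fixed at 0.

Proposal scales adapt toward standard acceptance targets during burnin only
(0.44 for scalar moves, 0.30 for small blocks) and are frozen afterwards, so
the retained chain is a valid time-homogeneous Markov chain.

The category-probability kernels are numba-compiled: each item loads on at
most two latent dimensions (its trait and faking), so the fused loops beat
dense einsum/softmax passes by a wide margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import solve_triangular

from .model_core import ModelParams, ResponseMatrix, ScoringWeights
from .mixture_spec import ClassSpec, build_class_masks

_SCALAR_TARGET = 0.44
_BLOCK_TARGET = 0.30


def _lse(x: np.ndarray, axis: int = -1, keepdims: bool = False) -> np.ndarray:
    """Minimal log-sum-exp (scipy's version carries too much call overhead
    for the sampler's inner loops)."""
    mx = np.max(x, axis=axis, keepdims=True)
    out = mx + np.log(np.sum(np.exp(x - mx), axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)


@njit(cache=True)
def _ll_all_kernel(theta, W, dims, gamma, y, obs):
    """Log p(y_ni | class c) for all classes: (C, N, I).

    W[c, i, 0/1, k] holds the class-masked products alpha * s for the item's
    trait slot and the faking slot; dims[i] gives the two theta columns.
    Missing responses contribute 0.
    """
    C, I, _, Kp1 = W.shape
    N = theta.shape[0]
    out = np.zeros((C, N, I))
    buf = np.empty(Kp1)
    for c in range(C):
        for n in range(N):
            for i in range(I):
                if not obs[n, i]:
                    continue
                t1 = theta[n, dims[i, 0]]
                t2 = theta[n, dims[i, 1]]
                m = -1.0e300
                for k in range(Kp1):
                    v = W[c, i, 0, k] * t1 + W[c, i, 1, k] * t2 + gamma[c, i, k]
                    buf[k] = v
                    if v > m:
                        m = v
                s = 0.0
                for k in range(Kp1):
                    s += np.exp(buf[k] - m)
                out[c, n, i] = buf[y[n, i]] - m - np.log(s)
    return out


@njit(cache=True)
def _ll_zeta_kernel(theta, W, dims, gamma, zeta, y, obs):
    """Log p(y_ni | zeta_n) under each person's own class: (N, I)."""
    _, I, _, Kp1 = W.shape
    N = theta.shape[0]
    out = np.zeros((N, I))
    buf = np.empty(Kp1)
    for n in range(N):
        c = zeta[n]
        for i in range(I):
            if not obs[n, i]:
                continue
            t1 = theta[n, dims[i, 0]]
            t2 = theta[n, dims[i, 1]]
            m = -1.0e300
            for k in range(Kp1):
                v = W[c, i, 0, k] * t1 + W[c, i, 1, k] * t2 + gamma[c, i, k]
                buf[k] = v
                if v > m:
                    m = v
            s = 0.0
            for k in range(Kp1):
                s += np.exp(buf[k] - m)
            out[n, i] = buf[y[n, i]] - m - np.log(s)
    return out


@dataclass
class PriorSpec:
    slope_sd: float = 2.0  # N+(0, sd^2), truncated to positive values
    intercept_sd: float = 5.0
    beta_sd: float = 2.0
    correlation: str = "uniform"  # "uniform" (pairwise U(-1,1) s.t. PD) or "lkj"

    def __post_init__(self):
        if min(self.slope_sd, self.intercept_sd, self.beta_sd) <= 0:
            raise ValueError("prior scales must be positive")
        if self.correlation not in ("uniform", "lkj"):
            raise ValueError("correlation prior must be 'uniform' or 'lkj'")


@dataclass
class SamplerConfig:
    chains: int = 4
    burnin: int = 2000
    iterations: int = 5000
    thinning: int = 1
    seed: int = 0
    adapt_interval: int = 25
    sweeps: int = 3  # person/item update sweeps per recorded iteration
    n_pilots: int = 3  # short pilot runs per chain; the best-likelihood state seeds the chain
    n_snapshots: int = 150  # thinned full-state snapshots kept for PPMC / recovery

    def __post_init__(self):
        if min(self.chains, self.burnin, self.iterations, self.thinning) < 1:
            raise ValueError("sampler counts must be positive")


#: settings mirroring the reference simulation (4 chains, 2000 burnin / 5000 kept)
SIMULATION_CONFIG = SamplerConfig()
#: heavier preset for empirical-scale data (12 chains, 5000 burnin / 10000 kept)
EMPIRICAL_CONFIG = SamplerConfig(chains=12, burnin=5000, iterations=10000)
#: reduced desk-scale preset used in examples and smoke runs
DESK_CONFIG = SamplerConfig(chains=2, burnin=500, iterations=1000)


@dataclass
class PosteriorResult:
    """Posterior draws plus everything downstream layers need.

    Draw arrays have leading axes (chains, draws).  ``resp_mean`` holds the
    posterior-mean class responsibilities; snapshots (``theta_draws``,
    ``resp_draws``) are thinned states used for posterior predictive checks
    and person-parameter recovery.
    """

    class_spec: ClassSpec
    weights: ScoringWeights
    item_scale_map: np.ndarray
    masks: np.ndarray
    active_dims: np.ndarray
    alpha_entries: list
    rho_pairs: list
    config: SamplerConfig
    priors: PriorSpec
    X: np.ndarray | None
    alpha_draws: np.ndarray  # (m, S, n_alpha)
    gamma_draws: np.ndarray  # (m, S, C, I, K)
    rho_draws: np.ndarray  # (m, S, n_pairs)
    beta_draws: np.ndarray  # (m, S, P1, C-1) non-reference columns
    beta_free_cols: list
    prop_draws: np.ndarray  # (m, S, C) per-draw person-mean responsibilities
    pointwise: np.ndarray  # (m, S, N) marginal per-person log-likelihood
    deviance: np.ndarray  # (m, S)
    resp_mean: np.ndarray  # (N, C)
    theta_mean: np.ndarray  # (N, D)
    theta_draws: np.ndarray  # (m, n_snap, N, D)
    resp_draws: np.ndarray  # (m, n_snap, N, C)
    rhat: dict
    converged: bool
    fixed_items: bool = False

    @property
    def n_classes(self) -> int:
        return self.masks.shape[0]

    @property
    def n_persons(self) -> int:
        return self.resp_mean.shape[0]

    @property
    def max_rhat(self) -> float:
        vals = [np.max(v) for v in self.rhat.values() if np.size(v)]
        return float(np.max(vals)) if vals else float("nan")

    def design_matrix(self) -> np.ndarray:
        n = self.n_persons
        if self.X is None:
            return np.ones((n, 1))
        return np.column_stack([np.ones(n), self.X])

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one group pooled across chains: (m*S, ...)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def mean_alpha(self) -> np.ndarray:
        I = self.item_scale_map.shape[0]
        D = self.weights.n_dims
        alpha = np.zeros((I, D))
        if self.alpha_draws.size:
            means = self.pooled("alpha_draws").mean(axis=0)
            for (i, d), v in zip(self.alpha_entries, means):
                alpha[i, d] = v
        return alpha

    def mean_gamma(self) -> np.ndarray:
        C, I = self.masks.shape[0], self.item_scale_map.shape[0]
        K = self.weights.K
        gamma = np.zeros((C, I, K + 1))
        if self.gamma_draws.size:
            gamma[:, :, 1:] = self.pooled("gamma_draws").mean(axis=0)
        return gamma

    def mean_sigma(self) -> np.ndarray:
        Da = len(self.active_dims)
        Sig = np.eye(Da)
        if self.rho_draws.size:
            r = self.pooled("rho_draws").mean(axis=0)
            for (a, b), v in zip(self.rho_pairs, r):
                Sig[a, b] = Sig[b, a] = v
        return Sig

    def mean_beta(self) -> np.ndarray:
        P1 = self.design_matrix().shape[1]
        beta = np.zeros((P1, self.n_classes))
        if self.beta_draws.size:
            b = self.pooled("beta_draws").mean(axis=0)
            for j, c in enumerate(self.beta_free_cols):
                beta[:, c] = b[:, j]
        return beta


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------


def rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, iterations) or (chains, iterations, ...);
    each chain is split in half, and R-hat = sqrt(((n-1)/n W + B/n) / W) is
    computed over the 2m half-chains for every trailing index.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    m, n = x.shape[:2]
    half = n // 2
    if half < 2:
        raise ValueError("need >= 4 iterations per chain")
    parts = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    mean = parts.mean(axis=1)
    W = parts.var(axis=1, ddof=1).mean(axis=0)
    B = half * mean.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    return np.where(W > 0, r, np.where(B > 0, np.inf, 1.0))


# ---------------------------------------------------------------------------
# adaptive scales
# ---------------------------------------------------------------------------


class _Adaptive:
    """Per-block log proposal scales with batchwise burnin-only adaptation."""

    def __init__(self, shape, init_scale, target):
        self.log_scale = np.full(shape, np.log(init_scale))
        self.target = target
        self.accepts = np.zeros(shape)
        self.tries = np.zeros(shape)
        self.batch = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def record(self, accepted, idx=None):
        if idx is None:
            self.accepts += accepted
            self.tries += 1
        else:
            self.accepts[idx] += accepted
            self.tries[idx] += 1

    def adapt(self):
        self.batch += 1
        delta = min(0.25, 2.0 / np.sqrt(self.batch))
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(self.tries > 0, self.accepts / np.maximum(self.tries, 1), self.target)
        self.log_scale += np.where(rate > self.target, delta, -delta)
        self.accepts[...] = 0.0
        self.tries[...] = 0.0


# ---------------------------------------------------------------------------
# single-chain sampler
# ---------------------------------------------------------------------------


class _Chain:
    def __init__(
        self,
        responses: ResponseMatrix,
        weights: ScoringWeights,
        masks: np.ndarray,
        X: np.ndarray | None,
        priors: PriorSpec,
        config: SamplerConfig,
        rng: np.random.Generator,
        fixed: dict | None = None,
    ):
        self.y = np.ascontiguousarray(responses.values.clip(0), dtype=np.int64)
        self.scale_map = np.asarray(responses.item_scale_map, dtype=int)
        self.obs = np.ascontiguousarray(responses.observed_mask)
        self.K = responses.K
        self.weights = weights
        self.S = weights.S
        self.masks = masks
        self.priors = priors
        self.config = config
        self.rng = rng
        self.fixed = fixed or {}
        self.C, self.I, self.D = masks.shape
        self.N = self.y.shape[0]
        self.Kp1 = self.K + 1

        self.active = np.flatnonzero(masks.any(axis=(0, 1)))
        self.Da = len(self.active)
        self.rho_pairs = [(a, b) for a in range(self.Da) for b in range(a + 1, self.Da)]

        # each item loads on (at most) its measured trait and faking
        fak = self.D - 1
        self.dims = np.column_stack([self.scale_map, np.full(self.I, fak)]).astype(np.int64)
        trait_mask = masks[:, np.arange(self.I), self.scale_map]  # (C, I)
        fak_mask = masks[:, :, fak]
        groups = []
        idx_t = np.flatnonzero(trait_mask.any(axis=0))
        if idx_t.size:
            groups.append(
                {"slot": 0, "items": idx_t, "dims": self.scale_map[idx_t],
                 "gmask": trait_mask[:, idx_t]}
            )
        idx_f = np.flatnonzero(fak_mask.any(axis=0))
        if idx_f.size:
            groups.append(
                {"slot": 1, "items": idx_f, "dims": np.full(idx_f.size, fak),
                 "gmask": fak_mask[:, idx_f]}
            )
        self.alpha_groups = groups
        self.alpha_entries = [
            (int(i), int(d)) for g in groups for i, d in zip(g["items"], g["dims"])
        ]

        self.Xd = np.ones((self.N, 1)) if X is None else np.column_stack([np.ones(self.N), X])
        self.P1 = self.Xd.shape[1]
        self.ref = 0
        self.beta_free_cols = [c for c in range(self.C) if c != self.ref] if self.C > 1 else []

        self.sample_items = "alpha" not in self.fixed
        self.sample_sigma = "Sigma" not in self.fixed and len(self.rho_pairs) > 0

        self._init_state()
        self._init_scales()

    # -- state ------------------------------------------------------------

    def _init_state(self):
        rng = self.rng
        self.alpha = np.zeros((self.I, self.D))
        if self.sample_items:
            for i, d in self.alpha_entries:
                self.alpha[i, d] = rng.uniform(0.6, 0.9)
            # intercept starting values from pooled category log-frequencies
            counts = np.zeros((self.I, self.Kp1))
            for k in range(self.Kp1):
                counts[:, k] = ((self.y == k) & self.obs).sum(axis=0)
            lf = np.log(counts + 0.5)
            g0 = lf - lf[:, :1]
            self.gamma = np.tile(g0, (self.C, 1, 1)) + rng.normal(0, 0.3, (self.C, self.I, self.Kp1))
            self.gamma[:, :, 0] = 0.0
        else:
            self.alpha = np.asarray(self.fixed["alpha"], dtype=float).copy()
            self.gamma = np.ascontiguousarray(self.fixed["gamma"], dtype=float).copy()

        # starting values for theta from classical scores (standardized scale
        # means for traits, desirability-weighted sum score for faking): chains
        # started at theta = 0 cannot tell the traits+faking class from the
        # traits-only class and can collapse into a degenerate mode early on
        self.theta = np.zeros((self.N, self.D))
        y0 = np.where(self.obs, self.y, 0).astype(float)
        cnt = np.maximum(self.obs.sum(axis=1), 1)
        for d in range(self.D - 1):
            items = self.scale_map == d
            if not items.any():
                continue
            sc = y0[:, items].sum(axis=1) / np.maximum(self.obs[:, items].sum(axis=1), 1)
            sd = sc.std()
            self.theta[:, d] = (sc - sc.mean()) / (sd if sd > 0 else 1.0)
        fw = self.S[:, self.D - 1, :]  # (I, K+1) desirability weights
        des = fw[np.arange(self.I)[None, :], self.y]
        fsc = np.where(self.obs, des, 0.0).sum(axis=1) / cnt
        sd = fsc.std()
        self.theta[:, self.D - 1] = (fsc - fsc.mean()) / (sd if sd > 0 else 1.0)
        self.theta[:, self.active] += 0.3 * rng.standard_normal((self.N, self.Da))
        inactive = np.setdiff1d(np.arange(self.D), self.active)
        self.theta[:, inactive] = 0.0

        self.rho = np.zeros(len(self.rho_pairs))
        if not self.sample_sigma and "Sigma" in self.fixed:
            Sig = np.asarray(self.fixed["Sigma"], dtype=float)
            self.rho = np.array([Sig[a, b] for a, b in self.rho_pairs])
        self._set_sigma()

        self.beta = np.zeros((self.P1, self.C))  # uniform class probabilities

        self._build_W()
        self._refresh_logpi()
        self._refresh_likelihood()
        self.th_prior = self._theta_logprior(self.theta[:, self.active])

    def _build_W(self):
        """Class-masked alpha * s products per item slot: (C, I, 2, K+1)."""
        ar = np.arange(self.I)
        W = np.zeros((self.C, self.I, 2, self.Kp1))
        tm = self.masks[:, ar, self.scale_map]  # (C, I)
        W[:, :, 0, :] = (
            tm[:, :, None] * self.alpha[ar, self.scale_map][None, :, None]
            * self.S[ar, self.scale_map, :][None]
        )
        fak = self.D - 1
        W[:, :, 1, :] = (
            self.masks[:, :, fak][:, :, None] * self.alpha[:, fak][None, :, None]
            * self.S[:, fak, :][None]
        )
        self.W = W

    def _set_sigma(self):
        Sig = np.eye(self.Da)
        for (a, b), r in zip(self.rho_pairs, self.rho):
            Sig[a, b] = Sig[b, a] = r
        self.Sigma = Sig
        self.chol = np.linalg.cholesky(Sig)
        self.logdet = 2.0 * np.log(np.diag(self.chol)).sum()

    def _theta_logprior(self, theta_act: np.ndarray) -> np.ndarray:
        u = solve_triangular(self.chol, theta_act.T, lower=True)
        return -0.5 * (u**2).sum(axis=0) - 0.5 * self.logdet

    def _ll_all(self, theta, gamma=None, W=None) -> np.ndarray:
        return _ll_all_kernel(
            theta, self.W if W is None else W, self.dims,
            self.gamma if gamma is None else gamma, self.y, self.obs,
        )

    def _ll_zeta(self, zeta, theta=None, gamma=None, W=None) -> np.ndarray:
        return _ll_zeta_kernel(
            self.theta if theta is None else theta, self.W if W is None else W,
            self.dims, self.gamma if gamma is None else gamma, zeta, self.y, self.obs,
        )

    def _refresh_likelihood(self):
        self.ll = self._ll_all(self.theta)
        self.Lc = self.ll.sum(axis=2).T  # (N, C)
        self.marg = _lse(self.logpi + self.Lc, axis=1)

    def _refresh_logpi(self):
        if self.C == 1:
            self.eta = np.zeros((self.N, 1))
            self.logpi = np.zeros((self.N, 1))
        else:
            self.eta = self.Xd @ self.beta
            self.logpi = self.eta - _lse(self.eta, axis=1, keepdims=True)

    # -- scales -----------------------------------------------------------

    def _init_scales(self):
        # theta moves in two blocks: substantive traits jointly, faking alone
        # (their posterior geometries differ markedly between latent classes)
        fak = self.D - 1
        blocks = []
        tr = self.active[self.active != fak]
        if tr.size:
            blocks.append(tr)
        if fak in self.active:
            blocks.append(np.array([fak]))
        self.theta_blocks = blocks
        # per-person proposal scales: posterior curvature differs sharply
        # between persons (e.g. members of classes where a dimension is inactive)
        self.s_theta = [
            _Adaptive(self.N, 0.4, _SCALAR_TARGET if len(b) == 1 else _BLOCK_TARGET)
            for b in blocks
        ]
        for g in self.alpha_groups:
            g["adapt"] = _Adaptive(len(g["items"]), 0.15, _SCALAR_TARGET)
        self.s_gamma = _Adaptive((self.C, self.I, self.K), 0.3, _SCALAR_TARGET)
        self.s_beta = _Adaptive(len(self.beta_free_cols), 0.25, _BLOCK_TARGET)

    # -- updates ----------------------------------------------------------

    def _update_theta(self):
        rng = self.rng
        for b, s in zip(self.theta_blocks, self.s_theta):
            prop = self.theta.copy()
            prop[:, b] += s.scale[:, None] * rng.standard_normal((self.N, len(b)))
            ll_p = self._ll_all(prop)
            Lc_p = ll_p.sum(axis=2).T
            marg_p = _lse(self.logpi + Lc_p, axis=1)
            pr_p = self._theta_logprior(prop[:, self.active])
            log_r = (marg_p - self.marg) + (pr_p - self.th_prior)
            acc = np.log(rng.uniform(size=self.N)) < log_r
            if np.any(acc):
                self.theta[acc] = prop[acc]
                self.ll[:, acc] = ll_p[:, acc]
                self.Lc[acc] = Lc_p[acc]
                self.marg[acc] = marg_p[acc]
                self.th_prior[acc] = pr_p[acc]
            s.record(acc.astype(float))

    def _sample_zeta(self) -> np.ndarray:
        """Draw class memberships from their full conditional (the current
        responsibilities)."""
        w = self.logpi + self.Lc
        r = np.exp(w - _lse(w, axis=1, keepdims=True))
        u = self.rng.uniform(size=self.N)
        return np.ascontiguousarray((r.cumsum(axis=1) < u[:, None]).sum(axis=1), dtype=np.int64)

    def _class_sums(self, diff: np.ndarray, zeta: np.ndarray) -> np.ndarray:
        out = np.zeros((self.C, diff.shape[1]))
        for c in range(self.C):
            sel = zeta == c
            if np.any(sel):
                out[c] = diff[sel].sum(axis=0)
        return out

    def _update_items(self, zeta: np.ndarray):
        """MH updates of slopes and intercepts given sampled memberships."""
        rng = self.rng
        ll_cur = self.ll[zeta, np.arange(self.N)].copy()  # (N, I)

        sd2a = 2.0 * self.priors.slope_sd**2
        for _ in range(3):  # slope moves are cheap; repeat for better mixing
            for g in self.alpha_groups:
                items, dims, slot, s = g["items"], g["dims"], g["slot"], g["adapt"]
                a_cur = self.alpha[items, dims]
                a_new = a_cur + s.scale * rng.standard_normal(items.size)
                ok = a_new > 0
                W_prop = self.W.copy()
                W_prop[:, items, slot, :] = (
                    g["gmask"][:, :, None] * np.where(ok, a_new, a_cur)[None, :, None]
                    * self.S[items, dims, :][None]
                )
                ll_new = self._ll_zeta(zeta, W=W_prop)
                log_r = (ll_new - ll_cur)[:, items].sum(axis=0) + (a_cur**2 - a_new**2) / sd2a
                acc = ok & (np.log(rng.uniform(size=items.size)) < log_r)
                if np.any(acc):
                    ii = items[acc]
                    self.alpha[ii, dims[acc]] = a_new[acc]
                    self.W[:, ii, slot, :] = W_prop[:, ii, slot, :]
                    ll_cur[:, ii] = ll_new[:, ii]
                s.record(acc.astype(float))

        sd2g = 2.0 * self.priors.intercept_sd**2
        for k in range(1, self.Kp1):
            G_cur = self.gamma[:, :, k]
            G_new = G_cur + self.s_gamma.scale[:, :, k - 1] * rng.standard_normal((self.C, self.I))
            gamma_prop = self.gamma.copy()
            gamma_prop[:, :, k] = G_new
            ll_prop = self._ll_zeta(zeta, gamma=gamma_prop)
            delta_ci = self._class_sums(ll_prop - ll_cur, zeta)
            log_r = delta_ci + (G_cur**2 - G_new**2) / sd2g
            acc = np.log(rng.uniform(size=(self.C, self.I))) < log_r
            if np.any(acc):
                self.gamma[:, :, k] = np.where(acc, G_new, G_cur)
                accp = acc[zeta]
                ll_cur = np.where(accp, ll_prop, ll_cur)
            self.s_gamma.accepts[:, :, k - 1] += acc
            self.s_gamma.tries[:, :, k - 1] += 1

    def _update_scale(self):
        """Joint rescaling move theta_d -> c * theta_d, alpha_.d -> alpha_.d / c.

        All category logits (alpha ∘ s)'theta are invariant, so the move costs
        no likelihood evaluation; it traverses the slope/person-score scale
        ridge that plain random-walk updates cross only slowly.  The
        acceptance ratio is prior ratio times the Jacobian c^(N - I_d).
        """
        rng = self.rng
        sd2a = 2.0 * self.priors.slope_sd**2
        for g in self.alpha_groups:
            items, dims, slot = g["items"], g["dims"], g["slot"]
            for d in np.unique(dims):
                sel = dims == d
                ii = items[sel]
                eps = 0.1 * rng.standard_normal()
                c = np.exp(eps)
                a_old = self.alpha[ii, d]
                a_new = a_old / c
                th_new = self.theta.copy()
                th_new[:, d] *= c
                pr_new = self._theta_logprior(th_new[:, self.active])
                log_r = (
                    (pr_new - self.th_prior).sum()
                    + ((a_old**2).sum() - (a_new**2).sum()) / sd2a
                    + (self.N - ii.size) * eps
                )
                if np.log(rng.uniform()) < log_r:
                    self.theta = th_new
                    self.alpha[ii, d] = a_new
                    self.th_prior = pr_new
                    self.W[:, ii, slot, :] /= c

    def _update_location(self):
        """Joint shift move theta_d -> theta_d + delta with the compensating
        intercept shear gamma_ikc -> gamma_ikc - delta * alpha_id (s_idk - s_id0).

        Category probabilities are invariant (the residual delta*alpha*s_id0 is
        a per-item constant absorbed by the softmax), so acceptance again only
        involves the theta and intercept priors.  This crosses the latent-mean
        versus intercept-location ridge.
        """
        rng = self.rng
        sd2g = 2.0 * self.priors.intercept_sd**2
        for g in self.alpha_groups:
            items, dims = g["items"], g["dims"]
            for d in np.unique(dims):
                ii = items[dims == d]
                delta = 0.1 * rng.standard_normal()
                shear = (
                    self.masks[:, ii, d][:, :, None]
                    * self.alpha[ii, d][None, :, None]
                    * (self.S[ii, d, :] - self.S[ii, d, :1])[None, :, :]
                )  # (C, nI, K+1)
                g_new = self.gamma[:, ii, :] - delta * shear
                th_new = self.theta.copy()
                th_new[:, d] += delta
                pr_new = self._theta_logprior(th_new[:, self.active])
                dgam = ((self.gamma[:, ii, 1:] ** 2).sum() - (g_new[:, :, 1:] ** 2).sum()) / sd2g
                log_r = (pr_new - self.th_prior).sum() + dgam
                if np.log(rng.uniform()) < log_r:
                    self.theta = th_new
                    self.gamma[:, ii, :] = g_new
                    self.th_prior = pr_new

    _RHO_GRID = np.linspace(-0.998, 0.998, 257)
    _RHO_NODES = np.array([-0.5, 0.0, 0.5])

    def _update_rho(self):
        """Draw each pairwise correlation from its full conditional on a fine
        grid (inverse-CDF sampling), restricted to the positive-definite
        region.  The uniform prior (and equally the flat LKJ(1) alternative)
        contributes no density term.

        Because the correlation enters Sigma through a rank-2 linear update,
        det Sigma(r) and tr(adj(Sigma(r)) S) are exact quadratics in r, so the
        whole grid is interpolated from three small-matrix evaluations.
        """
        rng = self.rng
        th = self.theta[:, self.active]
        Sth = th.T @ th
        grid = self._RHO_GRID
        nodes = self._RHO_NODES
        V = np.vander(nodes, 3)
        for j, (a, b) in enumerate(self.rho_pairs):
            dets = np.empty(3)
            numer = np.empty(3)
            Sig = self.Sigma.copy()
            for t, r in enumerate(nodes):
                Sig[a, b] = Sig[b, a] = r
                dets[t] = np.linalg.det(Sig)
                numer[t] = np.trace(np.linalg.inv(Sig) @ Sth) * dets[t]
            cd = np.linalg.solve(V, dets)
            cn = np.linalg.solve(V, numer)
            det_g = np.polyval(cd, grid)
            num_g = np.polyval(cn, grid)
            # PD region in one coordinate is the contiguous det > 0 interval
            # around the current (PD) value
            cur = min(int(np.searchsorted(grid, self.rho[j])), grid.size - 1)
            ok = det_g > 1e-12
            if not ok[cur]:  # numerically at the PD boundary: leave unchanged
                continue
            lo, hi = cur, cur
            while lo > 0 and ok[lo - 1]:
                lo -= 1
            while hi < grid.size - 1 and ok[hi + 1]:
                hi += 1
            sl = slice(lo, hi + 1)
            logp = -0.5 * (self.N * np.log(det_g[sl]) + num_g[sl] / det_g[sl])
            w = np.exp(logp - logp.max())
            w /= w.sum()
            cell = lo + int(rng.choice(hi + 1 - lo, p=w))
            step = grid[1] - grid[0]
            r_new = grid[cell] + step * (rng.uniform() - 0.5)
            if cell in (lo, hi):  # stay off the PD boundary
                r_new = grid[cell]
            r_new = float(np.clip(r_new, grid[0], grid[-1]))
            self.rho[j] = r_new
            self.Sigma[a, b] = self.Sigma[b, a] = r_new
        self._set_sigma()
        self.th_prior = self._theta_logprior(th)

    def _update_beta(self):
        rng = self.rng
        sd2 = 2.0 * self.priors.beta_sd**2
        scales = self.s_beta.scale
        for j, c in enumerate(self.beta_free_cols):
            b_new = self.beta[:, c] + scales[j] * rng.standard_normal(self.P1)
            eta_p = self.eta.copy()
            eta_p[:, c] = self.Xd @ b_new
            logpi_p = eta_p - _lse(eta_p, axis=1, keepdims=True)
            marg_p = _lse(logpi_p + self.Lc, axis=1)
            log_r = (marg_p - self.marg).sum() + (
                (self.beta[:, c] ** 2).sum() - (b_new**2).sum()
            ) / sd2
            if np.log(rng.uniform()) < log_r:
                self.beta[:, c] = b_new
                self.eta = eta_p
                self.logpi = logpi_p
                self.marg = marg_p
                self.s_beta.record(1.0, j)
            else:
                self.s_beta.record(0.0, j)

    def _iterate(self, freeze_beta: bool = False):
        for _ in range(self.config.sweeps):
            self._update_theta()
            if self.sample_items:
                for _ in range(2):
                    zeta = self._sample_zeta()
                    self._update_items(zeta)
                    self._refresh_likelihood()
                self._update_scale()
                self._update_location()
            if self.sample_sigma:
                self._update_rho()
            if self.C > 1 and not freeze_beta:
                self._update_beta()

    def _adapt_all(self):
        for s in (*self.s_theta, self.s_gamma, self.s_beta):
            s.adapt()
        for g in self.alpha_groups:
            g["adapt"].adapt()

    # -- main loop --------------------------------------------------------

    _STATE_ARRAYS = ("alpha", "gamma", "theta", "rho", "Sigma", "chol", "beta",
                     "eta", "logpi", "W", "ll", "Lc", "marg", "th_prior")

    def adopt_state(self, other: "_Chain") -> None:
        """Copy another chain's parameter state and adapted proposal scales;
        the RNG stays this chain's own."""
        for name in self._STATE_ARRAYS:
            setattr(self, name, getattr(other, name).copy())
        self.logdet = other.logdet
        for s_mine, s_theirs in zip(self.s_theta, other.s_theta):
            s_mine.log_scale = s_theirs.log_scale.copy()
        for g_mine, g_theirs in zip(self.alpha_groups, other.alpha_groups):
            g_mine["adapt"].log_scale = g_theirs["adapt"].log_scale.copy()
        self.s_gamma.log_scale = other.s_gamma.log_scale.copy()
        self.s_beta.log_scale = other.s_beta.log_scale.copy()
        self._pilot_done = getattr(other, "_pilot_done", 0)

    def pilot(self, n_iter: int) -> float:
        """Early-burnin exploration; returns the mean deviance of the last
        few iterations.  Mixtures with class-specific intercepts have
        metastable distorted modes (one class's intercepts specializing to
        another class's members); starting every chain from the best of a few
        independent pilot states reliably lands in the dominant basin without
        touching the retained chain's transition kernel."""
        tail = []
        for it in range(n_iter):
            self._iterate(freeze_beta=True)
            if (it + 1) % self.config.adapt_interval == 0:
                self._adapt_all()
            if it >= n_iter - 10:
                tail.append(-2.0 * self.marg.sum())
        self._pilot_done = n_iter
        return float(np.mean(tail))

    def run(self) -> dict:
        cfg = self.config
        n_keep = cfg.iterations // cfg.thinning
        nA = len(self.alpha_entries)
        out = {
            "alpha": np.zeros((n_keep, nA)),
            "gamma": np.zeros((n_keep, self.C, self.I, self.K)),
            "rho": np.zeros((n_keep, len(self.rho_pairs))),
            "beta": np.zeros((n_keep, self.P1, len(self.beta_free_cols))),
            "props": np.zeros((n_keep, self.C)),
            "pointwise": np.zeros((n_keep, self.N)),
            "deviance": np.zeros(n_keep),
        }
        snap_idx = np.unique(
            np.linspace(0, n_keep - 1, min(cfg.n_snapshots, n_keep)).astype(int)
        )
        snap_set = set(snap_idx.tolist())
        theta_snaps, resp_snaps = [], []
        resp_sum = np.zeros((self.N, self.C))
        theta_sum = np.zeros((self.N, self.D))

        # the latent regression stays at its (uniform) initialization for the
        # first half of burnin: class measurement models then separate on the
        # likelihood alone before class-proportion feedback can starve a class
        for it in range(getattr(self, "_pilot_done", 0), cfg.burnin):
            self._iterate(freeze_beta=it < cfg.burnin // 2)
            if (it + 1) % cfg.adapt_interval == 0:
                self._adapt_all()

        kept = 0
        for it in range(cfg.iterations):
            self._iterate()
            if (it + 1) % cfg.thinning:
                continue
            w = self.logpi + self.Lc
            r = np.exp(w - _lse(w, axis=1, keepdims=True))
            out["alpha"][kept] = [self.alpha[i, d] for i, d in self.alpha_entries]
            out["gamma"][kept] = self.gamma[:, :, 1:]
            out["rho"][kept] = self.rho
            out["beta"][kept] = self.beta[:, self.beta_free_cols]
            out["props"][kept] = r.mean(axis=0)
            out["pointwise"][kept] = self.marg
            out["deviance"][kept] = -2.0 * self.marg.sum()
            resp_sum += r
            theta_sum += self.theta
            if kept in snap_set:
                theta_snaps.append(self.theta.copy())
                resp_snaps.append(r)
            kept += 1

        out["resp_mean"] = resp_sum / kept
        out["theta_mean"] = theta_sum / kept
        out["theta_snaps"] = np.array(theta_snaps)
        out["resp_snaps"] = np.array(resp_snaps)
        return out


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------


def _check_degenerate(responses: ResponseMatrix):
    v = responses.values
    obs = responses.observed_mask
    for i in range(responses.n_items):
        col = v[obs[:, i], i]
        if col.size and np.all(col == col[0]):
            warnings.warn(f"item {i} is constant in the observed data", stacklevel=3)


def fit(
    responses: ResponseMatrix,
    weights: ScoringWeights,
    class_spec: ClassSpec,
    covariates: np.ndarray | None = None,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    fixed: dict | None = None,
) -> PosteriorResult:
    """Fit the (mixture) MNRM by MCMC and return posterior draws.

    ``covariates`` (N, P) activates the latent multinomial regression of class
    membership; without it the regression is intercept-only.  ``fixed`` may
    supply ``alpha``, ``gamma`` and ``Sigma`` to keep item parameters and
    latent correlations at known values (transfer scoring of new samples).
    """
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim != 2 or covariates.shape[0] != responses.n_persons:
            raise ValueError("covariates must be (N, P)")
    masks = build_class_masks(class_spec, responses.item_scale_map)
    weights.validate_structure(responses.item_scale_map)
    if weights.n_items != responses.n_items or weights.K != responses.K:
        raise ValueError("scoring weights do not match the response matrix")
    if fixed:
        a = np.asarray(fixed["alpha"])
        g = np.asarray(fixed["gamma"])
        if a.shape != (responses.n_items, weights.n_dims):
            raise ValueError("fixed alpha has wrong shape")
        if g.shape != (masks.shape[0], responses.n_items, responses.K + 1):
            raise ValueError("fixed gamma has wrong shape")
    # structural class identification: masks must differ pairwise
    C = masks.shape[0]
    for c1 in range(C):
        for c2 in range(c1 + 1, C):
            if np.array_equal(masks[c1], masks[c2]):
                raise ValueError("two classes have identical masks (not identified)")
    _check_degenerate(responses)

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chain_out = []
    proto = None
    # pilot selection targets the metastable modes of mixtures with
    # class-specific intercepts; single-class fits and fixed-item scoring
    # have none.  Every chain is started from the best pilot state (selected
    # by marginal likelihood) with its own RNG, the standard
    # initialize-near-the-dominant-basin strategy.
    n_pilots = 1 if (fixed or masks.shape[0] == 1) else max(1, config.n_pilots)
    pilot_len = min(150, config.burnin // 2)
    best = None
    if n_pilots > 1 and pilot_len >= 25:
        cands = [
            _Chain(responses, weights, masks, covariates, priors, config,
                   np.random.default_rng(sub), fixed)
            for sub in np.random.SeedSequence(config.seed).spawn(config.chains + n_pilots)[
                config.chains :
            ]
        ]
        devs = [ch.pilot(pilot_len) for ch in cands]
        best = cands[int(np.argmin(devs))]
    for s in seeds:
        chain = _Chain(
            responses, weights, masks, covariates, priors, config,
            np.random.default_rng(s), fixed,
        )
        if best is not None:
            chain.adopt_state(best)
        proto = chain
        chain_out.append(chain.run())

    def stack(key):
        return np.stack([o[key] for o in chain_out])

    alpha_draws = stack("alpha")
    gamma_draws = stack("gamma")
    rho_draws = stack("rho")
    beta_draws = stack("beta")

    rh: dict = {}
    if config.chains >= 2:
        if not fixed:
            if alpha_draws.shape[-1]:
                rh["alpha"] = rhat(alpha_draws)
            rh["gamma"] = rhat(gamma_draws)
            if rho_draws.shape[-1]:
                rh["rho"] = rhat(rho_draws)
        if beta_draws.shape[-1]:
            rh["beta"] = rhat(beta_draws)
    vals = [np.max(v) for v in rh.values() if np.size(v)]
    converged = bool(np.all(np.asarray(vals) < 1.1)) if vals else True
    if vals and not converged:
        warnings.warn(f"possible non-convergence: max R-hat = {max(vals):.3f}", stacklevel=2)

    resp_mean = np.mean([o["resp_mean"] for o in chain_out], axis=0)
    theta_mean = np.mean([o["theta_mean"] for o in chain_out], axis=0)

    return PosteriorResult(
        class_spec=class_spec,
        weights=weights,
        item_scale_map=np.asarray(responses.item_scale_map),
        masks=masks,
        active_dims=proto.active,
        alpha_entries=proto.alpha_entries,
        rho_pairs=proto.rho_pairs,
        config=config,
        priors=priors,
        X=covariates,
        alpha_draws=alpha_draws,
        gamma_draws=gamma_draws,
        rho_draws=rho_draws,
        beta_draws=beta_draws,
        beta_free_cols=proto.beta_free_cols,
        prop_draws=stack("props"),
        pointwise=stack("pointwise"),
        deviance=stack("deviance"),
        resp_mean=resp_mean,
        theta_mean=theta_mean,
        theta_draws=stack("theta_snaps"),
        resp_draws=stack("resp_snaps"),
        rhat=rh,
        converged=converged,
        fixed_items=bool(fixed),
    )


def fit_with_fixed_items(
    responses: ResponseMatrix,
    fixed_params: dict,
    class_spec: ClassSpec,
    weights: ScoringWeights | None = None,
    config: SamplerConfig | None = None,
    priors: PriorSpec | None = None,
) -> PosteriorResult:
    """Score a new sample with item parameters and latent correlations fixed.

    Only person parameters, class memberships and an intercept-only latent
    regression are estimated.  ``fixed_params`` needs ``alpha`` (I, D),
    ``gamma`` (C, I, K+1), ``Sigma`` (over active dimensions) and, unless
    given separately, ``weights``.
    """
    weights = weights or fixed_params.get("weights")
    if weights is None:
        raise ValueError("scoring weights are required")
    needed = {"alpha", "gamma", "Sigma"}
    if not needed <= set(fixed_params):
        raise ValueError(f"fixed_params needs {sorted(needed)}")
    return fit(
        responses,
        weights,
        class_spec,
        covariates=None,
        priors=priors,
        config=config or SamplerConfig(),
        fixed={k: fixed_params[k] for k in needed},
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def point_estimates(post: PosteriorResult) -> dict:
    """Posterior means of continuous parameters plus modal class assignments.

    Ties in the modal class are broken toward the lowest class index (the
    behaviour of argmax), recorded under ``"ties"``.
    """
    n_draws = post.pointwise.shape[0] * post.pointwise.shape[1]
    if n_draws < 100:
        raise ValueError("need at least 100 retained draws for point estimation")
    r = post.resp_mean
    zeta_hat = np.argmax(r, axis=1)
    ties = np.flatnonzero((r == r.max(axis=1, keepdims=True)).sum(axis=1) > 1)
    return {
        "alpha": post.mean_alpha(),
        "gamma": post.mean_gamma(),
        "Sigma": post.mean_sigma(),
        "beta": post.mean_beta(),
        "theta": post.theta_mean,
        "responsibilities": r,
        "zeta": zeta_hat,
        "posterior_prob": r[np.arange(r.shape[0]), zeta_hat],
        "ties": ties,
    }


def class_proportions(post: PosteriorResult) -> tuple:
    """Class-proportion estimates (mean over persons and draws) with 95%
    credible intervals from the draw-wise person-means."""
    draws = post.pooled("prop_draws")
    mean = draws.mean(axis=0)
    ci = np.percentile(draws, [2.5, 97.5], axis=0)
    return mean, ci


def params_at(post: PosteriorResult, chain: int, snap: int) -> ModelParams:
    """Reconstruct a ModelParams snapshot (thinned draw) for predictive checks."""
    n_keep = post.alpha_draws.shape[1]
    snap_positions = np.unique(
        np.linspace(0, n_keep - 1, post.theta_draws.shape[1]).astype(int)
    )
    s = snap_positions[snap]
    I, D = post.item_scale_map.shape[0], post.weights.n_dims
    alpha = np.zeros((I, D))
    for (i, d), v in zip(post.alpha_entries, post.alpha_draws[chain, s]):
        alpha[i, d] = v
    gamma = np.zeros((post.n_classes, I, post.weights.K + 1))
    gamma[:, :, 1:] = post.gamma_draws[chain, s]
    return ModelParams(
        weights=post.weights,
        alpha=alpha,
        gamma=gamma,
        theta=post.theta_draws[chain, snap],
        masks=post.masks,
    )
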