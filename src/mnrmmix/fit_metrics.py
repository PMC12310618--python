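"""Model comparison and diagnostics: DIC, WAIC, LOOIC, PPMC-SRMR, entropy.

All criteria operate on the person-level *marginal* log-likelihood (classes
summed out), which is the natural pointwise unit for a person-mixture model:
WAIC and LOOIC treat a person's whole response vector as one observation, and
the DIC deviance never plugs in discrete memberships.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .estimation import PosteriorResult, params_at
from .model_core import MISSING, ModelParams, ResponseMatrix, category_logits, masked_slope_weights

log = logging.getLogger(__name__)


@dataclass
class FitIndices:
    dic: float
    waic: float
    looic: float
    srmr: float
    entropy: float


# ---------------------------------------------------------------------------
# pointwise log-likelihood
# ---------------------------------------------------------------------------


def pointwise_loglik(post: PosteriorResult, responses: ResponseMatrix | None = None) -> np.ndarray:
    """Draws x persons matrix of log marginal response-vector probabilities.

    Stored during sampling; pooled across chains here.  ``responses`` is only
    used for a consistency check.
    """
    if responses is not None and responses.n_persons != post.n_persons:
        raise ValueError("responses do not match the posterior")
    return post.pooled("pointwise")


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def waic(pointwise: np.ndarray) -> float:
    """WAIC = -2 (lppd - p_waic); lppd = sum_n log mean_s p_ns,
    p_waic = sum_n var_s log p_ns (sample variance)."""
    pw = np.asarray(pointwise, dtype=float)
    if pw.ndim == 3:
        pw = pw.reshape(-1, pw.shape[-1])
    S = pw.shape[0]
    if S < 2:
        raise ValueError("WAIC needs >= 2 draws")
    lppd = (logsumexp(pw, axis=0) - np.log(S)).sum()
    p_waic_n = pw.var(axis=0, ddof=1)
    if np.any(p_waic_n > 0.4):
        log.warning("WAIC: %d persons with pointwise variance > 0.4", int((p_waic_n > 0.4).sum()))
    return float(-2.0 * (lppd - p_waic_n.sum()))


def looic(pointwise: np.ndarray) -> float:
    """LOOIC from Pareto-smoothed importance sampling (PSIS-LOO).

    Accepts (chains, draws, N) or (draws, N).  Persons with Pareto k > 0.7
    trigger a warning.
    """
    pw = np.asarray(pointwise, dtype=float)
    if pw.ndim == 2:
        pw = pw[None, :, :]
    idata = az.from_dict(log_likelihood={"y": pw})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # reff = 1: raw draws, no posterior group to estimate autocorrelation from
        res = az.loo(idata, pointwise=True, scale="deviance", reff=1.0)
    k = np.asarray(res.pareto_k)
    if np.any(k > 0.7):
        warnings.warn(f"PSIS-LOO: {int((k > 0.7).sum())} persons with Pareto k > 0.7")
    return float(res.elpd_loo)  # deviance scale: -2 * elpd


def dic_from_deviances(deviances: np.ndarray, deviance_at_mean: float, variant: str = "gelman") -> float:
    """DIC = D(theta_bar) + 2 p, with p = Var_s(D_s)/2 (variance-based
    effective parameters) or, for variant="spiegelhalter",
    p = mean(D_s) - D(theta_bar)."""
    d = np.asarray(deviances, dtype=float).ravel()
    if variant == "gelman":
        p = 0.5 * d.var(ddof=1)
    elif variant == "spiegelhalter":
        p = d.mean() - deviance_at_mean
    else:
        raise ValueError("variant must be 'gelman' or 'spiegelhalter'")
    return float(deviance_at_mean + 2.0 * p)


def deviance_at_posterior_mean(post: PosteriorResult, responses: ResponseMatrix) -> float:
    """-2 log marginal likelihood at posterior means of all continuous
    parameters (class memberships stay marginalized)."""
    params = ModelParams(
        weights=post.weights,
        alpha=post.mean_alpha(),
        gamma=post.mean_gamma(),
        theta=post.theta_mean,
        masks=post.masks,
    )
    from .model_core import person_class_loglik

    L_nc = person_class_loglik(params, responses)
    if post.n_classes == 1:
        marg = L_nc[:, 0]
    else:
        eta = post.design_matrix() @ post.mean_beta()
        log_pi = eta - logsumexp(eta, axis=1, keepdims=True)
        marg = logsumexp(log_pi + L_nc, axis=1)
    return float(-2.0 * marg.sum())


def dic(post: PosteriorResult, responses: ResponseMatrix, variant: str = "gelman") -> float:
    return dic_from_deviances(
        post.pooled("deviance"), deviance_at_posterior_mean(post, responses), variant
    )


# ---------------------------------------------------------------------------
# posterior predictive model checking
# ---------------------------------------------------------------------------


def _item_correlations(values: np.ndarray) -> np.ndarray:
    """Pearson correlations of raw category scores; missing entries pairwise
    deleted, constant items give NaN columns."""
    v = np.asarray(values, dtype=float)
    v[np.asarray(values) == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pd.DataFrame(v).corr().to_numpy()


def srmr_from_correlations(r_obs: np.ndarray, r_rep: np.ndarray) -> float:
    """sqrt(mean over item pairs i<j of (r_obs - r_rep)^2), NaN pairs skipped."""
    iu = np.triu_indices_from(r_obs, k=1)
    d = r_obs[iu] - r_rep[iu]
    ok = np.isfinite(d)
    if not np.all(ok):
        log.info("SRMR: skipped %d undefined item pairs", int((~ok).sum()))
    if not np.any(ok):
        raise ValueError("no valid item pairs for SRMR")
    return float(np.sqrt(np.mean(d[ok] ** 2)))


def _sample_responses(rng, params: ModelParams, zeta: np.ndarray) -> np.ndarray:
    A = masked_slope_weights(params.alpha, params.weights.S, params.masks)
    probs = softmax(category_logits(params.theta, A, params.gamma), axis=-1)
    N, I = params.theta.shape[0], params.weights.n_items
    u = rng.uniform(size=(N, I))
    out = np.zeros((N, I), dtype=int)
    for c in range(params.n_classes):
        sel = zeta == c
        if np.any(sel):
            cdf = probs[c, sel].cumsum(axis=-1)
            out[sel] = (cdf < u[sel, :, None]).sum(axis=-1)
    return out


def ppmc_srmr(
    post: PosteriorResult,
    responses: ResponseMatrix,
    n_rep: int = 200,
    seed: int = 0,
) -> float:
    """Posterior predictive SRMR: discrepancy between observed and replicated
    item intercorrelations, averaged over ``n_rep`` replicated datasets drawn
    from randomly selected posterior draws."""
    if n_rep < 50:
        raise ValueError("need n_rep >= 50 replicated datasets")
    rng = np.random.default_rng(seed)
    m, n_snap = post.theta_draws.shape[:2]
    r_obs = _item_correlations(responses.values)
    acc = np.zeros_like(r_obs)
    for _ in range(n_rep):
        chain = int(rng.integers(m))
        snap = int(rng.integers(n_snap))
        params = params_at(post, chain, snap)
        r = post.resp_draws[chain, snap]
        u = rng.uniform(size=r.shape[0])
        zeta = (r.cumsum(axis=1) < u[:, None]).sum(axis=1)
        y_rep = _sample_responses(rng, params, zeta)
        acc += _item_correlations(y_rep)
    return srmr_from_correlations(r_obs, acc / n_rep)


# ---------------------------------------------------------------------------
# classification diagnostics
# ---------------------------------------------------------------------------


def entropy(pi: np.ndarray) -> float:
    """Normalized separation index 1 - sum_n sum_c (-pi log pi) / (N log C).

    1 = perfectly separated classes, 0 = uniform responsibilities.  The log-C
    denominator generalizes the three-class formula to any number of classes.
    """
    p = np.asarray(pi, dtype=float)
    if p.ndim != 2:
        raise ValueError("pi must be (N, C)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("responsibility rows must sum to 1")
    n, C = p.shape
    if C == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log(p), 0.0)
    return float(1.0 - h.sum() / (n * np.log(C)))


def compute_fit_indices(
    post: PosteriorResult,
    responses: ResponseMatrix,
    n_rep: int = 200,
    seed: int = 0,
) -> FitIndices:
    pw = pointwise_loglik(post, responses)
    return FitIndices(
        dic=dic(post, responses),
        waic=waic(pw),
        looic=looic(post.pointwise),
        srmr=ppmc_srmr(post, responses, n_rep=n_rep, seed=seed),
        entropy=entropy(post.resp_mean),
    )
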