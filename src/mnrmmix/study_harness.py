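"""Recovery-study orchestration: conditions x replications x four models.

Runs the full pipeline (simulate -> fit the mixture model and the three
non-mixture special cases -> score recovery and model selection) and
aggregates bias, RMSE, hit rates, Fisher-z mean correlations of person
parameters with truth, and correct-selection percentages for DIC/WAIC/LOOIC.

Two scale presets are built in: ``paper`` reproduces the reference study
conditions (N=1500, 10 items per trait, 30 replications, 4 chains with
2000 burnin / 5000 kept iterations) and is a multi-hour run; ``desk`` is the
reduced configuration used throughout the examples and checks (N=300, 5 items
per trait, 3 replications, 2 chains with 500 / 1000 iterations).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fit_metrics
from .estimation import PosteriorResult, SamplerConfig, class_proportions, fit, point_estimates
from .mixture_spec import CANONICAL_LABELS, model_spec
from .model_core import MISSING, ResponseMatrix
from .simulator import CONDITIONS, GroundTruth, SimulatedData, SimulationDesign, simulate

log = logging.getLogger(__name__)

MODEL_NAMES = ("mix", "sf", "s", "f")
#: which single generating class corresponds to which non-mixture model
_SINGLE_CLASS_TRUTH = {(0,): "sf", (1,): "s", (2,): "f"}


@dataclass
class ScalePreset:
    n_persons: int
    items_per_trait: int
    reps: int
    sampler: SamplerConfig


PRESETS = {
    "paper": ScalePreset(1500, 10, 30, SamplerConfig(chains=4, burnin=2000, iterations=5000)),
    "desk": ScalePreset(300, 5, 3, SamplerConfig(chains=2, burnin=500, iterations=1000)),
}


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------


def bias_rmse(estimates, truths) -> tuple:
    """(mean error, root mean square error) of estimates against truths."""
    est = np.asarray(estimates, dtype=float).ravel()
    tru = np.asarray(truths, dtype=float).ravel()
    if est.size == 0:
        raise ValueError("empty input")
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have equal length")
    err = est - tru
    return float(err.mean()), float(np.sqrt((err**2).mean()))


def hit_rate(assigned, truth) -> float:
    """Fraction of persons whose assigned class equals the generating class."""
    a = np.asarray(assigned)
    t = np.asarray(truth)
    if a.shape != t.shape:
        raise ValueError("assigned and truth must have equal length")
    return float((a == t).mean())


def fisher_mean_correlation(correlations) -> float:
    """tanh(mean(atanh(r))): the Fisher-z average of correlations."""
    r = np.asarray(correlations, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) == 1):
        warnings.warn("|r| = 1 clipped before Fisher transform")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(r))))


def selection_percentages(fit_tables, truth_model: str) -> dict:
    """Correct-selection fractions per criterion.

    ``fit_tables`` is a list (one entry per replication) of
    {criterion: {model: value}}.  For each criterion the exact-model fraction
    (argmin equals the generating model) and the coarser mixture-vs-non-mixture
    fraction are reported; exact ties count as incorrect and are logged.
    """
    if not fit_tables:
        raise ValueError("no replications")
    crits = sorted(fit_tables[0])
    out = {}
    for crit in crits:
        exact = 0
        coarse = 0
        for rep in fit_tables:
            vals = rep[crit]
            best_val = min(vals.values())
            winners = [m for m, v in vals.items() if v == best_val]
            if len(winners) > 1:
                log.info("criterion %s: tie between %s counted incorrect", crit, winners)
                continue
            best = winners[0]
            if best == truth_model:
                exact += 1
            if (best == "mix") == (truth_model == "mix"):
                coarse += 1
        out[crit] = {
            "exact": exact / len(fit_tables),
            "mixture_vs_non": coarse / len(fit_tables),
        }
    return out


# ---------------------------------------------------------------------------
# per-replication scoring
# ---------------------------------------------------------------------------


def _truth_model_name(truth: GroundTruth) -> str:
    return _SINGLE_CLASS_TRUTH.get(tuple(truth.present_classes), "mix")


def _alpha_truth_pairs(post: PosteriorResult, truth: GroundTruth):
    est = post.pooled("alpha_draws").mean(axis=0)
    tru = np.array([truth.alpha[i, d] for i, d in post.alpha_entries])
    return est, tru


def _beta_recovery(post: PosteriorResult, truth: GroundTruth) -> dict | None:
    """Bias of latent-regression coefficients, re-referenced to the truth's
    reference class when the fitted reference class was absent in generation."""
    if truth.reg is None or len(truth.present_classes) < 2:
        return None
    beta_est = post.mean_beta()  # (P+1, 3), reference column 0
    present = list(truth.present_classes)
    ref_true = present[truth.reg.reference_index]
    # re-reference fitted coefficients to the generating reference class
    beta_rr = beta_est - beta_est[:, [ref_true]]
    errs_int, errs_by_cov = [], {}
    eff = truth.design.covariate_effects
    for local, canon in enumerate(present):
        if canon == ref_true:
            continue
        errs_int.append(beta_rr[0, canon] - truth.reg.beta0[local])
        for p in range(truth.reg.n_covariates):
            errs_by_cov.setdefault(eff[p], []).append(
                (beta_rr[1 + p, canon], truth.reg.beta[p, local])
            )
    out = {"intercepts": bias_rmse(errs_int, np.zeros(len(errs_int)))}
    for effname, pairs in errs_by_cov.items():
        est, tru = zip(*pairs)
        out[f"slopes_{effname}"] = bias_rmse(est, tru)
        out[f"slope_pairs_{effname}"] = [list(map(float, p)) for p in pairs]
    return out


def score_replication(sim: SimulatedData, fits: dict) -> dict:
    """All recovery metrics for one replication given its fitted models."""
    truth = sim.truth
    design = truth.design
    target = np.asarray(design.proportions)
    post = fits["mix"]
    pe = point_estimates(post)
    props, _ = class_proportions(post)

    # hit rates per class that is present in the truth
    hr = {}
    for canon in truth.present_classes:
        sel = truth.zeta == canon
        hr[CANONICAL_LABELS[canon]] = hit_rate(pe["zeta"][sel], truth.zeta[sel])
    overall_hr = hit_rate(pe["zeta"], truth.zeta)

    # item parameters
    a_est, a_tru = _alpha_truth_pairs(post, truth)
    slope_bias = bias_rmse(a_est, a_tru)
    gamma_est = post.mean_gamma()
    g_errs_est, g_errs_tru = [], []
    for local, canon in enumerate(truth.present_classes):
        g_errs_est.append(gamma_est[canon, :, 1:].ravel())
        g_errs_tru.append(truth.gamma[local, :, 1:].ravel())
    intercept_bias = bias_rmse(np.concatenate(g_errs_est), np.concatenate(g_errs_tru))

    # latent correlations among traits and faking-trait pairs
    Sig_est = post.mean_sigma()
    T = design.n_traits
    trait_pairs = [(a, b) for a in range(T) for b in range(a + 1, T)]
    est_tt = [Sig_est[a, b] for a, b in trait_pairs]
    tru_tt = [truth.Sigma[a, b] for a, b in trait_pairs]
    corr_tt = bias_rmse(est_tt, tru_tt)

    # person-parameter recovery (only dimensions that influenced the data)
    theta_corr = {}
    active_truth = sorted({d for c in truth.class_spec.classes for d in c.active_dims})
    rs = []
    for d in active_truth:
        if d < T:
            rs.append(np.corrcoef(pe["theta"][:, d], truth.theta[:, d])[0, 1])
    if rs:
        theta_corr["traits"] = fisher_mean_correlation(rs)
    if T in active_truth:
        theta_corr["faking"] = float(
            np.corrcoef(pe["theta"][:, T], truth.theta[:, T])[0, 1]
        )

    crit_table = {
        crit: {
            name: getattr(fits[name], "_criteria")[crit] for name in fits
        }
        for crit in ("dic", "waic", "looic")
    }

    # per-model slope bias and trait-correlation estimates for the
    # misspecification contrasts (non-mixture models fitted to mixture data)
    slope_bias_by_model = {}
    trait_corr_by_model = {}
    for name, p in fits.items():
        e, t = _alpha_truth_pairs(p, truth)
        if e.size:
            slope_bias_by_model[name] = bias_rmse(e, t)
        Sg = p.mean_sigma()
        act = list(p.active_dims)
        tp = [
            Sg[act.index(a), act.index(b)]
            for a, b in trait_pairs
            if a in act and b in act
        ]
        if tp:
            trait_corr_by_model[name] = [float(x) for x in tp]

    return {
        "condition": design.condition,
        "truth_model": _truth_model_name(truth),
        "proportion_bias": {
            CANONICAL_LABELS[c]: float(props[c] - target[c]) for c in range(3)
        },
        "hit_rates": hr,
        "overall_hit_rate": overall_hr,
        "slope_bias": slope_bias,
        "intercept_bias": intercept_bias,
        "trait_correlation_bias": corr_tt,
        "trait_correlation_estimates": trait_corr_by_model,
        "slope_bias_by_model": slope_bias_by_model,
        "theta_correlation": theta_corr,
        "beta_recovery": _beta_recovery(post, truth),
        "criteria": crit_table,
        "max_rhat": {name: fits[name].max_rhat for name in fits},
    }


# ---------------------------------------------------------------------------
# the study driver
# ---------------------------------------------------------------------------


def run_study(
    conditions=(1,),
    reps: int | None = None,
    scale_preset: str = "desk",
    seed: int = 0,
    out_dir=None,
    models=MODEL_NAMES,
    compute_srmr: bool = False,
):
    """Run the simulation study and return a RecoveryReport.

    ``scale_preset`` is "paper", "desk", or a ScalePreset instance.
    Individual replication failures are recorded and the study continues.
    """
    preset = scale_preset if isinstance(scale_preset, ScalePreset) else PRESETS[scale_preset]
    reps = preset.reps if reps is None else reps
    root = np.random.SeedSequence(seed)
    report = RecoveryReport(scale_preset=scale_preset, seed=seed)

    for cond in conditions:
        cond_rows = []
        tables = []
        for rep in range(reps):
            ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(cond, rep))
            data_seed, fit_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
            try:
                design = SimulationDesign(
                    items_per_trait=preset.items_per_trait,
                    n_persons=preset.n_persons,
                    condition=cond,
                    seed=data_seed,
                )
                sim = simulate(design)
                fits = {}
                for j, name in enumerate(models):
                    cfg = SamplerConfig(
                        chains=preset.sampler.chains,
                        burnin=preset.sampler.burnin,
                        iterations=preset.sampler.iterations,
                        seed=(fit_seed + 97 * j) % (2**31),
                    )
                    post = fit(
                        sim.responses,
                        sim.truth.weights,
                        model_spec(name, design.n_traits),
                        covariates=sim.X if name == "mix" else None,
                        config=cfg,
                    )
                    pw = fit_metrics.pointwise_loglik(post, sim.responses)
                    crit = {
                        "dic": fit_metrics.dic(post, sim.responses),
                        "waic": fit_metrics.waic(pw),
                        "looic": fit_metrics.looic(post.pointwise),
                    }
                    if compute_srmr:
                        crit["srmr"] = fit_metrics.ppmc_srmr(
                            post, sim.responses, n_rep=50, seed=fit_seed
                        )
                    post._criteria = crit
                    fits[name] = post
                row = score_replication(sim, fits)
                cond_rows.append(row)
                tables.append(row["criteria"])
            except Exception as exc:  # pragma: no cover - robustness path
                log.exception("condition %s rep %s failed", cond, rep)
                report.failures.append({"condition": cond, "rep": rep, "error": str(exc)})
        if cond_rows:
            report.per_condition[cond] = {
                "replications": cond_rows,
                "selection": selection_percentages(tables, cond_rows[0]["truth_model"]),
            }

    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


@dataclass
class RecoveryReport:
    """Aggregated study output; tables mirror the recovery summaries."""

    scale_preset: str
    seed: int
    per_condition: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def selection_table(self) -> pd.DataFrame:
        rows = []
        for cond, res in self.per_condition.items():
            for crit, v in res["selection"].items():
                rows.append(
                    {
                        "condition": cond,
                        "criterion": crit,
                        "exact": v["exact"],
                        "mixture_vs_non": v["mixture_vs_non"],
                    }
                )
        return pd.DataFrame(rows)

    def proportions_table(self) -> pd.DataFrame:
        rows = []
        for cond, res in self.per_condition.items():
            for label in CANONICAL_LABELS:
                biases = [r["proportion_bias"][label] for r in res["replications"]]
                hrs = [
                    r["hit_rates"][label]
                    for r in res["replications"]
                    if label in r["hit_rates"]
                ]
                rows.append(
                    {
                        "condition": cond,
                        "class": label,
                        "bias": float(np.mean(biases)),
                        "rmse": float(np.sqrt(np.mean(np.square(biases)))),
                        "hit_rate": float(np.mean(hrs)) if hrs else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def regression_table(self) -> pd.DataFrame:
        rows = []
        for cond, res in self.per_condition.items():
            recs = [r["beta_recovery"] for r in res["replications"] if r["beta_recovery"]]
            if not recs:
                continue
            for key in ("intercepts", "slopes_null", "slopes_weak", "slopes_strong"):
                vals = [r[key] for r in recs if key in r]
                if vals:
                    rows.append(
                        {
                            "condition": cond,
                            "coefficients": key,
                            "bias": float(np.mean([v[0] for v in vals])),
                            "rmse": float(np.mean([v[1] for v in vals])),
                        }
                    )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scale_preset": str(self.scale_preset),
            "seed": self.seed,
            "per_condition": {str(k): v for k, v in self.per_condition.items()},
            "failures": self.failures,
        }


def _write_report(report: RecoveryReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.selection_table().to_csv(out / "selection.csv", index=False)
    report.proportions_table().to_csv(out / "proportions.csv", index=False)
    report.regression_table().to_csv(out / "regression.csv", index=False)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1, default=default))


# ---------------------------------------------------------------------------
# class-conditional response distributions
# ---------------------------------------------------------------------------


def class_conditional_item_means(
    responses: ResponseMatrix,
    assignments: np.ndarray,
    desirability_peaks: np.ndarray,
    class_labels=CANONICAL_LABELS,
) -> pd.DataFrame:
    """Mean responses per class, with items grouped by the category of highest
    desirability (argmax of the item's faking scoring weights).

    For items whose most desirable category is the scale maximum, mean
    responses are expected to order F-only >= S&F >= S-only; for mid-peaked
    items the class differences shrink.
    """
    assignments = np.asarray(assignments)
    peaks = np.asarray(desirability_peaks)
    rows = []
    v = responses.values.astype(float)
    v[responses.values == MISSING] = np.nan
    for peak in np.unique(peaks):
        items = np.flatnonzero(peaks == peak)
        for c, label in enumerate(class_labels):
            sel = assignments == c
            if not np.any(sel):
                log.info("class %s empty; omitted from response-distribution table", label)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append(
                    {
                        "peak_category": int(peak),
                        "class": label,
                        "mean_response": float(np.nanmean(v[np.ix_(sel, items)])),
                        "n_items": len(items),
                        "n_persons": int(sel.sum()),
                    }
                )
    return pd.DataFrame(rows)
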