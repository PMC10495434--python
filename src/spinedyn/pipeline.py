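"""End-to-end orchestration of the three computational experiments.

* baseline analysis — fit the LN-OU model to a spontaneous series, simulate
  a matched cohort and compare it back to the data;
* stimulation analysis — separate fits for spontaneous vs stimulation
  snapshots, simulation of the model variants (stochasticity-only,
  drift-only, both, small-spine-only) and pre/post statistics;
* parameter recovery — bias / RMSE / CI-coverage of the estimator on
  synthetic data with known ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats as sps

from . import estimation as est
from . import stats_metrics as smx
from .core_models import (
    LNOUConfig,
    SizeDependentFit,
    StimulationModifier,
    simulate,
    simulate_stimulation_protocol,
)
from .config_io import config_to_dict
from .synthetic_data import GeneratorConfig, SpinePopulationSeries, generate_baseline_dataset

__all__ = [
    "AnalysisReport",
    "run_baseline_analysis",
    "run_stimulation_analysis",
    "run_parameter_recovery",
    "lnou_config_from_recovered",
]

logger = logging.getLogger("spinedyn.pipeline")


@dataclass(frozen=True)
class AnalysisReport:
    """Machine-readable analysis results plus run metadata."""

    statistics: dict
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"statistics": self.statistics, "metadata": self.metadata},
                fh,
                indent=2,
                default=_jsonable,
            )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _config_hash(cfg) -> str:
    payload = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def lnou_config_from_recovered(rec: est.RecoveredParameters) -> LNOUConfig:
    """Build a simulable LN-OU config from recovered parameters.

    Rates are clipped into [0, 1]; when the drift was not identified the
    target falls back to the center of the noise fit's valid range.
    """
    theta = float(np.clip(rec.theta_hat, 0.0, 1.0))
    theta_tilde = float(np.clip(rec.theta_tilde_hat, 0.0, 1.0))
    if np.isfinite(rec.mu_tilde_hat):
        mu_tilde = float(rec.mu_tilde_hat)
    else:
        mu_tilde = float(np.mean(rec.fit.valid_range))
    return LNOUConfig(
        fit=rec.fit,
        theta=theta,
        theta_tilde=theta_tilde,
        mu_tilde=mu_tilde,
        delta_hat=rec.delta_hat,
    )


def _gaussian_ks(changes, max_n=500, seed=0):
    """KS of pooled changes against the normal fitted to them."""
    d = np.asarray(changes, dtype=float).ravel()
    d = d[np.isfinite(d)]
    rng = np.random.default_rng(seed)
    if d.size > max_n:
        d = rng.choice(d, size=max_n, replace=False)
    stat, p = sps.kstest(d, "norm", args=(d.mean(), d.std(ddof=1)))
    return float(stat), float(p)


def run_baseline_analysis(
    data: SpinePopulationSeries,
    seed: int = 0,
    bin_width: float = 0.15,
    n_boot: int = 200,
    alpha: float = 0.05,
) -> AnalysisReport:
    """Fit LN-OU to a spontaneous series and compare a simulation back.

    Also runs the best-fit pure-LN diagnostic (raw fits, no drift or
    momentum), which is expected to show a declining population mean — the
    failure mode that motivates the drift term.
    """
    logger.info("baseline analysis: %d spines x %d timepoints",
                data.n_spines, data.n_timepoints)
    rec = est.recover_parameters(data, bin_width=bin_width, n_boot=n_boot, seed=seed)
    cfg = lnou_config_from_recovered(rec)
    init = data.areas[:, 0]
    init = np.maximum(init[np.isfinite(init)], cfg.size_floor)
    n_steps = data.n_timepoints - 1
    trace = simulate(cfg, init, n_steps, seed)

    data_changes = est.compute_stepwise_changes(data)
    sim_changes = np.diff(trace.sizes, axis=1)
    ks_sizes = smx.ks_two_sample(
        data.areas[np.isfinite(data.areas)], trace.sizes.ravel(), seed=seed
    )
    ks_changes = smx.ks_two_sample(
        data_changes[np.isfinite(data_changes)], sim_changes.ravel(), seed=seed + 1
    )
    data_pooled = est.pooled_change_stats(data_changes)
    gauss_data = _gaussian_ks(data_changes, seed=seed + 2)
    gauss_sim = _gaussian_ks(sim_changes, seed=seed + 3)
    lag_data = smx.lag_correlation_matrix(data_changes).lag1_mean()
    lag_sim = smx.lag_correlation_matrix(sim_changes).lag1_mean()

    # pure-LN diagnostic: raw fits, no drift, no momentum
    ln_cfg = LNOUConfig(
        fit=rec.raw_fit,
        theta=0.0,
        theta_tilde=0.0,
        mu_tilde=cfg.mu_tilde,
        delta_hat=rec.delta_hat,
    )
    ln_trace = simulate(ln_cfg, init, 50, seed + 7)
    ln_means = ln_trace.sizes.mean(axis=0)
    ln_slope, _, _, ln_p, _ = sps.linregress(np.arange(ln_means.size), ln_means)

    statistics = {
        "recovered": {
            "theta_hat": rec.theta_hat,
            "se_theta": rec.se_theta,
            "theta_tilde_hat": rec.theta_tilde_hat,
            "se_theta_tilde": rec.se_theta_tilde,
            "mu_tilde_hat": rec.mu_tilde_hat,
            "se_mu_tilde": rec.se_mu_tilde,
            "delta_hat": rec.delta_hat,
            "raw_slope_mu": rec.raw_fit.slope_mu,
            "raw_slope_sigma": rec.raw_fit.slope_sigma,
            "drift_identified": rec.drift_identified,
        },
        "pooled_change_mean": data_pooled.mu,
        "pooled_change_sd": data_pooled.sigma,
        "model_vs_data_size_ks": {"statistic": ks_sizes[0], "p_value": ks_sizes[1]},
        "model_vs_data_change_ks": {"statistic": ks_changes[0], "p_value": ks_changes[1]},
        "pooled_change_gaussian_ks_data": {"statistic": gauss_data[0], "p_value": gauss_data[1]},
        "pooled_change_gaussian_ks_sim": {"statistic": gauss_sim[0], "p_value": gauss_sim[1]},
        "lag1_correlation_data": lag_data,
        "lag1_correlation_sim": lag_sim,
        "ln_model_mean_slope": float(ln_slope),
        "ln_model_mean_drift_flagged": bool(ln_slope < 0 and ln_p < alpha),
    }
    metadata = {
        "seed": seed,
        "input_subset": "all spines, all timepoints",
        "n_spines": data.n_spines,
        "n_timepoints": data.n_timepoints,
        "config_hash": _config_hash(cfg),
        "floor_hits": trace.floor_hits,
    }
    return AnalysisReport(statistics=statistics, metadata=metadata)


def _fit_points(v, d, valid_range=(0.005, 5.0)) -> SizeDependentFit:
    """Direct (unbinned) size-dependence fit for small samples.

    OLS of the change on size gives the mean map; the SD map comes from a
    scale regression of |residual| * sqrt(pi/2) on size (exact for Gaussian
    residuals), floored so the map stays positive on the valid range.
    """
    v = np.asarray(v, float).ravel()
    d = np.asarray(d, float).ravel()
    keep = np.isfinite(v) & np.isfinite(d)
    v, d = v[keep], d[keep]
    if v.size < 4:
        raise est.EstimationError("too few points for a direct fit")
    slope_mu, icept_mu = np.polyfit(v, d, 1)
    resid = d - (icept_mu + slope_mu * v)
    scale = np.abs(resid) * np.sqrt(np.pi / 2.0)
    slope_sg, icept_sg = np.polyfit(v, scale, 1)
    lo, hi = valid_range
    # keep the SD map positive over the range without changing its slope
    min_val = min(icept_sg + slope_sg * lo, icept_sg + slope_sg * hi)
    if min_val <= 0:
        icept_sg += 1e-3 - min_val
    return SizeDependentFit(
        slope_mu=float(slope_mu),
        intercept_mu=float(icept_mu),
        slope_sigma=float(slope_sg),
        intercept_sigma=float(icept_sg),
        valid_range=valid_range,
    )


def _fit_binned_or_points(v, d, bin_width, n_boot, seed):
    try:
        stats = est.bin_and_summarize(v, d, bin_width, n_boot, seed)
        return est.fit_size_dependence(stats)
    except (est.EstimationError, ValueError):
        return _fit_points(v, d)


def run_stimulation_analysis(
    data: SpinePopulationSeries,
    seed: int = 0,
    bin_width: float = 0.15,
    n_boot: int = 200,
    n_post_sim: int = 30,
    alpha: float = 0.05,
) -> AnalysisReport:
    """Analyze a stimulation-cohort series and simulate the model variants.

    Baseline dynamics are fitted on the unstimulated spines; the
    stimulation snapshot of the homosynaptic spines gives the stimulated
    noise fits and the drift shift. Four variants are simulated:
    stochasticity-only, drift-only, both, and small-spine-only.
    """
    stim = data.stimulation_index
    if stim is None or "homosynaptic" not in data.labels:
        raise ValueError("need a series with homosynaptic labels and a "
                         "stimulation_index")
    homo = data.subset("homosynaptic")
    others_mask = np.array([l != "homosynaptic" for l in data.labels])
    others = SpinePopulationSeries(
        areas=data.areas[others_mask],
        times=data.times,
        labels=tuple(np.array(data.labels)[others_mask]),
        stimulation_index=None,
        provenance={**data.provenance, "subset": "unstimulated"},
    )
    logger.info("stimulation analysis: %d homosynaptic / %d other spines",
                homo.n_spines, others.n_spines)

    rec = est.recover_parameters(others, bin_width=bin_width, n_boot=n_boot, seed=seed)
    base_cfg = lnou_config_from_recovered(rec)

    # fits at the stimulation snapshot (homosynaptic spines)
    stim_change = stim - 1
    homo_changes = est.compute_stepwise_changes(homo)
    v_stim = homo.areas[:, stim_change]
    d_stim = homo_changes[:, stim_change]
    stim_fit = _fit_binned_or_points(v_stim, d_stim, bin_width, n_boot, seed + 1)
    nonstim_cols = [i for i in range(homo_changes.shape[1]) if i != stim_change]
    homo_base_fit = _fit_binned_or_points(
        homo.areas[:, nonstim_cols].ravel(),
        homo_changes[:, nonstim_cols].ravel(),
        bin_width, n_boot, seed + 2,
    )

    # drift shift: post- minus pre-stimulation homosynaptic mean
    pre_mean = float(np.nanmean(homo.areas[:, :stim]))
    post_mean = float(np.nanmean(homo.areas[:, stim:]))
    delta_mu_hat = post_mean - pre_mean

    variants = {
        "stochasticity_only": StimulationModifier(stim_fit=stim_fit, delta_mu=0.0),
        "drift_only": StimulationModifier(
            stim_fit=rec.fit, delta_mu=delta_mu_hat
        ),
        "both": StimulationModifier(stim_fit=stim_fit, delta_mu=delta_mu_hat),
        "small_spine_only": StimulationModifier(
            stim_fit=stim_fit, delta_mu=delta_mu_hat, small_spine_only=True
        ),
    }
    # simulate the variants on a bootstrap-enlarged cohort: entropy and mean
    # trajectories of a histogram need more spines than a 15-spine protocol
    pool = homo.areas[:, 0]
    pool = np.maximum(pool[np.isfinite(pool)], base_cfg.size_floor)
    sim_rng = np.random.default_rng(seed)
    n_sim = max(300, pool.size)
    init = sim_rng.choice(pool, size=n_sim, replace=True)
    n_pre = stim - 1
    variant_stats = {}
    for name, mod in variants.items():
        trace = simulate_stimulation_protocol(
            base_cfg, mod, n_pre, n_post_sim, init, seed
        )
        means = trace.sizes.mean(axis=0)
        stim_col = n_pre + 1
        edges = smx.entropy_bin_edges(trace.sizes, bin_width=bin_width)
        h_pre = smx.shannon_entropy(trace.sizes[:, n_pre], edges).entropy
        h_post = smx.shannon_entropy(trace.sizes[:, -1], edges).entropy
        jump = float(means[stim_col] - means[n_pre])
        final_gap = float(means[-1] - means[n_pre])
        variant_stats[name] = {
            "mean_trajectory": means.tolist(),
            "jump_at_stimulation": jump,
            "final_minus_pre_mean": final_gap,
            "sustained": bool(jump > 0 and final_gap > 0.5 * jump),
            "entropy_pre": h_pre,
            "entropy_post": h_post,
            "entropy_increase": h_post - h_pre,
        }

    report_stats = {
        "baseline_recovered": {
            "theta_hat": rec.theta_hat,
            "theta_tilde_hat": rec.theta_tilde_hat,
            "mu_tilde_hat": rec.mu_tilde_hat,
            "delta_hat": rec.delta_hat,
        },
        "stim_fit": config_to_dict(stim_fit),
        "homo_nonstim_fit": config_to_dict(homo_base_fit),
        "delta_mu_hat": delta_mu_hat,
        "pre_post_mean_test": smx.compare_pre_post(homo, "mean", alpha, bin_width),
        "pre_post_entropy_test": smx.compare_pre_post(homo, "entropy", alpha, bin_width),
        "binned_pre_post_ks": smx.binned_pre_post_ks(homo, bin_width, alpha, seed=seed),
        "variants": variant_stats,
    }
    metadata = {
        "seed": seed,
        "input_subset": {
            "baseline_fit": "heterosynaptic + baseline spines, all transitions",
            "stim_fit": "homosynaptic spines, stimulation transition",
        },
        "n_homosynaptic": homo.n_spines,
        "n_post_sim": n_post_sim,
        "config_hash": _config_hash(base_cfg),
    }
    return AnalysisReport(statistics=report_stats, metadata=metadata)


def run_parameter_recovery(
    configs: list[dict] | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    n_spines: int = 830,
    n_boot: int = 50,
) -> pd.DataFrame:
    """Bias / RMSE / CI-coverage of the estimator on known ground truth.

    Each config dict has ``name`` and ``ground_truth`` (LNOUConfig); 830
    spines x 8 timepoints per replicate by default. The reported
    ``combined_slope`` is the identifiable mean-map slope
    ``slope_mu - theta_tilde``, estimated as the canonical noise-fit slope
    minus the estimated drift rate (the raw binned fit is not used here
    because the momentum term adds a size-correlated component to raw
    changes that the partial regression removes).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if configs is None:
        from .synthetic_data import default_ground_truth

        gt = default_ground_truth()
        configs = [
            {"name": f"theta_{th:g}", "ground_truth": replace(gt, theta=th)}
            for th in (0.1, 0.3, 0.5)
        ]
    rows = []
    root = np.random.SeedSequence(seed)
    for cfg_idx, entry in enumerate(configs):
        gt: LNOUConfig = entry["ground_truth"]
        name = entry.get("name", f"config_{cfg_idx}")
        truth_combined_slope = gt.fit.slope_mu - gt.theta_tilde
        th_hats, tt_hats, mt_hats, slopes = [], [], [], []
        cover_theta = cover_tt = cover_mt = 0
        n_mt = 0
        rep_seeds = root.spawn(1)[0].generate_state(n_replicates) % (2**31)
        for r in range(n_replicates):
            cfg = GeneratorConfig.for_cohort(
                "activity_independent",
                seed=int(rep_seeds[r]) + 7919 * cfg_idx,
                n_spines=n_spines,
                ground_truth=gt,
            )
            data = generate_baseline_dataset(cfg)
            rec = est.recover_parameters(data, n_boot=n_boot, seed=r)
            th_hats.append(rec.theta_hat)
            tt_hats.append(rec.theta_tilde_hat)
            slopes.append(rec.fit.slope_mu - rec.theta_tilde_hat)
            if abs(rec.theta_hat - gt.theta) <= 1.96 * rec.se_theta:
                cover_theta += 1
            if abs(rec.theta_tilde_hat - gt.theta_tilde) <= 1.96 * rec.se_theta_tilde:
                cover_tt += 1
            if np.isfinite(rec.mu_tilde_hat):
                mt_hats.append(rec.mu_tilde_hat)
                n_mt += 1
                if abs(rec.mu_tilde_hat - gt.mu_tilde) <= 1.96 * rec.se_mu_tilde:
                    cover_mt += 1
        th = np.array(th_hats)
        tt = np.array(tt_hats)
        sl = np.array(slopes)
        rows.append(
            {
                "config": name,
                "n_replicates": n_replicates,
                "theta_true": gt.theta,
                "theta_bias": float(th.mean() - gt.theta),
                "theta_rmse": float(np.sqrt(np.mean((th - gt.theta) ** 2))),
                "theta_coverage": cover_theta / n_replicates,
                "theta_tilde_true": gt.theta_tilde,
                "theta_tilde_bias": float(tt.mean() - gt.theta_tilde),
                "theta_tilde_coverage": cover_tt / n_replicates,
                "mu_tilde_true": gt.mu_tilde,
                "mu_tilde_bias": float(np.mean(mt_hats) - gt.mu_tilde)
                if mt_hats
                else float("nan"),
                "mu_tilde_coverage": cover_mt / n_mt if n_mt else float("nan"),
                "combined_slope_true": truth_combined_slope,
                "combined_slope_rel_rmse": float(
                    np.sqrt(np.mean((sl - truth_combined_slope) ** 2))
                    / abs(truth_combined_slope)
                )
                if truth_combined_slope != 0
                else float("nan"),
            }
        )
        logger.info("recovery %s: theta bias %.4f", name, rows[-1]["theta_bias"])
    return pd.DataFrame(rows)
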