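"""Fitting the spine-dynamics model from spine-by-timepoint data.

The pipeline is: per-spine stepwise changes -> size-binned sample moments
with bootstrap CIs -> weighted linear fits of the mean / SD of changes
against size -> moment-to-log-normal parameter transforms -> shift selection
-> joint recovery of the drift and momentum parameters by regression.

Identifiability note: the conditional mean change is linear in the current
size through both the noise mean map f_mu and the drift term
-theta_tilde * (V - mu_tilde); only their sum is identifiable from data.
Estimation therefore works in a canonical gauge in which the drift absorbs
the whole systematic linear mean map and the noise fit (made on residual
changes) has a mean map near zero. The recovered configuration is
observationally equivalent to any other gauge of the same law. The raw
binned fit (the combined mean map, which is what one sees when plotting
binned changes against size) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .core_models import LNNoiseParams, SizeDependentFit

__all__ = [
    "BinnedChangeStats",
    "RecoveredParameters",
    "PooledChangeStats",
    "EstimationError",
    "compute_stepwise_changes",
    "bin_and_summarize",
    "fit_size_dependence",
    "lognormal_params_from_moments",
    "choose_shift",
    "recover_parameters",
    "pooled_change_stats",
]

MIN_BIN_COUNT = 5  # bins with fewer change observations are excluded from fits


class EstimationError(RuntimeError):
    """Raised when the data cannot support the requested fit."""


@dataclass(frozen=True)
class BinnedChangeStats:
    """Per-size-bin sample moments of stepwise changes.

    Bins are half-open ``[edge[k], edge[k+1])`` of equal width anchored at 0.
    ``usable`` marks bins with at least :data:`MIN_BIN_COUNT` observations;
    only those enter downstream fits. CI arrays are (n_bins, 2) lower/upper
    studentized-bootstrap 95% bounds (NaN for empty bins).
    """

    bin_edges: np.ndarray
    n: np.ndarray
    mu_s: np.ndarray
    sigma_s: np.ndarray
    ci_mu: np.ndarray
    ci_sigma: np.ndarray
    usable: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class PooledChangeStats:
    """Sample mean and SD of all stepwise changes pooled across spines/steps."""

    mu: float
    sigma: float
    n: int


@dataclass(frozen=True)
class RecoveredParameters:
    """Estimates of all LN-OU parameters with standard errors.

    ``fit`` is the canonical-gauge noise fit (residual changes; mean map
    near zero). ``raw_fit`` is the fit to raw binned changes — the combined,
    identifiable mean map equal to ``f_mu(V) - theta_tilde*(V - mu_tilde)``
    of whatever gauge generated the data. ``mu_tilde_hat`` is NaN (flagged)
    when the drift rate is indistinguishable from zero.
    """

    fit: SizeDependentFit
    raw_fit: SizeDependentFit
    theta_hat: float
    theta_tilde_hat: float
    mu_tilde_hat: float
    se_theta: float
    se_theta_tilde: float
    se_mu_tilde: float
    delta_hat: float
    drift_identified: bool = True


# ---------------------------------------------------------------------------


def compute_stepwise_changes(series) -> np.ndarray:
    """Consecutive differences ``dV_i = V_i - V_{i-1}`` per spine.

    Accepts a SpinePopulationSeries or a plain spines x timepoints array.
    Missing values (NaN) propagate into the adjacent changes.
    """
    areas = np.asarray(getattr(series, "areas", series), dtype=float)
    if areas.ndim != 2 or areas.shape[1] < 2:
        raise ValueError("need a spines x timepoints matrix with >= 2 timepoints")
    return np.diff(areas, axis=1)


def _studentized_ci(values, stat, se_fn, n_boot, rng, level=0.95):
    """Studentized (bootstrap-t) CI using a plug-in standard error.

    ``stat``/``se_fn`` compute the statistic and its SE on a (B, n) matrix of
    resamples along axis 1.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    est = stat(x[None, :])[0]
    se = se_fn(x[None, :])[0]
    if se == 0 or not np.isfinite(se):
        return est, est
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = x[idx]
    b_est = stat(boot)
    b_se = se_fn(boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (b_est - est) / b_se
    t = t[np.isfinite(t)]
    if t.size == 0:
        return est, est
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(t, [1.0 - alpha / 2.0, alpha / 2.0])
    return est - q_lo * se, est - q_hi * se


def bin_and_summarize(
    sizes_at_step_start,
    changes,
    bin_width: float = 0.15,
    n_boot: int = 1000,
    seed: int = 0,
) -> BinnedChangeStats:
    """Assign each change to the size bin of its start-of-step size.

    Returns per-bin counts, sample mean/SD of changes and studentized
    bootstrap 95% CIs. Bins are half-open, width ``bin_width``, anchored at
    0, covering the observed size range. NaN pairs are dropped.
    """
    v = np.asarray(sizes_at_step_start, dtype=float).ravel()
    d = np.asarray(changes, dtype=float).ravel()
    if v.shape != d.shape:
        raise ValueError("sizes and changes must align")
    keep = np.isfinite(v) & np.isfinite(d)
    v, d = v[keep], d[keep]
    if v.size == 0:
        raise ValueError("no finite (size, change) observations")
    n_bins = int(np.floor(v.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(v / bin_width).astype(int)
    rng = np.random.default_rng(seed)
    counts = np.bincount(idx, minlength=n_bins)
    mu_s = np.full(n_bins, np.nan)
    sigma_s = np.full(n_bins, np.nan)
    ci_mu = np.full((n_bins, 2), np.nan)
    ci_sigma = np.full((n_bins, 2), np.nan)

    def _mean(m):
        return m.mean(axis=1)

    def _mean_se(m):
        return m.std(axis=1, ddof=1) / np.sqrt(m.shape[1])

    def _sd(m):
        return m.std(axis=1, ddof=1)

    def _sd_se(m):
        # normal-theory delta-method SE of the sample SD
        return m.std(axis=1, ddof=1) / np.sqrt(2.0 * (m.shape[1] - 1))

    for k in range(n_bins):
        x = d[idx == k]
        if x.size == 0:
            continue
        mu_s[k] = x.mean()
        if x.size >= 2:
            sigma_s[k] = x.std(ddof=1)
            ci_mu[k] = _studentized_ci(x, _mean, _mean_se, n_boot, rng)
            ci_sigma[k] = _studentized_ci(x, _sd, _sd_se, n_boot, rng)
    return BinnedChangeStats(
        bin_edges=edges,
        n=counts,
        mu_s=mu_s,
        sigma_s=sigma_s,
        ci_mu=ci_mu,
        ci_sigma=ci_sigma,
        usable=counts >= MIN_BIN_COUNT,
    )


def fit_size_dependence(
    stats: BinnedChangeStats, form: str = "linear_in_V"
) -> SizeDependentFit:
    """Weighted least squares of binned mu_s and sigma_s against bin centers.

    Weights are bin counts; regressors are bin centers (or squared centers
    for ``form="linear_in_V_squared"``). Bins below the minimum count are
    excluded.
    """
    use = stats.usable & np.isfinite(stats.mu_s) & np.isfinite(stats.sigma_s)
    if use.sum() < 2:
        raise EstimationError(f"need >= 2 usable bins, have {int(use.sum())}")
    centers = stats.centers[use]
    x = centers**2 if form == "linear_in_V_squared" else centers
    X = sm.add_constant(x)
    w = stats.n[use].astype(float)
    res_mu = sm.WLS(stats.mu_s[use], X, weights=w).fit()
    res_sigma = sm.WLS(stats.sigma_s[use], X, weights=w).fit()
    lo = max(float(centers.min()), 1e-6)
    hi = float(centers.max())
    return SizeDependentFit(
        slope_mu=float(res_mu.params[1]),
        intercept_mu=float(res_mu.params[0]),
        slope_sigma=float(res_sigma.params[1]),
        intercept_sigma=float(res_sigma.params[0]),
        form=form,  # type: ignore[arg-type]
        valid_range=(lo, hi),
        stderr={
            "slope_mu": float(res_mu.bse[1]),
            "intercept_mu": float(res_mu.bse[0]),
            "slope_sigma": float(res_sigma.bse[1]),
            "intercept_sigma": float(res_sigma.bse[0]),
        },
    )


def lognormal_params_from_moments(
    mu_s: float, sigma_s: float, delta_hat: float
) -> LNNoiseParams:
    """Underlying-normal parameters of a shifted log-normal with given moments.

    The returned distribution ``exp(N(mu_log, sigma_log)) - delta_hat`` has
    mean ``mu_s`` and SD ``sigma_s`` exactly.
    """
    m = mu_s + delta_hat
    if m <= 0:
        raise ValueError(f"mu_s + delta_hat must be > 0, got {m}")
    if sigma_s < 0:
        raise ValueError("sigma_s must be >= 0")
    mu_log = float(np.log(m * m / np.sqrt(sigma_s**2 + m * m)))
    sigma_log = float(np.sqrt(np.log((sigma_s / m) ** 2 + 1.0)))
    return LNNoiseParams(mu_log=mu_log, sigma_log=sigma_log, delta_hat=delta_hat)


def choose_shift(all_changes) -> float:
    """One global shift making every change positive after shifting.

    ``delta_hat = max(0, -min(changes)) + margin`` where the margin is 1% of
    the change range (at least 1e-6), so ``min(changes) + delta_hat > 0``.
    """
    d = np.asarray(all_changes, dtype=float).ravel()
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no finite changes")
    margin = max(0.01 * float(d.max() - d.min()), 1e-6)
    return max(0.0, -float(d.min())) + margin


def pooled_change_stats(all_changes) -> PooledChangeStats:
    """Sample mean and SD of all changes pooled across spines and steps."""
    d = np.asarray(all_changes, dtype=float).ravel()
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("need at least 2 finite changes")
    return PooledChangeStats(
        mu=float(d.mean()), sigma=float(d.std(ddof=1)), n=int(d.size)
    )


def recover_parameters(
    series,
    bin_width: float = 0.15,
    n_boot: int = 1000,
    seed: int = 0,
    form: str = "linear_in_V",
) -> RecoveredParameters:
    """Recover all LN-OU parameters from a spine-by-timepoint series.

    Drift and momentum come from the pooled OLS regression of the next
    change on the centered current size and the current change,

        dV_{i+1} = c + b * (V_i - Vbar) + a * dV_i + eps,

    giving ``theta_hat = -a``, ``theta_tilde_hat = -b`` and, by matching the
    drift term, ``mu_tilde_hat = Vbar + c / theta_tilde_hat`` (delta-method
    SE). The noise fit is then made on residual changes with drift and
    momentum removed; the shift comes from the raw pooled changes. When the
    series marks a stimulation step, changes at that transition are excluded
    (they reflect induced, not spontaneous, plasticity). HC1-robust standard
    errors are used since the noise SD grows with size.
    """
    areas = np.asarray(getattr(series, "areas", series), dtype=float)
    if areas.ndim != 2 or areas.shape[1] < 3:
        raise EstimationError("need >= 3 timepoints to separate drift and momentum")
    changes = np.diff(areas, axis=1)
    n_ch = changes.shape[1]
    stim_index = getattr(series, "stimulation_index", None)
    stim_change = None if stim_index is None else stim_index - 1

    y_parts, v_parts, d_parts = [], [], []
    for i in range(1, n_ch):
        if stim_change is not None and (i == stim_change or i - 1 == stim_change):
            continue
        y_parts.append(changes[:, i])
        v_parts.append(areas[:, i])
        d_parts.append(changes[:, i - 1])
    if not y_parts:
        raise EstimationError("no usable transitions after exclusions")
    y = np.concatenate(y_parts)
    v = np.concatenate(v_parts)
    d_prev = np.concatenate(d_parts)
    keep = np.isfinite(y) & np.isfinite(v) & np.isfinite(d_prev)
    y, v, d_prev = y[keep], v[keep], d_prev[keep]
    if y.size < 10:
        raise EstimationError("too few complete (size, change, next-change) triples")
    v_bar = float(v.mean())
    if v.std() == 0 or d_prev.std() == 0 or y.std() == 0:
        raise EstimationError("zero-variance input: dynamics are degenerate")

    X = sm.add_constant(np.column_stack([v - v_bar, d_prev]))
    res = sm.OLS(y, X).fit(cov_type="HC1")
    c, b, a = res.params
    se_c, se_b, se_a = res.bse
    theta_hat = -float(a)
    theta_tilde_hat = -float(b)

    drift_identified = abs(b) > 2.0 * se_b
    if drift_identified:
        mu_tilde_hat = v_bar + float(c) / theta_tilde_hat
        cov = res.cov_params()
        var_mu = (
            (1.0 / b) ** 2 * cov[0, 0]
            + (c / b**2) ** 2 * cov[1, 1]
            - 2.0 * (c / b**3) * cov[0, 1]
        )
        se_mu_tilde = float(np.sqrt(max(var_mu, 0.0)))
    else:
        mu_tilde_hat = float("nan")
        se_mu_tilde = float("nan")

    # canonical-gauge noise fit: residual changes with drift + momentum removed
    resid = y + theta_hat * d_prev
    if drift_identified:
        resid = resid + theta_tilde_hat * (v - mu_tilde_hat)
    binned_resid = bin_and_summarize(v, resid, bin_width, n_boot, seed)
    fit = fit_size_dependence(binned_resid, form)

    # raw (combined-map) fit, excluding the stimulation snapshot if marked
    if stim_change is not None:
        cols = [i for i in range(n_ch) if i != stim_change]
    else:
        cols = list(range(n_ch))
    raw_v = areas[:, cols].ravel()
    raw_d = changes[:, cols].ravel()
    binned_raw = bin_and_summarize(raw_v, raw_d, bin_width, n_boot, seed + 1)
    raw_fit = fit_size_dependence(binned_raw, form)

    delta_hat = choose_shift(changes)
    return RecoveredParameters(
        fit=fit,
        raw_fit=raw_fit,
        theta_hat=theta_hat,
        theta_tilde_hat=theta_tilde_hat,
        mu_tilde_hat=mu_tilde_hat,
        se_theta=float(se_a),
        se_theta_tilde=float(se_b),
        se_mu_tilde=se_mu_tilde,
        delta_hat=delta_hat,
        drift_identified=drift_identified,
    )
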