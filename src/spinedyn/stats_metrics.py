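"""Descriptive and comparative statistics for spine size populations.

Shannon entropy of the binned size distribution, lag correlation structure
of stepwise changes, Kolmogorov–Smirnov based distribution ranking and
two-sample comparisons, and pre- vs post-stimulation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "EntropyResult",
    "DistributionFitResult",
    "LagCorrelationMatrix",
    "shannon_entropy",
    "entropy_bin_edges",
    "lag_correlation_matrix",
    "consecutive_change_slope",
    "rank_distribution_fits",
    "ks_two_sample",
    "compare_pre_post",
    "binned_pre_post_ks",
]

DEFAULT_FAMILIES = {
    "normal": sps.norm,
    "lognormal": sps.lognorm,
    "gamma": sps.gamma,
    "exponential": sps.expon,
    "weibull": sps.weibull_min,
}


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy (bits) of a binned size distribution."""

    entropy: float
    bin_edges: np.ndarray
    probabilities: np.ndarray
    n: int


@dataclass(frozen=True)
class DistributionFitResult:
    """Maximum-likelihood fits of candidate families ranked by KS statistic."""

    fits: list[dict]  # name, params, ks_statistic, p_value (or error)

    @property
    def ranking(self) -> list[str]:
        ok = [f for f in self.fits if "ks_statistic" in f]
        return [f["name"] for f in sorted(ok, key=lambda f: f["ks_statistic"])]

    @property
    def best(self) -> str:
        return self.ranking[0]


@dataclass(frozen=True)
class LagCorrelationMatrix:
    """Pearson correlations between change columns at all timestep pairs."""

    matrix: np.ndarray
    flagged: np.ndarray = field(default=None)  # zero-variance columns

    def lag1_mean(self) -> float:
        """Mean correlation over adjacent-step pairs (first off-diagonal)."""
        off = np.diagonal(self.matrix, offset=1)
        return float(np.nanmean(off))


def entropy_bin_edges(*samples, bin_width: float = 0.15) -> np.ndarray:
    """Shared fixed-width edges spanning the pooled range of all samples.

    Entropy values are only comparable when computed on shared edges.
    """
    pooled = np.concatenate([np.asarray(s, float).ravel() for s in samples])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no finite values")
    lo = np.floor(pooled.min() / bin_width) * bin_width
    n_bins = int(np.floor((pooled.max() - lo) / bin_width)) + 1
    return lo + np.arange(n_bins + 1) * bin_width


def shannon_entropy(sizes, bin_edges) -> EntropyResult:
    """Shannon entropy ``H = -sum p log2 p`` of the binned size histogram.

    Values outside the edges are captured by appended overflow bins so that
    the histogram always covers the data; ``0 * log 0`` is taken as 0.
    """
    x = np.asarray(sizes, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("sizes must be non-empty")
    edges = np.asarray(bin_edges, dtype=float)
    if x.min() < edges[0]:
        edges = np.concatenate([[x.min()], edges])
    if x.max() >= edges[-1]:
        edges = np.concatenate([edges, [np.nextafter(x.max(), np.inf)]])
    counts, edges = np.histogram(x, bins=edges)
    p = counts / counts.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return EntropyResult(entropy=h, bin_edges=edges, probabilities=p, n=int(x.size))


def lag_correlation_matrix(changes) -> LagCorrelationMatrix:
    """Pairwise Pearson correlations across spines between change columns.

    Missing values are handled pairwise-complete. Zero-variance columns are
    flagged and yield NaN entries rather than raising.
    """
    d = np.asarray(changes, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2 or d.shape[0] < 3:
        raise ValueError("need >= 3 spines and >= 2 change columns")
    df = pd.DataFrame(d)
    flagged = (df.std(ddof=1) == 0).to_numpy()
    mat = df.corr(method="pearson").to_numpy()
    np.fill_diagonal(mat, 1.0)
    return LagCorrelationMatrix(matrix=mat, flagged=flagged)


def consecutive_change_slope(
    changes, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Pooled OLS slope of the next change on the current change, with CI.

    Pools all (dV_i, dV_{i+1}) pairs across spines and steps; the bootstrap
    resamples pairs. This slope equals minus the momentum strength when the
    dynamics follow the negative-momentum recursion.
    """
    d = np.asarray(changes, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2:
        raise ValueError("need >= 2 change columns")
    x = d[:, :-1].ravel()
    y = d[:, 1:].ravel()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3 or x.std() == 0:
        raise ValueError("degenerate change variance")
    slope = float(np.polyfit(x, y, 1)[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb, yb = x[idx[b]], y[idx[b]]
        boots[b] = np.polyfit(xb, yb, 1)[0] if xb.std() > 0 else np.nan
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return slope, (float(lo), float(hi))


def rank_distribution_fits(
    sample, families: dict | None = None
) -> DistributionFitResult:
    """Fit candidate families by ML and rank by one-sample KS statistic.

    Each family in ``families`` (name -> frozen-able scipy distribution) is
    fitted by maximum likelihood; the KS statistic of the sample against the
    fitted distribution is the ranking key (smaller is better). Per-family
    fit failures are recorded, not fatal.
    """
    x = np.asarray(sample, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 observations")
    fams = DEFAULT_FAMILIES if families is None else families
    fits = []
    for name, dist in fams.items():
        try:
            params = dist.fit(x)
            stat, p = sps.kstest(x, dist.cdf, args=params)
            fits.append(
                {
                    "name": name,
                    "params": tuple(float(p_) for p_ in params),
                    "ks_statistic": float(stat),
                    "p_value": float(p),
                }
            )
        except Exception as exc:  # noqa: BLE001 — per-family failure is data
            fits.append({"name": name, "error": str(exc)})
    return DistributionFitResult(fits=fits)


def ks_two_sample(a, b, max_n: int = 500, seed: int = 0) -> tuple[float, float]:
    """Two-sample KS test with deterministic subsampling of large samples.

    Samples larger than ``max_n`` are subsampled without replacement using
    the fixed seed, so repeated calls agree. Returns (statistic, p_value).
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in (a, b):
        s = np.asarray(s, dtype=float).ravel()
        s = s[np.isfinite(s)]
        if s.size == 0:
            raise ValueError("both samples must be non-empty")
        if s.size > max_n:
            s = rng.choice(s, size=max_n, replace=False)
        out.append(s)
    res = sps.ks_2samp(out[0], out[1])
    return float(res.statistic), float(res.pvalue)


def _column_entropies(areas, cols, edges):
    vals = []
    for c in cols:
        x = areas[:, c]
        vals.append(shannon_entropy(x[np.isfinite(x)], edges).entropy)
    return np.array(vals)


def compare_pre_post(
    series,
    metric: str = "mean",
    alpha: float = 0.05,
    bin_width: float = 0.15,
) -> dict:
    """Pre- vs post-stimulation tests on a series with a marked stimulation.

    Two-sided t test comparing the per-timepoint metric (population mean or
    Shannon entropy of the size distribution) between pre- and
    post-stimulation columns, plus a one-way ANOVA across per-timepoint
    change distributions with a Tukey HSD post-hoc identifying which
    transitions differ.
    """
    stim = getattr(series, "stimulation_index", None)
    if stim is None:
        raise ValueError("series has no stimulation_index marker")
    areas = np.asarray(series.areas, dtype=float)
    pre_cols = list(range(stim))
    post_cols = list(range(stim, areas.shape[1]))
    if metric == "mean":
        pre_vals = np.array([np.nanmean(areas[:, c]) for c in pre_cols])
        post_vals = np.array([np.nanmean(areas[:, c]) for c in post_cols])
    elif metric == "entropy":
        edges = entropy_bin_edges(areas[np.isfinite(areas)], bin_width=bin_width)
        pre_vals = _column_entropies(areas, pre_cols, edges)
        post_vals = _column_entropies(areas, post_cols, edges)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    t_stat, t_p = sps.ttest_ind(pre_vals, post_vals)

    changes = np.diff(areas, axis=1)
    groups, labels = [], []
    for i in range(changes.shape[1]):
        g = changes[:, i]
        g = g[np.isfinite(g)]
        if g.size >= 2:
            groups.append(g)
            labels.append(i)
    f_stat, f_p = sps.f_oneway(*groups)
    flat = np.concatenate(groups)
    grp = np.concatenate([[str(l)] * len(g) for l, g in zip(labels, groups)])
    tukey = pairwise_tukeyhsd(flat, grp, alpha=alpha)
    tk = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    # a transition is an outlier if every Tukey comparison involving it rejects
    flagged = []
    for g in sorted(set(tk["group1"]) | set(tk["group2"]), key=int):
        rows = tk[(tk["group1"] == g) | (tk["group2"] == g)]
        if len(rows) and rows["reject"].all():
            flagged.append(int(g))
    return {
        "metric": metric,
        "t_statistic": float(t_stat),
        "t_p_value": float(t_p),
        "significant": bool(t_p < alpha),
        "pre_values": pre_vals.tolist(),
        "post_values": post_vals.tolist(),
        "anova_F": float(f_stat),
        "anova_p_value": float(f_p),
        "tukey_flagged_transitions": flagged,
        "stimulation_transition": int(stim - 1),
        "stimulation_transition_flagged": (stim - 1) in flagged,
    }


def binned_pre_post_ks(
    series,
    bin_width: float = 0.15,
    alpha: float = 0.05,
    max_n: int = 500,
    seed: int = 0,
) -> list[dict]:
    """Per-size-bin KS between spontaneous and stimulation-step changes.

    For each start-of-step size bin, compares the pooled changes of all
    non-stimulation transitions against the changes of the stimulation
    transition, and reports shifted log-normal fit parameters per bin. Bins
    with fewer than 2 observations on either side are skipped with a flag.
    """
    stim = getattr(series, "stimulation_index", None)
    if stim is None:
        raise ValueError("series has no stimulation_index marker")
    areas = np.asarray(series.areas, dtype=float)
    changes = np.diff(areas, axis=1)
    stim_change = stim - 1
    other = [i for i in range(changes.shape[1]) if i != stim_change]
    base_v = areas[:, other].ravel()
    base_d = changes[:, other].ravel()
    stim_v = areas[:, stim_change]
    stim_d = changes[:, stim_change]

    pooled = changes[np.isfinite(changes)]
    shift = max(0.0, -float(pooled.min())) + 0.01 * float(np.ptp(pooled))

    hi = np.nanmax(areas)
    n_bins = int(np.floor(hi / bin_width)) + 1
    reports = []
    for k in range(n_bins):
        lo_e, hi_e = k * bin_width, (k + 1) * bin_width
        sel_b = (base_v >= lo_e) & (base_v < hi_e) & np.isfinite(base_d)
        sel_s = (stim_v >= lo_e) & (stim_v < hi_e) & np.isfinite(stim_d)
        rep: dict = {"bin": (lo_e, hi_e), "n_base": int(sel_b.sum()), "n_stim": int(sel_s.sum())}
        if sel_b.sum() < 2 or sel_s.sum() < 2:
            rep["skipped"] = True
            reports.append(rep)
            continue
        stat, p = ks_two_sample(base_d[sel_b], stim_d[sel_s], max_n=max_n, seed=seed + k)
        rep.update(
            ks_statistic=stat, p_value=p, significant=bool(p < alpha), skipped=False
        )
        for label, vals in (("base", base_d[sel_b]), ("stim", stim_d[sel_s])):
            s, loc, scale = sps.lognorm.fit(vals + shift, floc=0.0)
            rep[f"lognormal_fit_{label}"] = {
                "sigma_log": float(s),
                "mu_log": float(np.log(scale)),
                "shift": float(shift),
            }
        reports.append(rep)
    return reports
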