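"""Synthetic spine-population datasets and the interchange CSV format.

The generator is a stand-in for two-photon imaging of dendritic spines on
CA1 pyramidal neurons: spine head areas (um^2) recorded at eight
acquisitions (-15, -10, -5, 2, 10, 20, 30, 40 min around a stimulation or
sham event). Ground truth is the LN-OU model; the defaults reproduce the
study conditions — a right-skewed stationary size distribution, small
spines growing on average with low change SD while large spines shrink
with high SD, approximately Gaussian pooled changes with SD near 0.074
um^2, and lag-1 change correlation near -0.3.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_models import (
    LNOUConfig,
    SizeDependentFit,
    StimulationModifier,
    ln_ou_step,
)

__all__ = [
    "SpinePopulationSeries",
    "GeneratorConfig",
    "DEFAULT_TIMES",
    "default_ground_truth",
    "default_stim_modifier",
    "generate_baseline_dataset",
    "generate_stimulation_dataset",
    "write_series",
    "read_series",
    "read_series_mapped",
    "ParseError",
]

DEFAULT_TIMES = (-15.0, -10.0, -5.0, 2.0, 10.0, 20.0, 30.0, 40.0)
VALID_LABELS = ("homosynaptic", "heterosynaptic", "sham", "baseline")

# Initial size distribution before burn-in: a plain log-normal chosen to give
# a right-skewed population with median ~0.32 um^2 and a long right tail,
# comparable to measured spine head areas.
INIT_MU_LOG = math.log(0.32)
INIT_SIGMA_LOG = 0.55


class ParseError(ValueError):
    """Raised for malformed series files; messages name line numbers."""


@dataclass(frozen=True)
class SpinePopulationSeries:
    """Spine-by-timepoint area matrix with labels and a time grid.

    ``areas`` is spines x timepoints (um^2, NaN = missing). ``labels`` is
    one of homosynaptic / heterosynaptic / sham / baseline per spine.
    ``stimulation_index`` marks the column whose incoming transition is the
    stimulation step (None for purely spontaneous series).
    """

    areas: np.ndarray
    times: tuple[float, ...] = DEFAULT_TIMES
    labels: tuple[str, ...] = ()
    stimulation_index: int | None = None
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "areas", areas)
        if areas.ndim != 2:
            raise ValueError("areas must be a 2-D spines x timepoints matrix")
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) != areas.shape[1]:
            raise ValueError("times length must match the number of columns")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        labels = tuple(self.labels) if self.labels else ("baseline",) * areas.shape[0]
        if len(labels) != areas.shape[0]:
            raise ValueError("labels length must match the number of spines")
        for lab in labels:
            if lab not in VALID_LABELS:
                raise ValueError(f"unknown label {lab!r}")
        object.__setattr__(self, "labels", labels)
        finite = areas[np.isfinite(areas)]
        if finite.size and finite.min() <= 0:
            raise ValueError("areas must be > 0 where present")
        if "homosynaptic" in labels:
            if self.stimulation_index is None or not (
                0 < self.stimulation_index < areas.shape[1]
            ):
                raise ValueError(
                    "stimulation_index must be an in-range column when "
                    "homosynaptic spines are present"
                )

    @property
    def n_spines(self) -> int:
        return self.areas.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.areas.shape[1]

    def subset(self, label: str) -> "SpinePopulationSeries":
        """Rows with the given label (stimulation marker preserved)."""
        mask = np.array([l == label for l in self.labels])
        return SpinePopulationSeries(
            areas=self.areas[mask],
            times=self.times,
            labels=tuple(np.array(self.labels)[mask]),
            stimulation_index=self.stimulation_index,
            provenance={**self.provenance, "subset": label},
        )


def default_ground_truth() -> LNOUConfig:
    """The generator's default LN-OU parameterization (canonical gauge).

    The noise mean map is zero — the size dependence of the mean change is
    carried entirely by the drift toward mu_tilde = 0.35 um^2 — and the
    noise SD grows linearly with size, which yields the right-skewed
    stationary distribution and the higher variability of large spines.
    """
    fit = SizeDependentFit(
        slope_mu=0.0,
        intercept_mu=0.0,
        slope_sigma=0.085,
        intercept_sigma=0.0375,
        valid_range=(0.005, 5.0),
    )
    return LNOUConfig(
        fit=fit,
        theta=0.3,
        theta_tilde=0.1,
        mu_tilde=0.35,
        delta_hat=1.0,
        size_floor=0.01,
    )


def default_stim_modifier(
    cohort: str = "stim15", small_spine_only: bool = False
) -> StimulationModifier:
    """Default structural-LTP modifier for a cohort.

    The stimulation-snapshot mean map gives small spines a large positive
    increment that shrinks with size, and the SD map is tilted upward. The
    15-spine protocol shifts the drift target persistently (tau = inf); the
    7-spine protocol decays back to baseline with tau = 3 steps.
    """
    stim_fit = SizeDependentFit(
        slope_mu=-0.3,
        intercept_mu=0.25,
        slope_sigma=0.15,
        intercept_sigma=0.05,
        valid_range=(0.005, 5.0),
    )
    tau = math.inf if cohort == "stim15" else 3.0
    return StimulationModifier(
        stim_fit=stim_fit,
        delta_mu=0.15,
        tau=tau,
        small_spine_only=small_spine_only,
        small_spine_threshold=0.35,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic dataset.

    Cohort defaults follow the study design: 830 spines for the
    activity-independent (sham) experiment; 204 / 338 total spines with 7 /
    15 stimulated spines for the two activity-dependent protocols.
    """

    cohort: str = "activity_independent"
    n_spines: int = 830
    n_stimulated: int = 0
    ground_truth: LNOUConfig = field(default_factory=default_ground_truth)
    modifier: StimulationModifier | None = None
    init: str = "fitted_shifted_lognormal"
    init_sample: np.ndarray | None = None
    heterosynaptic_fraction: float = 0.3
    burn_in: int = 20
    times: tuple[float, ...] = DEFAULT_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort not in ("activity_independent", "stim7", "stim15"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.n_stimulated > self.n_spines:
            raise ValueError("n_stimulated cannot exceed n_spines")

    @classmethod
    def for_cohort(cls, cohort: str, seed: int = 0, **overrides) -> "GeneratorConfig":
        defaults: dict = {"cohort": cohort, "seed": seed}
        if cohort == "activity_independent":
            defaults.update(n_spines=830, n_stimulated=0)
        elif cohort == "stim7":
            defaults.update(
                n_spines=204, n_stimulated=7, modifier=default_stim_modifier("stim7")
            )
        elif cohort == "stim15":
            defaults.update(
                n_spines=338, n_stimulated=15, modifier=default_stim_modifier("stim15")
            )
        else:
            raise ValueError(f"unknown cohort {cohort!r}")
        defaults.update(overrides)
        return cls(**defaults)


def _initial_sizes(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.init == "explicit_sample":
        if cfg.init_sample is None:
            raise ValueError("init='explicit_sample' requires init_sample")
        pool = np.asarray(cfg.init_sample, dtype=float)
        sizes = rng.choice(pool, size=cfg.n_spines, replace=True)
    elif cfg.init == "fitted_shifted_lognormal":
        sizes = rng.lognormal(INIT_MU_LOG, INIT_SIGMA_LOG, size=cfg.n_spines)
    else:
        raise ValueError(f"unknown init {cfg.init!r}")
    return np.maximum(sizes, cfg.ground_truth.size_floor)


def generate_baseline_dataset(cfg: GeneratorConfig) -> SpinePopulationSeries:
    """Spontaneous (activity-independent) dataset: all spines baseline.

    Initial sizes are drawn from the right-skewed initial distribution and
    burned in for ``cfg.burn_in`` LN-OU steps before the recorded columns,
    so the recorded series is near-stationary.
    """
    if cfg.cohort != "activity_independent":
        raise ValueError("generate_baseline_dataset requires the "
                         "activity_independent cohort")
    n_rec = len(cfg.times)
    n_steps = cfg.burn_in + (n_rec - 1)
    root = np.random.SeedSequence(cfg.seed)
    init_ss, *step_ss = root.spawn(1 + n_steps)
    gt = cfg.ground_truth
    sizes = _initial_sizes(cfg, np.random.default_rng(init_ss))
    prev = sizes.copy()
    recorded = []
    for i in range(n_steps + 1):
        if i >= cfg.burn_in:
            recorded.append(sizes.copy())
        if i == n_steps:
            break
        nxt = ln_ou_step(prev, sizes, gt, np.random.default_rng(step_ss[i]))
        prev, sizes = sizes, nxt
    areas = np.column_stack(recorded)
    return SpinePopulationSeries(
        areas=areas,
        times=cfg.times,
        labels=("baseline",) * cfg.n_spines,
        stimulation_index=None,
        provenance={"generator": "baseline", "seed": cfg.seed},
    )


def generate_stimulation_dataset(cfg: GeneratorConfig) -> SpinePopulationSeries:
    """Stimulation-cohort dataset with homo-/heterosynaptic labels.

    All spines burn in and evolve under baseline LN-OU through the three
    pre-stimulation columns. At the pre-stimulation snapshot, homosynaptic
    spines are drawn from the middle size tercile (medium-sized spines were
    preferentially targeted) and a configurable fraction of the remainder
    is labeled heterosynaptic (proximity to stimulation sites is emulated
    by the label only). Homosynaptic spines then follow the stimulation
    modifier; all others continue under baseline dynamics. The stimulation
    transition leads into column 3 (the +2 min acquisition).
    """
    if cfg.cohort not in ("stim7", "stim15"):
        raise ValueError("generate_stimulation_dataset requires a stim cohort")
    if cfg.modifier is None:
        raise ValueError("stimulation cohorts need a StimulationModifier")
    if cfg.n_stimulated <= 0:
        raise ValueError("n_stimulated must be positive for stim cohorts")
    n_rec = len(cfg.times)
    stim_index = 3
    n_pre_steps = stim_index - 1  # transitions among the recorded pre columns
    n_post_steps = n_rec - 1 - stim_index
    n_steps = cfg.burn_in + n_pre_steps + 1 + n_post_steps
    root = np.random.SeedSequence(cfg.seed)
    init_ss, select_ss, *step_ss = root.spawn(2 + n_steps)
    gt = cfg.ground_truth
    mod = cfg.modifier

    sizes = _initial_sizes(cfg, np.random.default_rng(init_ss))
    prev = sizes.copy()
    recorded: list[np.ndarray] = []
    labels: np.ndarray | None = None
    homo_mask = np.zeros(cfg.n_spines, dtype=bool)
    stim_step_global = cfg.burn_in + n_pre_steps  # step index of the stimulation

    for i in range(n_steps + 1):
        if i >= cfg.burn_in:
            recorded.append(sizes.copy())
        if i == stim_step_global and labels is None:
            # select homosynaptic spines from the middle tercile now
            sel_rng = np.random.default_rng(select_ss)
            lo, hi = np.quantile(sizes, [1 / 3, 2 / 3])
            medium = np.flatnonzero((sizes >= lo) & (sizes <= hi))
            if medium.size < cfg.n_stimulated:
                raise ValueError("middle tercile smaller than n_stimulated")
            homo = sel_rng.choice(medium, size=cfg.n_stimulated, replace=False)
            homo_mask[homo] = True
            rest = np.flatnonzero(~homo_mask)
            n_het = int(round(cfg.heterosynaptic_fraction * rest.size))
            het = sel_rng.choice(rest, size=n_het, replace=False)
            labels = np.full(cfg.n_spines, "baseline", dtype=object)
            labels[het] = "heterosynaptic"
            labels[homo] = "homosynaptic"
        if i == n_steps:
            break
        base_rng, stim_rng = (
            np.random.default_rng(s) for s in step_ss[i].spawn(2)
        )
        nxt = ln_ou_step(prev, sizes, gt, base_rng)
        if i >= stim_step_global:
            if i == stim_step_global:
                kwargs: dict = {"momentum": not mod.disable_momentum_at_stim}
                if mod.small_spine_only:
                    kwargs["small_spine_fit"] = (
                        mod.stim_fit,
                        mod.small_spine_threshold,
                    )
                else:
                    kwargs["fit"] = mod.stim_fit
            else:
                t_post = i - stim_step_global - 1
                kwargs = {"mu_tilde": mod.drift_target(gt, t_post)}
            prev_h = prev[homo_mask]
            if (
                i == stim_step_global + 1
                and mod.disable_momentum_at_stim
            ):  # stim change does not feed the momentum term
                prev_h = sizes[homo_mask]
            nxt_h = ln_ou_step(
                prev_h, sizes[homo_mask], gt, stim_rng, **kwargs
            )
            nxt[homo_mask] = nxt_h
        prev, sizes = sizes, nxt

    areas = np.column_stack(recorded)
    assert labels is not None
    return SpinePopulationSeries(
        areas=areas,
        times=cfg.times,
        labels=tuple(labels),
        stimulation_index=stim_index,
        provenance={"generator": cfg.cohort, "seed": cfg.seed},
    )


# ---------------------------------------------------------------------------
# interchange format
# ---------------------------------------------------------------------------


def _time_col(t: float) -> str:
    return f"t_{t:g}"


def write_series(series: SpinePopulationSeries, path) -> None:
    """Write a series as UTF-8 CSV with ``#``-prefixed metadata lines.

    The round-trip through :func:`read_series` is lossless for values
    (17 significant digits), labels, times and the stimulation marker.
    Missing values are written as empty fields.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# times: " + ",".join(f"{t:g}" for t in series.times) + "\n")
        if series.stimulation_index is not None:
            fh.write(f"# stimulation_index: {series.stimulation_index}\n")
        if series.provenance:
            fh.write("# provenance: " + json.dumps(series.provenance) + "\n")
        writer = csv.writer(fh)
        writer.writerow(["spine_id", "label"] + [_time_col(t) for t in series.times])
        for i in range(series.n_spines):
            row = [str(i), series.labels[i]]
            for v in series.areas[i]:
                row.append("" if not np.isfinite(v) else f"{v:.17g}")
            writer.writerow(row)


def read_series(path) -> SpinePopulationSeries:
    """Read the interchange CSV written by :func:`write_series`.

    Malformed headers, non-numeric areas and non-increasing time grids
    raise :class:`ParseError` naming the offending line number.
    """
    times: tuple[float, ...] | None = None
    stim_index: int | None = None
    provenance: dict = {}
    header: list[str] | None = None
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                try:
                    key, value = body.split(":", 1)
                except ValueError:
                    raise ParseError(f"line {lineno}: malformed metadata {line!r}")
                key = key.strip()
                value = value.strip()
                if key == "times":
                    try:
                        times = tuple(float(v) for v in value.split(","))
                    except ValueError:
                        raise ParseError(f"line {lineno}: non-numeric time in {value!r}")
                    if np.any(np.diff(times) <= 0):
                        raise ParseError(
                            f"line {lineno}: times must be strictly increasing"
                        )
                elif key == "stimulation_index":
                    stim_index = int(value)
                elif key == "provenance":
                    provenance = json.loads(value)
                continue
            cells = next(csv.reader([line]))
            if header is None:
                header = cells
                if len(header) < 3 or header[:2] != ["spine_id", "label"]:
                    raise ParseError(
                        f"line {lineno}: expected header starting with "
                        f"'spine_id,label', got {line!r}"
                    )
                continue
            if len(cells) != len(header):
                raise ParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(cells)}"
                )
            labels.append(cells[1])
            vals = []
            for col, cell in zip(header[2:], cells[2:]):
                if cell == "":
                    vals.append(float("nan"))
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-numeric area {cell!r} in column {col}"
                    )
            rows.append(vals)
    if header is None or not rows:
        raise ParseError("file contains no data rows")
    if times is None:
        raise ParseError("missing '# times:' metadata line")
    try:
        return SpinePopulationSeries(
            areas=np.array(rows, dtype=float),
            times=times,
            labels=tuple(labels),
            stimulation_index=stim_index,
            provenance={**provenance, "source": str(path)},
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def read_series_mapped(
    path,
    time_columns: Sequence[str],
    times: Sequence[float],
    label_column: str | None = None,
    default_label: str = "baseline",
    stimulation_index: int | None = None,
    label_map: dict | None = None,
) -> SpinePopulationSeries:
    """Read an arbitrary wide CSV via an explicit column mapping.

    Intended for externally deposited datasets whose layout differs from the
    interchange format: ``time_columns`` name the area columns in temporal
    order and ``times`` give the matching acquisition times. ``label_map``
    translates foreign label values onto the homosynaptic / heterosynaptic /
    sham / baseline vocabulary.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    missing = [c for c in time_columns if c not in df.columns]
    if missing:
        raise ParseError(f"columns not found: {missing}")
    areas = df[list(time_columns)].to_numpy(dtype=float)
    if label_column is not None:
        raw = df[label_column].astype(str)
        if label_map:
            raw = raw.map(lambda x: label_map.get(x, x))
        labels = tuple(raw)
    else:
        labels = (default_label,) * len(df)
    return SpinePopulationSeries(
        areas=areas,
        times=tuple(times),
        labels=labels,
        stimulation_index=stimulation_index,
        provenance={"source": str(path), "mapping": list(time_columns)},
    )
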