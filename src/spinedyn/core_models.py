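"""Generative stochastic models of dendritic spine size dynamics.

All models are discrete-time recursions on spine head area ``V_i`` (um^2),
one step per imaging acquisition. Four baseline models of increasing realism
are provided:

* walled Gaussian — additive Gaussian noise bounded by hard walls,
* discrete Ornstein–Uhlenbeck (OU) — Gaussian noise plus mean reversion,
* negative momentum — Gaussian noise plus a pull toward the previous size,
  which makes successive changes anti-correlated,
* shifted log-normal (LN) — size-dependent, right-skewed increments, and

the final LN-OU model, which combines size-dependent shifted log-normal
noise, a global OU drift toward a population set point, and the negative
momentum term:

    V_{i+1} = V_i + Lognormal(mu_log(V_i), sigma_log(V_i), -delta_hat)
                  - theta_tilde * (V_i - mu_tilde)
                  - theta * (V_i - V_{i-1})

Stimulation (structural LTP) is modeled as a one-step substitution of the
noise fits plus a persistent or exponentially decaying shift of the drift
target ``mu_tilde``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "WalledGaussianConfig",
    "OUConfig",
    "NegMomentumConfig",
    "LNNoiseParams",
    "SizeDependentFit",
    "LNOUConfig",
    "StimulationModifier",
    "SimulationTrace",
    "sample_shifted_lognormal",
    "gaussian_walled_step",
    "ou_step",
    "negative_momentum_step",
    "ln_step",
    "ln_ou_step",
    "simulate",
    "simulate_stimulation_protocol",
]


class ConfigurationError(ValueError):
    """Raised when a model configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WalledGaussianConfig:
    """Additive Gaussian increments bounded by two hard walls.

    ``wall_left``/``wall_right`` are meant to be set from data: the 5th
    percentile and the maximum of the observed sizes. ``mechanism`` selects
    what happens when a proposed step exits ``[wall_left, wall_right]``:
    ``"no_change"`` keeps the previous size, ``"bounce"`` reflects the
    proposal off the wall.
    """

    mu: float
    sigma: float
    wall_left: float
    wall_right: float
    mechanism: Literal["no_change", "bounce"] = "no_change"

    def __post_init__(self) -> None:
        if not self.wall_left < self.wall_right:
            raise ConfigurationError(
                f"wall_left ({self.wall_left}) must be < wall_right ({self.wall_right})"
            )
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


@dataclass(frozen=True)
class OUConfig:
    """Discrete Ornstein–Uhlenbeck: reversion at rate ``theta`` toward ``mu_bar``."""

    theta: float
    mu_bar: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError("theta must lie in [0, 1]")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


@dataclass(frozen=True)
class NegMomentumConfig:
    """Negative momentum: pull of strength ``theta`` toward the previous size.

    Successive changes follow an AR(1) law with coefficient ``-theta``, so the
    stationary lag-1 correlation of changes equals ``-theta`` exactly.
    """

    theta: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError("theta must lie in [0, 1]")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


@dataclass(frozen=True)
class LNNoiseParams:
    """Parameters of one shifted log-normal increment distribution.

    An increment is ``exp(N(mu_log, sigma_log)) - delta_hat``; its support is
    the open interval ``(-delta_hat, inf)``.
    """

    mu_log: float
    sigma_log: float
    delta_hat: float

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ConfigurationError("sigma_log must be >= 0")
        if self.delta_hat <= 0:
            raise ConfigurationError("delta_hat must be > 0")


@dataclass(frozen=True)
class SizeDependentFit:
    """Linear maps from spine size to the mean / SD of its next change.

    ``f_mu(V) = intercept_mu + slope_mu * x`` and
    ``f_sigma(V) = intercept_sigma + slope_sigma * x`` where ``x`` is ``V``
    (``form="linear_in_V"``) or ``V**2`` (``form="linear_in_V_squared"``).
    ``f_sigma`` must be strictly positive over ``valid_range``, which is
    checked at construction (linearity means checking the endpoints).
    ``stderr`` optionally carries standard errors from the fitting routine.
    """

    slope_mu: float
    intercept_mu: float
    slope_sigma: float
    intercept_sigma: float
    form: Literal["linear_in_V", "linear_in_V_squared"] = "linear_in_V"
    valid_range: tuple[float, float] = (0.01, 3.0)
    stderr: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not lo < hi:
            raise ConfigurationError("valid_range must be increasing")
        for v in (lo, hi):
            if self.sigma(v) <= 0:
                raise ConfigurationError(
                    f"f_sigma({v}) = {self.sigma(v):.4g} <= 0 on valid_range"
                )

    def _x(self, sizes):
        x = np.asarray(sizes, dtype=float)
        return x * x if self.form == "linear_in_V_squared" else x

    def mu(self, sizes):
        """Evaluate f_mu, the mean change map, at the given sizes."""
        return self.intercept_mu + self.slope_mu * self._x(sizes)

    def sigma(self, sizes):
        """Evaluate f_sigma, the SD-of-change map, at the given sizes."""
        return self.intercept_sigma + self.slope_sigma * self._x(sizes)


@dataclass(frozen=True)
class LNOUConfig:
    """Full parameterization of the LN-OU recursion."""

    fit: SizeDependentFit
    theta: float
    theta_tilde: float
    mu_tilde: float
    delta_hat: float
    size_floor: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError("theta must lie in [0, 1]")
        if not 0.0 <= self.theta_tilde <= 1.0:
            raise ConfigurationError("theta_tilde must lie in [0, 1]")
        if self.delta_hat <= 0:
            raise ConfigurationError("delta_hat must be > 0")
        if self.size_floor <= 0:
            raise ConfigurationError("size_floor must be > 0")


@dataclass(frozen=True)
class StimulationModifier:
    """How structural LTP perturbs the baseline LN-OU dynamics.

    At the stimulation step the noise fits are replaced by ``stim_fit``
    (restricted to spines below ``small_spine_threshold`` when
    ``small_spine_only``; their SD then stays at baseline) and, by default,
    the momentum term is dropped. Afterwards the drift target follows

        mu_tilde_post(t) = mu_tilde_pre + delta_mu * exp(-t / tau)

    with ``t`` counting post-stimulation steps from 0; ``tau = inf`` gives a
    persistent shift.
    """

    stim_fit: SizeDependentFit
    delta_mu: float = 0.0
    tau: float = math.inf
    small_spine_only: bool = False
    small_spine_threshold: float = 0.35
    disable_momentum_at_stim: bool = True

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ConfigurationError("tau must be > 0 (may be inf)")
        if self.small_spine_threshold <= 0:
            raise ConfigurationError("small_spine_threshold must be > 0")

    def drift_target(self, cfg: LNOUConfig, t_post: int) -> float:
        """Drift target at post-stimulation step ``t_post`` (0-based)."""
        if math.isinf(self.tau):
            return cfg.mu_tilde + self.delta_mu
        return cfg.mu_tilde + self.delta_mu * math.exp(-t_post / self.tau)


@dataclass(frozen=True)
class SimulationTrace:
    """Simulated spine size trajectories plus provenance.

    ``sizes`` is spines x (n_steps + 1); column 0 is the initial condition.
    ``step_labels`` has one entry per transition. ``floor_hits`` counts
    proposals that were clipped at the configured size floor.
    """

    sizes: np.ndarray
    step_labels: tuple[str, ...]
    seed: int
    config: object
    floor_hits: int = 0

    @property
    def n_spines(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.sizes.shape[1] - 1


# ---------------------------------------------------------------------------
# noise primitives and single-step recursions
# ---------------------------------------------------------------------------


def sample_shifted_lognormal(
    params: LNNoiseParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` increments from ``Lognormal(mu_log, sigma_log) - delta_hat``."""
    if n <= 0:
        raise ValueError(f"n must be a positive integer, got {n}")
    return rng.lognormal(params.mu_log, params.sigma_log, size=n) - params.delta_hat


def gaussian_walled_step(
    sizes, cfg: WalledGaussianConfig, rng: np.random.Generator
) -> np.ndarray:
    """One walled-Gaussian step: propose V + N(mu, sigma), then enforce walls."""
    v = np.asarray(sizes, dtype=float)
    proposal = v + rng.normal(cfg.mu, cfg.sigma, size=v.shape)
    out_of_range = (proposal < cfg.wall_left) | (proposal > cfg.wall_right)
    if cfg.mechanism == "no_change":
        return np.where(out_of_range, v, proposal)
    # bounce: reflect off whichever wall was crossed
    reflected = np.where(
        proposal < cfg.wall_left, 2 * cfg.wall_left - proposal, proposal
    )
    reflected = np.where(
        proposal > cfg.wall_right, 2 * cfg.wall_right - proposal, reflected
    )
    # a huge step could reflect past the other wall; clip as a last resort
    return np.clip(reflected, cfg.wall_left, cfg.wall_right)


def ou_step(sizes, cfg: OUConfig, rng: np.random.Generator) -> np.ndarray:
    """One discrete OU step: V + theta * (mu_bar - V) + N(0, sigma)."""
    v = np.asarray(sizes, dtype=float)
    return v + cfg.theta * (cfg.mu_bar - v) + rng.normal(0.0, cfg.sigma, size=v.shape)


def negative_momentum_step(
    prev_sizes, sizes, cfg: NegMomentumConfig, rng: np.random.Generator
) -> np.ndarray:
    """One negative-momentum step: V + theta * (V_prev - V) + N(0, sigma)."""
    prev = np.asarray(prev_sizes, dtype=float)
    v = np.asarray(sizes, dtype=float)
    if prev.shape != v.shape:
        raise ValueError(
            f"prev_sizes and sizes must align: {prev.shape} vs {v.shape}"
        )
    return v + cfg.theta * (prev - v) + rng.normal(0.0, cfg.sigma, size=v.shape)


def _lognormal_transform(mu_s, sigma_s, delta_hat):
    """Moment-matching transform to underlying-normal parameters.

    Maps the target mean/SD (mu_s, sigma_s) of a shifted log-normal with
    shift -delta_hat to the (mu_log, sigma_log) of the underlying normal.
    Vectorized; requires mu_s + delta_hat > 0.
    """
    m = np.asarray(mu_s, dtype=float) + delta_hat
    s = np.asarray(sigma_s, dtype=float)
    mu_log = np.log(m * m / np.sqrt(s * s + m * m))
    sigma_log = np.sqrt(np.log((s / m) ** 2 + 1.0))
    return mu_log, sigma_log


def _ln_noise(sizes, fit: SizeDependentFit, delta_hat: float, rng) -> np.ndarray:
    """Size-dependent shifted log-normal increments for each spine."""
    v = np.asarray(sizes, dtype=float)
    sigma_s = fit.sigma(v)
    if np.any(sigma_s <= 0):
        bad = float(v[np.argmax(sigma_s <= 0)])
        raise ConfigurationError(
            f"f_sigma is non-positive at spine size {bad:.4g} um^2"
        )
    mu_s = fit.mu(v)
    if np.any(mu_s + delta_hat <= 0):
        bad = float(v[np.argmax(mu_s + delta_hat <= 0)])
        raise ConfigurationError(
            f"f_mu + delta_hat is non-positive at spine size {bad:.4g} um^2"
        )
    mu_log, sigma_log = _lognormal_transform(mu_s, sigma_s, delta_hat)
    return rng.lognormal(mu_log, sigma_log) - delta_hat


def ln_step(
    sizes,
    fit: SizeDependentFit,
    delta_hat: float,
    size_floor: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One step of the pure size-dependent shifted log-normal model."""
    v = np.asarray(sizes, dtype=float)
    out = v + _ln_noise(v, fit, delta_hat, rng)
    return np.maximum(out, size_floor)


def ln_ou_step(
    prev_sizes,
    sizes,
    cfg: LNOUConfig,
    rng: np.random.Generator,
    *,
    fit: SizeDependentFit | None = None,
    mu_tilde: float | None = None,
    momentum: bool = True,
    small_spine_fit: tuple[SizeDependentFit, float] | None = None,
) -> np.ndarray:
    """One LN-OU step: noise minus drift minus momentum, floored.

    Keyword overrides serve the stimulation protocol: ``fit`` replaces the
    noise fit, ``mu_tilde`` replaces the drift target, ``momentum=False``
    drops the momentum term, and ``small_spine_fit=(stim_fit, threshold)``
    substitutes only the mean map of ``stim_fit`` for spines below the
    threshold (their SD stays at baseline).
    """
    prev = np.asarray(prev_sizes, dtype=float)
    v = np.asarray(sizes, dtype=float)
    if prev.shape != v.shape:
        raise ValueError(
            f"prev_sizes and sizes must align: {prev.shape} vs {v.shape}"
        )
    base_fit = cfg.fit if fit is None else fit
    if small_spine_fit is None:
        noise = _ln_noise(v, base_fit, cfg.delta_hat, rng)
    else:
        stim_fit, threshold = small_spine_fit
        mu_s = np.where(v < threshold, stim_fit.mu(v), base_fit.mu(v))
        sigma_s = base_fit.sigma(v)
        if np.any(sigma_s <= 0):
            raise ConfigurationError("f_sigma is non-positive at some spine size")
        mu_log, sigma_log = _lognormal_transform(mu_s, sigma_s, cfg.delta_hat)
        noise = rng.lognormal(mu_log, sigma_log) - cfg.delta_hat
    target = cfg.mu_tilde if mu_tilde is None else mu_tilde
    out = v + noise - cfg.theta_tilde * (v - target)
    if momentum:
        out = out - cfg.theta * (v - prev)
    return np.maximum(out, cfg.size_floor)


# ---------------------------------------------------------------------------
# simulation engine
# ---------------------------------------------------------------------------


def _step_rngs(seed: int, n_steps: int) -> list[np.random.Generator]:
    """Deterministic per-step substreams from one root seed.

    Spawning one child stream per step means that changing the number of
    spines never silently reorders draws across steps.
    """
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in root.spawn(n_steps)]


def _check_init(init_sizes) -> np.ndarray:
    init = np.asarray(init_sizes, dtype=float)
    if init.ndim != 1 or init.size == 0:
        raise ValueError("init_sizes must be a non-empty 1-D array")
    return init


def simulate(model, init_sizes, n_steps: int, seed: int) -> SimulationTrace:
    """Run any of the baseline models for ``n_steps`` from ``init_sizes``.

    ``model`` is one of :class:`WalledGaussianConfig`, :class:`OUConfig`,
    :class:`NegMomentumConfig` or :class:`LNOUConfig` (a pure LN model is an
    LN-OU with ``theta = theta_tilde = 0``). Momentum models use
    ``V_{-1} = V_0``, so the momentum term is zero on the first step.
    """
    init = _check_init(init_sizes)
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    sizes = np.empty((init.size, n_steps + 1), dtype=float)
    sizes[:, 0] = init
    floor_hits = 0
    rngs = _step_rngs(seed, n_steps)
    if isinstance(model, LNOUConfig):
        if np.any(init < model.size_floor):
            raise ValueError("init_sizes must be >= size_floor")
    prev = init.copy()
    for i in range(n_steps):
        cur = sizes[:, i]
        if isinstance(model, WalledGaussianConfig):
            nxt = gaussian_walled_step(cur, model, rngs[i])
        elif isinstance(model, OUConfig):
            nxt = ou_step(cur, model, rngs[i])
        elif isinstance(model, NegMomentumConfig):
            nxt = negative_momentum_step(prev, cur, model, rngs[i])
        elif isinstance(model, LNOUConfig):
            nxt = ln_ou_step(prev, cur, model, rngs[i])
            floor_hits += int(np.count_nonzero(nxt == model.size_floor))
        else:
            raise TypeError(f"unknown model config: {type(model).__name__}")
        prev = cur.copy()
        sizes[:, i + 1] = nxt
    return SimulationTrace(
        sizes=sizes,
        step_labels=("baseline",) * n_steps,
        seed=seed,
        config=model,
        floor_hits=floor_hits,
    )


def simulate_stimulation_protocol(
    cfg: LNOUConfig,
    mod: StimulationModifier,
    n_pre: int,
    n_post: int,
    init_sizes,
    seed: int,
) -> SimulationTrace:
    """Baseline steps, one stimulation step, then post-stimulation steps.

    The trace has ``n_pre + 1 + n_post`` transitions. During the stimulation
    transition the noise fits come from the modifier and the momentum term is
    (by default) disabled; the drift term stays active at the pre-stimulation
    target. Disabling momentum also keeps the stimulation-induced change out
    of the next step's momentum memory (otherwise the bounce-back would
    immediately undo part of the induced growth, which contradicts the
    premise that momentum is a feature of spontaneous dynamics only).
    Afterwards the drift target follows the modifier's decay law with the
    post-step clock starting at 0.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("n_pre and n_post must be >= 1")
    init = _check_init(init_sizes)
    if np.any(init < cfg.size_floor):
        raise ValueError("init_sizes must be >= size_floor")
    n_steps = n_pre + 1 + n_post
    labels = ("baseline",) * n_pre + ("stimulation",) + ("post",) * n_post
    sizes = np.empty((init.size, n_steps + 1), dtype=float)
    sizes[:, 0] = init
    rngs = _step_rngs(seed, n_steps)
    floor_hits = 0
    prev = init.copy()
    for i in range(n_steps):
        cur = sizes[:, i]
        if labels[i] == "baseline":
            nxt = ln_ou_step(prev, cur, cfg, rngs[i])
        elif labels[i] == "stimulation":
            kwargs: dict = {"momentum": not mod.disable_momentum_at_stim}
            if mod.small_spine_only:
                kwargs["small_spine_fit"] = (mod.stim_fit, mod.small_spine_threshold)
            else:
                kwargs["fit"] = mod.stim_fit
            nxt = ln_ou_step(prev, cur, cfg, rngs[i], **kwargs)
        else:  # post
            t_post = i - (n_pre + 1)
            prev_eff = prev
            if t_post == 0 and mod.disable_momentum_at_stim:
                prev_eff = cur  # stim change does not feed the momentum term
            nxt = ln_ou_step(
                prev_eff, cur, cfg, rngs[i], mu_tilde=mod.drift_target(cfg, t_post)
            )
        floor_hits += int(np.count_nonzero(nxt == cfg.size_floor))
        prev = cur.copy()
        sizes[:, i + 1] = nxt
    return SimulationTrace(
        sizes=sizes,
        step_labels=labels,
        seed=seed,
        config=(cfg, mod),
        floor_hits=floor_hits,
    )
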