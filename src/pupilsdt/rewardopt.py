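"""Reward-rate optimization of the Go/No-go decision criterion.

A simulated observer faces the session's trial economy: on an S+ trial the
evidence is N(mu, 1) with mu the mean perceptual sensitivity (0.52 by
default), on an S- trial N(0, 1), and the observer licks whenever the
evidence exceeds its decision criterion c.  Each outcome costs time:

    hit            : U(1, 3.5) wait + mean RT + 6 s inter-trial interval
    miss / correct : U(1, 3.5) wait + 1.3 s response window + 6 s ITI
    false alarm    : U(1, 3.5) wait + mean RT + 10 s timeout + 6 s ITI

and only hits pay (60 uL of water).  The reward rate (uL of water per
second of session time) is estimated for every criterion on a grid, and the
criterion maximizing it is the optimal criterion for that paradigm.  A
closed-form expectation of the same process is provided as an oracle.

The reward-rate curve is extremely flat on its liberal (negative) side,
especially for Go-rich paradigms, so the Monte-Carlo argmax has substantial
spread across repeats; means and standard errors over repeats are always
reported together.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .constants import MEAN_SENSITIVITY, OBSERVED_MEAN_RT
from .psychometrics import criterion_slope

__all__ = [
    "RewardSimConfig",
    "RewardCurve",
    "OptimalCriterion",
    "default_config",
    "trial_duration",
    "simulate_reward_rate",
    "analytic_reward_rate",
    "find_optimal_criterion",
    "optimal_slope",
]


@dataclass(frozen=True)
class RewardSimConfig:
    """Parameters of the reward-rate simulation for one paradigm."""

    go_fraction: float
    mean_rt: float
    observer_mean: float = MEAN_SENSITIVITY
    observer_sd: float = 1.0
    reward_volume: float = 60.0          # uL per hit
    wait_range: tuple[float, float] = (1.0, 3.5)
    response_window: float = 1.3
    timeout: float = 10.0
    iti: float = 6.0
    n_trials: int = 15_000
    n_repeats: int = 20
    criterion_grid: tuple[float, float, float] = (-4.0, 1.0, 0.05)

    def __post_init__(self):
        if not (0.0 < self.go_fraction < 1.0):
            raise ValueError("go_fraction must lie strictly in (0, 1)")
        lo, hi, step = self.criterion_grid
        if step <= 0 or lo >= hi:
            raise ValueError("criterion grid must have lo < hi and step > 0")
        if self.n_trials < 1 or self.n_repeats < 1:
            raise ValueError("n_trials and n_repeats must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        lo, hi, step = self.criterion_grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    @property
    def mean_wait(self) -> float:
        return 0.5 * (self.wait_range[0] + self.wait_range[1])


def default_config(go_fraction: float, **overrides) -> RewardSimConfig:
    """Config with the per-paradigm observed mean reaction time as default."""
    if go_fraction not in OBSERVED_MEAN_RT and "mean_rt" not in overrides:
        raise ValueError(
            f"no default mean RT for go_fraction={go_fraction}; pass mean_rt"
        )
    mean_rt = overrides.pop("mean_rt", OBSERVED_MEAN_RT.get(go_fraction))
    return RewardSimConfig(go_fraction=go_fraction, mean_rt=mean_rt, **overrides)


@dataclass(frozen=True)
class RewardCurve:
    """Monte-Carlo reward-rate estimates over the criterion grid."""

    criteria: np.ndarray
    rates: np.ndarray          # (n_repeats, n_criteria)
    analytic: np.ndarray

    @property
    def mean_rate(self) -> np.ndarray:
        return self.rates.mean(axis=0)

    @property
    def se_rate(self) -> np.ndarray:
        if self.rates.shape[0] < 2:
            return np.full(self.rates.shape[1], np.nan)
        return self.rates.std(axis=0, ddof=1) / np.sqrt(self.rates.shape[0])


@dataclass(frozen=True)
class OptimalCriterion:
    """Per-repeat argmax criteria with their mean and standard error."""

    mean: float
    se: float
    per_repeat: np.ndarray
    curve: RewardCurve


def trial_duration(outcome: str, config: RewardSimConfig, rng: np.random.Generator) -> float:
    """Draw the duration in seconds of one trial with the given outcome."""
    wait = rng.uniform(*config.wait_range)
    if outcome == "HIT":
        return wait + config.mean_rt + config.iti
    if outcome in ("MISS", "CORRECT_REJECTION"):
        return wait + config.response_window + config.iti
    if outcome == "FALSE_ALARM":
        return wait + config.mean_rt + config.timeout + config.iti
    raise ValueError(f"unknown outcome {outcome!r}")


def _simulate_rates_once(
    criteria: np.ndarray, config: RewardSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Reward rate at every criterion for one Monte-Carlo repeat.

    A single set of ``n_trials`` stimulus/evidence/wait draws is evaluated
    at every criterion (common random numbers), so each criterion sees
    n_trials trials and the estimated curve is smooth in the criterion.
    Sharing draws leaves every per-criterion estimate unbiased while making
    differences between nearby criteria nearly noise-free, which keeps the
    argmax of this very flat curve well conditioned.
    """
    n = config.n_trials
    is_go = rng.random(n) < config.go_fraction
    evidence = rng.standard_normal(n) * config.observer_sd
    evidence += np.where(is_go, config.observer_mean, 0.0)
    wait = rng.uniform(*config.wait_range, size=n)
    lick = evidence[None, :] > criteria[:, None]
    hit = lick & is_go[None, :]
    fa = lick & ~is_go[None, :]
    dur = (wait + config.iti)[None, :] + np.where(
        lick, config.mean_rt, config.response_window
    )
    dur = dur + np.where(fa, config.timeout, 0.0)
    reward = config.reward_volume * hit.sum(axis=1)
    return reward / dur.sum(axis=1)


def simulate_reward_rate(criterion: float, config: RewardSimConfig, seed=None) -> float:
    """Monte-Carlo reward rate (uL/s) at a single decision criterion."""
    if not np.isfinite(criterion):
        raise ValueError("criterion must be finite")
    rng = np.random.default_rng(seed)
    return float(_simulate_rates_once(np.array([criterion]), config, rng)[0])


def analytic_reward_rate(criterion, config: RewardSimConfig):
    """Expected reward rate (uL/s): closed-form counterpart of the simulation.

    With h = Phi((mu - c) / sd) the hit probability and f = Phi(-c / sd) the
    false-alarm probability, the expected reward per trial is p*h*V and the
    expected trial duration is the outcome-probability-weighted mean of the
    four duration recipes; their ratio is the long-run reward rate by the
    renewal-reward theorem.
    """
    c = np.asarray(criterion, dtype=float)
    p = config.go_fraction
    h = stats.norm.sf((c - config.observer_mean) / config.observer_sd)
    f = stats.norm.sf(c / config.observer_sd)
    base = config.mean_wait + config.iti
    dur_hit = base + config.mean_rt
    dur_quiet = base + config.response_window       # miss or correct rejection
    dur_fa = base + config.mean_rt + config.timeout
    mean_reward = p * h * config.reward_volume
    mean_dur = p * (h * dur_hit + (1 - h) * dur_quiet) + (1 - p) * (
        f * dur_fa + (1 - f) * dur_quiet
    )
    out = mean_reward / mean_dur
    return float(out) if out.ndim == 0 else out


def find_optimal_criterion(config: RewardSimConfig, seed=None) -> OptimalCriterion:
    """Grid-search the reward-maximizing criterion, repeated n_repeats times.

    Within each repeat the argmax over the grid is taken (ties resolved to
    the most negative criterion); the mean and standard error over repeats
    quantify the Monte-Carlo spread of the optimum.
    """
    grid = config.grid
    if grid.size < 2:
        raise ValueError("criterion grid must contain at least two points")
    rng = np.random.default_rng(seed)
    rates = np.empty((config.n_repeats, grid.size))
    for r in range(config.n_repeats):
        rates[r] = _simulate_rates_once(grid, config, rng)
    # grid is ascending, argmax returns the first (most negative) maximizer
    optima = grid[np.argmax(rates, axis=1)]
    se = optima.std(ddof=1) / np.sqrt(config.n_repeats) if config.n_repeats > 1 else np.nan
    curve = RewardCurve(criteria=grid, rates=rates, analytic=analytic_reward_rate(grid, config))
    return OptimalCriterion(mean=float(optima.mean()), se=float(se), per_repeat=optima, curve=curve)


def analytic_optimal_criterion(config: RewardSimConfig) -> float:
    """Argmax of the closed-form reward rate over the configured grid."""
    grid = config.grid
    return float(grid[np.argmax(analytic_reward_rate(grid, config))])


def optimal_slope(optima_by_go_fraction) -> float:
    """Slope of the optimal criterion across paradigms.

    ``optima_by_go_fraction`` maps go fraction to the (mean) optimal
    criterion; paradigms are placed on an ordinal axis ordered by decreasing
    Go fraction before the least-squares fit.
    """
    items = sorted(optima_by_go_fraction.items(), key=lambda kv: -kv[0])
    return criterion_slope([v for _, v in items])
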