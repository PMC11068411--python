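"""Drift-diffusion modeling of Go/No-go decisions with a response deadline.

The decision variable starts at a fraction ``z`` of the boundary separation
``a`` and drifts at rate ``v_go`` (S+ trials) or ``v_nogo`` (S- trials) with
unit diffusion.  Hitting the upper boundary produces a lick at the crossing
time plus the non-decision time ``t0``; hitting the lower boundary, or
failing to cross either boundary before the response deadline, produces a
withheld response.  Because withheld responses carry no reaction time, their
likelihood is the censored mixture

    P(withhold) = 1 - P(upper crossing before deadline - t0),

which lumps lower-boundary absorptions with deadline censoring.

Four variants with different constraints are compared:

    M1: z = 0.5, v_nogo = -v_go   (3 free parameters: a, v_go, t0)
    M2: z free, v_nogo = -v_go    (4)
    M3: z = 0.5, v_nogo free      (4)
    M4: z free,  v_nogo free      (5)

Fitting is multi-start bounded maximum likelihood; variants are ranked by
AIC (BIC reported alongside).  The first-passage density uses the classical
dual series expansion for the Wiener process between absorbing boundaries,
switching between the small-time and large-time forms where the required
number of terms is smallest.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DDMParams",
    "FitResult",
    "VARIANTS",
    "simulate_ddm",
    "simulate_ddm_trials",
    "wfpt_density",
    "upper_density",
    "prob_upper_before",
    "trial_nll",
    "total_nll",
    "fit_ddm",
    "compare_models",
]

VARIANTS = ("M1", "M2", "M3", "M4")

#: Free parameters per variant (boundary, drift(s), start bias, t0).
N_FREE = {"M1": 3, "M2": 4, "M3": 4, "M4": 5}

_LIK_FLOOR = 1e-300


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters; ``variant`` enforces its constraints."""

    a: float
    z: float
    v_go: float
    v_nogo: float
    t0: float
    variant: str | None = None

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if not (0.0 < self.z < 1.0):
            raise ValueError("start-point fraction z must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be nonnegative")
        if self.variant is not None:
            if self.variant not in VARIANTS:
                raise ValueError(f"unknown variant {self.variant!r}")
            if self.variant in ("M1", "M3") and self.z != 0.5:
                raise ValueError(f"{self.variant} requires z = 0.5")
            if self.variant in ("M1", "M2") and self.v_nogo != -self.v_go:
                raise ValueError(f"{self.variant} requires v_nogo = -v_go")

    def drift(self, stimulus: str) -> float:
        return self.v_go if stimulus == "S_PLUS" else self.v_nogo


@dataclass(frozen=True)
class FitResult:
    params: DDMParams
    nll: float
    aic: float
    bic: float
    n_trials: int
    converged: bool
    n_free: int


# ----------------------------------------------------------------------
# first-passage density


def _fpt_lower_unit(tau, w, err=1e-10):
    """Density of lower-boundary absorption for a=1, v=0, start w, at scaled
    time tau; dual series expansion with per-element form selection."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    t = tau[pos]
    if t.size == 0:
        return out

    with np.errstate(divide="ignore", invalid="ignore"):
        # required number of terms for each expansion (standard bounds)
        ks = 2.0 + np.sqrt(-2.0 * t * np.log(2.0 * err * np.sqrt(2.0 * np.pi * t)))
        ks = np.where(2.0 * err * np.sqrt(2.0 * np.pi * t) < 1.0, ks, 2.0)
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        kl = np.sqrt(-2.0 * np.log(np.pi * t * err) / (np.pi**2 * t))
        kl = np.where(np.pi * t * err < 1.0, kl, 1.0 / (np.pi * np.sqrt(t)))
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    val = np.empty_like(t)

    if np.any(use_small):
        ts = t[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 2)  # ceil(K) terms about 0
        arg = w + 2.0 * k[None, :]
        dens = (arg * np.exp(-(arg**2) / (2.0 * ts[:, None]))).sum(axis=1)
        val[use_small] = dens / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl = t[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        k = np.arange(1, K + 1)
        dens = (
            k[None, :]
            * np.exp(-(k[None, :] ** 2) * np.pi**2 * tl[:, None] / 2.0)
            * np.sin(k[None, :] * np.pi * w)
        ).sum(axis=1)
        val[~use_small] = dens * np.pi

    out[pos] = np.maximum(val, 0.0)
    return out


def wfpt_density(t, a: float, z: float, v: float, err: float = 1e-10):
    """First-passage density at the LOWER boundary.

    Start point is ``z * a``; drift ``v``; unit diffusion.  The upper-
    boundary density follows from the reflection (z, v) -> (1 - z, -v).
    Returns 0 for t <= 0 by convention.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    tau = t_arr / a**2
    base = _fpt_lower_unit(tau, z, err=err)
    with np.errstate(over="ignore"):
        dens = np.where(
            t_arr > 0,
            base / a**2 * np.exp(-v * a * z - v**2 * t_arr / 2.0),
            0.0,
        )
    return float(dens[0]) if scalar else dens


def upper_density(t, a: float, z: float, v: float, err: float = 1e-10):
    """First-passage density at the UPPER boundary (reflection identity)."""
    return wfpt_density(t, a, 1.0 - z, -v, err=err)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)


def prob_upper_before(T: float, a: float, z: float, v: float) -> float:
    """P(upper-boundary absorption occurs before time T), by quadrature."""
    if T <= 0:
        return 0.0
    # integrate on sqrt-time to resolve the sharp early rise of the density
    s = 0.5 * np.sqrt(T) * (_GL_NODES + 1.0)
    w = 0.5 * np.sqrt(T) * _GL_WEIGHTS
    vals = upper_density(s**2, a, z, v) * 2.0 * s
    return float(min(max(np.sum(w * vals), 0.0), 1.0))


# ----------------------------------------------------------------------
# forward simulation


def simulate_ddm_trials(
    params: DDMParams,
    stimuli,
    deadline: float | None = 1.3,
    dt: float = 1e-3,
    seed=None,
    max_time: float = 20.0,
):
    """Euler-Maruyama forward simulation of many trials.

    Parameters
    ----------
    stimuli : sequence of "S_PLUS"/"S_MINUS"
    deadline : float or None
        Response deadline in seconds (measured from stimulus onset,
        inclusive of ``t0``).  None removes the deadline (walks run until
        absorption or ``max_time``).

    Returns
    -------
    responded : bool array — upper-boundary crossing with rt <= deadline
    rt : float array — crossing time + t0 (NaN when not responded)
    """
    if deadline is not None and deadline <= params.t0:
        raise ValueError("deadline must exceed the non-decision time t0")
    rng = np.random.default_rng(seed)
    stimuli = np.asarray(stimuli)
    n = stimuli.size
    drift = np.where(stimuli == "S_PLUS", params.v_go, params.v_nogo)
    horizon = (deadline - params.t0) if deadline is not None else max_time
    n_steps = int(np.ceil(horizon / dt))
    x = np.full(n, params.z * params.a)
    active = np.ones(n, dtype=bool)
    upper = np.zeros(n, dtype=bool)
    cross_t = np.full(n, np.nan)
    sqdt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x[idx] += drift[idx] * dt + sqdt * rng.standard_normal(idx.size)
        up = x[idx] >= params.a
        lo = x[idx] <= 0.0
        hit = up | lo
        hit_idx = idx[hit]
        upper[hit_idx] = up[hit]
        cross_t[hit_idx] = step * dt
        active[hit_idx] = False
    rt = np.where(upper, cross_t + params.t0, np.nan)
    responded = upper & (rt <= deadline if deadline is not None else True)
    rt = np.where(responded, rt, np.nan)
    return responded, rt


def simulate_ddm(params: DDMParams, stimulus: str, deadline: float | None = 1.3,
                 dt: float = 1e-3, seed=None):
    """Single-trial forward simulation: (response, rt-or-None)."""
    responded, rt = simulate_ddm_trials(params, [stimulus], deadline, dt, seed)
    if responded[0]:
        return "lick", float(rt[0])
    return "withhold", None


# ----------------------------------------------------------------------
# likelihood


def trial_nll(params: DDMParams, stimulus: str, responded: bool,
              rt: float | None, deadline: float = 1.3) -> float:
    """Negative log-likelihood of a single trial."""
    v = params.drift(stimulus)
    if responded:
        if rt is None:
            raise ValueError("responded trial requires a reaction time")
        t_dec = rt - params.t0
        dens = upper_density(t_dec, params.a, params.z, v) if t_dec > 0 else 0.0
        return -float(np.log(max(dens, _LIK_FLOOR)))
    p_lick = prob_upper_before(deadline - params.t0, params.a, params.z, v)
    return -float(np.log(max(1.0 - p_lick, _LIK_FLOOR)))


def total_nll(params: DDMParams, trials: pd.DataFrame, deadline: float = 1.3) -> float:
    """Summed negative log-likelihood over a trial table.

    ``trials`` needs ``stimulus``, ``outcome`` and ``reaction_time`` columns;
    licks are HIT / FALSE_ALARM outcomes.  Reaction times at or below ``t0``
    hit the likelihood floor (with a warning) instead of raising, so the
    optimizer can move out of bad regions.
    """
    if deadline <= params.t0:
        return float(len(trials)) * -np.log(_LIK_FLOOR)
    stim = trials["stimulus"].astype(str).to_numpy()
    out = trials["outcome"].astype(str).to_numpy()
    licked = (out == "HIT") | (out == "FALSE_ALARM")
    rts = pd.to_numeric(trials["reaction_time"], errors="coerce").to_numpy()
    nll = 0.0
    n_floor = 0
    for v, sel in ((params.v_go, stim == "S_PLUS"), (params.v_nogo, stim == "S_MINUS")):
        lick_rt = rts[sel & licked] - params.t0
        ok = lick_rt > 0
        n_floor += int((~ok).sum())
        if ok.any():
            dens = upper_density(lick_rt[ok], params.a, params.z, v)
            nll -= float(np.log(np.maximum(dens, _LIK_FLOOR)).sum())
        nll -= (~ok).sum() * np.log(_LIK_FLOOR)
        n_withhold = int((sel & ~licked).sum())
        if n_withhold:
            p_lick = prob_upper_before(deadline - params.t0, params.a, params.z, v)
            nll -= n_withhold * np.log(max(1.0 - p_lick, _LIK_FLOOR))
    if n_floor:
        warnings.warn(
            f"{n_floor} reaction times at or below t0 hit the likelihood floor",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(nll)


# ----------------------------------------------------------------------
# fitting

_BOUNDS = {
    "a": (0.3, 5.0),
    "z": (0.05, 0.95),
    "v": (-8.0, 8.0),
    "t0": (0.01, 1.0),
}

_FREE_NAMES = {
    "M1": ("a", "v_go", "t0"),
    "M2": ("a", "z", "v_go", "t0"),
    "M3": ("a", "v_go", "v_nogo", "t0"),
    "M4": ("a", "z", "v_go", "v_nogo", "t0"),
}


def _theta_to_params(theta, variant) -> DDMParams:
    names = _FREE_NAMES[variant]
    d = dict(zip(names, theta))
    z = d.get("z", 0.5)
    v_go = d["v_go"]
    v_nogo = d.get("v_nogo", -v_go)
    return DDMParams(a=d["a"], z=z, v_go=v_go, v_nogo=v_nogo, t0=d["t0"],
                     variant=variant)


def fit_ddm(
    trials: pd.DataFrame,
    variant: str = "M1",
    deadline: float = 1.3,
    n_starts: int = 10,
    seed=None,
) -> FitResult:
    """Multi-start bounded maximum-likelihood fit of one variant.

    Starting points are drawn uniformly inside the parameter bounds (the
    first start sits at a mid-range default); the best converged local
    optimum wins.  Fewer than ~100 trials triggers a warning, since the
    censored-mixture likelihood identifies parameters poorly there.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if len(trials) < 100:
        warnings.warn("fewer than 100 trials; DDM parameters will be poorly "
                      "constrained", RuntimeWarning, stacklevel=2)
    names = _FREE_NAMES[variant]
    rts = pd.to_numeric(trials["reaction_time"], errors="coerce")
    min_rt = float(rts.min()) if rts.notna().any() else deadline
    t0_hi = max(0.02, min(0.95 * min_rt, deadline - 0.05))
    bounds = []
    for nm in names:
        if nm == "t0":
            bounds.append((_BOUNDS["t0"][0], t0_hi))
        elif nm in ("v_go", "v_nogo"):
            bounds.append(_BOUNDS["v"])
        else:
            bounds.append(_BOUNDS[nm])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(theta):
        try:
            p = _theta_to_params(theta, variant)
        except ValueError:
            return 1e12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            val = total_nll(p, trials, deadline)
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    center = 0.5 * (lo + hi)
    # a sensible mid-range start, then randomized restarts
    start0 = np.array([
        {"a": 1.5, "z": 0.5, "v_go": 1.0, "v_nogo": -1.0, "t0": min(0.25, t0_hi)}[nm]
        for nm in names
    ])
    starts = [np.clip(start0, lo + 1e-3, hi - 1e-3)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(lo + (hi - lo) * rng.random(len(names)))

    best = None
    failures = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 300},
            )
        except Exception as exc:  # pragma: no cover - optimizer blowups
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all optimizer starts failed: {failures}")

    params = _theta_to_params(best.x, variant)
    k = len(names)
    n = len(trials)
    return FitResult(
        params=params,
        nll=float(best.fun),
        aic=2.0 * k + 2.0 * best.fun,
        bic=k * np.log(n) + 2.0 * best.fun,
        n_trials=n,
        converged=bool(best.success),
        n_free=k,
    )


def compare_models(
    trials: pd.DataFrame,
    deadline: float = 1.3,
    n_starts: int = 10,
    seed=None,
) -> pd.DataFrame:
    """Fit all four variants and rank them by AIC.

    Returns a table with one row per variant (nll, k, AIC, BIC, dAIC),
    sorted by AIC; non-converged fits are kept out of the ranking but
    reported with ``converged=False``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for variant, child in zip(VARIANTS, ss.spawn(len(VARIANTS))):
        fit = fit_ddm(trials, variant, deadline=deadline, n_starts=n_starts,
                      seed=child)
        rows.append(
            {
                "variant": variant,
                "nll": fit.nll,
                "k": fit.n_free,
                "aic": fit.aic,
                "bic": fit.bic,
                "converged": fit.converged,
                "a": fit.params.a,
                "z": fit.params.z,
                "v_go": fit.params.v_go,
                "v_nogo": fit.params.v_nogo,
                "t0": fit.params.t0,
            }
        )
    table = pd.DataFrame(rows)
    ranked = table[table["converged"]]
    if len(ranked) == 0:
        raise RuntimeError("no variant converged")
    best_aic = ranked["aic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    return table.sort_values("aic", kind="stable").reset_index(drop=True)
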