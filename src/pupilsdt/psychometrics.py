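"""Signal-detection measures for Go/No-go sessions.

Response probabilities are summarized by the hit rate HR (hits / S+ trials)
and the false-alarm rate FAR (false alarms / S- trials).  Under the
equal-variance Gaussian model these yield

    d' = probit(HR) - probit(FAR)
    c  = -(probit(HR) + probit(FAR)) / 2

where ``probit`` is the standard-normal quantile function.  A more negative
criterion c means a more liberal observer (more licking).  When a rate hits
0 or 1 the quantile diverges; the log-linear correction (add 0.5 to the hit
and false-alarm counts and 1 to each stimulus count) keeps both rates
strictly inside (0, 1).

Session aggregation follows the convention that every per-session value is
computed first and grand means are taken across sessions with equal weight;
pooling trials across sessions is deliberately avoided because the two
estimators differ for heterogeneous cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SDTCounts",
    "SDTResult",
    "RTStats",
    "ParadigmSummary",
    "probit",
    "compute_rates",
    "sdt_measures",
    "sdt_from_trials",
    "reaction_time_stats",
    "impulsive_rate",
    "criterion_slope",
    "summarize_sessions",
]

#: Number of initial trials dropped from every session before any statistic
#: is computed (camera-adjustment period at the start of a recording).
DEFAULT_EXCLUDE_FIRST = 20


def probit(q):
    """Standard-normal quantile function (inverse cumulative Gaussian).

    Parameters
    ----------
    q : float or array-like
        Probability strictly inside (0, 1).

    Raises
    ------
    ValueError
        If any element lies outside the open interval (0, 1).
    """
    arr = np.asarray(q, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError(f"probit requires probabilities in (0, 1), got {q!r}")
    out = stats.norm.ppf(arr)
    return float(out) if np.isscalar(q) or arr.ndim == 0 else out


@dataclass(frozen=True)
class SDTCounts:
    """Trial counts entering a signal-detection computation."""

    n_splus: int
    n_sminus: int
    n_hits: int
    n_fa: int

    def __post_init__(self):
        if not (0 <= self.n_hits <= self.n_splus):
            raise ValueError("hit count must lie in [0, n_splus]")
        if not (0 <= self.n_fa <= self.n_sminus):
            raise ValueError("false-alarm count must lie in [0, n_sminus]")


@dataclass(frozen=True)
class SDTResult:
    """Rates, sensitivity and criterion for one set of trial counts."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float
    n_splus: int
    n_sminus: int
    n_hits: int
    n_fa: int
    loglinear_applied: bool


@dataclass(frozen=True)
class RTStats:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class ParadigmSummary:
    """Across-session grand means for one Go-fraction paradigm."""

    go_fraction: float
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float
    mean_rt: float | None
    impulsive_fraction: float
    n_sessions: int


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return pd.DataFrame([t.__dict__ if hasattr(t, "__dict__") else t for t in trials])


def compute_rates(trials, exclude_first: int = DEFAULT_EXCLUDE_FIRST) -> SDTCounts:
    """Count S+/S- presentations, hits, and false alarms.

    The first ``exclude_first`` trials of the session are dropped before
    counting.  ``trials`` must be ordered by trial index and carry
    ``stimulus`` and ``outcome`` columns.
    """
    df = _as_frame(trials)
    if exclude_first < 0:
        raise ValueError("exclude_first must be nonnegative")
    df = df.iloc[exclude_first:]
    stim = df["stimulus"].astype(str)
    out = df["outcome"].astype(str)
    n_splus = int((stim == "S_PLUS").sum())
    n_sminus = int((stim == "S_MINUS").sum())
    n_hits = int((out == "HIT").sum())
    n_fa = int((out == "FALSE_ALARM").sum())
    return SDTCounts(n_splus=n_splus, n_sminus=n_sminus, n_hits=n_hits, n_fa=n_fa)


def sdt_measures(counts: SDTCounts, loglinear: bool = False) -> SDTResult:
    """Hit/false-alarm rates, d' and criterion from trial counts.

    With ``loglinear=True`` the corrected rates are
    ``HR = (hits + 0.5) / (n_splus + 1)`` and
    ``FAR = (fa + 0.5) / (n_sminus + 1)``, which are strictly inside (0, 1)
    for any counts.  Without the correction a rate of exactly 0 or 1 raises,
    since the quantile function diverges there.
    """
    if counts.n_splus < 1 or counts.n_sminus < 1:
        raise ValueError("need at least one S+ and one S- trial")
    if loglinear:
        hr = (counts.n_hits + 0.5) / (counts.n_splus + 1)
        far = (counts.n_fa + 0.5) / (counts.n_sminus + 1)
    else:
        hr = counts.n_hits / counts.n_splus
        far = counts.n_fa / counts.n_sminus
        if hr in (0.0, 1.0) or far in (0.0, 1.0):
            raise ValueError(
                "hit or false-alarm rate is 0 or 1; apply the log-linear "
                "correction (loglinear=True) to keep the quantiles finite"
            )
    zh, zf = probit(hr), probit(far)
    return SDTResult(
        hit_rate=hr,
        fa_rate=far,
        d_prime=zh - zf,
        criterion=-(zh + zf) / 2.0,
        n_splus=counts.n_splus,
        n_sminus=counts.n_sminus,
        n_hits=counts.n_hits,
        n_fa=counts.n_fa,
        loglinear_applied=loglinear,
    )


def sdt_from_trials(
    trials,
    exclude_first: int = DEFAULT_EXCLUDE_FIRST,
    loglinear: bool | str = "auto",
) -> SDTResult:
    """Session-level SDT measures straight from a trial table.

    ``loglinear`` may be True, False, or ``"auto"`` (default), which applies
    the correction only when a raw rate would be exactly 0 or 1.
    """
    counts = compute_rates(trials, exclude_first=exclude_first)
    if loglinear == "auto":
        extreme = (
            counts.n_hits in (0, counts.n_splus)
            or counts.n_fa in (0, counts.n_sminus)
        )
        return sdt_measures(counts, loglinear=extreme)
    return sdt_measures(counts, loglinear=bool(loglinear))


def reaction_time_stats(trials) -> RTStats | None:
    """Mean/SD/count of reaction times on responded (hit, false-alarm) trials.

    Returns None when the session contains no responded trials; an absent
    reaction time is never coerced to zero.
    """
    df = _as_frame(trials)
    responded = df["outcome"].astype(str).isin(["HIT", "FALSE_ALARM"])
    rts = pd.to_numeric(df.loc[responded, "reaction_time"], errors="coerce").dropna()
    if len(rts) == 0:
        return None
    return RTStats(mean=float(rts.mean()), sd=float(rts.std(ddof=1)) if len(rts) > 1 else 0.0, n=len(rts))


def impulsive_rate(trials, exclude_first: int = DEFAULT_EXCLUDE_FIRST) -> float:
    """Fraction of trials with a pre-stimulus (impulsive) lick."""
    df = _as_frame(trials).iloc[exclude_first:]
    if len(df) == 0:
        raise ValueError("no trials left after exclusion")
    flags = df["impulsive_lick"].astype(bool)
    return float(flags.mean())


def criterion_slope(criteria: Sequence[float]) -> float:
    """Least-squares slope of criterion against paradigm index.

    ``criteria`` must be ordered by decreasing Go fraction (0.8, 0.5, 0.2);
    the abscissa is the ordinal paradigm index 1, 2, 3, ...  For exactly
    three paradigms the slope reduces to (c3 - c1) / 2.
    """
    c = np.asarray(criteria, dtype=float)
    if c.size < 2:
        raise ValueError("criterion_slope needs at least two paradigms")
    x = np.arange(1, c.size + 1, dtype=float)
    return float(np.polyfit(x, c, 1)[0])


def summarize_sessions(
    sessions: Iterable,
    exclude_first: int = DEFAULT_EXCLUDE_FIRST,
    loglinear: bool | str = "auto",
) -> tuple[pd.DataFrame, list[ParadigmSummary]]:
    """Per-session rows plus per-paradigm grand means.

    ``sessions`` is an iterable of objects with ``paradigm.go_fraction`` and
    a ``trials`` DataFrame (``SessionLog`` duck type).  All paradigm-level
    numbers are unweighted means of per-session values.
    """
    rows = []
    for s in sessions:
        res = sdt_from_trials(s.trials, exclude_first=exclude_first, loglinear=loglinear)
        rt = reaction_time_stats(s.trials.iloc[exclude_first:])
        rows.append(
            {
                "animal_id": getattr(s, "animal_id", ""),
                "seed": getattr(s, "seed", None),
                "go_fraction": s.paradigm.go_fraction,
                "hit_rate": res.hit_rate,
                "fa_rate": res.fa_rate,
                "d_prime": res.d_prime,
                "criterion": res.criterion,
                "mean_rt": rt.mean if rt is not None else np.nan,
                "impulsive_fraction": impulsive_rate(s.trials, exclude_first),
                "n_trials": len(s.trials),
            }
        )
    per_session = pd.DataFrame(rows)
    summaries = []
    for gf, grp in per_session.groupby("go_fraction"):
        summaries.append(
            ParadigmSummary(
                go_fraction=float(gf),
                hit_rate=float(grp["hit_rate"].mean()),
                fa_rate=float(grp["fa_rate"].mean()),
                d_prime=float(grp["d_prime"].mean()),
                criterion=float(grp["criterion"].mean()),
                mean_rt=float(grp["mean_rt"].mean()) if grp["mean_rt"].notna().any() else None,
                impulsive_fraction=float(grp["impulsive_fraction"].mean()),
                n_sessions=len(grp),
            )
        )
    summaries.sort(key=lambda s: -s.go_fraction)
    return per_session, summaries
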