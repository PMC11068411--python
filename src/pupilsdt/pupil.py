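"""Pupillometry preprocessing and arousal-conditioned behavioral analysis.

The raw pupil signal is an area time series sampled at 20 Hz (upstream, the
area comes from a circle fit to landmark points on the pupil contour).
Preprocessing runs in a fixed order:

    1. blink interpolation (linear across masked runs, edges held),
    2. zero-phase 4th-order Butterworth low-pass at 3.5 Hz,
    3. per-session Z-scoring.

From the processed trace, each trial gets a baseline (mean over the 0.5 s
preceding stimulus onset), a task-evoked dilation (mean over 0 to 5 s after
onset, minus the baseline), and a normalized baseline b in [0, 1] (min-max
within the session).  Trials are then grouped into 20 equal-width baseline
bins or into low / medium / high arousal tertiles (b < 0.33, 0.33 <= b <=
0.66, b > 0.66) and signal-detection measures are computed per group with
the log-linear correction always on, since small bins routinely produce
rates of exactly 0 or 1.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .psychometrics import (
    SDTCounts,
    SDTResult,
    criterion_slope,
    sdt_measures,
)

__all__ = [
    "PupilTrace",
    "TrialPupilFeatures",
    "fit_pupil_circle",
    "interpolate_blinks",
    "lowpass_trace",
    "zscore_session",
    "preprocess_trace",
    "extract_features",
    "normalize_baselines",
    "session_features",
    "bin_by_baseline",
    "tertile_group",
    "outcome_aligned_average",
    "arousal_conditioned_sdt",
]

#: Sentinel written into blink samples of exported traces.
BLINK_SENTINEL = -999.0

OUTCOMES = ("HIT", "FALSE_ALARM", "MISS", "CORRECT_REJECTION")


@dataclass(frozen=True)
class PupilTrace:
    """Uniformly sampled pupil time series with a blink mask."""

    values: np.ndarray
    blink_mask: np.ndarray
    sample_rate: float = 20.0
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "blink_mask", np.asarray(self.blink_mask, dtype=bool))
        if self.values.shape != self.blink_mask.shape:
            raise ValueError("values and blink_mask must have the same length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        vals = np.where(self.blink_mask, BLINK_SENTINEL, self.values)
        return pd.DataFrame(
            {"time_s": self.times, "pupil": vals, "blink": self.blink_mask.astype(int)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_rate: float = 20.0) -> "PupilTrace":
        t = df["time_s"].to_numpy(dtype=float)
        return cls(
            values=df["pupil"].to_numpy(dtype=float),
            blink_mask=df["blink"].to_numpy(dtype=bool),
            sample_rate=sample_rate,
            t0=float(t[0]) if t.size else 0.0,
        )


@dataclass(frozen=True)
class TrialPupilFeatures:
    """Per-trial pupil measures; None fields mean the window was unusable."""

    baseline: float | None
    dilation: float | None
    norm_baseline: float | None = None


def fit_pupil_circle(landmarks) -> tuple[tuple[float, float], float, float]:
    """Algebraic least-squares circle through planar landmark points.

    Solves the linear (Kasa) system for center (cx, cy) and radius r;
    returns ``((cx, cy), radius, area)`` with area = pi * r**2.  Requires at
    least three non-collinear points.
    """
    pts = np.asarray(landmarks, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three (x, y) landmark points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("landmark points are collinear; circle is undefined")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    r = float(np.sqrt(r2))
    return (float(cx), float(cy)), r, float(np.pi * r2)


def interpolate_blinks(trace: PupilTrace) -> PupilTrace:
    """Replace blink-masked runs by linear interpolation between neighbors.

    Leading and trailing masked runs are held at the nearest unmasked
    value.  The mask is preserved on the result so later stages can still
    discount interpolated spans.
    """
    mask = trace.blink_mask
    if mask.all():
        raise ValueError("trace is fully blink-masked; nothing to interpolate")
    if not mask.any():
        return trace
    idx = np.arange(trace.n)
    good = ~mask
    filled = trace.values.copy()
    filled[mask] = np.interp(idx[mask], idx[good], trace.values[good])
    return replace(trace, values=filled)


def lowpass_trace(trace: PupilTrace, cutoff: float = 3.5, order: int = 4) -> PupilTrace:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    One second of reflected padding suppresses edge transients.  The cutoff
    must stay below the Nyquist frequency.
    """
    nyq = trace.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({nyq} Hz)")
    b, a = signal.butter(order, cutoff / nyq)
    padlen = min(int(trace.sample_rate), trace.n - 1)
    filtered = signal.filtfilt(b, a, trace.values, padtype="even", padlen=padlen)
    return replace(trace, values=filtered)


def zscore_session(trace: PupilTrace) -> PupilTrace:
    """Z-score the trace using the mean and SD of its unmasked samples."""
    good = trace.values[~trace.blink_mask]
    if good.size == 0:
        raise ValueError("no unmasked samples to Z-score against")
    mu, sd = float(good.mean()), float(good.std())
    if sd == 0.0:
        raise ValueError("zero-variance trace cannot be Z-scored")
    return replace(trace, values=(trace.values - mu) / sd)


def preprocess_trace(trace: PupilTrace, cutoff: float = 3.5, order: int = 4) -> PupilTrace:
    """Canonical pipeline: blink-interpolate, low-pass, Z-score (in that order)."""
    return zscore_session(lowpass_trace(interpolate_blinks(trace), cutoff, order))


def extract_features(
    trace: PupilTrace,
    stimulus_onset: float,
    baseline_window: float = 0.5,
    dilation_window: float = 5.0,
    max_masked_fraction: float = 0.5,
) -> TrialPupilFeatures:
    """Baseline and task-evoked dilation around one stimulus onset.

    Windows are aligned to the sample grid: the baseline is the mean over
    [onset - 0.5 s, onset) (the onset sample excluded), the dilation the
    mean over [onset, onset + 5 s] (endpoint included) minus the baseline.
    A window falling outside the record, or more than half blink-masked,
    yields absent (None) features.
    """
    fs = trace.sample_rate
    i_on = int(round((stimulus_onset - trace.t0) * fs))
    nb = int(round(baseline_window * fs))
    nd = int(round(dilation_window * fs))
    b_lo, b_hi = i_on - nb, i_on
    d_lo, d_hi = i_on, i_on + nd + 1  # inclusive endpoint
    if b_lo < 0 or d_hi > trace.n:
        return TrialPupilFeatures(baseline=None, dilation=None)
    b_mask = trace.blink_mask[b_lo:b_hi]
    d_mask = trace.blink_mask[d_lo:d_hi]
    if b_mask.mean() > max_masked_fraction or d_mask.mean() > max_masked_fraction:
        return TrialPupilFeatures(baseline=None, dilation=None)
    baseline = float(trace.values[b_lo:b_hi].mean())
    dilation = float(trace.values[d_lo:d_hi].mean()) - baseline
    return TrialPupilFeatures(baseline=baseline, dilation=dilation)


def normalize_baselines(baselines) -> np.ndarray:
    """Min-max normalize a session's baselines to fractions in [0, 1].

    NaN entries (trials without usable features) propagate as NaN and are
    excluded from the min/max.
    """
    b = np.asarray(baselines, dtype=float)
    finite = b[np.isfinite(b)]
    if np.unique(finite).size < 2:
        raise ValueError("need at least two distinct baselines to normalize")
    lo, hi = finite.min(), finite.max()
    return (b - lo) / (hi - lo)


def tertile_group(norm_baseline: float) -> str:
    """Arousal tertile of one normalized baseline: boundary ties go medium."""
    if not np.isfinite(norm_baseline):
        raise ValueError("normalized baseline must be finite")
    if norm_baseline < 0.33:
        return "low"
    if norm_baseline <= 0.66:
        return "medium"
    return "high"


def _baseline_bin(b: float, n_bins: int) -> int:
    """Half-open equal-width bins on [0, 1]; b = 1 lands in the last bin."""
    return min(int(b * n_bins), n_bins - 1)


def session_features(session, exclude_first: int = 20,
                     max_masked_fraction: float = 0.5,
                     n_bins: int = 20) -> pd.DataFrame:
    """Per-trial pupil features for one session.

    Runs the preprocessing pipeline on the session's trace, extracts
    baseline/dilation per trial, min-max normalizes the baselines of the
    analyzed trials, and assigns each trial a tertile and a 20-bin index.
    Trials with unusable windows get NaN features and no group.
    """
    trace = preprocess_trace(session.pupil)
    trials = session.trials.iloc[exclude_first:]
    feats = [
        extract_features(trace, float(t), max_masked_fraction=max_masked_fraction)
        for t in trials["stimulus_onset"]
    ]
    baseline = np.array([f.baseline if f.baseline is not None else np.nan for f in feats])
    dilation = np.array([f.dilation if f.dilation is not None else np.nan for f in feats])
    norm = normalize_baselines(baseline)
    tert = [tertile_group(b) if np.isfinite(b) else None for b in norm]
    bins = [
        _baseline_bin(b, n_bins) if np.isfinite(b) else -1 for b in norm
    ]
    return pd.DataFrame(
        {
            "trial_index": trials["index"].to_numpy(),
            "baseline": baseline,
            "dilation": dilation,
            "norm_baseline": norm,
            "tertile": tert,
            "bin": bins,
        }
    )


def _counts_for(trials: pd.DataFrame) -> SDTCounts:
    stim = trials["stimulus"].astype(str)
    out = trials["outcome"].astype(str)
    return SDTCounts(
        n_splus=int((stim == "S_PLUS").sum()),
        n_sminus=int((stim == "S_MINUS").sum()),
        n_hits=int((out == "HIT").sum()),
        n_fa=int((out == "FALSE_ALARM").sum()),
    )


def bin_by_baseline(trials: pd.DataFrame, features: pd.DataFrame,
                    n_bins: int = 20) -> dict[int, SDTResult]:
    """SDT measures per normalized-baseline bin (log-linear always on).

    ``trials`` and ``features`` must be row-aligned (same trials, same
    order).  Bins without any trial of one stimulus class still yield
    finite measures thanks to the correction; entirely empty bins are
    simply absent from the result.
    """
    if len(trials) != len(features):
        raise ValueError("trials and features must be row-aligned")
    out: dict[int, SDTResult] = {}
    bins = features["bin"].to_numpy()
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        counts = _counts_for(trials.iloc[np.flatnonzero(sel)])
        if counts.n_splus + counts.n_sminus == 0:
            continue
        if counts.n_splus == 0 or counts.n_sminus == 0:
            # one-sided bins carry no d'/criterion information
            continue
        out[b] = sdt_measures(counts, loglinear=True)
    return out


def outcome_aligned_average(sessions, window: tuple[float, float] = (-0.5, 5.0),
                            exclude_first: int = 20):
    """Stimulus-aligned mean pupil time course per behavioral outcome.

    Each session's processed trace is cut into [-0.5 s, +5 s] segments
    around every stimulus onset (111 samples at 20 Hz, endpoints included),
    averaged within session per outcome, then averaged across sessions.
    Returns ``(curves, time_axis, n_skipped)`` where curves maps outcome to
    the grand-mean curve (absent outcomes are missing keys).
    """
    lo, hi = window
    per_session: dict[str, list[np.ndarray]] = {o: [] for o in OUTCOMES}
    n_skipped = 0
    t_axis = None
    for s in sessions:
        trace = preprocess_trace(s.pupil)
        fs = trace.sample_rate
        n_lo, n_hi = int(round(lo * fs)), int(round(hi * fs))
        if t_axis is None:
            t_axis = np.arange(n_lo, n_hi + 1) / fs
        segs: dict[str, list[np.ndarray]] = {o: [] for o in OUTCOMES}
        trials = s.trials.iloc[exclude_first:]
        for onset, outcome in zip(trials["stimulus_onset"], trials["outcome"].astype(str)):
            i_on = int(round((float(onset) - trace.t0) * fs))
            a, b = i_on + n_lo, i_on + n_hi + 1
            if a < 0 or b > trace.n:
                n_skipped += 1
                continue
            segs[outcome].append(trace.values[a:b])
        for o, lst in segs.items():
            if lst:
                per_session[o].append(np.mean(lst, axis=0))
    curves = {
        o: np.mean(lst, axis=0) for o, lst in per_session.items() if lst
    }
    return curves, t_axis, n_skipped


def arousal_conditioned_sdt(sessions, exclude_first: int = 20):
    """Criterion and d' per paradigm and arousal tertile, with tertile slopes.

    For every session, trials are split by baseline tertile and SDT measures
    are computed per tertile (log-linear always on); measures are then
    averaged across sessions within (go_fraction, tertile) cells.  Sessions
    contributing no trial of either stimulus class to a tertile are omitted
    from that cell.  For each tertile present in at least two paradigms, the
    criterion slope across paradigms (ordered by decreasing Go fraction) is
    computed; with fewer than two paradigms the slope is absent (None).

    Returns ``(table, slopes)``: a tidy DataFrame of per-cell means and a
    dict tertile -> slope.
    """
    rows = []
    for s in sessions:
        feats = session_features(s, exclude_first=exclude_first)
        trials = s.trials.iloc[exclude_first:].reset_index(drop=True)
        feats = feats.reset_index(drop=True)
        for tert in ("low", "medium", "high"):
            sel = (feats["tertile"] == tert).to_numpy()
            if not sel.any():
                continue
            counts = _counts_for(trials.iloc[np.flatnonzero(sel)])
            if counts.n_splus == 0 or counts.n_sminus == 0:
                continue
            res = sdt_measures(counts, loglinear=True)
            rows.append(
                {
                    "go_fraction": s.paradigm.go_fraction,
                    "tertile": tert,
                    "criterion": res.criterion,
                    "d_prime": res.d_prime,
                    "n_trials": counts.n_splus + counts.n_sminus,
                }
            )
    per_session = pd.DataFrame(rows)
    if per_session.empty:
        raise ValueError("no (session, tertile) cell had both stimulus classes")
    table = (
        per_session.groupby(["go_fraction", "tertile"])
        .agg(
            criterion=("criterion", "mean"),
            d_prime=("d_prime", "mean"),
            criterion_se=("criterion", "sem"),
            n_sessions=("criterion", "size"),
        )
        .reset_index()
    )
    slopes: dict[str, float | None] = {}
    for tert in ("low", "medium", "high"):
        sub = table[table["tertile"] == tert].sort_values("go_fraction", ascending=False)
        if len(sub) >= 2:
            slopes[tert] = criterion_slope(sub["criterion"].to_numpy())
        else:
            slopes[tert] = None
    return table, slopes
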