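"""Seeded synthetic Go/No-go sessions with pupil traces.

Every downstream analysis in this package consumes ``SessionLog`` objects:
an ordered trial table (stimulus class, outcome, reaction time, impulsive
lick flag, event times) plus a 20 Hz pupil trace.  This module generates
such sessions from a small set of interpretable parameters so the whole
pipeline is testable without recorded data.

The generator mirrors the task structure: each trial opens with a 0.3 s
onset tone and a uniform 1-3.5 s delay before the stimulus; an impulsive
lick in the pre-stimulus no-lick window adds one penalty delay drawn from
U(1, 2.5) (the real task can re-delay indefinitely, but trained animals
rarely trigger more than one, so a single re-draw captures the timing
statistics).  Licks within the 1.3 s response window terminate S+ trials
as hits (reward, then 6 s ITI) and S- trials as false alarms (10 s timeout,
then ITI); withheld responses end after the response window plus ITI.

The simulated observer is the equal-variance Gaussian one: evidence is
N(+d'/2, 1) on S+ trials and N(-d'/2, 1) on S- trials, and a lick is
initiated when the evidence exceeds the trial's criterion

    c_trial = criterion_base + g1 * (b - 0.5) + g2 * (b - 0.5)**2

with b the trial's normalized (min-max within session) baseline pupil size.
Centering the evidence distributions makes the generating ``criterion_base``
and ``d_prime`` exactly the quantities the signal-detection analysis
recovers.  Reaction times come from a truncated-by-demotion lognormal (or,
optionally, from the drift-diffusion forward simulator): draws exceeding
the response window are logged as misses / correct rejections, exactly as
a too-slow lick would be.

Pupil traces are built as a slow mean-reverting (OU) baseline process,
anchored per trial, plus an outcome-scaled dilation kernel peaking ~1.2 s
after each stimulus, white measurement noise, and Poisson blinks marked by
a sentinel value and mask channel.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    OBSERVED_CRITERION,
    OBSERVED_D_PRIME,
    OBSERVED_IMPULSIVE_RATE,
    OBSERVED_MEAN_RT,
)
from .pupil import BLINK_SENTINEL, PupilTrace

__all__ = [
    "TrialTiming",
    "Paradigm",
    "ObserverParams",
    "PupilGenParams",
    "TrialRecord",
    "SessionLog",
    "CohortConfig",
    "default_observer",
    "generate_trial_sequence",
    "generate_outcomes",
    "generate_pupil_trace",
    "generate_session",
    "generate_cohort",
    "write_session",
    "read_session",
]

def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


TRIAL_COLUMNS = [
    "index",
    "stimulus",
    "outcome",
    "reaction_time",
    "impulsive_lick",
    "stimulus_onset",
    "trial_end",
]


@dataclass(frozen=True)
class TrialTiming:
    """Task timing constants, all in seconds (reward volume in uL)."""

    delay_range: tuple[float, float] = (1.0, 3.5)
    no_lick_window: float = 1.0
    penalty_delay_range: tuple[float, float] = (1.0, 2.5)
    response_window: float = 1.3
    timeout: float = 10.0
    iti: float = 6.0
    onset_tone: float = 0.3
    stimulus_duration: float = 0.5
    reward_volume: float = 60.0

    def __post_init__(self):
        for name in ("no_lick_window", "response_window", "timeout", "iti",
                     "onset_tone", "stimulus_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.no_lick_window > self.delay_range[1]:
            raise ValueError("no-lick window cannot exceed the maximal delay")


@dataclass(frozen=True)
class Paradigm:
    """One sensory environment: Go-stimulus fraction and session size."""

    go_fraction: float
    n_trials: int = 270
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __post_init__(self):
        if not np.isfinite(self.go_fraction) or not (0.0 < self.go_fraction < 1.0):
            raise ValueError("go_fraction must be a finite probability in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class ObserverParams:
    """Generating observer: sensitivity, criterion, arousal coupling, RTs."""

    d_prime: float
    criterion_base: float
    arousal_gain_linear: float = 0.0
    arousal_gain_quadratic: float = 0.0
    impulsive_rate: float = 0.1
    rt_median: float = 0.59
    rt_sigma: float = 0.35          # lognormal shape (SD of log RT)
    rt_source: str = "lognormal"    # or "ddm"
    ddm_params: object | None = None

    def __post_init__(self):
        if not np.isfinite(self.d_prime):
            raise ValueError("d_prime must be finite")
        if not (0.0 <= self.impulsive_rate <= 1.0):
            raise ValueError("impulsive_rate must lie in [0, 1]")
        if self.rt_source not in ("lognormal", "ddm"):
            raise ValueError("rt_source must be 'lognormal' or 'ddm'")
        if self.rt_source == "ddm" and self.ddm_params is None:
            raise ValueError("rt_source='ddm' requires ddm_params")

    @property
    def has_arousal_coupling(self) -> bool:
        return self.arousal_gain_linear != 0.0 or self.arousal_gain_quadratic != 0.0


def default_observer(go_fraction: float, **overrides) -> ObserverParams:
    """Observer matching the observed grand means of one paradigm."""
    if go_fraction not in OBSERVED_D_PRIME:
        raise ValueError(f"no observed defaults for go_fraction={go_fraction}")
    kw = dict(
        d_prime=OBSERVED_D_PRIME[go_fraction],
        criterion_base=OBSERVED_CRITERION[go_fraction],
        impulsive_rate=OBSERVED_IMPULSIVE_RATE[go_fraction],
        rt_median=OBSERVED_MEAN_RT[go_fraction],
    )
    kw.update(overrides)
    return ObserverParams(**kw)


@dataclass(frozen=True)
class PupilGenParams:
    """Parameters of the synthetic pupil trace (arbitrary raw units)."""

    sample_rate: float = 20.0
    baseline_tau: float = 30.0      # OU reversion time constant, s
    baseline_sd: float = 1.0        # stationary SD of the baseline process
    dilation_amplitudes: dict = field(
        default_factory=lambda: {
            "HIT": 0.156,
            "FALSE_ALARM": 0.096,
            "MISS": 0.07,
            "CORRECT_REJECTION": 0.0095,
        }
    )
    kernel_peak_time: float = 1.2   # s after stimulus onset
    blink_rate: float = 2.0         # events per minute
    blink_duration: float = 0.3     # s
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.blink_duration >= 5.0:
            raise ValueError("blink_duration must be below 5 s")
        missing = {"HIT", "FALSE_ALARM", "MISS", "CORRECT_REJECTION"} - set(
            self.dilation_amplitudes
        )
        if missing:
            raise ValueError(f"dilation amplitude missing for {missing}")


@dataclass(frozen=True)
class TrialRecord:
    """One trial of a session log."""

    index: int
    stimulus: str
    outcome: str
    reaction_time: float | None
    impulsive_lick: bool
    stimulus_onset: float
    trial_end: float

    def __post_init__(self):
        go = self.stimulus == "S_PLUS"
        if go != (self.outcome in ("HIT", "MISS")):
            raise ValueError("outcome class inconsistent with stimulus class")
        responded = self.outcome in ("HIT", "FALSE_ALARM")
        if responded != (self.reaction_time is not None):
            raise ValueError("reaction time must be present iff the trial was responded")
        if self.trial_end <= self.stimulus_onset:
            raise ValueError("trial_end must follow stimulus_onset")


@dataclass
class SessionLog:
    """Paradigm, ordered trials (DataFrame), pupil trace, and provenance."""

    paradigm: Paradigm
    trials: pd.DataFrame
    pupil: PupilTrace
    seed: int
    animal_id: str = "synthetic"

    def records(self) -> list[TrialRecord]:
        out = []
        for _, row in self.trials.iterrows():
            rt = row["reaction_time"]
            out.append(
                TrialRecord(
                    index=int(row["index"]),
                    stimulus=row["stimulus"],
                    outcome=row["outcome"],
                    reaction_time=None if pd.isna(rt) else float(rt),
                    impulsive_lick=bool(row["impulsive_lick"]),
                    stimulus_onset=float(row["stimulus_onset"]),
                    trial_end=float(row["trial_end"]),
                )
            )
        return out


# ----------------------------------------------------------------------
# generation


def generate_trial_sequence(paradigm: Paradigm, seed=None) -> pd.DataFrame:
    """Stimulus classes and pre-stimulus event composition for one session.

    Each trial's stimulus is an independent Bernoulli draw with
    P(S+) = go_fraction.  The returned frame carries, per trial, the
    stimulus class, the impulsive-lick flag (drawn later against the
    observer's impulsive rate is NOT done here -- the flag here is
    structural placeholder False), the delay draw, and the onset offset
    from trial start (onset tone + delay, penalty added downstream when the
    trial is impulsive).
    """
    rng = np.random.default_rng(seed)
    t = paradigm.timing
    n = paradigm.n_trials
    stim = np.where(rng.random(n) < paradigm.go_fraction, "S_PLUS", "S_MINUS")
    delay = rng.uniform(*t.delay_range, size=n)
    penalty = rng.uniform(*t.penalty_delay_range, size=n)
    return pd.DataFrame(
        {
            "stimulus": stim,
            "delay": delay,
            "penalty_delay": penalty,
            "onset_offset": t.onset_tone + delay,
        }
    )


def _draw_rts(observer: ObserverParams, stimuli, rng) -> np.ndarray:
    """Latent lick latencies for lick-intent trials (may exceed the window)."""
    n = len(stimuli)
    if observer.rt_source == "lognormal":
        return observer.rt_median * np.exp(observer.rt_sigma * rng.standard_normal(n))
    from .ddm import simulate_ddm_trials  # local import avoids cycles

    responded, rt = simulate_ddm_trials(
        observer.ddm_params, np.asarray(stimuli), deadline=None,
        dt=1e-3, seed=rng,
    )
    # walks absorbed below or never absorbed have no lick latency; treat as
    # beyond-deadline licks so the trial demotes to miss / correct rejection
    return np.where(responded, rt, np.inf)


def generate_outcomes(
    stimuli,
    observer: ObserverParams,
    baselines=None,
    timing: TrialTiming | None = None,
    seed=None,
):
    """Outcomes and reaction times for a sequence of stimulus classes.

    ``baselines`` are the trials' normalized baselines in [0, 1]; they are
    required whenever the observer has nonzero arousal gains.  Evidence is
    N(+d'/2, 1) for S+ and N(-d'/2, 1) for S-; a lick is initiated when the
    evidence exceeds the trial criterion, and the lick latency must fall
    inside the response window for the trial to register as a hit / false
    alarm -- slower licks demote to miss / correct rejection.

    Returns ``(outcomes, reaction_times)`` as arrays (NaN RT when absent).
    """
    timing = timing or TrialTiming()
    stimuli = np.asarray(stimuli)
    n = stimuli.size
    if observer.has_arousal_coupling:
        if baselines is None:
            raise ValueError("arousal gains are nonzero but no baselines were given")
        b = np.asarray(baselines, dtype=float)
        if b.shape != (n,) or not np.all(np.isfinite(b)):
            raise ValueError("need one finite normalized baseline per trial")
    else:
        b = np.full(n, 0.5)
    rng = np.random.default_rng(seed)
    centered = b - 0.5
    c_trial = (
        observer.criterion_base
        + observer.arousal_gain_linear * centered
        + observer.arousal_gain_quadratic * centered**2
    )
    is_go = stimuli == "S_PLUS"
    evidence = rng.standard_normal(n) + np.where(is_go, 0.5, -0.5) * observer.d_prime
    intent = evidence > c_trial
    rts = np.full(n, np.nan)
    if intent.any():
        latent = _draw_rts(observer, stimuli[intent], rng)
        ok = latent <= timing.response_window
        idx = np.flatnonzero(intent)
        rts[idx[ok]] = latent[ok]
    responded = ~np.isnan(rts)
    outcomes = np.where(
        is_go,
        np.where(responded, "HIT", "MISS"),
        np.where(responded, "FALSE_ALARM", "CORRECT_REJECTION"),
    )
    return outcomes, rts


def _dilation_kernel(t: np.ndarray, peak_time: float) -> np.ndarray:
    """Smooth unit-peak kernel: (t/tp) * exp(1 - t/tp) for t >= 0."""
    x = np.clip(t / peak_time, 0.0, None)
    return np.where(t >= 0, x * np.exp(1.0 - x), 0.0)


def generate_pupil_trace(
    trials: pd.DataFrame,
    params: PupilGenParams,
    seed=None,
    baseline_anchors=None,
    duration: float | None = None,
) -> PupilTrace:
    """Synthetic 20 Hz pupil trace for a trial table with event times.

    The trace is an OU baseline (optionally pinned to per-trial anchor
    values at the stimulus onsets) plus an outcome-scaled dilation kernel
    per trial, white noise, and Poisson blink gaps (sentinel value, mask
    channel set).  Trials must be non-overlapping and sorted in time.
    """
    onsets = trials["stimulus_onset"].to_numpy(dtype=float)
    ends = trials["trial_end"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0) or np.any(onsets[1:] < ends[:-1]):
        raise ValueError("trials must be sorted and non-overlapping")
    rng = np.random.default_rng(seed)
    fs = params.sample_rate
    total = duration if duration is not None else ends[-1] + 5.0
    n = int(np.ceil(total * fs)) + 1
    t = np.arange(n) / fs

    if baseline_anchors is not None:
        anchors = np.asarray(baseline_anchors, dtype=float)
        base = np.interp(t, onsets, anchors)
    else:
        # exact OU recursion on the sample grid
        rho = np.exp(-1.0 / (fs * params.baseline_tau))
        innov = params.baseline_sd * np.sqrt(1.0 - rho**2)
        base = np.empty(n)
        base[0] = params.baseline_sd * rng.standard_normal()
        noise = rng.standard_normal(n - 1)
        for k in range(1, n):
            base[k] = rho * base[k - 1] + innov * noise[k - 1]

    values = base.copy()
    for onset, outcome in zip(onsets, trials["outcome"].astype(str)):
        amp = params.dilation_amplitudes[outcome]
        if amp == 0.0:
            continue
        i0 = int(np.round(onset * fs))
        i1 = min(n, i0 + int(8.0 * fs))  # kernel support truncated at 8 s
        if i0 >= n:
            continue
        values[i0:i1] += amp * _dilation_kernel(t[i0:i1] - onset, params.kernel_peak_time)

    if params.noise_sd > 0:
        values += params.noise_sd * rng.standard_normal(n)

    mask = np.zeros(n, dtype=bool)
    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate / 60.0 * total)
        starts = rng.uniform(0.0, total, size=n_blinks)
        for s in starts:
            a = int(np.round(s * fs))
            bnd = min(n, a + max(1, int(np.round(params.blink_duration * fs))))
            mask[a:bnd] = True
    values = np.where(mask, BLINK_SENTINEL, values)
    return PupilTrace(values=values, blink_mask=mask, sample_rate=fs, t0=0.0)


def generate_session(
    paradigm: Paradigm,
    observer: ObserverParams | None = None,
    pupil_params: PupilGenParams | None = None,
    seed=None,
    animal_id: str = "synthetic",
) -> SessionLog:
    """Generate one complete session log.

    Per-trial baselines are drawn first as a stationary AR(1) sequence
    across trials (decay set by the OU time constant and the expected
    trial spacing), so the arousal-coupled criterion can be evaluated
    before outcomes -- and therefore before the outcome-dependent event
    times -- are known.  The continuous trace is then pinned to these
    anchors at the realized onset times.
    """
    observer = observer or default_observer(paradigm.go_fraction)
    pupil_params = pupil_params or PupilGenParams()
    ss = _as_seedseq(seed)
    rng_seq, rng_base, rng_out, rng_trace = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]
    timing = paradigm.timing
    seq = generate_trial_sequence(paradigm, rng_seq)
    n = len(seq)

    impulsive = rng_base.random(n) < observer.impulsive_rate

    # stationary AR(1) baseline anchors across trials
    spacing = timing.onset_tone + np.mean(timing.delay_range) + timing.response_window + timing.iti
    rho = np.exp(-spacing / pupil_params.baseline_tau)
    anchors = np.empty(n)
    anchors[0] = pupil_params.baseline_sd * rng_base.standard_normal()
    innov = pupil_params.baseline_sd * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        anchors[i] = rho * anchors[i - 1] + innov * rng_base.standard_normal()
    if observer.has_arousal_coupling:
        span = anchors.max() - anchors.min()
        norm = (anchors - anchors.min()) / span if span > 0 else np.full(n, 0.5)
    else:
        norm = None

    outcomes, rts = generate_outcomes(
        seq["stimulus"].to_numpy(), observer, baselines=norm,
        timing=timing, seed=rng_out,
    )

    onset_offsets = seq["onset_offset"].to_numpy() + np.where(
        impulsive, seq["penalty_delay"].to_numpy(), 0.0
    )
    onsets = np.empty(n)
    ends = np.empty(n)
    cursor = 0.0
    for i in range(n):
        onsets[i] = cursor + onset_offsets[i]
        o = outcomes[i]
        if o == "HIT":
            ends[i] = onsets[i] + rts[i] + timing.iti
        elif o == "FALSE_ALARM":
            ends[i] = onsets[i] + rts[i] + timing.timeout + timing.iti
        else:
            ends[i] = onsets[i] + timing.response_window + timing.iti
        cursor = ends[i]

    trials = pd.DataFrame(
        {
            "index": np.arange(n),
            "stimulus": seq["stimulus"],
            "outcome": outcomes,
            "reaction_time": rts,
            "impulsive_lick": impulsive,
            "stimulus_onset": onsets,
            "trial_end": ends,
        }
    )
    trace = generate_pupil_trace(
        trials, pupil_params, seed=rng_trace, baseline_anchors=anchors
    )
    return SessionLog(
        paradigm=paradigm,
        trials=trials,
        pupil=trace,
        seed=-1 if seed is None else int(seed) if np.isscalar(seed) else -1,
        animal_id=animal_id,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for a multi-session cohort."""

    go_fractions: tuple[float, ...] = (0.8, 0.5, 0.2)
    n_sessions: int = 30
    n_trials: int = 270
    assignment: str = "round_robin"   # or "random"
    observers: dict | None = None      # go_fraction -> ObserverParams
    pupil: PupilGenParams = field(default_factory=PupilGenParams)
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __post_init__(self):
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.assignment not in ("round_robin", "random"):
            raise ValueError("assignment must be 'round_robin' or 'random'")

    def observer_for(self, go_fraction: float) -> ObserverParams:
        if self.observers and go_fraction in self.observers:
            return self.observers[go_fraction]
        return default_observer(go_fraction)


def generate_cohort(config: CohortConfig, master_seed=None) -> list[SessionLog]:
    """Generate a seeded cohort; child seeds derive from the master seed."""
    ss = _as_seedseq(master_seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(config.n_sessions)
    sessions = []
    for i, child in enumerate(children):
        if config.assignment == "round_robin":
            gf = config.go_fractions[i % len(config.go_fractions)]
        else:
            gf = config.go_fractions[assign_rng.integers(len(config.go_fractions))]
        paradigm = Paradigm(go_fraction=gf, n_trials=config.n_trials, timing=config.timing)
        s = generate_session(
            paradigm,
            observer=config.observer_for(gf),
            pupil_params=config.pupil,
            seed=child,
            animal_id=f"synthetic-{i % 5}",
        )
        s.seed = i
        sessions.append(s)
    return sessions


# ----------------------------------------------------------------------
# session I/O (plain CSV + JSON, '.' decimal, UTF-8)


def write_session(session: SessionLog, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(d / "trials.csv", index=False, columns=TRIAL_COLUMNS)
    session.pupil.to_frame().to_csv(d / "pupil.csv", index=False)
    meta = {
        "go_fraction": session.paradigm.go_fraction,
        "n_trials": session.paradigm.n_trials,
        "timing": asdict(session.paradigm.timing),
        "seed": session.seed,
        "animal_id": session.animal_id,
        "sample_rate": session.pupil.sample_rate,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return d


def read_session(directory) -> SessionLog:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    timing_kw = meta["timing"]
    for key in ("delay_range", "penalty_delay_range"):
        timing_kw[key] = tuple(timing_kw[key])
    paradigm = Paradigm(
        go_fraction=meta["go_fraction"],
        n_trials=meta["n_trials"],
        timing=TrialTiming(**timing_kw),
    )
    trials = pd.read_csv(d / "trials.csv")
    pupil = PupilTrace.from_frame(
        pd.read_csv(d / "pupil.csv"), sample_rate=meta["sample_rate"]
    )
    return SessionLog(
        paradigm=paradigm,
        trials=trials,
        pupil=pupil,
        seed=meta["seed"],
        animal_id=meta["animal_id"],
    )
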