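"""End-to-end orchestration: simulate -> analyze -> pupil -> rewardopt -> ddm.

A single run configuration (nested dict, typically loaded from YAML) drives
every stage; each stage writes its artifacts under the output directory and
a manifest records the configuration hash so a run is reproducible from
config + master seed alone.  Stages whose block is missing from the config
are skipped with a log line.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ddm import compare_models
from .psychometrics import summarize_sessions
from .pupil import arousal_conditioned_sdt, session_features
from .rewardopt import default_config, find_optimal_criterion, optimal_slope
from .synth import (
    CohortConfig,
    ObserverParams,
    PupilGenParams,
    generate_cohort,
    read_session,
    write_session,
)

logger = logging.getLogger("pupilsdt")

STAGES = ("synth", "psychometrics", "pupil", "rewardopt", "ddm")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def cohort_from_config(block: dict) -> CohortConfig:
    observers = None
    if "observers" in block:
        observers = {
            float(gf): ObserverParams(**kw) for gf, kw in block["observers"].items()
        }
    pupil = PupilGenParams(**block.get("pupil", {}))
    return CohortConfig(
        go_fractions=tuple(block.get("go_fractions", (0.8, 0.5, 0.2))),
        n_sessions=int(block.get("n_sessions", 30)),
        n_trials=int(block.get("n_trials", 270)),
        assignment=block.get("assignment", "round_robin"),
        observers=observers,
        pupil=pupil,
    )


def run_pipeline(config: dict, out_dir, master_seed: int = 0) -> dict:
    """Run all configured stages; returns a manifest dict.

    Artifact tree: ``sessions/``, ``features/``, ``summary.csv``,
    ``rewardopt/``, ``ddm/``, ``report.md`` and ``manifest.json``.  A stage
    failure raises with the stage name; artifacts of earlier stages are
    left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(master_seed)
    stage_seeds = dict(zip(STAGES, ss.spawn(len(STAGES))))
    manifest = {
        "version": __version__,
        "master_seed": master_seed,
        "config_hash": _config_hash(config),
        "stages_run": [],
    }
    cohort = None
    report: list[str] = ["# pupilsdt run report", ""]

    if "synth" in config:
        cohort = generate_cohort(cohort_from_config(config["synth"]), stage_seeds["synth"])
        sess_dir = out / "sessions"
        for i, s in enumerate(cohort):
            write_session(s, sess_dir / f"session-{i:03d}")
        manifest["stages_run"].append("synth")
        report += [f"## Cohort", f"- {len(cohort)} sessions generated", ""]
    else:
        logger.info("stage synth skipped (no config block)")

    if "psychometrics" in config:
        if cohort is None:
            cohort = load_sessions(out / "sessions")
        per_session, summaries = summarize_sessions(cohort)
        per_session.to_csv(out / "summary.csv", index=False)
        report.append("## Behavioral grand means (mean ± SE across sessions)")
        report.append("")
        report.append("| go fraction | HR | FAR | d' | criterion | RT (s) | impulsive |")
        report.append("|---|---|---|---|---|---|---|")
        for gf, grp in per_session.groupby("go_fraction"):
            row = [f"{gf:g}"] + [
                f"{grp[c].mean():.3f} ± {grp[c].sem():.3f}"
                for c in ("hit_rate", "fa_rate", "d_prime", "criterion",
                          "mean_rt", "impulsive_fraction")
            ]
            report.append("| " + " | ".join(row) + " |")
        report.append("")
        manifest["stages_run"].append("psychometrics")
    else:
        logger.info("stage psychometrics skipped (no config block)")

    if "pupil" in config:
        if cohort is None:
            cohort = load_sessions(out / "sessions")
        feat_dir = out / "features"
        feat_dir.mkdir(exist_ok=True)
        for i, s in enumerate(cohort):
            session_features(s).to_csv(feat_dir / f"session-{i:03d}.csv", index=False)
        table, slopes = arousal_conditioned_sdt(cohort)
        table.to_csv(out / "arousal_conditioned.csv", index=False)
        report.append("## Criterion by arousal tertile")
        report.append("")
        report.append(table.to_string(index=False))
        report.append("")
        report.append(f"criterion slopes per tertile: {slopes}")
        report.append("")
        manifest["stages_run"].append("pupil")
        manifest["tertile_slopes"] = {k: v for k, v in slopes.items()}
    else:
        logger.info("stage pupil skipped (no config block)")

    if "rewardopt" in config:
        block = config["rewardopt"]
        ro_dir = out / "rewardopt"
        ro_dir.mkdir(exist_ok=True)
        optima = {}
        rng = np.random.default_rng(stage_seeds["rewardopt"])
        for gf in block.get("go_fractions", (0.8, 0.5, 0.2)):
            cfg = default_config(
                float(gf),
                n_trials=int(block.get("n_trials", 15_000)),
                n_repeats=int(block.get("n_repeats", 20)),
            )
            res = find_optimal_criterion(cfg, seed=rng)
            optima[float(gf)] = res.mean
            pd.DataFrame(
                {
                    "criterion": res.curve.criteria,
                    "mean_rate": res.curve.mean_rate,
                    "se_rate": res.curve.se_rate,
                    "analytic_rate": res.curve.analytic,
                }
            ).to_csv(ro_dir / f"curve-p{gf}.csv", index=False)
        manifest["optimal_criteria"] = optima
        if len(optima) >= 2:
            manifest["optimal_slope"] = optimal_slope(optima)
        report.append("## Reward-rate optimal criteria")
        report.append("")
        for gf, c in sorted(optima.items(), reverse=True):
            report.append(f"- go fraction {gf:g}: optimal criterion {c:.3f}")
        if "optimal_slope" in manifest:
            report.append(f"- slope across paradigms: {manifest['optimal_slope']:.3f}")
        report.append("")
        manifest["stages_run"].append("rewardopt")
    else:
        logger.info("stage rewardopt skipped (no config block)")

    if "ddm" in config:
        if cohort is None:
            cohort = load_sessions(out / "sessions")
        block = config["ddm"]
        ddm_dir = out / "ddm"
        ddm_dir.mkdir(exist_ok=True)
        trials = pd.concat([s.trials for s in cohort], ignore_index=True)
        max_trials = int(block.get("max_trials", 4000))
        if len(trials) > max_trials:
            trials = trials.iloc[:max_trials]
        table = compare_models(
            trials,
            n_starts=int(block.get("n_starts", 5)),
            seed=stage_seeds["ddm"],
        )
        table.to_csv(ddm_dir / "model_comparison.csv", index=False)
        manifest["ddm_winner"] = str(table.iloc[0]["variant"])
        report.append("## DDM variant comparison (pooled synthetic trials)")
        report.append("")
        report.append(table.to_string(index=False))
        report.append("")
        manifest["stages_run"].append("ddm")
    else:
        logger.info("stage ddm skipped (no config block)")

    (out / "report.md").write_text("\n".join(report))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def load_sessions(directory) -> list:
    """Read every session-* subdirectory of a sessions folder."""
    d = Path(directory)
    dirs = sorted(p for p in d.iterdir() if p.is_dir())
    if not dirs:
        raise FileNotFoundError(f"no session directories under {d}")
    return [read_session(p) for p in dirs]
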