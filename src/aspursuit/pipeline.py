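"""End-to-end orchestration: simulate -> preprocess -> fit -> stats -> TWI.

A run is described by a :class:`RunConfig` (loadable from YAML).  One
master seed is recorded and per-stage seeds are derived from it
deterministically, so re-running the same config reproduces every
stochastic output.  All intermediates are flat text tables; a JSON
manifest records seeds, row counts, QC exclusion rates, and timing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DependencyError, UnusableTraceError
from .preprocess import desaccade_and_qc, detect_saccades, filter_and_differentiate
from .stats import (
    fit_probability_model,
    fit_sequence_model,
    prepare_analysis_table,
    to_long_axes,
)
from .synth import GenerativeParams, make_design, simulate_experiment
from .trialfit import fit_table
from .twi import bootstrap_twi, twi_table

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "trialfit", "stats", "twi")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    preset: str = "exp1a"
    n_participants: int = 3
    trials_scale: float = 1.0
    seed: int = 1
    params: dict = field(default_factory=dict)  # GenerativeParams overrides
    profile: str | None = None  # QC profile; defaults to the preset's
    fit_window: tuple[float, float] | None = None  # defaults to the design's
    stages: tuple[str, ...] = STAGES
    n_boot: int = 1000
    bootstrap_unit: str = "trial"
    outdir: str | None = None
    write_traces: bool = False

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        if cfg.fit_window is not None:
            cfg.fit_window = tuple(cfg.fit_window)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


#: Ready-made small demo configurations.
DEMO_CONFIGS = {
    "exp1a-small": RunConfig(preset="exp1a", n_participants=3, trials_scale=0.2, seed=1),
}


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one sub-2^31 seed per stage from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    design = make_design(config.preset, seed=config.seed, trials_scale=config.trials_scale)
    params = GenerativeParams().with_overrides(**config.params)
    profile = config.profile or design.qc_profile
    fit_window = config.fit_window or design.fit_window

    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
        "design": {"name": design.name, "n_blocks": len(design.blocks),
                   "blocks": [b.label for b in design.blocks], "mode": design.mode},
        "stages": {},
        "timing_s": {},
    }

    trials = truth = traces = qc = fits = None
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        if stage == "simulate":
            trials, traces, truth = simulate_experiment(
                design, params, n_participants=config.n_participants,
                seed=seeds["simulate"],
            )
            manifest["stages"]["simulate"] = {
                "n_trials": len(trials), "n_traces": len(traces),
                "n_participants": config.n_participants,
            }
            if outdir:
                _write_table(trials, outdir / "trials.tsv", config.seed)
                _write_table(truth, outdir / "truth.tsv", config.seed)
                if config.write_traces:
                    from .preprocess import write_trace_tsv

                    tdir = outdir / "traces"
                    tdir.mkdir(exist_ok=True)
                    for (p, b, i), tr in traces.items():
                        safe = b.replace("(", "").replace(")", "").replace("=", "")
                        write_trace_tsv(tr, tdir / f"p{p}_{safe}_t{i:04d}.tsv")
        elif stage == "preprocess":
            if traces is None:
                raise DependencyError("preprocess requires traces; enable the simulate stage")
            qc_rows = []
            clean = {}
            for key, tr in traces.items():
                try:
                    filt = filter_and_differentiate(tr)
                except UnusableTraceError as exc:
                    qc_rows.append(dict(zip(("participant", "block", "trial"), key),
                                        onset_window_missing=1.0, overall_missing=1.0,
                                        excluded=True, reason=str(exc)))
                    continue
                saccades = detect_saccades(filt)
                cleaned, report = desaccade_and_qc(filt, saccades, profile)
                clean[key] = cleaned
                qc_rows.append(dict(zip(("participant", "block", "trial"), key),
                                    onset_window_missing=report.onset_window_missing,
                                    overall_missing=report.overall_missing,
                                    excluded=report.excluded, reason=report.reason))
            qc = pd.DataFrame(qc_rows)
            traces = clean
            excl = float(qc["excluded"].mean()) if len(qc) else 0.0
            manifest["stages"]["preprocess"] = {
                "n_trials": len(qc), "exclusion_rate": excl, "profile": profile,
            }
            if outdir:
                _write_table(qc, outdir / "qc.tsv", config.seed)
        elif stage == "trialfit":
            if traces is None:
                raise DependencyError("trialfit requires preprocessed traces; enable preprocess")
            keep = traces
            if qc is not None:
                kept_keys = {
                    (r.participant, r.block, r.trial)
                    for r in qc.itertuples() if not r.excluded
                }
                keep = {k: v for k, v in traces.items() if k in kept_keys}
            max_speed = max(
                c.target_speed(np.array([0.0, c.duration])).max()
                for b in design.blocks for c in b.conditions
            )
            fits = fit_table(keep, fit_window=fit_window, max_target_speed=float(max_speed))
            manifest["stages"]["trialfit"] = {
                "n_fits": len(fits),
                "n_flagged": int(fits["flagged"].sum()) if len(fits) else 0,
            }
            if outdir:
                _write_table(fits, outdir / "fits.tsv", config.seed)
        elif stage == "stats":
            if fits is None:
                raise DependencyError("stats requires a fit table; enable the trialfit stage")
            records = prepare_analysis_table(fits, trials, qc)
            stage_out: dict = {"n_records": len(records)}
            if design.mode == "probability":
                oblique = any(
                    c.direction % 180 not in (0.0,)
                    for b in design.blocks for c in b.conditions
                )
                prob_records = to_long_axes(records) if oblique else records
                summary = fit_probability_model(prob_records)
                stage_out["probability"] = _coef_dict(summary)
                seq = records[records["prev_speed_class"].isin(["high", "low"])]
                if seq["prev_speed_class"].nunique() == 2:
                    seq_summary = fit_sequence_model(seq)
                    stage_out["sequence"] = _coef_dict(seq_summary)
                if outdir:
                    _write_table(summary.params.reset_index(names="effect"),
                                 outdir / "probability_model.tsv", config.seed)
            else:
                from .stats import fit_kinematics_model, pairwise_contrasts

                kin = fit_kinematics_model(records)
                stage_out["kinematics"] = {
                    "full": _coef_dict(kin["full"]),
                    "delta_bic": kin["delta_bic"],
                    "bayes_factor": kin["bayes_factor"],
                }
                contrasts = pairwise_contrasts(records)
                stage_out["n_contrasts"] = len(contrasts)
                if outdir:
                    _write_table(contrasts, outdir / "contrasts.tsv", config.seed)
            manifest["stages"]["stats"] = stage_out
            if outdir:
                _write_table(records, outdir / "analysis_table.tsv", config.seed)
        elif stage == "twi":
            if fits is None:
                raise DependencyError("twi requires a fit table; enable the trialfit stage")
            if design.mode != "kinematics":
                log.info("twi stage skipped: design %s has no constant/accelerating grid", design.name)
                continue
            records = prepare_analysis_table(fits, trials, qc)
            const = records[records["accel"] == 0]
            accel = records[records["accel"] != 0]
            estimates = bootstrap_twi(
                const, accel, n_boot=config.n_boot, seed=seeds["twi"],
                unit=config.bootstrap_unit,
            )
            table = twi_table(estimates)
            manifest["stages"]["twi"] = {
                "n_conditions": len(table),
                "twi_end": {r.condition: r.twi_end for r in table.itertuples()},
            }
            if outdir:
                _write_table(table, outdir / "twi.tsv", config.seed)
        manifest["timing_s"][stage] = round(time.perf_counter() - t0, 3)

    if outdir:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _coef_dict(summary) -> dict:
    return {
        name: {"estimate": float(row["estimate"]), "ci": [float(row["ci_low"]), float(row["ci_high"])],
               "p": float(row["p"])}
        for name, row in summary.params.iterrows()
    } | {"ladder_rung": summary.ladder_rung, "converged": summary.converged}


def _write_table(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
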