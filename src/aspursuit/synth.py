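"""Synthetic anticipatory-pursuit experiments: designs, latent truth, traces.

This module generates the study conditions the analysis chain expects:
block designs mixing target kinematic conditions with fixed probabilities,
per-trial latent anticipatory velocities drawn from a hierarchical linear
model (participant random intercepts and slopes, trial-history effect,
residual noise), and 1 kHz gaze position traces built from a generative
velocity profile:

* zero velocity during fixation and the first part of the 300 ms gap,
* a normalized convex exponential ramp starting at ``anticip_onset``
  (before the eye could possibly respond to the visual motion) and reaching
  the latent anticipatory velocity aSPv exactly at ``visual_latency``,
* a smooth sigmoidal transition toward ``gain x target_velocity(t)``
  (visually-guided pursuit, gain <= 1 for fast targets),
* optional catch-up saccades (brief raised-cosine velocity pulses) and
  white position noise.

Every simulator function is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import EyeTrace

PRESETS = ("exp1a", "exp1b", "exp2a", "exp2b", "exp3")


def mean_target_speed(v0: float, accel: float, duration: float) -> float:
    """Mean of the target speed ``v0 + accel*t`` over [0, duration] (deg/s).

    Closed form ``v0 + accel*duration/2``; equals the time integral of the
    linear speed ramp divided by the window length.
    """
    return v0 + accel * duration / 2.0


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinematicCondition:
    """One target kinematic condition.

    ``label`` follows the vXXc/vXXa/vXXd convention (initial radial speed
    XX deg/s; constant / accelerating +22 deg/s^2 / decelerating -22
    deg/s^2).  ``direction`` is the motion angle in degrees from horizontal
    (0 = rightward, 45 = oblique).
    """

    label: str
    v0: float
    accel: float
    duration: float
    direction: float = 0.0

    def __post_init__(self):
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def target_speed(self, t: np.ndarray) -> np.ndarray:
        """Radial target speed at time t >= 0, clipped at zero."""
        return np.maximum(self.v0 + self.accel * np.asarray(t, dtype=float), 0.0)

    def axis_components(self, radial: float | np.ndarray) -> tuple:
        """Split a radial quantity into (horizontal, vertical) components."""
        th = math.radians(self.direction)
        return radial * math.cos(th), radial * math.sin(th)

    @property
    def displacement(self) -> float:
        """Total target displacement over the motion epoch (deg)."""
        return self.v0 * self.duration + 0.5 * self.accel * self.duration**2


@dataclass(frozen=True)
class BlockDesign:
    """A block of trials mixing conditions with fixed probabilities.

    ``reference`` names the condition whose occurrence probability is the
    block's P (the high-speed / reference kinematics in the regressions).
    """

    label: str
    conditions: tuple[KinematicCondition, ...]
    probabilities: tuple[float, ...]
    n_trials: int
    reference: str
    fixation_duration_range: tuple[float, float] = (0.3, 0.45)
    gap_duration: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if len(self.conditions) != len(self.probabilities):
            raise ValueError("one probability per condition required")
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(self.probabilities)}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique within a block")
        if self.reference not in labels:
            raise ValueError(f"reference {self.reference!r} not among {labels}")

    @property
    def p_reference(self) -> float:
        return self.probabilities[[c.label for c in self.conditions].index(self.reference)]

    def condition(self, label: str) -> KinematicCondition:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class ExperimentDesign:
    """A named collection of blocks plus analysis conventions."""

    name: str
    blocks: tuple[BlockDesign, ...]
    mode: str  # "probability" (mixture blocks) or "kinematics" (fully predictable)
    qc_profile: str
    fit_window: tuple[float, float]
    seed: int = 0

    def block(self, label: str) -> BlockDesign:
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(label)


def make_design(preset_name: str, seed: int = 0, trials_scale: float = 1.0) -> ExperimentDesign:
    """Build one of the preset experimental designs.

    Presets: ``exp1a`` (horizontal 5.5/16.5 deg/s mixtures over seven
    probability levels), ``exp1b`` (oblique constant speeds 11/33 deg/s,
    equated displacement), ``exp2a``/``exp2b`` (oblique accelerating v11a
    vs decelerating v33d mixtures, equated displacement vs fixed 600 ms
    duration), ``exp3`` (3x3 initial speed x acceleration, fully
    predictable 500 ms blocks).  ``trials_scale`` shrinks every block's
    trial count proportionally for reduced-size runs.
    """
    if preset_name not in PRESETS:
        raise ConfigurationError(
            f"unknown design preset {preset_name!r}; valid presets: {', '.join(PRESETS)}"
        )
    scale = float(trials_scale)

    def n(count: int) -> int:
        return max(1, int(round(count * scale)))

    blocks: list[BlockDesign] = []
    if preset_name == "exp1a":
        ls = KinematicCondition("LS", v0=5.5, accel=0.0, duration=0.5, direction=0.0)
        hs = KinematicCondition("HS", v0=16.5, accel=0.0, duration=0.5, direction=0.0)
        for p_hs in (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0):
            n_trials = 250 if p_hs in (0.0, 1.0) else 500
            blocks.append(
                BlockDesign(
                    label=f"P(HS)={p_hs:g}",
                    conditions=(ls, hs),
                    probabilities=(1.0 - p_hs, p_hs),
                    n_trials=n(n_trials),
                    reference="HS",
                    fixation_duration_range=(0.3, 0.45),
                    seed=seed,
                )
            )
        return ExperimentDesign(
            name="exp1a", blocks=tuple(blocks), mode="probability",
            qc_profile="exp1a", fit_window=(-0.3, 0.35), seed=seed,
        )

    if preset_name in ("exp1b", "exp2a", "exp2b"):
        if preset_name == "exp1b":
            lo = KinematicCondition("v11c", v0=11.0, accel=0.0, duration=1.0, direction=45.0)
            hi = KinematicCondition("v33c", v0=33.0, accel=0.0, duration=0.52, direction=45.0)
        else:
            dur_lo, dur_hi = (0.87, 0.72) if preset_name == "exp2a" else (0.6, 0.6)
            lo = KinematicCondition("v11a", v0=11.0, accel=22.0, duration=dur_lo, direction=45.0)
            hi = KinematicCondition("v33d", v0=33.0, accel=-22.0, duration=dur_hi, direction=45.0)
        for p_hi in (0.0, 0.3, 0.7, 1.0):
            n_trials = 100 if p_hi in (0.0, 1.0) else 200
            blocks.append(
                BlockDesign(
                    label=f"P({hi.label})={p_hi:g}",
                    conditions=(lo, hi),
                    probabilities=(1.0 - p_hi, p_hi),
                    n_trials=n(n_trials),
                    reference=hi.label,
                    fixation_duration_range=(0.3, 0.6),
                    seed=seed,
                )
            )
        return ExperimentDesign(
            name=preset_name, blocks=tuple(blocks), mode="probability",
            qc_profile=preset_name, fit_window=(-0.3, 0.3), seed=seed,
        )

    # exp3: fully-crossed v0 x accel, fully predictable blocks
    for v0 in (11.0, 22.0, 33.0):
        for suffix, accel in (("a", 22.0), ("c", 0.0), ("d", -22.0)):
            label = f"v{v0:.0f}{suffix}"
            cond = KinematicCondition(label, v0=v0, accel=accel, duration=0.5, direction=45.0)
            blocks.append(
                BlockDesign(
                    label=label,
                    conditions=(cond,),
                    probabilities=(1.0,),
                    n_trials=n(120 if v0 == 33.0 else 100),
                    reference=label,
                    fixation_duration_range=(0.3, 0.6),
                    seed=seed,
                )
            )
    return ExperimentDesign(
        name="exp3", blocks=tuple(blocks), mode="kinematics",
        qc_profile="exp3", fit_window=(-0.3, 0.3), seed=seed,
    )


# ---------------------------------------------------------------------------
# generative parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenerativeParams:
    """Ground-truth parameters of the synthetic experiment.

    The latent anticipatory velocity of trial t for participant p in a
    probability-mixture block with reference probability P is

        aSPv = beta0 + b0_p + (beta1 + b1_p) * P
               + gamma_hist * 1[previous trial was the reference kinematics]
               + eps,   eps ~ N(0, trial_sd^2)

    with participant effects b0_p ~ N(0, participant_sd_intercept^2) and
    b1_p ~ N(0, participant_sd_slope^2).  In fully-predictable kinematic
    blocks the latent mean is instead ``beta0 + b0_p + speed_slope * TSE``
    where TSE is the mean target speed over the generative temporal window
    [0, twi_end] -- for constant-speed conditions simply the target speed.

    Trace-level parameters: the anticipatory ramp starts at
    ``anticip_onset`` (s, negative = before target onset, inside the gap)
    and reaches the latent aSPv at ``visual_latency`` (~100 ms, the usual
    human pursuit latency); ``exp_curvature`` sets the convexity of the
    normalized exponential; ``sigmoid_rate`` the steepness of the
    transition to visually-guided pursuit.  ``steady_gain=None`` applies a
    speed-dependent rule (1.0 up to 11 deg/s, 0.9 at 22, 0.8 at 33 deg/s).
    """

    beta0: float = 2.5          # baseline aSPv, deg/s
    beta1: float = 5.0          # probability slope, deg/s per unit probability
    gamma_hist: float = 0.5     # additive effect of an N-1 reference (high-speed) trial
    participant_sd_intercept: float = 0.4
    participant_sd_slope: float = 0.4
    trial_sd: float = 1.0       # residual aSPv sd, deg/s
    speed_slope: float = 0.2    # kinematic-mode slope, (deg/s aSPv) per (deg/s target)
    twi_end: float = 0.2        # generative temporal window of integration, s
    anticip_onset: float = -0.1  # s relative to target onset
    visual_latency: float = 0.1  # s
    exp_curvature: float = 15.0  # 1/s
    sigmoid_rate: float = 40.0   # 1/s
    sigmoid_mid_offset: float = 0.07  # s past visual_latency
    steady_gain: float | None = None
    position_noise_sd: float = 0.05  # deg per raw sample
    saccade_rate: float = 1.5    # expected catch-up saccades per trial
    onset_jitter_sd: float = 0.0  # optional trial-to-trial jitter of anticip_onset, s

    def __post_init__(self):
        for name in ("participant_sd_intercept", "participant_sd_slope", "trial_sd",
                     "position_noise_sd", "saccade_rate", "onset_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.visual_latency <= self.anticip_onset:
            raise ValueError("visual_latency must exceed anticip_onset")
        if self.steady_gain is not None and not (0 < self.steady_gain <= 1):
            raise ValueError("steady_gain must lie in (0, 1]")

    def gain_for(self, cond: KinematicCondition) -> float:
        if self.steady_gain is not None:
            return self.steady_gain
        if cond.v0 <= 11.0:
            return 1.0
        if cond.v0 <= 22.0:
            return 0.9
        return 0.8

    def with_overrides(self, **kwargs) -> "GenerativeParams":
        valid = {f.name for f in fields(self)}
        bad = set(kwargs) - valid
        if bad:
            raise ConfigurationError(f"unknown generative parameters: {sorted(bad)}")
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# single-trial trace generation
# ---------------------------------------------------------------------------


def generative_velocity(
    t: np.ndarray,
    cond: KinematicCondition,
    aspv_true: float,
    params: GenerativeParams,
    anticip_onset: float | None = None,
) -> np.ndarray:
    """Along-motion eye velocity profile of the generative model (deg/s).

    Zero until the anticipation onset; a normalized convex exponential
    ``aSPv * (exp(rho*(t - t_a)) - 1) / (exp(rho*(t_lat - t_a)) - 1)``
    reaching exactly ``aspv_true`` at the visual latency; then a normalized
    logistic transition from aSPv toward ``gain * target_velocity(t)``.
    """
    t = np.asarray(t, dtype=float)
    t_a = params.anticip_onset if anticip_onset is None else anticip_onset
    t_lat = params.visual_latency
    rho = params.exp_curvature
    v = np.zeros_like(t)

    mid = (t >= t_a) & (t < t_lat)
    denom = math.exp(rho * (t_lat - t_a)) - 1.0
    v[mid] = aspv_true * (np.exp(rho * (t[mid] - t_a)) - 1.0) / denom

    late = t >= t_lat
    gain = params.gain_for(cond)
    target = gain * cond.target_speed(np.maximum(t[late], 0.0))
    k = params.sigmoid_rate
    t_mid = t_lat + params.sigmoid_mid_offset
    s = 1.0 / (1.0 + np.exp(-k * (t[late] - t_mid)))
    s0 = 1.0 / (1.0 + math.exp(-k * (t_lat - t_mid)))
    frac = (s - s0) / (1.0 - s0)
    v[late] = aspv_true + (target - aspv_true) * frac
    return v


def simulate_trial(
    cond: KinematicCondition,
    aspv_true: float,
    params: GenerativeParams,
    seed: int | np.random.Generator = 0,
    t_start: float = -0.5,
    anticip_onset: float | None = None,
    with_saccades: bool = True,
    with_noise: bool = True,
) -> EyeTrace:
    """Simulate one 1 kHz position trace over [t_start, cond.duration].

    The generative along-motion velocity (plus injected saccade pulses) is
    decomposed into horizontal/vertical components by the direction
    cosines, integrated to position, and white Gaussian position noise is
    added.  Injected saccade intervals are recorded in ``trace.meta``.

    Raises ``ValueError`` for a negative ``aspv_true`` (the positive
    direction convention points along the expected target motion).
    """
    if not np.isfinite(aspv_true):
        raise ValueError("aspv_true must be finite")
    if aspv_true < 0:
        raise ValueError("aspv_true < 0 violates the positive-direction convention")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = 1000.0
    n = int(round((cond.duration - t_start) * fs)) + 1
    t = t_start + np.arange(n) / fs

    v_along = generative_velocity(t, cond, aspv_true, params, anticip_onset=anticip_onset)

    saccades: list[tuple[float, float, float]] = []
    if with_saccades and params.saccade_rate > 0:
        n_sacc = rng.poisson(params.saccade_rate)
        pulse_dur = 0.030  # raised-cosine catch-up saccade pulses
        t_lo = params.visual_latency
        t_hi = cond.duration - pulse_dur
        for _ in range(n_sacc):
            if t_hi <= t_lo:
                break
            onset = rng.uniform(t_lo, t_hi)
            peak = rng.uniform(80.0, 200.0)
            in_pulse = (t >= onset) & (t < onset + pulse_dur)
            phase = (t[in_pulse] - onset) / pulse_dur
            v_along = v_along.copy()
            v_along[in_pulse] += peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
            saccades.append((float(onset), float(onset + pulse_dur), float(peak)))

    vx, vy = cond.axis_components(v_along)
    dt = 1.0 / fs
    x = np.concatenate(([0.0], np.cumsum((vx[1:] + vx[:-1]) * 0.5 * dt)))
    y = np.concatenate(([0.0], np.cumsum((vy[1:] + vy[:-1]) * 0.5 * dt)))
    if with_noise and params.position_noise_sd > 0:
        x = x + rng.normal(0.0, params.position_noise_sd, size=n)
        y = y + rng.normal(0.0, params.position_noise_sd, size=n)

    return EyeTrace(
        time=t, x=x, y=y, sample_rate=fs,
        meta={
            "condition": cond.label,
            "direction": cond.direction,
            "aspv_true": float(aspv_true),
            "saccades": saccades,
        },
    )


# ---------------------------------------------------------------------------
# whole experiments
# ---------------------------------------------------------------------------


def simulate_experiment(
    design: ExperimentDesign,
    params: GenerativeParams,
    n_participants: int = 1,
    seed: int = 0,
    with_traces: bool = True,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Simulate a whole experiment: trial table, traces, and ground truth.

    Returns ``(trials, traces, truth)``: a per-trial metadata table
    (participant, block, trial, condition, kinematics, block probability P
    of the reference condition, previous-trial class), a dict of
    :class:`EyeTrace` keyed by ``(participant, block_label, trial)`` (empty
    when ``with_traces=False``), and the ground-truth table holding every
    latent aSPv, participant random effects, and trace timing parameters.

    Fully reproducible: the same seed yields byte-identical tables.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    root = np.random.SeedSequence(seed)
    part_seeds = root.spawn(n_participants)
    rows = []
    truth_rows = []
    traces: dict = {}

    for p in range(n_participants):
        pseq = part_seeds[p]
        prng = np.random.default_rng(pseq)
        b0 = prng.normal(0.0, params.participant_sd_intercept)
        b1 = prng.normal(0.0, params.participant_sd_slope)
        for block in design.blocks:
            labels = [c.label for c in block.conditions]
            draw = prng.choice(len(labels), size=block.n_trials, p=block.probabilities)
            prev_is_ref: bool | None = None
            for i in range(block.n_trials):
                cond = block.conditions[draw[i]]
                is_ref = cond.label == block.reference
                p_block = block.p_reference
                if design.mode == "probability":
                    mu = params.beta0 + b0 + (params.beta1 + b1) * p_block
                    if prev_is_ref is True:
                        mu += params.gamma_hist
                else:
                    tw = min(params.twi_end, cond.duration)
                    tse = mean_target_speed(cond.v0, cond.accel, tw)
                    mu = params.beta0 + b0 + params.speed_slope * tse
                aspv = mu + prng.normal(0.0, params.trial_sd)
                t_a = params.anticip_onset
                if params.onset_jitter_sd > 0:
                    t_a += prng.normal(0.0, params.onset_jitter_sd)
                fix_dur = prng.uniform(*block.fixation_duration_range)
                if prev_is_ref is None:
                    prev_class = "none"
                else:
                    prev_class = "high" if prev_is_ref else "low"
                rows.append(
                    {
                        "participant": p,
                        "block": block.label,
                        "trial": i,
                        "condition": cond.label,
                        "v0": cond.v0,
                        "accel": cond.accel,
                        "duration": cond.duration,
                        "direction": cond.direction,
                        "P": p_block,
                        "is_reference": is_ref,
                        "prev_speed_class": prev_class,
                    }
                )
                truth_rows.append(
                    {
                        "participant": p,
                        "block": block.label,
                        "trial": i,
                        "condition": cond.label,
                        "aspv_true": aspv,
                        "b0": b0,
                        "b1": b1,
                        "anticip_onset": t_a,
                        "visual_latency": params.visual_latency,
                        "fixation_duration": fix_dur,
                    }
                )
                if with_traces:
                    trace = simulate_trial(
                        cond,
                        max(aspv, 0.0),
                        params,
                        seed=prng,
                        t_start=-(block.gap_duration + min(fix_dur, 0.2)),
                        anticip_onset=t_a,
                    )
                    trace.meta.update(participant=p, block=block.label, trial=i, seed=seed)
                    traces[(p, block.label, i)] = trace
                    truth_rows[-1]["n_saccades"] = len(trace.meta["saccades"])
                prev_is_ref = is_ref
    trials = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return trials, traces, truth


def observed_records(trials: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Trial table with the latent aSPv attached as the observed response.

    Convenience for analyses that bypass trace generation and fitting: the
    latent aSPv already carries the residual trial-to-trial variability.
    """
    key = ["participant", "block", "trial"]
    merged = trials.merge(truth[key + ["aspv_true"]], on=key, validate="one_to_one")
    return merged.rename(columns={"aspv_true": "aSPv"})
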