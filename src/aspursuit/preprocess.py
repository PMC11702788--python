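"""Gaze-trace preprocessing: parsing, filtering, saccade removal, and trial QC.

The pipeline turns raw eye-position samples (1 kHz, degrees) into clean,
desaccaded velocity traces suitable for single-trial model fitting:

1. :func:`parse_samples` reads EyeLink-style ASCII or tab-separated files
   into an :class:`EyeTrace` with an onset-aligned time axis.
2. :func:`filter_and_differentiate` applies a zero-phase second-order
   Butterworth low-pass (30 Hz cutoff) to each position axis and computes
   velocity by central differences.
3. :func:`detect_saccades` combines an absolute speed threshold (30 deg/s)
   with a median-based relative threshold to find saccadic intervals.
4. :func:`desaccade_and_qc` blanks velocity inside saccades (NaN) and
   applies per-experiment trial-exclusion rules based on missing-data
   fractions around target motion onset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, ParseError, UnusableTraceError

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class EyeTrace:
    """Per-trial gaze samples on an onset-aligned time axis.

    ``time`` is in seconds relative to target motion onset (onset = 0) and
    must be strictly increasing with uniform step ``1/sample_rate``.
    Positions are in degrees of visual angle.  ``vx``/``vy`` (deg/s) are
    filled by :func:`filter_and_differentiate`; NaN marks missing samples
    (parser gaps or removed saccades).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float = 1000.0
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.x) or len(self.x) != len(self.y):
            raise ValueError("time, x, y must be 1-D arrays of equal length")
        if len(self.time) >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            dt = 1.0 / self.sample_rate
            if not np.allclose(steps, dt, rtol=0, atol=dt * 1e-3):
                raise ValueError("time must be uniformly sampled at sample_rate")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def has_velocity(self) -> bool:
        return self.vx is not None and self.vy is not None

    def speed(self) -> np.ndarray:
        """2-D eye speed (Euclidean norm of axis velocities), deg/s."""
        if not self.has_velocity:
            raise ValueError("velocity not computed; run filter_and_differentiate")
        return np.hypot(self.vx, self.vy)

    def along_motion_velocity(self, direction_deg: float | None = None) -> np.ndarray:
        """Velocity component along the target's motion direction (deg/s)."""
        if direction_deg is None:
            direction_deg = float(self.meta.get("direction", 0.0))
        th = math.radians(direction_deg)
        return self.vx * math.cos(th) + self.vy * math.sin(th)

    def copy(self) -> "EyeTrace":
        return EyeTrace(
            time=self.time.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            sample_rate=self.sample_rate,
            vx=None if self.vx is None else self.vx.copy(),
            vy=None if self.vy is None else self.vy.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class SaccadeInterval:
    """A detected saccadic epoch, in onset-relative seconds."""

    start: float
    end: float
    peak_velocity: float
    detection_rule: str  # "absolute", "relative", or "merged"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("saccade interval requires start < end")


@dataclass
class QCReport:
    """Missing-data fractions and the resulting keep/exclude decision."""

    onset_window_missing: float
    overall_missing: float
    excluded: bool
    reason: str = ""

    def __post_init__(self):
        for f in (self.onset_window_missing, self.overall_missing):
            if not 0.0 <= f <= 1.0:
                raise ValueError("missing fractions must lie in [0, 1]")
        if self.excluded and not self.reason:
            raise ValueError("excluded trials must carry a reason")


#: Per-experiment exclusion rules: onset window (s), maximum tolerated
#: missing fraction in that window, and the overall missing-fraction cap.
#: Exclusion is strict ("more than"), so a fraction exactly at the
#: threshold keeps the trial.
QC_PROFILES: dict[str, dict] = {
    "exp1a": {"window": (-0.1, 0.2), "window_max": 0.40, "overall_max": 0.60},
    "exp1b": {"window": (-0.1, 0.1), "window_max": 0.70, "overall_max": 0.60},
    "exp2a": {"window": (-0.1, 0.1), "window_max": 0.70, "overall_max": 0.60},
    "exp2b": {"window": (-0.1, 0.1), "window_max": 0.70, "overall_max": 0.60},
    "exp3": {"window": (-0.1, 0.1), "window_max": 0.70, "overall_max": 0.60},
}


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("time_s", "x_deg", "y_deg")


def write_trace_tsv(trace: EyeTrace, path: str | Path, header_meta: dict | None = None) -> None:
    """Write a trace as a plain tab-separated file (time_s, x_deg, y_deg).

    Metadata (seed, condition, ...) goes into ``# key: value`` header lines.
    Missing samples are written as ``nan``.
    """
    path = Path(path)
    meta = dict(trace.meta)
    if header_meta:
        meta.update(header_meta)
    with open(path, "w") as fh:
        for key, value in meta.items():
            if isinstance(value, (str, int, float, bool)):
                fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for t, x, y in zip(trace.time, trace.x, trace.y):
            fh.write(f"{t:.6f}\t{x:.9f}\t{y:.9f}\n")


def write_trace_asc(trace: EyeTrace, path: str | Path, start_timestamp_ms: int = 1_000_000) -> None:
    """Write a trace as EyeLink-style ASCII sample lines.

    Sample lines are ``<timestamp_ms> <x> <y> <pupil>``; a
    ``MSG <ts> TARGET_ONSET`` event line marks time zero so the parser can
    recover the onset-relative axis.  Missing samples are written as ``.``.
    """
    path = Path(path)
    fs = trace.sample_rate
    onset_ts = start_timestamp_ms - trace.time[0] * 1000.0
    with open(path, "w") as fh:
        fh.write(f"MSG\t{onset_ts:.0f} TARGET_ONSET\n")
        for i, (x, y) in enumerate(zip(trace.x, trace.y)):
            ts = start_timestamp_ms + i * 1000.0 / fs
            if np.isnan(x) or np.isnan(y):
                fh.write(f"{ts:.0f}\t.\t.\t0.0\n")
            else:
                fh.write(f"{ts:.0f}\t{x:.9f}\t{y:.9f}\t0.0\n")


def parse_samples(path: str | Path, format: str = "tsv", sample_rate: float = 1000.0) -> EyeTrace:
    """Read a trace file into an :class:`EyeTrace`.

    ``format="tsv"`` expects columns time_s, x_deg, y_deg with optional
    ``#`` header lines.  ``format="asc"`` expects EyeLink-style sample
    lines plus a ``MSG <ts> TARGET_ONSET`` event used to align time zero.
    Gaps in the timestamp sequence are filled with NaN samples and logged.
    """
    path = Path(path)
    if format == "tsv":
        return _parse_tsv(path, sample_rate)
    if format == "asc":
        return _parse_asc(path, sample_rate)
    raise ConfigurationError(f"unknown trace format {format!r}; expected 'tsv' or 'asc'")


def _parse_tsv(path: Path, sample_rate: float) -> EyeTrace:
    meta: dict = {}
    times, xs, ys = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line.lstrip("# ").partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if parts[0] == TSV_COLUMNS[0]:
                continue
            try:
                times.append(float(parts[0]))
                xs.append(float(parts[1]))
                ys.append(float(parts[2]))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"cannot parse sample: {line!r}", line=lineno) from exc
    time, x, y = _fill_gaps(np.array(times), np.array(xs), np.array(ys), sample_rate, path)
    return EyeTrace(time=time, x=x, y=y, sample_rate=sample_rate, meta=meta)


def _parse_asc(path: Path, sample_rate: float) -> EyeTrace:
    onset_ts = None
    ts_list, xs, ys = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "MSG":
                if len(parts) >= 3 and parts[2] == "TARGET_ONSET":
                    onset_ts = float(parts[1])
                continue
            if not parts[0][0].isdigit():
                continue  # other event lines (SFIX, EBLINK, ...)
            try:
                ts = float(parts[0])
                if parts[1] == ".":
                    x = y = np.nan
                else:
                    x, y = float(parts[1]), float(parts[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"cannot parse sample: {line!r}", line=lineno) from exc
            ts_list.append(ts)
            xs.append(x)
            ys.append(y)
    if not ts_list:
        raise ParseError(f"no samples found in {path}")
    if onset_ts is None:
        log.warning("%s: no TARGET_ONSET event; time zero set to first sample", path)
        onset_ts = ts_list[0]
    times = (np.array(ts_list) - onset_ts) / 1000.0
    time, x, y = _fill_gaps(times, np.array(xs), np.array(ys), sample_rate, path)
    return EyeTrace(time=time, x=x, y=y, sample_rate=sample_rate)


def _fill_gaps(times, xs, ys, sample_rate, path):
    """Re-grid samples onto the uniform clock, NaN-filling missing slots."""
    if len(times) < 2:
        return times, xs, ys
    if np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 2
        raise ParseError("timestamps not monotonically increasing", line=bad)
    dt = 1.0 / sample_rate
    idx = np.round((times - times[0]) / dt).astype(int)
    n = idx[-1] + 1
    if n != len(times):
        log.warning("%s: %d missing samples filled with NaN", path, n - len(times))
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    x[idx] = xs
    y[idx] = ys
    time = times[0] + dt * np.arange(n)
    return time, x, y


# ---------------------------------------------------------------------------
# filtering and differentiation
# ---------------------------------------------------------------------------


def filter_and_differentiate(
    trace: EyeTrace, cutoff_hz: float = 30.0, order: int = 2
) -> EyeTrace:
    """Low-pass filter positions and differentiate to velocity.

    A zero-phase (forward-backward) Butterworth filter of the given order
    and cutoff is applied to each position axis; velocity is the central
    difference scaled by the sample rate (one-sided at the endpoints), in
    deg/s.  Samples missing in the input stay missing in the velocity.
    """
    n = len(trace)
    if n < 50:
        raise UnusableTraceError(f"trace has {n} samples; at least 50 required for filtering")
    out = trace.copy()
    dt = 1.0 / trace.sample_rate
    b, a = butter(order, cutoff_hz / (trace.sample_rate / 2.0), btype="low")
    missing = np.isnan(trace.x) | np.isnan(trace.y)
    for axis in ("x", "y"):
        pos = getattr(trace, axis).copy()
        if missing.any():
            # interpolate across gaps so the acausal filter stays defined,
            # then re-blank the gap samples in the velocity below
            valid = ~np.isnan(pos)
            if valid.sum() < 2:
                raise UnusableTraceError("trace is almost entirely missing")
            pos = np.interp(trace.time, trace.time[valid], pos[valid])
        filt = filtfilt(b, a, pos)
        vel = np.gradient(filt, dt)
        vel[missing] = np.nan
        setattr(out, axis, filt)
        setattr(out, "v" + axis, vel)
    return out


# ---------------------------------------------------------------------------
# saccade detection
# ---------------------------------------------------------------------------


def _robust_sigma(values: np.ndarray, floor: float) -> float:
    """Median-absolute-deviation spread estimate with a noise floor."""
    v = values[~np.isnan(values)]
    if len(v) == 0:
        return floor
    med = np.median(v)
    return max(1.4826 * np.median(np.abs(v - med)), floor)


def detect_saccades(
    trace: EyeTrace,
    abs_threshold: float = 30.0,
    rel_lambda: float = 5.0,
    min_duration: float = 0.006,
    merge_gap: float = 0.020,
    pad: float = 0.005,
    smooth_window: float = 0.05,
    min_sigma: float = 0.3,
) -> list[SaccadeInterval]:
    """Detect saccades by a joint absolute + relative velocity criterion.

    A sample is flagged when either (a) its 2-D speed exceeds
    ``abs_threshold`` (30 deg/s, the EyeLink default), or (b) it exceeds a
    median-based relative ellipse threshold: per axis, the residual after
    subtracting a running-median smooth-pursuit component must stay within
    ``rel_lambda`` robust spreads.  Contiguous runs of at least
    ``min_duration`` become intervals; intervals closer than ``merge_gap``
    are merged and every interval is padded by ``pad`` on each side.

    The running-median subtraction adapts the classic fixation-based
    relative criterion to pursuit traces, where raw velocity is legitimately
    far from zero; ``min_sigma`` keeps the relative threshold from
    collapsing on noise-free traces.
    """
    if not trace.has_velocity:
        raise ValueError("velocity not computed; run filter_and_differentiate first")
    vx, vy = trace.vx, trace.vy
    if np.all(np.isnan(vx)):
        log.warning("all-missing velocity; no saccades detectable")
        return []
    fs = trace.sample_rate
    speed = np.hypot(vx, vy)
    abs_mask = speed > abs_threshold

    size = max(3, int(round(smooth_window * fs)) | 1)  # odd window
    rel_masks = []
    resids = []
    for v in (vx, vy):
        filled = np.where(np.isnan(v), 0.0, v)
        smooth = median_filter(filled, size=size, mode="nearest")
        resid = v - smooth
        sigma = _robust_sigma(resid, min_sigma)
        rel_masks.append((resid / (rel_lambda * sigma)) ** 2)
        resids.append(resid)
    rel_mask = (rel_masks[0] + rel_masks[1]) > 1.0
    rel_mask &= ~np.isnan(vx) & ~np.isnan(vy)

    flagged = abs_mask | rel_mask
    flagged = np.where(np.isnan(speed), False, flagged)

    min_len = max(1, int(round(min_duration * fs)))
    runs = _runs(flagged)
    runs = [(s, e) for s, e in runs if e - s >= min_len]
    if not runs:
        return []

    # annotate rule before merging
    annotated = []
    for s, e in runs:
        if abs_mask[s:e].any() and rel_mask[s:e].any():
            rule = "merged"
        elif abs_mask[s:e].any():
            rule = "absolute"
        else:
            rule = "relative"
        annotated.append((s, e, rule))

    gap_len = int(round(merge_gap * fs))
    merged: list[tuple[int, int, str]] = [annotated[0]]
    for s, e, rule in annotated[1:]:
        ps, pe, prule = merged[-1]
        if s - pe < gap_len:
            merged[-1] = (ps, e, prule if prule == rule else "merged")
        else:
            merged.append((s, e, rule))

    pad_len = int(round(pad * fs))
    n = len(trace)
    intervals = []
    for s, e, rule in merged:
        s = max(0, s - pad_len)
        e = min(n, e + pad_len)
        peak = np.nanmax(speed[s:e])
        intervals.append(
            SaccadeInterval(
                start=float(trace.time[s]),
                end=float(trace.time[e - 1]),
                peak_velocity=float(peak),
                detection_rule=rule,
            )
        )
    return intervals


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open (start, end)."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


# ---------------------------------------------------------------------------
# desaccading and trial QC
# ---------------------------------------------------------------------------


def desaccade_and_qc(
    trace: EyeTrace,
    intervals: list[SaccadeInterval],
    experiment_profile: str,
) -> tuple[EyeTrace, QCReport]:
    """Blank velocity inside saccadic intervals and apply exclusion rules.

    Velocity samples within each interval are set to NaN (positions are kept
    for reference).  The QC report computes the missing-data fraction within
    the profile's onset window and over the whole trial; a trial is excluded
    when either fraction strictly exceeds the profile's cap.  Denominators
    are the number of samples *expected* in the window at the nominal
    sampling rate, so truncated recordings count as missing.
    """
    if experiment_profile not in QC_PROFILES:
        raise ConfigurationError(
            f"unknown QC profile {experiment_profile!r}; valid: {sorted(QC_PROFILES)}"
        )
    if not trace.has_velocity:
        raise ValueError("velocity not computed; run filter_and_differentiate first")
    profile = QC_PROFILES[experiment_profile]
    out = trace.copy()
    for iv in intervals:
        mask = (out.time >= iv.start) & (out.time <= iv.end)
        out.vx[mask] = np.nan
        out.vy[mask] = np.nan

    missing = np.isnan(out.vx) | np.isnan(out.vy)
    w0, w1 = profile["window"]
    fs = trace.sample_rate
    n_expected = int(round((w1 - w0) * fs)) + 1
    in_window = (out.time >= w0) & (out.time <= w1)
    n_present = int(np.sum(~missing[in_window]))
    window_missing = 1.0 - n_present / n_expected
    window_missing = min(max(window_missing, 0.0), 1.0)
    overall_missing = float(np.mean(missing))

    excluded, reason = False, ""
    if window_missing > profile["window_max"]:
        excluded = True
        reason = f"onset-window missing > {profile['window_max']:.0%}"
    elif overall_missing > profile["overall_max"]:
        excluded = True
        reason = f"overall missing > {profile['overall_max']:.0%}"
    report = QCReport(
        onset_window_missing=window_missing,
        overall_missing=overall_missing,
        excluded=excluded,
        reason=reason,
    )
    return out, report
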