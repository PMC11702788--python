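"""Temporal-window-of-integration (TWI) inference for accelerating targets.

The hypothesis: the anticipatory drive for a predictably accelerating
target is set not by its instantaneous onset speed but by the mean target
speed over a finite window [0, TWI_end] after motion onset.  The chain:

1. Regress trial-level aSPv on target speed across the constant-speed
   conditions, pooling participants: ``aSPv = slope * Tk + intercept``.
2. Invert the regression for each accelerating condition i to get the
   target speed estimate ``TSE_i = (aSPv_i - intercept) / slope`` -- the
   constant speed that would have produced the observed group-mean aSPv.
3. Equate TSE_i with the mean of ``v0 + a*t`` over [0, TWI_end]
   (closed form ``v0 + a*TWI_end/2``) and solve:
   ``TWI_end = (2/a) * ((aSPv_i - intercept)/slope - v0)``.
4. Bootstrap the whole chain (default n = 1000), resampling trials with
   replacement within every condition, to get a distribution and
   percentile 95% CI per accelerating condition.

Negative or longer-than-motion TWI_end values are retained (they are part
of the evidence about the model's adequacy) and merely flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .synth import mean_target_speed

__all__ = [
    "SpeedRegression",
    "TWIEstimate",
    "fit_speed_regression",
    "estimate_tse",
    "twi_end",
    "bootstrap_twi",
    "mean_target_speed",
]


@dataclass(frozen=True)
class SpeedRegression:
    """Group-level linear relation between aSPv and constant target speed."""

    slope: float      # (deg/s of aSPv) per (deg/s of target speed)
    intercept: float  # deg/s
    r2: float
    n: int


@dataclass
class TWIEstimate:
    """Bootstrap TWI_end summary for one accelerating condition."""

    condition: str
    aspv_mean: float
    tse: float
    twi_end: float
    ci: tuple[float, float]
    distribution: np.ndarray
    n_boot: int
    n_missing: int
    implausible: bool  # point estimate outside [0, motion duration]


def fit_speed_regression(records: pd.DataFrame, speed_col: str = "v0") -> SpeedRegression:
    """OLS of trial-level aSPv on target speed, pooled across participants.

    ``records`` must contain constant-speed trials only.  Raises on fewer
    than two distinct speeds; warns when the slope is non-positive (the
    downstream inversion is then ill-posed).
    """
    x = records[speed_col].to_numpy(dtype=float)
    y = records["aSPv"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("speed regression needs at least two distinct target speeds")
    fit = linregress(x, y)
    if fit.slope <= 0:
        warnings.warn(
            f"non-positive aSPv-vs-speed slope ({fit.slope:.3g}); TSE inversion is ill-posed"
        )
    return SpeedRegression(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue**2), n=len(x),
    )


def estimate_tse(aspv: float, reg: SpeedRegression) -> float:
    """Target speed estimate: invert the aSPv-vs-speed regression."""
    if reg.slope == 0:
        raise ZeroDivisionError("speed regression slope is zero; TSE undefined")
    return (aspv - reg.intercept) / reg.slope


def twi_end(aspv: float, reg: SpeedRegression, v0: float, accel: float) -> float:
    """End of the temporal window of integration, in seconds.

    Solves ``(aSPv - intercept)/slope = mean of (v0 + a t) over [0, T]``
    for T, giving ``T = (2/a) * (TSE - v0)``.  The value may legitimately
    be negative (reported as-is); constant-speed conditions (a = 0) leave
    T undefined and raise.
    """
    if accel == 0:
        raise ValueError("TWI_end is undefined for constant-speed conditions (a = 0)")
    tse = estimate_tse(aspv, reg)
    return (2.0 / accel) * (tse - v0)


def bootstrap_twi(
    const_records: pd.DataFrame,
    accel_records: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    unit: str = "trial",
    duration: float = 0.5,
) -> list[TWIEstimate]:
    """Bootstrap the full regression-inversion chain per accelerating condition.

    ``const_records``: trial-level aSPv for the constant-speed conditions
    (columns condition, v0, aSPv); ``accel_records``: same for the
    accelerating/decelerating conditions (plus accel).  ``unit="trial"``
    resamples trials with replacement within every condition, pooled
    across participants, matching the pooled group-level regression;
    ``unit="participant"`` resamples whole participants (cluster
    bootstrap).  Replicates with a non-positive regression slope are
    recorded as missing; more than 10% such replicates triggers a warning.
    """
    if unit not in ("trial", "participant"):
        raise ValueError("unit must be 'trial' or 'participant'")
    rng = np.random.default_rng(seed)

    accel_conds = (
        accel_records.groupby("condition")
        .agg(v0=("v0", "first"), accel=("accel", "first"), aspv_mean=("aSPv", "mean"))
        .reset_index()
    )
    reg0 = fit_speed_regression(const_records)

    if unit == "trial":
        slopes, intercepts = _trial_bootstrap_regression(const_records, n_boot, rng)
        accel_means = {
            row.condition: _trial_bootstrap_means(
                accel_records.loc[accel_records["condition"] == row.condition, "aSPv"].to_numpy(),
                n_boot, rng,
            )
            for row in accel_conds.itertuples()
        }
    else:
        slopes, intercepts, accel_means = _participant_bootstrap(
            const_records, accel_records, accel_conds, n_boot, rng
        )

    bad = slopes <= 0
    n_missing = int(bad.sum())
    if n_missing > 0.1 * n_boot:
        warnings.warn(
            f"{n_missing}/{n_boot} bootstrap replicates had non-positive slope"
        )

    estimates = []
    for row in accel_conds.itertuples():
        means = accel_means[row.condition]
        dist = (2.0 / row.accel) * ((means - intercepts) / slopes - row.v0)
        dist = np.where(bad, np.nan, dist)
        valid = dist[~np.isnan(dist)]
        point = twi_end(row.aspv_mean, reg0, row.v0, row.accel)
        ci = (
            (float(np.percentile(valid, 2.5)), float(np.percentile(valid, 97.5)))
            if len(valid)
            else (np.nan, np.nan)
        )
        estimates.append(
            TWIEstimate(
                condition=row.condition,
                aspv_mean=float(row.aspv_mean),
                tse=estimate_tse(row.aspv_mean, reg0),
                twi_end=float(point),
                ci=ci,
                distribution=dist,
                n_boot=n_boot,
                n_missing=n_missing,
                implausible=not (0.0 <= point <= duration),
            )
        )
    return estimates


def _trial_bootstrap_regression(const_records, n_boot, rng):
    """Vectorized within-condition trial resampling + pooled OLS refit.

    Within each constant condition all trials share the same regressor
    value, so per-replicate sums over resampled responses are enough to
    rebuild the pooled slope/intercept in closed form.
    """
    groups = [
        (float(v0), grp["aSPv"].to_numpy(dtype=float))
        for v0, grp in const_records.groupby("v0")
    ]
    n_total = sum(len(y) for _, y in groups)
    sx = sum(v0 * len(y) for v0, y in groups)
    sxx = sum(v0 * v0 * len(y) for v0, y in groups)
    sy = np.zeros(n_boot)
    sxy = np.zeros(n_boot)
    for v0, y in groups:
        idx = rng.integers(0, len(y), size=(n_boot, len(y)))
        ysum = y[idx].sum(axis=1)
        sy += ysum
        sxy += v0 * ysum
    denom = n_total * sxx - sx * sx
    slopes = (n_total * sxy - sx * sy) / denom
    intercepts = (sy - slopes * sx) / n_total
    return slopes, intercepts


def _trial_bootstrap_means(values: np.ndarray, n_boot: int, rng) -> np.ndarray:
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    return values[idx].mean(axis=1)


def _participant_bootstrap(const_records, accel_records, accel_conds, n_boot, rng):
    participants = np.array(sorted(const_records["participant"].unique()))
    const_by_p = {p: g for p, g in const_records.groupby("participant")}
    accel_by_pc = {
        (p, c): g["aSPv"].to_numpy()
        for (p, c), g in accel_records.groupby(["participant", "condition"])
    }
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    accel_means = {row.condition: np.empty(n_boot) for row in accel_conds.itertuples()}
    for b in range(n_boot):
        chosen = rng.choice(participants, size=len(participants), replace=True)
        const = pd.concat([const_by_p[p] for p in chosen], ignore_index=True)
        x = const["v0"].to_numpy(dtype=float)
        y = const["aSPv"].to_numpy(dtype=float)
        xm, ym = x.mean(), y.mean()
        varx = np.mean((x - xm) ** 2)
        slope = np.mean((x - xm) * (y - ym)) / varx if varx > 0 else np.nan
        slopes[b] = slope
        intercepts[b] = ym - slope * xm
        for row in accel_conds.itertuples():
            vals = np.concatenate(
                [accel_by_pc.get((p, row.condition), np.empty(0)) for p in chosen]
            )
            accel_means[row.condition][b] = vals.mean() if len(vals) else np.nan
    return slopes, intercepts, accel_means


def twi_table(estimates: list[TWIEstimate]) -> pd.DataFrame:
    """Flatten TWI estimates to the tab-separated report layout."""
    return pd.DataFrame(
        [
            {
                "condition": e.condition, "aspv_mean": e.aspv_mean, "tse": e.tse,
                "twi_end": e.twi_end, "ci_low": e.ci[0], "ci_high": e.ci[1],
                "n_boot": e.n_boot, "n_missing": e.n_missing,
                "implausible": e.implausible,
            }
            for e in estimates
        ]
    )
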