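"""Hierarchical regression analyses of anticipatory pursuit velocity.

Four analyses, all with participants as a random effect:

* probability scaling: ``aSPv ~ 1 + P`` with random intercept and
  probability slope per participant (plus an axis main effect and
  axis-by-probability interaction for oblique-motion experiments),
* trial history: ``aSPv ~ 1 + P * TvN1`` adding the previous trial's
  speed class (low vs high, reference = high) and its interaction with
  the block probability,
* kinematics: ``aSPv ~ 1 + v0 * accel`` (numeric coding, raw units) with
  random v0 and accel slopes, compared against the v0-only model through
  a BIC-based Bayes factor,
* categorical contrasts: ``aSPv ~ 1 + Tk`` with all pairwise condition
  contrasts, Benjamini-Hochberg adjusted.

Estimation is by maximum likelihood (not REML) so nested-model BIC
comparisons are coherent.  Where the maximal random-effects structure
fails to converge, a deterministic fallback ladder is walked: correlated
random intercept + slopes, then uncorrelated variance components, then
random intercept only, then ordinary regression with participant-clustered
standard errors.  The ladder never changes the fixed-effect design matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DesignCoverageError

ALPHA = 0.01  # significance criterion used in reports (configurable per call)


@dataclass
class HierarchicalFitSummary:
    """Fixed-effect table, random-effect variances, and fit metadata."""

    params: pd.DataFrame  # index: effect; columns: estimate, ci_low, ci_high, p
    random_variances: dict
    formula: str
    n_obs: int
    converged: bool
    ladder_rung: str
    bic: float = np.nan
    llf: float = np.nan
    result: object = field(default=None, repr=False)

    def beta(self, name: str) -> float:
        return float(self.params.loc[name, "estimate"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.params.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, name: str) -> float:
        return float(self.params.loc[name, "p"])


# ---------------------------------------------------------------------------
# analysis-table preparation
# ---------------------------------------------------------------------------


def prepare_analysis_table(
    fits: pd.DataFrame,
    metadata: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    n_warmup: int = 10,
    response: str = "aspv",
) -> pd.DataFrame:
    """Join fits with trial metadata and apply the retention rules.

    Drops QC-excluded and flagged trials and the first ``n_warmup`` trials
    of each block (10 by default; 50 for the stricter control analysis),
    which removes the transient while participants learn the block's
    statistics.  The previous-trial speed class is taken from the
    *sequence position* (trial N-1 as presented), not from whether that
    trial survived retention, so it must already be present in the
    metadata (as produced by the simulator) or is derived here from the
    full, unfiltered sequence.
    """
    key = ["participant", "block", "trial"]
    meta = metadata.copy()
    if "prev_speed_class" not in meta.columns:
        meta = meta.sort_values(key)
        prev_ref = meta.groupby(["participant", "block"])["is_reference"].shift(1)
        meta["prev_speed_class"] = np.where(
            prev_ref.isna(), "none", np.where(prev_ref.astype("boolean").fillna(False), "high", "low")
        )
    merged = meta.merge(fits, on=key, how="left", validate="one_to_one", indicator=True)
    orphans = fits.merge(meta[key], on=key, how="left", indicator=True)
    orphans = orphans[orphans["_merge"] == "left_only"]
    if len(orphans):
        raise ValueError(
            f"{len(orphans)} fitted trials have no metadata, e.g. "
            f"{orphans[key].head(3).to_dict('records')}"
        )
    merged = merged.drop(columns="_merge")
    if qc is not None:
        merged = merged.merge(qc[key + ["excluded"]], on=key, how="left")
        merged = merged[~merged["excluded"].fillna(False).astype(bool)]
    if "flagged" in merged.columns:
        merged = merged[~merged["flagged"].fillna(False).astype(bool)]
    merged = merged[merged[response].notna()]
    merged = merged[merged["trial"] >= n_warmup]
    out = merged.rename(columns={response: "aSPv"}) if response != "aSPv" else merged
    return out.reset_index(drop=True)


def to_long_axes(records: pd.DataFrame) -> pd.DataFrame:
    """Stack horizontal/vertical aSPv components into long format.

    For oblique-motion experiments each trial contributes one row per
    axis, with an ``axis`` column ("horizontal"/"vertical"), mirroring how
    axis enters the regression as an interaction factor.
    """
    need = {"aspv_x", "aspv_y"}
    if not need.issubset(records.columns):
        raise ValueError("records lack aspv_x/aspv_y component columns")
    base = records.drop(columns=[c for c in ("aSPv",) if c in records.columns])
    h = base.assign(aSPv=records["aspv_x"].values, axis="horizontal")
    v = base.assign(aSPv=records["aspv_y"].values, axis="vertical")
    return pd.concat([h, v], ignore_index=True)


# ---------------------------------------------------------------------------
# mixed-model machinery
# ---------------------------------------------------------------------------


def _summarize(result, formula, rung, random_variances) -> HierarchicalFitSummary:
    fe_names = list(result.fe_params.index) if hasattr(result, "fe_params") else list(result.params.index)
    est = result.params[fe_names]
    ci = result.conf_int().loc[fe_names]
    pvals = result.pvalues[fe_names]
    params = pd.DataFrame(
        {"estimate": est, "ci_low": ci[0], "ci_high": ci[1], "p": pvals}
    )
    n_obs = int(result.nobs) if hasattr(result, "nobs") else int(result.model.exog.shape[0])
    return HierarchicalFitSummary(
        params=params,
        random_variances=random_variances,
        formula=formula,
        n_obs=n_obs,
        converged=bool(getattr(result, "converged", True)),
        ladder_rung=rung,
        bic=_bic(result),
        llf=float(result.llf),
        result=result,
    )


def _bic(result) -> float:
    """BIC from the ML log-likelihood; counts every free parameter."""
    model = getattr(result, "model", None)
    if hasattr(result, "fe_params"):
        k_fe = len(result.fe_params)
        k_re = getattr(model, "k_re", 0)
        k_cov = k_re * (k_re + 1) // 2 + getattr(model, "k_vc", 0)
        k = k_fe + k_cov + 1  # + residual variance
    else:
        k = len(result.params) + 1
    n = int(result.nobs)
    return float(k * np.log(n) - 2.0 * result.llf)


def _mixed_ok(result) -> bool:
    if not getattr(result, "converged", False):
        return False
    if not np.isfinite(result.llf):  # degenerate profile (variance collapsed)
        return False
    bse = result.bse_fe if hasattr(result, "bse_fe") else result.bse
    return bool(np.all(np.isfinite(bse)))


def fit_mixed_ladder(
    formula: str,
    data: pd.DataFrame,
    re_terms: list[str],
    groups: str = "participant",
) -> HierarchicalFitSummary:
    """Fit a linear mixed model, walking the random-structure fallback ladder.

    Rungs: (1) correlated random intercept + slopes, (2) uncorrelated
    variance components, (3) random intercept only, (4) OLS with
    participant-clustered standard errors.  The first rung that converges
    with finite standard errors wins; the rung name is recorded in the
    summary.  A single-participant table skips straight to plain OLS.
    """
    if data[groups].nunique() < 2:
        warnings.warn("single participant: falling back to ordinary regression")
        result = smf.ols(formula, data=data).fit()
        return _summarize(result, formula, "ols_single_participant", {})

    rungs: list[tuple[str, dict]] = []
    if re_terms:
        rungs.append(("correlated", {"re_formula": "1 + " + " + ".join(re_terms)}))
        rungs.append(
            ("uncorrelated", {"re_formula": "1", "vc_formula": {t.replace(':', '_'): f"0 + {t}" for t in re_terms}})
        )
    rungs.append(("intercept", {"re_formula": "1"}))

    for rung, kwargs in rungs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=data, groups=data[groups], **kwargs)
                result = model.fit(reml=False, method=["bfgs", "lbfgs", "powell"], maxiter=500)
                ok = _mixed_ok(result)
            if ok:
                rv = {"residual": float(result.scale)}
                cov_re_df = result.cov_re
                for name in getattr(cov_re_df, "index", []):
                    rv[str(name)] = float(cov_re_df.loc[name, name])
                vcomp = getattr(result, "vcomp", None)
                if vcomp is not None and len(vcomp):
                    vc_names = getattr(result.model.exog_vc, "names", None) or [
                        f"vc{i}" for i in range(len(vcomp))
                    ]
                    for name, v in zip(vc_names, vcomp):
                        rv[str(name)] = float(v)
                return _summarize(result, formula, rung, rv)
        except (np.linalg.LinAlgError, ValueError):
            continue
    warnings.warn("mixed models failed to converge; using cluster-robust OLS")
    ols = smf.ols(formula, data=data)
    result = ols.fit(cov_type="cluster", cov_kwds={"groups": data[groups]})
    return _summarize(result, formula, "ols_cluster", {})


# ---------------------------------------------------------------------------
# the four analyses
# ---------------------------------------------------------------------------


def fit_probability_model(
    records: pd.DataFrame,
    prob_col: str = "P",
    include_axis: bool | None = None,
) -> HierarchicalFitSummary:
    """Probability scaling of aSPv with participant random slopes.

    Fixed effects: intercept + block probability of the reference
    (high-speed) condition; when an ``axis`` column with both levels is
    present (oblique motion), an axis main effect and axis x probability
    interaction are added.  Random: intercept and probability slope per
    participant, subject to the fallback ladder.
    """
    if records[prob_col].nunique() < 2:
        raise ValueError("at least two probability levels required (design is rank deficient)")
    use_axis = include_axis
    if use_axis is None:
        use_axis = "axis" in records.columns and records["axis"].nunique() > 1
    formula = f"aSPv ~ {prob_col} * axis" if use_axis else f"aSPv ~ {prob_col}"
    return fit_mixed_ladder(formula, records, re_terms=[prob_col])


def fit_sequence_model(records: pd.DataFrame, prob_col: str = "P") -> HierarchicalFitSummary:
    """Probability x previous-trial-speed model (N-1 history effect).

    Requires ``prev_speed_class`` in {"high", "low"} (first-of-block trials
    carry "none" and must be dropped upstream).  The low class is coded
    against the high-speed reference, so a negative TvN1 coefficient means
    a low-speed predecessor lowers the next trial's anticipation.
    """
    bad = set(records["prev_speed_class"].unique()) - {"high", "low"}
    if bad:
        raise ValueError(f"prev_speed_class must be high/low only; found {sorted(bad)}")
    data = records.copy()
    data["TvN1"] = pd.Categorical(data["prev_speed_class"], categories=["high", "low"])
    formula = f"aSPv ~ {prob_col} * TvN1"
    return fit_mixed_ladder(formula, data, re_terms=[prob_col, "TvN1"])


def history_profile(records: pd.DataFrame, prob_col: str = "P") -> pd.DataFrame:
    """Per-probability deviation of aSPv by previous-trial speed class.

    For each participant, probability level, and predecessor class (high /
    low), computes mean(aSPv | prev, P) - mean(aSPv | P); then aggregates
    across participants with a t-based 95% CI.  Cells with no trials yield
    missing values rather than errors.
    """
    data = records[records["prev_speed_class"].isin(["high", "low"])]
    block_mean = records.groupby(["participant", prob_col])["aSPv"].mean().rename("block_mean")
    cell = (
        data.groupby(["participant", prob_col, "prev_speed_class"], observed=True)["aSPv"]
        .mean()
        .rename("cell_mean")
        .reset_index()
        .merge(block_mean.reset_index(), on=["participant", prob_col])
    )
    cell["delta"] = cell["cell_mean"] - cell["block_mean"]
    rows = []
    for (p_level, prev), grp in cell.groupby([prob_col, "prev_speed_class"], observed=True):
        d = grp["delta"].dropna().values
        n = len(d)
        mean = float(np.mean(d)) if n else np.nan
        if n > 1:
            half = sps.t.ppf(0.975, n - 1) * np.std(d, ddof=1) / np.sqrt(n)
        else:
            half = np.nan
        rows.append(
            {prob_col: p_level, "prev_speed_class": prev, "delta_mean": mean,
             "ci_low": mean - half, "ci_high": mean + half, "n_participants": n}
        )
    return pd.DataFrame(rows)


def bayes_factor_from_bic(bic_reduced: float, bic_full: float) -> float:
    """Bayes factor favoring the full model: exp((BIC_reduced - BIC_full)/2)."""
    return float(np.exp((bic_reduced - bic_full) / 2.0))


def fit_kinematics_model(records: pd.DataFrame) -> dict:
    """Initial-speed x acceleration model and its v0-only comparison.

    Numeric (raw-unit) coding of v0 (deg/s) and accel (deg/s^2).  Returns
    the full and reduced summaries, their BIC difference, and the Bayes
    factor ``exp((BIC_reduced - BIC_full)/2)`` for the full model.  Raises
    when any v0 x accel design cell is missing.
    """
    cells = records.groupby(["v0", "accel"]).size()
    n_v0 = records["v0"].nunique()
    n_ac = records["accel"].nunique()
    if len(cells) < n_v0 * n_ac:
        raise DesignCoverageError(
            f"kinematics design incomplete: {len(cells)} of {n_v0 * n_ac} v0 x accel cells present"
        )
    full = fit_mixed_ladder("aSPv ~ v0 * accel", records, re_terms=["v0", "accel"])
    reduced = fit_mixed_ladder("aSPv ~ v0", records, re_terms=["v0"])
    delta_bic = reduced.bic - full.bic
    return {
        "full": full,
        "reduced": reduced,
        "delta_bic": float(delta_bic),
        "bayes_factor": bayes_factor_from_bic(reduced.bic, full.bic),
    }


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Classic step-up FDR-adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def pairwise_contrasts(records: pd.DataFrame, condition_col: str = "condition") -> pd.DataFrame:
    """All pairwise condition contrasts from the categorical mixed model.

    Estimated marginal means come from the no-intercept categorical fit
    ``aSPv ~ 0 + C(condition)`` with a participant random intercept (the
    full random-slope structure over nine categorical levels is outside
    what the ladder can stabilize at package scale, so the intercept rung
    is used directly).  Differences are z-tested and Benjamini-Hochberg
    adjusted across the full family of pairs.
    """
    levels = sorted(records[condition_col].unique())
    if len(levels) < 2:
        raise ValueError("at least two condition levels required")
    formula = f"aSPv ~ 0 + C({condition_col})"
    summary = fit_mixed_ladder(formula, records, re_terms=[])
    result = summary.result
    fe_names = list(result.fe_params.index) if hasattr(result, "fe_params") else list(result.params.index)
    cov = pd.DataFrame(np.asarray(result.cov_params()), index=list(result.params.index),
                       columns=list(result.params.index)).loc[fe_names, fe_names]

    def name_of(level):
        return f"C({condition_col})[{level}]"

    rows = []
    for a, b in itertools.combinations(levels, 2):
        na, nb = name_of(a), name_of(b)
        diff = float(result.params[na] - result.params[nb])
        se = float(np.sqrt(cov.loc[na, na] + cov.loc[nb, nb] - 2.0 * cov.loc[na, nb]))
        z = diff / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"cond_a": a, "cond_b": b, "estimate": diff, "se": se, "z": z, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p"].values)
    table.attrs["model"] = summary
    return table
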