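"""Log-reliability statistics over reconciled encounter records.

Three analyses quantify how trustworthy tag-side logging is:

* :func:`reciprocity_stats` -- for dyadic records, the absolute between-side
  differences in max/min/mean RSSI and duration, with paired tests (a
  Table-1-style report of reciprocal agreement);
* :func:`fit_dyad_probability` -- logistic model of whether an encounter was
  recorded by both tags or only one; higher minimum RSSI (closer minimum
  distance) and longer duration raise the odds of a dyadic record;
* :func:`match_broken_logs` / :func:`broken_vs_unbroken_summary` -- pairs
  each broken record with an unbroken record of similar duration and
  compares RSSI levels and spread between the groups (broken records sit at
  lower RSSI -- farther apart -- not at larger within-log variation).
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "reciprocity_stats",
    "fit_dyad_probability",
    "match_broken_logs",
    "broken_vs_unbroken_summary",
]

_MEASURES = {
    "max_rssi": ("max_rssi_a", "max_rssi_b"),
    "min_rssi": ("min_rssi_a", "min_rssi_b"),
    "mean_rssi": ("mean_rssi_a", "mean_rssi_b"),
    "duration": (None, None),  # computed from side intervals
}


def _side_values(dyads: pd.DataFrame, measure: str) -> Tuple[np.ndarray, np.ndarray]:
    if measure == "duration":
        a = (dyads["end_a"] - dyads["start_a"]).to_numpy(dtype=float)
        b = (dyads["end_b"] - dyads["start_b"]).to_numpy(dtype=float)
    else:
        ca, cb = _MEASURES[measure]
        a = dyads[ca].to_numpy(dtype=float)
        b = dyads[cb].to_numpy(dtype=float)
    return a, b


def reciprocity_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Between-side agreement of dyadic records, one row per measure.

    Columns: ``mean_abs_diff``, ``sd_abs_diff``, ``min_abs_diff``,
    ``max_abs_diff``, ``t`` and ``p`` (paired test on the signed a-b
    differences), ``n``.  Values are invariant to swapping the side labels.
    """
    dyads = records.loc[records["status"] == "dyadic"]
    if len(dyads) < 2:
        warnings.warn("fewer than 2 dyadic records; reciprocity table is empty")
        return pd.DataFrame(
            columns=["mean_abs_diff", "sd_abs_diff", "min_abs_diff",
                     "max_abs_diff", "t", "p", "n"]
        )
    rows = {}
    for measure in _MEASURES:
        a, b = _side_values(dyads, measure)
        diff = a - b
        absd = np.abs(diff)
        if np.allclose(diff, diff[0]):
            t, p = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(a, b)
        rows[measure] = (
            absd.mean(), absd.std(ddof=1), absd.min(), absd.max(),
            float(t), float(p), len(absd),
        )
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["mean_abs_diff", "sd_abs_diff", "min_abs_diff",
                 "max_abs_diff", "t", "p", "n"],
    )


def fit_dyad_probability(
    records: pd.DataFrame,
    max_duration_s: int = 300,
    time_window: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Logistic model of dyadic (vs single) recording.

    Predictors are the combined-record maximum, minimum and mean RSSI and
    the encounter duration; the sample is restricted to encounters of at
    most ``max_duration_s`` (the firmware cap) and optionally to a time
    window (e.g. the early hours when downloads were guaranteed).  Returns
    a coefficient table with Wald z statistics; near-constant predictors
    are excluded with a warning.  Complete separation triggers a ridge-
    penalized fallback, flagged in the ``note`` attribute.
    """
    import statsmodels.api as sm

    df = records.loc[records["duration"] <= max_duration_s].copy()
    if time_window is not None:
        df = df.loc[(df["start"] >= time_window[0]) & (df["end"] <= time_window[1])]
    if df["status"].nunique() < 2:
        raise ValueError("need both dyadic and single records to fit the model")
    y = (df["status"] == "dyadic").astype(float)
    predictors = {
        "max_rssi": df["max_rssi"].astype(float),
        "min_rssi": df["min_rssi"].astype(float),
        "mean_rssi": df["mean_rssi"].astype(float),
        "duration": df["duration"].astype(float),
    }
    X = {}
    for name, col in predictors.items():
        if col.std(ddof=0) < 1e-12:
            warnings.warn(f"predictor '{name}' is constant; excluded from the model")
            continue
        X[name] = col
    X = pd.DataFrame(X)
    Xc = sm.add_constant(X, has_constant="add")
    note = "ml"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.bse)):
                raise np.linalg.LinAlgError("non-finite standard errors")
        except Exception:
            # separation or ill-conditioning: small ridge penalty
            fit = sm.Logit(y, Xc).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0)
            note = "ridge-penalized (separation fallback)"
    params = np.asarray(fit.params, dtype=float)
    try:
        bse = np.asarray(fit.bse, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
        p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"coef": params, "se": bse, "wald_z": z, "p": p}, index=Xc.columns)
    out.attrs["note"] = note
    out.attrs["n"] = len(df)
    return out


def match_broken_logs(records: pd.DataFrame) -> dict:
    """Greedy nearest-duration matching of broken to unbroken dyadic records.

    Broken records (in start order) each claim the still-available unbroken
    record of closest duration, ties going to the earlier start.  Returns
    the matched table, unmatched broken records and the mean +/- sd of the
    paired absolute duration differences.
    """
    dyads = records.loc[records["status"] == "dyadic"]
    broken = dyads.loc[dyads["broken"]].sort_values("start", kind="mergesort")
    unbroken = dyads.loc[~dyads["broken"]].sort_values("start", kind="mergesort")
    if len(broken) == 0 or len(unbroken) == 0:
        raise ValueError("need at least one broken and one unbroken dyadic record")
    avail = unbroken[["start", "duration"]].copy()
    pairs = []
    unmatched = []
    for r in broken.itertuples():
        if len(avail) == 0:
            unmatched.append(r.Index)
            continue
        delta = (avail["duration"] - r.duration).abs()
        best = delta.min()
        cand = avail.loc[delta == best].sort_values("start", kind="mergesort")
        pick = cand.index[0]
        pairs.append((r.Index, pick, float(best)))
        avail = avail.drop(index=pick)
    matched = pd.DataFrame(pairs, columns=["broken_idx", "unbroken_idx", "abs_duration_diff"])
    dd = matched["abs_duration_diff"]
    return {
        "matched": matched,
        "unmatched_broken": unmatched,
        "mean_duration_diff": float(dd.mean()) if len(dd) else np.nan,
        "sd_duration_diff": float(dd.std(ddof=1)) if len(dd) > 1 else np.nan,
        "records": records,
    }


def broken_vs_unbroken_summary(matching: dict) -> pd.DataFrame:
    """Group comparison over the duration-matched broken/unbroken pairs.

    One row per measure (max/min/mean RSSI and the within-record RSSI spread
    max-min): group means, Welch t, p, and Cohen's d.  A single-pulse log
    has spread 0 by definition.
    """
    records = matching["records"]
    matched = matching["matched"]
    if len(matched) < 2:
        raise ValueError("need >= 2 matched pairs for a group comparison")
    b = records.loc[matched["broken_idx"]]
    u = records.loc[matched["unbroken_idx"]]
    rows = []
    for measure in ("max_rssi", "min_rssi", "mean_rssi", "spread"):
        if measure == "spread":
            xb = (b["max_rssi"] - b["min_rssi"]).to_numpy(dtype=float)
            xu = (u["max_rssi"] - u["min_rssi"]).to_numpy(dtype=float)
        else:
            xb = b[measure].to_numpy(dtype=float)
            xu = u[measure].to_numpy(dtype=float)
        if np.allclose(xb, xu[: len(xb)]) and np.allclose(xb.var(), 0) and np.allclose(xu.var(), 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xb, xu, equal_var=False)
        sp = np.sqrt((xb.var(ddof=1) + xu.var(ddof=1)) / 2.0)
        d = (xb.mean() - xu.mean()) / sp if sp > 0 else 0.0
        rows.append((measure, xb.mean(), xu.mean(), float(t), float(p), float(d), len(xb)))
    return pd.DataFrame(
        rows,
        columns=["measure", "broken_mean", "unbroken_mean", "t", "p", "cohen_d", "n_pairs"],
    ).set_index("measure")
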