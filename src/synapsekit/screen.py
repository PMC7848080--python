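"""Knockout-screen statistics: response normalization, 4PL fits, F tests.

Responses are normalized per the screen convention: the change in
fraction-positive cells over the unstimulated baseline, scaled so the
maximum observed for the reference (CD19-targeted) control equals 100.
Dose-response curves are four-parameter logistic (4PL) fits in log10
concentration; Emax is the fitted response at the highest tested dose, and
whole curves are compared with the extra sum-of-squares F test.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import CurveFit, DoseResponseDataset, FTestResult

HILL_MAX = 10.0


def four_param_logistic(conc_ng_ml, bottom, top, log_ec50, hill):
    """R(c) = Bottom + (Top - Bottom) / (1 + 10**((logEC50 - log10 c) * Hill)).

    Defined by continuity as Bottom at zero concentration (hill > 0).
    """
    c = np.asarray(conc_ng_ml, dtype=float)
    out = np.full(c.shape, float(bottom))
    pos = c > 0
    out[pos] = bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - np.log10(c[pos])) * hill))
    return out if out.shape else float(out)


def normalize_response(frac_pos, frac_baseline, reference_max: float):
    """100 * (frac_pos - frac_baseline) / reference_max.

    ``reference_max`` is the largest baseline-subtracted response of the
    reference control, so the control's own maximum maps to exactly 100.
    """
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    return 100.0 * (np.asarray(frac_pos, dtype=float) - np.asarray(frac_baseline, dtype=float)) / reference_max


def normalize_screen(
    dataset: DoseResponseDataset,
    reference_target: str = "CD19",
) -> pd.DataFrame:
    """Normalize a whole screen table against its reference control.

    Per (target, donor, marker), the zero-dose row is the baseline; the
    reference scale is the maximum mean baseline-subtracted response of
    ``reference_target`` across doses (per marker). Baseline rows are
    consumed by the subtraction and dropped from the output. Returns a table
    (target, donor, marker, conc_ng_ml, response).
    """
    table = dataset.table
    if reference_target not in set(table["target"]):
        raise ValueError(f"reference target {reference_target!r} absent from the table")
    rows = []
    for marker, mgrp in table.groupby("marker"):
        deltas = []
        for (target, donor), grp in mgrp.groupby(["target", "donor"]):
            baseline = float(grp.loc[grp["conc_ng_ml"] == 0, "frac_pos"].iloc[0])
            sub = grp[grp["conc_ng_ml"] > 0]
            deltas.append(
                pd.DataFrame({
                    "target": target, "donor": donor, "marker": marker,
                    "conc_ng_ml": sub["conc_ng_ml"].to_numpy(),
                    "delta": sub["frac_pos"].to_numpy() - baseline,
                })
            )
        deltas = pd.concat(deltas, ignore_index=True)
        ref = deltas[deltas["target"] == reference_target]
        reference_max = float(ref.groupby("conc_ng_ml")["delta"].mean().max())
        if reference_max <= 0:
            raise ValueError("reference control shows no positive response")
        deltas["response"] = 100.0 * deltas["delta"] / reference_max
        rows.append(deltas.drop(columns="delta"))
    return pd.concat(rows, ignore_index=True)


def fit_4pl(concentrations, responses) -> CurveFit:
    """Least-squares 4PL fit of normalized responses against dose.

    Zero concentrations cannot enter the log-domain model and are rejected
    (baselines are consumed by normalization upstream). Constraints:
    Bottom >= 0 on the normalized scale and 0 < Hill <= 10, for
    identifiability with short titrations.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(c <= 0):
        raise ValueError("zero or negative concentrations cannot enter the log-domain fit")
    distinct = np.unique(c)
    if len(distinct) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    logc = np.log10(c)
    if logc.max() - logc.min() < 2.0:
        raise ValueError("concentrations must span at least 2 log10 units")
    if len(c) <= 4:
        raise ValueError("fewer points than parameters")

    p0 = (max(float(r.min()), 0.0), float(r.max()), float(np.median(logc)), 1.0)
    bounds = (
        [0.0, -np.inf, logc.min() - 3.0, 1e-6],
        [np.inf, np.inf, logc.max() + 3.0, HILL_MAX],
    )
    try:
        popt, _ = optimize.curve_fit(
            four_param_logistic, c, r, p0=p0, bounds=bounds, maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt = np.asarray(p0)
        converged = False
    resid = r - four_param_logistic(c, *popt)
    fit = CurveFit(
        bottom=float(popt[0]),
        top=float(popt[1]),
        log_ec50=float(popt[2]),
        hill=float(popt[3]),
        rss=float((resid**2).sum()),
        df=int(len(c) - 4),
        n_points=int(len(c)),
        converged=converged,
    )
    fit._max_conc = float(c.max())
    return fit


def extra_ss_f(rss_shared, rss_separate, df_shared, df_separate) -> FTestResult:
    """F statistic and p-value from shared- and separate-model fit residuals."""
    if df_separate <= 0:
        raise ValueError("separate fits leave no residual degrees of freedom")
    if rss_separate == 0:
        raise ValueError("separate fits are exact; the F statistic is undefined")
    f = max(0.0, ((rss_shared - rss_separate) / (df_shared - df_separate)) / (rss_separate / df_separate))
    p = float(stats.f.sf(f, df_shared - df_separate, df_separate))
    return FTestResult(
        f_statistic=float(f), df_num=int(df_shared - df_separate),
        df_den=int(df_separate), p_value=p,
    )


def ess_f_test(data_a, data_b) -> FTestResult:
    """Extra sum-of-squares F test comparing two whole dose-response curves.

    The null model fits one shared 4PL parameter set to the pooled data; the
    alternative fits each dataset separately (all four parameters free per
    curve). F = ((RSS_shared - RSS_sep) / (df_shared - df_sep)) /
    (RSS_sep / df_sep), with p from the F distribution. Symmetric in its two
    arguments.
    """
    (ca, ra), (cb, rb) = data_a, data_b
    fit_a = fit_4pl(ca, ra)
    fit_b = fit_4pl(cb, rb)
    pooled_c = np.concatenate([np.asarray(ca, float), np.asarray(cb, float)])
    pooled_r = np.concatenate([np.asarray(ra, float), np.asarray(rb, float)])
    shared = fit_4pl(pooled_c, pooled_r)
    rss_sep = fit_a.rss + fit_b.rss
    df_sep = fit_a.df + fit_b.df
    df_shared = len(pooled_c) - 4
    return extra_ss_f(shared.rss, rss_sep, df_shared, df_sep)


def screen_summary(
    normalized: pd.DataFrame,
    reference_target: str = "CD19",
    *,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-target Emax, logEC50, and F-test p against the reference control.

    One row per (target, marker). Raw p-values are reported; Benjamini-
    Hochberg adjusted values are added (column ``p_adj``) only when
    ``bh_correction`` is requested, and are never used for the main columns.
    """
    rows = []
    for marker, mgrp in normalized.groupby("marker"):
        ref = mgrp[mgrp["target"] == reference_target]
        ref_data = (ref["conc_ng_ml"].to_numpy(), ref["response"].to_numpy())
        for target, grp in mgrp.groupby("target"):
            data = (grp["conc_ng_ml"].to_numpy(), grp["response"].to_numpy())
            fit = fit_4pl(*data)
            if target == reference_target:
                f, p = 0.0, 1.0
            else:
                res = ess_f_test(data, ref_data)
                f, p = res.f_statistic, res.p_value
            rows.append((target, marker, fit.emax, fit.log_ec50, f, p, fit.model))
    out = pd.DataFrame(
        rows, columns=["target", "marker", "emax", "log_ec50", "f_statistic", "p_value", "model"]
    )
    if bh_correction:
        out["p_adj"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
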