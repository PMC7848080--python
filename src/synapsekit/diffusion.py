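"""Per-track diffusion-mode classification from the time-averaged MSD.

Each trajectory is summarized by its anomalous exponent alpha (log-log slope
of the time-averaged MSD over short lags), a short-lag diffusion coefficient
D = MSD(tau_1) / (4 tau_1), and the mean frame-to-frame speed. Tracks are
labeled confined (alpha below a low threshold), active (alpha above a high
threshold) or normal otherwise — a transparent MSD-exponent rule with the
standard thresholds 0.7 / 1.3. Displacement pairs spanning detection gaps
are excluded from both the MSD and the mean speed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    MODE_ACTIVE,
    MODE_CONFINED,
    MODE_NORMAL,
    MODES,
    ClassificationResult,
    DegenerateTrackError,
    MSDCurve,
    TrackSet,
    Trajectory,
)

ALPHA_LOW = 0.7
ALPHA_HIGH = 1.3
N_FIT_LAGS = 10
MAX_LAG_FRACTION = 1.0 / 3.0


def msd(traj: Trajectory, max_lag_fraction: float = MAX_LAG_FRACTION) -> MSDCurve:
    """Time-averaged MSD of one track.

    MSD(k dt) averages squared displacements over every gap-free pair of
    frames exactly k apart; a pair whose intermediate frames were not
    detected spans a gap and is excluded. Lags run up to
    ``max_lag_fraction`` of the track's frame span.
    """
    if traj.n_detected < 2:
        raise DegenerateTrackError("track too short for an MSD")
    span = int(traj.frames[-1] - traj.frames[0])
    max_lag = max(1, int(np.floor(span * max_lag_fraction)))
    frames = traj.frames
    index = np.arange(len(frames))
    lags = np.arange(1, max_lag + 1)
    values = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for k in lags:
        has_pair = np.isin(frames + k, frames)
        if not has_pair.any():
            continue
        later = np.searchsorted(frames, frames[has_pair] + k)
        # exclude pairs spanning a detection gap: every intermediate frame
        # must itself be detected (index distance equals the frame lag)
        contiguous = later - index[has_pair] == k
        if contiguous.any():
            d = traj.positions[later[contiguous]] - traj.positions[index[has_pair][contiguous]]
            values[k - 1] = float((d**2).sum(axis=1).mean())
            counts[k - 1] = int(contiguous.sum())
    return MSDCurve(lags_s=lags * traj.dt, msd_um2=values, counts=counts)


def fit_alpha_D(curve: MSDCurve, n_fit_lags: int = N_FIT_LAGS) -> tuple[float, float, dict]:
    """Anomalous exponent and short-lag diffusion coefficient from an MSD.

    alpha is the ordinary least-squares slope of log MSD against log lag over
    the first ``n_fit_lags`` usable lags; D is MSD at the first usable lag
    divided by 4 tau. An all-zero MSD (stationary track) is flagged
    degenerate rather than fit.
    """
    usable = (curve.counts > 0) & (curve.msd_um2 > 0)
    if not usable.any():
        return float("nan"), 0.0, {"degenerate": True, "n_lags": 0, "r_squared": float("nan")}
    first = int(np.flatnonzero(usable)[0])
    tau1 = curve.lags_s[first]
    D = float(curve.msd_um2[first] / (4.0 * tau1))
    idx = np.flatnonzero(usable)[:n_fit_lags]
    if len(idx) < 4:
        raise DegenerateTrackError("fewer than 4 usable MSD lags")
    x = np.log(curve.lags_s[idx])
    y = np.log(curve.msd_um2[idx])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = float(1.0 - (resid**2).sum() / ss_tot) if ss_tot > 0 else 1.0
    return float(slope), D, {"degenerate": False, "n_lags": int(len(idx)), "r_squared": r2}


def mean_speed(traj: Trajectory) -> float:
    """Mean frame-to-frame displacement over dt, gap-spanning pairs excluded."""
    consecutive = np.diff(traj.frames) == 1
    if not consecutive.any():
        return 0.0
    steps = np.diff(traj.positions, axis=0)[consecutive]
    return float(np.hypot(steps[:, 0], steps[:, 1]).mean() / traj.dt)


def classify_track(
    traj: Trajectory,
    *,
    alpha_low: float = ALPHA_LOW,
    alpha_high: float = ALPHA_HIGH,
    n_fit_lags: int = N_FIT_LAGS,
    max_lag_fraction: float = MAX_LAG_FRACTION,
) -> ClassificationResult:
    """Label one track normal, active, or confined by its MSD exponent.

    alpha below ``alpha_low`` is confined/subdiffusive, above ``alpha_high``
    active, otherwise normal; a degenerate (stationary) MSD is classified
    confined and flagged.
    """
    curve = msd(traj, max_lag_fraction=max_lag_fraction)
    alpha, D, diag = fit_alpha_D(curve, n_fit_lags=n_fit_lags)
    if diag["degenerate"]:
        mode = MODE_CONFINED
    elif alpha < alpha_low:
        mode = MODE_CONFINED
    elif alpha > alpha_high:
        mode = MODE_ACTIVE
    else:
        mode = MODE_NORMAL
    return ClassificationResult(
        track_id=traj.track_id,
        mode=mode,
        alpha=alpha,
        D_um2_s=D,
        mean_speed_um_s=mean_speed(traj),
        r_squared=diag["r_squared"],
        n_fit_lags=diag["n_lags"],
        degenerate=diag["degenerate"],
    )


def classify_trackset(trackset: TrackSet, **kwargs) -> pd.DataFrame:
    """Classify every track; returns a table with one row per track."""
    rows = []
    for t in trackset:
        r = classify_track(t, **kwargs)
        rows.append((r.track_id, r.mode, r.alpha, r.D_um2_s, r.mean_speed_um_s,
                     r.r_squared, r.degenerate, t.true_mode))
    return pd.DataFrame(
        rows,
        columns=["track_id", "mode", "alpha", "D_um2_s", "mean_speed_um_s",
                 "r_squared", "degenerate", "true_mode"],
    )


def mode_proportions(labels: pd.DataFrame, cell_column: str | None = None) -> pd.DataFrame:
    """Per-cell fraction of tracks in each diffusion mode.

    ``labels`` needs a ``mode`` column; with no ``cell_column`` the whole
    table is one cell. Fractions per cell cover all three modes and sum to 1.
    """
    if "mode" not in labels.columns:
        raise ValueError("labels table needs a 'mode' column")
    if len(labels) == 0:
        raise ValueError("empty label table")
    df = labels.copy()
    if cell_column is None:
        df["_cell"] = "cell0"
        cell_column = "_cell"
    rows = []
    for cell, grp in df.groupby(cell_column):
        n = len(grp)
        for mode in MODES:
            rows.append((cell, mode, float((grp["mode"] == mode).sum()) / n))
    return pd.DataFrame(rows, columns=["cell", "mode", "fraction"])
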