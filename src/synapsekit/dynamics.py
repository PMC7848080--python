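"""Relating trajectories to the SMAC partition.

Covers region occupancy ("a minimum of three frames" in a region, counted as
total detected frames by default), normalized distance-to-center series with
their regression slopes (the starting distance of each track is given the
value one), and run-collapsed transition summaries between regions.
"""
from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .types import (
    REGION_NAMES,
    SMAC_REGIONS,
    DegenerateTrackError,
    RegionPartition,
    RegionSequence,
    TrackSet,
    Trajectory,
    TransitionSummary,
)

MIN_OCCUPANCY_FRAMES = 3
MIN_START_DISTANCE_UM = 0.1


def assign_regions(
    traj: Trajectory,
    partition: RegionPartition,
    mode: str | None = None,
) -> RegionSequence:
    """Region label at the pixel containing each detected position.

    Positions outside the image (or in no labeled pixel) map to ``outside``;
    a position exactly on a pixel boundary belongs to the pixel with the
    floor index, so the lookup is deterministic.
    """
    if partition.pixel_size is None or partition.pixel_size <= 0:
        raise ValueError("partition lacks a valid pixel size; units cannot be matched")
    labels = np.asarray(
        [partition.region_at(x, y) for x, y in traj.positions], dtype=int
    )
    return RegionSequence(track_id=traj.track_id, frames=traj.frames.copy(), labels=labels, mode=mode)


def occupancy(
    trackset: TrackSet,
    partition: RegionPartition,
    *,
    min_frames: int = MIN_OCCUPANCY_FRAMES,
    consecutive: bool = False,
) -> dict[str, float]:
    """Fraction of tracks that spend at least ``min_frames`` in each region.

    Frames in a region are totaled across the whole track by default;
    ``consecutive`` instead requires a single run of that length. A track can
    satisfy the criterion in several regions, so the fractions need not sum
    to one.
    """
    if len(trackset) == 0:
        raise ValueError("empty TrackSet")
    counts = {code: 0 for code in SMAC_REGIONS}
    for traj in trackset:
        seq = assign_regions(traj, partition)
        for code in SMAC_REGIONS:
            hit = seq.labels == code
            if consecutive:
                best, run = 0, 0
                for h in hit:
                    run = run + 1 if h else 0
                    best = max(best, run)
                qualifies = best >= min_frames
            else:
                qualifies = int(hit.sum()) >= min_frames
            counts[code] += int(qualifies)
    n = len(trackset)
    return {REGION_NAMES[code]: counts[code] / n for code in SMAC_REGIONS}


def normalized_distance(
    traj: Trajectory,
    center: tuple[float, float],
    *,
    min_start_distance: float = MIN_START_DISTANCE_UM,
) -> tuple[np.ndarray, float]:
    """Distance-to-center series scaled so the starting distance is one.

    Returns the series and the ordinary least-squares slope of the series
    against time (units 1/s). Tracks starting within ``min_start_distance``
    of the center are excluded (DegenerateTrackError) since the
    normalization divides by the starting distance.
    """
    d = np.hypot(traj.positions[:, 0] - center[0], traj.positions[:, 1] - center[1])
    if d[0] <= min_start_distance:
        raise DegenerateTrackError(
            f"track {traj.track_id} starts within {min_start_distance} um of the center"
        )
    series = d / d[0]
    t = (traj.frames - traj.frames[0]) * traj.dt
    slope = float(np.polyfit(t, series, 1)[0]) if len(t) > 1 else float("nan")
    return series, slope


def distance_slopes(
    trackset: TrackSet,
    center: tuple[float, float],
    *,
    min_start_distance: float = MIN_START_DISTANCE_UM,
) -> pd.DataFrame:
    """Per-track normalized-distance slopes plus one pooled regression.

    Returns a table (track_id, slope, excluded); the pooled OLS fit over all
    included series is attached as ``df.attrs['pooled_slope']``.
    """
    rows, all_t, all_d = [], [], []
    for traj in trackset:
        try:
            series, slope = normalized_distance(
                traj, center, min_start_distance=min_start_distance
            )
        except DegenerateTrackError:
            rows.append((traj.track_id, float("nan"), True))
            continue
        rows.append((traj.track_id, slope, False))
        all_t.append((traj.frames - traj.frames[0]) * traj.dt)
        all_d.append(series)
    df = pd.DataFrame(rows, columns=["track_id", "slope", "excluded"])
    if all_t:
        t = np.concatenate(all_t)
        d = np.concatenate(all_d)
        df.attrs["pooled_slope"] = float(np.polyfit(t, d, 1)[0])
    else:
        df.attrs["pooled_slope"] = float("nan")
    return df


def collapse_runs(labels: np.ndarray) -> list[int]:
    """Collapse a label sequence to its runs of identical consecutive labels."""
    runs = []
    for lab in labels:
        if not runs or runs[-1] != int(lab):
            runs.append(int(lab))
    return runs


def transitions(sequences: list[RegionSequence]) -> TransitionSummary:
    """Starting-region and between-region transition counts, per mode.

    Each sequence is collapsed to runs of identical labels; every boundary
    between two distinct consecutive runs counts one transition, and the
    first run's label is the starting region. Gap frames carry no label, so
    a gap breaks a run only when the post-gap label differs.
    """
    if not sequences:
        raise ValueError("transitions requires at least one sequence")
    starts: dict = {}
    trans: dict = {}
    for seq in sequences:
        runs = collapse_runs(seq.labels)
        starts.setdefault(seq.mode, Counter())[runs[0]] += 1
        counter = trans.setdefault(seq.mode, Counter())
        for a, b in zip(runs[:-1], runs[1:]):
            counter[(a, b)] += 1
    return TransitionSummary(
        starts={m: dict(c) for m, c in starts.items()},
        transitions={m: dict(c) for m, c in trans.items()},
    )
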