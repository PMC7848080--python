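"""Synthetic microscopy inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here: concentric
synapse geometries, multi-channel snapshots, Gaussian-PSF spot movies,
single-particle trajectories under three diffusion modes, and superantigen
dose-response screen tables. The defaults mirror typical TIRF acquisition of
T cell synapses on supported lipid bilayers: 0.1 um pixels, 50 ms frames,
movies capped at 300 frames (15 s).

Every operation takes one explicit integer ``seed``; identical seeds and
parameters give bit-identical outputs. No global RNG state is used.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import erf

from .types import (
    MODE_ACTIVE,
    MODE_CONFINED,
    MODE_NORMAL,
    MODES,
    DoseResponseDataset,
    Movie,
    SynapseGeometry,
    SynapseImage,
    TrackSet,
    Trajectory,
)

# Per-mode defaults: D in um^2/s, drift speed v in um/s, corral radius R in um.
DEFAULT_MODE_PARAMS = {
    MODE_NORMAL: {"D": 0.1},
    MODE_ACTIVE: {"D": 0.1, "v": 0.5},
    MODE_CONFINED: {"D": 0.1, "corral_radius": 0.15},
}
DEFAULT_DT = 0.05  # s/frame
DEFAULT_TRACK_FRAMES = 300  # 15 s at 50 ms/frame


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trajectory(
    mode: str,
    *,
    n_frames: int,
    dt: float = DEFAULT_DT,
    start: tuple[float, float] = (0.0, 0.0),
    seed=None,
    D: float = 0.1,
    v: float = 0.5,
    direction: tuple[float, float] | None = None,
    center: tuple[float, float] | None = None,
    corral_radius: float | None = None,
    track_id: int = 0,
    t0: int = 0,
) -> Trajectory:
    """Simulate one track under normal, active, or confined diffusion.

    Normal diffusion is a 2D random walk with per-axis step variance
    ``2 * D * dt`` (ensemble MSD ``4 * D * tau``). Active diffusion adds a
    constant-speed drift of magnitude ``v``, directed toward ``center`` if one
    is supplied (re-evaluated each frame, clamped so the drift never
    overshoots the center) or along a fixed ``direction`` unit vector
    otherwise. Confined diffusion reflects each Brownian step off a circular
    corral of radius ``corral_radius`` centered on the start position.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = _rng(seed)
    sigma = np.sqrt(2.0 * D * dt)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, 2)) if sigma > 0 else np.zeros((n_frames - 1, 2))

    pos = np.empty((n_frames, 2))
    pos[0] = start

    if mode == MODE_NORMAL:
        pos[1:] = start + np.cumsum(steps, axis=0)
    elif mode == MODE_ACTIVE:
        if v < 0:
            raise ValueError("drift speed v must be non-negative")
        if center is None and direction is None:
            direction = (1.0, 0.0)
        if direction is not None:
            u = np.asarray(direction, dtype=float)
            norm = np.hypot(*u)
            if norm == 0:
                raise ValueError("direction must be a nonzero vector")
            u = u / norm
        for k in range(1, n_frames):
            p = pos[k - 1]
            if center is not None:
                delta = np.asarray(center, dtype=float) - p
                dist = np.hypot(*delta)
                drift = delta if dist <= v * dt or dist == 0 else delta / dist * v * dt
            else:
                drift = u * v * dt
            pos[k] = p + drift + steps[k - 1]
    else:  # confined
        if corral_radius is None or corral_radius <= 0:
            raise ValueError("confined mode requires corral_radius > 0")
        if D <= 0:
            raise ValueError("confined mode requires D > 0")
        c0 = np.asarray(start, dtype=float)
        for k in range(1, n_frames):
            p = pos[k - 1] + steps[k - 1]
            r = np.hypot(*(p - c0))
            # Radial fold across the reflecting boundary until inside.
            while r > corral_radius:
                p = c0 + (p - c0) * (2.0 * corral_radius - r) / r
                r = np.hypot(*(p - c0))
            pos[k] = p

    return Trajectory(
        track_id=track_id,
        frames=np.arange(t0, t0 + n_frames),
        positions=pos,
        dt=dt,
        true_mode=mode,
    )


def largest_remainder_allocation(n: int, proportions) -> np.ndarray:
    """Integer counts summing exactly to ``n``, by largest-remainder rounding.

    Ties in the fractional remainders are broken toward lower index, so the
    allocation is deterministic.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must lie in [0, 1] and sum to 1")
    quota = n * p
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n - counts.sum()
    order = np.lexsort((np.arange(len(p)), -remainder))
    counts[order[:short]] += 1
    return counts


def simulate_trackset(
    geometry: SynapseGeometry,
    proportions: tuple[float, float, float],
    n_tracks: int,
    *,
    n_frames: int = DEFAULT_TRACK_FRAMES,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    mode_params: dict | None = None,
    random_modes: bool = False,
) -> TrackSet:
    """Simulate a per-cell population of tracks with known mode labels.

    ``proportions`` orders as (normal, active, confined). Mode counts follow
    deterministic largest-remainder rounding of ``n_tracks * proportions``
    unless ``random_modes`` draws per-track labels instead. Start positions
    are uniform over the contact disc; active drift points at the contact
    center.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = _rng(seed)
    params = {m: dict(DEFAULT_MODE_PARAMS[m]) for m in MODES}
    for m, extra in (mode_params or {}).items():
        params[m].update(extra)

    if random_modes:
        modes = rng.choice(MODES, size=n_tracks, p=np.asarray(proportions, dtype=float))
    else:
        counts = largest_remainder_allocation(n_tracks, proportions)
        modes = np.repeat(MODES, counts)

    cx, cy = geometry.center
    u = rng.uniform(0.0, 1.0, size=n_tracks)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_tracks)
    radii = geometry.r_contact * np.sqrt(u)
    starts = np.column_stack((cx + radii * np.cos(theta), cy + radii * np.sin(theta)))

    tracks = []
    for i, mode in enumerate(modes):
        kw = dict(params[mode])
        if mode == MODE_ACTIVE and "center" not in kw and "direction" not in kw:
            kw["center"] = geometry.center
        tracks.append(
            simulate_trajectory(
                mode,
                n_frames=n_frames,
                dt=dt,
                start=tuple(starts[i]),
                seed=rng,
                track_id=i,
                **kw,
            )
        )
    meta = {
        "seed": seed,
        "proportions": tuple(float(x) for x in proportions),
        "mode_params": params,
        "geometry": geometry,
    }
    return TrackSet(tracks=tracks, dt=dt, meta=meta)


def default_radial_specs(geometry: SynapseGeometry) -> dict:
    """Radial intensity functions emulating an early activating synapse.

    Receptor signal is enriched toward the dSMAC, UCHT1 (TCR ligand) fills
    the cSMAC, ICAM1 the pSMAC annulus, and IRM is dark inside the contact
    (close membrane apposition) and bright outside.
    """
    rc, rp, rd = geometry.r_csmac, geometry.r_psmac, geometry.r_contact

    def receptor(r):
        r = np.asarray(r, dtype=float)
        ring = 30.0 + 120.0 * np.exp(-0.5 * ((r - 0.9 * rd) / (0.35 * rd)) ** 2)
        return np.where(r < rd, ring, 4.0)

    def ucht1(r):
        r = np.asarray(r, dtype=float)
        return np.where(r < rc, 150.0, np.where(r < rd, 8.0, 3.0))

    def icam1(r):
        r = np.asarray(r, dtype=float)
        return np.where((r >= rc) & (r < rp), 120.0, np.where(r < rd, 8.0, 3.0))

    def irm(r):
        r = np.asarray(r, dtype=float)
        return np.where(r < rd, 20.0, 110.0)

    return {"receptor": receptor, "ucht1": ucht1, "icam1": icam1, "irm": irm}


def render_synapse_channels(
    geometry: SynapseGeometry,
    radial_spec: dict | None = None,
    *,
    noise: str = "none",
    poisson_scale: float = 1.0,
    seed: int = 0,
) -> SynapseImage:
    """Render the four-channel snapshot from per-channel radial profiles.

    Each pixel takes the value of its channel's radial function evaluated at
    the pixel-center distance from the contact center, optionally replaced by
    a scaled Poisson draw with that mean.
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    spec = radial_spec if radial_spec is not None else default_radial_specs(geometry)
    radius = geometry.radius_map()
    rng = _rng(seed)
    channels = {}
    for ch, fn in spec.items():
        clean = np.asarray(fn(radius), dtype=float)
        if np.any(clean < 0):
            raise ValueError(f"radial spec for {ch!r} produced negative intensities")
        if noise == "poisson":
            channels[ch] = rng.poisson(clean * poisson_scale).astype(float) / poisson_scale
        else:
            channels[ch] = clean
    return SynapseImage(channels=channels, pixel_size=geometry.pixel_size)


def _integrated_gaussian(shape, x0, y0, sigma, pixel_size):
    """Pixel-integrated isotropic 2D Gaussian of unit mass at (x0, y0) um."""
    rows, cols = shape
    xe = np.arange(cols + 1) * pixel_size
    ye = np.arange(rows + 1) * pixel_size
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xe[1:] - x0) / s) - erf((xe[:-1] - x0) / s))
    fy = 0.5 * (erf((ye[1:] - y0) / s) - erf((ye[:-1] - y0) / s))
    return np.outer(fy, fx)


def render_movie(
    trackset: TrackSet,
    *,
    psf_sigma: float = 0.15,
    photons_per_spot: float = 500.0,
    background: float = 10.0,
    noise: str = "none",
    pixel_size: float = 0.1,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> Movie:
    """Render a spot movie from a TrackSet.

    Each detected position contributes a pixel-integrated Gaussian of
    ``photons_per_spot`` total photons on a constant background. Positions
    outside the frame are clipped into bounds for rendering (with a warning
    and a metadata flag). Frame count is ``max frame index + 1``.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    rows, cols = shape
    n_frames = max(int(t.frames.max()) for t in trackset) + 1
    frames = np.full((n_frames, rows, cols), float(background))
    clipped = False
    xmax, ymax = cols * pixel_size, rows * pixel_size
    for t in trackset:
        for f, (x, y) in zip(t.frames, t.positions):
            if not (0.0 <= x <= xmax and 0.0 <= y <= ymax):
                clipped = True
                x = float(np.clip(x, 0.0, xmax))
                y = float(np.clip(y, 0.0, ymax))
            frames[int(f)] += photons_per_spot * _integrated_gaussian(shape, x, y, psf_sigma, pixel_size)
    if clipped:
        warnings.warn("some track positions fell outside the frame and were clip-rendered")
    if noise == "poisson":
        frames = _rng(seed).poisson(frames).astype(float)
    meta = {"seed": seed, "psf_sigma": psf_sigma, "photons_per_spot": photons_per_spot,
            "background": background, "clipped": clipped}
    return Movie(frames=frames, dt=trackset.dt, pixel_size=pixel_size, meta=meta)


# Superantigen titration used to drive T cell activation, in ng/ml; the zero
# dose is the unstimulated baseline.
DEFAULT_CONCENTRATIONS = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0)

DEFAULT_CURVE_PARAMS = {
    # fraction-positive scale: baseline + logistic rise with dose
    "CD19": {"baseline": 0.05, "bottom": 0.0, "top": 0.55, "log_ec50": 0.0, "hill": 1.0},
    "CXCR4": {"baseline": 0.05, "bottom": 0.0, "top": 0.35, "log_ec50": 1.0, "hill": 1.0},
}


def simulate_screen_dataset(
    curve_params: dict | None = None,
    *,
    concentrations=DEFAULT_CONCENTRATIONS,
    n_donors: int = 6,
    noise_sd: float = 0.02,
    marker: str = "CD69",
    seed: int = 0,
) -> DoseResponseDataset:
    """Simulate a knockout-screen table of fraction-positive responses.

    Per target, ``frac_pos = baseline + 4PL(c) + N(0, noise_sd)`` clipped to
    [0, 1]; the zero-concentration row carries the baseline. Donor noise is
    i.i.d. per row.
    """
    from .screen import four_param_logistic

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    conc = np.asarray(sorted(concentrations), dtype=float)
    if 0.0 not in conc:
        raise ValueError("concentrations must include the zero-dose baseline")
    params = curve_params if curve_params is not None else DEFAULT_CURVE_PARAMS
    rng = _rng(seed)
    rows = []
    for target, p in params.items():
        for donor in range(1, n_donors + 1):
            for c in conc:
                mean = p.get("baseline", 0.0) + four_param_logistic(
                    c, p.get("bottom", 0.0), p["top"], p["log_ec50"], p.get("hill", 1.0)
                )
                value = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((target, f"donor{donor}", marker, c, float(np.clip(value, 0.0, 1.0))))
    table = pd.DataFrame(rows, columns=["target", "donor", "marker", "conc_ng_ml", "frac_pos"])
    return DoseResponseDataset(table=table)
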