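"""Core data containers shared across the analysis pipeline.

All spatial quantities are in micrometers (um) and all times in seconds.
Image arrays follow the numpy row/column convention; a particle located at
the center of pixel ``(i, j)`` has continuous coordinates
``x = (j + 0.5) * pixel_size`` and ``y = (i + 0.5) * pixel_size``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

# Diffusion-mode labels.
MODE_NORMAL = "normal"
MODE_ACTIVE = "active"
MODE_CONFINED = "confined"
MODES = (MODE_NORMAL, MODE_ACTIVE, MODE_CONFINED)

# Region label codes used in partition label maps.
OUTSIDE = 0
DSMAC = 1
PSMAC = 2
CSMAC = 3
REGION_NAMES: Mapping[int, str] = {
    OUTSIDE: "outside",
    DSMAC: "dSMAC",
    PSMAC: "pSMAC",
    CSMAC: "cSMAC",
}
REGION_CODES: Mapping[str, int] = {v: k for k, v in REGION_NAMES.items()}
SMAC_REGIONS = (DSMAC, PSMAC, CSMAC)


class NoContactError(ValueError):
    """No cell-substrate contact could be segmented from the IRM channel."""


class DegenerateTrackError(ValueError):
    """A trajectory is unusable for the requested statistic."""


@dataclass(frozen=True)
class SynapseGeometry:
    """Concentric contact model: cSMAC disc, pSMAC annulus, dSMAC annulus.

    Parameters
    ----------
    center : (x, y) position of the contact center in um.
    r_csmac, r_psmac, r_contact : radii in um, strictly increasing.
    pixel_size : um per pixel of the associated images.
    image_shape : (rows, cols) of the associated images.
    """

    center: tuple[float, float] = (6.4, 6.4)
    r_csmac: float = 1.5
    r_psmac: float = 3.5
    r_contact: float = 5.0
    pixel_size: float = 0.1
    image_shape: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if not (0.0 < self.r_csmac < self.r_psmac < self.r_contact):
            raise ValueError("radii must satisfy 0 < r_csmac < r_psmac < r_contact")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        rows, cols = self.image_shape
        cx, cy = self.center
        if not (
            self.r_contact <= cx <= cols * self.pixel_size - self.r_contact
            and self.r_contact <= cy <= rows * self.pixel_size - self.r_contact
        ):
            raise ValueError("contact disc must fit within the image bounds")

    def radius_map(self) -> np.ndarray:
        """Distance of every pixel center from the contact center, in um."""
        rows, cols = self.image_shape
        y = (np.arange(rows) + 0.5) * self.pixel_size
        x = (np.arange(cols) + 0.5) * self.pixel_size
        xx, yy = np.meshgrid(x, y)
        return np.hypot(xx - self.center[0], yy - self.center[1])

    def region_of(self, x: float, y: float) -> int:
        r = float(np.hypot(x - self.center[0], y - self.center[1]))
        if r < self.r_csmac:
            return CSMAC
        if r < self.r_psmac:
            return PSMAC
        if r < self.r_contact:
            return DSMAC
        return OUTSIDE


@dataclass
class Trajectory:
    """A time-ordered single-particle track.

    ``frames`` holds absolute (detected) frame indices; gaps in a track are
    represented by missing frame indices, never by placeholder positions.
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray
    dt: float
    true_mode: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions must have equal length")
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one position")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.true_mode is not None and self.true_mode not in MODES:
            raise ValueError(f"unknown mode {self.true_mode!r}")

    @property
    def n_detected(self) -> int:
        return len(self.frames)

    @property
    def t0(self) -> int:
        return int(self.frames[0])

    @property
    def duration_s(self) -> float:
        return float((self.frames[-1] - self.frames[0]) * self.dt)


@dataclass
class TrackSet:
    """A collection of trajectories sharing one frame interval."""

    tracks: list[Trajectory]
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique")
        for t in self.tracks:
            if not np.isclose(t.dt, self.dt):
                raise ValueError("all tracks must share the TrackSet dt")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns track_id, frame, x_um, y_um, true_mode."""
        rows = []
        for t in self.tracks:
            for f, (x, y) in zip(t.frames, t.positions):
                rows.append((t.track_id, int(f), x, y, t.true_mode))
        return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "true_mode"])


CHANNELS = ("receptor", "ucht1", "icam1", "irm")


@dataclass
class SynapseImage:
    """Multi-channel snapshot of one synapse (receptor, UCHT1, ICAM1, IRM)."""

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, a in self.channels.items():
            a = np.asarray(a, dtype=float)
            if np.any(a < 0):
                raise ValueError(f"channel {ch!r} has negative intensities")
            self.channels[ch] = a
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, ch: str) -> np.ndarray:
        return self.channels[ch]


@dataclass
class Movie:
    """Time-lapse of 2D frames with a fixed frame interval."""

    frames: np.ndarray  # (T, rows, cols)
    dt: float
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a nonempty (T, rows, cols) array")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("dt and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ContactMask:
    """Boolean footprint of the IRM-defined cell-substrate contact."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2


@dataclass
class RegionPartition:
    """Pixel label map {outside, dSMAC, pSMAC, cSMAC} over one contact."""

    labels: np.ndarray
    pixel_size: float
    center: tuple[float, float]
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(self.labels, list(REGION_NAMES)).all():
            raise ValueError("labels must be in {0, 1, 2, 3}")

    @property
    def contact_mask(self) -> np.ndarray:
        return self.labels != OUTSIDE

    def area_um2(self, region: int) -> float:
        return float((self.labels == region).sum()) * self.pixel_size**2

    def region_at(self, x: float, y: float) -> int:
        """Region label of the pixel containing position (x, y) in um.

        A position exactly on a pixel boundary belongs to the pixel whose
        index is ``floor(coord / pixel_size)``; positions outside the image
        map to ``outside``.
        """
        i = int(np.floor(y / self.pixel_size))
        j = int(np.floor(x / self.pixel_size))
        rows, cols = self.labels.shape
        if not (0 <= i < rows and 0 <= j < cols):
            return OUTSIDE
        return int(self.labels[i, j])


@dataclass
class RadialProfile:
    """Mean intensity versus radius, optionally min-max normalized."""

    radii_um: np.ndarray
    intensity: np.ndarray
    normalized: np.ndarray | None = None
    degenerate_normalization: bool = False

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.radii_um) <= 0):
            raise ValueError("radii must be strictly increasing")


@dataclass
class EnrichmentResult:
    """Per-region enrichment index with its ingredient fractions.

    The index for region r is (intensity fraction of r) / (area fraction of r),
    both fractions taken over the contact footprint; 1 means no enrichment.
    """

    index: dict[str, float]
    intensity_fraction: dict[str, float]
    area_fraction: dict[str, float]


@dataclass
class PCCResult:
    coefficient: float
    n_pixels: int
    threshold_a: float
    threshold_b: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    null_value: float


@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement per lag."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)


@dataclass
class ClassificationResult:
    track_id: int
    mode: str
    alpha: float
    D_um2_s: float
    mean_speed_um_s: float
    r_squared: float
    n_fit_lags: int
    degenerate: bool = False


@dataclass
class RegionSequence:
    """Region label at each detected frame of one track."""

    track_id: int
    frames: np.ndarray
    labels: np.ndarray
    mode: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.frames) != len(self.labels):
            raise ValueError("frames and labels must have equal length")


@dataclass
class TransitionSummary:
    """Counts of starting regions and of transitions between distinct regions.

    Keyed by diffusion mode (or ``None`` for unlabeled input); transitions are
    pairs of region codes.
    """

    starts: dict[str | None, dict[int, int]]
    transitions: dict[str | None, dict[tuple[int, int], int]]

    def n_sequences(self) -> int:
        return sum(sum(c.values()) for c in self.starts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mode, counter in self.transitions.items():
            for (a, b), n in sorted(counter.items()):
                rows.append((mode, REGION_NAMES[a], REGION_NAMES[b], n))
        return pd.DataFrame(rows, columns=["mode", "from_region", "to_region", "count"])


@dataclass
class ZStack:
    """Ordered z-planes, basal (closest to the coverslip) first."""

    planes: np.ndarray  # (n_z, rows, cols)
    z_spacing: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] < 3:
            raise ValueError("a z-stack needs at least 3 planes")
        if self.z_spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("z_spacing and pixel_size must be positive")


@dataclass
class MembraneProfile:
    """Intensity sampled along a membrane contour at fixed arc-length spacing."""

    arclength_um: np.ndarray
    intensity: np.ndarray
    is_contact: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        self.arclength_um = np.asarray(self.arclength_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.is_contact = np.asarray(self.is_contact, dtype=bool)
        n = len(self.arclength_um)
        if not (len(self.intensity) == len(self.is_contact) == n):
            raise ValueError("profile arrays must have equal length")
        if not self.is_contact.any():
            raise ValueError("contact segment is empty")
        idx = np.flatnonzero(self.is_contact)
        if idx[0] == 0 or idx[-1] == n - 1:
            raise ValueError("contact segment must be interior to the samples")
        if np.any(np.diff(idx) != 1):
            raise ValueError("contact segment must be contiguous")


@dataclass
class DoseResponseDataset:
    """Screen table: one row per (target, donor, marker, concentration)."""

    table: pd.DataFrame

    REQUIRED = ("target", "donor", "marker", "conc_ng_ml", "frac_pos")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        frac = self.table["frac_pos"]
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("frac_pos must lie in [0, 1]")
        for key, grp in self.table.groupby(["target", "donor", "marker"]):
            if not (grp["conc_ng_ml"] == 0).any():
                raise ValueError(f"group {key} lacks a zero-concentration baseline row")


@dataclass
class CurveFit:
    """Four-parameter logistic fit of a normalized dose-response curve."""

    bottom: float
    top: float
    log_ec50: float
    hill: float
    rss: float
    df: int
    n_points: int
    converged: bool
    model: str = "4PL"

    def predict(self, conc_ng_ml) -> np.ndarray:
        from .screen import four_param_logistic

        return four_param_logistic(conc_ng_ml, self.bottom, self.top, self.log_ec50, self.hill)

    @property
    def emax(self) -> float:
        """Fitted response at the highest concentration used in the fit."""
        return float(self.predict(self._max_conc))

    _max_conc: float = float("nan")


@dataclass
class FTestResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
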