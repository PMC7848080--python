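"""Reading and writing the pipeline's on-disk formats.

Images and movies are multi-page TIFF with a JSON metadata payload in the
ImageDescription tag (pixel size in um, frame interval in s, channel order,
IRM convention). Tracks, spots, profiles and screen tables are CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import (
    REGION_NAMES,
    DoseResponseDataset,
    Movie,
    RegionPartition,
    SynapseGeometry,
    SynapseImage,
    TrackSet,
    Trajectory,
)

TRACK_CSV_HEADER = (
    "# coordinates: x_um = (col + 0.5) * pixel_size, y_um = (row + 0.5) * pixel_size; "
    "0-based pixel indices\n"
)


def write_synapse_image(path, image: SynapseImage) -> None:
    names = list(image.channels)
    stack = np.stack([image.channels[ch] for ch in names]).astype(np.float32)
    meta = {"pixel_size_um": image.pixel_size, "channels": names, "irm_convention": "contact=dark"}
    tifffile.imwrite(path, stack, description=json.dumps(meta), photometric="minisblack")


def read_synapse_image(path) -> SynapseImage:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    channels = dict(zip(meta["channels"], np.asarray(stack, dtype=float)))
    return SynapseImage(channels=channels, pixel_size=float(meta["pixel_size_um"]))


def write_movie(path, movie: Movie) -> None:
    meta = {"pixel_size_um": movie.pixel_size, "dt_s": movie.dt, **movie.meta}
    tifffile.imwrite(path, movie.frames.astype(np.float32), description=json.dumps(meta))


def read_movie(path) -> Movie:
    with tifffile.TiffFile(path) as tif:
        frames = np.asarray(tif.asarray(), dtype=float)
        meta = json.loads(tif.pages[0].description)
    dt = float(meta.pop("dt_s"))
    ps = float(meta.pop("pixel_size_um"))
    return Movie(frames=frames, dt=dt, pixel_size=ps, meta=meta)


def write_tracks_csv(path, trackset: TrackSet) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(TRACK_CSV_HEADER)
        fh.write(f"# dt_s={trackset.dt}\n")
        trackset.to_frame().to_csv(fh, index=False)


def read_tracks_csv(path, dt: float | None = None) -> TrackSet:
    with open(path) as fh:
        header_dt = None
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "dt_s=" in line:
                header_dt = float(line.split("dt_s=")[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    dt = dt if dt is not None else header_dt
    if dt is None:
        raise ValueError("frame interval not recorded in the file; pass dt explicitly")
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        mode = grp["true_mode"].iloc[0] if "true_mode" in grp and pd.notna(grp["true_mode"].iloc[0]) else None
        tracks.append(
            Trajectory(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(),
                positions=grp[["x_um", "y_um"]].to_numpy(),
                dt=dt,
                true_mode=mode,
            )
        )
    return TrackSet(tracks=tracks, dt=dt)


def write_partition(path_tiff, path_json, partition: RegionPartition) -> None:
    tifffile.imwrite(
        path_tiff,
        partition.labels.astype(np.uint8),
        description=json.dumps({"labels": {str(k): v for k, v in REGION_NAMES.items()}}),
    )
    summary = {
        "pixel_size_um": partition.pixel_size,
        "center_um": list(partition.center),
        "areas_um2": {REGION_NAMES[c]: partition.area_um2(c) for c in (1, 2, 3)},
        "flags": partition.flags,
    }
    Path(path_json).write_text(json.dumps(summary, indent=2))


def read_partition(path_tiff, pixel_size: float, center: tuple[float, float]) -> RegionPartition:
    labels = tifffile.imread(path_tiff)
    return RegionPartition(labels=labels, pixel_size=pixel_size, center=center)


def write_screen_csv(path, dataset: DoseResponseDataset) -> None:
    dataset.table.to_csv(path, index=False)


def read_screen_csv(path) -> DoseResponseDataset:
    return DoseResponseDataset(table=pd.read_csv(path))


def write_geometry_json(path, geometry: SynapseGeometry) -> None:
    Path(path).write_text(json.dumps({
        "center": list(geometry.center),
        "r_csmac": geometry.r_csmac,
        "r_psmac": geometry.r_psmac,
        "r_contact": geometry.r_contact,
        "pixel_size": geometry.pixel_size,
        "image_shape": list(geometry.image_shape),
    }, indent=2))


def read_geometry_json(path) -> SynapseGeometry:
    d = json.loads(Path(path).read_text())
    return SynapseGeometry(
        center=tuple(d["center"]),
        r_csmac=d["r_csmac"],
        r_psmac=d["r_psmac"],
        r_contact=d["r_contact"],
        pixel_size=d["pixel_size"],
        image_shape=tuple(d["image_shape"]),
    )
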