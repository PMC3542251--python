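"""File formats: CSV profiles and detections, GeoJSON annotations, images.

All coordinates in files are microns, origin at the image top-left, y
downward.  Floats are written with ``repr`` so CSV round-trips are exact;
malformed or truncated files raise a :class:`ValueError` naming the line.
"""

from __future__ import annotations

import csv
import json
import re

import numpy as np

from .detection import CellDetection, IHCImage
from .geometry import (
    FrontAnnotation,
    RectangleROI,
    front_from_geojson,
    front_to_geojson,
    roi_from_geojson,
    roi_to_geojson,
)
from .profiling import DensityProfile

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "write_detections_csv",
    "read_detections_csv",
    "write_front_geojson",
    "read_front_geojson",
    "write_roi_geojson",
    "read_roi_geojson",
    "load_image",
    "save_image",
]

_PROFILE_COLUMNS = ["v_um", "offset_um", "density_per_5000um2"]
_DETECTION_COLUMNS = ["x_um", "y_um", "area_um2", "intensity"]


def write_profile_csv(profile: DensityProfile, path) -> None:
    """Write a density curve as CSV (v_um, offset_um, density_per_5000um2).

    Metadata (bin size, merged-rectangle count, width) goes into ``#``
    comment lines so the profile round-trips exactly.
    """
    bin_um = float(profile.bin_edges[1] - profile.bin_edges[0])
    with open(path, "w", newline="") as fh:
        fh.write("# lqli density profile; coordinates um, origin image top-left, y down\n")
        fh.write(f"# bin_um={bin_um!r}\n")
        fh.write(f"# n_rectangles={profile.n_rectangles}\n")
        fh.write(f"# width_used={profile.width_used!r}\n")
        writer = csv.writer(fh)
        writer.writerow(_PROFILE_COLUMNS)
        for v, off, d in zip(profile.bin_centers, profile.offsets, profile.density):
            writer.writerow([repr(float(v)), repr(float(off)), repr(float(d))])


def read_profile_csv(path) -> DensityProfile:
    meta = {"n_rectangles": 1, "width_used": 1000.0, "bin_um": None}
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)=(.+)", line)
                if m and m.group(1) in meta:
                    meta[m.group(1)] = float(m.group(2))
                continue
            fields = line.split(",")
            if fields == _PROFILE_COLUMNS:
                continue
            if len(fields) != len(_PROFILE_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(_PROFILE_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    centers, density = arr[:, 0], arr[:, 2]
    if meta["bin_um"] is None:
        if len(centers) < 2:
            raise ValueError(f"{path}: cannot infer bin size from a single row")
        meta["bin_um"] = float(centers[1] - centers[0])
    half = meta["bin_um"] / 2.0
    edges = np.concatenate([centers - half, [centers[-1] + half]])
    return DensityProfile(
        bin_edges=edges,
        density=density,
        n_rectangles=int(meta["n_rectangles"]),
        width_used=float(meta["width_used"]),
    )


def write_detections_csv(dets: list[CellDetection], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# lqli detections; coordinates um, origin image top-left, y down\n")
        writer = csv.writer(fh)
        writer.writerow(_DETECTION_COLUMNS)
        for d in dets:
            writer.writerow(
                [repr(d.x_um), repr(d.y_um), repr(d.area_um2), repr(d.mean_positive_intensity)]
            )


def read_detections_csv(path) -> list[CellDetection]:
    out: list[CellDetection] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(",")
            if fields == _DETECTION_COLUMNS:
                continue
            if len(fields) != len(_DETECTION_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(_DETECTION_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            try:
                x, y, a, i = (float(v) for v in fields)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append(CellDetection(x, y, a, i))
    return out


def write_front_geojson(front: FrontAnnotation, path, mpp: float | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(front_to_geojson(front, mpp), fh, indent=1)


def read_front_geojson(path) -> FrontAnnotation:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed GeoJSON: {exc}") from exc
    return front_from_geojson(obj)


def write_roi_geojson(roi: RectangleROI, path, mpp: float | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(roi_to_geojson(roi, mpp), fh, indent=1)


def read_roi_geojson(path) -> RectangleROI:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed GeoJSON: {exc}") from exc
    return roi_from_geojson(obj)


# ---------------------------------------------------------------------------
# images


def _mpp_from_ome(path) -> float | None:
    """Physical pixel size from OME-TIFF metadata, if present."""
    try:
        import tifffile

        with tifffile.TiffFile(path) as tif:
            ome = tif.ome_metadata
        if ome:
            m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', ome)
            if m:
                return float(m.group(1))
    except Exception:
        return None
    return None


def load_image(path, mpp: float | None = None) -> IHCImage:
    """Read a TIFF/PNG RGB raster.

    The micron-per-pixel calibration is taken from OME-TIFF metadata when
    present, otherwise from the ``mpp`` argument (e.g. a config/sidecar
    value).
    """
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        pixels = tifffile.imread(path)
        meta_mpp = _mpp_from_ome(path)
        if meta_mpp is not None:
            mpp = meta_mpp
    else:
        from PIL import Image

        pixels = np.asarray(Image.open(path).convert("RGB"))
    if mpp is None:
        raise ValueError(f"{path}: no mpp metadata found; pass mpp explicitly")
    return IHCImage(pixels=pixels, mpp=mpp)


def save_image(img: IHCImage, path) -> None:
    """Write TIFF (with OME pixel-size metadata) or PNG."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(
            path,
            img.pixels,
            photometric="rgb",
            ome=True,
            metadata={"axes": "YXS", "PhysicalSizeX": img.mpp, "PhysicalSizeY": img.mpp},
        )
    else:
        from PIL import Image

        Image.fromarray(img.pixels).save(path)
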