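"""Analysis-rectangle geometry over the tumor invasive front.

The invasive front — the microscopic interface between host tissue and the
tumor mass — is annotated as an oriented polyline, with a flag saying on
which side of the travel direction the tumor lies.  A rectangular region of
interest (1 mm wide x 4 mm long by default) is anchored on the front, its
long axis perpendicular to the local tangent, oriented so the front sits at
the middle of the axis and the tumor occupies the inner half.

Coordinates are microns in the image frame: origin at the top-left corner,
x rightward, y *downward* (raster convention).  With the travel direction
``t``, the "right" side of the polyline is ``(-t_y, t_x)`` — i.e. 90 deg
clockwise as the image is displayed.

The local (u, v) frame of a rectangle:

* ``v`` runs along the rectangle axis from 0 (outermost, host side) to L
  (innermost, tumor side); the front sits at ``v = L/2``.
* ``u`` is the signed across-width offset, ``|u| <= W/2`` inside the ROI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString

__all__ = [
    "FrontAnnotation",
    "RectangleROI",
    "build_roi",
    "point_to_uv",
    "point_from_uv",
    "roi_contains",
    "front_to_geojson",
    "front_from_geojson",
    "roi_to_geojson",
    "roi_from_geojson",
]

#: default rectangle width across the front, um (1 mm)
DEFAULT_WIDTH_UM = 1000.0
#: default rectangle length along the perpendicular axis, um (4 mm)
DEFAULT_LENGTH_UM = 4000.0
#: default segment (bin) thickness along the axis, um
DEFAULT_BIN_UM = 5.0

_EPS = 1e-9


@dataclass(frozen=True)
class FrontAnnotation:
    """Oriented polyline marking the invasive front.

    Parameters
    ----------
    points : (N, 2) array of um coordinates in the image frame, N >= 2,
        consecutive points distinct.
    tumor_side : {"left", "right"} — side of the travel direction on which
        the tumor mass lies.
    """

    points: np.ndarray
    tumor_side: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("front annotation needs >= 2 two-dimensional points")
        seg = np.diff(pts, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) <= _EPS):
            raise ValueError("consecutive front points must be distinct")
        if self.tumor_side not in ("left", "right"):
            raise ValueError(f"tumor_side must be 'left' or 'right', got {self.tumor_side!r}")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        """Total polyline arc length, um."""
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def as_linestring(self) -> LineString:
        return LineString(self.points)


@dataclass(frozen=True)
class RectangleROI:
    """Analysis rectangle in the front-centred local frame.

    ``anchor`` lies on the front, ``normal`` is the unit vector pointing
    into the tumor.  The front sits at ``v = length/2`` of the local axis.
    """

    anchor: np.ndarray
    normal: np.ndarray
    width: float = DEFAULT_WIDTH_UM
    length: float = DEFAULT_LENGTH_UM
    bin_um: float = DEFAULT_BIN_UM

    def __post_init__(self) -> None:
        anchor = np.asarray(self.anchor, dtype=float).reshape(2)
        normal = np.asarray(self.normal, dtype=float).reshape(2)
        norm = float(np.hypot(*normal))
        if abs(norm - 1.0) > 1e-9:
            if norm <= _EPS:
                raise ValueError("normal vector must be non-zero")
            normal = normal / norm
        if self.width <= 0 or self.length <= 0 or self.bin_um <= 0:
            raise ValueError("width, length and bin size must be positive")
        n_bins = self.length / self.bin_um
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("bin size must divide the rectangle length exactly")
        object.__setattr__(self, "anchor", anchor)
        object.__setattr__(self, "normal", normal)

    @property
    def tangent(self) -> np.ndarray:
        """Unit vector along the width direction (normal rotated -90 deg)."""
        return np.array([self.normal[1], -self.normal[0]])

    @property
    def n_bins(self) -> int:
        return int(round(self.length / self.bin_um))

    @property
    def area_um2(self) -> float:
        return self.width * self.length

    @property
    def bin_area_um2(self) -> float:
        """Area covered by one segment: bin thickness x full width."""
        return self.bin_um * self.width

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_bins + 1)

    def corners(self) -> np.ndarray:
        """The 4 corners in image coordinates, counter-clockwise in (u,v)."""
        w2 = self.width / 2.0
        uv = [(-w2, 0.0), (w2, 0.0), (w2, self.length), (-w2, self.length)]
        return np.array([point_from_uv(u, v, self) for u, v in uv])

    def with_dims(self, **overrides) -> "RectangleROI":
        return replace(self, **overrides)


def _tangent_at(front: FrontAnnotation, arc_position: float) -> tuple[np.ndarray, np.ndarray]:
    """Anchor point and unit travel direction at an arc position.

    Strictly inside a segment the tangent is the segment direction; at a
    shared vertex it is the bisector of the adjacent segment directions
    (central difference on the polyline), which keeps normals stable.
    """
    pts = front.points
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if arc_position < -_EPS or arc_position > total + _EPS:
        raise ValueError(
            f"arc_position {arc_position} outside polyline arc length [0, {total}]"
        )
    s = min(max(arc_position, 0.0), total)

    # vertex hit (including endpoints)?
    hit = np.flatnonzero(np.abs(cum - s) <= 1e-9)
    if hit.size:
        i = int(hit[0])
        anchor = pts[i]
        dirs = []
        if i > 0:
            dirs.append(seg[i - 1] / seg_len[i - 1])
        if i < len(seg):
            dirs.append(seg[i] / seg_len[i])
        t = np.sum(dirs, axis=0)
        tn = float(np.hypot(*t))
        if tn <= _EPS:
            raise ValueError("degenerate tangent: adjacent segments reverse direction")
        return anchor, t / tn

    i = int(np.searchsorted(cum, s) - 1)
    frac = (s - cum[i]) / seg_len[i]
    anchor = pts[i] + frac * seg[i]
    return anchor, seg[i] / seg_len[i]


def build_roi(
    front: FrontAnnotation,
    arc_position: float,
    *,
    width: float = DEFAULT_WIDTH_UM,
    length: float = DEFAULT_LENGTH_UM,
    bin_um: float = DEFAULT_BIN_UM,
) -> RectangleROI:
    """Place an analysis rectangle on the front at a given arc position.

    The anchor lies on the polyline; the normal is perpendicular to the
    local tangent and points toward ``front.tumor_side``.
    """
    anchor, t = _tangent_at(front, arc_position)
    if front.tumor_side == "right":
        normal = np.array([-t[1], t[0]])
    else:
        normal = np.array([t[1], -t[0]])
    return RectangleROI(anchor=anchor, normal=normal, width=width, length=length, bin_um=bin_um)


def point_to_uv(p, roi: RectangleROI):
    """Map image-frame point(s) to the rectangle's local (u, v) frame, um.

    ``v = length/2`` on the front line through the anchor and increases
    toward the tumor; ``u`` is the signed across-width offset.  Accepts a
    single (2,) point or an (N, 2) array.
    """
    p = np.asarray(p, dtype=float)
    d = p - roi.anchor
    v = roi.length / 2.0 + d @ roi.normal
    u = d @ roi.tangent
    return u, v


def point_from_uv(u, v, roi: RectangleROI) -> np.ndarray:
    """Inverse of :func:`point_to_uv`."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return (
        roi.anchor
        + np.multiply.outer(u, roi.tangent)
        + np.multiply.outer(v - roi.length / 2.0, roi.normal)
    )


def roi_contains(p, roi: RectangleROI):
    """True where a point lies inside the rectangle (closed boundaries)."""
    u, v = point_to_uv(p, roi)
    return (np.abs(u) <= roi.width / 2.0 + _EPS) & (v >= -_EPS) & (v <= roi.length + _EPS)


# ---------------------------------------------------------------------------
# GeoJSON serialization (coordinates in um; mpp recorded at top level)


def front_to_geojson(front: FrontAnnotation, mpp: float | None = None) -> dict:
    obj = {
        "type": "Feature",
        "geometry": {
            "type": "LineString",
            "coordinates": front.points.tolist(),
        },
        "properties": {"tumor_side": front.tumor_side, "units": "um"},
    }
    if mpp is not None:
        obj["mpp"] = float(mpp)
    return obj


def front_from_geojson(obj: dict) -> FrontAnnotation:
    if obj.get("type") == "FeatureCollection":
        obj = obj["features"][0]
    geom = obj["geometry"]
    if geom["type"] != "LineString":
        raise ValueError(f"expected LineString front annotation, got {geom['type']}")
    return FrontAnnotation(
        points=np.asarray(geom["coordinates"], dtype=float),
        tumor_side=obj.get("properties", {}).get("tumor_side", "right"),
    )


def roi_to_geojson(roi: RectangleROI, mpp: float | None = None) -> dict:
    corners = roi.corners()
    ring = np.vstack([corners, corners[:1]])
    obj = {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
        "properties": {
            "anchor": roi.anchor.tolist(),
            "normal": roi.normal.tolist(),
            "width_um": roi.width,
            "length_um": roi.length,
            "bin_um": roi.bin_um,
            "units": "um",
        },
    }
    if mpp is not None:
        obj["mpp"] = float(mpp)
    return obj


def roi_from_geojson(obj: dict) -> RectangleROI:
    if obj.get("type") == "FeatureCollection":
        obj = obj["features"][0]
    props = obj.get("properties", {})
    try:
        return RectangleROI(
            anchor=np.asarray(props["anchor"], dtype=float),
            normal=np.asarray(props["normal"], dtype=float),
            width=float(props["width_um"]),
            length=float(props["length_um"]),
            bin_um=float(props["bin_um"]),
        )
    except KeyError as exc:
        raise ValueError(f"ROI GeoJSON missing property {exc}") from exc


def dump_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_geojson(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
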