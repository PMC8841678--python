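"""RECIST/WHO diameter measurement from closed contours.

The longest in-plane diameter of a contour is the maximum pairwise
distance between boundary points in mm (anisotropic pixel spacing applied
per axis).  For lymph nodes RECIST 1.1 measures the *short axis* instead:
the longest chord perpendicular to the longest diameter.  In 3D mode the
slice with the maximum cut-plane area is selected first and the diameter
measured there.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, MultiLineString, Polygon

from .contour_engine import Contour
from .volumetric import LesionContourSet


@dataclass
class MeasurementRecord:
    """One lesion measurement: the RECIST-relevant diameters in mm."""

    lesion_id: str
    mode: str  # "2D" or "3D"
    slice_index: int
    longest_diameter_mm: float
    short_axis_mm: float | None = None
    who_product_mm2: float | None = None
    endpoints: tuple[tuple[float, float], tuple[float, float]] | None = None
    nodal: bool = False
    organ: str = ""

    @property
    def recist_value_mm(self) -> float:
        """Short axis for nodal disease, longest diameter otherwise."""
        if self.nodal:
            if self.short_axis_mm is None:
                raise ValueError("nodal lesion without a short-axis measurement")
            return self.short_axis_mm
        return self.longest_diameter_mm


def _vertices_mm(c: Contour) -> np.ndarray:
    return c.vertices * np.asarray(c.spacing)


def longest_diameter(c: Contour) -> tuple[float, tuple[tuple[float, float], tuple[float, float]]]:
    """Longest diameter in mm and its endpoints (pixel coordinates).

    The diameter of a polygon is attained at a pair of convex-hull
    vertices, so the search runs over hull vertices only.  Ties are broken
    by the lexicographically smallest endpoint pair (in pixel coordinates,
    endpoints sorted), making the reported endpoints deterministic.
    """
    if len(c.vertices) < 3:
        raise ValueError("contour has fewer than 3 vertices")
    mm = _vertices_mm(c)
    try:
        hull_idx = ConvexHull(mm).vertices
    except QhullError:  # collinear contour: fall back to all points
        hull_idx = np.arange(len(mm))
    pts = mm[hull_idx]
    d = cdist(pts, pts)
    dmax = d.max()
    ii, jj = np.where(d >= dmax - 1e-12)
    best = None
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        a = tuple(c.vertices[hull_idx[i]])
        b = tuple(c.vertices[hull_idx[j]])
        pair = tuple(sorted((a, b)))
        if best is None or pair < best:
            best = pair
    if best is None:
        raise ValueError("degenerate contour: no distinct vertex pair")
    return float(dmax), best


def short_axis(
    c: Contour,
    long_axis: tuple[tuple[float, float], tuple[float, float]],
) -> float:
    """Longest chord perpendicular to the long axis, in mm.

    The contour is rotated so the long axis lies along x; the maximum
    single connected intersection of a vertical line with the polygon is
    then the perpendicular diameter.  The chord length as a function of x
    is piecewise linear with breakpoints at vertex abscissas, so scanning
    the vertex abscissas (and interval midpoints, to dodge degenerate
    lines through vertices) attains the maximum.
    """
    mm = _vertices_mm(c)
    (r1, c1), (r2, c2) = long_axis
    sp = np.asarray(c.spacing)
    a = np.array([r1, c1]) * sp
    b = np.array([r2, c2]) * sp
    axis = b - a
    norm = np.hypot(*axis)
    if norm <= 0:
        raise ValueError("degenerate long axis")
    ca, sa = axis[0] / norm, axis[1] / norm
    # rotate so the long axis maps to +x (coordinates (y=row_mm, x=col_mm))
    y, x = mm[:, 0], mm[:, 1]
    u = ca * y + sa * x      # along-axis coordinate
    v = -sa * y + ca * x     # perpendicular coordinate
    poly = Polygon(np.column_stack([u, v]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0:
        raise ValueError("degenerate polygon")
    vmin, vmax = v.min() - 1.0, v.max() + 1.0
    us = np.unique(u)
    candidates = np.concatenate([us, (us[:-1] + us[1:]) / 2.0])
    best = 0.0
    for uu in candidates:
        cut = poly.intersection(LineString([(uu, vmin), (uu, vmax)]))
        if cut.is_empty:
            continue
        if isinstance(cut, MultiLineString):
            length = max(g.length for g in cut.geoms)
        elif isinstance(cut, LineString):
            length = cut.length
        else:  # point or collection of points
            length = max(
                (g.length for g in getattr(cut, "geoms", [cut])), default=0.0
            )
        best = max(best, length)
    return float(best)


def contour_area_mm2(c: Contour) -> float:
    """Shoelace polygon area in mm²."""
    mm = _vertices_mm(c)
    x, y = mm[:, 1], mm[:, 0]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def max_area_slice(contour_set: LesionContourSet) -> int:
    """Slice index with the largest cut-plane area; ties -> lowest index."""
    if not contour_set.contours:
        raise ValueError("empty contour set")
    best_idx, best_area = None, -1.0
    for idx in sorted(contour_set.contours):
        area = contour_area_mm2(contour_set.contours[idx])
        if area > best_area + 1e-12:
            best_idx, best_area = idx, area
    return best_idx


def measure_lesion(
    contour_set: LesionContourSet,
    mode: str = "3D",
    slice_index: int | None = None,
) -> MeasurementRecord:
    """RECIST measurement of a lesion.

    In 3D mode the diameter is taken on the maximum-area slice of the
    volumetric contour set; in 2D mode on the single contoured slice (or a
    designated ``slice_index``).  Nodal lesions report the short axis as
    the RECIST value; the WHO product (longest x perpendicular) is always
    recorded.
    """
    if mode not in ("2D", "3D"):
        raise ValueError("mode must be '2D' or '3D'")
    indices = contour_set.slice_indices()
    if mode == "2D":
        if slice_index is None:
            if len(indices) != 1:
                raise ValueError(
                    "2D mode with multiple contours requires a designated slice"
                )
            slice_index = indices[0]
    else:
        slice_index = max_area_slice(contour_set)
    contour = contour_set.contours[slice_index]
    long_mm, endpoints = longest_diameter(contour)
    short_mm = short_axis(contour, endpoints)
    return MeasurementRecord(
        lesion_id=contour_set.lesion_id,
        mode=mode,
        slice_index=slice_index,
        longest_diameter_mm=long_mm,
        short_axis_mm=short_mm,
        who_product_mm2=long_mm * short_mm,
        endpoints=endpoints,
        nodal=contour_set.nodal,
        organ=contour_set.organ,
    )


def manual_measurement(
    lesion_id: str,
    diameter_mm: float,
    slice_index: int = 0,
    nodal: bool = False,
    organ: str = "",
) -> MeasurementRecord:
    """Pass-through record for a manually placed two-endpoint measurement."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    return MeasurementRecord(
        lesion_id=lesion_id,
        mode="2D",
        slice_index=slice_index,
        longest_diameter_mm=diameter_mm,
        short_axis_mm=diameter_mm if nodal else None,
        nodal=nodal,
        organ=organ,
    )


_CSV_FIELDS = [
    "patient_id", "lesion_id", "timepoint", "reader_id", "method",
    "mode", "diameter_mm", "short_axis_mm", "slice_index",
]


def write_measurement_csv(
    rows: list[dict],
    path: str | Path,
) -> None:
    """Write measurement rows (dicts with the standard columns) to CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in _CSV_FIELDS})


def measurement_row(
    record: MeasurementRecord,
    patient_id: str = "",
    timepoint: int = 0,
    reader_id: str = "",
    method: str = "CAC",
) -> dict:
    return {
        "patient_id": patient_id,
        "lesion_id": record.lesion_id,
        "timepoint": timepoint,
        "reader_id": reader_id,
        "method": method,
        "mode": record.mode,
        "diameter_mm": record.longest_diameter_mm,
        "short_axis_mm": "" if record.short_axis_mm is None else record.short_axis_mm,
        "slice_index": record.slice_index,
    }
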