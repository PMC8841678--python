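"""Between-slice contour propagation for volumetric lesion contouring.

The user contours a lesion on a subset of *key slices* (first, last, and
every few slices in between).  For each slice between two key slices the
two key contours are resampled to a common number of control points by
normalized arc length, the matched points are blended linearly in z to
estimate an initial contour, and the band-restricted two-pass search then
snaps that estimate to the local boundary.  Key-slice contours are never
modified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from .contour_engine import Contour, Trajectory, two_pass_contour
from .image_graph import SliceImage, compute_cost_field


@dataclass
class LesionContourSet:
    """Contours of one lesion across slices.

    ``contours`` maps slice index to :class:`Contour`; ``key_slices`` flags
    the user-contoured subset.  ``nodal`` marks lymph-node lesions, which
    RECIST measures by short axis rather than longest diameter.
    """

    contours: dict[int, Contour]
    key_slices: set[int] = field(default_factory=set)
    lesion_id: str = "lesion"
    organ: str = ""
    nodal: bool = False

    def __post_init__(self) -> None:
        self.contours = dict(sorted(self.contours.items()))
        self.key_slices = set(self.key_slices)
        if not self.key_slices:
            raise ValueError("at least one key slice is required")
        missing = self.key_slices - set(self.contours)
        if missing:
            raise ValueError(f"key slices without contours: {sorted(missing)}")
        keys = sorted(self.key_slices)
        for idx in self.contours:
            if idx not in self.key_slices and not (keys[0] < idx < keys[-1]):
                raise ValueError(
                    f"non-key contour at slice {idx} outside the key-slice range"
                )

    def slice_indices(self) -> list[int]:
        return sorted(self.contours)

    def to_dict(self) -> dict:
        return {
            "lesion_id": self.lesion_id,
            "organ": self.organ,
            "nodal": self.nodal,
            "key_slices": sorted(self.key_slices),
            "contours": {str(i): c.to_dict() for i, c in self.contours.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LesionContourSet":
        return cls(
            contours={int(i): Contour.from_dict(c) for i, c in d["contours"].items()},
            key_slices=set(d["key_slices"]),
            lesion_id=d.get("lesion_id", "lesion"),
            organ=d.get("organ", ""),
            nodal=bool(d.get("nodal", False)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LesionContourSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def resample_closed_contour(vertices: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polygon to ``n_points`` by normalized arc length.

    The starting phase is anchored at the boundary point lying at polar
    angle zero (the +col direction) from the centroid, and the orientation
    is forced counter-clockwise in (col, row) axes, so two independently
    drawn contours of the same shape resample to matched point sequences.
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 vertices")
    ring = np.vstack([v, v[:1]])
    steps = np.hypot(*(np.diff(ring, axis=0).T))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")

    # dense uniform resampling as a working parameterization
    dense_n = max(512, 4 * len(v))
    t = np.linspace(0.0, total, dense_n, endpoint=False)
    dense = np.column_stack(
        [np.interp(t, cum, ring[:, 0]), np.interp(t, cum, ring[:, 1])]
    )

    # counter-clockwise in (x=col, y=row): positive shoelace area
    x, y = dense[:, 1], dense[:, 0]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    if area2 < 0:
        dense = dense[::-1]
        x, y = dense[:, 1], dense[:, 0]

    centroid = dense.mean(axis=0)
    ang = np.arctan2(dense[:, 0] - centroid[0], dense[:, 1] - centroid[1])
    start = int(np.argmin(np.abs(ang)))
    dense = np.roll(dense, -start, axis=0)

    idx = np.floor(np.arange(n_points) * dense_n / n_points).astype(int)
    return dense[idx]


def interpolate_control_points(
    lower: Contour, upper: Contour, z: float, n_points: int = 32
) -> np.ndarray:
    """Control points on the slice at position ``z`` between two key contours.

    Both key contours are resampled to ``n_points`` matched points and
    blended linearly with weight ``(z - z_lower) / (z_upper - z_lower)``.
    """
    if not (lower.slice_z < z < upper.slice_z):
        raise ValueError(
            f"z={z} not strictly between key slices at "
            f"{lower.slice_z} and {upper.slice_z}"
        )
    a = resample_closed_contour(lower.vertices, n_points)
    b = resample_closed_contour(upper.vertices, n_points)
    t = (z - lower.slice_z) / (upper.slice_z - lower.slice_z)
    return (1.0 - t) * a + t * b


def estimate_initial_contour(
    points: np.ndarray, band_half_width: float = 10.0
) -> Trajectory:
    """Closed trajectory through interpolated control points, in order.

    The polygon must be simple; a self-intersecting estimate indicates a
    failed correspondence between the key contours and is rejected.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 control points")
    poly = Polygon(pts)
    if (not poly.is_valid) or poly.area == 0:
        raise ValueError("control points form a degenerate or self-intersecting polygon")
    return Trajectory(points=pts, closed=True, band_half_width=band_half_width)


def detect_between_slices(
    volume: list[SliceImage],
    key_set: LesionContourSet,
    weights: tuple[float, float, float] = (0.43, 0.14, 0.43),
    band_half_width: float = 10.0,
    n_seeds: int = 8,
    n_points: int = 32,
    log_sigma: float = 1.0,
    zx_gradient_gate: float = 0.10,
) -> LesionContourSet:
    """Fill in contours on every slice between consecutive key slices.

    One two-pass search runs per between-slice; key-slice contours pass
    through unchanged.  ``volume`` is indexed by slice index.
    """
    keys = sorted(key_set.key_slices)
    if len(keys) < 2:
        raise ValueError("need at least 2 key slices to propagate between")
    contours: dict[int, Contour] = {k: key_set.contours[k] for k in keys}
    for lo, hi in zip(keys[:-1], keys[1:]):
        for idx in range(lo + 1, hi):
            if idx >= len(volume) or volume[idx] is None:
                raise ValueError(f"no image data for between-slice {idx}")
            img = volume[idx]
            pts = interpolate_control_points(
                key_set.contours[lo], key_set.contours[hi], img.slice_z, n_points
            )
            traj = estimate_initial_contour(pts, band_half_width)
            fld = compute_cost_field(
                img, weights, log_sigma=log_sigma, zx_gradient_gate=zx_gradient_gate
            )
            contours[idx] = two_pass_contour(img, traj, fld, n_seeds=n_seeds)
    return LesionContourSet(
        contours=contours,
        key_slices=set(keys),
        lesion_id=key_set.lesion_id,
        organ=key_set.organ,
        nodal=key_set.nodal,
    )
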