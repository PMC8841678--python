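"""Band-restricted two-pass optimal-path contouring.

The user sketches a rough closed trajectory near the lesion boundary.
The true boundary is assumed to lie inside a *band* — the set of pixels
within a fixed half-width of the trajectory.  Seed pixels are sampled at
equal arc length along the trajectory and minimum-cost paths are chained
between consecutive seeds inside the band (pass one).  Because the
user-placed seeds are rarely on the boundary, each pass-one segment is
then scanned for its lowest-cost pixel, these become the refined seeds,
and the chained search is repeated (pass two).  The refined seeds sit on
strong edge pixels, so the final contour is insensitive to the exact
trajectory: different sketches whose bands contain the boundary converge
to the same closed path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .image_graph import CostField, SliceImage, shortest_path


@dataclass
class Trajectory:
    """User-drawn polyline in pixel coordinates ``(row, col)``."""

    points: np.ndarray
    closed: bool = True
    band_half_width: float = 10.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (row, col)")
        if len(self.points) == 0:
            raise ValueError("empty trajectory")
        if self.closed and len(self.points) < 3:
            raise ValueError("a closed trajectory needs at least 3 points")
        if self.band_half_width <= 0:
            raise ValueError("band_half_width must be positive")

    def to_dict(self, slice_index: int | None = None) -> dict:
        d = {
            "points": [[float(r), float(c)] for r, c in self.points],
            "closed": self.closed,
            "band_half_width": self.band_half_width,
        }
        if slice_index is not None:
            d["slice_index"] = slice_index
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        return cls(
            points=np.asarray(d["points"], dtype=float),
            closed=bool(d.get("closed", True)),
            band_half_width=float(d.get("band_half_width", 10.0)),
        )


@dataclass
class Contour:
    """Closed polygon on one slice, vertices in pixel coordinates (row, col)."""

    vertices: np.ndarray
    slice_z: float = 0.0
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("spacing must be positive")

    def vertices_mm(self) -> np.ndarray:
        """Vertices scaled to mm, ``(y, x) = (row*sp_row, col*sp_col)``."""
        return self.vertices * np.asarray(self.spacing)

    def to_dict(self) -> dict:
        return {
            "vertices": [[float(r), float(c)] for r, c in self.vertices],
            "slice_z": float(self.slice_z),
            "spacing": [float(self.spacing[0]), float(self.spacing[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Contour":
        return cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            slice_z=float(d.get("slice_z", 0.0)),
            spacing=tuple(d.get("spacing", (1.0, 1.0))),
        )


def rasterize_trajectory(traj: Trajectory) -> list[tuple[int, int]]:
    """Closed 8-connected pixel chain through the trajectory points.

    Consecutive duplicates are removed; for a closed trajectory the chain
    wraps back to its first pixel, which is not repeated at the end.
    """
    pts = np.rint(traj.points).astype(int)
    segments = list(zip(pts[:-1], pts[1:]))
    if traj.closed:
        segments.append((pts[-1], pts[0]))
    chain: list[tuple[int, int]] = []
    for a, b in segments:
        rr, cc = draw_line(a[0], a[1], b[0], b[1])
        for p in zip(rr.tolist(), cc.tolist()):
            if not chain or p != chain[-1]:
                chain.append(p)
    if traj.closed and len(chain) > 1 and chain[-1] == chain[0]:
        chain.pop()
    return chain


def build_band(traj: Trajectory, img_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels within ``band_half_width`` of the trajectory.

    Distances are Euclidean to the rasterized polyline, so the band around
    a single segment is stadium-shaped and around a loop an annulus-like
    corridor, clipped to the image.
    """
    h, w = img_shape
    chain = rasterize_trajectory(traj)
    rows = np.array([p[0] for p in chain])
    cols = np.array([p[1] for p in chain])
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if not inside.any():
        raise ValueError("trajectory lies entirely outside the image")
    on_chain = np.zeros(img_shape, dtype=bool)
    on_chain[rows[inside], cols[inside]] = True
    dist = ndi.distance_transform_edt(~on_chain)
    return dist <= traj.band_half_width


def _chain_arclengths(chain: list[tuple[int, int]], closed: bool) -> np.ndarray:
    pts = np.asarray(chain, dtype=float)
    steps = np.hypot(*(np.diff(pts, axis=0).T))
    if closed:
        wrap = np.hypot(*(pts[0] - pts[-1]))
        steps = np.append(steps, wrap)
    return np.concatenate([[0.0], np.cumsum(steps)])


def select_seeds(traj: Trajectory, n_seeds: int) -> list[tuple[int, int]]:
    """Seed pixels at equal arc-length intervals along the trajectory.

    The first seed is the trajectory start; subsequent seeds are the chain
    pixels nearest (from below) to each arc-length quantile.
    """
    chain = rasterize_trajectory(traj)
    if n_seeds > len(chain):
        raise ValueError(
            f"n_seeds={n_seeds} exceeds trajectory pixel count {len(chain)}"
        )
    if n_seeds == len(chain):
        return list(chain)
    cum = _chain_arclengths(chain, traj.closed)
    total = cum[-1]
    seeds = []
    prev = -1
    for k in range(n_seeds):
        target = total * k / n_seeds if traj.closed else total * k / max(n_seeds - 1, 1)
        i = int(np.searchsorted(cum[: len(chain)], target, side="left"))
        # advance strictly so seeds are distinct chain pixels
        i = min(max(i, prev + 1), len(chain) - 1)
        prev = i
        seeds.append(chain[i])
    return seeds


def _refine_seed(
    segment: list[tuple[int, int]], node_cost: np.ndarray
) -> tuple[int, int]:
    """Lowest node-cost pixel of a path segment; ties -> row-major order."""
    best = segment[0]
    best_key = (node_cost[best], best)
    for p in segment[1:]:
        key = (node_cost[p], p)
        if key < best_key:
            best, best_key = p, key
    return best


def _chain_paths(
    field: CostField,
    seeds: list[tuple[int, int]],
    band: np.ndarray,
) -> list[list[tuple[int, int]]]:
    """Optimal paths between consecutive seeds (wrapping), inside the band."""
    segments = []
    n = len(seeds)
    for i in range(n):
        a, b = seeds[i], seeds[(i + 1) % n]
        try:
            segments.append(shortest_path(field, a, b, mask=band))
        except ValueError as exc:
            raise ValueError(
                f"search band disconnects consecutive seeds {a} and {b}"
            ) from exc
    return segments


def _concatenate_cycle(segments: list[list[tuple[int, int]]]) -> list[tuple[int, int]]:
    cycle: list[tuple[int, int]] = []
    for seg in segments:
        for p in seg[:-1]:  # each segment ends where the next begins
            if not cycle or p != cycle[-1]:
                cycle.append(p)
    while len(cycle) > 1 and cycle[-1] == cycle[0]:
        cycle.pop()
    return cycle


def two_pass_contour(
    img: SliceImage,
    traj: Trajectory,
    field: CostField,
    n_seeds: int = 8,
    forced_seeds: dict[int, tuple[int, int]] | None = None,
) -> Contour:
    """Closed lesion contour from a rough trajectory by two-pass search.

    Pass one chains band-restricted optimal paths through seeds sampled on
    the trajectory.  Pass two replaces each seed segment's weakest link:
    the pixel with the lowest node-local cost in every pass-one segment
    becomes a refined seed, and the chained search is re-run through the
    refined seeds.  ``forced_seeds`` maps segment index to a pixel that
    overrides the automatically refined seed there (interactive
    correction); the pixel must lie inside the band.
    """
    if not traj.closed:
        raise ValueError("only closed trajectories are supported")
    band = build_band(traj, field.shape)
    seeds = select_seeds(traj, n_seeds)

    pass1 = _chain_paths(field, seeds, band)

    node_cost = field.node_cost()
    refined = [_refine_seed(seg, node_cost) for seg in pass1]
    if forced_seeds:
        for i, px in forced_seeds.items():
            px = (int(px[0]), int(px[1]))
            if not band[px]:
                raise ValueError(f"forced seed {px} lies outside the band")
            refined[i] = px
    # adjacent segments may refine to the same strong pixel; collapse
    deduped: list[tuple[int, int]] = []
    for p in refined:
        if p not in deduped:
            deduped.append(p)
    if len(deduped) < 3:
        raise ValueError("refined seeds collapsed onto fewer than 3 pixels")

    pass2 = _chain_paths(field, deduped, band)
    cycle = _concatenate_cycle(pass2)
    return Contour(
        vertices=np.asarray(cycle, dtype=float),
        slice_z=img.slice_z,
        spacing=(img.spacing_row, img.spacing_col),
    )


def smooth_contour(contour: Contour, window: int = 5) -> Contour:
    """Circular moving-average smoothing of a pixel-chain contour.

    A digital boundary quantizes the true curve to pixel centers, and the
    maximum-distance diameter is biased upward by the resulting half-pixel
    spikes.  Averaging each vertex with its ``window`` cyclic neighbours
    suppresses that quantization noise while moving a smooth boundary by
    far less than a pixel (the curvature-induced shrinkage of the window
    is second order).  The result is a polygon, no longer a pixel chain.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    v = contour.vertices
    if window == 1 or len(v) <= window:
        return contour
    half = window // 2
    ext = np.vstack([v[-half:], v, v[:half]])
    kernel = np.ones(window) / window
    smoothed = np.column_stack(
        [np.convolve(ext[:, 0], kernel, "valid"), np.convolve(ext[:, 1], kernel, "valid")]
    )
    return Contour(vertices=smoothed, slice_z=contour.slice_z, spacing=contour.spacing)


# --- JSON round-trips -------------------------------------------------------

def save_trajectories(trajs: dict[int, Trajectory], path: str | Path) -> None:
    data = [t.to_dict(slice_index=i) for i, t in sorted(trajs.items())]
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def load_trajectories(path: str | Path) -> dict[int, Trajectory]:
    data = json.loads(Path(path).read_text())
    return {int(d["slice_index"]): Trajectory.from_dict(d) for d in data}
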