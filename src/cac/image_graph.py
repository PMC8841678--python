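"""Pixel-graph representation of a CT slice and minimum-cost path search.

A transversal slice is modelled as an 8-connected weighted bi-directed
graph whose nodes are pixels.  The cost of traversing a link from pixel
``u`` into pixel ``v`` combines three edge features evaluated at ``v``:

* ``S_zx(v)`` — Laplacian zero-crossing: 0 on pixels where the discrete
  Laplacian changes sign against a 4-neighbour (with ``|L|`` locally
  minimal across the crossing), 1 elsewhere;
* ``S_g(v)`` — inverted normalized gradient magnitude ``1 - G/max(G)``,
  so strong edges are cheap;
* ``S_d(u, v)`` — gradient-direction term penalizing links that are not
  perpendicular to the local gradient (a boundary runs perpendicular to
  the gradient).

``c(u, v) = w_zx * S_zx(v) + w_g * S_g(v) * len(u, v) + w_d * S_d(u, v)``

where ``len`` scales the gradient term of diagonal links so that cost
accrues per unit geometric length.  An object boundary then coincides
with a minimum-cost path, which Dijkstra's algorithm finds as a tree of
optimal paths rooted at a seed pixel.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

# 8-neighbourhood offsets in row-major order; index into the link-cost stack.
OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

_EPS_GRAD = 1e-12


@dataclass
class SliceImage:
    """One 2D transversal CT slice in Hounsfield units.

    ``pixels[row, col]`` holds HU values; ``spacing_row``/``spacing_col``
    are the physical pixel sizes in mm and ``slice_z`` the position of the
    slice along the scan axis in mm.
    """

    pixels: np.ndarray
    spacing_row: float = 1.0
    spacing_col: float = 1.0
    slice_z: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if self.spacing_row <= 0 or self.spacing_col <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CostField:
    """Per-pixel local-cost features realizing the link cost ``c(u, v)``."""

    s_zx: np.ndarray
    s_g: np.ndarray
    grad_row: np.ndarray
    grad_col: np.ndarray
    weights: tuple[float, float, float]
    diagonal_scale: float = math.sqrt(2.0)
    _stack: np.ndarray | None = field(default=None, repr=False, compare=False)
    _node_cost: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for a in (self.s_zx, self.s_g):
            if a.min() < 0 or a.max() > 1:
                raise ValueError("cost features must lie in [0, 1]")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.s_g.shape

    def node_cost(self) -> np.ndarray:
        """Node-local part of the cost, ``w_zx*S_zx + w_g*S_g``.

        Used to rank pixels along a path when refining seeds; the
        direction term is link-based and therefore excluded.
        """
        if self._node_cost is None:
            w_zx, w_g, _ = self.weights
            self._node_cost = w_zx * self.s_zx + w_g * self.s_g
        return self._node_cost

    def link_cost_stack(self) -> np.ndarray:
        """``stack[k, r, c]`` = cost of the link from ``(r, c)`` into its
        ``OFFSETS[k]`` neighbour; ``inf`` where the neighbour falls outside
        the image.  Computed once, vectorized, then reused by every search.
        """
        if self._stack is not None:
            return self._stack
        h, w = self.shape
        w_zx, w_g, w_d = self.weights

        gmag = np.hypot(self.grad_row, self.grad_col)
        safe = np.where(gmag > _EPS_GRAD, gmag, 1.0)
        # Boundary direction = gradient rotated by 90 degrees (unit vectors;
        # zero where the gradient vanishes, which yields a neutral mid cost).
        nz = gmag > _EPS_GRAD
        d_row = np.where(nz, -self.grad_col / safe, 0.0)
        d_col = np.where(nz, self.grad_row / safe, 0.0)

        stack = np.full((len(OFFSETS), h, w), np.inf)
        for k, (dr, dc) in enumerate(OFFSETS):
            length = math.hypot(dr, dc)
            lr, lc = dr / length, dc / length
            # features at v = u + offset, aligned onto u's grid
            s_zx_v = _shift(self.s_zx, dr, dc)
            s_g_v = _shift(self.s_g, dr, dc)
            d_row_v = _shift(d_row, dr, dc)
            d_col_v = _shift(d_col, dr, dc)

            # Bidirectional link vector: orient along the boundary direction
            # at u so the angle terms land in a fixed range.
            dp = d_row * lr + d_col * lc
            sign = np.where(dp >= 0, 1.0, -1.0)
            dp = np.abs(dp)
            dq = sign * (d_row_v * lr + d_col_v * lc)
            s_d = (2.0 / (3.0 * math.pi)) * (
                np.arccos(np.clip(dp, -1, 1)) + np.arccos(np.clip(dq, -1, 1))
            )

            len_scale = self.diagonal_scale if (dr != 0 and dc != 0) else 1.0
            cost = w_zx * s_zx_v + w_g * s_g_v * len_scale + w_d * s_d
            # invalidate links leaving the image
            rows = np.arange(h)[:, None] + dr
            cols = np.arange(w)[None, :] + dc
            valid = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
            stack[k] = np.where(valid, cost, np.inf)
        self._stack = stack
        return stack


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Value of ``a`` at ``(r+dr, c+dc)`` placed at ``(r, c)``; edge padded."""
    padded = np.pad(a, 1, mode="edge")
    h, w = a.shape
    return padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]


@dataclass
class PathTree:
    """Tree of minimum-cost paths from one seed pixel to every reachable pixel.

    ``parent`` holds the flat index of each pixel's predecessor (-1 at the
    seed and at unreachable pixels); ``cum_cost`` the minimal cumulative
    cost from the seed (``inf`` where unreachable).
    """

    seed: tuple[int, int]
    parent: np.ndarray
    cum_cost: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.cum_cost.shape

    def reachable(self, pixel: tuple[int, int]) -> bool:
        return bool(np.isfinite(self.cum_cost[pixel]))


def compute_cost_field(
    img: SliceImage,
    weights: tuple[float, float, float] = (0.43, 0.14, 0.43),
    diagonal_scale: float = math.sqrt(2.0),
    log_sigma: float = 1.0,
    zx_gradient_gate: float = 0.10,
) -> CostField:
    """Derive the local-cost features of a slice.

    Gradients use the 3x3 Sobel operator and the zero-crossing feature the
    Laplacian of a Gaussian-smoothed image (sigma ``log_sigma``), both with
    edge replication at the image border.  A zero-crossing only counts
    where the local gradient magnitude exceeds ``zx_gradient_gate`` times
    its image maximum — the standard edge-strength gate that stops flat
    noisy regions from producing spurious crossings.  Features are
    computed on raw HU values; display window/level settings never enter.
    A constant image has no edges anywhere: ``S_g`` and ``S_zx`` are all
    ones and every path is equally expensive.
    """
    pix = img.pixels
    if pix.shape[0] < 3 or pix.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for kernel support")

    grad_row = ndi.sobel(pix, axis=0, mode="nearest")
    grad_col = ndi.sobel(pix, axis=1, mode="nearest")
    gmag = np.hypot(grad_row, grad_col)
    gmax = gmag.max()
    s_g = np.ones_like(gmag) if gmax <= _EPS_GRAD else 1.0 - gmag / gmax

    smoothed = ndi.gaussian_filter(pix, log_sigma) if log_sigma > 0 else pix
    lap = ndi.laplace(smoothed, mode="nearest")
    crossing = np.zeros(pix.shape, dtype=bool)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        lap_n = _shift(lap, dr, dc)
        sign_change = lap * lap_n < 0
        local_min = np.abs(lap) <= np.abs(lap_n)
        exact_zero = (lap == 0) & (lap_n != 0)
        crossing |= (sign_change & local_min) | exact_zero
    crossing &= gmag > zx_gradient_gate * gmax
    s_zx = np.where(crossing, 0.0, 1.0)

    return CostField(
        s_zx=s_zx,
        s_g=s_g,
        grad_row=grad_row,
        grad_col=grad_col,
        weights=tuple(float(w) for w in weights),
        diagonal_scale=diagonal_scale,
    )


def link_cost(field: CostField, u: tuple[int, int], v: tuple[int, int]) -> float:
    """Cost of the directed link from pixel ``u`` into 8-neighbour ``v``."""
    dr, dc = v[0] - u[0], v[1] - u[1]
    if (dr, dc) not in OFFSETS:
        raise ValueError(f"{u} and {v} are not 8-neighbours")
    k = OFFSETS.index((dr, dc))
    return float(field.link_cost_stack()[k][u])


def shortest_path_tree(
    field: CostField,
    seed: tuple[int, int],
    mask: np.ndarray | None = None,
) -> PathTree:
    """Dijkstra's algorithm from ``seed`` over the whole graph (or band).

    Pixels outside ``mask`` are unreachable.  Ties on cumulative cost are
    broken by path length (fewer steps) and then by row-major pixel index,
    so the tree is platform-independent and two runs on identical inputs
    are bit-identical.
    """
    parent, cum = _dijkstra(field, seed, mask, target=None)
    return PathTree(seed=tuple(seed), parent=parent, cum_cost=cum)


def extract_path(tree: PathTree, target: tuple[int, int]) -> list[tuple[int, int]]:
    """Seed-to-target pixel sequence read off the tree's parent links."""
    if not tree.reachable(tuple(target)):
        raise ValueError(f"target {tuple(target)} is unreachable from seed {tree.seed}")
    h, w = tree.shape
    path = []
    idx = target[0] * w + target[1]
    while idx >= 0:
        path.append((idx // w, idx % w))
        idx = int(tree.parent[idx // w, idx % w])
    path.reverse()
    if path[0] != tuple(tree.seed):  # pragma: no cover - structural invariant
        raise RuntimeError("parent chain did not terminate at the seed")
    return path


def shortest_path(
    field: CostField,
    source: tuple[int, int],
    target: tuple[int, int],
    mask: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Minimum-cost pixel path from ``source`` to ``target``.

    Early-exits once the target is settled, which is what the interactive
    band search uses between consecutive seeds.
    """
    parent, cum = _dijkstra(field, source, mask, target=tuple(target))
    h, w = field.shape
    if not np.isfinite(cum[tuple(target)]):
        raise ValueError(f"no path from {tuple(source)} to {tuple(target)} within the band")
    tree = PathTree(seed=tuple(source), parent=parent, cum_cost=cum)
    return extract_path(tree, tuple(target))


def _dijkstra(
    field: CostField,
    seed: tuple[int, int],
    mask: np.ndarray | None,
    target: tuple[int, int] | None,
) -> tuple[np.ndarray, np.ndarray]:
    h, w = field.shape
    sr, sc = int(seed[0]), int(seed[1])
    if not (0 <= sr < h and 0 <= sc < w):
        raise ValueError(f"seed {seed} outside image of shape {(h, w)}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ValueError("mask shape must match the cost field")
        if not mask[sr, sc]:
            raise ValueError(f"seed {seed} lies outside the search band")

    stack = field.link_cost_stack()
    flat_stack = stack.reshape(len(OFFSETS), -1)
    in_mask = np.ones(h * w, dtype=bool) if mask is None else mask.ravel()

    cum = np.full(h * w, np.inf)
    hops = np.full(h * w, np.iinfo(np.int64).max, dtype=np.int64)
    parent = np.full(h * w, -1, dtype=np.int64)
    done = np.zeros(h * w, dtype=bool)

    start = sr * w + sc
    cum[start] = 0.0
    hops[start] = 0
    heap: list[tuple[float, int, int]] = [(0.0, 0, start)]
    target_idx = None if target is None else target[0] * w + target[1]

    push = heapq.heappush
    pop = heapq.heappop
    offsets = [(dr * w + dc, dr, dc) for dr, dc in OFFSETS]

    while heap:
        cost, nh, idx = pop(heap)
        if done[idx]:
            continue
        done[idx] = True
        if idx == target_idx:
            break
        r, c = idx // w, idx % w
        for k, (flat_off, dr, dc) in enumerate(offsets):
            nr, nc = r + dr, c + dc
            if nr < 0 or nr >= h or nc < 0 or nc >= w:
                continue
            nidx = idx + flat_off
            if done[nidx] or not in_mask[nidx]:
                continue
            new_cost = cost + flat_stack[k, idx]
            new_hops = nh + 1
            # ties on cumulative cost resolved by fewer steps, then by the
            # smaller row-major parent index: deterministic everywhere
            if (
                new_cost < cum[nidx]
                or (
                    new_cost == cum[nidx]
                    and (
                        new_hops < hops[nidx]
                        or (new_hops == hops[nidx] and idx < parent[nidx])
                    )
                )
            ):
                cum[nidx] = new_cost
                hops[nidx] = new_hops
                parent[nidx] = idx
                push(heap, (new_cost, new_hops, nidx))

    cum = cum.reshape(h, w)
    parent_grid = parent.reshape(h, w)
    return parent_grid, cum
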