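"""Synthetic CT-like phantoms with known lesion boundaries.

Every downstream module is testable without patient data: a phantom is a
rasterized lesion (disk, ellipse, sphere, ellipsoid, or a lobulated shape
with a Fourier-perturbed radius) of known HU contrast on a uniform
background, Gaussian-blurred at the edge and overlaid with additive
Gaussian HU noise.  The analytic boundary polygon per slice and the
analytic longest diameter come along as ground truth.

The module also simulates the two arms of a reader study: jittered mouse
trajectories around the true boundary (the contouring arm) and noisy
two-endpoint diameter placements (the manual arm), so the end-to-end
reproducibility comparison can be run entirely on synthetic lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .config import StudyConfig
from .contour_engine import Contour, Trajectory, smooth_contour, two_pass_contour
from .image_graph import SliceImage, compute_cost_field
from .measurement import longest_diameter
from .volumetric import LesionContourSet

_SHAPES = ("disk", "ellipse", "sphere", "ellipsoid", "lobulated")
_TRUTH_POINTS = 360


@dataclass
class PhantomSpec:
    """Recipe for one synthetic lesion.

    ``size_px`` is the square in-plane image side.  Radii and semi-axes
    are in pixels; ``semi_axes_px`` is (row, col) for planar shapes and
    (row, col, z) for ellipsoids.  ``lobulated`` perturbs a disk radius by
    a low-order Fourier series (``lobulation_modes`` cosine modes of
    relative amplitude ``lobulation_amplitude``).  HU contrast, edge blur
    and noise model the appearance of a soft-tissue lesion on
    contrast-enhanced CT.
    """

    shape: str = "disk"
    size_px: int = 64
    radius_px: float = 15.0
    semi_axes_px: tuple[float, ...] = (20.0, 10.0)
    lobulation_modes: int = 3
    lobulation_amplitude: float = 0.15
    lesion_hu: float = 60.0
    background_hu: float = -100.0
    edge_blur_sigma_px: float = 1.0
    noise_sigma_hu: float = 5.0
    spacing: tuple[float, float] = (1.0, 1.0)
    slice_spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.lesion_hu == self.background_hu:
            raise ValueError("lesion/background contrast must be non-zero")
        if self.size_px < 8:
            raise ValueError("image too small")


@dataclass
class Phantom:
    """Rendered phantom: image volume, ground truth, analytic diameter."""

    volume: list[SliceImage]
    truth: LesionContourSet
    diameter_mm: float
    spec: PhantomSpec = field(repr=False)


def _radius_profile(spec: PhantomSpec, rng: np.random.Generator):
    """Radius as a function of polar angle for planar shapes."""
    if spec.shape == "disk":
        return lambda theta: np.full_like(theta, spec.radius_px, dtype=float)
    if spec.shape == "ellipse":
        a, b = spec.semi_axes_px[0], spec.semi_axes_px[1]

        def r_ellipse(theta):
            # polar radius of an ellipse with semi-axes a (row) and b (col)
            return (a * b) / np.sqrt(
                (b * np.sin(theta)) ** 2 + (a * np.cos(theta)) ** 2
            )

        return r_ellipse
    if spec.shape == "lobulated":
        amps = rng.normal(0.0, 1.0, spec.lobulation_modes)
        phases = rng.uniform(0.0, 2 * np.pi, spec.lobulation_modes)
        scale = spec.lobulation_amplitude / max(np.abs(amps).sum(), 1e-12)

        def r_lobulated(theta):
            pert = sum(
                scale * amps[k] * np.cos((k + 1) * theta + phases[k])
                for k in range(spec.lobulation_modes)
            )
            return spec.radius_px * (1.0 + pert)

        return r_lobulated
    raise ValueError(f"{spec.shape} has no planar radius profile")


def _truth_polygon(radius_fn, center: float, n: int = _TRUTH_POINTS) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = radius_fn(theta)
    rows = center + r * np.sin(theta)
    cols = center + r * np.cos(theta)
    return np.column_stack([rows, cols])


def _rasterize(radius_fn, size: int, center: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    theta = np.arctan2(rr - center, cc - center)
    rad = np.hypot(rr - center, cc - center)
    return rad <= radius_fn(theta)


def render_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom volume with analytic ground truth.

    A fixed ``spec.seed`` gives bit-identical output.  The analytic
    longest diameter is evaluated on a dense boundary polygon in mm; for
    3D shapes the equatorial slice carries it.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size_px
    center = (size - 1) / 2.0

    planar = spec.shape in ("disk", "ellipse", "lobulated")
    if planar:
        radius_fn = _radius_profile(spec, rng)
        max_r = float(np.max(radius_fn(np.linspace(0, 2 * np.pi, 720))))
        if max_r >= center:
            raise ValueError("lesion larger than the image")
        slice_radius_fns = {0: radius_fn}
        z_positions = {0: 0.0}
    else:
        if spec.shape == "sphere":
            a = b = cz = spec.radius_px
        else:
            a, b, cz = spec.semi_axes_px
        if max(a, b) >= center:
            raise ValueError("lesion larger than the image")
        half = int(np.floor(cz - 1.0))
        slice_radius_fns = {}
        z_positions = {}
        for i, dz in enumerate(range(-half, half + 1)):
            frac = np.sqrt(max(1.0 - (dz / cz) ** 2, 0.0))
            ai, bi = a * frac, b * frac

            def r_fn(theta, ai=ai, bi=bi):
                return (ai * bi) / np.sqrt(
                    (bi * np.sin(theta)) ** 2 + (ai * np.cos(theta)) ** 2
                )

            slice_radius_fns[i] = r_fn
            z_positions[i] = dz * spec.slice_spacing_mm

    volume: list[SliceImage] = []
    contours: dict[int, Contour] = {}
    for idx in sorted(slice_radius_fns):
        inside = _rasterize(slice_radius_fns[idx], size, center)
        img = np.where(inside, spec.lesion_hu, spec.background_hu).astype(float)
        if spec.edge_blur_sigma_px > 0:
            img = ndi.gaussian_filter(img, spec.edge_blur_sigma_px)
        if spec.noise_sigma_hu > 0:
            img = img + rng.normal(0.0, spec.noise_sigma_hu, img.shape)
        volume.append(
            SliceImage(
                pixels=img,
                spacing_row=spec.spacing[0],
                spacing_col=spec.spacing[1],
                slice_z=z_positions[idx],
            )
        )
        contours[idx] = Contour(
            vertices=_truth_polygon(slice_radius_fns[idx], center),
            slice_z=z_positions[idx],
            spacing=spec.spacing,
        )

    truth = LesionContourSet(
        contours=contours,
        key_slices=set(contours),
        lesion_id=f"phantom-{spec.shape}",
    )
    diameter = max(
        longest_diameter(c)[0] for c in contours.values()
    )
    return Phantom(volume=volume, truth=truth, diameter_mm=diameter, spec=spec)


def simulate_trajectory(
    truth: Contour,
    jitter_px: float,
    seed: int,
    band_half_width: float = 10.0,
    n_points: int = 120,
) -> Trajectory:
    """A plausible mouse trajectory: the true boundary under smooth jitter.

    The truth polygon is resampled and displaced radially by a smooth
    low-order Fourier field whose maximum magnitude does not exceed
    ``jitter_px``.  Trajectories with jitter at or beyond the band
    half-width may push the boundary outside the band, voiding the
    invariance guarantee; that raises a warning, not an error.
    """
    if jitter_px >= band_half_width:
        warnings.warn(
            "jitter reaches the band half-width; contour invariance is "
            "not guaranteed",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    v = truth.vertices
    n = len(v)
    take = np.linspace(0, n, n_points, endpoint=False).astype(int)
    pts = v[take]
    centroid = pts.mean(axis=0)
    theta = np.arctan2(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])

    if jitter_px > 0:
        modes = 4
        amps = rng.normal(0.0, 1.0, modes)
        phases = rng.uniform(0.0, 2 * np.pi, modes)
        disp = sum(
            amps[k] * np.cos((k + 1) * theta + phases[k]) for k in range(modes)
        )
        peak = np.abs(disp).max()
        if peak > 0:
            disp = disp * (jitter_px * rng.uniform(0.5, 1.0) / peak)
    else:
        disp = np.zeros(n_points)

    radial = np.column_stack([np.sin(theta), np.cos(theta)])
    moved = pts + radial * disp[:, None]
    return Trajectory(points=moved, closed=True, band_half_width=band_half_width)


def simulate_manual_readings(
    true_diameter_mm: float,
    n_readers: int,
    rel_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthetic manual two-endpoint measurements of one lesion.

    Each reader's diameter is the truth scaled by a Gaussian relative
    error, modelling variable endpoint placement and slice choice; the
    relative SD is calibrated so repeated manual readings show the
    dispersion reported for unaided measurements.  Values are floored at
    5% of the truth to stay positive.
    """
    readings = true_diameter_mm * (1.0 + rng.normal(0.0, rel_sigma, n_readers))
    return np.maximum(readings, 0.05 * true_diameter_mm)


def reader_study(
    n_phantoms: int = 50,
    n_readers: int = 5,
    config: StudyConfig | None = None,
    seed: int = 0,
    size_px: int = 64,
    jitter_px: float = 4.0,
) -> dict:
    """Simulated multi-reader study on random phantoms, both arms.

    Per phantom, each simulated reader contributes one contouring
    measurement (a jittered trajectory fed through the two-pass search,
    diameter of the resulting contour) and one manual measurement.
    Returns per-lesion measurement tables and summary statistics: mean CV
    per arm, good-agreement fractions, the fraction of phantoms whose
    reader contours are pixel-identical, and the mean absolute diameter
    error of the contouring arm against the analytic truth.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    cac_rows, man_rows = [], []
    identical = 0
    diam_err_pct = []
    for i in range(n_phantoms):
        shape = "disk" if i % 2 == 0 else "lobulated"
        spec = PhantomSpec(
            shape=shape,
            size_px=size_px,
            radius_px=float(rng.uniform(9.0, 16.0)),
            lobulation_amplitude=0.10,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ph = render_phantom(spec)
        img = ph.volume[0]
        fld = compute_cost_field(
            img,
            cfg.cost_weights,
            cfg.diagonal_scale,
            log_sigma=cfg.log_sigma_px,
            zx_gradient_gate=cfg.zx_gradient_gate,
        )
        truth_c = ph.truth.contours[0]

        contours = []
        for r in range(n_readers):
            traj = simulate_trajectory(
                truth_c,
                jitter_px=jitter_px,
                seed=int(rng.integers(0, 2**31 - 1)),
                band_half_width=cfg.band_half_width_px,
            )
            contours.append(two_pass_contour(img, traj, fld, n_seeds=cfg.n_seeds))
        diams = [
            longest_diameter(smooth_contour(c, cfg.smooth_window))[0]
            for c in contours
        ]
        cac_rows.append(diams)
        pixel_sets = [frozenset(map(tuple, c.vertices.astype(int))) for c in contours]
        if all(s == pixel_sets[0] for s in pixel_sets):
            identical += 1
        diam_err_pct.append(
            100.0 * abs(np.mean(diams) - ph.diameter_mm) / ph.diameter_mm
        )
        man_rows.append(
            simulate_manual_readings(
                ph.diameter_mm, n_readers, cfg.manual_rel_sigma, rng
            )
        )

    cac = np.asarray(cac_rows)
    man = np.asarray(man_rows)
    cac_cv = np.array([cv_safe(row) for row in cac])
    man_cv = np.array([cv_safe(row) for row in man])
    thr = cfg.cv_good_threshold
    return {
        "cac_measurements": cac,
        "manual_measurements": man,
        "cac_mean_cv": float(cac_cv.mean()),
        "manual_mean_cv": float(man_cv.mean()),
        "cac_good_agreement_fraction": float((cac_cv < thr).mean()),
        "manual_good_agreement_fraction": float((man_cv < thr).mean()),
        "trajectory_invariance_fraction": identical / n_phantoms,
        "cac_diameter_mean_abs_error_pct": float(np.mean(diam_err_pct)),
    }


def cv_safe(values: np.ndarray) -> float:
    """CV with an exact zero for identical values (no roundoff residue)."""
    v = np.asarray(values, dtype=float)
    if np.all(v == v[0]):
        return 0.0
    return float(v.std(ddof=1) / v.mean())
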