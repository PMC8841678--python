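"""Image input/output and the end-to-end pipeline.

CT volumes are read from DICOM series (one file per slice, sorted along
the scan axis, Hounsfield rescale applied) or from NIfTI files.  All
in-package processing uses 0-based ``(row, col)`` pixel indices; physical
spacing enters only at measurement time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .config import StudyConfig
from .contour_engine import Trajectory, smooth_contour, two_pass_contour
from .image_graph import SliceImage, compute_cost_field
from .measurement import measure_lesion
from .volumetric import LesionContourSet, detect_between_slices

logger = logging.getLogger("cac")


def read_ct(path: str | Path) -> list[SliceImage]:
    """Read a CT volume as a list of slices sorted along the scan axis.

    A directory is treated as a DICOM series; a file as NIfTI.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def _read_dicom_series(folder: Path) -> list[SliceImage]:
    datasets = []
    for f in sorted(folder.iterdir()):
        if f.is_file():
            try:
                datasets.append(pydicom.dcmread(str(f)))
            except Exception:  # non-DICOM clutter in the folder
                continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {folder}")

    orientations = {
        tuple(np.round(np.asarray(ds.ImageOrientationPatient, dtype=float), 6))
        for ds in datasets
        if hasattr(ds, "ImageOrientationPatient")
    }
    if len(orientations) > 1:
        raise ValueError("mixed-orientation DICOM series are not supported")

    def z_of(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            if orientations:
                row_dir, col_dir = np.asarray(next(iter(orientations))).reshape(2, 3)
                normal = np.cross(row_dir, col_dir)
                return float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(float) * slope + intercept
        sp = getattr(ds, "PixelSpacing", [1.0, 1.0])
        slices.append(
            SliceImage(
                pixels=hu,
                spacing_row=float(sp[0]),
                spacing_col=float(sp[1]),
                slice_z=z_of(ds),
            )
        )
    return slices


def _read_nifti(path: Path) -> list[SliceImage]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D/3D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    slices = []
    for k in range(data.shape[2]):
        slices.append(
            SliceImage(
                pixels=data[:, :, k],
                spacing_row=float(zooms[0]),
                spacing_col=float(zooms[1]),
                slice_z=float(k * zooms[2]),
            )
        )
    return slices


def write_nifti(volume: list[SliceImage], path: str | Path) -> None:
    """Write slices to NIfTI (axis 0 = row, axis 1 = col, axis 2 = slice)."""
    data = np.stack([s.pixels for s in volume], axis=2)
    first = volume[0]
    dz = (
        volume[1].slice_z - volume[0].slice_z
        if len(volume) > 1
        else 1.0
    )
    affine = np.diag([first.spacing_row, first.spacing_col, abs(dz) or 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def run_pipeline(
    config: StudyConfig,
    volume: list[SliceImage],
    trajectories: dict[int, Trajectory],
    lesion_id: str = "lesion",
    nodal: bool = False,
    mode: str = "3D",
) -> dict:
    """Segment key slices, propagate between them, and measure the lesion.

    ``trajectories`` maps key-slice index to the user trajectory on that
    slice.  Returns the contour set and the measurement record; an empty
    trajectory set is a warned no-op.
    """
    logger.info("pipeline config: %s", config.to_json())
    if not trajectories:
        logger.warning("no trajectories supplied; nothing to do")
        return {"contour_set": None, "measurement": None}

    contours = {}
    for idx, traj in sorted(trajectories.items()):
        img = volume[idx]
        field = compute_cost_field(
            img,
            config.cost_weights,
            config.diagonal_scale,
            log_sigma=config.log_sigma_px,
            zx_gradient_gate=config.zx_gradient_gate,
        )
        contours[idx] = two_pass_contour(img, traj, field, n_seeds=config.n_seeds)
        logger.info("segmented key slice %d (%d boundary pixels)", idx, len(contours[idx].vertices))

    key_set = LesionContourSet(
        contours=contours,
        key_slices=set(contours),
        lesion_id=lesion_id,
        nodal=nodal,
    )
    if len(key_set.key_slices) >= 2:
        full_set = detect_between_slices(
            volume,
            key_set,
            weights=config.cost_weights,
            band_half_width=config.band_half_width_px,
            n_seeds=config.n_seeds,
            n_points=config.interp_n_points,
            log_sigma=config.log_sigma_px,
            zx_gradient_gate=config.zx_gradient_gate,
        )
    else:
        full_set = key_set
    smoothed = LesionContourSet(
        contours={
            i: smooth_contour(c, config.smooth_window)
            for i, c in full_set.contours.items()
        },
        key_slices=full_set.key_slices,
        lesion_id=full_set.lesion_id,
        nodal=full_set.nodal,
    )
    record = measure_lesion(smoothed, mode=mode)
    logger.info(
        "lesion %s: longest diameter %.2f mm (slice %d)",
        lesion_id,
        record.longest_diameter_mm,
        record.slice_index,
    )
    return {"contour_set": full_set, "measurement": record}
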