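"""RECIST 1.1 tumor-response classification from target-lesion measurements.

Per timepoint the sum of diameters over the target lesions (longest
diameter for extranodal disease, short axis for nodes) is compared with
the baseline sum and the nadir (smallest sum recorded so far):

* **CR** — all target lesions disappeared (sum 0; lymph nodes below
  10 mm short axis count as disappeared when nodal normalization is on);
* **PD** — at least a 20% increase over the nadir that is also at least
  5 mm absolute;
* **PR** — at least a 30% decrease from baseline (and not PD);
* **SD** — neither.

Exactly one category applies to every evaluation.  New lesions and
non-target disease are out of scope; classification works on target-lesion
sums only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import StudyConfig
from .measurement import MeasurementRecord

CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass
class ResponseRecord:
    patient_id: str
    timepoint: int
    sum_of_diameters_mm: float
    baseline_sum_mm: float
    nadir_sum_mm: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")


def sum_target_diameters(
    records: list[MeasurementRecord],
    max_lesions: int = 5,
    max_per_organ: int = 2,
) -> float:
    """Sum of RECIST diameters over the target lesions, in mm.

    RECIST 1.1 allows up to 5 target lesions with at most 2 per organ;
    violations on input data raise a warning (and the largest lesions are
    kept up to the limits), not an error, since follow-up tables sometimes
    carry extras.
    """
    if not records:
        raise ValueError("no target-lesion measurements at this timepoint")
    records = sorted(records, key=lambda r: -r.recist_value_mm)
    kept: list[MeasurementRecord] = []
    per_organ: dict[str, int] = {}
    dropped = 0
    for rec in records:
        organ = rec.organ or rec.lesion_id
        if len(kept) >= max_lesions or per_organ.get(organ, 0) >= max_per_organ:
            dropped += 1
            continue
        kept.append(rec)
        per_organ[organ] = per_organ.get(organ, 0) + 1
    if dropped:
        warnings.warn(
            f"{len(records)} lesions supplied; keeping the {len(kept)} largest "
            f"per the {max_lesions}-lesion / {max_per_organ}-per-organ rule",
            stacklevel=2,
        )
    return float(sum(r.recist_value_mm for r in kept))


def classify_response(
    current,
    baseline,
    nadir,
    pr_threshold: float = 0.30,
    pd_threshold: float = 0.20,
    pd_min_increase_mm: float = 5.0,
    cr_sum_mm: float = 0.0,
):
    """RECIST 1.1 category for a diameter sum (scalar or array, mm).

    Precedence: disappearance (CR), then progression (PD), then response
    (PR), else SD.  With a zero current sum progression cannot fire (the
    absolute-increase floor requires growth), so the categories partition
    every admissible input.
    """
    scalar = np.isscalar(current) and np.isscalar(baseline) and np.isscalar(nadir)
    current = np.atleast_1d(np.asarray(current, dtype=float))
    baseline_a = np.atleast_1d(np.asarray(baseline, dtype=float))
    nadir_a = np.atleast_1d(np.asarray(nadir, dtype=float))
    if np.any(current < 0) or np.any(baseline_a <= 0) or np.any(nadir_a < 0):
        raise ValueError("diameter sums must be non-negative (baseline positive)")
    if np.any(nadir_a > baseline_a):
        raise ValueError("nadir cannot exceed baseline")

    cr = current <= cr_sum_mm
    growth = current - nadir_a
    pd = (~cr) & (growth >= pd_threshold * nadir_a) & (growth >= pd_min_increase_mm)
    pr = (~cr) & (~pd) & (baseline_a - current >= pr_threshold * baseline_a)

    shape = np.broadcast(current, baseline_a, nadir_a).shape
    out = np.full(shape, "SD", dtype="<U2")
    out[np.broadcast_to(cr, shape)] = "CR"
    out[np.broadcast_to(pd, shape)] = "PD"
    out[np.broadcast_to(pr, shape)] = "PR"
    if scalar:
        return str(out[0])
    return out


def evaluate_patient(
    measurements_by_timepoint: dict[int, list[MeasurementRecord]],
    patient_id: str = "",
    config: StudyConfig | None = None,
) -> list[ResponseRecord]:
    """Classify every follow-up timepoint of one patient.

    The first timepoint is the baseline; the nadir is tracked as the
    minimum sum at or after baseline.  Lesions must be present at every
    timepoint (the sum is otherwise not comparable) — a missing lesion is
    an error.  With nodal normalization on, a timepoint where every
    extranodal lesion measures 0 and every node is below the nodal CR
    cut-off is complete response even though the sum is positive (unless
    it is progression).
    """
    cfg = config or StudyConfig()
    timepoints = sorted(measurements_by_timepoint)
    if len(timepoints) < 2:
        raise ValueError("need a baseline and at least one follow-up timepoint")
    baseline_records = measurements_by_timepoint[timepoints[0]]
    baseline_ids = {r.lesion_id for r in baseline_records}
    baseline = sum_target_diameters(baseline_records)
    nadir = baseline

    out: list[ResponseRecord] = []
    for tp in timepoints[1:]:
        records = measurements_by_timepoint[tp]
        ids = {r.lesion_id for r in records}
        if ids != baseline_ids:
            missing = sorted(baseline_ids - ids)
            raise ValueError(
                f"timepoint {tp}: target lesions missing or added "
                f"(missing: {missing})"
            )
        current = sum_target_diameters(records)
        category = classify_response(
            current,
            baseline,
            nadir,
            pr_threshold=cfg.pr_threshold,
            pd_threshold=cfg.pd_threshold,
            pd_min_increase_mm=cfg.pd_min_increase_mm,
            cr_sum_mm=cfg.cr_sum_mm,
        )
        if cfg.nodal_cr_normalization and category != "PD":
            extranodal_gone = all(
                r.recist_value_mm == 0 for r in records if not r.nodal
            )
            nodes_normal = all(
                r.recist_value_mm < cfg.nodal_cr_short_axis_mm
                for r in records
                if r.nodal
            )
            if extranodal_gone and nodes_normal and any(r.nodal for r in records):
                category = "CR"
        out.append(
            ResponseRecord(
                patient_id=patient_id,
                timepoint=tp,
                sum_of_diameters_mm=current,
                baseline_sum_mm=baseline,
                nadir_sum_mm=nadir,
                category=str(category),
            )
        )
        nadir = min(nadir, current)
    return out
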