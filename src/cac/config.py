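"""Study-wide configuration.

All tunable parameters of the contouring pipeline and of the downstream
statistics live in a single serializable :class:`StudyConfig` so that a
complete run can be reproduced from one declarative file.  Every stage
receives its parameters from here; nothing reads global state.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class StudyConfig:
    """Resolved parameters for a contouring + evaluation study.

    Attributes
    ----------
    cost_weights:
        ``(w_zx, w_g, w_d)`` weights of the Laplacian zero-crossing,
        gradient-magnitude and gradient-direction terms of the local link
        cost.  Defaults follow the classical intelligent-scissors
        formulation.
    diagonal_scale:
        Factor applied to the gradient-magnitude term of diagonal links so
        that cost accrues per unit geometric length rather than per step
        (``sqrt(2)`` for an 8-connected grid).
    log_sigma_px:
        Gaussian smoothing (pixels) applied before the Laplacian when
        detecting zero-crossings.
    zx_gradient_gate:
        Fraction of the maximum gradient magnitude a pixel must carry for
        a Laplacian sign change there to count as an edge crossing;
        suppresses spurious crossings in flat noisy regions.
    smooth_window:
        Odd cyclic moving-average window (vertices) applied to detected
        pixel-chain contours before measurement, suppressing pixel
        quantization spikes.
    band_half_width_px:
        Half-width of the search band around the user trajectory, in pixels.
    n_seeds:
        Number of seed points sampled at equal arc length along the
        trajectory for the two-pass optimal-path search.
    interp_n_points:
        Number of control points used when interpolating contours between
        key slices.
    pr_threshold / pd_threshold / pd_min_increase_mm / cr_sum_mm:
        RECIST 1.1 response cut-offs: partial response requires a
        ``pr_threshold`` fractional decrease from baseline; progression a
        ``pd_threshold`` fractional increase over the nadir that is also at
        least ``pd_min_increase_mm`` absolute; complete response a diameter
        sum of at most ``cr_sum_mm``.
    nodal_cr_normalization:
        Whether lymph nodes shrinking below 10 mm short axis are compatible
        with complete response even though their measured sum is non-zero.
    icc_variant:
        ``"icc3"`` (two-way mixed, consistency) or ``"icc2"`` (two-way
        random, absolute agreement), single measures.
    cv_good_threshold:
        Coefficient-of-variation cut-off below which a set of repeated
        measurements counts as "good agreement" (strict inequality).
    manual_rel_sigma:
        Relative standard deviation of the simulated manual
        endpoint-placement measurement (synthetic reader model).
    seed:
        Root RNG seed; all randomness in a run flows from it.
    """

    cost_weights: tuple[float, float, float] = (0.43, 0.14, 0.43)
    diagonal_scale: float = math.sqrt(2.0)
    log_sigma_px: float = 1.0
    zx_gradient_gate: float = 0.10
    smooth_window: int = 7
    band_half_width_px: float = 10.0
    n_seeds: int = 8
    interp_n_points: int = 32
    pr_threshold: float = 0.30
    pd_threshold: float = 0.20
    pd_min_increase_mm: float = 5.0
    cr_sum_mm: float = 0.0
    nodal_cr_normalization: bool = True
    nodal_cr_short_axis_mm: float = 10.0
    icc_variant: str = "icc3"
    cv_good_threshold: float = 0.20
    manual_rel_sigma: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        self.cost_weights = tuple(float(w) for w in self.cost_weights)
        if len(self.cost_weights) != 3 or any(w < 0 for w in self.cost_weights):
            raise ValueError("cost_weights must be three non-negative reals")
        if self.band_half_width_px <= 0:
            raise ValueError("band_half_width_px must be positive")
        if self.n_seeds < 3:
            raise ValueError("n_seeds must be at least 3 for a closed contour")
        if self.icc_variant not in ("icc3", "icc2"):
            raise ValueError("icc_variant must be 'icc3' or 'icc2'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


DEFAULT_CONFIG = StudyConfig()
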