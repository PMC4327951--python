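"""Parametric generator of scoliotic back-surface scans with known truth.

No public scan repository exists for laser-profilometry back scans, so every
detection and statistics stage in this package is validated against surfaces
generated here.  The model reproduces the morphology the method exploits:

* an elliptic-cylinder torso section (convex toward the camera),
* a smooth sagittal offset s(X) giving the double-S kyphosis/lordosis shape,
* the posterior median furrow: a Gaussian depression of depth
  ``furrow_depth_mm`` and lateral half-width ``furrow_halfwidth_mm`` whose
  centerline c(X) is the ground-truth spine curve.  The furrow depth tapers
  linearly to 30% over the cranial quarter of the scan, mimicking the real
  furrow fading above the shoulder blades (which is what forces the ROI
  reduction in X before RMSD comparison),
* a dark marker line in the brightness channel, laterally offset from c(X)
  by ``marker_offset_mm`` to emulate palpation error (palpating the midpoint
  of a spinous process is only accurate to ~9.8 mm, the mean process width),
* independent Gaussian sensor noise on Z, default SD 0.1 mm — the stated
  single-point accuracy of the scanner.

Default sampling emulates the scanner: 0.9 mm profile spacing over a 700-row
sweep and 1 mm lateral sampling over a 300 mm field.

The lateral centerline c(X) and sagittal offset s(X) are polynomials in the
normalized coordinate t = X / X_max (coefficients lowest order first); the
defaults give a single-lobe ~10 mm lateral scoliotic deviation and a ±4 mm
double-S sagittal profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surface_model import BackScan
from .curve3d import Curve3D

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_scan",
    "ground_truth_curve",
    "simulate_repeat_curve_pairs",
]

#: taper of the furrow depth over the cranial quarter of rows
_TAPER_START = 0.75
_TAPER_FLOOR = 0.30


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic scan.  All lengths in mm."""

    n_rows: int = 700
    n_cols: int = 300
    profile_spacing_mm: float = 0.9
    col_spacing_mm: float = 1.0
    torso_half_width_mm: float = 200.0
    torso_depth_mm: float = 40.0
    sagittal_profile: tuple = (0.0, 40.0, -120.0, 80.0)
    spine_curve: tuple = (0.0, 100.0, -300.0, 200.0)
    furrow_depth_mm: float = 4.0
    furrow_halfwidth_mm: float = 10.0
    marker_offset_mm: float = 0.0
    marker_halfwidth_mm: float = 6.0
    marker_contrast: float = 0.95
    noise_sd_mm: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError("grid must be at least 3x3")
        for name in ("profile_spacing_mm", "col_spacing_mm",
                     "torso_half_width_mm", "torso_depth_mm",
                     "furrow_halfwidth_mm", "marker_halfwidth_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.furrow_depth_mm < 0:
            raise ValueError("furrow_depth_mm must be >= 0")
        if self.furrow_halfwidth_mm >= self.torso_half_width_mm:
            raise ValueError("furrow wider than the torso")
        if not 0.0 <= self.marker_contrast <= 1.0:
            raise ValueError("marker_contrast must lie in [0, 1]")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    # -- analytic pieces ----------------------------------------------------

    @property
    def x_rows(self) -> np.ndarray:
        return np.arange(self.n_rows) * self.profile_spacing_mm

    @property
    def y_cols(self) -> np.ndarray:
        return (np.arange(self.n_cols) - (self.n_cols - 1) / 2) \
            * self.col_spacing_mm

    def _t(self, x: np.ndarray) -> np.ndarray:
        x_max = (self.n_rows - 1) * self.profile_spacing_mm
        return np.asarray(x, dtype=float) / x_max

    def centerline(self, x: np.ndarray) -> np.ndarray:
        """Lateral spine centerline c(X) in mm."""
        return np.polynomial.polynomial.polyval(self._t(x), self.spine_curve)

    def sagittal_offset(self, x: np.ndarray) -> np.ndarray:
        """Sagittal Z offset s(X) in mm."""
        return np.polynomial.polynomial.polyval(
            self._t(x), self.sagittal_profile)

    def furrow_depth_at(self, x: np.ndarray) -> np.ndarray:
        """Effective furrow depth, tapering cranially to 30%."""
        t = self._t(x)
        frac = np.clip((t - _TAPER_START) / (1.0 - _TAPER_START), 0.0, 1.0)
        return self.furrow_depth_mm * (1.0 - (1.0 - _TAPER_FLOOR) * frac)

    def torso_section(self, y: np.ndarray) -> np.ndarray:
        """Elliptic torso cross-section Z(Y), clipped at the torso edge."""
        r = np.clip(1.0 - (np.asarray(y) / self.torso_half_width_mm) ** 2,
                    0.0, None)
        return self.torso_depth_mm * np.sqrt(r)

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Noise-free analytic surface Z(X, Y); x, y broadcast together."""
        c = self.centerline(x)
        depth = self.furrow_depth_at(x)
        furrow = depth * np.exp(-((y - c) ** 2)
                                / (2.0 * self.furrow_halfwidth_mm ** 2))
        return self.torso_section(y) + self.sagittal_offset(x) - furrow

    def brightness_field(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        center = self.centerline(x) + self.marker_offset_mm
        dip = self.marker_contrast * np.exp(
            -((y - center) ** 2) / (2.0 * self.marker_halfwidth_mm ** 2))
        return 1.0 - dip


@dataclass
class GroundTruth:
    """Analytic reference curves of a synthetic scan, one sample per row."""

    spine_curve_3d: np.ndarray   # (n_rows, 3): X, c(X), Z at furrow bottom
    marker_curve_3d: np.ndarray  # (n_rows, 3): marker centerline on surface

    @property
    def x(self) -> np.ndarray:
        return self.spine_curve_3d[:, 0]

    @property
    def spine_y(self) -> np.ndarray:
        return self.spine_curve_3d[:, 1]

    @property
    def marker_y(self) -> np.ndarray:
        return self.marker_curve_3d[:, 1]


def ground_truth_curve(spec: SyntheticSpec) -> GroundTruth:
    """Noise-free evaluation of the spine and marker centerlines per row."""
    x = spec.x_rows
    cy = spec.centerline(x)
    my = cy + spec.marker_offset_mm
    return GroundTruth(
        spine_curve_3d=np.column_stack([x, cy, spec.surface(x, cy)]),
        marker_curve_3d=np.column_stack([x, my, spec.surface(x, my)]),
    )


def generate_scan(spec: SyntheticSpec) -> tuple[BackScan, GroundTruth]:
    """Generate one synthetic scan plus its analytic ground truth.

    The same spec (including seed) always returns bit-identical output.
    """
    x_rows = spec.x_rows
    y_cols = spec.y_cols
    xg = np.broadcast_to(x_rows[:, None], (spec.n_rows, spec.n_cols)).copy()
    yg = np.broadcast_to(y_cols[None, :], (spec.n_rows, spec.n_cols)).copy()
    zg = spec.surface(x_rows[:, None], y_cols[None, :])
    if spec.noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        zg = zg + rng.normal(0.0, spec.noise_sd_mm, zg.shape)
    bg = spec.brightness_field(x_rows[:, None], y_cols[None, :])
    valid = np.abs(yg) < spec.torso_half_width_mm
    scan = BackScan(
        x=xg, y=yg, z=zg, brightness=bg, valid_mask=valid,
        profile_spacing_mm=spec.profile_spacing_mm,
        metadata={"generator": "synthetic_back", "seed": str(spec.seed)},
    )
    return scan, ground_truth_curve(spec)


def simulate_repeat_curve_pairs(
    n_repeats: int,
    posture_sd_mm: float,
    detection_sd_mm: float,
    seed: int,
    spec: SyntheticSpec | None = None,
) -> list[tuple[Curve3D, Curve3D]]:
    """Simulate repeated (manual, auto) curve determinations of one subject.

    Emulates the repeatability experiment of scanning the same person
    ``n_repeats`` times: each repeat r draws one rigid posture shift per
    plane (N(0, posture_sd^2), shared by the manual and automatic curves of
    that repeat — the body actually moved), plus independent per-row
    detection noise N(0, detection_sd^2) on each curve separately.

    Under this model the per-X SD of the manual curve across repeats is
    sqrt(posture_sd^2 + detection_sd^2) and the per-X SD of the
    manual-minus-auto difference is detection_sd * sqrt(2), which is what
    the repeatability statistics are expected to recover.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    spec = spec or SyntheticSpec()
    truth = ground_truth_curve(spec)
    rng = np.random.default_rng(seed)
    x = truth.x
    base_y = truth.spine_y
    base_z = truth.spine_curve_3d[:, 2]
    pairs = []
    for _ in range(n_repeats):
        dy, dz = rng.normal(0.0, posture_sd_mm, 2)
        man_y = base_y + dy + rng.normal(0.0, detection_sd_mm, x.size)
        man_z = base_z + dz + rng.normal(0.0, detection_sd_mm, x.size)
        aut_y = base_y + dy + rng.normal(0.0, detection_sd_mm, x.size)
        aut_z = base_z + dz + rng.normal(0.0, detection_sd_mm, x.size)
        pairs.append((
            Curve3D(samples=np.column_stack([x, man_y, man_z]),
                    provenance="manual"),
            Curve3D(samples=np.column_stack([x, aut_y, aut_z]),
                    provenance="automatic"),
        ))
    return pairs
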