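"""Lifting detected 2D curves to spatial 3D spine curves and smoothing.

A detected curve lives in image coordinates (u, v).  Since v indexes laser
profiles and u samples along a profile, the spatial curve is recovered by
reading X, Y, Z off the scan grid at each row's sub-pixel u position
(linear interpolation along the row).  The lifted curve is then smoothed
with a least-squares cubic spline, fitted independently to Y(X) and Z(X):
splines keep the handful of anatomical curvature lobes of the back while
suppressing point noise, and — unlike high-degree polynomials — do not
oscillate near the interval ends (Runge's phenomenon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

from .surface_model import BackScan
from .curve_detect import Curve2D

__all__ = ["Curve3D", "lift", "smooth_spline", "project",
           "DEFAULT_KNOT_SPACING_MM"]

DEFAULT_KNOT_SPACING_MM = 30.0


@dataclass
class Curve3D:
    """Spatial spine curve: one (X, Y, Z) sample per covered profile row."""

    samples: np.ndarray              # (n, 3) mm
    smoothed: bool = False
    provenance: str = "automatic"    # "manual" | "automatic"
    dropped_rows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be (n, 3)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite coordinates")
        d = np.diff(self.samples[:, 0])
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("X must be strictly monotonic")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.samples[:, 2]

    def save(self, path) -> None:
        """Write as 4-column text: X Y Z smoothed-flag."""
        flag = np.full(len(self), int(self.smoothed))
        np.savetxt(path, np.column_stack([self.samples, flag]),
                   header=f"X_mm Y_mm Z_mm smoothed provenance="
                          f"{self.provenance}")

    @classmethod
    def load(cls, path) -> "Curve3D":
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] < 3:
            raise ValueError(f"{path}: expected >= 3 columns")
        smoothed = bool(data[:, 3].all()) if data.shape[1] > 3 else False
        return cls(samples=data[:, :3], smoothed=smoothed)


def lift(scan: BackScan, curve: Curve2D) -> Curve3D:
    """Lift a 2D image-coordinate curve onto the measured surface.

    X, Y, Z are linearly interpolated along each row at the curve's
    sub-pixel u position; rows whose two bracketing grid cells are not
    both valid are dropped (and listed in ``dropped_rows``).
    """
    samples = []
    dropped = []
    for v, u_star in zip(curve.v, curve.u):
        if not (0 <= v < scan.n_rows and 0 <= u_star <= scan.n_cols - 1):
            dropped.append(int(v))
            continue
        u0 = int(np.floor(u_star))
        u1 = min(u0 + 1, scan.n_cols - 1)
        if u0 == u1 or u_star == u0:
            if not scan.valid_mask[v, u0]:
                dropped.append(int(v))
                continue
            p = (scan.x[v, u0], scan.y[v, u0], scan.z[v, u0])
        else:
            if not (scan.valid_mask[v, u0] and scan.valid_mask[v, u1]):
                dropped.append(int(v))
                continue
            w = u_star - u0
            p = tuple((1 - w) * a[v, u0] + w * a[v, u1]
                      for a in (scan.x, scan.y, scan.z))
        samples.append(p)
    if not samples:
        raise ValueError("curve lies entirely outside valid data")
    provenance = "manual" if curve.mode == "intensity-min" else "automatic"
    return Curve3D(samples=np.asarray(samples), smoothed=False,
                   provenance=provenance, dropped_rows=dropped)


def smooth_spline(curve: Curve3D,
                  knot_spacing_mm: float = DEFAULT_KNOT_SPACING_MM
                  ) -> Curve3D:
    """Least-squares cubic-spline smoothing of Y(X) and Z(X).

    Interior knots are placed uniformly every ``knot_spacing_mm``
    (~30 mm by default: fine enough to resolve the anatomical curvature
    lobes over a thoraco-lumbar span, coarse enough to suppress
    point-level noise).  The smoothed curve is evaluated at the original X
    positions.  Requires >= 8 samples and a knot spacing above twice the
    sample spacing.
    """
    if len(curve) < 8:
        raise ValueError("need at least 8 samples to smooth")
    x = curve.x
    ascending = x[0] < x[-1]
    order = slice(None) if ascending else slice(None, None, -1)
    xs = x[order]
    dx = float(np.median(np.diff(xs)))
    if knot_spacing_mm <= 2 * dx:
        raise ValueError(
            f"knot_spacing_mm={knot_spacing_mm} must exceed twice the "
            f"sample spacing ({dx:.3g} mm)")
    knots = np.arange(xs[0] + knot_spacing_mm, xs[-1] - 1e-9,
                      knot_spacing_mm)
    new_cols = [x]
    for vals in (curve.y, curve.z):
        try:
            spl = LSQUnivariateSpline(xs, vals[order], knots, k=3)
        except ValueError as exc:
            raise ValueError(
                f"too few samples for knot spacing {knot_spacing_mm} mm"
            ) from exc
        new_cols.append(spl(x))
    return Curve3D(samples=np.column_stack(new_cols), smoothed=True,
                   provenance=curve.provenance,
                   dropped_rows=list(curve.dropped_rows))


def project(curve: Curve3D, plane: str) -> np.ndarray:
    """Project to the frontal (X-Y) or sagittal (X-Z) plane.

    Returns an (n, 2) array of (X, value) pairs in the curve's order.
    """
    if plane == "frontal":
        return np.column_stack([curve.x, curve.y])
    if plane == "sagittal":
        return np.column_stack([curve.x, curve.z])
    raise ValueError(f"unknown plane {plane!r}; expected frontal|sagittal")
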