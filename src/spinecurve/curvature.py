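"""Transverse surface-curvature map of the depth grid.

The automatic spine curve is found by tracking the ridge of positive
transverse curvature created by the posterior median furrow.  For each
laser profile the curvature of the graph Z(Y) is

    K = Z'' / (1 + Z'^2)^(3/2)          [1/mm]

with derivatives taken along the profile (the Y direction).  Because K is
the geometric curvature of the profile section, it is invariant to how the
patient is rotated about the X axis — only the section's shape matters,
not its orientation in the Y-Z plane.

Sign convention: Z points from the back toward the camera, so a concave
depression (the furrow) is a local minimum of Z along Y and yields K > 0;
convex ridges (the bulk of the torso, shoulder blades) yield K < 0.

Derivatives use 3-point central finite differences with
non-uniform-spacing weights.  The depth values may be pre-smoothed with a
1-D Gaussian before differentiation, since second differences amplify the
~0.1 mm sensor noise.  The default sigma of 5 samples is matched to the
furrow: for ridge detection by second derivatives, the optimal smoothing
scale is about half the feature's half-width (~10 mm here), large enough
that the curvature noise stays well below the ridge amplitude yet small
enough not to flatten the ridge.  Set ``presmooth_sigma=0`` to
differentiate the raw profile (appropriate for noise-free analytic
profiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .surface_model import BackScan, ProfileSamples, ROI

__all__ = ["CurvatureMap", "profile_curvature", "curvature_map",
           "DEFAULT_PRESMOOTH_SIGMA"]

DEFAULT_PRESMOOTH_SIGMA = 5.0


@dataclass
class CurvatureMap:
    """Per-point transverse curvature aligned with the source scan grid."""

    k: np.ndarray          # 1/mm; zero where invalid
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.k.shape != self.valid_mask.shape:
            raise ValueError("curvature and mask shapes differ")
        if not np.all(np.isfinite(self.k[self.valid_mask])):
            raise ValueError("non-finite curvature on valid cells")


def _central_derivatives(y: np.ndarray, z: np.ndarray):
    """First and second derivative of z(y) by non-uniform central
    differences; endpoints are returned NaN."""
    h1 = y[1:-1] - y[:-2]
    h2 = y[2:] - y[1:-1]
    denom = h1 * h2 * (h1 + h2)
    d1 = (h1 ** 2 * z[2:] + (h2 ** 2 - h1 ** 2) * z[1:-1]
          - h2 ** 2 * z[:-2]) / denom
    d2 = 2.0 * (h1 * z[2:] - (h1 + h2) * z[1:-1] + h2 * z[:-2]) / denom
    out1 = np.full_like(z, np.nan)
    out2 = np.full_like(z, np.nan)
    out1[1:-1] = d1
    out2[1:-1] = d2
    return out1, out2


def profile_curvature(profile: ProfileSamples,
                      presmooth_sigma: float = DEFAULT_PRESMOOTH_SIGMA
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Curvature along one profile.

    Returns ``(k, valid)`` aligned with the profile's u index.  Curvature
    is computed independently on every contiguous run of >= 5 valid
    samples; the first and last sample of each run, and all invalid cells,
    are flagged invalid.  Raises ValueError if no run is long enough or if
    Y is not strictly increasing within a run.
    """
    if presmooth_sigma < 0:
        raise ValueError("presmooth_sigma must be >= 0")
    n = len(profile.ys)
    k = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    any_run = False
    for start, stop in _valid_runs(profile.valid):
        if stop - start < 5:
            continue
        ys = np.asarray(profile.ys[start:stop], dtype=float)
        zs = np.asarray(profile.zs[start:stop], dtype=float)
        if np.any(np.diff(ys) <= 0):
            raise ValueError("profile Y not strictly increasing")
        if presmooth_sigma > 0:
            zs = gaussian_filter1d(zs, presmooth_sigma, mode="nearest")
        d1, d2 = _central_derivatives(ys, zs)
        kk = d2 / (1.0 + d1 ** 2) ** 1.5
        k[start + 1:stop - 1] = kk[1:-1]
        valid[start + 1:stop - 1] = True
        any_run = True
    if not any_run:
        raise ValueError("fewer than 5 contiguous valid samples in profile")
    return k, valid


def _valid_runs(mask: np.ndarray):
    """Yield (start, stop) half-open index ranges of True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return
    idx = np.flatnonzero(np.diff(np.concatenate(([False], m, [False]))
                                 .astype(int)))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def curvature_map(scan: BackScan, roi: ROI | None = None,
                  presmooth_sigma: float = DEFAULT_PRESMOOTH_SIGMA
                  ) -> CurvatureMap:
    """Apply :func:`profile_curvature` to every row inside ``roi``.

    Rows with too few valid samples are left fully invalid; the map keeps
    the full scan shape (cells outside the ROI invalid).  Raises if no row
    in the ROI is computable.
    """
    roi = roi or ROI.full(scan)
    roi.check_within(scan)
    k = np.zeros_like(scan.z)
    valid = np.zeros_like(scan.valid_mask)
    n_ok = 0
    for v in range(roi.v_min, roi.v_max + 1):
        prof = scan.profile(v)
        sub = ProfileSamples(
            ys=prof.ys[roi.u_min:roi.u_max + 1],
            zs=prof.zs[roi.u_min:roi.u_max + 1],
            brightness=prof.brightness[roi.u_min:roi.u_max + 1],
            valid=prof.valid[roi.u_min:roi.u_max + 1],
        )
        try:
            kk, vv = profile_curvature(sub, presmooth_sigma)
        except ValueError:
            continue
        k[v, roi.u_min:roi.u_max + 1] = kk
        valid[v, roi.u_min:roi.u_max + 1] = vv
        n_ok += 1
    if n_ok == 0:
        raise ValueError("ROI contains no computable rows")
    return CurvatureMap(k=k, valid_mask=valid)
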