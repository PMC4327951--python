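"""Curve comparison (RMSD), cohort summaries and repeatability statistics.

The manual (palpation-based) and automatic (curvature-based) spine curves
are compared per anatomical plane by the root mean square deviation over
the rows both curves cover:

    RMSD_XY = sqrt( sum_i (Y_M,i - Y_A,i)^2 / n )
    RMSD_XZ = sqrt( sum_i (Z_M,i - Z_A,i)^2 / n )

with one difference per X row inside the common X span (the automatic
curve is typically shorter — the furrow fades cranially — so the region of
interest is first reduced in X to the interval both curves cover).

Repeatability over repeated scans of one subject is quantified by the
standard deviation, at each X, of the manual curve across repeats (posture
variability) and of the per-repeat manual-minus-auto difference (method
variability), in each plane; the scalar summaries are the means of those
SD-versus-X curves.

All standard deviations use the population convention (divisor n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve3d import Curve3D

__all__ = [
    "ComparisonResult",
    "CohortSummary",
    "RepeatabilityResult",
    "common_span",
    "compare_curves",
    "cohort_summary",
    "repeatability",
]


@dataclass(frozen=True)
class ComparisonResult:
    """RMSD between a manual and an automatic curve, per plane."""

    rmsd_xy_mm: float
    rmsd_xz_mm: float
    n_rows: int
    x_span_mm: tuple[float, float]

    def report(self) -> str:
        lo, hi = self.x_span_mm
        return (f"rmsd_xy_mm: {self.rmsd_xy_mm:.2f}\n"
                f"rmsd_xz_mm: {self.rmsd_xz_mm:.2f}\n"
                f"n_rows: {self.n_rows}\n"
                f"x_span_mm: [{lo:.1f}, {hi:.1f}]")


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of one per-patient column."""

    mean: float
    sd: float
    median: float
    min: float
    max: float
    n: int

    def report(self) -> str:
        return (f"n: {self.n}\nmean: {self.mean:.2f}\nsd: {self.sd:.2f}\n"
                f"median: {self.median:.2f}\nmin: {self.min:.2f}\n"
                f"max: {self.max:.2f}")


@dataclass
class RepeatabilityResult:
    """Per-X and averaged repeatability quantities (all mm).

    ``per_x_sd_manual_*`` is the SD across repeats of the manual curve at
    each X (posture variability); ``per_x_sd_diff_*`` the SD across
    repeats of the manual-minus-auto difference (method variability).
    """

    x: np.ndarray
    per_x_sd_manual_frontal: np.ndarray
    per_x_sd_diff_frontal: np.ndarray
    per_x_sd_manual_sagittal: np.ndarray
    per_x_sd_diff_sagittal: np.ndarray

    @property
    def avg_sd_manual_frontal(self) -> float:
        return float(self.per_x_sd_manual_frontal.mean())

    @property
    def avg_sd_diff_frontal(self) -> float:
        return float(self.per_x_sd_diff_frontal.mean())

    @property
    def avg_sd_manual_sagittal(self) -> float:
        return float(self.per_x_sd_manual_sagittal.mean())

    @property
    def avg_sd_diff_sagittal(self) -> float:
        return float(self.per_x_sd_diff_sagittal.mean())

    def report(self) -> str:
        return (
            f"n_rows: {len(self.x)}\n"
            f"avg_sd_manual_frontal_mm: {self.avg_sd_manual_frontal:.2f}\n"
            f"avg_sd_diff_frontal_mm: {self.avg_sd_diff_frontal:.2f}\n"
            f"avg_sd_manual_sagittal_mm: {self.avg_sd_manual_sagittal:.2f}\n"
            f"avg_sd_diff_sagittal_mm: {self.avg_sd_diff_sagittal:.2f}")


def common_span(a: Curve3D, b: Curve3D) -> tuple[float, float]:
    """Intersection of the two curves' X ranges; error if disjoint."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty curve")
    lo = max(min(a.x[0], a.x[-1]), min(b.x[0], b.x[-1]))
    hi = min(max(a.x[0], a.x[-1]), max(b.x[0], b.x[-1]))
    if lo >= hi:
        raise ValueError(f"disjoint X spans: [{lo:g}, {hi:g}] is empty")
    return float(lo), float(hi)


def _resample(curve: Curve3D, xg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = curve.x
    if x[0] > x[-1]:
        x, y, z = x[::-1], curve.y[::-1], curve.z[::-1]
    else:
        y, z = curve.y, curve.z
    return np.interp(xg, x, y), np.interp(xg, x, z)


def compare_curves(manual: Curve3D, auto: Curve3D) -> ComparisonResult:
    """RMSD between the two curves over their common X span.

    Both curves are resampled by linear interpolation at the manual
    curve's profile-row X positions inside the common span, so every term
    of the sum is a difference of two points in the same X row.
    """
    lo, hi = common_span(manual, auto)
    xg = manual.x[(manual.x >= lo) & (manual.x <= hi)]
    if len(xg) < 2:
        raise ValueError(f"only {len(xg)} common rows; need at least 2")
    my, mz = _resample(manual, xg)
    ay, az = _resample(auto, xg)
    return ComparisonResult(
        rmsd_xy_mm=float(np.sqrt(np.mean((my - ay) ** 2))),
        rmsd_xz_mm=float(np.sqrt(np.mean((mz - az) ** 2))),
        n_rows=len(xg),
        x_span_mm=(lo, hi),
    )


def cohort_summary(values) -> CohortSummary:
    """Mean, SD (divisor n), median, min, max of a per-patient column."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("need a non-empty 1-D sequence")
    return CohortSummary(
        mean=float(v.mean()), sd=float(v.std(ddof=0)),
        median=float(np.median(v)), min=float(v.min()), max=float(v.max()),
        n=int(v.size),
    )


def repeatability(pairs, n_repeats: int | None = None) -> RepeatabilityResult:
    """Repeatability statistics over repeated (manual, auto) curve pairs.

    All curves are resampled onto the first manual curve's rows inside the
    X span common to every curve; SDs are taken across repeats at each X.
    """
    pairs = list(pairs)
    if n_repeats is None:
        n_repeats = len(pairs)
    if n_repeats != len(pairs):
        raise ValueError("n_repeats inconsistent with the pairs given")
    if len(pairs) < 2:
        raise ValueError("need at least 2 repeats")
    lo = -np.inf
    hi = np.inf
    for m, a in pairs:
        s_lo, s_hi = common_span(m, a)
        lo, hi = max(lo, s_lo), min(hi, s_hi)
    if lo >= hi:
        raise ValueError("no X span common to all repeats")
    ref = pairs[0][0]
    xg = ref.x[(ref.x >= lo) & (ref.x <= hi)]
    if len(xg) < 2:
        raise ValueError("fewer than 2 rows in the common span")
    man_y, man_z, dif_y, dif_z = [], [], [], []
    for m, a in pairs:
        my, mz = _resample(m, xg)
        ay, az = _resample(a, xg)
        man_y.append(my)
        man_z.append(mz)
        dif_y.append(my - ay)
        dif_z.append(mz - az)
    man_y, man_z = np.array(man_y), np.array(man_z)
    dif_y, dif_z = np.array(dif_y), np.array(dif_z)
    return RepeatabilityResult(
        x=xg,
        per_x_sd_manual_frontal=man_y.std(axis=0, ddof=0),
        per_x_sd_diff_frontal=dif_y.std(axis=0, ddof=0),
        per_x_sd_manual_sagittal=man_z.std(axis=0, ddof=0),
        per_x_sd_diff_sagittal=dif_z.std(axis=0, ddof=0),
    )
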