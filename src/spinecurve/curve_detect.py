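"""Per-row extremum detection and linking into candidate spine curves.

Two detectors share the same machinery:

* the *automatic* detector tracks the positive-curvature ridge of the
  posterior median furrow: per image row, every local maximum of the
  transverse curvature above a threshold (zero by default, so every
  candidate ridge is kept) is localized to sub-pixel accuracy by a
  quadratic fit, and detections are linked across rows into candidate
  curves, one of which is selected by a seed point (the scriptable
  equivalent of the operator's single mouse click);

* the *manual* detector finds the dark marker line drawn on the skin along
  the palpated spinous processes: the brightness image is smoothed with a
  7x7 Gaussian kernel, the per-row global intensity minimum is accepted
  when it falls below the configured intensity threshold (0.08-0.15 on the
  normalized scale), refined by the same quadratic fit, and gaps are closed
  by 1-D interpolation to yield a continuous 2D curve.

All positions here are image coordinates: u (sub-pixel column) per row v.
Lifting to millimetres happens in :mod:`spinecurve.curve3d`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .surface_model import BackScan, ROI
from .curvature import curvature_map, DEFAULT_PRESMOOTH_SIGMA

__all__ = [
    "RowDetection",
    "Curve2D",
    "CandidateCurveSet",
    "DetectionError",
    "LinkParams",
    "subpixel_extremum",
    "detect_rows",
    "link_candidates",
    "select_curve",
    "detect_manual",
    "detect_auto",
]

#: sigma of the 7x7 brightness-smoothing kernel (truncated at 2 sigma)
MANUAL_SMOOTH_SIGMA = 1.5
DEFAULT_INTENSITY_THRESHOLD = 0.10
DEFAULT_FIT_WINDOW = 5


class DetectionError(RuntimeError):
    """Raised when a detector finds nothing usable."""


@dataclass(frozen=True)
class RowDetection:
    """One sub-pixel extremum on one image row."""

    v: int
    u_star: float
    strength: float          # curvature (1/mm) or brightness-dip depth
    mode: str                # "curvature-max" | "intensity-min"
    fallback: bool = False   # quadratic fit rejected, discrete position used


@dataclass
class Curve2D:
    """Continuous detected curve in image coordinates.

    One sample per covered row; ``v`` is consecutive, rows bridged by
    interpolation are flagged in ``interpolated``.
    """

    v: np.ndarray            # int, consecutive
    u: np.ndarray            # float, sub-pixel columns
    strength: np.ndarray
    interpolated: np.ndarray  # bool
    mode: str
    roi: ROI | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=int)
        self.u = np.asarray(self.u, dtype=float)
        self.strength = np.asarray(self.strength, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if not (len(self.v) == len(self.u) == len(self.strength)
                == len(self.interpolated)):
            raise ValueError("curve arrays must have equal length")
        if len(self.v) and np.any(np.diff(self.v) != 1):
            raise ValueError("curve rows must be consecutive")

    def __len__(self) -> int:
        return len(self.v)

    @property
    def mean_strength(self) -> float:
        m = ~self.interpolated
        return float(self.strength[m].mean()) if m.any() else 0.0


@dataclass
class CandidateCurveSet:
    """All linked curves that are possible candidates for the spine curve,
    ordered by decreasing length."""

    candidates: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


@dataclass(frozen=True)
class LinkParams:
    """Parameters of the automatic detection / linking stage."""

    threshold: float = 0.0       # curvature acceptance threshold (1/mm)
    window: int = DEFAULT_FIT_WINDOW
    presmooth_sigma: float = DEFAULT_PRESMOOTH_SIGMA
    max_jump: float = 3.0        # columns, row-to-row association limit
    max_gap: int = 5             # rows bridged by interpolation
    min_length: int = 20         # rows, minimum candidate length


# ---------------------------------------------------------------------------
# Sub-pixel refinement
# ---------------------------------------------------------------------------

def subpixel_extremum(values, positions, window: int | None = None,
                      mode: str = "max") -> tuple[float, float, bool]:
    """Vertex of the least-squares quadratic through a window of samples.

    ``window`` (odd, >= 3) selects that many points centered on the
    discrete extremum of ``values``; if omitted, all samples are used.
    Returns ``(position, value, fallback)``.  If the fitted parabola opens
    the wrong way or its vertex leaves the window, the discrete extremum is
    returned with ``fallback=True``.  All-equal values raise ValueError.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if values.shape != positions.shape or values.ndim != 1:
        raise ValueError("values and positions must be equal-length 1-D")
    if len(values) < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if np.ptp(values) == 0:
        raise ValueError("degenerate window: all values equal")
    sign = 1.0 if mode == "max" else -1.0
    i0 = int(np.argmax(sign * values))
    if window is not None:
        if window < 3 or window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        half = window // 2
        lo = max(0, min(i0 - half, len(values) - window))
        values = values[lo:lo + window]
        positions = positions[lo:lo + window]
        i0 -= lo
    a, b, c = np.polyfit(positions, values, 2)
    vertex_ok = (sign * a < 0) and abs(a) > 0
    if vertex_ok:
        p = -b / (2.0 * a)
        if positions[0] <= p <= positions[-1]:
            return float(p), float(np.polyval((a, b, c), p)), False
    return float(positions[i0]), float(values[i0]), True


# ---------------------------------------------------------------------------
# Row-wise detection
# ---------------------------------------------------------------------------

def detect_rows(map_values: np.ndarray, roi: ROI, mode: str,
                threshold: float, window: int = DEFAULT_FIT_WINDOW,
                valid_mask: np.ndarray | None = None) -> list[RowDetection]:
    """Find every qualifying local extremum on each row inside ``roi``.

    ``mode="curvature-max"``: local maxima with value strictly above
    ``threshold``; strength is the refined curvature value.
    ``mode="intensity-min"``: local minima accepted when the (smoothed)
    brightness is below ``threshold``; strength is 1 - brightness.
    Positions are sub-pixel u columns.
    """
    if mode not in ("curvature-max", "intensity-min"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = np.asarray(map_values, dtype=float)
    if vals.ndim != 2:
        raise ValueError("map_values must be 2-D")
    if roi.v_max >= vals.shape[0] or roi.u_max >= vals.shape[1]:
        raise ValueError("ROI outside grid")
    if valid_mask is None:
        valid_mask = np.ones_like(vals, dtype=bool)
    sign = 1.0 if mode == "curvature-max" else -1.0
    out: list[RowDetection] = []
    u_all = np.arange(vals.shape[1], dtype=float)
    for v in range(roi.v_min, roi.v_max + 1):
        row = vals[v]
        rvalid = valid_mask[v].copy()
        rvalid[:roi.u_min] = False
        rvalid[roi.u_max + 1:] = False
        s = sign * row
        for u in np.flatnonzero(rvalid[1:-1]) + 1:
            if not (rvalid[u - 1] and rvalid[u + 1]):
                continue
            if not (s[u] > s[u - 1] and s[u] >= s[u + 1]):
                continue
            if mode == "curvature-max":
                if not row[u] > threshold:
                    continue
            else:
                if not row[u] < threshold:
                    continue
            half = window // 2
            lo = max(roi.u_min, u - half)
            hi = min(roi.u_max, u + half)
            seg = slice(lo, hi + 1)
            if not valid_mask[v, seg].all() or hi - lo + 1 < 3:
                u_star, fb = float(u), True
            else:
                try:
                    u_star, _, fb = subpixel_extremum(
                        row[seg], u_all[seg],
                        mode="max" if sign > 0 else "min")
                except ValueError:
                    continue
            # strength reads the measured extremum, not the fitted vertex
            strength = row[u] if mode == "curvature-max" else 1.0 - row[u]
            out.append(RowDetection(v=v, u_star=u_star, strength=strength,
                                    mode=mode, fallback=fb))
    return out


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

class _Track:
    __slots__ = ("vs", "us", "strengths")

    def __init__(self, det: RowDetection):
        self.vs = [det.v]
        self.us = [det.u_star]
        self.strengths = [det.strength]

    def extend(self, det: RowDetection):
        self.vs.append(det.v)
        self.us.append(det.u_star)
        self.strengths.append(det.strength)


def link_candidates(detections: list[RowDetection], max_jump: float = 3.0,
                    max_gap: int = 5, min_length: int = 20
                    ) -> CandidateCurveSet:
    """Greedy row-by-row association of detections into candidate curves.

    Walking rows in increasing v, open tracks extend in seniority order
    (longest first): each track takes the unused detection nearest in u to
    its last position, if within ``max_jump`` columns; unmatched
    detections open new tracks.  Seniority keeps weak single-row noise
    maxima from stealing the tail of a long ridge track.  Tracks silent
    for more than ``max_gap`` rows are closed.  Row gaps inside a track are bridged by linear
    interpolation (flagged); tracks spanning fewer than ``min_length`` rows
    are discarded.  Output sorted by length descending.
    """
    by_row: dict[int, list[RowDetection]] = {}
    for d in sorted(detections, key=lambda d: d.v):
        by_row.setdefault(d.v, []).append(d)
    open_tracks: list[_Track] = []
    closed: list[_Track] = []
    for v in sorted(by_row):
        still_open = []
        for t in open_tracks:
            if v - t.vs[-1] - 1 > max_gap:
                closed.append(t)
            else:
                still_open.append(t)
        open_tracks = still_open
        dets = by_row[v]
        used_d: set[int] = set()
        order = sorted(range(len(open_tracks)),
                       key=lambda ti: (-len(open_tracks[ti].vs), ti))
        for ti in order:
            t = open_tracks[ti]
            best_di = -1
            best_dist = max_jump
            for di, d in enumerate(dets):
                if di in used_d:
                    continue
                dist = abs(d.u_star - t.us[-1])
                if dist <= best_dist:
                    best_dist = dist
                    best_di = di
            if best_di >= 0:
                t.extend(dets[best_di])
                used_d.add(best_di)
        for di, d in enumerate(dets):
            if di not in used_d:
                open_tracks.append(_Track(d))
    closed.extend(open_tracks)
    curves = []
    for t in closed:
        span = t.vs[-1] - t.vs[0] + 1
        if span < min_length:
            continue
        vs = np.arange(t.vs[0], t.vs[-1] + 1)
        us = np.interp(vs, t.vs, t.us)
        st = np.interp(vs, t.vs, t.strengths)
        interp = ~np.isin(vs, t.vs)
        curves.append(Curve2D(v=vs, u=us, strength=st, interpolated=interp,
                              mode=detections[0].mode if detections else ""))
    curves.sort(key=lambda c: (-len(c), -c.mean_strength))
    return CandidateCurveSet(candidates=curves)


# ---------------------------------------------------------------------------
# Selection (scripted stand-in for the operator's mouse click)
# ---------------------------------------------------------------------------

def _point_polyline_dist(pu: float, pv: float, us: np.ndarray,
                         vs: np.ndarray) -> float:
    if len(us) == 1:
        return float(np.hypot(us[0] - pu, vs[0] - pv))
    au, av = us[:-1], vs[:-1]
    du, dv = np.diff(us), np.diff(vs)
    seg2 = du ** 2 + dv ** 2
    t = np.clip(((pu - au) * du + (pv - av) * dv) / np.where(seg2 == 0, 1,
                                                             seg2), 0, 1)
    cx = au + t * du
    cy = av + t * dv
    return float(np.min(np.hypot(cx - pu, cy - pv)))


def select_curve(candidates: CandidateCurveSet,
                 seed_uv: tuple[float, float]) -> Curve2D:
    """Pick the candidate nearest to the seed point (u, v).

    Distance is the perpendicular distance from the seed to the candidate
    polyline; ties are broken by greater length, then greater mean
    strength.
    """
    if not len(candidates):
        raise DetectionError("empty candidate set")
    pu, pv = float(seed_uv[0]), float(seed_uv[1])
    scored = []
    for c in candidates:
        d = _point_polyline_dist(pu, pv, c.u, c.v.astype(float))
        scored.append((round(d, 9), -len(c), -c.mean_strength, c))
    scored.sort(key=lambda s: s[:3])
    return scored[0][3]


# ---------------------------------------------------------------------------
# End-to-end detectors
# ---------------------------------------------------------------------------

def detect_manual(scan: BackScan, roi: ROI | None = None,
                  intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
                  window: int = DEFAULT_FIT_WINDOW) -> Curve2D:
    """Detect the drawn marker line in the brightness channel.

    The brightness image is smoothed with a 7x7 Gaussian kernel
    (sigma 1.5, truncated at 2 sigma); per row the global minimum of the
    smoothed brightness is accepted if it lies below
    ``intensity_threshold`` and refined by a quadratic fit; rows without an
    accepted minimum are filled by 1-D interpolation between neighbouring
    accepted rows, yielding a continuous curve.
    """
    roi = roi or ROI.full(scan)
    roi.check_within(scan)
    # invalid cells read as skin-white so they never win the minimum search
    b = np.where(scan.valid_mask, scan.brightness, 1.0)
    sm = gaussian_filter(b, MANUAL_SMOOTH_SIGMA, mode="nearest",
                         truncate=2.0)
    accepted: list[RowDetection] = []
    u_all = np.arange(scan.n_cols, dtype=float)
    for v in range(roi.v_min, roi.v_max + 1):
        seg = slice(roi.u_min, roi.u_max + 1)
        row = sm[v, seg]
        rvalid = scan.valid_mask[v, seg]
        if not rvalid.any():
            continue
        masked = np.where(rvalid, row, np.inf)
        u_rel = int(np.argmin(masked))
        if not masked[u_rel] < intensity_threshold:
            continue
        u_abs = u_rel + roi.u_min
        half = window // 2
        lo = max(roi.u_min, u_abs - half)
        hi = min(roi.u_max, u_abs + half)
        if hi - lo + 1 >= 3 and scan.valid_mask[v, lo:hi + 1].all():
            try:
                u_star, _, fb = subpixel_extremum(
                    sm[v, lo:hi + 1], u_all[lo:hi + 1], mode="min")
            except ValueError:
                u_star, fb = float(u_abs), True
        else:
            u_star, fb = float(u_abs), True
        accepted.append(RowDetection(v=v, u_star=u_star,
                                     strength=1.0 - float(masked[u_rel]),
                                     mode="intensity-min", fallback=fb))
    if not accepted:
        raise DetectionError(
            f"no row in the ROI has smoothed brightness below "
            f"{intensity_threshold}")
    vs = np.arange(accepted[0].v, accepted[-1].v + 1)
    v_acc = np.array([d.v for d in accepted])
    us = np.interp(vs, v_acc, [d.u_star for d in accepted])
    st = np.interp(vs, v_acc, [d.strength for d in accepted])
    return Curve2D(v=vs, u=us, strength=st,
                   interpolated=~np.isin(vs, v_acc),
                   mode="intensity-min", roi=roi)


def detect_auto(scan: BackScan, roi: ROI | None = None,
                params: LinkParams = LinkParams()) -> CandidateCurveSet:
    """Detect all candidate spine curves from the surface-curvature map.

    Composition of curvature computation, per-row curvature-maximum
    detection (threshold zero keeps every possible candidate) and greedy
    linking; fully deterministic for fixed input and parameters.
    """
    roi = roi or ROI.full(scan)
    cmap = curvature_map(scan, roi, presmooth_sigma=params.presmooth_sigma)
    dets = detect_rows(cmap.k, roi, "curvature-max", params.threshold,
                       window=params.window, valid_mask=cmap.valid_mask)
    cands = link_candidates(dets, max_jump=params.max_jump,
                            max_gap=params.max_gap,
                            min_length=params.min_length)
    for c in cands:
        c.roi = roi
    return cands
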