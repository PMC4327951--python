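"""Data model and file I/O for ordered back-surface scans.

A laser-triangulation profilometer sweeps a light plane along the back
(the X direction) and stores one measured profile per sweep position.  The
result is an *ordered point cloud*: a regular (v, u) grid where v indexes
profiles (rows of roughly constant X) and u indexes samples along each
profile, every cell carrying spatial coordinates X, Y, Z in millimetres
plus a normalized brightness value.

Coordinate convention
---------------------
* X increases caudal -> cranial along the scanner translation,
* Y is lateral (positive toward the patient's left),
* Z is depth, positive from the back toward the camera.

With this convention the posterior median furrow — the midline skin
depression overlying the spinous processes — is a local *minimum* of Z
along Y, which fixes the sign of the transverse surface curvature used
downstream (concave depression => positive curvature).

Dropouts (laser occlusion, specular loss) are encoded in a per-cell
validity mask, never as sentinel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BackScan",
    "ROI",
    "ProfileSamples",
    "ScanFormatError",
    "load_scan",
    "save_scan",
    "crop_roi",
    "rotate_about_x",
]


class ScanFormatError(ValueError):
    """Raised for malformed or inconsistent scan files."""


@dataclass
class BackScan:
    """Ordered grid of measured back-surface points.

    Arrays are indexed ``[v, u]``: v runs along the scanner translation
    (profiles), u along each laser profile.
    """

    x: np.ndarray          # mm, shape (n_rows, n_cols)
    y: np.ndarray          # mm
    z: np.ndarray          # mm
    brightness: np.ndarray  # dimensionless, in [0, 1] where valid
    valid_mask: np.ndarray  # bool
    profile_spacing_mm: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.x.shape[0]

    @property
    def n_cols(self) -> int:
        return self.x.shape[1]

    def __post_init__(self) -> None:
        arrs = (self.x, self.y, self.z, self.brightness, self.valid_mask)
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent grid shapes: {shapes}")
        self.validate()

    def validate(self) -> None:
        """Check the BackScan invariants, raising ValueError on violation."""
        if self.x.ndim != 2 or self.n_rows < 3 or self.n_cols < 3:
            raise ValueError(
                f"grid must be at least 3x3, got {self.x.shape}"
            )
        if not np.isfinite(self.profile_spacing_mm) or self.profile_spacing_mm <= 0:
            raise ValueError("profile_spacing_mm must be positive")
        # Profiles must be ordered along the translation direction.
        row_x = self.row_mean_x()
        d = np.diff(row_x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("mean X is not strictly monotonic in v")
        b = self.brightness[self.valid_mask]
        if b.size and (b.min() < -1e-12 or b.max() > 1 + 1e-12):
            raise ValueError("brightness outside [0, 1] on valid cells")

    def row_mean_x(self) -> np.ndarray:
        """Mean X of each profile, ignoring invalid cells (all-invalid rows
        fall back to the row mean over every cell)."""
        counts = self.valid_mask.sum(axis=1)
        sums = (self.x * self.valid_mask).sum(axis=1)
        return np.where(counts > 0, sums / np.maximum(counts, 1),
                        self.x.mean(axis=1))

    def profile(self, v: int) -> "ProfileSamples":
        """Row view of the scan (one laser profile)."""
        return ProfileSamples(
            ys=self.y[v].copy(),
            zs=self.z[v].copy(),
            brightness=self.brightness[v].copy(),
            valid=self.valid_mask[v].copy(),
        )

    def allclose(self, other: "BackScan", atol: float = 1e-6) -> bool:
        if self.x.shape != other.x.shape:
            return False
        if not np.array_equal(self.valid_mask, other.valid_mask):
            return False
        m = self.valid_mask
        for a, b in ((self.x, other.x), (self.y, other.y), (self.z, other.z),
                     (self.brightness, other.brightness)):
            if not np.allclose(a[m], b[m], atol=atol, rtol=0):
                return False
        return True


@dataclass(frozen=True)
class ROI:
    """Inclusive grid-index bounds of a region of interest."""

    v_min: int
    v_max: int
    u_min: int
    u_max: int

    def __post_init__(self) -> None:
        if self.v_min > self.v_max or self.u_min > self.u_max:
            raise ValueError(f"degenerate ROI {self}")
        if min(self.v_min, self.u_min) < 0:
            raise ValueError(f"negative ROI bounds {self}")

    @classmethod
    def full(cls, scan: BackScan) -> "ROI":
        return cls(0, scan.n_rows - 1, 0, scan.n_cols - 1)

    def check_within(self, scan: BackScan) -> None:
        if self.v_max >= scan.n_rows or self.u_max >= scan.n_cols:
            raise ValueError(
                f"ROI {self} outside {scan.n_rows}x{scan.n_cols} grid"
            )

    @property
    def n_rows(self) -> int:
        return self.v_max - self.v_min + 1

    @property
    def n_cols(self) -> int:
        return self.u_max - self.u_min + 1


@dataclass
class ProfileSamples:
    """Samples of one laser profile, aligned by the u index."""

    ys: np.ndarray
    zs: np.ndarray
    brightness: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        n = {len(self.ys), len(self.zs), len(self.brightness), len(self.valid)}
        if len(n) != 1:
            raise ValueError("profile arrays must have equal length")


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
# grid-text: human-diffable structured text.
#   line 1: "<n_rows> <n_cols>"
#   line 2: "<profile_spacing_mm>"
#   then n_rows*n_cols lines (row-major, u fastest):
#   "X Y Z brightness valid"
#
# PLY: standard vertex list with double-precision x, y, z, intensity and a
# uchar valid flag; the grid shape and profile spacing are declared in
# header comments ("grid_rows R grid_cols C", "profile_spacing_mm S").

_FORMATS = ("ply", "grid-text")


def save_scan(scan: BackScan, path, format_name: str = "ply",
              binary: bool = True) -> None:
    """Write a scan to disk; ``load_scan`` recovers it within 1e-6 mm."""
    path = Path(path)
    if format_name == "grid-text":
        _save_grid_text(scan, path)
    elif format_name == "ply":
        _save_ply(scan, path, binary=binary)
    else:
        raise ScanFormatError(
            f"unsupported format {format_name!r}; expected one of {_FORMATS}"
        )


def load_scan(path, format_name: str | None = None) -> BackScan:
    """Read a scan written by :func:`save_scan` (or a conforming exporter).

    ``format_name`` may be omitted, in which case it is inferred from the
    file suffix (``.ply`` -> ply, anything else -> grid-text).  Brightness
    stored on another scale (e.g. 0-255 camera counts) is min-max
    normalized to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scan file not found: {path}")
    if format_name is None:
        format_name = "ply" if path.suffix.lower() == ".ply" else "grid-text"
    if format_name == "grid-text":
        scan = _load_grid_text(path)
    elif format_name == "ply":
        scan = _load_ply(path)
    else:
        raise ScanFormatError(
            f"unsupported format {format_name!r}; expected one of {_FORMATS}"
        )
    scan.validate()
    return scan


def _build_scan(x, y, z, b, valid, spacing, metadata) -> BackScan:
    """Assemble a loaded scan, min-max normalizing brightness stored on a
    non-[0,1] scale (e.g. raw camera counts)."""
    if valid.any():
        lo, hi = b[valid].min(), b[valid].max()
        if lo < -1e-12 or hi > 1 + 1e-12:
            if hi > lo:
                b = np.where(valid, (b - lo) / (hi - lo), 0.0)
            else:
                b = np.where(valid, 1.0, 0.0)
            metadata.setdefault(
                "brightness_normalized", f"min-max from [{lo:g}, {hi:g}]")
    return BackScan(x=x, y=y, z=z, brightness=b, valid_mask=valid,
                    profile_spacing_mm=spacing, metadata=metadata)


def _save_grid_text(scan: BackScan, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{scan.n_rows} {scan.n_cols}\n")
        fh.write(f"{float(scan.profile_spacing_mm)!r}\n")
        for v in range(scan.n_rows):
            for u in range(scan.n_cols):
                fh.write(
                    f"{float(scan.x[v, u])!r} {float(scan.y[v, u])!r} "
                    f"{float(scan.z[v, u])!r} "
                    f"{float(scan.brightness[v, u])!r} "
                    f"{int(scan.valid_mask[v, u])}\n"
                )


def _load_grid_text(path: Path) -> BackScan:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ScanFormatError(f"{path}: bad dimension header {header}")
        try:
            n_rows, n_cols = int(header[0]), int(header[1])
            spacing = float(fh.readline().strip())
        except ValueError as exc:
            raise ScanFormatError(f"{path}: malformed header") from exc
        try:
            data = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise ScanFormatError(f"{path}: malformed data rows") from exc
    if data.shape != (n_rows * n_cols, 5):
        raise ScanFormatError(
            f"{path}: header declares {n_rows}x{n_cols} grid "
            f"({n_rows * n_cols} points x 5 columns) but file has "
            f"shape {data.shape}"
        )
    shape = (n_rows, n_cols)
    return _build_scan(
        data[:, 0].reshape(shape), data[:, 1].reshape(shape),
        data[:, 2].reshape(shape), data[:, 3].reshape(shape),
        data[:, 4].reshape(shape).astype(bool), spacing,
        {"source": str(path), "format": "grid-text"},
    )


_PLY_PROPS = ("x", "y", "z", "intensity", "valid")


def _save_ply(scan: BackScan, path: Path, binary: bool) -> None:
    n = scan.n_rows * scan.n_cols
    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        f"comment grid_rows {scan.n_rows} grid_cols {scan.n_cols}",
        f"comment profile_spacing_mm {float(scan.profile_spacing_mm)!r}",
        f"element vertex {n}",
        "property double x",
        "property double y",
        "property double z",
        "property double intensity",
        "property uchar valid",
        "end_header",
    ]
    cols = [scan.x.ravel(), scan.y.ravel(), scan.z.ravel(),
            scan.brightness.ravel(), scan.valid_mask.ravel()]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = np.empty(n, dtype=[("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                                     ("i", "<f8"), ("v", "u1")])
            for name, col in zip(("x", "y", "z", "i", "v"), cols):
                rec[name] = col
            fh.write(rec.tobytes())
        else:
            for xx, yy, zz, bb, vv in zip(*cols):
                fh.write(f"{float(xx)!r} {float(yy)!r} {float(zz)!r} "
                         f"{float(bb)!r} {int(vv)}\n".encode("ascii"))


def _load_ply(path: Path) -> BackScan:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ScanFormatError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        grid_rows = grid_cols = None
        spacing = None
        props: list[tuple[str, str]] = []
        while True:
            line = fh.readline()
            if not line:
                raise ScanFormatError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "comment":
                if len(tokens) >= 5 and tokens[1] == "grid_rows":
                    grid_rows, grid_cols = int(tokens[2]), int(tokens[4])
                elif len(tokens) >= 3 and tokens[1] == "profile_spacing_mm":
                    spacing = float(tokens[2])
            elif tokens[0] == "element" and tokens[1] == "vertex":
                n_vertex = int(tokens[2])
            elif tokens[0] == "property":
                props.append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ScanFormatError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None or grid_rows is None:
            raise ScanFormatError(
                f"{path}: missing vertex element or grid_rows/grid_cols "
                "comment")
        if [p[1] for p in props] != list(_PLY_PROPS):
            raise ScanFormatError(
                f"{path}: expected vertex properties {_PLY_PROPS}, "
                f"got {[p[1] for p in props]}")
        if grid_rows * grid_cols != n_vertex:
            raise ScanFormatError(
                f"{path}: grid {grid_rows}x{grid_cols} inconsistent with "
                f"{n_vertex} vertices")
        if fmt == "binary_little_endian":
            itemsize = 4 * 8 + 1
            raw = fh.read(n_vertex * itemsize)
            if len(raw) != n_vertex * itemsize:
                raise ScanFormatError(
                    f"{path}: vertex data truncated "
                    f"({len(raw)} of {n_vertex * itemsize} bytes)")
            rec = np.frombuffer(raw, dtype=[("x", "<f8"), ("y", "<f8"),
                                            ("z", "<f8"), ("i", "<f8"),
                                            ("v", "u1")])
            data = np.column_stack([rec["x"], rec["y"], rec["z"], rec["i"],
                                    rec["v"].astype(float)])
        else:
            try:
                data = np.loadtxt(fh, dtype=float, ndmin=2)
            except ValueError as exc:
                raise ScanFormatError(f"{path}: malformed ASCII vertex data") \
                    from exc
            if data.shape != (n_vertex, 5):
                raise ScanFormatError(
                    f"{path}: expected {n_vertex} x 5 vertex rows, "
                    f"got {data.shape}")
    shape = (grid_rows, grid_cols)
    return _build_scan(
        data[:, 0].reshape(shape), data[:, 1].reshape(shape),
        data[:, 2].reshape(shape), data[:, 3].reshape(shape),
        data[:, 4].reshape(shape) != 0,
        1.0 if spacing is None else spacing,
        {"source": str(path), "format": "ply"},
    )


# ---------------------------------------------------------------------------
# Geometric utilities
# ---------------------------------------------------------------------------

def crop_roi(scan: BackScan, roi: ROI) -> BackScan:
    """Return the sub-scan covered by ``roi`` (coordinates unchanged)."""
    roi.check_within(scan)
    if roi.n_rows < 3 or roi.n_cols < 3:
        raise ValueError(f"cropped grid {roi.n_rows}x{roi.n_cols} "
                         "is smaller than 3x3")
    sl = (slice(roi.v_min, roi.v_max + 1), slice(roi.u_min, roi.u_max + 1))
    return BackScan(
        x=scan.x[sl].copy(), y=scan.y[sl].copy(), z=scan.z[sl].copy(),
        brightness=scan.brightness[sl].copy(),
        valid_mask=scan.valid_mask[sl].copy(),
        profile_spacing_mm=scan.profile_spacing_mm,
        metadata={**scan.metadata, "roi": f"{roi}"},
    )


def _rotated_yz(y: np.ndarray, z: np.ndarray, angle_deg: float):
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return c * y - s * z, s * y + c * z


def rotate_about_x(scan: BackScan, angle_deg: float) -> BackScan:
    """Rigidly rotate the surface about the X axis and re-grid.

    Each point's (Y, Z) is rotated by ``angle_deg``; the rotated profile is
    then resampled back onto the row's original uniform Y positions by
    linear interpolation so the result stays a graph Z(Y).  Cells whose Y
    position falls outside the rotated profile's span become invalid.

    The patient leaning slightly differently against the rest corresponds
    to exactly such a rotation, which is why detection is required to be
    insensitive to it.
    """
    y_new = scan.y.copy()
    z_new = np.full_like(scan.z, np.nan)
    b_new = np.zeros_like(scan.brightness)
    valid_new = np.zeros_like(scan.valid_mask)
    for v in range(scan.n_rows):
        m = scan.valid_mask[v]
        if m.sum() < 2:
            continue
        yr, zr = _rotated_yz(scan.y[v, m], scan.z[v, m], angle_deg)
        order = np.argsort(yr)
        yr, zr = yr[order], zr[order]
        br = scan.brightness[v, m][order]
        targets = scan.y[v]
        inside = (targets >= yr[0]) & (targets <= yr[-1])
        z_new[v, inside] = np.interp(targets[inside], yr, zr)
        b_new[v, inside] = np.interp(targets[inside], yr, br)
        valid_new[v, inside] = True
    z_new[~valid_new] = 0.0
    return BackScan(
        x=scan.x.copy(), y=y_new, z=z_new, brightness=b_new,
        valid_mask=valid_new,
        profile_spacing_mm=scan.profile_spacing_mm,
        metadata={**scan.metadata, "rotated_about_x_deg": f"{angle_deg:g}"},
    )
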