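"""Central-axis dose profiles: extraction, normalization and comparison.

Film profiles are compared against planned-dose profiles or independent
detector measurements (a parallel-plate chamber array sampled at 5 mm
pitch, or a scanning diode at 0.5 mm steps).  Profiles are conventionally
normalized to the mean value in the central 5 mm of the field, and per-point
percentage dose differences follow

    relative (with scaling):  100 * (D_meas,i * SF - D_ref,i) / D_global
    absolute (SF = 1):        100 * (D_meas,i        - D_ref,i) / D_global

where SF rescales the measured maximum to the reference maximum and
D_global is the maximum of the reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .planes import DosePlane, robust_max

#: Half-width (mm) of the central normalization window ("central 5 mm").
CENTRAL_WINDOW_HALF_MM = 2.5

#: Penumbra bounds as fractions of the central-axis value (20-80% convention).
PENUMBRA_LOW, PENUMBRA_HIGH = 0.2, 0.8


@dataclass
class Profile:
    axis: str  # "x" | "y"
    positions_mm: np.ndarray
    values: np.ndarray
    source: str = "film"  # film | plan | ic_profiler | diode
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_mm.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


@dataclass
class ProfileComparison:
    positions_mm: np.ndarray
    diff_pct: np.ndarray  # signed, per paired point
    sf: float
    d_global_gy: float
    mean_abs_diff_pct: float = field(init=False)
    max_abs_diff_pct: float = field(init=False)
    max_diff_position_mm: float = field(init=False)
    mean_signed_diff_pct: float = field(init=False)

    def __post_init__(self) -> None:
        ad = np.abs(self.diff_pct)
        self.mean_abs_diff_pct = float(ad.mean())
        self.max_abs_diff_pct = float(ad.max())
        self.max_diff_position_mm = float(self.positions_mm[int(np.argmax(ad))])
        self.mean_signed_diff_pct = float(self.diff_pct.mean())


# ---------------------------------------------------------------------------


def extract_profile(plane: DosePlane, axis: str, offset_mm: float = 0.0) -> Profile:
    """Bilinear samples along the central x or y axis at native spacing.

    ``offset_mm`` displaces the sampling line perpendicular to the axis
    (e.g. an off-axis x-profile at y = offset).  Samples falling outside the
    plane are dropped.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if axis == "x":
        positions = plane.x_coords()
        x, y = positions, np.full_like(positions, offset_mm)
    else:
        positions = plane.y_coords()[::-1]  # increasing
        x, y = np.full_like(positions, offset_mm), positions
    row, col = plane.xy_to_rowcol(x, y)
    nrow, ncol = plane.shape
    eps = 1e-9
    inside = (row >= -eps) & (row <= nrow - 1 + eps) & (col >= -eps) & (col <= ncol - 1 + eps)
    if not inside.any():
        raise ValueError(f"{axis}-profile at offset {offset_mm} mm lies outside the plane")
    row = np.clip(row[inside], 0, nrow - 1)
    col = np.clip(col[inside], 0, ncol - 1)
    values = ndimage.map_coordinates(plane.dose_gy, np.vstack([row, col]), order=1, mode="nearest")
    finite = np.isfinite(values)
    return Profile(
        axis=axis,
        positions_mm=positions[inside][finite],
        values=values[finite],
        source=plane.provenance if plane.provenance in ("film", "plan") else "plan",
    )


def normalize_profile(profile: Profile) -> Profile:
    """Divide by the mean value within the central 5 mm (|pos| <= 2.5 mm)."""
    window = np.abs(profile.positions_mm) <= CENTRAL_WINDOW_HALF_MM
    if not window.any():
        raise ValueError("no samples within the central 5 mm window")
    center = profile.values[window].mean()
    if center == 0:
        raise ValueError("central window mean is zero; cannot normalize")
    return Profile(
        axis=profile.axis,
        positions_mm=profile.positions_mm.copy(),
        values=profile.values / center,
        source=profile.source,
        normalized=True,
    )


def resample_to_positions(profile: Profile, positions_mm: np.ndarray) -> Profile:
    """Linear interpolation at detector/sampling positions (no extrapolation)."""
    positions_mm = np.asarray(positions_mm, dtype=float)
    lo, hi = profile.positions_mm[0], profile.positions_mm[-1]
    if positions_mm.min() < lo - 1e-9 or positions_mm.max() > hi + 1e-9:
        raise ValueError(
            f"requested positions [{positions_mm.min():g}, {positions_mm.max():g}] mm "
            f"extend beyond the profile span [{lo:g}, {hi:g}] mm"
        )
    values = np.interp(positions_mm, profile.positions_mm, profile.values)
    return Profile(
        axis=profile.axis,
        positions_mm=positions_mm,
        values=values,
        source=profile.source,
        normalized=profile.normalized,
    )


def detector_positions(span_mm: float, spacing_mm: float) -> np.ndarray:
    """Symmetric detector sampling positions: 0, ±s, ±2s ... within ±span/2."""
    n = int(np.floor(span_mm / 2.0 / spacing_mm))
    return np.arange(-n, n + 1) * spacing_mm


def compare_profiles(
    measured: Profile,
    reference: Profile,
    mode: str = "relative_sf",
    use_robust_max: bool = True,
) -> ProfileComparison:
    """Per-point % dose differences between a measured and reference profile.

    Both profiles must already share positions (see
    :func:`resample_to_positions`).  ``relative_sf`` applies the scaling
    factor SF = max(reference)/max(measured) to the measured values first;
    ``absolute`` uses SF = 1.  Differences are expressed as % of the
    reference maximum (D_global).  The summary reports mean and max of the
    absolute per-point differences (signed values are retained).
    """
    if mode not in ("relative_sf", "absolute"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    if measured.positions_mm.shape != reference.positions_mm.shape or not np.allclose(
        measured.positions_mm, reference.positions_mm
    ):
        raise ValueError("profiles must be resampled to common positions before comparison")
    maxfun = robust_max if use_robust_max else (lambda v: float(np.max(v)))
    d_global = maxfun(reference.values)
    if d_global <= 0:
        raise ValueError("reference profile maximum must be positive")
    sf = d_global / maxfun(measured.values) if mode == "relative_sf" else 1.0
    diff = 100.0 * (measured.values * sf - reference.values) / d_global
    return ProfileComparison(
        positions_mm=reference.positions_mm.copy(),
        diff_pct=diff,
        sf=float(sf),
        d_global_gy=float(d_global),
    )


# ---------------------------------------------------------------------------


def _crossings(positions: np.ndarray, values: np.ndarray, level: float) -> list[float]:
    """All linearly interpolated crossings of ``values`` through ``level``."""
    out = []
    for i in range(len(values) - 1):
        v0, v1 = values[i], values[i + 1]
        if (v0 - level) * (v1 - level) < 0:
            t = (level - v0) / (v1 - v0)
            out.append(float(positions[i] + t * (positions[i + 1] - positions[i])))
        elif v0 == level and (i == 0 or values[i - 1] != level):
            out.append(float(positions[i]))
    return out


def field_metrics(profile: Profile) -> tuple[float, float, float]:
    """(FWHM, left penumbra width, right penumbra width) in mm.

    FWHM is the distance between the 50% crossings of the central-axis
    value; penumbra widths are the 20%-80% distances on each edge.  The
    profile must contain a single connected high-dose region.
    """
    pos, val = profile.positions_mm, profile.values
    center_idx = int(np.argmin(np.abs(pos)))
    central = val[center_idx]
    if central <= 0:
        raise ValueError("central-axis value must be positive")
    rel = val / central

    def edge_crossings(level: float) -> tuple[float, float]:
        xs = _crossings(pos, rel, level)
        below_left = [x for x in xs if x < pos[center_idx]]
        below_right = [x for x in xs if x > pos[center_idx]]
        if not below_left or not below_right:
            raise ValueError(f"profile has no {100 * level:g}% crossing on both sides")
        return max(below_left), min(below_right)

    l50, r50 = edge_crossings(0.5)
    fwhm = r50 - l50
    l20, r20 = edge_crossings(PENUMBRA_LOW)
    l80, r80 = edge_crossings(PENUMBRA_HIGH)
    return fwhm, abs(l80 - l20), abs(r20 - r80)


def read_detector_csv(path: str | Path) -> Profile:
    """Read a two-column ``position_mm,dose`` detector CSV.

    A leading ``# source: ic_profiler|diode`` comment sets the source tag;
    an optional ``# axis: x|y`` comment sets the axis (default x).
    """
    path = Path(path)
    source, axis = "ic_profiler", "x"
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() == "source":
                source = value.strip()
            elif key.strip() == "axis":
                axis = value.strip()
            continue
        if line.lower().startswith("position"):
            continue
        p, d = line.split(",")
        rows.append((float(p), float(d)))
    rows.sort()
    arr = np.array(rows)
    return Profile(axis=axis, positions_mm=arr[:, 0], values=arr[:, 1], source=source)


def write_detector_csv(profile: Profile, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# source: {profile.source}", f"# axis: {profile.axis}", "position_mm,dose"]
    lines += [f"{p:.6g},{v:.9g}" for p, v in zip(profile.positions_mm, profile.values)]
    path.write_text("\n".join(lines) + "\n")
    return path
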