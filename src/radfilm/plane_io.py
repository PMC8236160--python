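"""Reading, writing, resampling and registering planar dose grids.

Three on-disk forms are supported:

* DICOM RT Dose (read only) — a single coronal frame is extracted and
  ``DoseGridScaling`` is applied to give Gy.
* A plain-text grid dialect (read/write): comment header lines carrying the
  unit, pixel spacing and origin, followed by whitespace-separated rows with
  row 0 at the top (largest y).
* A flat binary container (read/write): raw little-endian float64 pixels with
  a JSON sidecar describing geometry — lossless round trips.

Film-to-plan registration is fiducial-driven: the user marks the film pixel
that lay at the room lasers' crosshair (the plan origin) and states the
rotation/flip; no automatic dose-based registration is attempted, so spatial
delivery errors remain visible to the downstream gamma analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .planes import DosePlane

_MAX_GRID = 4096

_TEXT_SUFFIX = ".txt"
_BINARY_SUFFIX = ".raw"


class PlaneFormatError(ValueError):
    """Raised when an on-disk plane cannot be interpreted."""


@dataclass
class RegistrationSpec:
    """Rigid film-to-plan registration parameters from laser fiducials.

    ``film_center_px`` is the (row, col) film pixel (fractional allowed) that
    was marked at the laser crosshair, i.e. the point that maps to the plan's
    isocenter (0, 0).  ``rotation_deg`` rotates the film counter-clockwise in
    the plan frame; ``flip_lr`` mirrors the film left-right first.
    """

    film_center_px: tuple[float, float]
    rotation_deg: float = 0.0
    flip_lr: bool = False

    def __post_init__(self) -> None:
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ValueError("rotation_deg must lie in (-180, 180]")


# ---------------------------------------------------------------------------
# text / binary dialects
# ---------------------------------------------------------------------------

def write_plane(plane: DosePlane, path: str | Path, fmt: str = "text") -> Path:
    """Write a plane to ``path`` in ``text`` or ``binary`` format."""
    path = Path(path)
    if fmt == "text":
        header = (
            f"# unit: {plane.unit}\n"
            f"# spacing_mm: {plane.pixel_spacing_mm[0]:.10g} {plane.pixel_spacing_mm[1]:.10g}\n"
            f"# origin_mm: {plane.origin_mm[0]:.10g} {plane.origin_mm[1]:.10g}\n"
            f"# provenance: {plane.provenance}\n"
            f"# label: {plane.label}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, plane.dose_gy, fmt="%.9e")
    elif fmt == "binary":
        path.write_bytes(np.ascontiguousarray(plane.dose_gy, dtype="<f8").tobytes())
        sidecar = {
            "shape": list(plane.shape),
            "dtype": "<f8",
            "unit": plane.unit,
            "spacing_mm": list(plane.pixel_spacing_mm),
            "origin_mm": list(plane.origin_mm),
            "provenance": plane.provenance,
            "label": plane.label,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'text' or 'binary'")
    return path


def _read_text_plane(path: Path) -> DosePlane:
    header: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                header[key.strip()] = value.strip()
            else:
                rows.append(line)
    if "spacing_mm" not in header:
        raise PlaneFormatError(f"{path}: missing '# spacing_mm' header line")
    values = np.array([[float(v) for v in r.split()] for r in rows], dtype=float)
    sx, sy = (float(v) for v in header["spacing_mm"].split())
    ox, oy = (float(v) for v in header.get("origin_mm", "0 0").split())
    return DosePlane(
        values,
        (sx, sy),
        (ox, oy),
        provenance=header.get("provenance", "plan"),  # type: ignore[arg-type]
        label=header.get("label", ""),
        unit=header.get("unit", "Gy"),
    )


def _read_binary_plane(path: Path) -> DosePlane:
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise PlaneFormatError(f"{path}: missing JSON sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    values = np.frombuffer(path.read_bytes(), dtype=meta["dtype"]).reshape(meta["shape"])
    return DosePlane(
        values.astype(float),
        tuple(meta["spacing_mm"]),
        tuple(meta["origin_mm"]),
        provenance=meta.get("provenance", "plan"),
        label=meta.get("label", ""),
        unit=meta.get("unit", "Gy"),
    )


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

def _read_dicom_plane(path: Path, frame: int | None) -> DosePlane:
    import pydicom

    ds = pydicom.dcmread(path, force=True)
    if "DoseGridScaling" not in ds:
        raise PlaneFormatError(f"{path}: RT Dose is missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    pixels = ds.pixel_array
    if pixels.ndim == 3:
        if frame is None:
            raise PlaneFormatError(
                f"{path}: multi-frame dose grid ({pixels.shape[0]} frames) "
                "requires an explicit frame index"
            )
        pixels = pixels[frame]
    dose = pixels.astype(float) * scaling
    if max(dose.shape) > _MAX_GRID:
        raise PlaneFormatError(f"{path}: grid {dose.shape} exceeds {_MAX_GRID} pixels per axis")
    sy, sx = (float(v) for v in ds.PixelSpacing)  # DICOM: (row, col) spacing
    if "ImagePositionPatient" in ds:
        ipp = [float(v) for v in ds.ImagePositionPatient]
        ox, oy = ipp[0], -ipp[1]
    else:
        rows, cols = dose.shape
        ox, oy = -sx * (cols - 1) / 2.0, sy * (rows - 1) / 2.0
    return DosePlane(dose, (sx, sy), (ox, oy), provenance="plan", label=path.name)


def read_plan_plane(path: str | Path, frame: int | None = None) -> DosePlane:
    """Read a planned dose plane (DICOM RT Dose, text dialect, or binary).

    The format is chosen by suffix: ``.dcm`` → DICOM, ``.raw`` → binary,
    anything else → text dialect.  DICOM stored values are converted to Gy
    via ``DoseGridScaling``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".dcm":
        plane = _read_dicom_plane(path, frame)
    elif path.suffix.lower() == _BINARY_SUFFIX:
        plane = _read_binary_plane(path)
    else:
        plane = _read_text_plane(path)
    if max(plane.shape) > _MAX_GRID:
        raise PlaneFormatError(f"{path}: grid {plane.shape} exceeds {_MAX_GRID} pixels per axis")
    return plane


def read_plane(path: str | Path) -> DosePlane:
    """Alias of :func:`read_plan_plane` for planes of any provenance."""
    return read_plan_plane(path)


# ---------------------------------------------------------------------------
# resampling and registration
# ---------------------------------------------------------------------------

def _sample_plane(plane: DosePlane, x: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    """Interpolate plane values at physical positions; outside → NaN."""
    row, col = plane.xy_to_rowcol(x, y)
    nrow, ncol = plane.shape
    eps = 1e-9
    inside = (row >= -eps) & (row <= nrow - 1 + eps) & (col >= -eps) & (col <= ncol - 1 + eps)
    row = np.clip(row, 0, nrow - 1)
    col = np.clip(col, 0, ncol - 1)
    order = {"bilinear": 1, "nearest": 0}[method]
    out = ndimage.map_coordinates(
        plane.dose_gy, np.vstack([row.ravel(), col.ravel()]), order=order, mode="nearest"
    ).reshape(row.shape)
    out = np.where(inside, out, np.nan)
    return out


def resample_plane(
    plane: DosePlane,
    new_spacing_mm: float | tuple[float, float] | None = None,
    target: DosePlane | None = None,
    method: str = "bilinear",
) -> DosePlane:
    """Resample a plane to a new pixel pitch or onto another plane's grid.

    Interpolation is bilinear (or nearest) on pixel-center coordinates.
    Target pixels outside the source extent are NaN.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown interpolation method {method!r}")
    if (new_spacing_mm is None) == (target is None):
        raise ValueError("specify exactly one of new_spacing_mm or target")
    if target is not None:
        xs, ys = target.x_coords(), target.y_coords()
        spacing = target.pixel_spacing_mm
        origin = target.origin_mm
    else:
        if np.isscalar(new_spacing_mm):
            spacing = (float(new_spacing_mm), float(new_spacing_mm))  # type: ignore[arg-type]
        else:
            spacing = (float(new_spacing_mm[0]), float(new_spacing_mm[1]))  # type: ignore[index]
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValueError("target spacing must be positive")
        x0, x1 = plane.x_coords()[0], plane.x_coords()[-1]
        y0, y1 = plane.y_coords()[-1], plane.y_coords()[0]  # min, max
        xs = np.arange(x0, x1 + spacing[0] / 2, spacing[0])
        ys = np.arange(y1, y0 - spacing[1] / 2, -spacing[1])
        origin = (float(xs[0]), float(ys[0]))
    xx, yy = np.meshgrid(xs, ys)
    values = _sample_plane(plane, xx, yy, method)
    return DosePlane(
        values, spacing, origin, provenance=plane.provenance, label=plane.label, unit=plane.unit
    )


def register_film_to_plan(
    film: DosePlane,
    plan: DosePlane,
    spec: RegistrationSpec,
    overlap_threshold_pct: float = 10.0,
) -> tuple[DosePlane, DosePlane]:
    """Map a film plane onto the plan grid using laser-fiducial registration.

    The film pixel ``spec.film_center_px`` is placed at the plan origin, the
    film is rotated by ``rotation_deg`` (counter-clockwise, about that
    center) and optionally mirrored left-right, then resampled bilinearly
    onto the plan's pixel grid.  Returns ``(film_on_plan_grid, plan)``.

    A warning is attached to the result's ``meta`` if less than half of the
    plan area above ``overlap_threshold_pct`` % of its maximum is covered by
    valid film pixels.
    """
    xs, ys = plan.x_coords(), plan.y_coords()
    xx, yy = np.meshgrid(xs, ys)

    # invert: plan position p -> film-frame offset q = S · R(-theta) · p
    theta = np.deg2rad(spec.rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    qx = c * xx + s * yy
    qy = -s * xx + c * yy
    if spec.flip_lr:
        qx = -qx

    sx, sy = film.pixel_spacing_mm
    r0, c0 = spec.film_center_px
    col = c0 + qx / sx
    row = r0 - qy / sy

    nrow, ncol = film.shape
    eps = 1e-9
    inside = (row >= -eps) & (row <= nrow - 1 + eps) & (col >= -eps) & (col <= ncol - 1 + eps)
    row = np.clip(row, 0, nrow - 1)
    col = np.clip(col, 0, ncol - 1)
    values = ndimage.map_coordinates(
        film.dose_gy, np.vstack([row.ravel(), col.ravel()]), order=1, mode="nearest"
    ).reshape(row.shape)
    values = np.where(inside, values, np.nan)

    out = DosePlane(
        values,
        plan.pixel_spacing_mm,
        plan.origin_mm,
        provenance="film",
        label=film.label,
        unit=film.unit,
        meta=dict(film.meta),
    )
    roi = plan.dose_gy > overlap_threshold_pct / 100.0 * plan.max_dose()
    if roi.any():
        covered = np.isfinite(values) & roi
        coverage = covered.sum() / roi.sum()
        out.meta["registration_coverage"] = float(coverage)
        if coverage < 0.5:
            out.meta["registration_warning"] = (
                f"film covers only {100 * coverage:.1f}% of the plan's in-threshold area"
            )
    return out, plan
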