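"""Synthetic inputs for the film-QA pipeline, with seeded reproducibility.

No public film-scan or planar-dose dataset accompanies this kind of QA
work, so every pipeline input is generated here:

* planned open square fields (0.83 x 0.83 cm^2 up to 19.92 x 19.92 cm^2)
  with error-function penumbrae,
* the nine-level 3x3 calibration grid (3-21 Gy),
* simulated four-orientation flatbed scans of a film exposed to any dose
  plane, using a monotone cubic netOD-dose response per color channel,
  multiplicative per-pixel scanner noise, and an optional lateral-response
  multiplicative OD bias peaking at the film edges,
* PSQA-style patterned plans with injectable delivery errors (global
  scaling, translation, hotspot) to exercise gamma sensitivity.

The film response model is synthetic: its cubic coefficients are chosen for
plausible netOD magnitudes (about 0.45 at 10 Gy on red, 0.55 at 21 Gy on
green), not measured from any physical film lot.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

from .calibration import GridGeometry, standard_grid_doses
from .planes import DosePlane, centered_plane
from .scan_processing import CHANNELS, FilmScanImage, Orientation

#: Open-field edge lengths used for uniformity tests (cm).
STANDARD_FIELD_SIZES_CM = (0.83, 1.66, 2.49, 4.98, 9.96, 14.94, 19.92)

_INVERSE_KNOTS = 4097


@dataclass
class FieldSpec:
    """Geometry of a synthetic open square field.

    ``extent_mm`` is the full plane width/height; it defaults to the field
    size plus a 50 mm margin (and always at least field + 6 sigma, so the
    penumbra tails are contained).
    """

    size_cm: float | tuple[float, float]
    d_max_gy: float = 5.0
    penumbra_sigma_mm: float = 1.5
    spacing_mm: float = 0.5
    extent_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if np.isscalar(self.size_cm):
            self.size_cm = (float(self.size_cm), float(self.size_cm))  # type: ignore[assignment]
        if min(self.size_cm) <= 0 or self.d_max_gy <= 0:
            raise ValueError("field size and dose must be positive")
        if self.penumbra_sigma_mm <= 0 or self.spacing_mm <= 0:
            raise ValueError("penumbra sigma and spacing must be positive")
        size_mm = (10.0 * self.size_cm[0], 10.0 * self.size_cm[1])
        if self.extent_mm is None:
            margin = max(50.0, 6.0 * self.penumbra_sigma_mm)
            self.extent_mm = (size_mm[0] + margin, size_mm[1] + margin)
        if (self.extent_mm[0] < size_mm[0] + 6 * self.penumbra_sigma_mm
                or self.extent_mm[1] < size_mm[1] + 6 * self.penumbra_sigma_mm):
            raise ValueError("extent must cover the field plus 6 penumbra sigmas")

    @property
    def size_mm(self) -> tuple[float, float]:
        return (10.0 * self.size_cm[0], 10.0 * self.size_cm[1])


def _edge_profile(t: np.ndarray, width_mm: float, sigma_mm: float) -> np.ndarray:
    """1-D field shape: unit plateau of ``width`` with erf-blurred edges."""
    s = sigma_mm * np.sqrt(2.0)
    return 0.5 * (special.erf((t + width_mm / 2) / s) - special.erf((t - width_mm / 2) / s))


def _symmetric_axis(extent_mm: float, spacing_mm: float) -> np.ndarray:
    n = int(np.floor(extent_mm / 2.0 / spacing_mm))
    return np.arange(-n, n + 1) * spacing_mm


def make_open_field_plane(spec: FieldSpec) -> DosePlane:
    """Separable open-field dose plane D(x, y) = d_max E(x) E(y), centered."""
    xs = _symmetric_axis(spec.extent_mm[0], spec.spacing_mm)
    ys = _symmetric_axis(spec.extent_mm[1], spec.spacing_mm)
    ex = _edge_profile(xs, spec.size_mm[0], spec.penumbra_sigma_mm)
    ey = _edge_profile(ys, spec.size_mm[1], spec.penumbra_sigma_mm)
    dose = spec.d_max_gy * np.outer(ey[::-1], ex)  # row 0 = top (largest y)
    return centered_plane(dose, spec.spacing_mm, provenance="synthetic",
                          label=f"open field {spec.size_cm[0]:g}x{spec.size_cm[1]:g} cm2")


def make_calibration_grid_plane(
    doses_gy: Sequence[float] | None = None,
    geometry: GridGeometry | None = None,
    sigma_mm: float = 1.5,
    spacing_mm: float = 0.5,
) -> DosePlane:
    """Nine-block calibration-grid dose plane on a film-sized canvas.

    Each block is an erf-edged square field at its grid position; the block
    interiors carry the requested dose levels (standard nine-level pattern
    by default, row-major).  Blocks must stay separated after blurring.
    """
    if doses_gy is None:
        doses_gy = standard_grid_doses()
    geometry = geometry or GridGeometry()
    if len(doses_gy) != geometry.n_rows * geometry.n_cols:
        raise ValueError(f"expected {geometry.n_rows * geometry.n_cols} doses, got {len(doses_gy)}")
    gap_x = geometry.block_pitch_mm[0] - geometry.block_size_mm[0]
    gap_y = geometry.block_pitch_mm[1] - geometry.block_size_mm[1]
    if min(gap_x, gap_y) < 6 * sigma_mm and geometry.n_rows * geometry.n_cols > 1:
        raise ValueError("blocks would overlap after edge blur (pitch < size + 6 sigma)")
    w_mm, h_mm = geometry.film_size_mm
    ncol = int(round(w_mm / spacing_mm)) + 1
    nrow = int(round(h_mm / spacing_mm)) + 1
    # image-frame coordinates: x right, y down, from the top-left pixel center
    xi = spacing_mm * np.arange(ncol)
    yi = spacing_mm * np.arange(nrow)
    dose = np.zeros((nrow, ncol))
    map_size = (xi[-1], yi[-1])
    for d, (cx, cy) in zip(doses_gy, geometry.block_centers_mm(map_size)):
        ex = _edge_profile(xi - cx, geometry.block_size_mm[0], sigma_mm)
        ey = _edge_profile(yi - cy, geometry.block_size_mm[1], sigma_mm)
        dose += d * np.outer(ey, ex)
    return centered_plane(dose, spacing_mm, provenance="synthetic", label="calibration grid")


# ---------------------------------------------------------------------------
# film response model
# ---------------------------------------------------------------------------


@dataclass
class FilmModel:
    """Synthetic film + scanner response.

    ``coefficients`` are per-channel (a0..a3) of the netOD→dose cubic; film
    exposure inverts this numerically (tabulated inverse, linear
    interpolation on a dense knot grid).  ``noise_sigma_fraction`` is the
    relative sigma of multiplicative Gaussian pixel-value noise;
    ``lateral_amplitude`` the peak fractional OD bias at the film's
    left/right edge (parabolic across the scan axis, 0 disables it).
    """

    coefficients: dict[str, tuple[float, float, float, float]]
    netod_max: dict[str, float]
    unexposed_pv: dict[str, int]
    noise_sigma_fraction: float = 0.0
    lateral_amplitude: float = 0.0
    seed: int = 0
    _inverse_tables: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.noise_sigma_fraction < 0 or self.lateral_amplitude < 0:
            raise ValueError("noise and lateral amplitude must be non-negative")
        for ch in CHANNELS:
            if not 0 < self.unexposed_pv[ch] <= 65535:
                raise ValueError(f"unexposed PV for {ch} must lie in (0, 65535]")
            knots = np.linspace(0.0, self.netod_max[ch], _INVERSE_KNOTS)
            doses = self._cubic(ch, knots)
            if np.any(np.diff(doses) <= 0):
                raise ValueError(f"{ch} response is not monotone over its netOD range")
            self._inverse_tables[ch] = (doses, knots)

    def _cubic(self, channel: str, x: np.ndarray) -> np.ndarray:
        a0, a1, a2, a3 = self.coefficients[channel]
        return a0 + x * (a1 + x * (a2 + x * a3))

    def max_dose_gy(self, channel: str) -> float:
        return float(self._inverse_tables[channel][0][-1])

    def netod_from_dose(self, channel: str, dose_gy: np.ndarray) -> np.ndarray:
        doses, knots = self._inverse_tables[channel]
        dose_gy = np.asarray(dose_gy, dtype=float)
        if np.nanmax(dose_gy, initial=0.0) > doses[-1] + 1e-9:
            raise ValueError(
                f"dose {np.nanmax(dose_gy):.2f} Gy exceeds the {channel} channel's "
                f"maximum representable dose {doses[-1]:.2f} Gy"
            )
        return np.interp(dose_gy, doses, knots)


def default_film_model(
    seed: int = 0, noise_sigma_fraction: float = 0.0, lateral_amplitude: float = 0.0
) -> FilmModel:
    """A plausible synthetic triple-channel response (not a measured film)."""
    return FilmModel(
        coefficients={
            "red": (0.0, 13.0, 6.0, 32.0),    # netOD 0.45 -> ~10 Gy
            "green": (0.0, 19.0, 8.0, 48.0),  # netOD 0.55 -> ~21 Gy
            "blue": (0.0, 30.0, 15.0, 80.0),  # least sensitive
        },
        netod_max={"red": 0.90, "green": 0.85, "blue": 0.80},
        unexposed_pv={"red": 42000, "green": 44000, "blue": 46000},
        noise_sigma_fraction=noise_sigma_fraction,
        lateral_amplitude=lateral_amplitude,
        seed=seed,
    )


_SCAN_ORIENTATIONS = (Orientation.ORIGINAL, Orientation.VFLIP, Orientation.HFLIP, Orientation.ROT180)


def simulate_film_scan(
    dose: DosePlane, model: FilmModel
) -> tuple[list[FilmScanImage], FilmScanImage]:
    """Simulate the four-orientation scan set of an exposed film.

    Per pixel and channel the dose is inverted to netOD, the optional
    lateral OD bias applied (parabolic in the distance from the vertical
    scanner midline), and converted to a transmission pixel value
    PV = PV_unexposed * 10^(-netOD).  The four scans are the tagged flips of
    that noiseless geometry, each with an independent multiplicative noise
    draw; the unexposed companion scan gets its own draw.  Returns
    ``(scans, unexposed_scan)``.
    """
    rng = np.random.default_rng(model.seed)
    dose_vals = np.nan_to_num(dose.dose_gy, nan=0.0)
    nrow, ncol = dose_vals.shape
    xs = np.arange(ncol, dtype=float)
    half_width = (ncol - 1) / 2.0
    lateral = 1.0 + model.lateral_amplitude * ((xs - half_width) / half_width) ** 2 \
        if model.lateral_amplitude > 0 and ncol > 1 else np.ones(ncol)

    pv = np.empty((nrow, ncol, 3))
    for k, ch in enumerate(CHANNELS):
        netod = model.netod_from_dose(ch, dose_vals)
        netod = netod * lateral[None, :]
        pv[:, :, k] = model.unexposed_pv[ch] * np.power(10.0, -netod)

    dpi = 25.4 / dose.pixel_spacing_mm[0]

    def finish(raw: np.ndarray) -> np.ndarray:
        if model.noise_sigma_fraction > 0:
            raw = raw * (1.0 + model.noise_sigma_fraction * rng.standard_normal(raw.shape))
        return np.clip(np.rint(raw), 0, 65535).astype(np.uint16)

    scans = []
    for i, orient in enumerate(_SCAN_ORIENTATIONS, start=1):
        geom = pv
        if orient in (Orientation.VFLIP, Orientation.ROT180):
            geom = geom[::-1, :, :]
        if orient in (Orientation.HFLIP, Orientation.ROT180):
            geom = geom[:, ::-1, :]
        scans.append(FilmScanImage(finish(geom), dpi=dpi, orientation=orient, scan_index=i))

    unexp_raw = np.empty_like(pv)
    for k, ch in enumerate(CHANNELS):
        unexp_raw[:, :, k] = model.unexposed_pv[ch]
    unexposed = FilmScanImage(finish(unexp_raw), dpi=dpi, orientation=Orientation.ORIGINAL)
    return scans, unexposed


# ---------------------------------------------------------------------------
# PSQA-style patterned cases with injectable delivery errors
# ---------------------------------------------------------------------------


@dataclass
class PSQACase:
    plan: DosePlane
    delivered: DosePlane  # plan with injected errors; what the film "saw"
    scans: list[FilmScanImage]
    unexposed: FilmScanImage


def _translate_plane(plane: DosePlane, shift_mm: tuple[float, float]) -> DosePlane:
    """Shift a plane's dose pattern by (dx, dy) mm on its own grid."""
    from .plane_io import resample_plane

    moved = plane.copy()
    moved.origin_mm = (plane.origin_mm[0] + shift_mm[0], plane.origin_mm[1] + shift_mm[1])
    out = resample_plane(moved, target=plane)
    out.dose_gy = np.nan_to_num(out.dose_gy, nan=0.0)
    return out


def make_psqa_pair(
    pattern: str,
    params: dict | None = None,
    model: FilmModel | None = None,
) -> PSQACase:
    """A patterned plan plus simulated film scans with injectable errors.

    Patterns: ``two_level`` (a broad field with a central boost),
    ``wedge`` (a linear dose gradient across the field) and
    ``offset_hotspot`` (an off-axis Gaussian boost).  Error-injection
    params: ``scale_error`` (delivered = scale x plan), ``shift_mm``
    ((dx, dy) translation) and ``blob`` ((amp_gy, sigma_mm, x_mm, y_mm)
    additive Gaussian).
    """
    params = dict(params or {})
    model = model or default_film_model()
    size = params.pop("field_size_cm", 9.96)
    d_max = params.pop("d_max_gy", 8.0)
    spacing = params.pop("spacing_mm", 0.5)
    sigma = params.pop("penumbra_sigma_mm", 1.5)
    spec = FieldSpec(size, d_max_gy=d_max, spacing_mm=spacing, penumbra_sigma_mm=sigma)
    plan = make_open_field_plane(spec)
    xx, yy = np.meshgrid(plan.x_coords(), plan.y_coords())

    if pattern == "two_level":
        boost = params.pop("boost_fraction", 0.5)
        inner = FieldSpec(size / 2.0, d_max_gy=d_max * boost, spacing_mm=spacing,
                          penumbra_sigma_mm=sigma, extent_mm=spec.extent_mm)
        plan.dose_gy = plan.dose_gy + make_open_field_plane(inner).dose_gy
    elif pattern == "wedge":
        grad = params.pop("gradient", 0.3)
        half = spec.size_mm[0] / 2.0
        plan.dose_gy = plan.dose_gy * (1.0 + grad * np.clip(xx / half, -1, 1))
    elif pattern == "offset_hotspot":
        amp = params.pop("hotspot_amp_fraction", 0.3)
        hs_sigma = params.pop("hotspot_sigma_mm", 8.0)
        off = params.pop("hotspot_offset_mm", spec.size_mm[0] / 4.0)
        plan.dose_gy = plan.dose_gy + d_max * amp * np.exp(
            -(((xx - off) ** 2 + yy**2) / (2 * hs_sigma**2))
        ) * (plan.dose_gy > 0.05 * d_max)
    else:
        raise ValueError(f"unknown PSQA pattern {pattern!r}")
    plan.provenance = "plan"
    plan.label = f"psqa {pattern}"

    delivered = plan.copy()
    scale_error = params.pop("scale_error", 1.0)
    shift = params.pop("shift_mm", (0.0, 0.0))
    blob = params.pop("blob", None)
    if params:
        raise ValueError(f"unknown parameters: {sorted(params)}")
    delivered.dose_gy = delivered.dose_gy * scale_error
    if shift != (0.0, 0.0):
        delivered = _translate_plane(delivered, shift)
    if blob is not None:
        amp, bsigma, bx, by = blob
        delivered.dose_gy = delivered.dose_gy + amp * np.exp(
            -(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * bsigma**2))
        )
    delivered.provenance = "synthetic"
    scans, unexposed = simulate_film_scan(delivered, model)
    return PSQACase(plan=plan, delivered=delivered, scans=scans, unexposed=unexposed)
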