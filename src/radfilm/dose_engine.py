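"""Convert a netOD map into a calibrated film dose plane.

The fitted cubic is evaluated per pixel on the chosen channel.  Outside the
calibrated netOD span the cubic is not trusted: netOD above the largest
fitted point is clamped there (the film is saturated for this curve) and
the pixel flagged; below the smallest point the cubic is still evaluated
but any negative dose is floored to 0 Gy and flagged separately.
"""

from __future__ import annotations

import logging

import numpy as np

from .calibration import CalibrationCurve, channel_index, select_channel
from .planes import DosePlane, centered_plane
from .scan_processing import NetODMap

logger = logging.getLogger(__name__)


def apply_calibration(
    netod_map: NetODMap,
    curve: CalibrationCurve,
    channel: str = "auto",
    max_plan_dose_gy: float | None = None,
    origin_mm: tuple[float, float] | None = None,
) -> DosePlane:
    """Evaluate the calibration cubic on one channel of a netOD map.

    ``channel='auto'`` applies the dose-range policy (red <= 10 Gy, green
    above) using ``max_plan_dose_gy``; an explicit channel must match the
    curve's.  The returned plane is centered at isocenter unless
    ``origin_mm`` is given; provenance is ``film``.
    """
    if channel == "auto":
        if max_plan_dose_gy is None:
            raise ValueError("channel='auto' requires max_plan_dose_gy")
        channel = select_channel(max_plan_dose_gy)
    if channel != curve.channel:
        raise ValueError(
            f"requested channel {channel!r} but calibration curve is for {curve.channel!r}"
        )
    x = netod_map.netod[:, :, channel_index(channel)].copy()
    lo, hi = curve.netod_span()
    saturated = x > hi
    x[saturated] = hi
    dose = np.asarray(curve.dose(x), dtype=float)
    floored = dose < 0
    dose[floored] = 0.0

    n_sat, n_floor = int(saturated.sum()), int(floored.sum())
    if n_sat:
        logger.warning("%d pixels above the calibrated netOD span were clamped", n_sat)
    plane = centered_plane(dose, netod_map.pixel_spacing_mm, provenance="film")
    if origin_mm is not None:
        plane.origin_mm = (float(origin_mm[0]), float(origin_mm[1]))
    plane.meta.update(
        {
            "channel": channel,
            "n_saturated_pixels": n_sat,
            "n_floored_pixels": n_floor,
            "calibration_coefficients": list(curve.coefficients),
        }
    )
    return plane


def saturation_report(plane: DosePlane) -> dict:
    """Counts and fractions of clamped (saturated) and dose-floored pixels."""
    if "n_saturated_pixels" not in plane.meta:
        raise ValueError("plane was not produced by apply_calibration")
    n = plane.dose_gy.size
    n_sat = plane.meta["n_saturated_pixels"]
    n_floor = plane.meta["n_floored_pixels"]
    report = {
        "n_pixels": n,
        "n_saturated": n_sat,
        "fraction_saturated": n_sat / n,
        "n_floored": n_floor,
        "fraction_floored": n_floor / n,
    }
    logger.info("saturation report: %s", report)
    return report
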