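"""netOD-to-dose calibration from the nine-level grid pattern.

A calibration film is irradiated with a 3x3 grid of known dose levels
(3-21 Gy for the high-dose curve).  The mean netOD inside each block gives
nine (netOD, dose) pairs per color channel, to which a third-order
polynomial dose = a0 + a1*x + a2*x^2 + a3*x^3 (x = netOD) is fitted by
ordinary least squares.  The red channel is used for plans up to 10 Gy
(where its sensitometric slope is steepest) and the green channel above.

Curves measured under different conditions are compared by sampling both
over their common netOD span and computing the Pearson correlation of the
sampled dose vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .scan_processing import CHANNELS, NetODMap

#: Nine-level calibration pattern doses in row-major grid order (Gy).
STANDARD_GRID_DOSES_GY = (3.0, 6.25, 7.75, 10.0, 13.0, 15.0, 16.25, 19.25, 21.0)

#: Red channel for low-dose work, green above this plan maximum (Gy).
RED_CHANNEL_MAX_DOSE_GY = 10.0


def standard_grid_doses() -> list[float]:
    """The standard nine-level grid doses (Gy), row-major."""
    return list(STANDARD_GRID_DOSES_GY)


@dataclass
class GridGeometry:
    """Placement of the 3x3 calibration blocks on the scanned film.

    Distances are mm in the image frame: x right, y down, measured from the
    center of the top-left pixel.  ``origin_mm`` is the center of block
    (0, 0); ``None`` centers the grid on the map.  ``margin_fraction``
    symmetrically shrinks each block before taking its mean netOD, so edge
    blur and penumbra never contaminate the calibration samples.
    """

    n_rows: int = 3
    n_cols: int = 3
    block_size_mm: tuple[float, float] = (40.0, 40.0)
    block_pitch_mm: tuple[float, float] = (60.0, 60.0)
    origin_mm: tuple[float, float] | None = None
    margin_fraction: float = 0.25
    film_size_mm: tuple[float, float] = (203.2, 254.0)

    def __post_init__(self) -> None:
        if not (0 <= self.margin_fraction < 0.5):
            raise ValueError("margin_fraction must lie in [0, 0.5)")
        if (self.block_size_mm[0] > self.block_pitch_mm[0]
                or self.block_size_mm[1] > self.block_pitch_mm[1]):
            raise ValueError("block size must not exceed block pitch")

    def block_centers_mm(self, map_size_mm: tuple[float, float] | None = None) -> list[tuple[float, float]]:
        """Row-major (x, y) block centers; auto-centered if origin is None."""
        if self.origin_mm is not None:
            ox, oy = self.origin_mm
        else:
            if map_size_mm is None:
                map_size_mm = self.film_size_mm
            ox = (map_size_mm[0] - (self.n_cols - 1) * self.block_pitch_mm[0]) / 2.0
            oy = (map_size_mm[1] - (self.n_rows - 1) * self.block_pitch_mm[1]) / 2.0
        return [
            (ox + j * self.block_pitch_mm[0], oy + i * self.block_pitch_mm[1])
            for i in range(self.n_rows)
            for j in range(self.n_cols)
        ]


@dataclass
class CalibrationPoint:
    netod: float
    dose_gy: float
    channel: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.netod) or not np.isfinite(self.dose_gy):
            raise ValueError("calibration point must be finite")
        if not 0 <= self.dose_gy <= 60:
            raise ValueError(f"dose {self.dose_gy} Gy outside the film's usable 0-60 Gy range")


@dataclass
class CalibrationCurve:
    """Cubic netOD→dose response for one color channel.

    ``coefficients`` are (a0, a1, a2, a3) of
    dose = a0 + a1 x + a2 x^2 + a3 x^3 with x = netOD.
    """

    channel: str
    coefficients: tuple[float, float, float, float]
    dose_range_gy: tuple[float, float]
    points: list[CalibrationPoint] = field(default_factory=list)
    rms_residual_gy: float = 0.0
    monotone: bool = True

    def netod_span(self) -> tuple[float, float]:
        if not self.points:
            raise ValueError("curve has no fit points")
        nods = [p.netod for p in self.points]
        return min(nods), max(nods)

    def dose(self, netod: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(netod, dtype=float)
        a0, a1, a2, a3 = self.coefficients
        out = a0 + x * (a1 + x * (a2 + x * a3))
        return out if out.ndim else float(out)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "channel": self.channel,
            "coefficients": list(self.coefficients),
            "dose_range_gy": list(self.dose_range_gy),
            "rms_residual_gy": self.rms_residual_gy,
            "monotone": self.monotone,
            "points": [
                {"netod": p.netod, "dose_gy": p.dose_gy, "channel": p.channel} for p in self.points
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationCurve":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            channel=d["channel"],
            coefficients=tuple(d["coefficients"]),
            dose_range_gy=tuple(d["dose_range_gy"]),
            points=[CalibrationPoint(**p) for p in d["points"]],
            rms_residual_gy=d["rms_residual_gy"],
            monotone=d.get("monotone", True),
        )


# ---------------------------------------------------------------------------


def extract_grid_means(
    netod_map: NetODMap, geometry: GridGeometry, channel: str
) -> list[CalibrationPoint]:
    """Mean netOD inside each (margin-shrunk) grid block, row-major.

    Doses are attached by the caller (zero placeholders here), so the same
    extraction serves non-standard dose patterns.
    """
    data = netod_map.channel(channel)
    sx, sy = netod_map.pixel_spacing_mm
    nrow, ncol = data.shape
    map_size = (sx * (ncol - 1), sy * (nrow - 1))
    shrink = 1.0 - 2.0 * geometry.margin_fraction
    half_w = geometry.block_size_mm[0] * shrink / 2.0
    half_h = geometry.block_size_mm[1] * shrink / 2.0
    points = []
    for idx, (cx, cy) in enumerate(geometry.block_centers_mm(map_size)):
        c0 = int(np.ceil((cx - half_w) / sx))
        c1 = int(np.floor((cx + half_w) / sx))
        r0 = int(np.ceil((cy - half_h) / sy))
        r1 = int(np.floor((cy + half_h) / sy))
        if r0 < 0 or c0 < 0 or r1 >= nrow or c1 >= ncol or r1 < r0 or c1 < c0:
            raise ValueError(
                f"calibration block {idx} at ({cx:.1f}, {cy:.1f}) mm falls outside the netOD map"
            )
        mean = float(data[r0:r1 + 1, c0:c1 + 1].mean())
        points.append(CalibrationPoint(netod=mean, dose_gy=0.0, channel=channel))
    return points


def fit_calibration(points: list[CalibrationPoint], channel: str | None = None) -> CalibrationCurve:
    """Ordinary least-squares cubic fit dose = P3(netOD).

    Requires at least four points with distinct netOD values; with exactly
    four the fit interpolates.  Monotonicity of the fitted cubic over the
    point span is checked numerically (1000 samples); a non-monotone curve
    is flagged, not rejected.
    """
    if channel is None:
        channel = points[0].channel
    x = np.array([p.netod for p in points], dtype=float)
    y = np.array([p.dose_gy for p in points], dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError(
            f"cubic calibration needs >= 4 distinct netOD values, got {len(np.unique(x))}"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, 3)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    rms = float(np.sqrt(np.mean((fitted - y) ** 2)))
    xs = np.linspace(x.min(), x.max(), 1000)
    ys = np.polynomial.polynomial.polyval(xs, coeffs)
    monotone = bool(np.all(np.diff(ys) >= -1e-12 * max(1.0, abs(ys).max())))
    return CalibrationCurve(
        channel=channel,
        coefficients=tuple(float(c) for c in coeffs),
        dose_range_gy=(float(y.min()), float(y.max())),
        points=list(points),
        rms_residual_gy=rms,
        monotone=monotone,
    )


def select_channel(max_plan_dose_gy: float) -> str:
    """Channel policy: red for plan maxima <= 10 Gy, green above."""
    if max_plan_dose_gy <= 0:
        raise ValueError("max plan dose must be positive")
    return "red" if max_plan_dose_gy <= RED_CHANNEL_MAX_DOSE_GY else "green"


def compare_curves(curve_a: CalibrationCurve, curve_b: CalibrationCurve, n_samples: int = 200) -> float:
    """Pearson correlation of two curves sampled over their common netOD span."""
    if curve_a.channel != curve_b.channel:
        raise ValueError(f"cannot compare {curve_a.channel} curve against {curve_b.channel} curve")
    lo = max(curve_a.netod_span()[0], curve_b.netod_span()[0])
    hi = min(curve_a.netod_span()[1], curve_b.netod_span()[1])
    if hi <= lo:
        raise ValueError("curves have no overlapping netOD span")
    xs = np.linspace(lo, hi, n_samples)
    ya, yb = curve_a.dose(xs), curve_b.dose(xs)
    if np.std(ya) == 0 or np.std(yb) == 0:
        raise ValueError("sampled curve has zero variance; correlation undefined")
    r, _ = stats.pearsonr(ya, yb)
    return float(r)


def channel_index(channel: str) -> int:
    return CHANNELS.index(channel)
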