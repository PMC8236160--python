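"""Flatbed film-scan handling: orientation alignment, averaging, netOD.

Radiochromic film is scanned four times in transmission mode, rotating the
film between scans (original landscape, vertical flip, horizontal flip, and
the combination of both, i.e. a 180-degree rotation).  Averaging the four
registered scans suppresses both scanner response variation and film grain.
Net optical density is then computed per color channel against an unexposed
reference:

    netOD = log10(PV_unexposed / PV_exposed)

with PV the (averaged) 16-bit transmission pixel value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

CHANNELS = ("red", "green", "blue")


class Orientation(str, Enum):
    """How the film lay on the scanner bed relative to the first scan."""

    ORIGINAL = "original"
    VFLIP = "vflip"      # vertical symmetrical flip: rows reversed
    HFLIP = "hflip"      # horizontal symmetrical flip: columns reversed
    ROT180 = "rot180"    # asymmetrical flip: both reversed


_SUFFIX_TO_ORIENTATION = {
    "_o": Orientation.ORIGINAL,
    "_v": Orientation.VFLIP,
    "_h": Orientation.HFLIP,
    "_r": Orientation.ROT180,
}


@dataclass
class FilmScanImage:
    """One flatbed scan: (rows, cols, 3) pixel grid in the 16-bit range."""

    pixels: np.ndarray
    dpi: float = 150.0
    orientation: Orientation = Orientation.ORIGINAL
    film_lot: str = ""
    scan_index: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError(f"expected a (rows, cols, 3) pixel grid, got shape {self.pixels.shape}")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        self.orientation = Orientation(self.orientation)

    @property
    def pixel_spacing_mm(self) -> float:
        return 25.4 / self.dpi


@dataclass
class AveragedScan:
    """Per-pixel mean of 1-4 aligned scans (real-valued pixels)."""

    pixels: np.ndarray
    dpi: float
    n_scans_averaged: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not 1 <= self.n_scans_averaged <= 4:
            raise ValueError("n_scans_averaged must be in 1..4")

    @property
    def pixel_spacing_mm(self) -> float:
        return 25.4 / self.dpi


@dataclass
class NetODMap:
    """Per-channel net optical density grid (dimensionless)."""

    netod: np.ndarray  # (rows, cols, 3)
    pixel_spacing_mm: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.netod = np.asarray(self.netod, dtype=float)
        if not np.all(np.isfinite(self.netod)):
            raise ValueError("netOD map contains non-finite values")

    def channel(self, name: str) -> np.ndarray:
        return self.netod[:, :, CHANNELS.index(name)]


# ---------------------------------------------------------------------------


def orientation_from_filename(path: str | Path) -> Orientation | None:
    """Recognize the ``_o/_v/_h/_r`` filename-suffix orientation convention."""
    stem = Path(path).stem
    for suffix, orient in _SUFFIX_TO_ORIENTATION.items():
        if stem.endswith(suffix):
            return orient
    return None


def read_scan(
    path: str | Path,
    orientation: Orientation | str | None = None,
    dpi_override: float | None = None,
    scan_index: int = 1,
) -> FilmScanImage:
    """Read a 3-channel 8- or 16-bit TIFF transmission scan.

    8-bit data are rescaled by 257 into the 16-bit range (preserving the
    white point exactly).  The dpi is read from the TIFF resolution tags
    when present, else ``dpi_override`` (else 150).  If ``orientation`` is
    not given, the ``_o/_v/_h/_r`` filename convention is consulted.
    """
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        dpi = dpi_override
        if dpi is None:
            try:
                xres = page.tags["XResolution"].value
                dpi = float(xres[0]) / float(xres[1])
            except (KeyError, ZeroDivisionError, TypeError):
                dpi = None
    if arr.ndim != 3 or arr.shape[-1] != 3:
        nchan = 1 if arr.ndim == 2 else arr.shape[-1]
        raise ValueError(f"{path}: expected a 3-channel image, got {nchan} channel(s)")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.uint16) * 257
    elif arr.dtype != np.uint16:
        raise ValueError(f"{path}: expected 8- or 16-bit channels, got dtype {arr.dtype}")
    if orientation is None:
        orientation = orientation_from_filename(path) or Orientation.ORIGINAL
    return FilmScanImage(
        arr, dpi=float(dpi or 150.0), orientation=Orientation(orientation), scan_index=scan_index
    )


def align_orientation(scan: FilmScanImage) -> FilmScanImage:
    """Map a scan back to the original-landscape frame by undoing its flip.

    Each tagged transform is its own inverse (flips are involutions), so the
    alignment simply re-applies it and clears the tag.
    """
    px = scan.pixels
    if scan.orientation in (Orientation.VFLIP, Orientation.ROT180):
        px = px[::-1, :, :]
    if scan.orientation in (Orientation.HFLIP, Orientation.ROT180):
        px = px[:, ::-1, :]
    return FilmScanImage(
        px.copy(),
        dpi=scan.dpi,
        orientation=Orientation.ORIGINAL,
        film_lot=scan.film_lot,
        scan_index=scan.scan_index,
    )


def _best_integer_shift(reference: np.ndarray, moving: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer-pixel shift of ``moving`` minimizing SSD to ``reference``.

    Exhaustive search over ±max_shift in both axes, scored on the overlap of
    the green channel (best film contrast).
    """
    ref = reference[:, :, 1].astype(float)
    mov = moving[:, :, 1].astype(float)
    best = (0, 0)
    best_score = np.inf
    nr, nc = ref.shape
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            r0, r1 = max(0, dr), min(nr, nr + dr)
            c0, c1 = max(0, dc), min(nc, nc + dc)
            if r1 - r0 < 2 or c1 - c0 < 2:
                continue
            diff = ref[r0:r1, c0:c1] - mov[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            score = np.mean(diff * diff)
            if score < best_score - 1e-12:
                best_score = score
                best = (dr, dc)
    return best


def average_scans(
    scans: list[FilmScanImage],
    register: bool = False,
    max_shift_px: int = 5,
) -> AveragedScan:
    """Average 1-4 orientation-aligned scans pixelwise.

    With ``register=True``, scans 2..n are first shifted (integer pixels,
    exhaustive ±``max_shift_px`` search) onto scan 1 to absorb mechanical
    repositioning error; shifted-in border pixels replicate the edge.
    """
    if not 1 <= len(scans) <= 4:
        raise ValueError("average_scans expects 1-4 scans")
    shapes = {s.pixels.shape for s in scans}
    if len(shapes) > 1:
        raise ValueError(f"scan shapes differ after alignment: {sorted(shapes)}")
    if len({s.dpi for s in scans}) > 1:
        raise ValueError("scan dpi values differ")
    aligned = [align_orientation(s) if s.orientation != Orientation.ORIGINAL else s for s in scans]
    stack = []
    shifts = [(0, 0)]
    for i, scan in enumerate(aligned):
        px = scan.pixels.astype(float)
        if register and i > 0:
            dr, dc = _best_integer_shift(aligned[0].pixels, scan.pixels, max_shift_px)
            shifts.append((dr, dc))
            px = np.roll(px, (dr, dc), axis=(0, 1))
            # replicate edges where roll wrapped
            if dr > 0:
                px[:dr] = px[dr]
            elif dr < 0:
                px[dr:] = px[dr - 1]
            if dc > 0:
                px[:, :dc] = px[:, dc:dc + 1]
            elif dc < 0:
                px[:, dc:] = px[:, dc - 1:dc]
        stack.append(px)
    mean = np.mean(stack, axis=0)
    if register and any(s != (0, 0) for s in shifts[1:]):
        logger.info("registration shifts applied: %s", shifts)
    return AveragedScan(mean, dpi=scans[0].dpi, n_scans_averaged=len(scans))


def compute_netod(
    exposed: AveragedScan,
    unexposed: AveragedScan | None = None,
    background_region: tuple[slice, slice] | None = None,
) -> NetODMap:
    """Per-channel net optical density of an exposed film.

    The unexposed reference is either a companion unexposed scan (pixelwise
    ratio) or an unirradiated region of the exposed film itself
    (``background_region`` as (row_slice, col_slice); its per-channel mean is
    used as a scalar reference).  Pixel values are floored at 1 before the
    log ratio; floored (dead) pixels are counted in ``meta``.
    """
    if (unexposed is None) == (background_region is None):
        raise ValueError("provide exactly one of unexposed scan or background_region")
    pv_exp = np.maximum(exposed.pixels, 1.0)
    n_floored = int(np.sum(exposed.pixels < 1.0))
    if unexposed is not None:
        if unexposed.pixels.shape != exposed.pixels.shape:
            raise ValueError(
                f"exposed {exposed.pixels.shape} and unexposed {unexposed.pixels.shape} shapes differ"
            )
        pv_ref = np.maximum(unexposed.pixels, 1.0)
    else:
        region = exposed.pixels[background_region[0], background_region[1], :]
        if region.size == 0:
            raise ValueError("background region is empty")
        pv_ref = np.maximum(region.reshape(-1, 3).mean(axis=0), 1.0)[None, None, :]
    if n_floored:
        logger.warning("%d dead pixels floored to 1 before netOD", n_floored)
    netod = np.log10(pv_ref / pv_exp)
    spacing = exposed.pixel_spacing_mm
    return NetODMap(netod, (spacing, spacing), meta={"n_floored_pixels": n_floored})
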