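"""Gamma-index comparison of measured vs planned dose planes.

The gamma index combines a dose-difference criterion (here global: the
percentage applies to the maximum dose of the reference distribution,
D_global) with a distance-to-agreement criterion.  For a reference point m
at position r_m with dose D_ref(m),

    gamma(m) = min over candidates c of
               sqrt( (|r_c - r_m| / dta)^2
                     + ((D_eval(c) - D_ref(m)) / (dose_pct/100 * D_global))^2 )

where candidates c lie on a fine subgrid of the evaluated plane within a
search radius.  A point passes when gamma <= 1.  Only reference pixels
above a dose threshold (default 10% of D_global) are evaluated.

Two normalization modes are supported: *absolute* compares calibrated doses
directly; *relative* first rescales the evaluated (measured) plane to the
reference maximum, removing any uniform output difference.

``compute_gamma`` is the production implementation (vectorized, capped
search);  ``brute_force_gamma`` is an independent exhaustive oracle kept
deliberately free of the production code paths for verification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .planes import DosePlane, robust_max

#: The three clinical criteria evaluated throughout: (dose %, DTA mm).
STANDARD_CRITERIA = ("3%/3 mm", "3%/1 mm", "2%/2 mm")

#: Pass convention is boundary-inclusive (gamma <= 1 passes); this float
#: tie-break keeps a dose difference exactly at the criterion passing.
_PASS_EPS = 1e-9


@dataclass
class GammaCriteria:
    """One gamma evaluation setup.

    dose_pct is the dose-difference criterion as % of the global reference
    maximum; dta_mm the distance-to-agreement; threshold_pct excludes
    low-dose reference pixels; gamma values are capped at gamma_cap (a
    gamma above the cap never changes pass/fail).
    """

    dose_pct: float
    dta_mm: float
    threshold_pct: float = 10.0
    normalization: str = "absolute"  # absolute | relative
    gamma_cap: float = 2.0
    use_robust_max: bool = True  # relative-mode scaling: top-0.5% mean vs exact max

    def __post_init__(self) -> None:
        if self.dose_pct <= 0 or self.dta_mm <= 0 or self.gamma_cap <= 0:
            raise ValueError("dose_pct, dta_mm and gamma_cap must be positive")
        if not 0 <= self.threshold_pct < 100:
            raise ValueError("threshold_pct must lie in [0, 100)")
        if self.normalization not in ("absolute", "relative"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def label(self) -> str:
        dose = f"{self.dose_pct:g}"
        dta = f"{self.dta_mm:g}"
        return f"{dose}%/{dta} mm"


@dataclass
class GammaResult:
    gamma_map: np.ndarray  # NaN outside threshold/overlap
    pass_rate_pct: float
    n_evaluated: int
    criteria: GammaCriteria
    d_global_gy: float
    scale_factor: float = 1.0  # applied to the evaluated plane (relative mode)
    meta: dict = field(default_factory=dict)

    @property
    def mean_gamma(self) -> float:
        return float(np.nanmean(self.gamma_map))

    @property
    def max_gamma(self) -> float:
        return float(np.nanmax(self.gamma_map))


def parse_criteria(text: str, **kwargs) -> GammaCriteria:
    """Parse the conventional ``'<dose>%/<dta> mm'`` criteria string."""
    m = re.fullmatch(r"\s*([\d.]+)\s*%\s*/\s*([\d.]+)\s*mm\s*", text)
    if not m:
        raise ValueError(f"cannot parse gamma criteria {text!r}; expected e.g. '3%/1 mm'")
    return GammaCriteria(dose_pct=float(m.group(1)), dta_mm=float(m.group(2)), **kwargs)


# ---------------------------------------------------------------------------
# search-grid construction shared by nothing: compute_gamma builds its own
# offsets; the brute-force oracle builds its own independently.
# ---------------------------------------------------------------------------


def _evaluation_mask(reference: DosePlane, criteria: GammaCriteria) -> tuple[np.ndarray, float]:
    ref = reference.dose_gy
    d_global = float(np.nanmax(ref))
    if not np.isfinite(d_global) or d_global <= 0:
        raise ValueError("reference plane has no positive dose; cannot normalize")
    mask = np.isfinite(ref) & (ref > criteria.threshold_pct / 100.0 * d_global)
    if not mask.any():
        raise ValueError("no reference pixels above the dose threshold")
    return mask, d_global


def _relative_scale(reference: DosePlane, evaluated: DosePlane, criteria: GammaCriteria) -> float:
    if criteria.use_robust_max:
        return robust_max(reference.dose_gy) / robust_max(evaluated.dose_gy)
    return float(np.nanmax(reference.dose_gy) / np.nanmax(evaluated.dose_gy))


def compute_gamma(
    reference: DosePlane,
    evaluated: DosePlane,
    criteria: GammaCriteria,
    chunk_size: int = 64,
    subgrid_step_mm: float | None = None,
) -> GammaResult:
    """Gamma map and pass rate of ``evaluated`` against ``reference``.

    The planes must already be registered to a common physical frame (they
    need not share a grid: the evaluated plane is interpolated).  Candidate
    positions lie on a square subgrid of step min(dta/10, native evaluated
    spacing) within radius gamma_cap * dta of each reference pixel;
    evaluated dose is bilinearly interpolated there.  The returned map is
    NaN at unevaluated pixels (below threshold or outside the evaluated
    plane's support).

    ``subgrid_step_mm`` overrides the candidate-lattice step.  Passing the
    same step when evaluating several criteria on one plane pair puts all
    evaluations on a shared lattice, which makes the criteria-dominance
    property (looser criteria => pointwise smaller gamma) hold exactly
    rather than up to discretization.
    """
    mask, d_global = _evaluation_mask(reference, criteria)
    scale = 1.0
    if criteria.normalization == "relative":
        scale = _relative_scale(reference, evaluated, criteria)
    eval_dose = evaluated.dose_gy * scale

    dose_denom = criteria.dose_pct / 100.0 * d_global
    radius = criteria.gamma_cap * criteria.dta_mm
    step = subgrid_step_mm or min(criteria.dta_mm / 10.0, min(evaluated.pixel_spacing_mm))

    n = int(np.floor(radius / step))
    grid = np.arange(-n, n + 1) * step
    ox, oy = np.meshgrid(grid, grid)
    keep = ox**2 + oy**2 <= radius**2 + 1e-12
    offsets = np.column_stack([ox[keep], oy[keep]])
    dist2_term = (np.hypot(offsets[:, 0], offsets[:, 1]) / criteria.dta_mm) ** 2

    xs, ys = reference.x_coords(), reference.y_coords()
    rows, cols = np.nonzero(mask)
    px = xs[cols]
    py = ys[rows]
    ref_dose = reference.dose_gy[rows, cols]

    nrow_e, ncol_e = evaluated.shape
    eps = 1e-9
    best = np.full(px.shape, np.inf)
    for start in range(0, offsets.shape[0], chunk_size):
        off = offsets[start:start + chunk_size]
        d2 = dist2_term[start:start + chunk_size]
        cx = px[None, :] + off[:, 0:1]
        cy = py[None, :] + off[:, 1:2]
        row_e, col_e = evaluated.xy_to_rowcol(cx, cy)
        inside = (
            (row_e >= -eps) & (row_e <= nrow_e - 1 + eps)
            & (col_e >= -eps) & (col_e <= ncol_e - 1 + eps)
        )
        row_e = np.clip(row_e, 0, nrow_e - 1)
        col_e = np.clip(col_e, 0, ncol_e - 1)
        d_eval = ndimage.map_coordinates(
            eval_dose, np.vstack([row_e.ravel(), col_e.ravel()]), order=1, mode="nearest"
        ).reshape(row_e.shape)
        gamma2 = d2[:, None] + ((d_eval - ref_dose[None, :]) / dose_denom) ** 2
        gamma2 = np.where(inside & np.isfinite(gamma2), gamma2, np.inf)
        best = np.minimum(best, gamma2.min(axis=0))

    gamma = np.sqrt(best)
    valid = np.isfinite(gamma)
    gamma = np.minimum(gamma, criteria.gamma_cap)

    gamma_map = np.full(reference.shape, np.nan)
    gamma_map[rows[valid], cols[valid]] = gamma[valid]
    n_eval = int(valid.sum())
    if n_eval == 0:
        raise ValueError("no reference pixels overlap the evaluated plane")
    pass_rate = 100.0 * float(np.sum(gamma[valid] <= 1.0 + _PASS_EPS)) / n_eval
    return GammaResult(
        gamma_map=gamma_map,
        pass_rate_pct=pass_rate,
        n_evaluated=n_eval,
        criteria=criteria,
        d_global_gy=d_global,
        scale_factor=scale,
    )


def brute_force_gamma(
    reference: DosePlane,
    evaluated: DosePlane,
    criteria: GammaCriteria,
    subgrid_factor: int = 10,
) -> np.ndarray:
    """Exhaustive per-pixel gamma oracle for small planes (<= 128 x 128).

    Loops over every evaluated reference pixel; for each, enumerates every
    candidate on a dta/subgrid_factor square lattice within the capped
    search radius, interpolates the evaluated dose there with an explicit
    bilinear formula, and minimizes.  No pruning, no early exit, no shared
    code with :func:`compute_gamma`.  Normalization (relative-mode scaling)
    is the caller's responsibility; the planes are compared as given.
    Returns the gamma map only.
    """
    if max(reference.shape) > 128 or max(evaluated.shape) > 128:
        raise ValueError("brute_force_gamma is an oracle for planes up to 128 x 128")
    mask, d_global = _evaluation_mask(reference, criteria)
    dose_denom = criteria.dose_pct / 100.0 * d_global
    radius = criteria.gamma_cap * criteria.dta_mm
    step = criteria.dta_mm / subgrid_factor

    n = int(np.floor(radius / step))
    lattice = np.arange(-n, n + 1) * step
    offx, offy = np.meshgrid(lattice, lattice)
    inside_disc = offx**2 + offy**2 <= radius**2 + 1e-12
    offx, offy = offx[inside_disc], offy[inside_disc]
    dist_term2 = (offx**2 + offy**2) / criteria.dta_mm**2

    ev = evaluated.dose_gy
    nrow_e, ncol_e = ev.shape
    sx_e, sy_e = evaluated.pixel_spacing_mm
    ox_e, oy_e = evaluated.origin_mm

    xs, ys = reference.x_coords(), reference.y_coords()
    gamma_map = np.full(reference.shape, np.nan)
    for r in range(reference.shape[0]):
        for c in range(reference.shape[1]):
            if not mask[r, c]:
                continue
            cand_x = xs[c] + offx
            cand_y = ys[r] + offy
            # explicit bilinear interpolation in evaluated pixel coordinates
            fc = (cand_x - ox_e) / sx_e
            fr = (oy_e - cand_y) / sy_e
            ok = (fr >= -1e-9) & (fr <= nrow_e - 1 + 1e-9) & (fc >= -1e-9) & (fc <= ncol_e - 1 + 1e-9)
            if not ok.any():
                continue
            fr_ok = np.clip(fr[ok], 0, nrow_e - 1)
            fc_ok = np.clip(fc[ok], 0, ncol_e - 1)
            r0 = np.minimum(np.floor(fr_ok).astype(int), nrow_e - 2) if nrow_e > 1 else np.zeros_like(fr_ok, int)
            c0 = np.minimum(np.floor(fc_ok).astype(int), ncol_e - 2) if ncol_e > 1 else np.zeros_like(fc_ok, int)
            tr = fr_ok - r0
            tc = fc_ok - c0
            r1 = np.minimum(r0 + 1, nrow_e - 1)
            c1 = np.minimum(c0 + 1, ncol_e - 1)
            d_eval = (
                ev[r0, c0] * (1 - tr) * (1 - tc)
                + ev[r1, c0] * tr * (1 - tc)
                + ev[r0, c1] * (1 - tr) * tc
                + ev[r1, c1] * tr * tc
            )
            gamma2 = dist_term2[ok] + ((d_eval - reference.dose_gy[r, c]) / dose_denom) ** 2
            gamma2 = gamma2[np.isfinite(gamma2)]
            if gamma2.size == 0:
                continue
            gamma_map[r, c] = min(np.sqrt(gamma2.min()), criteria.gamma_cap)
    return gamma_map


def pass_rate_from_map(gamma_map: np.ndarray) -> float:
    """Pass rate (%) of an oracle gamma map: fraction of valid pixels <= 1."""
    valid = np.isfinite(gamma_map)
    if not valid.any():
        raise ValueError("gamma map has no evaluated pixels")
    return 100.0 * float(np.sum(gamma_map[valid] <= 1.0 + _PASS_EPS)) / int(valid.sum())


def pass_table(
    reference: DosePlane,
    evaluated: DosePlane,
    criteria_list: list[str | GammaCriteria] | None = None,
    modes: tuple[str, ...] = ("absolute", "relative"),
    threshold_pct: float = 10.0,
) -> pd.DataFrame:
    """Pass rates for every (criteria, normalization mode) combination.

    Defaults to the three clinical criteria in both absolute and relative
    mode, i.e. the six-row report shape used for open-field QA.
    """
    if criteria_list is None:
        criteria_list = list(STANDARD_CRITERIA)
    records = []
    for crit in criteria_list:
        for mode in modes:
            if isinstance(crit, GammaCriteria):
                c = GammaCriteria(
                    crit.dose_pct, crit.dta_mm, threshold_pct=crit.threshold_pct,
                    normalization=mode, gamma_cap=crit.gamma_cap,
                    use_robust_max=crit.use_robust_max,
                )
            else:
                c = parse_criteria(crit, threshold_pct=threshold_pct, normalization=mode)
            res = compute_gamma(reference, evaluated, c)
            records.append(
                {
                    "criteria": c.label(),
                    "mode": mode,
                    "pass_rate_pct": res.pass_rate_pct,
                    "mean_gamma": res.mean_gamma,
                    "max_gamma": res.max_gamma,
                    "n_evaluated": res.n_evaluated,
                }
            )
    return pd.DataFrame.from_records(records)
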