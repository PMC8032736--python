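"""Burn-severity chain: NBR, dNBR, compositing, background correction,
gap-filling, and the dNBR -> CBI -> combustion-fraction mapping.

The chain converts two-band reflectance scenes into per-fire burn-severity
records.  The Normalized Burn Ratio is computed from near-infrared (B4) and
shortwave-infrared (B7) reflectance; its pre-fire minus post-fire difference
(dNBR) indexes burn severity, which a pair of field-calibrated linear
regressions maps onto the Composite Burn Index (CBI, 0-3 scale) and then
onto the fractions of canopy and organic-soil carbon consumed by the fire.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

# dNBR -> CBI linear regression (field-calibrated, boreal forest).
CBI_SLOPE = 0.0023
CBI_INTERCEPT = 0.5561
CBI_MAX = 3.0

# CBI -> combustion percentage regressions (black-spruce-dominated sites).
SOIL_SLOPE = 51.42
SOIL_INTERCEPT = -63.49
CANOPY_SLOPE = 14.15
CANOPY_INTERCEPT = 48.63

#: dNBR below which the fitted soil-combustion relation is non-positive
#: (its exact zero crossing); soils are effectively unburned below ~300.
SOIL_COMBUSTION_DNBR_THRESHOLD = (
    (-SOIL_INTERCEPT / SOIL_SLOPE) - CBI_INTERCEPT
) / CBI_SLOPE  # ~295.058

#: Summer compositing window (inclusive, month/day).
SUMMER_WINDOW = ((7, 15), (9, 15))

#: Background buffer ring distances outside the fire boundary, metres.
BUFFER_RING_M = (1500.0, 1800.0)

GAP_FILL_POOL = 10


class NoSummerImageryError(ValueError):
    """No scene falls inside the summer compositing window for a year."""


@dataclass
class Scene:
    """A two-band reflectance scene.

    b4, b7
        Near-infrared and shortwave-infrared reflectance grids (unitless,
        non-negative), identical shapes.
    acq_date
        Acquisition date.
    pixel_size_m
        Ground pixel size in metres (square pixels).
    """

    b4: np.ndarray
    b7: np.ndarray
    acq_date: date
    pixel_size_m: float = 100.0

    def __post_init__(self) -> None:
        self.b4 = np.asarray(self.b4, dtype=float)
        self.b7 = np.asarray(self.b7, dtype=float)
        if self.b4.shape != self.b7.shape:
            raise ValueError(
                f"band shape mismatch: {self.b4.shape} vs {self.b7.shape}"
            )
        if (self.b4 < 0).any() or (self.b7 < 0).any():
            raise ValueError("reflectance bands must be non-negative")


@dataclass
class SeverityRecord:
    """Per-fire burn severity and derived combustion fractions."""

    fire_id: int
    year: int
    area_km2: float
    dnbr_raw: float
    dnbr_background: float
    dnbr: float  # corrected (raw - background); may be negative
    gap_filled: bool = False
    cbi: float = field(init=False)
    soil_frac: float = field(init=False)
    canopy_frac: float = field(init=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.dnbr):  # missing imagery, awaiting gap-fill
            self.cbi = self.soil_frac = self.canopy_frac = float("nan")
            return
        # Negative corrected dNBR means "no detected burn": floor at 0
        # before entering the CBI regression.
        self.cbi = dnbr_to_cbi(max(self.dnbr, 0.0))
        self.soil_frac, self.canopy_frac = cbi_to_fractions(self.cbi)


def compute_nbr(scene: Scene) -> np.ndarray:
    """Normalized Burn Ratio, (B4 - B7) / (B4 + B7) x 1000.

    Pixels with B4 + B7 == 0 are returned as NaN (missing).
    """
    total = scene.b4 + scene.b7
    with np.errstate(invalid="ignore", divide="ignore"):
        nbr = np.where(total > 0, (scene.b4 - scene.b7) / total * 1000.0, np.nan)
    return nbr


def in_summer_window(d: date) -> bool:
    lo, hi = SUMMER_WINDOW
    return lo <= (d.month, d.day) <= hi


def composite_summer(scenes: list[Scene], year: int) -> np.ndarray:
    """Per-pixel mean NBR over scenes inside the Jul 15 - Sep 15 window.

    Raises
    ------
    NoSummerImageryError
        If no scene of that year falls inside the window.  Callers treat
        this as the "no imagery" signal that routes a fire to gap-filling.
    """
    selected = [
        s for s in scenes if s.acq_date.year == year and in_summer_window(s.acq_date)
    ]
    if not selected:
        raise NoSummerImageryError(f"no summer imagery for year {year}")
    stack = np.stack([compute_nbr(s) for s in selected])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def compute_dnbr(pre_nbr: np.ndarray, post_nbr: np.ndarray) -> np.ndarray:
    """dNBR = pre-fire NBR - post-fire NBR, per pixel."""
    pre_nbr = np.asarray(pre_nbr, dtype=float)
    post_nbr = np.asarray(post_nbr, dtype=float)
    if pre_nbr.shape != post_nbr.shape:
        raise ValueError(
            f"misaligned grids: {pre_nbr.shape} vs {post_nbr.shape}"
        )
    return pre_nbr - post_nbr


def buffer_ring_mask(
    fire_mask: np.ndarray, pixel_size_m: float, ring_m: tuple[float, float] = BUFFER_RING_M
) -> np.ndarray:
    """Pixels whose distance outside the fire boundary lies in ``ring_m``."""
    fire_mask = np.asarray(fire_mask, dtype=bool)
    dist = ndimage.distance_transform_edt(~fire_mask) * pixel_size_m
    return (~fire_mask) & (dist >= ring_m[0]) & (dist <= ring_m[1])


def background_correct(
    dnbr_grid: np.ndarray,
    fire_mask: np.ndarray,
    mode: str = "buffer",
    pixel_size_m: float = 100.0,
    prior_year_dnbr: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Mean in-perimeter dNBR minus a background dNBR.

    ``mode="buffer"`` uses the mean dNBR in a ring 1500-1800 m outside the
    fire boundary; ``mode="prior_year"`` uses the mean dNBR within the
    perimeter in the year before the fire (``prior_year_dnbr``).  An empty
    buffer ring (perimeter at the scene edge) falls back to prior-year mode
    with a logged warning.

    Returns ``(raw, background, corrected)``.
    """
    if mode not in ("buffer", "prior_year"):
        raise ValueError(f"unknown background mode: {mode!r}")
    fire_mask = np.asarray(fire_mask, dtype=bool)
    if fire_mask.shape != np.shape(dnbr_grid):
        raise ValueError("fire mask and dNBR grid are misaligned")
    raw = float(np.nanmean(np.asarray(dnbr_grid, dtype=float)[fire_mask]))

    if mode == "buffer":
        ring = buffer_ring_mask(fire_mask, pixel_size_m)
        ring_vals = np.asarray(dnbr_grid, dtype=float)[ring]
        ring_vals = ring_vals[np.isfinite(ring_vals)]
        if ring_vals.size == 0:
            logger.warning(
                "empty buffer ring (perimeter at scene edge); "
                "falling back to prior-year background"
            )
            mode = "prior_year"
        else:
            background = float(ring_vals.mean())
    if mode == "prior_year":
        if prior_year_dnbr is None:
            raise ValueError("prior_year background requires prior_year_dnbr")
        background = float(np.nanmean(np.asarray(prior_year_dnbr, dtype=float)[fire_mask]))

    return raw, background, raw - background


def dnbr_to_cbi(dnbr: float) -> float:
    """CBI = 0.0023 * dNBR + 0.5561, clamped to the 0-3 CBI scale."""
    if not np.isfinite(dnbr):
        raise ValueError("dNBR must be finite")
    return float(np.clip(CBI_SLOPE * dnbr + CBI_INTERCEPT, 0.0, CBI_MAX))


def cbi_to_fractions(cbi: float) -> tuple[float, float]:
    """Fractions of organic-soil and canopy C combusted at a given CBI.

    soil% = 51.42*CBI - 63.49 and canopy% = 14.15*CBI + 48.63, each clamped
    to [0, 100] (the fitted lines run negative / over 100 outside their
    calibration range) and returned as fractions in [0, 1].
    """
    if not 0.0 <= cbi <= CBI_MAX:
        raise ValueError(f"CBI must lie in [0, {CBI_MAX}], got {cbi}")
    soil_pct = np.clip(SOIL_SLOPE * cbi + SOIL_INTERCEPT, 0.0, 100.0)
    canopy_pct = np.clip(CANOPY_SLOPE * cbi + CANOPY_INTERCEPT, 0.0, 100.0)
    return float(soil_pct) / 100.0, float(canopy_pct) / 100.0


def soil_fraction_to_dnbr(soil_fraction: float) -> float:
    """Invert the soil-combustion regression, then the CBI regression.

    dNBR = (((100 f + 63.49) / 51.42) - 0.5561) / 0.0023.  Only defined for
    fractions above the zero crossing (f > 0).
    """
    if not 0.0 < soil_fraction <= 1.0:
        raise ValueError("soil fraction must lie in (0, 1]")
    cbi = (100.0 * soil_fraction - SOIL_INTERCEPT) / SOIL_SLOPE
    return (cbi - CBI_INTERCEPT) / CBI_SLOPE


def gap_fill(records: list[SeverityRecord]) -> list[SeverityRecord]:
    """Fill missing dNBR from the mean of the 10 fires closest in size.

    A record is "missing" when its corrected dNBR is NaN.  Each missing
    fire receives the unweighted mean corrected dNBR of the (up to) ten
    known-dNBR fires with smallest \\|area difference\\|; ties in area
    difference are broken by fire id order.  Smaller pools use all
    available fires.
    """
    known = [r for r in records if np.isfinite(r.dnbr)]
    if any(not np.isfinite(r.dnbr) for r in records) and not known:
        raise ValueError("cannot gap-fill: no fire has a known dNBR")
    out: list[SeverityRecord] = []
    for rec in records:
        if np.isfinite(rec.dnbr):
            out.append(rec)
            continue
        pool = sorted(known, key=lambda k: (abs(k.area_km2 - rec.area_km2), k.fire_id))
        nearest = pool[:GAP_FILL_POOL]
        filled = float(np.mean([k.dnbr for k in nearest]))
        out.append(
            replace(
                rec,
                dnbr_raw=float("nan"),
                dnbr_background=float("nan"),
                dnbr=filled,
                gap_filled=True,
            )
        )
    return out


def severity_table(records: list[SeverityRecord]):
    """Severity records as a tidy DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "fire_id": [r.fire_id for r in records],
            "year": [r.year for r in records],
            "area_km2": [r.area_km2 for r in records],
            "dnbr_raw": [r.dnbr_raw for r in records],
            "dnbr_background": [r.dnbr_background for r in records],
            "dnbr": [r.dnbr for r in records],
            "gap_filled": [r.gap_filled for r in records],
            "cbi": [r.cbi for r in records],
            "soil_frac": [r.soil_frac for r in records],
            "canopy_frac": [r.canopy_frac for r in records],
        }
    )
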