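"""Synthetic inputs with the statistical structure the analysis assumes.

Generates monthly climate forcing, fire histories and two-band reflectance
scene pairs so that every downstream stage (severity extraction, ecosystem
simulation, regional accounting) can be exercised without any downloads.
Each generator draws from its own RNG stream split from the master seed, so
adding a generator never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import NamedTuple

import numpy as np
from scipy import stats

from .severity import Scene

# RNG stream tags (split from the master seed).
_STREAM_CLIMATE = 1
_STREAM_FIRES = 2
_STREAM_SCENES = 3

#: Reference NBR (x1000 scale) of unburned mature forest in generated scenes.
PRE_FIRE_NBR = 400.0
#: Constant B4+B7 total used when converting NBR back to reflectance bands.
BAND_TOTAL = 0.4

DNBR_MAX_REPRESENTABLE = 1300.0


@dataclass
class SynthConfig:
    """Configuration of the synthetic study region and fire regime.

    The defaults emulate a small boreal domain on a 0.5-degree grid over
    1986-2016 with a per-fire mean dNBR distribution concentrated in
    200-400 (truncated normal, mean 272.5, SD 120, bounds [60, 1300]) so
    the area-weighted regional mean sits near 272.5.
    """

    ny: int = 2
    nx: int = 2
    resolution_deg: float = 0.5
    year_start: int = 1986
    year_end: int = 2016
    # climate: annual mean, seasonal amplitude, interannual noise SD
    tair_mean: float = -3.0
    tair_amp: float = 19.0
    tair_sd: float = 1.5
    prec_mean: float = 40.0  # mm per month
    prec_amp: float = 20.0
    prec_sd: float = 8.0
    vapr_mean: float = 6.0  # hPa
    vapr_amp: float = 4.0
    vapr_sd: float = 0.5
    cloud_mean: float = 60.0  # percent
    cloud_amp: float = 10.0
    cloud_sd: float = 5.0
    co2_start: float = 347.0  # ppm in year_start
    co2_rate: float = 1.7  # ppm per year
    # fire regime
    fire_rate: float = 2.0  # expected fires per year
    area_lognorm_mu: float = math.log(30.0)  # ln km2
    area_lognorm_sigma: float = 1.2
    dnbr_mean: float = 272.5
    dnbr_sd: float = 120.0
    dnbr_min: float = 60.0
    dnbr_max: float = 1300.0
    missing_dnbr_frac: float = 0.0053
    # landscape
    cell_area_km2: float = 2500.0
    forest_frac: float = 0.8
    subpixels: int = 20  # fine-raster pixels per cell side (cohort overlay)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ny <= 0 or self.nx <= 0 or self.resolution_deg <= 0:
            raise ValueError("grid extent and resolution must be positive")
        if self.year_end < self.year_start:
            raise ValueError("non-positive year span")
        for sd in (self.tair_sd, self.prec_sd, self.vapr_sd, self.cloud_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")
        if self.fire_rate < 0:
            raise ValueError("fire rate must be >= 0")
        if not (0.0 <= self.dnbr_min < self.dnbr_max <= 1300.0):
            raise ValueError("dNBR truncation bounds must lie within [0, 1300]")
        if not 0.0 <= self.missing_dnbr_frac <= 1.0:
            raise ValueError("missing-dNBR fraction must lie in [0, 1]")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


class FireEvent(NamedTuple):
    """One fire: year, area, rectangular perimeter on the fine raster,
    and its per-fire mean dNBR (None when no imagery is available)."""

    fire_id: int
    year: int
    area_km2: float
    bounds: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    dnbr: float | None


@dataclass
class ClimateForcing:
    """Monthly climate drivers per grid cell plus annual CO2.

    Arrays are shaped ``(ny, nx, n_years * 12)``; CO2 is ``(n_years,)``.
    """

    years: np.ndarray
    tair: np.ndarray  # degC
    prec: np.ndarray  # mm / month
    vapr: np.ndarray  # hPa
    cloud: np.ndarray  # percent
    co2: np.ndarray  # ppm, annual

    @property
    def n_months(self) -> int:
        return self.tair.shape[-1]

    def cell(self, iy: int, ix: int) -> dict[str, np.ndarray]:
        return {
            "tair": self.tair[iy, ix],
            "prec": self.prec[iy, ix],
            "vapr": self.vapr[iy, ix],
            "cloud": self.cloud[iy, ix],
        }

    def climatology(self, iy: int, ix: int) -> dict[str, np.ndarray]:
        """Mean seasonal cycle (12 values per variable) for one cell."""
        out = {}
        for name, arr in self.cell(iy, ix).items():
            out[name] = arr.reshape(-1, 12).mean(axis=0)
        return out


def _seasonal(mean: float, amp: float, n_years: int) -> np.ndarray:
    months = np.arange(n_years * 12)
    # peak in July (month index 6 within the year)
    return mean - amp * np.cos(2.0 * np.pi * ((months % 12) + 0.5) / 12.0)


def gen_climate(config: SynthConfig) -> ClimateForcing:
    """Sinusoidal seasonal cycle plus Gaussian interannual noise per cell."""
    rng = np.random.default_rng([_STREAM_CLIMATE, config.seed])
    ny, nx, nyr = config.ny, config.nx, config.n_years
    nm = nyr * 12

    def series(mean, amp, sd, lo=None, hi=None):
        base = _seasonal(mean, amp, nyr)
        arr = base[None, None, :] + rng.normal(0.0, 1.0, (ny, nx, nm)) * sd
        return np.clip(arr, lo, hi) if lo is not None or hi is not None else arr

    tair = series(config.tair_mean, config.tair_amp, config.tair_sd)
    prec = series(config.prec_mean, config.prec_amp, config.prec_sd, lo=0.0)
    vapr = series(config.vapr_mean, config.vapr_amp, config.vapr_sd, lo=0.0)
    cloud = series(config.cloud_mean, config.cloud_amp, config.cloud_sd, 0.0, 100.0)
    co2 = config.co2_start + config.co2_rate * np.arange(nyr, dtype=float)
    return ClimateForcing(config.years.copy(), tair, prec, vapr, cloud, co2)


def _truncnorm(config: SynthConfig):
    a = (config.dnbr_min - config.dnbr_mean) / config.dnbr_sd
    b = (config.dnbr_max - config.dnbr_mean) / config.dnbr_sd
    return stats.truncnorm(a, b, loc=config.dnbr_mean, scale=config.dnbr_sd)


def gen_fire_history(config: SynthConfig, n_events: int | None = None) -> list[FireEvent]:
    """Fire events with Poisson annual counts, log-normal areas, rectangular
    perimeters on the fine raster, and truncated-normal per-fire dNBR.

    A configurable fraction of events carries no dNBR (missing imagery), to
    exercise the gap-fill path.  ``n_events`` overrides the Poisson draw
    with a fixed total (events then spread uniformly over years).
    """
    rng = np.random.default_rng([_STREAM_FIRES, config.seed])
    sub = config.subpixels
    if n_events is None:
        counts = rng.poisson(config.fire_rate, config.n_years)
    else:
        counts = np.bincount(
            rng.integers(0, config.n_years, n_events), minlength=config.n_years
        )
    total = int(counts.sum())
    if total == 0:
        return []
    areas = rng.lognormal(config.area_lognorm_mu, config.area_lognorm_sigma, total)
    dnbrs = _truncnorm(config).rvs(size=total, random_state=rng)
    missing = rng.random(total) < config.missing_dnbr_frac

    events: list[FireEvent] = []
    fid = 0
    for iyr, year in enumerate(config.years):
        for _ in range(int(counts[iyr])):
            iy = int(rng.integers(0, config.ny))
            ix = int(rng.integers(0, config.nx))
            h = int(rng.integers(max(2, sub // 5), max(3, int(sub * 0.9))))
            w = int(rng.integers(max(2, sub // 5), max(3, int(sub * 0.9))))
            r0 = iy * sub + int(rng.integers(0, sub - h + 1))
            c0 = ix * sub + int(rng.integers(0, sub - w + 1))
            events.append(
                FireEvent(
                    fire_id=fid,
                    year=int(year),
                    area_km2=float(areas[fid]),
                    bounds=(r0, r0 + h, c0, c0 + w),
                    dnbr=None if missing[fid] else float(dnbrs[fid]),
                )
            )
            fid += 1
    return events


class ScenePair(NamedTuple):
    pre: Scene
    post: Scene
    fire_mask: np.ndarray  # boolean, aligned with the scene grids


def gen_scene_pair(
    event: FireEvent,
    target_dnbr: float,
    seed: int | np.random.Generator = 0,
    background_drift: float = 0.0,
    noise_sd: float = 2.0,
    margin_px: int = 30,
    pixel_size_m: float = 100.0,
) -> ScenePair:
    """Pre/post two-band scenes that embed a prescribed mean dNBR.

    The fire footprint is a centred rectangle sized from the event area;
    inside it the post-fire NBR is depressed by ``target_dnbr`` (plus a
    scene-wide ``background_drift`` that the background correction must
    remove); outside-perimeter pixels change only by the drift and
    independent pixel noise.  After background correction the recovered
    in-perimeter mean dNBR equals the target to within about +/-1 unit.
    """
    if not 0.0 <= target_dnbr <= DNBR_MAX_REPRESENTABLE:
        raise ValueError(
            f"target dNBR {target_dnbr} outside representable range "
            f"[0, {DNBR_MAX_REPRESENTABLE}]"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng([_STREAM_SCENES, seed, event.fire_id])
    )
    side_m = math.sqrt(max(event.area_km2, 1.0)) * 1000.0
    half = max(5, int(round(side_m / pixel_size_m / 2)))
    n = 2 * (half + margin_px)
    mask = np.zeros((n, n), dtype=bool)
    c = n // 2
    mask[c - half : c + half, c - half : c + half] = True

    nbr_pre = PRE_FIRE_NBR + rng.normal(0.0, noise_sd, (n, n))
    dnbr_field = background_drift + np.where(mask, target_dnbr, 0.0)
    nbr_post = PRE_FIRE_NBR - dnbr_field + rng.normal(0.0, noise_sd, (n, n))

    def bands(nbr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b4 = BAND_TOTAL * (1.0 + nbr / 1000.0) / 2.0
        b4 = np.clip(b4, 0.0, BAND_TOTAL)
        return b4, BAND_TOTAL - b4

    pre = Scene(*bands(nbr_pre), acq_date=date(event.year - 1, 8, 1),
                pixel_size_m=pixel_size_m)
    post = Scene(*bands(nbr_post), acq_date=date(event.year + 1, 8, 1),
                 pixel_size_m=pixel_size_m)
    return ScenePair(pre, post, mask)
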