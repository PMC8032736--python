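"""Reduced-form monthly carbon-nitrogen ecosystem simulator with fire.

The kernel tracks four pools per land cohort — vegetation C, soil organic
C, soil organic N and available inorganic N — at a monthly step, with
diagnostic soil temperature (air temperature damped and offset by the
insulating moss/organic layer) and soil moisture (single bucket; evapo-
transpiration scales with foliage).  Fire removes canopy and soil carbon
according to the burn-severity combustion fractions, volatilizes part of
the combusted nitrogen, and resets the foliage and moss recovery clocks.

Functional forms:

* NPP  = NPPmax * f_fol * g_T(T_air) * g_W(theta) * g_N(N_av) * g_CO2(CO2)
  with Gaussian g_T, Michaelis-Menten g_W and g_N, and g_CO2 linear in
  ln(CO2 / 280 ppm).
* R_H  = k_d * C_soil * Q10^((T_soil - T_ref)/10) * h_W(theta).
* Litterfall = k_lf * C_veg; decomposed C is fully respired.
* Net N mineralization = (1 - f_imm) * R_H * (N_soil / C_soil).
* Post-fire foliage recovers linearly for 5 years then along a logistic;
  moss depth recovers exponentially toward its asymptote.

Pools are advanced by explicit Euler at the monthly step; carbon mass
balance Delta(C_veg + C_soil) = NPP - R_H - emission holds to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import NamedTuple

import numpy as np
import yaml

from .severity import SeverityRecord

CO2_REFERENCE_PPM = 280.0


class EcosysError(RuntimeError):
    """A step produced an invalid state (negative pool, divergence)."""


@dataclass(frozen=True)
class Parameters:
    """Tunable kernel parameters (units in comments)."""

    npp_max: float = 230.0        # g C m-2 month-1, unstressed canopy
    t_opt: float = 14.0           # degC, NPP temperature optimum
    t_width: float = 13.0         # degC, Gaussian width of g_T
    w_half_npp: float = 30.0      # % porosity, g_W half saturation
    n_half: float = 10.0          # g N m-2, g_N half saturation
    co2_beta: float = 0.4         # per ln(CO2/280)
    k_litter: float = 0.0095      # month-1, litterfall rate
    k_decomp: float = 0.018       # month-1 at T_ref, moist soil
    q10: float = 2.0              # decomposition temperature sensitivity
    t_ref: float = 10.0           # degC
    cn_soil: float = 30.0         # g C / g N, soil organic matter
    cn_veg: float = 50.0          # g C / g N, vegetation (foliage-weighted)
    imm_frac: float = 0.4         # fraction of gross mineralization immobilized
    n_input: float = 0.0008       # g N m-2 month-1 (deposition + fixation)
    n_vol_frac: float = 0.7       # fraction of combusted soil N volatilized
    insulation: float = 0.09      # degC per cm of moss/organic layer
    t_damp: float = 0.8           # soil-air temperature coupling
    fol_linear_years: float = 5.0
    fol_recovery_at_5: float = 0.25  # fraction of foliage gap closed at yr 5
    fol_sig_steepness: float = 0.35  # yr-1, logistic steepness
    fol_sig_midpoint: float = 10.0   # yr, logistic midpoint
    moss_tau: float = 40.0        # yr, moss e-folding recovery time
    moss_max: float = 15.0        # cm, moss/organic-layer asymptote
    et_coeff: float = 6.0         # mm degC-1 month-1
    et_base: float = 0.97         # foliage-independent ET fraction
    bucket_mm: float = 400.0      # plant-available water capacity
    w_half_rh: float = 300.0      # % porosity, h_W half saturation (weak)

    def __post_init__(self) -> None:
        if self.q10 <= 1.0:
            raise ValueError("Q10 must be > 1")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("imm_frac", "n_vol_frac", "et_base", "fol_recovery_at_5"):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{f.name} must lie in [0, 1]")
            elif f.name not in ("t_opt",) and v < 0:
                raise ValueError(f"{f.name} must be >= 0")


def default_parameters(overrides: dict | None = None) -> Parameters:
    """Load the versioned default-parameter file shipped with the package."""
    text = resources.files("cflux.data").joinpath("default_params.yaml").read_text()
    raw = yaml.safe_load(text)
    raw.pop("version", None)
    if overrides:
        raw.update(overrides)
    return Parameters(**raw)


def load_parameters(path) -> Parameters:
    """Read a parameter YAML file, validating names and ranges."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw.pop("version", None)
    known = {f.name for f in fields(Parameters)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    return Parameters(**raw)


@dataclass
class CohortState:
    """Pools and diagnostics of one land cohort (per m2 of ground)."""

    cveg: float = 2200.0      # g C m-2
    csoil: float = 10100.0    # g C m-2
    nsoil: float = 336.7      # g N m-2
    navail: float = 7.9       # g N m-2
    f_fol: float = 1.0        # fraction of mature canopy
    moss_cm: float = 15.0     # organic/moss layer depth
    tsoil: float = 0.0        # diagnostic, degC
    water_mm: float = 300.0   # bucket water content
    years_since_fire: float = math.inf
    f_fol_prefire: float = 1.0   # recovery target
    f_fol_postfire: float = 1.0  # recovery origin
    moss_postfire: float = 15.0

    # diagnostic moisture (% of total porosity), set by step_month
    _moist: float = field(default=75.0, repr=False)

    @property
    def moisture(self) -> float:
        """Soil moisture as % of total porosity (diagnostic)."""
        return self._moist

    def total_c(self) -> float:
        return self.cveg + self.csoil


class MonthClimate(NamedTuple):
    tair: float   # degC
    prec: float   # mm
    vapr: float   # hPa (carried, unused by the reduced kernel)
    cloud: float  # percent (carried, unused by the reduced kernel)
    co2: float    # ppm
    tair_annual_mean: float  # degC, mean seasonal baseline of the cell


class MonthlyFlux(NamedTuple):
    npp: float        # g C m-2 month-1
    rh: float
    nep: float        # npp - rh, exactly
    litterfall: float
    net_nmin: float   # g N m-2 month-1


class FireEmission(NamedTuple):
    veg: float    # g C m-2
    soil: float
    total: float  # veg + soil, exactly
    n_lost: float  # g N m-2 volatilized


def soil_temperature(tair: float, tair_annual_mean: float, moss_cm: float,
                     params: Parameters) -> float:
    """Damped air temperature minus the moss-layer insulation offset.

    Losing moss therefore warms the soil linearly: removing ``d`` cm raises
    soil temperature by ``insulation * d`` degC.
    """
    smoothed = tair_annual_mean + params.t_damp * (tair - tair_annual_mean)
    return smoothed - params.insulation * moss_cm


def soil_moisture(state: CohortState, month: MonthClimate,
                  params: Parameters) -> tuple[float, float]:
    """One bucket-balance step: + precipitation, - ET (ET scales with
    foliage).  Returns (new water mm, moisture % of capacity, clamped)."""
    et = (
        params.et_coeff
        * max(month.tair, 0.0)
        * (params.et_base + (1.0 - params.et_base) * state.f_fol)
    )
    water = float(np.clip(state.water_mm + month.prec - et, 0.0, params.bucket_mm))
    return water, 100.0 * water / params.bucket_mm


def foliage_recovery(years_since_fire: float, state: CohortState,
                     params: Parameters) -> float:
    """Piecewise post-fire foliage trajectory.

    Linear from the post-fire foliage fraction to a junction value at year
    5, then a logistic approach to the pre-fire reference; continuous at
    the junction and asymptoting to the reference.
    """
    if years_since_fire < 0:
        raise ValueError("years since fire must be >= 0")
    f0, fref = state.f_fol_postfire, state.f_fol_prefire
    t5 = params.fol_linear_years
    f5 = f0 + (fref - f0) * params.fol_recovery_at_5
    t = years_since_fire
    if t <= t5:
        return f0 + (f5 - f0) * t / t5
    s, m = params.fol_sig_steepness, params.fol_sig_midpoint
    logistic = lambda x: 1.0 / (1.0 + math.exp(-s * (x - m)))
    l5 = logistic(t5)
    g = (logistic(t) - l5) / (1.0 - l5)
    return f5 + (fref - f5) * g


def moss_recovery(years_since_fire: float, state: CohortState,
                  params: Parameters) -> float:
    """Exponential recovery: depth(t) = A - (A - d0) exp(-t / tau)."""
    if years_since_fire < 0:
        raise ValueError("years since fire must be >= 0")
    a, d0 = params.moss_max, state.moss_postfire
    return a - (a - d0) * math.exp(-years_since_fire / params.moss_tau)


def step_month(state: CohortState, month: MonthClimate,
               params: Parameters) -> tuple[CohortState, MonthlyFlux]:
    """Advance one cohort by one month (pure function; explicit Euler)."""
    if not all(np.isfinite(month[:6])):
        raise EcosysError(f"non-finite climate forcing: {month}")

    ysf = state.years_since_fire
    if math.isfinite(ysf):
        f_fol = foliage_recovery(ysf, state, params)
        moss = moss_recovery(ysf, state, params)
    else:
        f_fol, moss = state.f_fol_prefire, state.moss_cm

    tsoil = soil_temperature(month.tair, month.tair_annual_mean, moss, params)
    water, moist = soil_moisture(replace(state, f_fol=f_fol), month, params)

    # heterotrophic respiration and N mineralization
    h_w = moist / (moist + params.w_half_rh)
    rh = params.k_decomp * state.csoil * params.q10 ** ((tsoil - params.t_ref) / 10.0) * h_w
    gross_min = rh * (state.nsoil / state.csoil) if state.csoil > 0 else 0.0
    net_nmin = (1.0 - params.imm_frac) * gross_min

    # production, nitrogen-limited and hard-capped by available N
    g_t = math.exp(-(((month.tair - params.t_opt) / params.t_width) ** 2))
    g_w = moist / (moist + params.w_half_npp)
    g_n = state.navail / (state.navail + params.n_half)
    g_co2 = 1.0 + params.co2_beta * math.log(month.co2 / CO2_REFERENCE_PPM)
    npp = params.npp_max * f_fol * g_t * g_w * g_n * g_co2
    avail = state.navail + net_nmin + params.n_input
    uptake = npp / params.cn_veg
    if uptake > avail:
        uptake = avail
        npp = uptake * params.cn_veg

    litter = params.k_litter * state.cveg

    new = replace(
        state,
        cveg=state.cveg + npp - litter,
        csoil=state.csoil + litter - rh,
        nsoil=state.nsoil + litter / params.cn_veg - net_nmin,
        navail=avail - uptake,
        f_fol=f_fol,
        moss_cm=moss,
        tsoil=tsoil,
        water_mm=water,
        _moist=moist,
        years_since_fire=ysf + 1.0 / 12.0 if math.isfinite(ysf) else ysf,
    )
    for name in ("cveg", "csoil", "nsoil", "navail"):
        if getattr(new, name) < 0:
            raise EcosysError(
                f"negative pool {name}={getattr(new, name):.4g} after update; "
                "rate parameters are inconsistent with the state"
            )
    return new, MonthlyFlux(npp, rh, npp - rh, litter, net_nmin)


def apply_fire(state: CohortState, severity: SeverityRecord,
               params: Parameters) -> tuple[CohortState, FireEmission]:
    """Combust canopy and soil pools according to the severity fractions.

    E_veg = canopy_frac * C_veg, E_soil = soil_frac * C_soil; soil N is
    removed proportionally to soil C.  Combusted canopy N is exported
    entirely (it burns aloft); of the combusted soil N a fixed fraction
    volatilizes and the remainder stays on site as plant-available ash N.
    Foliage and moss drop by their respective fractions and the
    time-since-fire clock restarts.
    """
    cf, sf = severity.canopy_frac, severity.soil_frac
    if not (0.0 <= cf <= 1.0 and 0.0 <= sf <= 1.0):
        raise ValueError("combustion fractions must lie in [0, 1]")
    e_veg = cf * state.cveg
    e_soil = sf * state.csoil
    n_veg = e_veg / params.cn_veg
    n_soil = sf * state.nsoil
    n_vol = n_veg + params.n_vol_frac * n_soil
    f_fol_post = state.f_fol * (1.0 - cf)
    moss_post = state.moss_cm * (1.0 - sf)
    new = replace(
        state,
        cveg=state.cveg - e_veg,
        csoil=state.csoil - e_soil,
        nsoil=state.nsoil - n_soil,
        navail=state.navail + (1.0 - params.n_vol_frac) * n_soil,
        f_fol=f_fol_post,
        moss_cm=moss_post,
        years_since_fire=0.0,
        f_fol_prefire=state.f_fol_prefire,
        f_fol_postfire=f_fol_post,
        moss_postfire=moss_post,
    )
    return new, FireEmission(e_veg, e_soil, e_veg + e_soil, n_vol)


def make_climatology(cell_clim: dict[str, np.ndarray], co2: float) -> list[MonthClimate]:
    """Twelve repeating MonthClimate entries from a mean seasonal cycle."""
    amean = float(np.mean(cell_clim["tair"]))
    return [
        MonthClimate(
            tair=float(cell_clim["tair"][m]),
            prec=float(cell_clim["prec"][m]),
            vapr=float(cell_clim["vapr"][m]),
            cloud=float(cell_clim["cloud"][m]),
            co2=co2,
            tair_annual_mean=amean,
        )
        for m in range(12)
    ]


def spinup(
    state0: CohortState,
    climatology: list[MonthClimate],
    params: Parameters,
    years: int = 120,
) -> tuple[CohortState, float]:
    """Run repeating mean-seasonal forcing for ``years``; return the final
    state and the residual drift \\|annual Delta C_total\\| / C_total (yr-1)
    over the last year."""
    state = state0
    c_prev = state.total_c()
    init_total = max(state0.total_c(), 1.0)
    drift = math.inf
    for _ in range(years):
        for mc in climatology:
            state, _ = step_month(state, mc, params)
        if state.total_c() > 10.0 * init_total:
            raise EcosysError("spin-up divergence: pools exceeded 10x initial")
        drift = abs(state.total_c() - c_prev) / max(state.total_c(), 1e-9)
        c_prev = state.total_c()
    return state, drift
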