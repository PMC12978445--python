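"""Surrogate process-based rice growth simulator.

Maps a cultivar coefficient vector plus an environment (soil, daily weather,
management) to seasonal phenotype outputs: biomass, grain yield, grain and
tiller numbers, anthesis/maturity dates, cumulative evapotranspiration,
harvest index and water-use efficiency.

The simulator is intentionally minimal: it reproduces the qualitative
physiology attached to each coefficient (thermal-time phenology with
photoperiod modulation, phyllochron-driven canopy build-up, tillering,
single-bucket soil water balance, heat/cold sterility around flowering,
source-limited grain filling) without porting any external crop model.
All surrogate constants live in :class:`SimulatorConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "GeneticCoefficients",
    "SoilProfile",
    "WeatherSeries",
    "EnvironmentScenario",
    "SimulationResult",
    "SimulatorConfig",
    "WaterStep",
    "thermal_time",
    "photothermal_requirement",
    "water_balance_step",
    "sterility_fraction",
    "daylength_hours",
    "simulate",
    "DEFAULT_COEFFICIENTS",
]

COEFFICIENT_NAMES = (
    "P1", "P2O", "P2R", "P5", "PHINT", "G1", "G2", "G3", "THOT", "TCLDP", "TCLDF",
)

#: The subset searched by the optimizer, in panel column order.
OPTIMIZED_COEFFICIENTS = ("P1", "P5", "P2R", "PHINT", "P2O", "G1", "G2", "G3")


@dataclass(frozen=True)
class GeneticCoefficients:
    """Cultivar coefficient vector.

    Thermal-time units (GDD) are degree-Celsius days above the base
    temperature; G2 is grams per grain; the three thresholds are in degrees
    Celsius.
    """

    P1: float = 450.0     # emergence -> panicle initiation (GDD)
    P2O: float = 12.0     # critical photoperiod (h)
    P2R: float = 60.0     # delay per hour of daylength above P2O (GDD/h)
    P5: float = 320.0     # grain-filling duration (GDD)
    PHINT: float = 75.0   # phyllochron interval (GDD per leaf)
    G1: float = 60.0      # spikelets per panicle (scaling)
    G2: float = 0.025     # potential single-grain weight (g)
    G3: float = 1.0       # tillering coefficient
    THOT: float = 36.0    # heat-sterility onset (degC on tmax)
    TCLDP: float = 15.0   # cold panicle-delay onset (degC on tmin)
    TCLDF: float = 13.0   # cold-sterility onset (degC on tmin)

    def __post_init__(self) -> None:
        for name in COEFFICIENT_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 < self.P2O < 24.0:
            raise ValueError(f"P2O must be in (0, 24), got {self.P2O}")
        for name in ("P1", "P5", "PHINT", "G1", "G2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.P2R < 0 or self.G3 < 0:
            raise ValueError("P2R and G3 must be non-negative")

    def as_array(self, names: Sequence[str] = COEFFICIENT_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_values(self, names: Sequence[str], values: Sequence[float]) -> "GeneticCoefficients":
        return replace(self, **{n: float(v) for n, v in zip(names, values)})

    @classmethod
    def from_mapping(cls, mapping) -> "GeneticCoefficients":
        return cls(**{n: float(mapping[n]) for n in COEFFICIENT_NAMES if n in mapping})


DEFAULT_COEFFICIENTS = GeneticCoefficients()


@dataclass(frozen=True)
class SoilProfile:
    """Single-bucket soil profile with volumetric water limits."""

    depth: float = 60.0   # rooting depth (cm)
    SLLL: float = 0.16    # wilting point (cm3/cm3)
    SDUL: float = 0.29    # field capacity (cm3/cm3)
    SSAT: float = 0.44    # saturation (cm3/cm3)
    SSKS: float = 0.75    # saturated conductivity (cm/h)
    sand: float = 400.0   # texture (g/kg)
    silt: float = 300.0
    clay: float = 300.0
    SBDM: float = 1.5     # bulk density (g/cm3)
    SLOC: float = 0.6     # organic carbon (%) -- metadata
    SLNI: float = 0.05    # nitrogen (%) -- metadata
    SLHW: float = 5.9     # pH -- metadata
    SLCF: float = 0.0     # coarse fraction (%) -- metadata
    label: str = "soil"

    def __post_init__(self) -> None:
        if not 0.0 < self.SLLL < self.SDUL < self.SSAT < 1.0:
            raise ValueError(
                f"require 0 < SLLL < SDUL < SSAT < 1, got "
                f"({self.SLLL}, {self.SDUL}, {self.SSAT})"
            )
        if self.depth <= 0 or self.SSKS <= 0:
            raise ValueError("depth and SSKS must be positive")

    # stores in mm over the rooting depth
    @property
    def ll_store(self) -> float:
        return self.SLLL * self.depth * 10.0

    @property
    def dul_store(self) -> float:
        return self.SDUL * self.depth * 10.0

    @property
    def sat_store(self) -> float:
        return self.SSAT * self.depth * 10.0


@dataclass(frozen=True)
class WeatherSeries:
    """Daily weather arrays; ``daylength`` optional (computed from latitude)."""

    tmin: np.ndarray          # degC
    tmax: np.ndarray          # degC
    srad: np.ndarray          # MJ/m2/day
    rh: np.ndarray            # %
    wind: np.ndarray          # m/s
    rain: np.ndarray          # mm/day
    daylength: np.ndarray | None = None  # hours
    latitude: float = 12.5
    start_doy: int = 182      # day of year of the first record

    def __post_init__(self) -> None:
        arrays = {
            "tmin": self.tmin, "tmax": self.tmax, "srad": self.srad,
            "rh": self.rh, "wind": self.wind, "rain": self.rain,
        }
        n = len(self.tmin)
        for name, arr in arrays.items():
            object.__setattr__(self, name, np.asarray(arr, dtype=float))
        for name in arrays:
            if len(getattr(self, name)) != n:
                raise ValueError("weather arrays must share one length")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin in weather record")
        if np.any(self.rain < 0) or np.any(self.srad < 0):
            raise ValueError("rain and srad must be non-negative")
        if np.any((self.rh < 0) | (self.rh > 100)):
            raise ValueError("rh must lie in [0, 100]")
        if self.daylength is not None:
            dl = np.asarray(self.daylength, dtype=float)
            if len(dl) != n:
                raise ValueError("daylength length mismatch")
            if np.any((dl <= 0) | (dl >= 24)):
                raise ValueError("daylength must lie in (0, 24)")
            object.__setattr__(self, "daylength", dl)

    def __len__(self) -> int:
        return len(self.tmin)

    def resolved_daylength(self) -> np.ndarray:
        if self.daylength is not None:
            return self.daylength
        doy = (self.start_doy - 1 + np.arange(len(self))) % 365 + 1
        return daylength_hours(self.latitude, doy)


@dataclass(frozen=True)
class EnvironmentScenario:
    """Soil + weather + management: the E in GxE."""

    soil: SoilProfile
    weather: WeatherSeries
    sowing_day: int = 0
    season_cap: int = 160
    initial_water_fraction: float = 1.0  # of plant-available range above wilting
    label: str = "env"
    weight: float | None = None          # optional area weight metadata


@dataclass(frozen=True)
class SimulationResult:
    biomass: float        # kg/ha
    grain_yield: float    # kg/ha
    grains: float         # count/m2
    tillers: float        # count/m2
    anthesis: int         # days after sowing (0 if never reached)
    maturity: int         # days after sowing
    cum_et: float         # mm
    hi: float             # dimensionless
    wue: float            # kg/ha/mm
    sterility: float      # fraction
    flowered: bool = True
    water_balance_residual: float = 0.0  # mm; diagnostics, ~0

    def channels(self) -> dict:
        """The six output channels screened by the sensitivity layer."""
        return {
            "biomass": self.biomass,
            "yield": self.grain_yield,
            "grains": self.grains,
            "tillers": self.tillers,
            "anthesis": float(self.anthesis),
            "maturity": float(self.maturity),
        }


@dataclass(frozen=True)
class SimulatorConfig:
    """Every surrogate constant, with documented defaults.

    tbase
        Base temperature for thermal time (degC).
    rue
        Radiation-use efficiency (g biomass per MJ intercepted).
    kc
        Crop coefficient scaling reference ET to paddy ET demand.
    base_density
        Baseline tiller density before the tillering response (per m2).
    panicle_span
        Thermal span of the panicle phase, initiation -> anthesis (GDD);
        sized so default-coefficient seasons run 90-120 days.
    heat_ramp / cold_ramp
        Width of the linear sterility ramps above THOT / below TCLDF (degC).
    raw_fraction
        Readily-available-water fraction p of the DUL-LL range.
    flower_window
        Half-width of the flowering window around anthesis (days).
    canopy_rate
        Saturation rate of light interception per appeared leaf.
    fill_partition
        Fraction of daily assimilate routed to grain during filling.
    remob_fraction
        Fraction of anthesis biomass remobilizable to grain.
    pot_fill_fraction
        Hard cap on yield as a fraction of final biomass.
    cold_delay_slope
        Extra panicle-phase GDD per degC of tmin below TCLDP per day.
    soil_evap_fraction
        Bare-soil evaporation coefficient applied to the canopy-uncovered
        share of ET demand; not scaled by the water-stress factor.
    fill_stress_abort
        Yield fraction lost per unit mean water-stress deficit over the
        filling phase (unfilled-grain abortion under terminal drought).
    """

    tbase: float = 9.0
    rue: float = 0.9
    base_density: float = 220.0
    panicle_span: float = 750.0
    kc: float = 1.4
    heat_ramp: float = 5.0
    cold_ramp: float = 4.0
    raw_fraction: float = 0.6
    flower_window: int = 5
    canopy_rate: float = 0.11
    fill_partition: float = 0.45
    remob_fraction: float = 0.15
    pot_fill_fraction: float = 0.85
    cold_delay_slope: float = 5.0
    soil_evap_fraction: float = 0.5
    fill_stress_abort: float = 0.8


DEFAULT_CONFIG = SimulatorConfig()


def thermal_time(tmin: float, tmax: float, tbase: float) -> float:
    """Daily growing-degree-day increment: max(0, mean temperature - base)."""
    if tmax < tmin:
        raise ValueError(f"malformed weather record: tmax {tmax} < tmin {tmin}")
    return max(0.0, 0.5 * (tmin + tmax) - tbase)


def photothermal_requirement(P1: float, P2O: float, P2R: float, daylength: float) -> float:
    """Effective thermal time to panicle initiation under the day's photoperiod.

    Below the critical photoperiod P2O there is no delay; above it the
    requirement grows by P2R GDD per hour of excess daylength.
    """
    return P1 + P2R * max(0.0, daylength - P2O)


class WaterStep(NamedTuple):
    store: float      # mm at end of step
    actual_et: float  # mm
    drainage: float   # mm
    runoff: float     # mm
    stress: float     # water-availability factor in [0, 1]; 1 = unstressed


def water_balance_step(
    store: float,
    rain: float,
    et_demand: float,
    soil: SoilProfile,
    *,
    raw_fraction: float = 0.6,
    evap_demand: float = 0.0,
) -> WaterStep:
    """One day of a single-bucket water balance; mass-conserving.

    Rain infiltrates first (excess above saturation leaves as runoff), the
    stress factor is evaluated on the post-infiltration store, actual ET is
    stress-limited transpiration bounded by the extractable water, and water
    above field capacity drains toward it at a rate capped by SSKS.

    ``evap_demand`` is an optional bare-soil evaporation demand extracted
    after transpiration: unlike transpiration it is not scaled by the stress
    factor, only bounded by the water remaining above wilting point.
    """
    ll, dul, sat = soil.ll_store, soil.dul_store, soil.sat_store
    if not (ll - 1e-9 <= store <= sat + 1e-9):
        raise ValueError(f"soil store {store} mm outside physical bounds [{ll}, {sat}]")
    if rain < 0 or et_demand < 0 or evap_demand < 0:
        raise ValueError("rain and ET demands must be non-negative")

    wet = store + rain
    runoff = max(0.0, wet - sat)
    wet -= runoff

    stress = (wet - ll) / (raw_fraction * (dul - ll))
    stress = min(1.0, max(0.0, stress))

    transpiration = min(stress * et_demand, wet - ll)
    wet -= transpiration
    evaporation = min(evap_demand, wet - ll)
    wet -= evaporation
    actual_et = transpiration + evaporation

    drainage = 0.0
    if wet > dul:
        drainage = min(wet - dul, soil.SSKS * 240.0)  # cm/h -> mm/day
        wet -= drainage

    return WaterStep(wet, actual_et, drainage, runoff, stress)


def _ramp_up(x: np.ndarray, onset: float, width: float) -> np.ndarray:
    return np.clip((x - onset) / width, 0.0, 1.0)


def sterility_fraction(
    window_tmax: Sequence[float],
    window_tmin: Sequence[float],
    THOT: float,
    TCLDF: float,
    *,
    heat_ramp: float = 5.0,
    cold_ramp: float = 4.0,
) -> float:
    """Spikelet sterility from thermal stress in the flowering window.

    Heat acts on daily tmax (linear 0 at THOT to 1 at THOT + heat_ramp),
    cold on daily tmin (0 at TCLDF down to 1 at TCLDF - cold_ramp); the two
    window-averaged terms combine independently.
    """
    tmax = np.asarray(window_tmax, dtype=float)
    tmin = np.asarray(window_tmin, dtype=float)
    if tmax.size == 0 or tmin.size == 0:
        raise ValueError("empty flowering window: phenology failed upstream")
    heat = float(np.mean(_ramp_up(tmax, THOT, heat_ramp)))
    cold = float(np.mean(_ramp_up(TCLDF - tmin, 0.0, cold_ramp)))
    return 1.0 - (1.0 - heat) * (1.0 - cold)


def daylength_hours(latitude: float, doy: np.ndarray | int) -> np.ndarray:
    """Astronomical daylength from latitude and day of year (CBM-free form)."""
    doy = np.asarray(doy, dtype=float)
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    lat = np.radians(latitude)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_h)


def _reference_et(tmean: float, srad: float) -> float:
    # Hargreaves radiation form: mm/day from mean temperature and solar input.
    return max(0.0, 0.0135 * (tmean + 17.8) * srad / 2.45)


def simulate(
    coeffs: GeneticCoefficients,
    env: EnvironmentScenario,
    config: SimulatorConfig = DEFAULT_CONFIG,
) -> SimulationResult:
    """Run one season; deterministic in its inputs.

    Daily loop: thermal time drives three phases (vegetative until the
    photothermal requirement is met, a fixed-span panicle phase extendable by
    cold nights below TCLDP, then grain filling for P5 GDD). Leaves appear
    every PHINT GDD and build a saturating light-interception factor; biomass
    grows as RUE x radiation x interception x water stress. Grain number is
    set at anthesis from tillering, flowering-window water stress and thermal
    sterility; grain filling is source-limited (daily partitioned assimilate
    plus a capped remobilization pool). A season that never reaches anthesis
    yields a flagged zero-yield result rather than an exception.
    """
    soil = env.soil
    wx = env.weather
    cfg = config
    start = env.sowing_day
    n_days = min(len(wx) - start, env.season_cap)
    if n_days <= 0:
        raise ValueError("weather series does not cover the sowing day")

    daylength = wx.resolved_daylength()

    ll, dul = soil.ll_store, soil.dul_store
    store = ll + env.initial_water_fraction * (dul - ll)
    initial_store = store

    cum_gdd = 0.0
    leaves = 0.0
    canopy = 0.0
    biomass = 0.0
    cum_et = 0.0
    grain = 0.0

    phase = 0  # 0 vegetative, 1 panicle, 2 filling, 3 mature
    pan_gdd = 0.0
    pan_req = cfg.panicle_span
    fill_gdd = 0.0
    anthesis_day = 0
    maturity_day = 0

    veg_stress_sum = 0.0
    veg_days = 0
    stress_trace = np.empty(n_days)

    tillers = cfg.base_density
    grains = 0.0
    sterility = 0.0
    sink = 0.0
    remob_pool = 0.0
    biomass_anthesis = 0.0
    fill_deficit_sum = 0.0
    fill_days = 0

    sum_rain = sum_et = sum_drain = sum_runoff = 0.0

    for d in range(n_days):
        i = start + d
        tmin_d, tmax_d = wx.tmin[i], wx.tmax[i]
        gdd = thermal_time(tmin_d, tmax_d, cfg.tbase)
        tmean = 0.5 * (tmin_d + tmax_d)

        if phase < 2:
            leaves += gdd / coeffs.PHINT
            canopy = 1.0 - math.exp(-cfg.canopy_rate * leaves)
            canopy_eff = canopy
        else:
            # linear senescence to 20% interception over the filling phase
            frac = min(1.0, fill_gdd / coeffs.P5)
            canopy_eff = canopy * max(0.2, 1.0 - 0.8 * frac)

        et0 = cfg.kc * _reference_et(tmean, wx.srad[i])
        transp_demand = et0 * canopy_eff
        evap_demand = et0 * (1.0 - canopy_eff) * cfg.soil_evap_fraction
        step = water_balance_step(
            store, wx.rain[i], transp_demand, soil,
            raw_fraction=cfg.raw_fraction, evap_demand=evap_demand,
        )
        store = step.store
        stress_trace[d] = step.stress
        sum_rain += wx.rain[i]
        sum_et += step.actual_et
        sum_drain += step.drainage
        sum_runoff += step.runoff
        cum_et += step.actual_et

        assim = cfg.rue * wx.srad[i] * canopy_eff * step.stress * 10.0  # kg/ha
        biomass += assim

        if phase == 0:
            veg_stress_sum += step.stress
            veg_days += 1
            cum_gdd += gdd
            req = photothermal_requirement(
                coeffs.P1, coeffs.P2O, coeffs.P2R, float(daylength[i])
            )
            if cum_gdd >= req:
                phase = 1
        elif phase == 1:
            if tmin_d < coeffs.TCLDP:
                pan_req += cfg.cold_delay_slope * (coeffs.TCLDP - tmin_d)
            pan_gdd += gdd
            if pan_gdd >= pan_req:
                phase = 2
                anthesis_day = d + 1
                biomass_anthesis = biomass
                remob_pool = cfg.remob_fraction * biomass_anthesis
                veg_stress = veg_stress_sum / max(1, veg_days)
                tillers = cfg.base_density * (
                    1.0 + coeffs.G3 * canopy * veg_stress
                )
                lo = max(0, i - cfg.flower_window)
                hi = min(len(wx), i + cfg.flower_window + 1)
                sterility = sterility_fraction(
                    wx.tmax[lo:hi], wx.tmin[lo:hi],
                    coeffs.THOT, coeffs.TCLDF,
                    heat_ramp=cfg.heat_ramp, cold_ramp=cfg.cold_ramp,
                )
                w0 = max(0, d - cfg.flower_window)
                flower_stress = float(np.mean(stress_trace[w0:d + 1]))
                grains = coeffs.G1 * tillers * (1.0 - sterility) * flower_stress
                sink = grains * coeffs.G2 * 10.0  # g/m2 -> kg/ha
        elif phase == 2:
            gdd_frac = min(gdd, max(0.0, coeffs.P5 - fill_gdd)) / coeffs.P5
            remob = remob_pool * gdd_frac
            gain = min(max(0.0, sink - grain), cfg.fill_partition * assim + remob)
            grain += gain
            fill_deficit_sum += 1.0 - step.stress
            fill_days += 1
            fill_gdd += gdd
            if fill_gdd >= coeffs.P5:
                phase = 3
                maturity_day = d + 1
                break

    if phase < 2:
        # never flowered: flagged failure with zero yield
        residual = sum_rain + initial_store - store - sum_et - sum_drain - sum_runoff
        return SimulationResult(
            biomass=biomass, grain_yield=0.0, grains=0.0, tillers=tillers,
            anthesis=0, maturity=n_days, cum_et=cum_et, hi=0.0, wue=0.0,
            sterility=0.0, flowered=False, water_balance_residual=residual,
        )

    if maturity_day == 0:
        # season cap reached during filling; keep maturity strictly after anthesis
        maturity_day = max(n_days, anthesis_day + 1)

    if fill_days > 0:
        # unfilled-grain abortion under sustained filling-phase water stress
        mean_deficit = fill_deficit_sum / fill_days
        grain *= max(0.0, 1.0 - cfg.fill_stress_abort * mean_deficit)
    grain = min(grain, cfg.pot_fill_fraction * biomass)
    hi = grain / biomass if biomass > 0 else 0.0
    wue = grain / cum_et if cum_et > 0 else 0.0
    residual = sum_rain + initial_store - store - sum_et - sum_drain - sum_runoff

    return SimulationResult(
        biomass=biomass,
        grain_yield=grain,
        grains=grains,
        tillers=tillers,
        anthesis=anthesis_day,
        maturity=maturity_day,
        cum_et=cum_et,
        hi=hi,
        wue=wue,
        sterility=sterility,
        flowered=True,
        water_balance_residual=residual,
    )
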