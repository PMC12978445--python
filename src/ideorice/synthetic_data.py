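"""Synthetic weather, soils, environments and cultivar panels.

Generators reproduce the statistical structure of the study region's two
climate archetypes (a humid southern type and a drier, hotter northern
type) and two soil archetypes, so every pipeline stage runs without any
external data. Also hosts the vapor-pressure-deficit computation (Tetens
saturation curve) and a simplified Saxton-Rawls pedotransfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ideorice.crop_model import (
    EnvironmentScenario,
    GeneticCoefficients,
    SoilProfile,
    WeatherSeries,
)
from ideorice.sensitivity import ParameterSpace, default_space
from ideorice.similarity import CultivarPanel, PANEL_COEFFICIENTS

__all__ = [
    "ClimateArchetype",
    "SoilArchetype",
    "ClimateSummary",
    "SOUTH_CLIMATE",
    "NORTH_CLIMATE",
    "SOIL_TYPE_1",
    "SOIL_TYPE_2",
    "vpd",
    "generate_weather",
    "pedotransfer",
    "generate_panel",
    "generate_environment_set",
]


@dataclass(frozen=True)
class ClimateArchetype:
    """Seasonal climate statistics driving the weather generator."""

    label: str
    tmin_mean: float          # degC
    tmax_mean: float
    tavg_mean: float
    rh_mean: float            # %
    srad_mean: float          # MJ/m2/day
    srad_sd: float
    season_rain_total: float  # mm over the wet season
    wet_season_days: int
    temp_sd: float = 1.5
    rh_sd: float = 5.0
    wet_persistence: float = 0.75   # P(wet | wet)
    wet_onset: float = 0.35         # P(wet | dry)
    rain_taper: float = 0.0         # occurrence decline toward season end

    def __post_init__(self) -> None:
        if self.season_rain_total <= 0 or self.wet_season_days <= 0:
            raise ValueError("season totals must be positive")
        if self.tmax_mean <= self.tmin_mean:
            raise ValueError("tmax_mean must exceed tmin_mean")


# Printed archetype statistics for the two climate types.
SOUTH_CLIMATE = ClimateArchetype(
    label="south",
    tmin_mean=22.19, tmax_mean=30.60, tavg_mean=26.39,
    rh_mean=80.33, srad_mean=19.16, srad_sd=3.44,
    season_rain_total=917.0, wet_season_days=120,
)
# Northern srad sd is not printed; default mirrors the southern value.
NORTH_CLIMATE = ClimateArchetype(
    label="north",
    tmin_mean=22.51, tmax_mean=33.04, tavg_mean=27.78,
    rh_mean=67.98, srad_mean=19.62, srad_sd=3.5,
    season_rain_total=513.24, wet_season_days=90,
    wet_persistence=0.6, wet_onset=0.25, rain_taper=1.0,
)


@dataclass(frozen=True)
class SoilArchetype:
    label: str
    profile: SoilProfile


SOIL_TYPE_1 = SoilArchetype(
    label="type-1",
    profile=SoilProfile(
        depth=60.0, SLLL=0.16, SDUL=0.29, SSAT=0.44, SSKS=0.75,
        sand=431.4, silt=305.3, clay=263.3, SBDM=1.50, SLHW=5.91,
        label="type-1",
    ),
)
SOIL_TYPE_2 = SoilArchetype(
    label="type-2",
    profile=SoilProfile(
        depth=60.0, SLLL=0.10, SDUL=0.23, SSAT=0.42, SSKS=1.09,
        sand=565.9, silt=250.0, clay=184.1, SBDM=1.55, SLHW=5.87,
        label="type-2",
    ),
)


@dataclass(frozen=True)
class ClimateSummary:
    tavg: float   # degC
    rh: float     # %
    es: float     # saturation vapor pressure (kPa)
    vpd: float    # kPa


def vpd(tavg: float, rh: float) -> ClimateSummary:
    """Vapor pressure deficit from mean temperature and relative humidity.

    Tetens saturation curve: es = 0.6108 exp(17.27 T / (T + 237.3));
    vpd = es (1 - RH/100).
    """
    if not 0.0 <= rh <= 100.0:
        raise ValueError(f"relative humidity {rh} outside [0, 100]")
    es = 0.6108 * math.exp(17.27 * tavg / (tavg + 237.3))
    return ClimateSummary(tavg=tavg, rh=rh, es=es, vpd=es * (1.0 - rh / 100.0))


def generate_weather(
    archetype: ClimateArchetype,
    n_days: int,
    seed: int | np.random.Generator = 0,
    latitude: float = 12.5,
    start_doy: int = 182,
) -> WeatherSeries:
    """Daily weather with the archetype's statistics; pure in (config, seed).

    Temperatures and radiation are Gaussian around the archetype means
    (tmax >= tmin enforced by pairwise resampling); rain follows a
    two-state wet/dry occurrence chain with exponential intensities over the
    wet-season span, rescaled so the realized total matches the archetype's
    seasonal total (pro-rated when fewer days are generated).
    """
    if n_days < 120:
        raise ValueError("n_days >= 120 required for a full season")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tmax = rng.normal(archetype.tmax_mean, archetype.temp_sd, n_days)
    tmin = rng.normal(archetype.tmin_mean, archetype.temp_sd, n_days)
    for _ in range(100):
        bad = tmax < tmin
        if not bad.any():
            break
        tmax[bad] = rng.normal(archetype.tmax_mean, archetype.temp_sd, bad.sum())
        tmin[bad] = rng.normal(archetype.tmin_mean, archetype.temp_sd, bad.sum())
    swap = tmax < tmin  # pathological sd; keep the invariant regardless
    tmax[swap], tmin[swap] = tmin[swap], tmax[swap]

    srad = np.clip(rng.normal(archetype.srad_mean, archetype.srad_sd, n_days), 0.0, None)
    rh = np.clip(rng.normal(archetype.rh_mean, archetype.rh_sd, n_days), 0.0, 100.0)
    wind = np.clip(rng.normal(1.8, 0.6, n_days), 0.1, None)

    span = min(n_days, archetype.wet_season_days)
    target = archetype.season_rain_total * span / archetype.wet_season_days
    wet = np.zeros(n_days, dtype=bool)
    state = True  # wet season starts wet
    for d in range(span):
        p = archetype.wet_persistence if state else archetype.wet_onset
        # monsoon retreat: occurrence probability declines toward season end
        p *= (1.0 - d / span) ** archetype.rain_taper
        state = rng.uniform() < p
        wet[d] = state
    if not wet.any():
        wet[rng.integers(span)] = True
    expected_wet = max(1, int(span * 0.5))
    rain = np.zeros(n_days)
    rain[wet] = rng.exponential(target / expected_wet, wet.sum())
    rain *= target / rain.sum()

    return WeatherSeries(
        tmin=tmin, tmax=tmax, srad=srad, rh=rh, wind=wind, rain=rain,
        latitude=latitude, start_doy=start_doy,
    )


def pedotransfer(sand: float, clay: float, om: float = 1.5) -> tuple[float, float, float, float]:
    """Simplified Saxton-Rawls regressions: (SLLL, SDUL, SSAT, SSKS).

    ``sand`` and ``clay`` are mass fractions (0-1), ``om`` is organic matter
    in percent. Returns volumetric wilting point, field capacity and
    saturation (cm3/cm3) plus saturated conductivity in cm/h.
    """
    if sand < 0 or clay < 0 or om < 0:
        raise ValueError("texture inputs must be non-negative")
    if sand + clay > 1.0:
        raise ValueError("sand + clay must not exceed 1")
    s, c = sand, clay
    t1500 = -0.024 * s + 0.487 * c + 0.006 * om \
        + 0.005 * s * om - 0.013 * c * om + 0.068 * s * c + 0.031
    theta_wp = t1500 + (0.14 * t1500 - 0.02)
    t33 = -0.251 * s + 0.195 * c + 0.011 * om \
        + 0.006 * s * om - 0.027 * c * om + 0.452 * s * c + 0.299
    theta_fc = t33 + (1.283 * t33**2 - 0.374 * t33 - 0.015)
    ts33 = 0.278 * s + 0.034 * c + 0.022 * om \
        - 0.018 * s * om - 0.027 * c * om - 0.584 * s * c + 0.078
    theta_s33 = ts33 + (0.636 * ts33 - 0.107)
    theta_sat = theta_fc + theta_s33 - 0.097 * s + 0.043
    lam = (math.log(theta_fc) - math.log(theta_wp)) / (math.log(1500.0) - math.log(33.0))
    ks_mm_h = 1930.0 * (theta_sat - theta_fc) ** (3.0 - lam)
    if not 0.0 < theta_wp < theta_fc < theta_sat:
        raise ValueError(
            f"texture (sand={sand}, clay={clay}, om={om}) outside the "
            "pedotransfer validity domain"
        )
    return theta_wp, theta_fc, theta_sat, ks_mm_h / 10.0


def generate_panel(
    n: int,
    space: ParameterSpace | None = None,
    groups: Sequence[str] = ("indica", "japonica", "hybrid"),
    seed: int = 0,
    plant: GeneticCoefficients | None = None,
) -> CultivarPanel:
    """Random cultivar panel within bounds; optional planted truth vector.

    Group labels cycle through ``groups``; the planted vector (for recovery
    tests) is appended as its own entry named ``planted``.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    if space is None:
        space = default_space(PANEL_COEFFICIENTS)
    if tuple(space.names) != PANEL_COEFFICIENTS:
        space = space.subset(PANEL_COEFFICIENTS)
    rng = np.random.default_rng(seed)
    values = space.lower + rng.uniform(size=(n, space.k)) * (space.upper - space.lower)
    names = [f"CV{i + 1:02d}" for i in range(n)]
    labels = [groups[i % len(groups)] for i in range(n)]
    if plant is not None:
        values = np.vstack([values, plant.as_array(PANEL_COEFFICIENTS)])
        names.append("planted")
        labels.append("ideotype")
    return CultivarPanel(names=names, groups=labels, values=values)


#: Field capacities of the four target environments and their area weights.
_ENV_SPECS = (
    ("env1", SOUTH_CLIMATE, 0.30, 0.16, 0.75, 0.30),
    ("env2", NORTH_CLIMATE, 0.28, 0.15, 0.80, 0.18),
    ("env3", SOUTH_CLIMATE, 0.24, 0.11, 1.00, 0.21),
    ("env4", NORTH_CLIMATE, 0.23, 0.10, 1.09, 0.20),
)


def generate_environment_set(
    seed: int = 0,
    n_days: int = 170,
    season_cap: int = 160,
) -> list[EnvironmentScenario]:
    """The four study environments: two climates crossed with soil retention.

    Environments 1 and 3 use the humid southern climate, 2 and 4 the drier
    northern one; field capacity falls from 0.30 to 0.23 cm3/cm3 across the
    set. Area-weight metadata (0.30, 0.18, 0.21, 0.20) sums to 0.89.
    """
    rng = np.random.default_rng(seed)
    scenarios = []
    for label, climate, sdul, slll, ssks, weight in _ENV_SPECS:
        soil = SoilProfile(
            depth=60.0, SLLL=slll, SDUL=sdul, SSAT=max(0.42, sdul + 0.13),
            SSKS=ssks, label=label,
        )
        weather = generate_weather(
            climate, n_days, seed=np.random.default_rng(rng.integers(2**63 - 1))
        )
        scenarios.append(
            EnvironmentScenario(
                soil=soil, weather=weather, season_cap=season_cap,
                label=label, weight=weight,
            )
        )
    return scenarios
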