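"""Readers and writers for the plain-text formats used across the pipeline.

Weather travels either as a DSSAT-style ``.WTH`` dialect or as CSV; soil
profiles as CSV/JSON records keyed by the standard hydraulic field names;
cultivar panels as CSV with the header
``name,group,P1,P5,P2R,PHINT,P2O,G1,G2,G3``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ideorice.crop_model import SoilProfile, WeatherSeries

__all__ = [
    "read_wth", "write_wth", "read_weather_csv", "write_weather_csv",
    "read_soil", "write_soil",
]

_WTH_COLUMNS = ["DATE", "SRAD", "TMAX", "TMIN", "RAIN", "RH", "WIND"]


def write_wth(series: WeatherSeries, path, station: str = "SYNT") -> None:
    """Write a DSSAT-dialect .WTH file (fixed header + whitespace columns)."""
    path = Path(path)
    n = len(series)
    doy = (series.start_doy - 1 + np.arange(n)) % 365 + 1
    year = 25 + (series.start_doy - 1 + np.arange(n)) // 365  # 2-digit year
    dates = year * 1000 + doy
    lines = [
        f"*WEATHER DATA : {station}",
        "",
        "@ INSI      LAT     LONG  ELEV   TAV   AMP REFHT WNDHT",
        f"  {station:<4} {series.latitude:8.3f} {-15.0:8.3f} {10:5d} {27.0:5.1f} {3.0:5.1f} {2.0:5.2f} {2.0:5.2f}",
        "@DATE  SRAD  TMAX  TMIN  RAIN    RH  WIND",
    ]
    for i in range(n):
        lines.append(
            f"{dates[i]:05d} {series.srad[i]:5.2f} {series.tmax[i]:5.2f} "
            f"{series.tmin[i]:5.2f} {series.rain[i]:5.2f} {series.rh[i]:5.2f} "
            f"{series.wind[i]:5.2f}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_wth(path, latitude: float | None = None) -> WeatherSeries:
    """Read the .WTH dialect written by :func:`write_wth`."""
    rows = []
    lat = latitude
    lat_pending = False
    header_cols: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("*"):
            continue
        if stripped.startswith("@"):
            cols = stripped[1:].split()
            if "DATE" in cols:
                header_cols = cols
                lat_pending = False
            else:
                lat_pending = "LAT" in cols
                if lat_pending:
                    _lat_index = cols.index("LAT")
            continue
        parts = stripped.split()
        if lat_pending and lat is None:
            lat = float(parts[_lat_index])
            lat_pending = False
            continue
        if lat_pending:
            lat_pending = False
            continue
        if header_cols is not None:
            rows.append([float(x) for x in parts[: len(header_cols)]])
    if not rows:
        raise ValueError(f"no weather records found in {path}")
    frame = pd.DataFrame(rows, columns=header_cols)
    start_doy = int(frame["DATE"].iloc[0]) % 1000
    return WeatherSeries(
        tmin=frame["TMIN"].to_numpy(),
        tmax=frame["TMAX"].to_numpy(),
        srad=frame["SRAD"].to_numpy(),
        rh=frame["RH"].to_numpy(),
        wind=frame["WIND"].to_numpy(),
        rain=frame["RAIN"].to_numpy(),
        latitude=lat if lat is not None else 12.5,
        start_doy=start_doy,
    )


def write_weather_csv(series: WeatherSeries, path) -> None:
    frame = pd.DataFrame(
        {
            "tmin": series.tmin,
            "tmax": series.tmax,
            "srad": series.srad,
            "rh": series.rh,
            "wind": series.wind,
            "rain": series.rain,
        }
    )
    if series.daylength is not None:
        frame["daylength"] = series.daylength
    frame.to_csv(path, index=False)


def read_weather_csv(path, latitude: float = 12.5, start_doy: int = 182) -> WeatherSeries:
    frame = pd.read_csv(path)
    daylength = frame["daylength"].to_numpy() if "daylength" in frame else None
    return WeatherSeries(
        tmin=frame["tmin"].to_numpy(),
        tmax=frame["tmax"].to_numpy(),
        srad=frame["srad"].to_numpy(),
        rh=frame["rh"].to_numpy(),
        wind=frame["wind"].to_numpy(),
        rain=frame["rain"].to_numpy(),
        daylength=daylength,
        latitude=latitude,
        start_doy=start_doy,
    )


_SOIL_FIELDS = [
    "depth", "SLLL", "SDUL", "SSAT", "SSKS", "sand", "silt", "clay",
    "SBDM", "SLOC", "SLNI", "SLHW", "SLCF", "label",
]


def write_soil(soil: SoilProfile, path) -> None:
    """Write a soil profile as JSON (.json) or one-row CSV (anything else)."""
    record = {f: getattr(soil, f) for f in _SOIL_FIELDS}
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(record, indent=2) + "\n")
    else:
        pd.DataFrame([record]).to_csv(path, index=False)


def read_soil(path) -> SoilProfile:
    path = Path(path)
    if path.suffix.lower() == ".json":
        record = json.loads(path.read_text())
    else:
        record = pd.read_csv(path).iloc[0].to_dict()
    kwargs = {f: record[f] for f in _SOIL_FIELDS if f in record}
    if "label" in kwargs:
        kwargs["label"] = str(kwargs["label"])
    return SoilProfile(**kwargs)
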