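"""CSV dialects for gas and liquid series.

Gas series: columns ``time_h, o2_pct, n2_pct, co_pct, co2_pct, h2_pct,
ar_pct, flow_l_h``; header required, UTF-8, decimal point.  Liquid
series: ``time_h`` plus one ``<species>_g_l`` column per measured
concentration (sugars, products, biomass dry weight).

``write_* o read_*`` is the identity on valid series at the declared
precision (10 significant digits).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gas import GAS_COLUMNS, GasStreamSeries

__all__ = ["LiquidSeries", "read_gas_series", "write_gas_series", "read_liquid_series", "write_liquid_series"]

_FLOAT_FMT = "%.10g"


@dataclass
class LiquidSeries:
    """Time-stamped liquid-phase concentrations in g/L."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        if "time_h" not in df.columns:
            raise ValueError("liquid series must contain a 'time_h' column")
        t = df["time_h"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        value_cols = [c for c in df.columns if c != "time_h"]
        if not value_cols:
            raise ValueError("liquid series has no concentration columns")
        if np.any(df[value_cols].to_numpy(float) < -1e-9):
            raise ValueError("concentrations must be nonnegative")
        self.data = df

    @property
    def time_h(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    def concentration(self, species: str) -> np.ndarray:
        return self.data[f"{species}_g_l"].to_numpy(float)

    @property
    def species(self) -> list[str]:
        return [c[: -len("_g_l")] for c in self.data.columns if c.endswith("_g_l")]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    try:
        return pd.read_csv(path, encoding="utf-8")
    except Exception as exc:  # re-raise with the offending file named
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc


def read_gas_series(path, temperature_c: float = 37.0, pressure_atm: float = 1.0) -> GasStreamSeries:
    df = _read_csv(path)
    missing = {"time_h", "flow_l_h", *GAS_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        return GasStreamSeries(df, temperature_c=temperature_c, pressure_atm=pressure_atm)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_gas_series(series: GasStreamSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["time_h", *GAS_COLUMNS, "flow_l_h"]
    series.data[cols].to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")
    return path


def read_liquid_series(path) -> LiquidSeries:
    df = _read_csv(path)
    try:
        return LiquidSeries(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_liquid_series(series: LiquidSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.data.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")
    return path
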