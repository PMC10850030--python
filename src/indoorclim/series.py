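"""Timestamped meteorological and indoor series containers.

Both containers wrap a :class:`pandas.DataFrame` indexed by UTC timestamps
with a fixed step of 1 or 3 hours. Columns use short lowercase names:

==========  =========================================  =========
column      meaning                                    unit
==========  =========================================  =========
``ta``      outdoor air temperature at 2 m             degC
``td``      dew point temperature at 2 m               degC
``v``       wind speed at 10 m                         m s-1
``p``       surface pressure                           hPa
``g``       global irradiance                          W m-2
``ag``      long-wave downwelling radiation            W m-2
``ti``      indoor air temperature                     degC
``rh``      indoor relative humidity                   %
``tg``      globe temperature                          degC
``vi``      indoor air speed                           m s-1
``pet``     indoor physiologically equivalent temp.    degC
==========  =========================================  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METEO_VARS = ("ta", "td", "v", "p", "g", "ag")
INDOOR_VARS = ("ti", "rh", "tg", "vi", "pet")

VALID_STEPS = (1, 3)


class SeriesValidationError(ValueError):
    """Raised when a series container violates its invariants."""


def _check_regular_index(index: pd.DatetimeIndex, step_hours: int, calendar: str) -> None:
    if not isinstance(index, pd.DatetimeIndex):
        raise SeriesValidationError("index must be a DatetimeIndex")
    if len(index) < 2:
        return
    if not index.is_monotonic_increasing or index.has_duplicates:
        raise SeriesValidationError("timestamps must be strictly increasing")
    deltas = np.diff(index.view("i8"))
    step_ns = step_hours * 3_600_000_000_000
    if calendar == "noleap":
        # Feb 29 removal leaves one 24 h + step gap per leap year.
        ok = (deltas == step_ns) | (deltas == step_ns + 24 * 3_600_000_000_000)
    else:
        ok = deltas == step_ns
    if not ok.all():
        raise SeriesValidationError(f"timestamps not regular at {step_hours} h step")


@dataclass
class MeteoSeries:
    """Regular outdoor meteorological series (the surrogate's input space)."""

    data: pd.DataFrame
    step_hours: int = 3
    calendar: str = "standard"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.step_hours not in VALID_STEPS:
            raise SeriesValidationError(f"step must be one of {VALID_STEPS} h")
        if self.calendar not in ("standard", "noleap"):
            raise SeriesValidationError("calendar must be 'standard' or 'noleap'")
        missing = [c for c in METEO_VARS if c not in self.data.columns]
        if missing:
            raise SeriesValidationError(f"missing variables: {missing}")
        _check_regular_index(self.data.index, self.step_hours, self.calendar)
        df = self.data
        if df[list(METEO_VARS)].isna().any().any():
            raise SeriesValidationError("missing values present")
        if (df["td"] > df["ta"] + 1e-9).any():
            raise SeriesValidationError("dew point exceeds air temperature")
        for var, low in (("g", 0.0), ("v", 0.0)):
            if (df[var] < low - 1e-12).any():
                raise SeriesValidationError(f"{var} below {low}")
        if (df["p"] <= 0).any() or (df["ag"] <= 0).any():
            raise SeriesValidationError("p and ag must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    def copy(self) -> "MeteoSeries":
        return MeteoSeries(self.data.copy(), self.step_hours, self.calendar)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%SZ"))
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, step_hours: int = 3, calendar: str = "standard") -> "MeteoSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        df = df.set_index("timestamp")
        df.index = pd.DatetimeIndex(df.index).tz_localize(None)
        df.index.name = None
        return cls(df, step_hours, calendar)


@dataclass
class IndoorSeries:
    """Indoor observations/predictions aligned to a driving MeteoSeries."""

    data: pd.DataFrame
    step_hours: int = 3
    calendar: str = "standard"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.step_hours not in VALID_STEPS:
            raise SeriesValidationError(f"step must be one of {VALID_STEPS} h")
        required = ("ti", "rh", "tg")
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise SeriesValidationError(f"missing variables: {missing}")
        _check_regular_index(self.data.index, self.step_hours, self.calendar)
        df = self.data
        if df[list(required)].isna().any().any():
            raise SeriesValidationError("missing values present")
        if ((df["rh"] < 0) | (df["rh"] > 100)).any():
            raise SeriesValidationError("rh outside [0, 100]")
        if "vi" in df.columns and (df["vi"] < 0).any():
            raise SeriesValidationError("vi must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    def copy(self) -> "IndoorSeries":
        return IndoorSeries(self.data.copy(), self.step_hours, self.calendar)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%SZ"))
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, step_hours: int = 3, calendar: str = "standard") -> "IndoorSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        df = df.set_index("timestamp")
        df.index = pd.DatetimeIndex(df.index).tz_localize(None)
        df.index.name = None
        return cls(df, step_hours, calendar)
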