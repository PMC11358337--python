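"""24 h-periodic environmental forcing for a subaerial biofilm (SAB).

A forcing is a table of (t, T_a, T_s, RH_a, I) samples over one day:
air temperature, stone temperature, air relative humidity (fraction) and
photosynthetically active light intensity.  It is sampled at arbitrary
simulation times by piecewise-linear interpolation with periodic wrap, so
a measured day that is not exactly periodic keeps its wrap-point jump.

Forcings come either from a CSV table or from a synthetic diel generator
with seasonal presets.  The generator is a stand-in for measured profiles:
air temperature is sinusoidal, light is a half-sine between sunrise and
sunset, stone temperature leads air temperature during insolation and lags
it at night, and humidity follows a fixed dewpoint through the Magnus
saturation-pressure curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .microclimate import magnus_saturation_pressure

PERIOD_H = 24.0

FORCING_COLUMNS = ["time_h", "T_air_C", "T_stone_C", "RH_air", "light_uE"]


@dataclass(frozen=True)
class EnvSample:
    """Environmental conditions at one instant."""

    t: float          # time of day [h]
    T_a: float        # air temperature [degC]
    T_s: float        # stone temperature [degC]
    RH_a: float       # air relative humidity [fraction, 0-1]
    I: float          # light intensity [uE m-2 s-1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.RH_a <= 1.0:
            raise ValueError(f"RH_a must be in [0, 1], got {self.RH_a}")
        if self.I < 0.0:
            raise ValueError(f"light intensity must be >= 0, got {self.I}")


@dataclass(frozen=True)
class SeasonPreset:
    """Shape parameters of the synthetic diel generator.

    Defaults (see :data:`SEASON_PRESETS`) are chosen so that mean daily
    water activity increases from the warmest to the coldest season while
    summer/spring show the strong midday drop typical of insolated stone.
    """

    name: str
    T_a_min: float            # pre-dawn air temperature [degC]
    T_a_max: float            # mid-afternoon air temperature [degC]
    dewpoint: float           # constant dewpoint [degC]
    I_max: float              # midday peak light [uE m-2 s-1]
    sunrise: float = 6.0      # [h]
    sunset: float = 20.0      # [h]
    stone_day_offset: float = 10.0    # stone above air at peak light [degC]
    stone_night_offset: float = 3.0   # stone below air at night [degC]

    def __post_init__(self) -> None:
        if self.T_a_min > self.T_a_max:
            raise ValueError("T_a_min must be <= T_a_max")
        if not 0.0 <= self.sunrise < self.sunset <= 24.0:
            raise ValueError("require 0 <= sunrise < sunset <= 24")
        if self.I_max < 0.0:
            raise ValueError("I_max must be >= 0")


#: Default seasonal presets.  Values are generator defaults, not claims about
#: any particular site; their ordering yields higher water activity in the
#: colder seasons.
SEASON_PRESETS: dict[str, SeasonPreset] = {
    "summer": SeasonPreset("summer", 20.0, 33.0, dewpoint=15.0, I_max=2000.0,
                           stone_day_offset=10.0, stone_night_offset=3.0),
    "spring": SeasonPreset("spring", 10.0, 24.0, dewpoint=7.0, I_max=1600.0,
                           sunrise=6.5, sunset=19.5,
                           stone_day_offset=8.0, stone_night_offset=3.0),
    "autumn": SeasonPreset("autumn", 8.0, 18.0, dewpoint=10.0, I_max=1000.0,
                           sunrise=7.0, sunset=18.5,
                           stone_day_offset=5.0, stone_night_offset=2.5),
    "winter": SeasonPreset("winter", 0.0, 8.0, dewpoint=6.0, I_max=700.0,
                           sunrise=7.5, sunset=17.0,
                           stone_day_offset=4.0, stone_night_offset=2.0),
}


@dataclass
class EnvironmentalForcing:
    """One 24 h-periodic forcing table.

    ``times`` are strictly increasing within [0, 24); sampling interpolates
    linearly with periodic wrap between the last and first sample.
    """

    times: np.ndarray     # [h], strictly increasing in [0, 24)
    T_a: np.ndarray       # [degC]
    T_s: np.ndarray       # [degC]
    RH_a: np.ndarray      # [fraction]
    I: np.ndarray         # [uE m-2 s-1]
    period: float = field(default=PERIOD_H)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("T_a", "T_s", "RH_a", "I"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} length does not match times")
            setattr(self, name, arr)
        if self.period != PERIOD_H:
            raise ValueError("period must be exactly 24 h")
        if self.times.size < 4:
            raise ValueError("need at least 4 samples per day")
        if np.any(self.times < 0.0) or np.any(self.times >= PERIOD_H):
            raise ValueError("sample times must lie in [0, 24)")
        if np.any(np.diff(self.times) <= 0.0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.RH_a < 0.0) or np.any(self.RH_a > 1.0):
            raise ValueError("RH_a must be within [0, 1]")
        if np.any(self.I < 0.0):
            raise ValueError("light intensity must be >= 0")
        # Pre-extend one wrap sample on each side for fast interpolation.
        self._tx = np.concatenate(
            ([self.times[-1] - PERIOD_H], self.times, [self.times[0] + PERIOD_H])
        )
        self._vx = {
            name: np.concatenate(([getattr(self, name)[-1]],
                                  getattr(self, name),
                                  [getattr(self, name)[0]]))
            for name in ("T_a", "T_s", "RH_a", "I")
        }

    def _interp(self, name: str, t: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(t, PERIOD_H), self._tx, self._vx[name])

    def sample_arrays(self, t) -> dict[str, np.ndarray]:
        """Vectorized sampling; returns arrays keyed by field name."""
        t = np.asarray(t, dtype=float)
        return {name: self._interp(name, t) for name in ("T_a", "T_s", "RH_a", "I")}

    def sample_tuple(self, t: float) -> tuple[float, float, float, float]:
        """Scalar fast path: (T_a, T_s, RH_a, I) at time t [h]."""
        tm = t % PERIOD_H
        tx = self._tx
        return (float(np.interp(tm, tx, self._vx["T_a"])),
                float(np.interp(tm, tx, self._vx["T_s"])),
                float(np.interp(tm, tx, self._vx["RH_a"])),
                float(np.interp(tm, tx, self._vx["I"])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times, "T_air_C": self.T_a, "T_stone_C": self.T_s,
            "RH_air": self.RH_a, "light_uE": self.I,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_forcing(forcing: EnvironmentalForcing, t: float) -> EnvSample:
    """Sample the forcing at simulation time ``t`` [h] (periodic in 24 h)."""
    if t < 0.0:
        raise ValueError("t must be >= 0")
    v = forcing.sample_arrays(t)
    return EnvSample(t=float(np.mod(t, PERIOD_H)),
                     T_a=float(v["T_a"]), T_s=float(v["T_s"]),
                     RH_a=float(np.clip(v["RH_a"], 0.0, 1.0)),
                     I=float(max(v["I"], 0.0)))


def make_diel_forcing(preset: SeasonPreset,
                      resolution_h: float = 0.25) -> EnvironmentalForcing:
    """Generate a synthetic diel forcing from a seasonal preset.

    Air temperature is sinusoidal with its minimum just before dawn (05:00)
    and maximum in late afternoon (17:00), the phase typical of insolated
    stone; light is a half-sine over the daylight window; stone temperature
    blends smoothly between ``T_a - stone_night_offset`` at night and
    ``T_a + stone_day_offset`` at peak light; relative humidity follows the
    preset dewpoint, clipped to [0, 1].
    """
    if resolution_h <= 0.0:
        raise ValueError("resolution must be positive")
    t = np.arange(0.0, PERIOD_H, resolution_h)

    mid = 0.5 * (preset.T_a_min + preset.T_a_max)
    amp = 0.5 * (preset.T_a_max - preset.T_a_min)
    T_a = mid + amp * np.sin(2.0 * np.pi * (t - 11.0) / PERIOD_H)

    daylight = (t >= preset.sunrise) & (t <= preset.sunset)
    I = np.zeros_like(t)
    I[daylight] = preset.I_max * np.sin(
        np.pi * (t[daylight] - preset.sunrise) / (preset.sunset - preset.sunrise)
    )
    I = np.clip(I, 0.0, None)

    # fractional insolation drives the day/night stone offset blend
    s = I / preset.I_max if preset.I_max > 0.0 else np.zeros_like(t)
    T_s = T_a + preset.stone_day_offset * s - preset.stone_night_offset * (1.0 - s)

    RH_a = magnus_saturation_pressure(preset.dewpoint) / magnus_saturation_pressure(T_a)
    RH_a = np.clip(RH_a, 0.0, 1.0)

    return EnvironmentalForcing(times=t, T_a=T_a, T_s=T_s, RH_a=RH_a, I=I)


def read_forcing_table(source) -> EnvironmentalForcing:
    """Read a forcing from a CSV table.

    Requires columns ``time_h, T_air_C, T_stone_C, RH_air, light_uE``.
    Humidity is accepted as fraction or percent (any value > 1.5 implies
    percent); times are normalized into [0, 24) and must be distinct.
    """
    df = pd.read_csv(source)
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forcing table missing columns: {missing}")
    t = np.mod(df["time_h"].to_numpy(dtype=float), PERIOD_H)
    order = np.argsort(t, kind="stable")
    t = t[order]
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("forcing table has duplicate or non-distinct times")
    rh = df["RH_air"].to_numpy(dtype=float)[order]
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise ValueError("RH_air must lie within [0, 100]")
    if np.any(rh > 1.5):
        rh = rh / 100.0
    return EnvironmentalForcing(
        times=t,
        T_a=df["T_air_C"].to_numpy(dtype=float)[order],
        T_s=df["T_stone_C"].to_numpy(dtype=float)[order],
        RH_a=np.clip(rh, 0.0, 1.0),
        I=df["light_uE"].to_numpy(dtype=float)[order],
    )


def get_preset(name: str, **overrides) -> SeasonPreset:
    """Look up a named preset, optionally overriding shape parameters."""
    try:
        preset = SEASON_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown season preset {name!r}; choose from {sorted(SEASON_PRESETS)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset
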