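"""Biofilm-air interface temperature and SAB water activity.

The SAB is a thin (tens of microns) biofilm-water layer on stone, below a
thermal boundary layer of air.  With 1-D steady diffusive heat transport,
the interface temperature T* is a flux-matching weighted mean of air and
stone temperatures.  Water activity then follows from vapor-pressure
equilibrium with ambient air:

    a_w = RH_a * e_sat(T_a) / e_sat(T*)

with the Magnus form e_sat(T) ∝ exp(b*T/(c+T)).  Both quantities are
evaluated quasi-statically: evaporation/condensation and heat transport are
assumed fast relative to biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Magnus reference pressure [hPa]; only ratios of e_sat matter here.
_E0_HPA = 6.112


def magnus_saturation_pressure(T_C, b: float = 17.62, c: float = 243.12):
    """Saturation vapor pressure over liquid water [hPa], Magnus form.

    Valid for ordinary ambient temperatures; diverges at T -> -c.
    """
    T_C = np.asarray(T_C, dtype=float)
    if np.any(T_C <= -c):
        raise ValueError(f"temperature at or below Magnus singularity -{c} degC")
    out = _E0_HPA * np.exp(b * T_C / (c + T_C))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MicroclimateParams:
    """Geometry and transport parameters of the SAB-air heat balance.

    ``k_a``/``k_b`` are effective thermal transport coefficients of air and
    biofilm; only their ratio (together with the thickness ratio) enters T*.
    """

    b: float = 17.62            # Magnus coefficient [-]
    c: float = 243.12           # Magnus coefficient [degC]
    lambda_m: float = 15e-6     # SAB thickness [m]
    delta_m: float = 1e-3       # thermal boundary-layer thickness [m]
    k_a: float = 0.026          # air transport coefficient [W m-1 K-1]
    k_b: float = 0.6            # SAB transport coefficient [W m-1 K-1]

    def __post_init__(self) -> None:
        if self.lambda_m <= 0 or self.delta_m <= 0:
            raise ValueError("thicknesses must be positive")
        if self.k_a <= 0 or self.k_b <= 0:
            raise ValueError("transport coefficients must be positive")
        if self.c <= 0:
            raise ValueError("Magnus coefficient c must be positive")


def interface_temperature(T_a, T_s, p: MicroclimateParams = MicroclimateParams()):
    """Steady-state biofilm-air interface temperature [degC].

    Convex combination of T_a and T_s; with a micron-scale film under a
    millimetre-scale boundary layer the stone temperature dominates.
    """
    w_a = p.k_a * p.lambda_m
    w_s = p.k_b * p.delta_m
    T_a = np.asarray(T_a, dtype=float)
    T_s = np.asarray(T_s, dtype=float)
    out = (T_a * w_a + T_s * w_s) / (w_a + w_s)
    return out if out.ndim else float(out)


def water_activity(RH_a, T_a, T_star, p: MicroclimateParams = MicroclimateParams()):
    """SAB water activity from ambient humidity and interface temperature.

    a_w = RH_a * exp(b*T_a/(c+T_a)) * exp(-b*T*/(c+T*)), clipped to [0, 1].
    Equals RH_a when the interface is at air temperature; a warmer interface
    (insolated stone) lowers a_w below ambient humidity.
    """
    RH_a = np.asarray(RH_a, dtype=float)
    if np.any(RH_a < 0.0) or np.any(RH_a > 1.0):
        raise ValueError("RH_a must be within [0, 1]")
    ratio = (magnus_saturation_pressure(T_a, p.b, p.c)
             / magnus_saturation_pressure(T_star, p.b, p.c))
    out = np.clip(RH_a * ratio, 0.0, 1.0)
    return out if out.ndim else float(out)


def aw_profile(forcing, p: MicroclimateParams = MicroclimateParams(),
               grid_h: float = 0.1):
    """Pointwise (t, T*, a_w) series over one period on a regular grid.

    Returns arrays ``(t, T_star, a_w)``; composition of
    :func:`interface_temperature` and :func:`water_activity`.
    """
    if grid_h <= 0.0:
        raise ValueError("grid step must be positive")
    t = np.arange(0.0, 24.0, grid_h)
    v = forcing.sample_arrays(t)
    T_star = interface_temperature(v["T_a"], v["T_s"], p)
    a_w = water_activity(np.clip(v["RH_a"], 0.0, 1.0), v["T_a"], T_star, p)
    return t, T_star, a_w
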