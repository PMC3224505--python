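"""Chemostat washout kinetics for an impulse of the limiting nutrient.

A chemostat exchanges broth at dilution rate ``D`` (h^-1), so an
instantaneously injected nutrient that is not consumed washes out by
first-order dilution:

    dC/dt = -D * (C - C_base),   C(0) = C_base + delta_C0

with the closed form ``C(t) = C_base + delta_C0 * exp(-D t)``.  Cellular
uptake is deliberately excluded, so the curve is an upper bound on the real
residual concentration; the model is used to set the sampling horizon and to
time-stamp synthetic responses.
"""

from __future__ import annotations

import numpy as np

from .types import PulseModel

__all__ = [
    "washout_concentration",
    "impulse_dose",
    "residence_times_to_hours",
    "GLUCOSE_PULSE",
    "AMMONIUM_PULSE",
]


def washout_concentration(model: PulseModel, t):
    """Limiting-nutrient concentration (% w/v) ``t`` hours after the impulse.

    Accepts a scalar or array of non-negative times and evaluates the
    washout closed form ``C_base + delta_C0 * exp(-D t)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since impulse must be non-negative")
    c = model.C_base + model.delta_C0 * np.exp(-model.D * t)
    return float(c) if c.ndim == 0 else c


def impulse_dose(stock_conc: float, v_inj: float, V: float) -> float:
    """Concentration increment (% w/v) from injecting ``v_inj`` L of stock
    at ``stock_conc`` % w/v into a working volume of ``V`` L."""
    if stock_conc <= 0 or v_inj <= 0 or V <= 0:
        raise ValueError("stock_conc, v_inj and V must all be positive")
    if v_inj > V:
        raise ValueError("injected volume cannot exceed the working volume")
    return stock_conc * v_inj / V


def residence_times_to_hours(n: float, D: float) -> float:
    """Duration in hours of ``n`` chemostat residence times at dilution
    rate ``D`` (h^-1); one residence time is 1/D."""
    if n <= 0:
        raise ValueError("number of residence times must be positive")
    if D <= 0:
        raise ValueError("dilution rate must be positive")
    return n / D


# The two dosing schemes of the study conditions: 50 mL of 40% w/v glucose or
# of 6.26% w/v ammonium sulphate into a 1 L working volume at D = 0.1 h^-1.
GLUCOSE_PULSE = PulseModel(D=0.1, V=1.0, v_inj=0.05, stock_conc=40.0)
AMMONIUM_PULSE = PulseModel(D=0.1, V=1.0, v_inj=0.05, stock_conc=6.26)
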