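"""Redox-potential corrections and dissolved-oxygen unit conversions.

Field Eh measurements (mV vs SHE) taken at different pH are made comparable
by correcting to pH 7 along the theoretical Nernst slope:

    Eh7 = Eh + (dEh/dpH) * (7 - pH),    dEh/dpH = -ln(10)*R*T/F

which is -59.16 mV per pH unit at 25 degC.  Oxygen concentrations arrive in
mg/L, uM, or percent air saturation; everything is normalized to uM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "R_GAS",
    "FARADAY",
    "LN10",
    "O2_MOLAR_MASS",
    "EhConditions",
    "nernst_slope",
    "eh_to_eh7",
    "o2_mg_per_L_to_uM",
    "o2_percent_sat_to_uM",
    "o2_to_uM",
    "BensonKrause1984",
]

R_GAS = 8.31446          # J mol-1 K-1
FARADAY = 96485.33       # C mol-1
LN10 = math.log(10.0)
ABS_ZERO_C = -273.15
O2_MOLAR_MASS = 31.9988  # g/mol


@dataclass(frozen=True)
class EhConditions:
    """A redox measurement: Eh in mV vs SHE with the pH and temperature at
    which it was taken.  Missing pH or T default to 7 and 25 degC."""

    eh_mV: float
    pH: float = 7.0
    T_C: float = 25.0

    def __post_init__(self) -> None:
        if self.T_C <= ABS_ZERO_C:
            raise ValueError(f"nonphysical temperature {self.T_C} degC")
        if not 0.0 <= self.pH <= 14.0:
            warnings.warn(f"pH {self.pH} outside [0, 14]", stacklevel=2)

    @property
    def eh7_mV(self) -> float:
        return eh_to_eh7(self.eh_mV, self.pH, self.T_C)


def nernst_slope(T_C: float = 25.0) -> float:
    """Theoretical dEh/dpH in mV per pH unit: -ln(10)*R*T/F.

    Negative; -59.16 mV/pH at 25 degC, steeper (more negative) when hotter.
    """
    if T_C <= ABS_ZERO_C:
        raise ValueError(f"nonphysical temperature {T_C} degC")
    T_K = T_C - ABS_ZERO_C
    return -LN10 * R_GAS * T_K / FARADAY * 1000.0


def eh_to_eh7(eh_mV: float, pH: float | None = None, T_C: float | None = None) -> float:
    """Correct a measured Eh (mV vs SHE) to pH 7.

    ``Eh7 = Eh + nernst_slope(T) * (7 - pH)``.  Missing pH or temperature
    are taken as 7 and 25 degC, making the correction the identity.
    """
    if pH is None:
        pH = 7.0
    if T_C is None:
        T_C = 25.0
    return eh_mV + nernst_slope(T_C) * (7.0 - pH)


def eh7_to_eh(eh7_mV: float, pH: float, T_C: float = 25.0) -> float:
    """Inverse of :func:`eh_to_eh7`: the Eh that would be measured at ``pH``."""
    return eh7_mV - nernst_slope(T_C) * (7.0 - pH)


def o2_mg_per_L_to_uM(x_mg_L: float) -> float:
    """mg/L O2 -> umol/L using the molar mass of O2 (31.9988 g/mol)."""
    if x_mg_L < 0:
        raise ValueError("O2 concentration cannot be negative")
    return x_mg_L * 1000.0 / O2_MOLAR_MASS


class BensonKrause1984:
    """Air-saturated dissolved-oxygen concentration vs temperature.

    Benson & Krause (1984) correlation for equilibrium with water-saturated
    air at 1 atm (O2 partial pressure ~0.2095 atm at sea level), the basis of
    the standard USGS solubility tables.  Valid 0-40 degC.  Swappable: any
    object with ``saturation_uM(T_C)`` works in :func:`o2_percent_sat_to_uM`.
    """

    T_MIN_C = 0.0
    T_MAX_C = 40.0

    def saturation_mg_L(self, T_C: float) -> float:
        if not self.T_MIN_C <= T_C <= self.T_MAX_C:
            raise ValueError(
                f"temperature {T_C} degC outside correlation validity "
                f"[{self.T_MIN_C}, {self.T_MAX_C}]"
            )
        T = T_C - ABS_ZERO_C
        ln_do = (
            -139.34411
            + 1.575701e5 / T
            - 6.642308e7 / T**2
            + 1.243800e10 / T**3
            - 8.621949e11 / T**4
        )
        return math.exp(ln_do)

    def saturation_uM(self, T_C: float) -> float:
        return o2_mg_per_L_to_uM(self.saturation_mg_L(T_C))


_DEFAULT_SAT_MODEL = BensonKrause1984()


def o2_percent_sat_to_uM(
    pct: float, T_C: float = 25.0, model: BensonKrause1984 | None = None
) -> float:
    """Percent air saturation -> umol/L via a saturation-concentration model."""
    if pct < 0:
        raise ValueError("percent saturation cannot be negative")
    model = model or _DEFAULT_SAT_MODEL
    return model.saturation_uM(T_C) * pct / 100.0


def o2_to_uM(value: float, unit: str, T_C: float = 25.0) -> float:
    """Normalize an O2 concentration to uM.  ``unit`` is mg_L, uM or pct_sat.

    Values reported as zero or below detection are passed through as 0.
    """
    if unit == "uM":
        if value < 0:
            raise ValueError("O2 concentration cannot be negative")
        return value
    if unit == "mg_L":
        return o2_mg_per_L_to_uM(value)
    if unit == "pct_sat":
        return o2_percent_sat_to_uM(value, T_C)
    raise ValueError(f"unknown O2 unit {unit!r}")
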