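"""Heat stress index (HSI) from air temperature and relative humidity.

The HSI is the US National Weather Service heat index expressed in degrees
Celsius: Steadman's simple apparent-temperature formula below the 80 degF
threshold, the nine-term Rothfusz regression above it, with the NWS
low-humidity (RH < 13 %, 80-112 degF) and high-humidity (RH > 85 %,
80-87 degF) adjustment terms.

Two evaluation modes are provided.  ``nws`` (default) computes the standard
NWS index internally in Fahrenheit and converts the result to Celsius; its
Celsius temperature thresholds 26.7 / 30.5 / 44.5 degC are exactly
80 / 87 / 112 degF.  ``paper_literal`` evaluates the same piecewise formulas
verbatim with Celsius inputs and no unit conversion, for auditability of
sources that print the equations on the Celsius scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["Branch", "HSIValue", "heat_index_point", "heat_index_series"]


class Branch(str, Enum):
    SIMPLE = "simple"
    ROTHFUSZ = "rothfusz"
    ROTHFUSZ_DRY_ADJ = "rothfusz_dry_adj"
    ROTHFUSZ_HUMID_ADJ = "rothfusz_humid_adj"


@dataclass(frozen=True)
class HSIValue:
    """A single heat-index evaluation: value in degC and the formula branch."""

    hsi: float
    branch: Branch


# Rothfusz regression coefficients (Fahrenheit scale).
_ROTHFUSZ = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)

# Branch windows on the Celsius input temperature (inclusive).
_T_LO_C, _T_DRY_HI_C, _T_HUMID_HI_C = 26.7, 44.5, 30.5


def _rothfusz(t, rh):
    c0, c1, c2, c3, c4, c5, c6, c7, c8 = _ROTHFUSZ
    return (
        c0
        + c1 * t
        + c2 * rh
        + c3 * t * rh
        + c4 * t * t
        + c5 * rh * rh
        + c6 * t * t * rh
        + c7 * t * rh * rh
        + c8 * t * t * rh * rh
    )


def _simple(t, rh):
    # Steadman simple formula; with t in degC this evaluates on the
    # Fahrenheit scale (identical to 1.1*T_F - 10.3 + 0.047*RH).
    return 1.98 * t + 24.9 + 0.047 * rh


def _dry_adj(t_c, rh):
    # ((13-RH)/4) * sqrt(1 - |9T-315|/85), T in degC; the NWS term
    # ((17-|T_F-95|)/17)^(1/2) after T_F = 1.8T+32 substitution.
    return (13.0 - rh) / 4.0 * np.sqrt(np.clip(1.0 - np.abs(9.0 * t_c - 315.0) / 85.0, 0.0, None))


def _humid_adj(t_c, rh):
    # ((RH-85)/10) * ((275-9T)/25), T in degC; equals ((RH-85)/10)*((87-T_F)/5).
    return (rh - 85.0) / 10.0 * (275.0 - 9.0 * t_c) / 25.0


def _evaluate(t_c, rh, mode):
    """Vectorized piecewise HSI.  Returns (hsi degC, branch code array)."""
    t_c = np.asarray(t_c, dtype=float)
    rh = np.asarray(rh, dtype=float)
    t_c, rh = np.broadcast_arrays(t_c, rh)

    if mode == "nws":
        t_eval = 1.8 * t_c + 32.0  # Rothfusz argument in degF
        simple_val = _simple(t_c, rh)  # already on the degF scale
        threshold = 80.0
    elif mode == "paper_literal":
        t_eval = t_c
        simple_val = _simple(t_c, rh)
        threshold = 26.7
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'nws' or 'paper_literal'")

    hsi = _rothfusz(t_eval, rh)
    branch = np.full(t_c.shape, Branch.ROTHFUSZ.value, dtype=object)

    dry = (rh < 13.0) & (t_c >= _T_LO_C) & (t_c <= _T_DRY_HI_C)
    humid = (rh > 85.0) & (t_c >= _T_LO_C) & (t_c <= _T_HUMID_HI_C)
    hsi = np.where(dry, hsi - _dry_adj(t_c, rh), hsi)
    hsi = np.where(humid, hsi + _humid_adj(t_c, rh), hsi)
    branch[dry] = Branch.ROTHFUSZ_DRY_ADJ.value
    branch[humid] = Branch.ROTHFUSZ_HUMID_ADJ.value

    use_simple = simple_val < threshold
    hsi = np.where(use_simple, simple_val, hsi)
    branch[use_simple] = Branch.SIMPLE.value

    if mode == "nws":
        hsi = (hsi - 32.0) / 1.8  # degF -> degC

    hsi = np.where(np.isnan(t_c) | np.isnan(rh), np.nan, hsi)
    return hsi, branch


def heat_index_point(t: float, rh: float, mode: str = "nws") -> HSIValue:
    """Heat index for one (temperature degC, relative humidity %) pair.

    Raises ``ValueError`` on non-finite input or RH outside [0, 100].
    """
    if not np.isfinite(t) or not np.isfinite(rh):
        raise ValueError("temperature and humidity must be finite")
    if not 0.0 <= rh <= 100.0:
        raise ValueError(f"relative humidity {rh} outside [0, 100] %")
    hsi, branch = _evaluate(np.array([t]), np.array([rh]), mode)
    return HSIValue(hsi=float(hsi[0]), branch=Branch(branch[0]))


def heat_index_series(t, rh, mode: str = "nws") -> np.ndarray:
    """Elementwise heat index (degC) for arrays of T (degC) and RH (%).

    NaN inputs propagate to NaN output; validation rejects finite RH outside
    [0, 100].
    """
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if t.shape != rh.shape:
        raise ValueError(f"shape mismatch: t {t.shape} vs rh {rh.shape}")
    finite_rh = rh[np.isfinite(rh)]
    if finite_rh.size and (finite_rh.min() < 0.0 or finite_rh.max() > 100.0):
        raise ValueError("relative humidity outside [0, 100] %")
    hsi, _ = _evaluate(t, rh, mode)
    return hsi
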