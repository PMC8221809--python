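"""Fluorometry: % NADH reduction and TMRM-ratio membrane potential.

% Reduction = (F - F0) / (F100 - F0) * 100 with the 0% anchor set before
substrate addition and the 100% anchor after cyanide.  Membrane potential is
the 576/590-over-551/590 excitation ratio mapped to millivolts through a
KCl/valinomycin calibration whose anchor points are converted by the Nernst
equation (inside-negative convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .respirometry import EventMark

__all__ = [
    "FluorescenceTrace",
    "PotentialCalibration",
    "FluorometryError",
    "percent_reduction",
    "tmrm_ratio",
    "nernst_mv",
    "build_calibration",
    "calibrate_and_apply",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT_J = 8.31446261815324  # J/mol/K

CH_576 = "576/590"
CH_551 = "551/590"
CH_NADH = "350/450"


class FluorometryError(ValueError):
    pass


@dataclass
class FluorescenceTrace:
    time: np.ndarray
    channels: dict[str, np.ndarray]
    events: list[EventMark] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, ch in self.channels.items():
            if ch.size != self.time.size:
                raise FluorometryError(f"channel {name!r} length mismatch")
            if not np.all(np.isfinite(ch)):
                raise FluorometryError(f"channel {name!r} has non-finite intensities")


def percent_reduction(f, f0: float, f100: float):
    """(F - F0)/(F100 - F0) * 100; values outside [0, 100] are allowed."""
    if f100 == f0:
        raise FluorometryError("f100 == f0: anchors do not span a range")
    return (np.asarray(f, dtype=float) - f0) / (f100 - f0) * 100.0


def tmrm_ratio(
    trace: FluorescenceTrace, numerator: str = CH_576, denominator: str = CH_551
) -> np.ndarray:
    """Pointwise excitation ratio; zero-denominator samples become NaN."""
    for name in (numerator, denominator):
        if name not in trace.channels:
            raise FluorometryError(f"channel {name!r} missing from trace")
    num = trace.channels[numerator]
    den = trace.channels[denominator]
    out = np.full_like(num, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} zero-denominator samples flagged as NaN",
            stacklevel=2,
        )
    return out


def nernst_mv(k_out: float, k_in: float, temperature: float = 310.15) -> float:
    """Potassium equilibrium potential, mV, inside-negative convention."""
    if k_out <= 0 or k_in <= 0:
        raise FluorometryError("potassium concentrations must be > 0")
    return -(GAS_CONSTANT_J * temperature / FARADAY) * np.log(k_in / k_out) * 1e3


@dataclass
class PotentialCalibration:
    """Monotone ratio -> mV map anchored on Nernst KCl points."""

    k_in: float
    temperature: float
    points: list[tuple[float, float, float]]  # (k_out, ratio, mv)
    _ratios: np.ndarray = field(init=False, repr=False)
    _mvs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise FluorometryError("calibration needs >= 2 points")
        ratios = np.array([p[1] for p in self.points], dtype=float)
        mvs = np.array([p[2] for p in self.points], dtype=float)
        order = np.argsort(ratios)
        ratios, mvs = ratios[order], mvs[order]
        if np.any(np.diff(ratios) <= 0):
            raise FluorometryError("calibration ratios must be strictly monotone")
        dmv = np.diff(mvs)
        if not (np.all(dmv > 0) or np.all(dmv < 0)):
            raise FluorometryError("calibration mV must be monotone in ratio")
        self._ratios, self._mvs = ratios, mvs

    def apply(self, ratios) -> np.ndarray:
        """Piecewise-linear interpolation; out-of-span ratios extrapolate."""
        r = np.asarray(ratios, dtype=float)
        out = np.interp(r, self._ratios, self._mvs)
        below = r < self._ratios[0]
        above = r > self._ratios[-1]
        if np.any(below) or np.any(above):
            warnings.warn(
                "ratios outside the calibration span; linearly extrapolated",
                stacklevel=2,
            )
            s_lo = (self._mvs[1] - self._mvs[0]) / (self._ratios[1] - self._ratios[0])
            s_hi = (self._mvs[-1] - self._mvs[-2]) / (self._ratios[-1] - self._ratios[-2])
            out = np.where(below, self._mvs[0] + s_lo * (r - self._ratios[0]), out)
            out = np.where(above, self._mvs[-1] + s_hi * (r - self._ratios[-1]), out)
        return out

    def forward(self, mvs) -> np.ndarray:
        """Inverse map mV -> ratio (used by simulations and round-trip tests)."""
        m = np.asarray(mvs, dtype=float)
        x, y = self._mvs, self._ratios
        if x[0] > x[-1]:
            x, y = x[::-1], y[::-1]
        return np.interp(m, x, y)


def build_calibration(
    points: Sequence[tuple[float, float]],
    k_in: float = 0.120,
    temperature: float = 310.15,
) -> PotentialCalibration:
    """Build a ratio -> mV calibration from (k_out mol/L, ratio) anchors."""
    full = [(k, r, nernst_mv(k, k_in, temperature)) for k, r in points]
    return PotentialCalibration(k_in=k_in, temperature=temperature, points=full)


def calibrate_and_apply(
    ratios,
    points: Sequence[tuple[float, float]],
    k_in: float = 0.120,
    temperature: float = 310.15,
) -> np.ndarray:
    """Convert a TMRM ratio series to mV via a KCl/valinomycin standard curve."""
    return build_calibration(points, k_in=k_in, temperature=temperature).apply(ratios)
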