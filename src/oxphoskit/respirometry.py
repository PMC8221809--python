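"""Chamber respirometry: O2 traces -> oxygen flux -> steady-state rates.

Flux follows the consumption-positive convention:
JO2(t) = -d[O2]/dt * chamber volume, in pmol O2/s for [O2] in umol/L and
volume in mL.  Steady states are windowed means of the flux between event
marks; short or noisy windows are flagged, never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sample",
    "OxygenTrace",
    "EventMark",
    "SteadyState",
    "WindowPolicy",
    "NormalizationBasis",
    "NormalizedRate",
    "TraceError",
    "FitError",
    "compute_flux",
    "extract_steady_states",
    "correct_nonmito",
    "normalize",
    "fccp_km",
    "read_trace_csv",
    "read_events_csv",
    "states_to_frame",
]


class TraceError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class Sample:
    label: str = ""
    cell_count_millions: float | None = None
    protein_mg: float | None = None


@dataclass
class OxygenTrace:
    """Time-stamped chamber O2 concentration series.

    time in seconds (strictly increasing), o2 in umol/L, chamber volume in mL.
    """

    time: np.ndarray
    o2: np.ndarray
    chamber_volume_ml: float
    sample: Sample = field(default_factory=Sample)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.time.size < 2:
            raise TraceError("trace needs at least 2 samples")
        if self.time.size != self.o2.size:
            raise TraceError("time and o2 must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise TraceError("time must be strictly increasing")
        if np.any(self.o2 < 0):
            raise TraceError("o2 must be >= 0")
        if self.chamber_volume_ml <= 0:
            raise TraceError("chamber_volume_ml must be > 0")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


@dataclass(frozen=True)
class EventMark:
    time: float
    label: str
    reagent_conc: str | None = None


@dataclass
class SteadyState:
    label: str
    jo2: float  # pmol O2/s, chamber total
    window: tuple[float, float]
    cv: float
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class WindowPolicy:
    """Post-event lag, window length and auto-accept CV for plateau means.

    ``guard_s`` keeps the window clear of the next event so smoothed flux
    estimates spanning the boundary do not contaminate the plateau mean;
    match it to the flux smoothing halfwidth.
    """

    lag_s: float = 90.0
    window_s: float = 60.0
    cv_max: float = 0.1
    guard_s: float = 0.0


class NormalizationBasis(str, Enum):
    PER_MILLION_CELLS = "per_million_cells"
    PER_MG_PROTEIN = "per_mg_protein"
    PERCENT_BASAL = "percent_basal"


@dataclass
class NormalizedRate:
    label: str
    rate: float
    basis: NormalizationBasis


def compute_flux(trace: OxygenTrace, smoothing_halfwidth: float = 0.0) -> np.ndarray:
    """Oxygen flux JO2(t), pmol O2/s, by centered local linear regression.

    The slope of [O2] is estimated over the window |t - t_i| <= halfwidth;
    with halfwidth 0 a central finite difference is used.
    """
    t, y = trace.time, trace.o2
    span = t[-1] - t[0]
    if smoothing_halfwidth < 0:
        raise TraceError("smoothing_halfwidth must be >= 0")
    if smoothing_halfwidth >= span:
        raise TraceError("smoothing_halfwidth must be smaller than the trace span")

    if smoothing_halfwidth == 0.0:
        slope = np.gradient(y, t)
    else:
        x = t - t[0]
        lo = np.searchsorted(t, t - smoothing_halfwidth, side="left")
        hi = np.searchsorted(t, t + smoothing_halfwidth, side="right")
        cs1 = np.concatenate(([0.0], np.cumsum(np.ones_like(x))))
        csx = np.concatenate(([0.0], np.cumsum(x)))
        csy = np.concatenate(([0.0], np.cumsum(y)))
        csxx = np.concatenate(([0.0], np.cumsum(x * x)))
        csxy = np.concatenate(([0.0], np.cumsum(x * y)))
        n = cs1[hi] - cs1[lo]
        sx = csx[hi] - csx[lo]
        sy = csy[hi] - csy[lo]
        sxx = csxx[hi] - csxx[lo]
        sxy = csxy[hi] - csxy[lo]
        denom = n * sxx - sx * sx
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(denom > 0, (n * sxy - sx * sy) / denom, np.nan)
        bad = ~np.isfinite(slope)
        if np.any(bad):  # windows with < 2 points fall back to finite differences
            slope[bad] = np.gradient(y, t)[bad]

    # umol/L/s * mL -> pmol/s : x 1e-3 L x 1e6 pmol/umol
    return -slope * trace.chamber_volume_ml * 1e3


def _segment_labels(events: Sequence[EventMark]) -> list[str]:
    labels, seen = [], {}
    for ev in events:
        n = seen.get(ev.label, 0)
        seen[ev.label] = n + 1
        labels.append(ev.label if n == 0 else f"{ev.label} #{n + 1}")
    return labels


def extract_steady_states(
    trace: OxygenTrace,
    flux: np.ndarray,
    events: Sequence[EventMark],
    policy: WindowPolicy = WindowPolicy(),
    basal_label: str = "basal",
) -> list[SteadyState]:
    """One steady state per inter-event segment (plus the pre-event basal)."""
    t = trace.time
    t0, t1 = trace.span
    times = [ev.time for ev in events]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise TraceError("events must be sorted with non-overlapping windows")
    for ev in events:
        if not (t0 <= ev.time <= t1):
            raise TraceError(f"event {ev.label!r} at t={ev.time} outside trace span")

    bounds = [t0] + times + [t1]
    labels = [basal_label] + _segment_labels(events)
    states: list[SteadyState] = []
    for i, (label, lo, hi) in enumerate(zip(labels, bounds, bounds[1:])):
        if hi <= lo:
            continue
        start = lo + policy.lag_s
        wend = hi - policy.guard_s if i < len(labels) - 1 else hi
        wstart = max(start, wend - policy.window_s)
        flagged, note = False, ""
        if wstart >= wend:
            wstart, wend, flagged = lo, hi, True
            note = "segment shorter than lag + window"
        sel = (t >= wstart) & (t <= wend)
        if sel.sum() < 2:
            sel = (t >= lo) & (t <= hi)
            flagged, note = True, "too few samples in window"
        vals = flux[sel]
        mean = float(np.mean(vals))
        cv = float(np.std(vals) / abs(mean)) if mean != 0 else float(np.std(vals))
        if cv > policy.cv_max:
            flagged = True
            note = note or f"cv {cv:.3f} exceeds {policy.cv_max}"
        states.append(
            SteadyState(
                label=label,
                jo2=mean,
                window=(float(wstart), float(wend)),
                cv=cv,
                flagged=flagged,
                note=note,
            )
        )
    return states


def correct_nonmito(
    states: Sequence[SteadyState], residual_label: str
) -> list[SteadyState]:
    """Subtract the terminal (rotenone/antimycin) residual from earlier states."""
    idx = next(
        (i for i, s in enumerate(states) if s.label == residual_label), None
    )
    if idx is None:
        raise TraceError(
            f"residual state {residual_label!r} not found among "
            f"{[s.label for s in states]}"
        )
    residual = states[idx].jo2
    out = []
    for i, s in enumerate(states):
        if i < idx:
            corrected = s.jo2 - residual
            if corrected < 0:
                warnings.warn(
                    f"state {s.label!r}: residual {residual:.3g} exceeds rate "
                    f"{s.jo2:.3g}; floored at 0",
                    stacklevel=2,
                )
                corrected = 0.0
            out.append(replace(s, jo2=corrected))
        else:
            out.append(replace(s))
    return out


def normalize(
    states: Sequence[SteadyState],
    sample: Sample,
    basis: NormalizationBasis,
    basal_label: str = "basal",
) -> list[NormalizedRate]:
    """Normalize chamber rates to cell count, protein, or percent of basal."""
    basis = NormalizationBasis(basis)
    if basis is NormalizationBasis.PER_MILLION_CELLS:
        if sample.cell_count_millions is None:
            raise TraceError("basis per_million_cells requires sample.cell_count_millions")
        denom = sample.cell_count_millions
        return [NormalizedRate(s.label, s.jo2 / denom, basis) for s in states]
    if basis is NormalizationBasis.PER_MG_PROTEIN:
        if sample.protein_mg is None:
            raise TraceError("basis per_mg_protein requires sample.protein_mg")
        denom = sample.protein_mg
        return [NormalizedRate(s.label, s.jo2 / denom, basis) for s in states]
    basal = next((s for s in states if s.label == basal_label), None)
    if basal is None:
        raise TraceError(f"basis percent_basal requires a state labelled {basal_label!r}")
    if basal.jo2 == 0:
        raise TraceError("basal rate is 0; percent of basal undefined")
    return [NormalizedRate(s.label, 100.0 * s.jo2 / basal.jo2, basis) for s in states]


def fccp_km(
    titration: Sequence[tuple[float, float]], tol: float = 1e-9
) -> tuple[float, float]:
    """Km (uM) and Vmax of uncoupler dose response, fit on the ascending limb.

    Points at doses at or beyond the dose achieving the maximum observed rate
    are excluded (high uncoupler collapses flux, which a hyperbola cannot
    represent); the fit is on the above-baseline increment.
    """
    from scipy.optimize import curve_fit

    pts = sorted(titration, key=lambda p: p[0])
    doses = np.array([p[0] for p in pts], dtype=float)
    rates = np.array([p[1] for p in pts], dtype=float)
    baseline = float(rates[doses == 0][0]) if np.any(doses == 0) else 0.0

    pos = doses > 0
    d, r = doses[pos], rates[pos]
    if d.size == 0:
        raise FitError("no positive-dose points")
    rmax = r.max()
    dmax = d[np.nonzero(r >= rmax - tol)[0][0]]  # first dose achieving the max
    keep = d < dmax
    d, r = d[keep], r[keep] - baseline
    if d.size < 3:
        raise FitError(f"only {d.size} usable ascending-limb points (need >= 3)")

    def hyperbola(x, vmax, km):
        return vmax * x / (km + x)

    try:
        popt, _ = curve_fit(
            hyperbola,
            d,
            r,
            p0=(float(r.max()), float(np.median(d))),
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        raise FitError(f"Km fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    return km, vmax


# ---------------------------------------------------------------------------
# CSV dialects


def read_trace_csv(
    path, chamber_volume_ml: float, sample: Sample | None = None
) -> OxygenTrace:
    """Read a trace CSV with columns time_s,o2_uM."""
    df = pd.read_csv(path)
    return OxygenTrace(
        time=df["time_s"].to_numpy(float),
        o2=df["o2_uM"].to_numpy(float),
        chamber_volume_ml=chamber_volume_ml,
        sample=sample or Sample(),
    )


def read_events_csv(path) -> list[EventMark]:
    """Read an events CSV with columns time_s,label[,reagent,conc]."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        conc = None
        if "reagent" in df.columns and pd.notna(row.get("reagent")):
            conc = f"{row['reagent']} {row.get('conc', '')}".strip()
        out.append(EventMark(time=float(row["time_s"]), label=str(row["label"]), reagent_conc=conc))
    return out


def states_to_frame(states: Sequence[SteadyState]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.label for s in states],
            "jo2_pmol_s": [s.jo2 for s in states],
            "window_start_s": [s.window[0] for s in states],
            "window_end_s": [s.window[1] for s in states],
            "cv": [s.cv for s in states],
            "flagged": [s.flagged for s in states],
            "note": [s.note for s in states],
        }
    )
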