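"""Synthetic data with embedded ground truth for every pipeline stage.

Each generator returns its ground truth alongside the data; round-trip
tests reference only that embedded truth.  All randomness flows from one
explicit seed per call.  Noise models are the simplest consistent with each
data type: gaussian on O2 concentration and fluorescence, gaussian on voxel
intensities, lognormal on reporter intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .fluorometry import CH_551, CH_576, FluorescenceTrace, PotentialCalibration
from .imaging import VoxelStack
from .oxphos import DEFAULT_CLAMP_FORCES, OxphosKinetics
from .proteomics import PlexDesign
from .respirometry import EventMark, OxygenTrace, Sample

__all__ = [
    "Segment",
    "BioenergeticGroundTruth",
    "SyntheticCell",
    "make_respirometry_trace",
    "make_kinetics",
    "make_ck_protocol",
    "make_stack",
    "make_tmt",
    "make_tmrm_trace",
    "make_po_traces",
]


class Segment(NamedTuple):
    """One protocol step: segment label, duration (s) and true rate (pmol O2/s)."""

    label: str
    duration_s: float
    rate_pmol_s: float


def make_respirometry_trace(
    segments: Sequence[Segment],
    chamber_volume_ml: float = 1.0,
    o2_start_uM: float = 200.0,
    dt_s: float = 2.0,
    noise_sd_uM: float = 0.0,
    seed: int | None = None,
    sample: Sample | None = None,
) -> tuple[OxygenTrace, list[EventMark], dict]:
    """Integrate a step protocol into an O2 trace plus event marks.

    O2(t) declines at rate/volume per segment; events sit at segment
    boundaries and are labelled by the segment they start.
    """
    if any(s.rate_pmol_s < 0 for s in segments):
        raise ValueError("segment rates must be >= 0")
    if any(s.duration_s <= 0 for s in segments):
        raise ValueError("segment durations must be > 0")
    rng = np.random.default_rng(seed)
    total = sum(s.duration_s for s in segments)
    time = np.arange(0.0, total + dt_s / 2, dt_s)

    o2 = np.empty_like(time)
    events: list[EventMark] = []
    truth_rates: dict[str, float] = {}
    t_cursor, level = 0.0, o2_start_uM
    for i, seg in enumerate(segments):
        # pmol/s -> uM/s decline in the chamber
        slope = seg.rate_pmol_s / (chamber_volume_ml * 1e3)
        sel = (time >= t_cursor) & (time <= t_cursor + seg.duration_s)
        o2[sel] = level - slope * (time[sel] - t_cursor)
        level -= slope * seg.duration_s
        truth_rates[seg.label] = seg.rate_pmol_s
        if i > 0:
            events.append(EventMark(time=t_cursor, label=seg.label))
        t_cursor += seg.duration_s
    if noise_sd_uM > 0:
        o2 = o2 + rng.normal(0.0, noise_sd_uM, size=o2.size)
    o2 = np.clip(o2, 0.0, None)
    trace = OxygenTrace(
        time=time, o2=o2, chamber_volume_ml=chamber_volume_ml, sample=sample or Sample()
    )
    truth = {
        "rates_pmol_s": truth_rates,
        "chamber_volume_ml": chamber_volume_ml,
        "noise_sd_uM": noise_sd_uM,
        "seed": seed,
    }
    return trace, events, truth


@dataclass(frozen=True)
class BioenergeticGroundTruth:
    """Planted per-"cell type" bioenergetic profile.

    ``fractional_oxphos`` near 1 with ``fccp_effect`` near 1 emulates a
    healthy-donor-like profile; ~0.5 for both emulates the ATP-inhibited
    regime with elevated content.
    """

    label: str
    basal_rate: float
    content_scale: float
    jh_total: float
    fractional_oxphos: float
    fccp_effect: float
    dg_sensitivity: float  # fraction of jh_oxphos lost across the force span
    po_ratio: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if min(self.basal_rate, self.jh_total, self.po_ratio) < 0:
            raise ValueError("rates and po_ratio must be >= 0")
        for name in ("fractional_oxphos", "fccp_effect"):
            v = getattr(self, name)
            if not 0 < v <= 1.5:
                raise ValueError(f"{name} must be in (0, 1.5]")
        if not 0 <= self.dg_sensitivity <= 1:
            raise ValueError("dg_sensitivity must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def jh_oxphos(self) -> float:
        return self.fractional_oxphos * self.jh_total


def make_kinetics(
    gt: BioenergeticGroundTruth,
    forces: Sequence[float] = DEFAULT_CLAMP_FORCES,
    noise_sd: float | None = None,
) -> tuple[OxphosKinetics, dict]:
    """Kinetics declining with force per the planted sensitivity shape."""
    forces = list(forces)
    rng = np.random.default_rng(gt.seed)
    sd = gt.noise_sd if noise_sd is None else noise_sd
    span = forces[0] - forces[-1] if len(forces) > 1 else 1.0
    rates = []
    for f in forces:
        x = (forces[0] - f) / span if span else 0.0
        r = gt.jh_oxphos * (1.0 - gt.dg_sensitivity * x)
        rates.append(max(0.0, r + (rng.normal(0.0, sd) if sd > 0 else 0.0)))
    fccp = gt.fccp_effect * gt.jh_oxphos
    kin = OxphosKinetics(
        points=list(zip(forces, rates)), fccp_dgatp=fccp, assay_id=gt.label
    )
    truth = {
        "jh_oxphos": gt.jh_oxphos,
        "jh_total": gt.jh_total,
        "fractional_oxphos": gt.fractional_oxphos,
        "fccp_effect": gt.fccp_effect,
        "forces": forces,
    }
    return kin, truth


def make_ck_protocol(
    gt: BioenergeticGroundTruth,
    forces: Sequence[float] = DEFAULT_CLAMP_FORCES,
    segment_s: float = 240.0,
    dt_s: float = 2.0,
    chamber_volume_ml: float = 1.0,
    residual_rate: float = 2.0,
) -> dict:
    """Paired CK-clamp and uncoupler-titration protocols for one profile.

    Returns traces, events, the per-label clamp forces and the embedded
    truth.  The non-mitochondrial residual is present in every segment so
    the rotenone/antimycin correction recovers the planted mito rates.
    """
    forces = list(forces)
    span = forces[0] - forces[-1] if len(forces) > 1 else 1.0
    pcr_labels = [f"PCR {i + 1}" for i in range(len(forces))]
    ck_segments = [Segment("basal", segment_s, gt.basal_rate + residual_rate)]
    label_forces: dict[str, float] = {}
    for label, f in zip(pcr_labels, forces):
        x = (forces[0] - f) / span if span else 0.0
        rate = gt.jh_oxphos * (1.0 - gt.dg_sensitivity * x)
        ck_segments.append(Segment(label, segment_s, rate + residual_rate))
        label_forces[label] = f
    ck_segments.append(Segment("Oligo", segment_s, 0.05 * gt.jh_oxphos + residual_rate))
    ck_segments.append(
        Segment("FC", segment_s, gt.fccp_effect * gt.jh_oxphos + residual_rate)
    )
    ck_segments.append(Segment("Ant", segment_s, residual_rate))

    ets_segments = [
        Segment("basal", segment_s, gt.basal_rate + residual_rate),
        Segment("FC 0.5", segment_s, 0.6 * gt.jh_total + residual_rate),
        Segment("FC 1.0", segment_s, gt.jh_total + residual_rate),
        Segment("FC 2.0", segment_s, 0.9 * gt.jh_total + residual_rate),
        Segment("Ant", segment_s, residual_rate),
    ]

    o2_start = 400.0  # generous head-room so the trace stays positive
    ck_trace, ck_events, _ = make_respirometry_trace(
        ck_segments,
        chamber_volume_ml=chamber_volume_ml,
        o2_start_uM=o2_start,
        dt_s=dt_s,
        noise_sd_uM=gt.noise_sd,
        seed=gt.seed,
    )
    ets_trace, ets_events, _ = make_respirometry_trace(
        ets_segments,
        chamber_volume_ml=chamber_volume_ml,
        o2_start_uM=o2_start,
        dt_s=dt_s,
        noise_sd_uM=gt.noise_sd,
        seed=gt.seed + 1,
    )
    return {
        "ck_trace": ck_trace,
        "ck_events": ck_events,
        "ets_trace": ets_trace,
        "ets_events": ets_events,
        "label_forces": label_forces,
        "fccp_label": "FC",
        "residual_label": "Ant",
        "ets_fccp_labels": ["FC 0.5", "FC 1.0", "FC 2.0"],
        "truth": {
            "jh_oxphos": gt.jh_oxphos,
            "jh_total": gt.jh_total,
            "fractional_oxphos": gt.fractional_oxphos,
            "fccp_effect": gt.fccp_effect,
            "residual_rate": residual_rate,
        },
    }


# ---------------------------------------------------------------------------
# Imaging


@dataclass(frozen=True)
class SyntheticCell:
    cell_id: str
    cx: float
    cy: float
    cz: float
    nuclear_radius_px: float
    mito_inner_px: float
    mito_outer_px: float


def make_stack(
    cells: Sequence[SyntheticCell],
    shape: tuple[int, int, int] = (20, 128, 128),
    pixel_size_um: float = 0.1,
    optical_section_um: float = 0.4,
    step_um: float = 0.2,
    background: int = 10,
    signal: int = 200,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[VoxelStack, dict]:
    """Voxel stack with spherical nuclei and spherical-shell mitochondria.

    True volumes are analytic: voxel count x pixel_size^2 x step.  The z
    coordinate is isotropic in *steps*, so voxel volume uses the step size.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[:nz, :ny, :nx].astype(float)
    # z in units of xy pixels so radii are spherical in pixel units
    z_scale = step_um / pixel_size_um
    nuclear = np.zeros(shape, dtype=bool)
    mito = np.zeros(shape, dtype=bool)
    voxel_um3 = pixel_size_um**2 * step_um
    truth: dict = {"cells": {}, "voxel_um3": voxel_um3}
    for cell in cells:
        r2 = (
            ((zz - cell.cz) * z_scale) ** 2
            + (yy - cell.cy) ** 2
            + (xx - cell.cx) ** 2
        )
        nuc = r2 <= cell.nuclear_radius_px**2
        shell = (r2 >= cell.mito_inner_px**2) & (r2 <= cell.mito_outer_px**2)
        nuclear |= nuc
        mito |= shell
        truth["cells"][cell.cell_id] = {
            "nuclear_voxels": int(nuc.sum()),
            "mito_voxels": int(shell.sum()),
            "nuclear_volume_um3": float(nuc.sum()) * voxel_um3,
            "mito_volume_um3": float(shell.sum()) * voxel_um3,
        }

    def channel(mask: np.ndarray) -> np.ndarray:
        arr = np.where(mask, float(signal), float(background))
        if noise_sd > 0:
            arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
        return np.clip(np.round(arr), 0, 65535).astype(np.uint16)

    stack = VoxelStack(
        channels={
            "nuclear": channel(nuclear),
            "mtg": channel(mito),
            "tmrm": channel(mito),
        },
        pixel_size_um=pixel_size_um,
        optical_section_um=optical_section_um,
        step_um=step_um,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Proteomics


def make_tmt(
    n_proteins: int = 200,
    n_kits: int = 2,
    channels_per_kit: int = 10,
    loading_biases: Sequence[float] | None = None,
    planted_log2fc: dict[str, float] | None = None,
    missing_rate: float = 0.0,
    noise_sd_log2: float = 0.15,
    psms_per_protein: int = 2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, PlexDesign, dict]:
    """PSM table with planted channel loading biases and group effects.

    Channels split half control / half case within each kit.  Intensities
    are baseline x loading bias x 2^(planted fc, case channels) x lognormal
    noise.  Truth lists planted effects per protein.
    """
    rng = np.random.default_rng(seed)
    planted = planted_log2fc or {}
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    channels, kits, groups_, bridge = [], [], [], []
    for k in range(n_kits):
        for c in range(channels_per_kit):
            channels.append(f"k{k}c{c}")
            kits.append(f"kit{k}")
            groups_.append("ctrl" if c < channels_per_kit // 2 else "case")
            bridge.append(c == 0 and n_kits > 1)
    n_ch = len(channels)
    biases = (
        np.asarray(loading_biases, dtype=float)
        if loading_biases is not None
        else np.ones(n_ch)
    )
    if biases.size != n_ch:
        raise ValueError("loading_biases length must equal total channel count")

    baseline = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=n_proteins)
    fc = np.array([planted.get(p, 0.0) for p in proteins])
    is_case = np.array([g == "case" for g in groups_])
    noise = rng.lognormal(
        mean=0.0, sigma=noise_sd_log2 * np.log(2), size=(n_proteins, n_ch)
    )
    intensity = (
        baseline[:, None]
        * biases[None, :]
        * np.where(is_case[None, :], 2.0 ** fc[:, None], 1.0)
        * noise
    )
    if missing_rate > 0:
        mask = rng.random(intensity.shape) < missing_rate
        intensity = np.where(mask, np.nan, intensity)

    rows = []
    for i, prot in enumerate(proteins):
        shares = rng.dirichlet(np.ones(psms_per_protein))
        for j in range(psms_per_protein):
            rows.append(
                {
                    "protein": prot,
                    "peptide": f"{prot}_pep{j}",
                    "psm_id": f"{prot}_psm{j}",
                    "coiso": float(rng.uniform(0.0, 0.4)),
                    "sn": float(rng.uniform(20.0, 100.0)),
                    **{ch: intensity[i, c] * shares[j] for c, ch in enumerate(channels)},
                }
            )
    table = pd.DataFrame(rows)
    design = PlexDesign(
        pd.DataFrame(
            {
                "channel": channels,
                "kit": kits,
                "sample": [f"s_{ch}" for ch in channels],
                "group": groups_,
                "is_bridge": bridge,
            }
        )
    )
    truth = {
        "planted_log2fc": dict(zip(proteins, fc)),
        "loading_biases": dict(zip(channels, biases)),
        "seed": seed,
    }
    return table, design, truth


# ---------------------------------------------------------------------------
# Fluorometry


def make_tmrm_trace(
    mv_profile: np.ndarray,
    calibration: PotentialCalibration,
    base_551: float = 100.0,
    dt_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[FluorescenceTrace, dict]:
    """Dual-channel trace whose 576/551 ratio encodes a known mV profile."""
    rng = np.random.default_rng(seed)
    mv = np.asarray(mv_profile, dtype=float)
    ratio = calibration.forward(mv)
    time = np.arange(mv.size) * dt_s
    ch551 = np.full(mv.size, base_551)
    ch576 = ratio * base_551
    if noise_sd > 0:
        ch551 = ch551 + rng.normal(0, noise_sd, mv.size)
        ch576 = ch576 + rng.normal(0, noise_sd, mv.size)
    trace = FluorescenceTrace(time=time, channels={CH_576: ch576, CH_551: ch551})
    return trace, {"mv_profile": mv, "ratio": ratio, "seed": seed}


def make_po_traces(
    jo2_pmol_s: float,
    po_ratio: float,
    duration_s: float = 300.0,
    dt_s: float = 2.0,
    chamber_volume_ml: float = 2.5,
    noise_sd_uM: float = 0.0,
    seed: int | None = None,
) -> tuple[OxygenTrace, tuple[np.ndarray, np.ndarray], dict]:
    """Paired O2 decline and ATP accumulation with a planted P/O ratio.

    Returns the O2 trace and an (time, atp_pmol) accumulation series whose
    slope is JATP = P/O x 2 x JO2.
    """
    rng = np.random.default_rng(seed)
    jatp = po_ratio * 2.0 * jo2_pmol_s
    trace, _, _ = make_respirometry_trace(
        [Segment("steady", duration_s, jo2_pmol_s)],
        chamber_volume_ml=chamber_volume_ml,
        o2_start_uM=250.0,
        dt_s=dt_s,
        noise_sd_uM=noise_sd_uM,
        seed=seed,
    )
    time = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    atp = jatp * time
    if noise_sd_uM > 0:
        atp = atp + rng.normal(0.0, noise_sd_uM * chamber_volume_ml * 1e3, time.size)
    truth = {"jo2": jo2_pmol_s, "jatp": jatp, "po_ratio": po_ratio, "seed": seed}
    return trace, (time, atp), truth
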