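"""Confocal z-stack signal volumes.

Signal is selected with Huang's fuzzy-entropy auto-threshold; the volume of
the thresholded signal is [A * Z] / N where A is the summed signal-positive
area (um^2) across retained slices, Z the optical-section thickness (um)
and N the number of z-steps per optical section (axial resolution divided
by the step size), which corrects for axial oversampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelStack",
    "CircleRoi",
    "VolumeResult",
    "ImagingError",
    "huang_threshold",
    "signal_volume",
    "n_steps_from_geometry",
    "volume_ratio",
    "respiratory_deficiency",
    "roi_touches_border",
    "measure_roi_volume",
    "quantify_stack",
    "auto_rois",
]


class ImagingError(ValueError):
    pass


@dataclass
class VoxelStack:
    """Per-channel (z, y, x) intensity arrays with voxel geometry in um."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    optical_section_um: float
    step_um: float

    def __post_init__(self) -> None:
        if min(self.pixel_size_um, self.optical_section_um, self.step_um) <= 0:
            raise ImagingError("all geometry values must be > 0")
        if self.step_um > self.optical_section_um:
            raise ImagingError(
                "step_um must be <= optical_section_um (oversampling regime)"
            )
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ImagingError("all channels must share one shape")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ImagingError(f"channel {name!r} must be 3-D (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_steps(self) -> int:
        return n_steps_from_geometry(self.optical_section_um, self.step_um)


@dataclass(frozen=True)
class CircleRoi:
    cell_id: str
    cx: float
    cy: float
    radius_px: float
    z_min: int = 0
    z_max: int | None = None  # inclusive; None = last slice


@dataclass
class VolumeResult:
    channel: str
    volume_um3: float
    threshold: float
    roi_id: str


def n_steps_from_geometry(optical_section_um: float, step_um: float) -> int:
    """N = optical section / step size, rounded to the nearest integer >= 1."""
    return max(1, round(optical_section_um / step_um))


def _histogram(arr: np.ndarray, max_levels: int = 2048):
    """(levels, counts) for Huang's criterion.

    Integer images up to 16 bit keep their native levels (unique values);
    anything else is min-max scaled onto 256 bins.
    """
    flat = np.asarray(arr).ravel()
    if np.issubdtype(flat.dtype, np.integer) and flat.dtype.itemsize <= 2:
        levels, counts = np.unique(flat, return_counts=True)
        levels = levels.astype(float)
        if levels.size > max_levels:
            counts, edges = np.histogram(flat, bins=max_levels)
            levels = 0.5 * (edges[:-1] + edges[1:])
            keep = counts > 0
            levels, counts = levels[keep], counts[keep]
        return levels, counts.astype(float)
    flat = flat.astype(float)
    counts, edges = np.histogram(flat, bins=256)
    levels = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return levels[keep], counts[keep].astype(float)


def _fuzzy_entropy(mu: np.ndarray) -> np.ndarray:
    h = np.zeros_like(mu)
    interior = (mu > 0) & (mu < 1)
    m = mu[interior]
    h[interior] = -m * np.log(m) - (1 - m) * np.log(1 - m)
    return h


def huang_threshold(image: np.ndarray) -> float:
    """Huang's fuzzy-membership entropy threshold.

    For each candidate threshold the image is split into background and
    foreground with class means m0, m1; each grey level g gets membership
    mu = 1 / (1 + |g - m_class| / C) with C the grey-level range, and the
    threshold minimizing the summed Shannon fuzziness is returned (as the
    midpoint between the two classes' boundary levels).
    """
    levels, counts = _histogram(image)
    if levels.size < 2:
        raise ImagingError("constant image: no threshold exists")
    c = levels[-1] - levels[0]
    w = counts
    cw = np.cumsum(w)
    cwx = np.cumsum(w * levels)
    total_w, total_wx = cw[-1], cwx[-1]

    # candidate k: background = levels[:k+1], foreground = levels[k+1:]
    ks = np.arange(levels.size - 1)
    m0 = cwx[ks] / cw[ks]
    m1 = (total_wx - cwx[ks]) / (total_w - cw[ks])

    # membership matrix over (candidate, level)
    g = levels[None, :]
    lower = np.arange(levels.size)[None, :] <= ks[:, None]
    mclass = np.where(lower, m0[:, None], m1[:, None])
    mu = 1.0 / (1.0 + np.abs(g - mclass) / c)
    s = (_fuzzy_entropy(mu) * w[None, :]).sum(axis=1)
    k = int(np.argmin(s))
    return float(0.5 * (levels[k] + levels[k + 1]))


def signal_volume(areas_um2: Sequence[float], z_um: float, n_steps: int) -> float:
    """SignalVolume (um^3) = [A * Z] / N with A summed over retained slices."""
    if n_steps < 1:
        raise ImagingError("n_steps must be >= 1")
    if z_um <= 0:
        raise ImagingError("z_um must be > 0")
    areas = np.asarray(areas_um2, dtype=float)
    if np.any(areas < 0):
        raise ImagingError("areas must be >= 0")
    return float(areas.sum() * z_um / n_steps)


def volume_ratio(mito_volume_um3: float, nuclear_volume_um3: float) -> float:
    if nuclear_volume_um3 <= 0:
        raise ImagingError("nuclear volume must be > 0")
    return mito_volume_um3 / nuclear_volume_um3


def respiratory_deficiency(
    capacity: float,
    content: float,
    reference_capacity: float,
    reference_content: float,
) -> float:
    """(capacity/content) / (reference capacity/reference content)."""
    for name, v in (
        ("capacity", capacity),
        ("content", content),
        ("reference_capacity", reference_capacity),
        ("reference_content", reference_content),
    ):
        if v <= 0:
            raise ImagingError(f"{name} must be > 0")
    return (capacity / content) / (reference_capacity / reference_content)


def roi_touches_border(roi: CircleRoi, shape_yx: tuple[int, int]) -> bool:
    ny, nx = shape_yx
    return (
        roi.cx - roi.radius_px < 0
        or roi.cy - roi.radius_px < 0
        or roi.cx + roi.radius_px > nx - 1
        or roi.cy + roi.radius_px > ny - 1
    )


def _circle_mask(shape_yx: tuple[int, int], roi: CircleRoi) -> np.ndarray:
    yy, xx = np.mgrid[: shape_yx[0], : shape_yx[1]]
    return (yy - roi.cy) ** 2 + (xx - roi.cx) ** 2 <= roi.radius_px**2


def measure_roi_volume(
    stack: VoxelStack, roi: CircleRoi, channel: str, threshold: float | None = None
) -> VolumeResult:
    """Threshold one channel inside a circular ROI and apply the volume formula.

    The threshold defaults to Huang's criterion computed from the ROI
    subvolume of that channel.
    """
    arr = stack.channels[channel]
    nz = arr.shape[0]
    z_lo = max(0, roi.z_min)
    z_hi = nz - 1 if roi.z_max is None else min(nz - 1, roi.z_max)
    circle = _circle_mask(arr.shape[1:], roi)
    sub = arr[z_lo : z_hi + 1][:, circle]
    if threshold is None:
        threshold = huang_threshold(sub)
    px_area = stack.pixel_size_um**2
    areas = [(slice_vals > threshold).sum() * px_area for slice_vals in sub]
    vol = signal_volume(areas, stack.optical_section_um, stack.n_steps)
    return VolumeResult(channel=channel, volume_um3=vol, threshold=float(threshold), roi_id=roi.cell_id)


def quantify_stack(
    stack: VoxelStack,
    rois: Sequence[CircleRoi],
    channels: Sequence[str] | None = None,
    exclude_border: bool = True,
) -> list[VolumeResult]:
    """Per-ROI, per-channel signal volumes; border-touching cells excluded."""
    channels = list(channels or stack.channels)
    shape_yx = stack.shape[1:]
    results: list[VolumeResult] = []
    for roi in rois:
        if exclude_border and roi_touches_border(roi, shape_yx):
            warnings.warn(
                f"ROI {roi.cell_id!r} touches the field-of-view border; excluded",
                stacklevel=2,
            )
            continue
        for ch in channels:
            results.append(measure_roi_volume(stack, roi, ch))
    return results


def auto_rois(
    stack: VoxelStack, channel: str, pad_px: float = 2.0
) -> list[CircleRoi]:
    """Connected-component fallback for ROI selection on a max projection."""
    from skimage import measure

    arr = stack.channels[channel]
    proj = arr.max(axis=0)
    thr = huang_threshold(proj)
    labels = measure.label(proj > thr)
    rois = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        radius = float(np.sqrt(region.area / np.pi)) + pad_px
        rois.append(CircleRoi(cell_id=f"cell{region.label}", cx=cx, cy=cy, radius_px=radius))
    return rois


# ---------------------------------------------------------------------------
# IO helpers


def load_stack(tiff_path, metadata_path, channel_order: Sequence[str] | None = None) -> VoxelStack:
    """Load a (c, z, y, x) or (z, c, y, x) multi-channel TIFF plus sidecar JSON.

    The sidecar declares pixel_size_um, optical_section_um, step_um and
    channel order.
    """
    import tifffile

    with open(metadata_path) as fh:
        meta = json.load(fh)
    order = list(channel_order or meta["channels"])
    data = tifffile.imread(tiff_path)
    if data.ndim != 4:
        raise ImagingError("expected a 4-D (c, z, y, x) stack")
    if data.shape[0] != len(order):
        if data.shape[1] == len(order):
            data = np.moveaxis(data, 1, 0)
        else:
            raise ImagingError("channel axis does not match declared channel order")
    return VoxelStack(
        channels={name: data[i] for i, name in enumerate(order)},
        pixel_size_um=float(meta["pixel_size_um"]),
        optical_section_um=float(meta["optical_section_um"]),
        step_um=float(meta["step_um"]),
    )


def read_roi_csv(path) -> list[CircleRoi]:
    """ROI CSV: cell_id,cx,cy,radius_px[,z_min,z_max]."""
    import pandas as pd

    df = pd.read_csv(path)
    rois = []
    for _, row in df.iterrows():
        rois.append(
            CircleRoi(
                cell_id=str(row["cell_id"]),
                cx=float(row["cx"]),
                cy=float(row["cy"]),
                radius_px=float(row["radius_px"]),
                z_min=int(row["z_min"]) if "z_min" in df.columns else 0,
                z_max=int(row["z_max"]) if "z_max" in df.columns else None,
            )
        )
    return rois
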