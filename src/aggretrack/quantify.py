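"""Trace-level readouts: ROI means, cytosolic intensities, normalization,
and per-field aggregate-count curves.

All intensity measurements operate on maximum-intensity projections, with
a pixel-center-in-disk rule for ROIs.  Traces are normalized to their
value at the first time point, mirroring how long-term fluorescence data
are conventionally reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .detect_track import AggregateTrack, Detection, max_project
from .synthgen import ImageSeries


@dataclass
class Trace:
    """A single intensity (or amount) time course."""

    times: np.ndarray  # h
    values: np.ndarray  # a.u.
    subject: str = ""
    channel: str = ""
    normalized: bool = False
    reference_value: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class CountCurve:
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")


def measure_roi(projection: np.ndarray, center: tuple[float, float], radius: float) -> float:
    """Mean of the pixels whose centers lie within the disk ROI.

    ``center`` is (x, y) in continuous pixel coordinates (pixel centers at
    integers).  ``radius = 0`` degenerates to the nearest single pixel.
    """
    proj = np.asarray(projection, dtype=float)
    Y, X = proj.shape
    cx, cy = center
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        xi, yi = int(round(cx)), int(round(cy))
        if not (0 <= xi < X and 0 <= yi < Y):
            raise ValueError("ROI entirely outside the image")
        return float(proj[yi, xi])
    x0, x1 = int(math.floor(cx - radius)), int(math.ceil(cx + radius)) + 1
    y0, y1 = int(math.floor(cy - radius)), int(math.ceil(cy + radius)) + 1
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(X, x1), min(Y, y1)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("ROI entirely outside the image")
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    if not inside.any():
        raise ValueError("ROI contains no pixel centers")
    return float(proj[y0:y1, x0:x1][inside].mean())


def measure_roi_background(
    projection: np.ndarray, center: tuple[float, float], r_in: float, r_out: float
) -> float:
    """Median intensity in an annulus around the ROI (local background)."""
    proj = np.asarray(projection, dtype=float)
    Y, X = proj.shape
    cx, cy = center
    x0, x1 = max(0, int(cx - r_out) - 1), min(X, int(cx + r_out) + 2)
    y0, y1 = max(0, int(cy - r_out) - 1), min(Y, int(cy + r_out) + 2)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("annulus entirely outside the image")
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    ring = (r2 > r_in ** 2) & (r2 <= r_out ** 2)
    if not ring.any():
        raise ValueError("annulus contains no pixel centers")
    return float(np.median(proj[y0:y1, x0:x1][ring]))


def aggregate_footprint(
    shape: tuple[int, int],
    detections: Sequence[Detection],
    dilation: int = 2,
) -> np.ndarray:
    """Binary mask covering detected puncta, grown by ``dilation`` px."""
    mask = np.zeros(shape, dtype=bool)
    for d in detections:
        xi, yi = int(round(d.x)), int(round(d.y))
        if 0 <= yi < shape[0] and 0 <= xi < shape[1]:
            core = max(1, int(round(math.sqrt(max(d.area, 1) / math.pi))))
            mask |= _disk(shape, (xi, yi), core + dilation)
    return mask


def _disk(shape, center_xy, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius ** 2


def measure_cytosol(
    projection: np.ndarray,
    region_mask: np.ndarray,
    detections: Sequence[Detection] = (),
    dilation: int = 2,
) -> float:
    """Mean intensity over a manually placed region, puncta excluded.

    The region mask is meant to be drawn once (on the first frame) and
    reused across the series; detected aggregate footprints, dilated by
    ``dilation`` pixels, are removed before averaging so puncta do not
    bleed into the cytosolic estimate.
    """
    proj = np.asarray(projection, dtype=float)
    region = np.asarray(region_mask, dtype=bool)
    if region.shape != proj.shape:
        raise ValueError("region mask shape mismatch")
    if not region.any():
        raise ValueError("empty region mask")
    keep = region
    if len(detections):
        keep = region & ~aggregate_footprint(proj.shape, detections, dilation)
    if not keep.any():
        raise ValueError("aggregate exclusion removed every region pixel")
    return float(proj[keep].mean())


def normalize_trace(trace: Trace, eps: float = 1e-6) -> Trace:
    """Divide a trace by its value at the first time point.

    Re-normalizing an already-normalized trace is refused (it would
    silently divide twice), as is a first value at or below ``eps``.
    """
    if trace.normalized:
        raise ValueError("trace is already normalized")
    first = float(trace.values[0])
    if not np.isfinite(first) or first <= eps:
        raise ValueError(f"cannot normalize: value at t=0 is {first!r}")
    return replace(
        trace,
        values=trace.values / first,
        normalized=True,
        reference_value=first,
    )


def count_curve(tracks: Sequence[AggregateTrack], times: np.ndarray) -> CountCurve:
    """Number of concurrently present tracks at each frame.

    A track counts at frame ``i`` while it spans that frame, including
    frames inside an open gap (the aggregate is presumed present but
    briefly undetected or occluded).
    """
    times = np.asarray(times, dtype=float)
    counts = np.zeros(len(times), dtype=int)
    for tr in tracks:
        counts[tr.start : tr.end + 1] += 1
    return CountCurve(times=times, counts=counts)


# ---------------------------------------------------------------------------
# series-level conveniences
# ---------------------------------------------------------------------------


def roi_trace(
    series: ImageSeries,
    track: AggregateTrack,
    channel: str,
    radius: float = 4.0,
    background_annulus: Optional[tuple[float, float]] = None,
) -> Trace:
    """Per-frame disk-ROI mean around the track's position.

    With ``background_annulus=(r_in, r_out)`` the local background median
    is subtracted, isolating the punctum from surrounding cytosolic
    signal (standard punctum photometry).
    """
    ci = series.channel(channel)
    times, vals = [], []
    for f in range(track.start, track.end + 1):
        x, y = track.position_at(f)
        proj = max_project(series.data[f, ci].astype(float))
        times.append(f * series.dt)
        v = measure_roi(proj, (x, y), radius)
        if background_annulus is not None:
            v -= measure_roi_background(proj, (x, y), *background_annulus)
        vals.append(v)
    return Trace(
        times=np.array(times),
        values=np.array(vals),
        subject=f"track{track.id}",
        channel=channel,
    )


def punctum_contrast_trace(
    series: ImageSeries,
    track: AggregateTrack,
    channel: str,
    sigma: float = 1.3,
) -> Trace:
    """Band-pass (spot-scale) response at the track position per frame.

    Proportional to the punctum's bound amount but insensitive to smooth
    cytosolic background — the readout of choice when asking whether an
    aggregate carries a label at all, e.g. for second-ligand uptake in a
    pulse-chase series.
    """
    ci = series.channel(channel)
    times, vals = [], []
    for f in range(track.start, track.end + 1):
        x, y = track.position_at(f)
        proj = max_project(series.data[f, ci].astype(float))
        dog = ndimage.gaussian_filter(proj, sigma) - ndimage.gaussian_filter(
            proj, 1.6 * sigma
        )
        xi = int(np.clip(round(x), 0, proj.shape[1] - 1))
        yi = int(np.clip(round(y), 0, proj.shape[0] - 1))
        times.append(f * series.dt)
        vals.append(float(dog[yi, xi]))
    return Trace(
        times=np.array(times),
        values=np.array(vals),
        subject=f"track{track.id}",
        channel=channel,
    )


def static_roi_trace(
    series: ImageSeries,
    center: tuple[float, float],
    channel: str,
    radius: float = 4.0,
) -> Trace:
    """ROI fixed in place for the whole series (bleach-recovery readout)."""
    ci = series.channel(channel)
    vals = [
        measure_roi(max_project(series.data[f, ci].astype(float)), center, radius)
        for f in range(series.n_frames)
    ]
    return Trace(
        times=series.times,
        values=np.array(vals),
        subject=f"roi@{center[0]:.0f},{center[1]:.0f}",
        channel=channel,
    )


def cytosol_trace(
    series: ImageSeries,
    channel: str,
    region_mask: np.ndarray,
    detections_by_frame: Optional[dict[int, list[Detection]]] = None,
    dilation: int = 2,
) -> Trace:
    """Cytosolic mean intensity over the series, same region each frame."""
    ci = series.channel(channel)
    vals = []
    for f in range(series.n_frames):
        proj = max_project(series.data[f, ci].astype(float))
        dets = detections_by_frame.get(f, []) if detections_by_frame else []
        vals.append(measure_cytosol(proj, region_mask, dets, dilation))
    return Trace(
        times=series.times, values=np.array(vals), subject="cytosol", channel=channel
    )


def somatodendritic_mask(series: ImageSeries, morph_channel: str = "morph",
                         k_mad: float = 2.0) -> np.ndarray:
    """Bright-morphology mask from the first frame (somata + dendrites)."""
    ci = series.channel(morph_channel)
    proj = max_project(series.data[0, ci].astype(float))
    med = np.median(proj)
    mad = np.median(np.abs(proj - med))
    mask = proj > med + k_mad * max(mad, 1e-12)
    return ndimage.binary_opening(mask, iterations=1)


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    """Tidy long-format export of a collection of traces."""
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.subject, tr.channel, t, v, tr.normalized))
    return pd.DataFrame(
        rows, columns=["subject", "channel", "time_h", "value", "normalized"]
    )
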