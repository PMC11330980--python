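"""Punctum detection on maximum-intensity projections and track linking.

Detection is deliberately parameter-light: a band-pass (difference of
Gaussians) at the expected spot scale, a robust intensity threshold
(background median plus a multiple of the MAD), local-maxima extraction
and sub-pixel centroid refinement.  The same parameters are applied to
every frame of a series.  Linking is per-frame-pair global assignment
(minimum total displacement, Hungarian algorithm) with a hard per-step
displacement gate and gap closing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .synthgen import ImageSeries


@dataclass
class DetectConfig:
    sigma_spot: float = 1.3  # expected punctum scale, px
    k_mad: float = 8.0  # threshold = median + k * MAD of the band-passed image
    min_distance: int = 3  # px between accepted maxima
    min_area: int = 2  # px above half-maximum
    refine_window: int = 2  # half-width of the centroid window
    n_sigma_local: float = 5.0  # local Poisson-noise gate on the band-pass response
    rel_floor: float = 0.2  # min response as a fraction of local signal over background
    edge_ratio: float = 12.0  # Hessian trace^2/det gate; rejects ridge responses
    exclude_mask: Optional[np.ndarray] = None  # e.g. bright-cytosol regions


@dataclass
class LinkConfig:
    d_max: float = 15.0  # max displacement px / frame step
    gap_max: int = 2  # frames a track survives without a detection


@dataclass
class Detection:
    frame: int
    channel: str
    x: float
    y: float
    z_best: int
    peak_intensity: float
    area: float


@dataclass
class MergeEvent:
    frame: int
    track_id: int  # track that ended by merging
    into_track_id: int


@dataclass
class AggregateTrack:
    """Longitudinal identity of one punctum (frames strictly increasing)."""

    id: int
    detections: list[Detection] = field(default_factory=list)
    roi_radius: float = 4.0

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    @property
    def start(self) -> int:
        return self.detections[0].frame

    @property
    def end(self) -> int:
        return self.detections[-1].frame

    def detection_at(self, frame: int) -> Optional[Detection]:
        for d in self.detections:
            if d.frame == frame:
                return d
        return None

    def active_at(self, frame: int) -> bool:
        """True while the track spans ``frame`` (open gaps included)."""
        return self.start <= frame <= self.end

    def position_at(self, frame: int) -> tuple[float, float]:
        """Position at ``frame``; linear interpolation inside gaps."""
        d = self.detection_at(frame)
        if d is not None:
            return d.x, d.y
        if not self.active_at(frame):
            raise ValueError(f"track {self.id} not active at frame {frame}")
        frames = np.array(self.frames)
        xs = np.array([d.x for d in self.detections])
        ys = np.array([d.y for d in self.detections])
        return float(np.interp(frame, frames, xs)), float(np.interp(frame, frames, ys))


# ---------------------------------------------------------------------------
# projection and detection
# ---------------------------------------------------------------------------


def _dog_noise_gain(sigma: float) -> float:
    """Std-dev gain of the band-pass for unit-variance white noise."""
    n = int(math.ceil(8 * sigma)) * 2 + 1
    impulse = np.zeros((n, n))
    impulse[n // 2, n // 2] = 1.0
    k = ndimage.gaussian_filter(impulse, sigma) - ndimage.gaussian_filter(
        impulse, 1.6 * sigma
    )
    return float(np.sqrt((k ** 2).sum()))


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z.  Accepts (C, Z, Y, X) or (Z, Y, X)."""
    stack = np.asarray(stack)
    if stack.ndim not in (3, 4):
        raise ValueError("expected a (C, Z, Y, X) or (Z, Y, X) stack")
    if stack.shape[-3] == 0:
        raise ValueError("empty stack: no z planes")
    return stack.max(axis=-3)


def detect_spots(
    image: np.ndarray,
    config: Optional[DetectConfig] = None,
    frame: int = 0,
    channel: str = "",
    stack: Optional[np.ndarray] = None,
) -> list[Detection]:
    """Detect punctate objects on a single-channel projection.

    ``stack`` (the frame's Z x Y x X data for this channel) is only used
    to report the best-focus plane of each detection.
    """
    cfg = config or DetectConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_spots expects a 2-D projection")
    if not np.isfinite(image).all():
        raise ValueError("non-finite pixels in projection")

    s = cfg.sigma_spot
    dog = ndimage.gaussian_filter(image, s) - ndimage.gaussian_filter(image, 1.6 * s)
    med = np.median(dog)
    mad = np.median(np.abs(dog - med))
    thr = med + cfg.k_mad * max(mad, 1e-12)
    # Poisson noise grows with brightness, so the response inside bright
    # cytosolic regions must clear a local gate as well as the global one
    thr_map = np.full_like(dog, thr)
    if cfg.n_sigma_local > 0 or cfg.rel_floor > 0:
        local = ndimage.gaussian_filter(image, 2.5 * s)
        if cfg.n_sigma_local > 0:
            gain = _dog_noise_gain(s)
            thr_map = np.maximum(
                thr_map, cfg.n_sigma_local * gain * np.sqrt(np.clip(local, 0, None))
            )
        if cfg.rel_floor > 0:
            # structured clutter (dendritic varicosities, soma texture)
            # scales with brightness, not its square root
            bg_med = np.median(image)
            thr_map = np.maximum(
                thr_map, cfg.rel_floor * np.clip(local - bg_med, 0, None)
            )
    peaks = peak_local_max(
        dog, min_distance=cfg.min_distance, threshold_abs=thr, exclude_border=False
    )
    # deterministic ordering: by row, then column
    peaks = sorted(
        (py, px) for (py, px) in map(tuple, peaks) if dog[py, px] > thr_map[py, px]
    )

    out: list[Detection] = []
    w = cfg.refine_window
    Y, X = image.shape
    for (py, px) in peaks:
        if cfg.exclude_mask is not None and cfg.exclude_mask[py, px]:
            continue
        # ridge rejection: a punctum has an isotropic negative-definite
        # Hessian; elongated cytosol-filled neurites do not
        if 1 <= py < Y - 1 and 1 <= px < X - 1 and cfg.edge_ratio > 0:
            hxx = dog[py, px + 1] - 2 * dog[py, px] + dog[py, px - 1]
            hyy = dog[py + 1, px] - 2 * dog[py, px] + dog[py - 1, px]
            hxy = 0.25 * (
                dog[py + 1, px + 1] - dog[py + 1, px - 1]
                - dog[py - 1, px + 1] + dog[py - 1, px - 1]
            )
            det = hxx * hyy - hxy * hxy
            if det <= 0 or (hxx + hyy) ** 2 / det > cfg.edge_ratio:
                continue
        y0, y1 = max(0, py - w), min(Y, py + w + 1)
        x0, x1 = max(0, px - w), min(X, px + w + 1)
        win = dog[y0:y1, x0:x1] - thr
        win = np.clip(win, 0, None)
        half = 0.5 * dog[py, px]
        area = int((dog[max(0, py - 3): py + 4, max(0, px - 3): px + 4] >= half).sum())
        if area < cfg.min_area:
            continue
        tot = win.sum()
        if tot <= 0:
            cx, cy = float(px), float(py)
        else:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cy = float((yy * win).sum() / tot)
            cx = float((xx * win).sum() / tot)
        z_best = 0
        if stack is not None:
            z_best = int(np.argmax(stack[:, py, px]))
        out.append(
            Detection(
                frame=frame,
                channel=channel,
                x=cx,
                y=cy,
                z_best=z_best,
                peak_intensity=float(image[py, px]),
                area=float(area),
            )
        )
    return out


def detect_series(
    series: ImageSeries, channel: str, config: Optional[DetectConfig] = None
) -> list[Detection]:
    """Run the detector with identical parameters on every frame."""
    ci = series.channel(channel)
    dets: list[Detection] = []
    for t in range(series.n_frames):
        stack = series.data[t, ci].astype(float)
        proj = max_project(stack)
        dets.extend(
            detect_spots(proj, config, frame=t, channel=channel, stack=stack)
        )
    return dets


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------


def link_tracks(
    detections: Sequence[Detection],
    config: Optional[LinkConfig] = None,
) -> tuple[list[AggregateTrack], list[MergeEvent]]:
    """Link detections into tracks by per-frame-pair optimal assignment.

    Unmatched detections seed new tracks; a track survives up to
    ``gap_max`` missed frames before it is closed.  A track that ends
    while another track's matched detection lies within ``d_max`` of its
    last position is recorded as a merge event (small aggregates
    occasionally coalesce into larger ones).
    """
    cfg = config or LinkConfig()
    if cfg.d_max <= 0:
        raise ValueError("d_max must be > 0")
    dets = sorted(detections, key=lambda d: (d.frame, d.y, d.x))
    if not dets:
        return [], []

    tracks: list[AggregateTrack] = []
    merges: list[MergeEvent] = []
    active: list[AggregateTrack] = []
    next_id = 0
    frames = sorted({d.frame for d in dets})
    by_frame = {f: [d for d in dets if d.frame == f] for f in frames}

    for f in range(frames[0], frames[-1] + 1):
        cur = by_frame.get(f, [])
        # retire tracks whose gap exceeded the limit
        active = [tr for tr in active if f - tr.end <= cfg.gap_max + 1]

        matched_dets: dict[int, AggregateTrack] = {}
        if cur and active:
            cost = np.full((len(active), len(cur)), 1e9)
            for i, tr in enumerate(active):
                last = tr.detections[-1]
                span = f - last.frame
                for j, d in enumerate(cur):
                    dist = float(np.hypot(d.x - last.x, d.y - last.y))
                    if dist <= cfg.d_max * span:
                        cost[i, j] = dist
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < 1e9:
                    active[i].detections.append(cur[j])
                    matched_dets[j] = active[i]

        # merge bookkeeping: a just-stranded track adjacent to a matched
        # detection ends by coalescing into that detection's track
        for tr in list(active):
            if tr.end == f:
                continue
            last = tr.detections[-1]
            if f - last.frame <= cfg.gap_max:
                continue
            for j, d in enumerate(cur):
                if j in matched_dets and np.hypot(d.x - last.x, d.y - last.y) <= cfg.d_max:
                    merges.append(MergeEvent(f, tr.id, matched_dets[j].id))
                    active.remove(tr)
                    break

        for j, d in enumerate(cur):
            if j not in matched_dets:
                tr = AggregateTrack(id=next_id, detections=[d])
                next_id += 1
                tracks.append(tr)
                active.append(tr)

    tracks.sort(key=lambda t: t.id)
    return tracks, merges


def tracks_to_frame(
    tracks: Sequence[AggregateTrack], dt: float = 1.0
) -> pd.DataFrame:
    """One row per detection: track_id, frame, time_h, x, y, z_best, ..."""
    rows = []
    for tr in tracks:
        for d in tr.detections:
            rows.append(
                (tr.id, d.frame, d.frame * dt, d.x, d.y, d.z_best, d.channel,
                 d.peak_intensity, d.area)
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "time_h", "x", "y", "z_best", "channel",
                 "peak", "area"],
    )
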