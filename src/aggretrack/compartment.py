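"""Compartment assignment of tracked aggregates.

Each aggregate is followed over all frames of its track (both before and
after its intensity peak) and compared per frame against the morphology
reference: inside the nucleus mask (at a plausible z), inside the soma
mask, or near an axon/dendrite skeleton whose local morphology signal is
actually visible.  The final call is a majority vote over frames with
evidence; tracks without sufficient support are 'unresolved' rather than
guessed — faint axons must clear a visibility floor before they can
attract a call, and a structure that is invisible yields no evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect_track import AggregateTrack
from .synthgen import NeuronGeometry, Polyline, Soma

LABELS = ("axon", "dendrite", "soma", "nucleus", "unresolved")


@dataclass
class AssignConfig:
    d_assign: float = 3.0  # px: max distance to a skeleton
    f_min: float = 0.6  # required support fraction among evidence frames
    visibility_k: float = 4.0  # floor = bg median + k * MAD of the smoothed morphology
    morph_smooth_sigma: float = 1.5  # px: single pixels are too noisy to judge visibility
    z_tol: float = 1.5  # planes: nuclear calls need z agreement with the soma


@dataclass
class FrameEvidence:
    frame: int
    structure: str  # compartment kind
    distance: float  # px to the supporting structure
    morph_intensity: float


@dataclass
class CompartmentCall:
    track_id: int
    label: str
    confidence: float  # fraction of evidence frames supporting the label
    evidence: list[FrameEvidence] = field(default_factory=list)

    @property
    def n_frames_evidence(self) -> int:
        return len(self.evidence)


@dataclass
class CompartmentMasks:
    """Morphology reference: masks, skeletons, and (optionally) the
    rendered morphology projection used for the visibility floor."""

    nucleus_mask: np.ndarray
    soma_mask: np.ndarray
    skeletons: Sequence[Polyline]
    somata: Sequence[Soma] = ()
    morph_image: Optional[np.ndarray] = None

    def smoothed_morph(self, sigma: float) -> Optional[np.ndarray]:
        if self.morph_image is None:
            return None
        cache = getattr(self, "_morph_cache", None)
        if cache is None or cache[0] != sigma:
            from scipy import ndimage

            object.__setattr__(
                self, "_morph_cache",
                (sigma, ndimage.gaussian_filter(self.morph_image, sigma)),
            )
            cache = self._morph_cache
        return cache[1]

    @classmethod
    def from_geometry(
        cls, geom: NeuronGeometry, morph_image: Optional[np.ndarray] = None
    ) -> "CompartmentMasks":
        return cls(
            nucleus_mask=geom.nucleus_mask,
            soma_mask=geom.soma_mask,
            skeletons=list(geom.skeletons),
            somata=list(geom.somata),
            morph_image=morph_image,
        )


class _SkeletonIndex:
    """KD-tree over densely resampled skeleton points."""

    def __init__(self, skeletons: Sequence[Polyline]):
        pts, kinds = [], []
        for pl in skeletons:
            cum = pl.arclengths()
            total = cum[-1]
            if total <= 0:
                continue
            for s in np.arange(0, total, 0.5):
                pts.append(pl.point_at(s))
                kinds.append(pl.kind)
        self.points = np.array(pts) if pts else np.empty((0, 2))
        self.kinds = kinds
        self.tree = cKDTree(self.points) if len(pts) else None

    def candidates(self, xy, radius):
        if self.tree is None:
            return []
        idx = self.tree.query_ball_point(xy, radius)
        out = [(float(np.hypot(*(self.points[i] - xy))), self.kinds[i], i) for i in idx]
        out.sort()
        return out


def _visibility_floor(morph: Optional[np.ndarray], k: float) -> float:
    if morph is None:
        return -np.inf  # no image: structures are taken at face value
    med = float(np.median(morph))
    mad = float(np.median(np.abs(morph - med)))
    return med + k * max(mad, 1e-12)


def assign_compartment(
    track: AggregateTrack,
    masks: CompartmentMasks | NeuronGeometry,
    config: Optional[AssignConfig] = None,
    index: Optional[_SkeletonIndex] = None,
) -> CompartmentCall:
    """Classify one track as axon / dendrite / soma / nucleus / unresolved.

    Pass a prebuilt ``index`` (see :func:`assign_all`) when classifying
    many tracks against the same geometry.
    """
    cfg = config or AssignConfig()
    if isinstance(masks, NeuronGeometry):
        masks = CompartmentMasks.from_geometry(masks)
    if not track.detections:
        raise ValueError(f"track {track.id} has no detections")
    idx = index or _SkeletonIndex(masks.skeletons)
    morph = masks.smoothed_morph(cfg.morph_smooth_sigma)
    floor = _visibility_floor(morph, cfg.visibility_k)
    Y, X = masks.soma_mask.shape

    evidence: list[FrameEvidence] = []
    for d in track.detections:
        xi, yi = int(round(d.x)), int(round(d.y))
        if not (0 <= xi < X and 0 <= yi < Y):
            continue
        # nuclear containment is judged at the plane of peak intensity,
        # not on the projection, to avoid out-of-plane overlap
        if masks.nucleus_mask[yi, xi]:
            z_ok = True
            if masks.somata:
                nearest = min(
                    masks.somata,
                    key=lambda s: float(np.hypot(s.center[0] - d.x, s.center[1] - d.y)),
                )
                z_ok = abs(d.z_best - nearest.z) <= cfg.z_tol
            if z_ok:
                evidence.append(FrameEvidence(d.frame, "nucleus", 0.0, np.nan))
                continue
        if masks.soma_mask[yi, xi]:
            evidence.append(FrameEvidence(d.frame, "soma", 0.0, np.nan))
            continue
        for dist, kind, pi in idx.candidates((d.x, d.y), cfg.d_assign):
            px, py = idx.points[pi]
            xi2, yi2 = int(round(px)), int(round(py))
            if not (0 <= xi2 < X and 0 <= yi2 < Y):
                continue
            inten = float(morph[yi2, xi2]) if morph is not None else np.inf
            if inten >= floor:
                evidence.append(FrameEvidence(d.frame, kind, dist, inten))
                break

    if not evidence:
        return CompartmentCall(track.id, "unresolved", 0.0, [])
    votes = pd.Series([e.structure for e in evidence]).value_counts()
    # deterministic tie-break: most votes, then fixed compartment order
    order = {k: i for i, k in enumerate(LABELS)}
    top = sorted(votes.items(), key=lambda kv: (-kv[1], order[kv[0]]))[0]
    support = top[1] / len(evidence)
    if support < cfg.f_min:
        return CompartmentCall(track.id, "unresolved", support, evidence)
    return CompartmentCall(track.id, top[0], support, evidence)


def assign_all(
    tracks: Sequence[AggregateTrack],
    masks: CompartmentMasks | NeuronGeometry,
    config: Optional[AssignConfig] = None,
) -> list[CompartmentCall]:
    if isinstance(masks, NeuronGeometry):
        masks = CompartmentMasks.from_geometry(masks)
    index = _SkeletonIndex(masks.skeletons)
    return [assign_compartment(t, masks, config, index) for t in tracks]


def calls_to_frame(calls: Sequence[CompartmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.track_id, c.label, c.confidence, c.n_frames_evidence) for c in calls],
        columns=["track_id", "label", "confidence", "n_frames_evidence"],
    )


def label_fractions(calls: Sequence[CompartmentCall]) -> dict[str, float]:
    """Fraction of tracks per compartment label (pie-chart data)."""
    n = max(len(calls), 1)
    return {lab: sum(c.label == lab for c in calls) / n for lab in LABELS}
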