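"""Synthetic neuron geometries and rendered multi-channel z-stack series.

Emulates the acquisition regime of long-term confocal imaging of cultured
cortical neurons: 640x480 px fields of view, 12-bit intensities, 12 focal
planes 0.8 um apart, frames every 1-2 h (5 min for bleach-recovery runs).
A morphology channel shows bright somatodendritic structures and faint
axons; reporter channels show a compartment-filling cytosolic signal plus
diffraction-limited puncta whose integrated intensity is proportional to
the aggregate-bound fluorescent amount from the kinetic model.  Noise is
Poisson (photon) plus Gaussian (read), then clipped and quantized to
12 bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import kinetics
from .kinetics import CellState, KineticParams, LabelSchedule, LabelEvent

MAX_DN = 4095  # 12-bit full scale

PROTOCOLS = ("longterm_WT", "longterm_KR", "pulsechase_WT", "pulsechase_KR", "frap")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class GeometryConfig:
    """Morphology-generation knobs (pixel units unless noted)."""

    fov_shape: tuple[int, int] = (480, 640)  # (Y, X)
    pixel_size: float = 0.3  # um / px
    n_neurons: int = 3
    soma_radius: float = 10.0
    nucleus_radius: float = 5.0
    n_dendrites: tuple[int, int] = (3, 5)  # inclusive range
    dendrite_length: tuple[float, float] = (40.0, 90.0)
    dendrite_width: float = 8.0
    n_axons: tuple[int, int] = (1, 2)
    n_bg_axons: int = 8  # axon segments of unseen neurons crossing the field
    axon_length: tuple[float, float] = (250.0, 600.0)
    axon_width: float = 1.1
    axon_visibility: float = 0.1  # morphology brightness of axons vs dendrites
    n_z: int = 12
    z_step: float = 0.8  # um
    margin: float = 20.0  # soma centers kept this far from the border

    def scaled(self, factor: float) -> "GeometryConfig":
        """Downscale the field of view (and length scales) for fast runs."""
        return replace(
            self,
            fov_shape=(int(self.fov_shape[0] * factor), int(self.fov_shape[1] * factor)),
            soma_radius=max(4.0, self.soma_radius * factor ** 0.5),
            nucleus_radius=max(2.0, self.nucleus_radius * factor ** 0.5),
            dendrite_length=tuple(v * factor for v in self.dendrite_length),
            axon_length=tuple(v * factor for v in self.axon_length),
            margin=max(8.0, self.margin * factor),
        )


@dataclass
class OpticsConfig:
    """Rendering and noise model."""

    sigma_xy: float = 1.3  # punctum lateral Gaussian sigma, px
    sigma_z: float = 0.8  # punctum axial sigma, z-planes
    punctum_gain: float = 6000.0  # photons per a.u. of bound reporter
    cyto_gain: float = 1.2  # photons/px per a.u. of cytosolic reporter
    morph_soma: float = 1500.0
    morph_nucleus: float = 900.0
    morph_dendrite: float = 900.0
    background: float = 50.0  # photons/px offset
    read_noise: float = 2.0  # DN, Gaussian sigma
    noise: bool = True
    motion_step: float = 1.5  # punctum random-walk step along skeleton, px per 2-h frame
    #                           (scaled by sqrt(frame_dt / 2 h): diffusive transport)
    soma_z_sigma: float = 1.5  # axial extent of somata, planes
    neurite_z_sigma: float = 0.8


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass
class Polyline:
    """One neurite skeleton: sampled points, z-plane, and kind."""

    points: np.ndarray  # (N, 2) float, (x, y) px
    z: float  # plane index (float, clamped to stack)
    kind: str  # 'axon' | 'dendrite'
    neuron: int
    exits_fov: bool = False

    def arclengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def point_at(self, s: float) -> np.ndarray:
        """Position at arclength ``s`` (clamped to the polyline)."""
        cum = self.arclengths()
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(cum) - 2)
        span = cum[i + 1] - cum[i]
        frac = 0.0 if span == 0 else (s - cum[i]) / span
        return self.points[i] + frac * (self.points[i + 1] - self.points[i])


@dataclass
class Soma:
    center: np.ndarray  # (x, y)
    z: float
    radius: float
    nucleus_radius: float


@dataclass
class NeuronGeometry:
    fov_shape: tuple[int, int]
    pixel_size: float
    n_z: int
    z_step: float
    nucleus_mask: np.ndarray
    soma_mask: np.ndarray
    dendrites: list[Polyline]
    axons: list[Polyline]
    somata: list[Soma]
    n_neurons: int
    axon_visibility: float = 0.1
    dendrite_width: float = 8.0
    axon_width: float = 1.1

    @property
    def skeletons(self) -> list[Polyline]:
        return self.dendrites + self.axons


def _disk_mask(shape, center_xy, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius ** 2


def _wander(rng, start, angle, length, step, jitter, shape, stop_at_border):
    """Random-walk polyline from ``start`` heading ``angle``."""
    pts = [np.asarray(start, dtype=float)]
    pos = pts[0].copy()
    traveled = 0.0
    exits = False
    while traveled < length:
        angle += rng.normal(0.0, jitter)
        pos = pos + step * np.array([math.cos(angle), math.sin(angle)])
        traveled += step
        inside = 0 <= pos[0] < shape[1] and 0 <= pos[1] < shape[0]
        if not inside:
            exits = True
            if stop_at_border:
                pts.append(pos.copy())
                break
            # dendrites bounce back into the field
            angle += math.pi / 2
            pos = np.clip(pos, [0, 0], [shape[1] - 1, shape[0] - 1])
        pts.append(pos.copy())
    return np.array(pts), exits


def make_geometry(seed, config: Optional[GeometryConfig] = None) -> NeuronGeometry:
    """Reproducible random neuron morphology for one field of view.

    Somata (with concentric nuclei) are placed away from the borders;
    dendrites radiate from each soma and stay in the field; axons are
    longer, thinner, straighter and frequently leave the field of view,
    mirroring the fact that a soma's axon may originate outside the
    imaged region.
    """
    cfg = config or GeometryConfig()
    rng = np.random.default_rng(seed)
    Y, X = cfg.fov_shape
    if cfg.n_neurons > 0:
        needed = cfg.n_neurons * (4 * cfg.soma_radius) ** 2
        if needed > Y * X:
            raise ValueError(
                f"field of view {cfg.fov_shape} too small for {cfg.n_neurons} neurons"
            )
    nucleus = np.zeros((Y, X), dtype=bool)
    soma = np.zeros((Y, X), dtype=bool)
    somata: list[Soma] = []
    dendrites: list[Polyline] = []
    axons: list[Polyline] = []

    for ni in range(cfg.n_neurons):
        m = cfg.margin
        for _attempt in range(200):
            center = np.array(
                [rng.uniform(m, X - m), rng.uniform(m, Y - m)]
            )
            if all(
                np.linalg.norm(center - s.center) > 3.5 * cfg.soma_radius
                for s in somata
            ):
                break
        z_soma = float(rng.uniform(cfg.n_z * 0.3, cfg.n_z * 0.7))
        somata.append(Soma(center, z_soma, cfg.soma_radius, cfg.nucleus_radius))
        soma |= _disk_mask((Y, X), center, cfg.soma_radius)
        nucleus |= _disk_mask((Y, X), center, cfg.nucleus_radius)

        n_den = rng.integers(cfg.n_dendrites[0], cfg.n_dendrites[1] + 1)
        base = rng.uniform(0, 2 * math.pi)
        for d in range(n_den):
            ang = base + 2 * math.pi * d / n_den + rng.normal(0, 0.3)
            start = center + cfg.soma_radius * np.array([math.cos(ang), math.sin(ang)])
            length = rng.uniform(*cfg.dendrite_length)
            pts, _ = _wander(rng, start, ang, length, 4.0, 0.25, (Y, X), False)
            z = float(np.clip(z_soma + rng.normal(0, 1.0), 0, cfg.n_z - 1))
            dendrites.append(Polyline(pts, z, "dendrite", ni))

        n_ax = rng.integers(cfg.n_axons[0], cfg.n_axons[1] + 1)
        for _a in range(n_ax):
            ang = rng.uniform(0, 2 * math.pi)
            start = center + cfg.soma_radius * np.array([math.cos(ang), math.sin(ang)])
            length = rng.uniform(*cfg.axon_length)
            pts, exits = _wander(rng, start, ang, length, 4.0, 0.12, (Y, X), True)
            z = float(np.clip(z_soma + rng.normal(0, 1.5), 0, cfg.n_z - 1))
            axons.append(Polyline(pts, z, "axon", ni, exits_fov=exits))

    # remote axonal segments of neurons outside the field: they enter at
    # one border and usually leave at another
    if cfg.n_neurons > 0:
        for _b in range(cfg.n_bg_axons):
            side = rng.integers(4)
            if side == 0:
                start, ang = [rng.uniform(0, X - 1), 0.0], math.pi / 2
            elif side == 1:
                start, ang = [rng.uniform(0, X - 1), Y - 1.0], -math.pi / 2
            elif side == 2:
                start, ang = [0.0, rng.uniform(0, Y - 1)], 0.0
            else:
                start, ang = [X - 1.0, rng.uniform(0, Y - 1)], math.pi
            ang += rng.uniform(-0.6, 0.6)
            length = rng.uniform(*cfg.axon_length)
            pts, exits = _wander(rng, start, ang, length, 4.0, 0.12, (Y, X), True)
            z = float(rng.uniform(0, cfg.n_z - 1))
            axons.append(Polyline(pts, z, "axon", -1, exits_fov=True))

    return NeuronGeometry(
        fov_shape=(Y, X),
        pixel_size=cfg.pixel_size,
        n_z=cfg.n_z,
        z_step=cfg.z_step,
        nucleus_mask=nucleus,
        soma_mask=soma,
        dendrites=dendrites,
        axons=axons,
        somata=somata,
        n_neurons=cfg.n_neurons,
        axon_visibility=cfg.axon_visibility,
        dendrite_width=cfg.dendrite_width,
        axon_width=cfg.axon_width,
    )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ImageSeries:
    """T x C x Z x Y x X intensity data plus physical metadata."""

    data: np.ndarray  # uint16, values within [0, 4095]
    dt: float  # h between frames
    z_step: float  # um
    pixel_size: float  # um / px
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("data must be 5-D (T, C, Z, Y, X)")
        if self.data.shape[0] < 1:
            raise ValueError("series needs at least one frame")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match data's channel axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def channel(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in series (have {self.channel_names})"
            )


@dataclass
class GroundTruth:
    """Per-frame aggregate positions/contents and cytosolic amounts."""

    aggregates: pd.DataFrame  # frame, time_h, aggregate_id, x, y, z, compartment,
    #                           amount_<label>..., amount_fluor, saturated
    cytosol: pd.DataFrame  # frame, time_h, label, amount

    def count_at(self, frame: int) -> int:
        df = self.aggregates
        return int((df["frame"] == frame).sum())


class SimulationResult(NamedTuple):
    series: ImageSeries
    truth: GroundTruth
    geometry: NeuronGeometry
    states: list[CellState]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _rasterize_polyline(shape, pline: Polyline, width: float) -> np.ndarray:
    """Smooth 2-D tube image of a polyline, peak height ~1."""
    canvas = np.zeros(shape, dtype=float)
    pts = pline.points
    cum = pline.arclengths()
    total = cum[-1]
    if total <= 0:
        return canvas
    n_samples = max(2, int(total / 0.5))
    for s in np.linspace(0, total, n_samples):
        x, y = pline.point_at(s)
        xi, yi = int(round(x)), int(round(y))
        if 0 <= yi < shape[0] and 0 <= xi < shape[1]:
            canvas[yi, xi] = 1.0
    sigma = max(width / 2.0, 0.5)
    canvas = ndimage.gaussian_filter(canvas, sigma)
    peak = canvas.max()
    return canvas / peak if peak > 0 else canvas


def _z_profile(n_z: int, z_center: float, sigma: float) -> np.ndarray:
    z = np.arange(n_z, dtype=float)
    return np.exp(-0.5 * ((z - z_center) / sigma) ** 2)


class _StaticTemplates:
    """Per-geometry morphology and cytosol-occupancy volumes (render once)."""

    def __init__(self, geom: NeuronGeometry, optics: OpticsConfig):
        Y, X = geom.fov_shape
        n_z = geom.n_z
        morph = np.zeros((n_z, Y, X), dtype=float)
        cyto = np.zeros((n_z, Y, X), dtype=float)

        for s in geom.somata:
            # generous smoothing: real somata have no crisp pixel edges
            disk = ndimage.gaussian_filter(
                _disk_mask((Y, X), s.center, s.radius).astype(float), 2.5
            )
            nuc = ndimage.gaussian_filter(
                _disk_mask((Y, X), s.center, s.nucleus_radius).astype(float), 2.0
            )
            zp = _z_profile(n_z, s.z, optics.soma_z_sigma)
            body = optics.morph_soma * disk + (optics.morph_nucleus - optics.morph_soma) * nuc
            morph += zp[:, None, None] * body[None, :, :]
            # cytosolic reporter fills the soma; nuclei carry about half
            occ = disk - 0.5 * nuc
            cyto += zp[:, None, None] * occ[None, :, :]

        for pline in geom.dendrites:
            tube = _rasterize_polyline((Y, X), pline, geom.dendrite_width)
            zp = _z_profile(n_z, pline.z, optics.neurite_z_sigma)
            morph += optics.morph_dendrite * zp[:, None, None] * tube[None, :, :]
            cyto += zp[:, None, None] * tube[None, :, :]

        for pline in geom.axons:
            tube = _rasterize_polyline((Y, X), pline, geom.axon_width)
            zp = _z_profile(n_z, pline.z, optics.neurite_z_sigma)
            w = geom.axon_visibility
            morph += optics.morph_dendrite * w * zp[:, None, None] * tube[None, :, :]
            cyto += w * zp[:, None, None] * tube[None, :, :]

        self.morph = morph
        self.cyto = cyto  # occupancy, multiplied by cyto_gain * c(t) per frame


def _add_punctum(vol, x, y, z, photons, sxy, sz):
    """Add a 3-D Gaussian with integrated intensity ``photons`` to ``vol``."""
    n_z, Y, X = vol.shape
    r = int(math.ceil(4 * sxy))
    x0, x1 = max(0, int(x) - r), min(X, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(Y, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    zs = np.arange(n_z, dtype=float)
    gx = np.exp(-0.5 * ((xs - x) / sxy) ** 2)
    gy = np.exp(-0.5 * ((ys - y) / sxy) ** 2)
    gz = np.exp(-0.5 * ((zs - z) / sz) ** 2)
    norm = photons / ((2 * math.pi) ** 1.5 * sxy * sxy * sz)
    vol[:, y0:y1, x0:x1] += norm * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


class _PunctumPosition:
    """Aggregate position state: host structure plus random-walk coordinate."""

    def __init__(self, geom, agg, rng):
        self.compartment = agg.compartment
        self.geom = geom
        if agg.compartment in ("axon", "dendrite"):
            pool = geom.axons if agg.compartment == "axon" else geom.dendrites
            if not pool:  # fall back to soma placement on bare geometries
                self.compartment = "soma"
            else:
                # hosts weighted by in-field arclength, so short stubs do
                # not accumulate a disproportionate share of aggregates
                Y, X = geom.fov_shape
                weights = []
                for pl in pool:
                    pts = pl.points
                    inside = ((pts[:, 0] >= 2) & (pts[:, 0] < X - 2)
                              & (pts[:, 1] >= 2) & (pts[:, 1] < Y - 2))
                    weights.append(max(inside.sum(), 1))
                w = np.asarray(weights, dtype=float)
                self.host = pool[rng.choice(len(pool), p=w / w.sum())]
                cum = self.host.arclengths()
                for _ in range(60):
                    self.s = rng.uniform(0, cum[-1])
                    x, y = self.host.point_at(self.s)
                    if 2 <= x < X - 2 and 2 <= y < Y - 2:
                        break
                self.z = float(np.clip(self.host.z + rng.normal(0, 0.3), 0, geom.n_z - 1))
                return
        soma = geom.somata[rng.integers(len(geom.somata))] if geom.somata else None
        if soma is None:
            Y, X = geom.fov_shape
            self.xy = np.array([rng.uniform(2, X - 2), rng.uniform(2, Y - 2)])
            self.z = float(geom.n_z // 2)
            return
        r = soma.nucleus_radius if self.compartment == "nucleus" else soma.radius
        rad = (soma.radius * 0.55 + 0.35 * soma.nucleus_radius
               ) if self.compartment == "soma" else r * 0.6
        ang = rng.uniform(0, 2 * math.pi)
        rho = rad * math.sqrt(rng.uniform())
        if self.compartment == "soma":
            # keep somatic puncta out of the nucleus
            rho = soma.nucleus_radius + (soma.radius - soma.nucleus_radius) * 0.7 * rng.uniform()
        self.xy = soma.center + rho * np.array([math.cos(ang), math.sin(ang)])
        self.z = soma.z

    def step(self, rng, step_px):
        if hasattr(self, "host"):
            total = float(self.host.arclengths()[-1])
            Y, X = self.geom.fov_shape
            for _ in range(12):
                cand = self.s + rng.normal(0, step_px)
                # reflect at both polyline ends
                if total > 0:
                    cand = math.fmod(cand, 2 * total)
                    if cand < 0:
                        cand += 2 * total
                    if cand > total:
                        cand = 2 * total - cand
                else:
                    cand = 0.0
                x, y = self.host.point_at(cand)
                if 1 <= x < X - 1 and 1 <= y < Y - 1:
                    self.s = cand
                    break
        else:
            self.xy = self.xy + rng.normal(0, step_px * 0.2, size=2)

    @property
    def position(self) -> tuple[float, float, float]:
        if hasattr(self, "host"):
            x, y = self.host.point_at(self.s)
        else:
            x, y = self.xy
        return float(x), float(y), float(self.z)


def render_series(
    states: Sequence[CellState],
    geom: NeuronGeometry,
    optics: Optional[OpticsConfig] = None,
    seed: int | np.random.Generator = 0,
    frame_dt: Optional[float] = None,
    channels: Optional[list[str]] = None,
) -> tuple[ImageSeries, GroundTruth]:
    """Render a kinetic trajectory into a noisy 12-bit image series.

    Channels are ``morph`` (static morphology marker) plus one channel per
    fluorescent label present.  Aggregates are 3-D Gaussian puncta whose
    integrated photon count is ``punctum_gain`` times the bound fluorescent
    amount; the cytosolic pool fills the somatodendritic occupancy map
    (axons at the visibility ratio).  Aggregates move along their host
    skeleton as a reflected random walk.
    """
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if channels is None:
        present = set()
        for st in states:
            for lab in kinetics.FLUORESCENT_LABELS:
                if st.c[lab] > 0 or any(a.a[lab] > 0 for a in st.aggregates):
                    present.add(lab)
        channels = ["morph"] + [lab for lab in kinetics.FLUORESCENT_LABELS if lab in present]
        if len(channels) == 1:
            channels.append("L1")
    for ch in channels:
        if ch != "morph" and ch not in kinetics.FLUORESCENT_LABELS:
            raise ValueError(f"requested channel {ch!r} is not a fluorescent label")

    if frame_dt is None:
        frame_dt = states[1].t - states[0].t if len(states) > 1 else 1.0
    Y, X = geom.fov_shape
    n_z = geom.n_z
    T, C = len(states), len(channels)
    tmpl = _StaticTemplates(geom, optics)

    data = np.empty((T, C, n_z, Y, X), dtype=np.uint16)
    positions: dict[int, _PunctumPosition] = {}
    agg_rows = []
    cyto_rows = []

    step_px = optics.motion_step * math.sqrt(frame_dt / 2.0)
    for ti, st in enumerate(states):
        # advance / create punctum positions
        for agg in st.aggregates:
            if agg.id not in positions:
                positions[agg.id] = _PunctumPosition(geom, agg, rng)
            elif ti > 0:
                positions[agg.id].step(rng, step_px)

        for ci, ch in enumerate(channels):
            if ch == "morph":
                vol = tmpl.morph.copy()
            else:
                vol = tmpl.cyto * (optics.cyto_gain * st.c[ch])
                for agg in st.aggregates:
                    amt = agg.a[ch]
                    if amt <= 0:
                        continue
                    x, y, z = positions[agg.id].position
                    _add_punctum(
                        vol, x, y, z, optics.punctum_gain * amt,
                        optics.sigma_xy, optics.sigma_z,
                    )
            vol = vol + optics.background
            if optics.noise:
                vol = rng.poisson(vol).astype(float)
                if optics.read_noise > 0:
                    vol += rng.normal(0.0, optics.read_noise, size=vol.shape)
            elif optics.background == 0 and optics.read_noise == 0:
                pass
            np.clip(vol, 0, MAX_DN, out=vol)
            data[ti, ci] = np.round(vol).astype(np.uint16)

        for agg in st.aggregates:
            x, y, z = positions[agg.id].position
            xi, yi, zi = int(round(x)), int(round(y)), int(round(z))
            sat = False
            for ci, ch in enumerate(channels):
                if ch == "morph":
                    continue
                if 0 <= yi < Y and 0 <= xi < X:
                    sat = sat or data[ti, ci, zi, yi, xi] >= MAX_DN
            row = {
                "frame": ti,
                "time_h": st.t,
                "aggregate_id": agg.id,
                "x": x,
                "y": y,
                "z": z,
                "compartment": agg.compartment,
                "saturated": sat,
            }
            for lab in kinetics.LABELS:
                row[f"amount_{lab}"] = agg.a[lab]
            row["amount_fluor"] = agg.fluorescent()
            agg_rows.append(row)
        for lab in kinetics.LABELS:
            cyto_rows.append(
                {"frame": ti, "time_h": st.t, "label": lab, "amount": st.c[lab]}
            )

    agg_cols = ["frame", "time_h", "aggregate_id", "x", "y", "z", "compartment",
                "saturated"] + [f"amount_{lab}" for lab in kinetics.LABELS] + ["amount_fluor"]
    truth = GroundTruth(
        aggregates=pd.DataFrame(agg_rows, columns=agg_cols),
        cytosol=pd.DataFrame(cyto_rows, columns=["frame", "time_h", "label", "amount"]),
    )
    series = ImageSeries(
        data=data,
        dt=frame_dt,
        z_step=geom.z_step,
        pixel_size=geom.pixel_size,
        channel_names=list(channels),
    )
    return series, truth


# ---------------------------------------------------------------------------
# experiment protocols
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """End-to-end simulation settings for one field of view."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    horizon: Optional[float] = None  # h; protocol default when None
    frame_dt: Optional[float] = None  # h; protocol default when None
    burn_in: float = 48.0  # pulse-chase: kinetics time before the first ligand
    render_burn_in: float = 0.0  # longterm: kinetics time elapsed before frame 0
    frap_burn_in: float = 96.0  # frap: aggregate maturation time before bleaching
    frap_bleach_time: float = 1.0 / 6.0  # h after series start
    frap_max_bleached: int = 8
    preset: Optional[KineticParams] = None  # override the protocol's preset


def simulate_experiment(
    protocol: str, config: Optional[SimConfig] = None, seed: int = 0
) -> SimulationResult:
    """Simulate one field of view of a named experimental protocol.

    ``longterm_*``: constitutively fluorescent reporter imaged every 2 h
    for 12 days.  ``pulsechase_*``: sequential-labeling schedule (first
    ligand at series start, blocker 1 h later, persistent second ligand at
    5 h) imaged every 1.5 h for 72 h after a 48 h expression burn-in.
    ``frap``: 5-min frames over 5 h; all (up to ``frap_max_bleached``)
    existing aggregates are photobleached shortly after the series starts.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; valid: {PROTOCOLS}")
    cfg = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    rng_kin, rng_geom, rng_render = [np.random.default_rng(s) for s in ss.spawn(3)]

    geom = make_geometry(rng_geom, cfg.geometry)
    preset_name = "KR" if protocol.endswith("_KR") else "WT"
    params = cfg.preset or kinetics.get_preset(preset_name)

    if protocol.startswith("longterm"):
        horizon = cfg.horizon if cfg.horizon is not None else 288.0
        frame_dt = cfg.frame_dt if cfg.frame_dt is not None else 2.0
        states = kinetics.simulate_trajectory(
            params, horizon, frame_dt, rng_kin, initial_label="L1",
            burn_in=cfg.render_burn_in,
        )
    elif protocol.startswith("pulsechase"):
        horizon = cfg.horizon if cfg.horizon is not None else 72.0
        frame_dt = cfg.frame_dt if cfg.frame_dt is not None else 1.5
        schedule = LabelSchedule.pulse_chase(0.0, 1.0, 5.0)
        states = kinetics.simulate_trajectory(
            params, horizon, frame_dt, rng_kin,
            schedule=schedule, burn_in=cfg.burn_in, initial_label="dark",
        )
    else:  # frap
        horizon = cfg.horizon if cfg.horizon is not None else 5.0
        frame_dt = cfg.frame_dt if cfg.frame_dt is not None else 5.0 / 60.0
        # mature the cell first so there are aggregates to bleach
        pre = kinetics.simulate_trajectory(
            params, cfg.frap_burn_in, cfg.frap_burn_in, rng_kin, initial_label="L1"
        )
        state = pre[-1]
        state.t = 0.0
        by_content = sorted(state.aggregates, key=lambda a: -a.fluorescent())
        ids = tuple(a.id for a in by_content[: cfg.frap_max_bleached])
        schedule = LabelSchedule(
            (LabelEvent(cfg.frap_bleach_time, "bleach", aggregate_ids=ids),)
        ) if ids else None
        states = kinetics.simulate_trajectory(
            params, horizon, frame_dt, rng_kin, schedule=schedule, state=state
        )

    series, truth = render_series(
        states, geom, cfg.optics, rng_render, frame_dt=frame_dt
    )
    return SimulationResult(series, truth, geom, states)
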