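# Methods

## The sequestration model

`aggretrack.kinetics` models one neuron (equivalently, one imaged field
containing a small group of neurons) as a well-mixed cytosolic reporter
pool exchanging material with a set of discrete aggregates.  Per label
`x` (see *Label bookkeeping* below):

    dc_x/dt    = s·1[x = synthesis label] − k_deg·c_x
                 − n_agg·k_on·c_x + k_off·Σ_i a_{i,x}
    da_{i,x}/dt = k_on·c_x − (k_off + k_deg_agg)·a_{i,x}

New aggregates appear as a Poisson process with rate
`k_nuc · max(0, c_total − c_nuc)`: visible puncta nucleate only while the
cytosolic concentration exceeds a threshold, and each newborn aggregate
starts empty and fills by association.

The three loss routes have distinct roles:

* `k_deg` — ordinary cytosolic turnover of the reporter;
* `k_off` — dissociation back to the cytosol.  Exchange alone makes an
  aggregate a *buffer*, not a sink: at steady state it returns exactly
  what it takes;
* `k_deg_agg` — slow degradation of aggregate-bound material that never
  returns.  This term makes aggregates net sinks, so the steady-state
  cytosolic level decreases with aggregate number,
  `c* = s / (k_deg + n·k_on·(1 − k_off/(k_off+k_deg_agg)))`,
  and it is what lets sustained sequestration depress cytosolic levels.

A fully bleached aggregate in a constant fluorescent cytosol refills as
`f(t) = f_∞(1 − e^{−(k_off+k_deg_agg)t})`, so the fluorescence-recovery
time constant is `τ = 1/(k_off + k_deg_agg)`.  With no exchange
(`k_off = k_deg_agg = 0`) recovery is identically zero — a permanent
deposit.

### Parameters and presets

All amounts are in arbitrary units (a.u.), times in hours.  Two presets
are shipped:

| parameter | WT | KR | meaning |
|---|---|---|---|
| `s` | 1.0 | 1.0 | synthesis rate (a.u./h) |
| `k_deg` | 0.003 | 0.003 | cytosolic degradation (1/h) |
| `k_nuc` | 0.02 | 0.002 | nucleation propensity (events/h per a.u. excess) |
| `c_nuc` | 110 | 110 | nucleation threshold (a.u.) |
| `k_on` | 0.001 | 0.001 | per-aggregate association (1/h) |
| `k_off` | 0.0951 | 0 | per-aggregate dissociation (1/h) |
| `k_deg_agg` | 0.016 | 0 | bound-pool degradation (1/h) |
| `placement` | axon .83 / dendrite .09 / soma .08 | nucleus .5 / soma .2 / axon .2 / dendrite .1 | compartment of newborn aggregates |
| `c0` | 80 | 80 | cytosolic amount at imaging start (a.u.) |
| `block_freezes_uptake` | no | yes | blocker event permanently stops uptake |

The WT preset is calibrated so that, per field of view: the FRAP time
constant is 9 h; aggregate counts reach ≈30 by hour 144 and ≈45 by hour
288; the old-ligand content of aggregates present at a pulse-chase
labeling (48 h into the run) peaks ≈27–30 h after labeling; and the
cytosolic trace rises ≈1.6× before declining well below its peak.  The
KR preset reduces nucleation (≈5 aggregates per field at day 6), places
half of the aggregates in nuclei, and abolishes exchange, so aggregates
are permanent deposits and never acquire the second pulse-chase ligand.
`k_on` and `c_nuc` are individually degenerate against these composite
observables — only products and ratios are constrained — so the preset
values are a documented choice, not an inference.

The calibration lives in a single dynamical regime: `c0 < c_nuc`, so the
cytosol rises for ≈35 h before nucleation begins; the aggregate number
then overshoots its equilibrium while the cytosol turns over and decays
back toward the threshold.  This yields near-linear count growth over
days (the property the long-term experiments show), a young —
far-from-equilibrium — aggregate cohort at the pulse-chase labeling
time (which is what makes the old-label trace rise for tens of hours
despite a 9 h exchange constant), and a late cytosolic decline.

**Known limitation.** Because nucleation pins the late cytosol near
`c_nuc`, and a delayed onset requires `c_nuc > c0`, this one-compartment
model cannot make the late cytosol fall below its *initial* value while
simultaneously matching the printed counts and the ~30 h old-label
peak.  The suite therefore asserts a strong decline from peak (final
< 90% of maximum over 440 h) rather than a drop below the t = 0 level.
Reproducing the deeper drop would need an extension such as aggregate
uptake capacity growing with aggregate mass.

### Label bookkeeping

Labels track covalent pulse-chase chemistry and photobleaching:
`dark` (no fluorophore yet), `L1` (first ligand), `blocked`
(non-fluorescent blocker), `L2` (second ligand), `bleached`
(photodestroyed fluorophore; mass stays in place and keeps exchanging).
Label events are instantaneous conversions of the `dark` pool; a
*persistent* ligand (the second one, left in the medium) additionally
redirects synthesis so later-made protein is born labeled.  A `block`
resets synthesis to `dark`.  In the KR preset a block also freezes
uptake (`k_on → 0`), which is what keeps aggregate-bound `L2` exactly
zero in pulse-chase runs.

### Integration

Fixed-step explicit RK4 with substeps ≤ 0.05 h; nucleation by thinning
(Poisson draw per substep at the substep's starting rate).  The system
is far from stiff at these rates; the fixed step gives bit-reproducible
trajectories per seed.  A step producing a negative amount raises
(never silently clipped).  A deterministic mean-field variant
(`mean_field_trajectory`) integrates expected aggregate number and
pooled contents, optionally split into cohorts born before/after a
given time — the pre-existing cohort's per-aggregate trace is the
deterministic analogue of following individual aggregates from a
labeling event.

## Synthetic time-lapse generator

`aggretrack.synthgen` renders trajectories into 5-D (T×C×Z×Y×X) 12-bit
series mimicking the acquisition regime of long-term confocal imaging:
640×480 px fields, 12 planes 0.8 µm apart, 2 h frames (1.5 h for
pulse-chase, 5 min for bleach-recovery).  Geometry: somata with
concentric nuclei, wiggly in-field dendrites, long thin axons that
leave the field, plus axon segments of unseen neurons entering at the
borders.  Channels: a static morphology marker (somatodendritic bright,
axons at a configurable visibility ratio, default 0.1 — the classifier
must face genuinely faint axons) and one channel per fluorescent label
(compartment-filling cytosolic signal plus 3-D Gaussian puncta whose
integrated intensity is proportional to bound amount).  Noise: Poisson
on the photon signal plus Gaussian read noise, then clipped and
quantized to [0, 4095].  Aggregates move along their host skeleton as a
reflected random walk with diffusive time scaling (step ∝ √frame
interval); somatic/nuclear puncta jitter in place.  Ground-truth tables
(per-frame positions, per-label contents, compartments, saturation
flags) are emitted alongside every render.

What the generator does **not** emulate: real point-spread functions
(Gaussian only), focal drift, photobleaching of the morphology channel,
cell death, extracellular deposits, aggregate splitting, and true
anatomical variety of neurites.  Passing the recovery targets therefore
shows the analysis stages are unbiased against data with known truth
and realistic noise/clutter — not that they would be unbiased against
every real-microscope artifact.

## Detection and tracking

Detection operates per frame on maximum-intensity projections with
identical parameters across a series: difference-of-Gaussians at the
spot scale (σ = 1.3 px), local maxima (min distance 3 px), and a
threshold that is the pointwise maximum of (i) the global background
median + 8·MAD of the band-passed image, (ii) a local Poisson gate —
5 × the band-pass noise gain × √(local mean) — and (iii) a relative
floor of 0.2 × the local signal above background, which rejects
varicosity-like texture and crossing-point bumps of bright cytosolic
neurites.  An isotropy (Hessian ratio) gate rejects ridge responses.
Sub-pixel positions come from a center-of-mass refinement; each
detection records its best-focus plane.

Linking is per-frame-pair global assignment (Hungarian) with a hard
displacement gate (15 px/frame-step) and gap closing (≤ 2 missed
frames); unmatched detections seed tracks; a freshly stranded track
adjacent to a matched detection is recorded as a merge event.  Ties are
resolved deterministically.  Tracks shorter than 5 detections are
dropped by the pipeline before quantification.

## Quantification

ROI means use pixel-center-in-disk containment (radius 4 px default);
cytosolic traces reuse one region mask across frames with detected
puncta (dilated 2 px) excluded.  Optional punctum photometry subtracts
the median of a local annulus.  For the question "does this punctum
carry a given label at all", the pipeline instead reads the spot-scale
band-pass response at the track position — proportional to bound
amount but blind to smooth cytosolic background, which otherwise
contaminates second-ligand calls near labeled cell bodies.  Count
curves report concurrently open tracks (gap frames count as present).
Traces are normalized to their first time point; re-normalizing or a
near-zero reference is an error.

## Compartment classification

Per frame of each track: nucleus if inside a nucleus mask with the
detection's best-focus plane within 1.5 planes of that soma's plane
(projection overlap alone never makes a nuclear call); else soma by
mask; else the nearest skeleton within 3 px whose locally smoothed
morphology intensity clears a visibility floor (background median +
4·MAD of the smoothed morphology image — single pixels are too noisy to
judge visibility).  The final label is a majority vote over evidence
frames, requiring ≥ 60% support, else `unresolved`; a structure that is
invisible yields no evidence, so invisible axons produce `unresolved`
calls rather than dendrite mislabels.  Calls are invariant under frame
reversal by construction.

## Turnover readouts

FRAP traces are fit by least squares to
`F(t) = F_∞ − (F_∞ − F0)·e^{−(t−t_b)/τ}` over post-bleach samples
(≥ 5 required); flat traces and optimizer failures report
`converged = False` rather than raising.  The mobile fraction is
`(F_∞ − F0)/(F_pre − F0)`.  Because averaging before or after fitting
weighs heterogeneity differently, summaries report both the median of
per-trace constants and the constant of the mean trace.  Pulse-chase
metrics: peak time of the 3-frame-smoothed old trace, post-peak
log-linear decay rate, and a new-label flag comparing the final
smoothed value against the pre-addition baseline median plus k times a
robust noise scale (k = 3 for model traces; k = 5 for image traces,
whose noise estimate comes from frame-to-frame differences).

## Problem sizes used by the recovery targets

The packaged recovery runs use reduced rasters chosen to keep the whole
set in a few minutes on one CPU while preserving per-field kinetics:
axonal-fraction recovery renders 12 fields at 448×336 px, 4 planes, 8
frames at the day-6 state (~350 tracked aggregates); count recovery
renders 8 fields per genotype at 448×336 px, 4 planes, 145 frames
(2 h × 12 days).  A reduced raster compresses one full field's neuron
population, so per-field counts are already full-field equivalents.
The FRAP target fits 35 model-generated traces (5-min sampling, 5 h,
5% multiplicative noise); the pulse-chase peak target is a
deterministic mean-field run sampled every 1.5 h.
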