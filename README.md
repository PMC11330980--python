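# aggretrack

Simulation and quantitative analysis of polyglutamine-expanded
huntingtin (mHtt exon-1 reporter) aggregation in long-term neuronal
time-lapse microscopy.

In cultured cortical neurons expressing an aggregation-prone polyQ
reporter, micron-scale aggregates appear over days — mostly in axons —
while the cytosolic reporter level first rises and then falls as
material is sequestered.  Pulse-chase labeling shows aggregates
continually lose old reporter copies and gain newly synthesized ones;
photobleaching recovers with a time constant of hours.  A
ubiquitination-deficient variant (K6,9R) instead forms few, largely
nuclear, non-exchanging deposits.  `aggretrack` packages both sides of
the analysis problem:

* an explicit **cytosol ⇄ aggregate exchange model** with pulse-chase
  label bookkeeping.  Per label x:
  `dc_x/dt = s·1[x=syn] − k_deg c_x − n·k_on c_x + k_off Σᵢ a_{i,x}`,
  `da_{i,x}/dt = k_on c_x − (k_off + k_deg,agg) a_{i,x}`, with Poisson
  nucleation at rate `k_nuc · max(0, c_tot − c_nuc)`.  A bleached
  aggregate recovers fluorescence with τ = 1/(k_off + k_deg,agg);
  calibrated presets `WT` (τ = 9 h, axon-dominated placement) and `KR`
  (no exchange, nucleus-biased) are included;
* a **synthetic time-lapse generator** that renders trajectories into
  noisy 12-bit, multi-channel z-stack series (640×480 px, 12 planes,
  Poisson + read noise) with full ground truth;
* the **analysis pipeline**: maximum-intensity projection, punctum
  detection (band-pass + robust local thresholds), track linking
  (optimal assignment with gap closing), ROI/cytosol trace
  quantification and t=0 normalization, per-field count curves,
  axon/dendrite/soma/nucleus compartment classification, FRAP
  single-exponential fitting, and pulse-chase old/new-label summaries.

Because every stage can be exercised against rendered data with known
truth, the package doubles as a test bed for punctum analysis at
realistic noise and clutter.

## Worked example

Simulate a reduced-scale long-term wild-type experiment (12 days, 2-h
frames) and run the full pipeline on the rendered images:

```sh
aggretrack run-all --protocol longterm_WT --seed 7 \
    --output-dir demo --fov-scale 0.5 --n-z 4 --n-neurons 3
```

prints (abridged):

```json
{
  "protocol": "longterm_WT",
  "seed": 7,
  "n_tracks": 56,
  "count_day6": 24,
  "count_day12": 33,
  "compartment_fractions": {
    "axon": 0.875,
    "dendrite": 0.071,
    "soma": 0.018,
    "nucleus": 0.018,
    "unresolved": 0.018
  },
  "axonal_fraction": 0.875
}
```

Reading this: the detector/tracker followed 56 aggregates over the run;
24 were concurrently present at day 6 and 33 at day 12 of this
particular field (per-field counts are Poisson-variable around the
preset's expectation of ≈30 and ≈45); and 87.5% of tracked aggregates
were classified as axonal, consistent with the preset's axon-dominated
placement.  The output directory holds the rendered OME-TIFF, ground
truth, tidy CSVs (tracks, traces, counts, compartment calls) and
`summary.json`.

The same stages are available as a library:

```python
from aggretrack import kinetics, synthgen, detect_track

params = kinetics.get_preset("WT")
print(1 / params.exchange_rate)        # 9.0009... h recovery constant
res = synthgen.simulate_experiment("pulsechase_WT", seed=1)
dets = detect_track.detect_series(res.series, "L1")
```

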