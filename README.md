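# placeremap

Analysis pipeline for place-cell remapping in light/dark/light (L1/D/L2)
open-field experiments, plus a fully seeded synthetic-data generator that
emulates the experiment so every stage of the analysis can be validated
without animal recordings.

Place cells fire when the animal occupies a specific location (the place
field).  When visual input is removed, claustral place fields shift to a new
location and return when the light comes back; this package quantifies that
remapping and the accompanying firing-rate and LFP changes.

## What it computes

Given per-session trajectories, spike trains, and LFP traces:

* **Rate maps** — binned occupancy, spike counts, and firing rate over the
  arena (default 2.5 cm bins, mask-aware 3×3 boxcar smoothing, bins with
  < 0.1 s occupancy excluded).
* **Place fields and their centre of mass (COM)** — largest 4-connected
  component above a fraction of the peak rate; COM is the rate-weighted mean
  of the field's bin centres.
* **Remapping geometry** — per unit with a field in all three sessions:

  - the **L1DL2 angle** at the dark-session centroid,
    `θ = arccos[ (D→L1 · D→L2) / (‖D→L1‖ ‖D→L2‖) ]`,
  - the pairwise COM distances `Δ = √((x_b−x_a)² + (y_b−y_a)²)` for
    L1–D, L1–L2, and D–L2,

  with cohort mean ± SEM.
* **Spatial statistics** — Skaggs spatial information
  `I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)` in bits/spike, and spatial coherence
  (Pearson correlation between each bin's raw rate and the mean of its
  valid 3×3 neighbours).
* **Unit metrics and classification** — waveform amplitude (first positive
  minus first negative peak, µV) and width (between the 25 %-amplitude
  crossings, µs); mean rate and ISI; burst detection (runs of spikes with
  ISIs ≤ 6 ms, events merged when separated by < 50 ms).  Units are place
  cells when information ≥ 0.5 bits/spike, coherence ≥ 0.25, mean rate
  ≥ 0.25 Hz, and a field is present; otherwise bursting cells when burst
  propensity and rate are high.
* **LFP band power** — Welch periodogram (2 s Hamming windows, 50 %
  overlap) integrated with Simpson's rule over delta 1.5–4 Hz, theta
  5–11 Hz, and gamma 30–90 Hz; relative power divides by the 1.5–90 Hz
  total.
* **Paired statistics** — two-tailed paired t or Wilcoxon signed-rank
  (chosen by a Shapiro normality gate on the differences) for every metric
  across L1 vs D, D vs L2, and L1 vs L2.

The synthetic generator produces three 10-minute sessions in an
80 × 80 cm arena: a smoothed-random-walk trajectory at ~10 cm/s, Gaussian
place fields whose dark-session COM is displaced by a configurable distance
and angle (defaults 12.75 cm, 50°), firing scaled to 0.65× in darkness,
~3 Hz bursting cells, and LFP with configurable delta/theta/gamma
composition — all deterministic given a seed, with the ground truth written
to a manifest.

## Worked example

```python
import placeremap as pr

config = pr.ExperimentConfig(n_place_cells=20, duration=600.0, n_lfp_channels=1)
experiment = pr.generate_ldl_experiment(config, seed=1)
report = pr.run_ldl_analysis(experiment.sessions)

r = report.remap
print(f"units with a field in all three sessions: {r.n}")
print(f"L1DL2 angle: {r.mean_angle:.2f} +/- {r.sem_angle:.2f} deg (true 50.0)")
print(f"d(L1,D):  {r.mean_d_l1d:.2f} +/- {r.sem_d_l1d:.2f} cm (true 12.75)")
rates = report.unit_metrics.groupby("session")["rate_hz"].mean()
print(f"mean rate L1/D/L2: {rates['L1']:.3f} / {rates['D']:.3f} / {rates['L2']:.3f} Hz")
theta = report.band_powers.query("band == 'theta'").set_index("session")["relative"]
print(f"relative theta L1/D: {theta['L1']:.3f} / {theta['D']:.3f}")
```

prints

```
units with a field in all three sessions: 20
L1DL2 angle: 57.09 +/- 3.67 deg (true 50.0)
d(L1,D):  10.99 +/- 0.56 cm (true 12.75)
mean rate L1/D/L2: 0.352 / 0.219 / 0.351 Hz
relative theta L1/D: 0.272 / 0.312
```

The recovered angle and displacement sit near the configured ground truth
(estimation noise from 10-minute sessions moves individual cohorts by a few
degrees / centimetres); the dark session shows the configured ~0.65× rate
drop and the theta-power rise of the dark LFP profile.

The same run is available from a shell:

```sh
placeremap simulate --out exp --seed 1 --angle 50 --shift 12.75 --n-place-cells 20
placeremap analyze --l1 exp/L1 --d exp/D --l2 exp/L2 --out report
```

`report/` then holds `unit_metrics.csv`, `remapping.csv`, `band_powers.csv`,
`paired_tests.csv`, and `summary.json`.

## Session directory format

```
<session>/
  meta.json               label, arena size, duration, sampling rates
  position.csv            t, x, y          (s, cm, cm)
  spikes/unit_<id>.csv    t                (s)
  waveforms/unit_<id>.csv uv               (µV mean waveform, optional)
  lfp/ch<k>.csv           t, uv            (s, µV)
```

See `docs/methods.md` for the model details, parameter defaults, numerical
choices, and known limitations.
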