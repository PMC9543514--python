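# Methods

This note documents the models and procedures implemented in `placeremap`,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic data do and do not establish about real recordings.

## Rate maps

The arena is divided into square bins (default 2.5 cm, a 32×32 grid over
80 cm; origin at the south-west corner, bin centres at `(i + 0.5)·bin_size`,
indices 0-based, intervals half-open).  Occupancy credits each position
sample with its sampling interval (the last sample receives the median
interval, so total occupancy equals session duration to within one sample).
Each spike is assigned to the bin of the temporally nearest position sample.
Bins with less than `min_occupancy` (default 0.1 s) dwell are invalid and
excluded from every statistic.  The smoothed map is a mask-aware 3×3 boxcar:
each valid bin becomes the mean of its valid neighbours including itself;
invalid bins stay undefined rather than leaking zeros.  No speed filtering
of spikes is applied.

Place fields are the largest 4-connected component of valid bins whose
smoothed rate reaches `peak_fraction` (default 0.2) of the map peak,
accepted when it has at least `min_bins` (default 9) bins.  Area ties break
by higher mean rate, then lowest row-major bin index.  A map whose peak rate
is zero has no field.  The field's centre of mass (COM) is the
smoothed-rate-weighted mean of the member bins' centre coordinates —
field-restricted, not whole-map, so baseline firing elsewhere cannot drag
the centroid.

## Remapping geometry

For each unit with a field in L1, D, and L2, the L1DL2 angle is the angle at
the dark centroid between the vectors to the two light centroids
(`arccos` of their normalised dot product, clamped to [−1, 1] to absorb
floating error at the collinear extremes; result in [0, 180]°, symmetric in
L1 ↔ L2).  Pairwise centroid distances are Euclidean.  When the dark
centroid coincides exactly with a light centroid the angle is undefined; the
unit is reported as "no remap" and excluded from the angle aggregate while
still contributing distances.  Aggregates are mean ± SEM (sd/√n; SEM absent
for n = 1).  In the full pipeline the remap cohort is restricted to units
classified as a place cell in at least one session, because the field
detector will happily find a spurious blob on a non-spatial unit's noise
map.

Interpretation note: the angle is ill-conditioned exactly where it is most
interesting — `arccos` amplifies eps-level error in the cosine near 0° and
180° — so tests near those endpoints compare cosines, not angles.

## Spatial statistics

Skaggs spatial information is
`I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)` bits/spike over valid bins, with `pᵢ` the
occupancy fraction and `λ̄` the occupancy-weighted mean rate; zero-rate bins
contribute nothing, and results within 1e-12 of zero are flushed to exactly
zero so a uniform map reports 0.  Bits per spike (not per second) is
implemented.  The estimator carries the well-known upward small-sample bias
of roughly `n_bins / (2 ln 2 · N_spikes)` bits: at place-cell rates
(~0.35 Hz, ~200 spikes over ~900 visited bins) even a spatially uniform
unit estimates ~3 bits/spike.  The classification threshold of
0.5 bits/spike therefore separates spatial from non-spatial firing only at
rates high enough to beat the bias (the ~3 Hz bursting-cell regime), which
is exactly where the pipeline applies it as a *negative* criterion.

Spatial coherence is the Pearson correlation, over valid bins, between the
raw rate and the mean of the up-to-8 valid neighbours (centre excluded) —
raw r, no Fisher transform.  Degenerate inputs (constant maps) raise an
explicit undefined-coherence error instead of silently returning 0.
Because the neighbour average includes diagonals, a ±1 checkerboard's
interior neighbour mean is identically zero and coherence is driven to
strong (not perfect) anticorrelation by the boundary bins.

## Unit metrics and classification

Waveform amplitude is the value at the first (earliest) positive local peak
minus the value at the first negative local peak, in µV; a monophasic bump
falls back to the global extremum of the missing sign, so its amplitude is
peak-minus-baseline.  Width is the time between the two crossings of the
25 %-of-amplitude level bracketing the principal (largest-magnitude) peak,
linearly interpolated between samples — for a Gaussian bump of width σ this
is `2σ√(2 ln 4)`.

A burst is a maximal run of ≥ 2 spikes whose consecutive ISIs are all
≤ 6 ms; two candidate bursts separated by less than the 50 ms minimum
inter-burst interval merge into one event spanning every spike between its
first and last member.  The summary reports burst count, mean spikes per
burst, durations, and propensity (fraction of spikes inside bursts).

Classification: **place** requires information ≥ 0.5 bits/spike AND
coherence ≥ 0.25 AND mean rate ≥ 0.25 Hz AND a detected field; otherwise
**bursting** requires propensity ≥ 0.1 and mean rate ≥ 1 Hz; otherwise
unclassified.  All thresholds are configurable (`ClassifierConfig`); the
bursting thresholds are operationalisations of the bursting-cell profile
(fast firing, short ISIs) rather than published cut-offs, and the
"ISI of minimum 6 ms" burst phrasing is read in the standard sense of
intra-burst ISI ≤ 6 ms.  ISI-histogram autocorrelation scoring is not part
of the classification rule.

## LFP band power

PSDs come from Welch's method: 2 s Hamming windows, 50 % overlap, per-
segment linear detrend (these are implementation defaults; the analysis
they reproduce did not state them, and all are configurable).  Band power
is the Simpson's-rule integral over the band, with the band edges included
by linear interpolation onto the frequency grid.  Bands are delta 1.5–4 Hz,
theta 5–11 Hz, gamma 30–90 Hz; total power integrates 1.5–90 Hz and
relative power divides by it.  The gaps (4–5 and 11–30 Hz) are deliberate:
the three relative powers sum to less than 1.

Numerical subtlety: composite Simpson weights a narrow spectral peak by
2/3 or 4/3 of the grid step depending on the parity of its position in the
integration range, which made a pure 8 Hz tone's theta/total ratio depend
on quadrature bookkeeping rather than on the spectrum.  The total integral
is therefore computed piecewise, split at the band edges; total power is
then exactly the sum of band and gap powers, and band/total ratios are
parity-independent.  Relative fractions are clamped into [0, 1] against
residual quadrature slivers.  Splits at arbitrary other frequencies remain
approximate at the usual composite-Simpson level.

## Paired statistics

Each metric is compared across L1 vs D, D vs L2, and L1 vs L2 on matched
units (or LFP channels).  With `test="auto"` a Shapiro-Wilk check on the
paired differences at α = 0.05 selects the paired t test when normality is
not rejected and the Wilcoxon signed-rank test otherwise; either can be
forced.  All-zero differences report the conventional t = 0, p = 1;
constant non-zero differences are flagged degenerate (zero variance in the
denominator) rather than given a fabricated p.  No multiple-comparison
correction is applied; the pairwise p-values are reported unadjusted, by
design, and the report says so.

## Synthetic data generator

The generator encodes the study conditions as defaults and is the ground
truth for every recovery test.

**Trajectory.** Constant-interval samples (default 50 Hz) of a smoothed
random walk: speed is an Ornstein-Uhlenbeck process (mean 10 cm/s, sd
3 cm/s, relaxation 1 s, clipped at zero) and heading is Brownian with
diffusion 1.0 rad/√s; the unconstrained path is folded into the arena by
reflection.  The heading diffusion was chosen so the path mixes over the
80 cm arena ~19 times in a 10-minute session, giving the roughly uniform
occupancy of pellet-chasing foraging (occupancy CV ≈ 0.5 on 5 cm bins);
more tortuous settings leave visibly lumpy occupancy that no foraging
session shows.

**Place cells.** Inhomogeneous Poisson spikes by thinning against
`λ(x,y) = scale·(baseline + (peak − baseline)·exp(−d²/2σ²))`.  Defaults:
σ = 10 cm, baseline 0.05 Hz, peak 3.3 Hz.  Field size is an assumption (no
published value was available), documented here as such.  The peak rate is
calibrated so the realised light-session mean rate is ~0.35 Hz on the
default trajectory; the dark-session scale of 0.65 (= 0.23/0.35) then gives
~0.23 Hz in darkness.

**Remap geometry.** Each unit's L1 centroid is drawn uniformly with a
6 cm wall margin; D is displaced `shift_cm` (default 12.75) in a random
direction; L2 is L1 rotated about D by the configured angle (default 50°,
random sign), so |D−L2| = |D−L1| by construction.  This one-parameter
rotation is the only geometry in which a zero angle degenerates to exact
light-field stability (L2 ≡ L1) while any other angle is realised exactly;
with the defaults it implies |L1−L2| = 2·12.75·sin 25° ≈ 10.8 cm.  A zero
shift degenerates to D ≡ L1 ≡ L2 — no remap, reported as such rather than
as an angle.

**Bursting cells.** Burst events from a renewal process whose gap is the
50 ms minimum inter-burst interval plus an exponential tail sized so the
overall rate hits the target (default 3 Hz); each event carries
`2 + Poisson(mean − 2)` spikes (default mean 3) at intra-burst intervals
jittered in 0.7–1.1 × 4 ms, always below the 6 ms criterion.

**LFP.** Spectrally shaped Gaussian noise: per-band band-passed white noise
(4th-order Butterworth, forward-backward, corners inset 5 % of the
bandwidth so filter skirts stay in-band) scaled so each band's power is the
requested fraction of total 1.5–90 Hz power, plus components filling the
inter-band gaps and a flat broadband floor whose analytic in-band
contribution is subtracted from each budget.  Filtered noise rather than
sinusoids so Welch estimates have realistic variance.  Default fs 250 Hz
(Nyquist comfortably above the 90 Hz gamma edge); light profile
δ/θ/γ = 0.312/0.274/0.099, dark profile 0.280/0.314/0.099.

**Determinism.** Every operation is a pure function of its arguments and an
integer seed; the experiment generator derives per-component seeds from one
master seed, and simulate → write → load → analyse → write is byte-identical
across runs.

## What the synthetic data do not show

The generator emulates the statistical structure of the experiment, not its
biology or its recording chain: no spike sorting or cluster-cutting noise,
no electrode drift (real sessions lost ~16 % of units after L1; simulated
units never disappear unless configured), no thigmotaxis or wall-following
bias, no theta-modulated spiking or phase precession, no speed-rate
coupling, no non-stationary LFP, and isotropic single fields only.  Passing
recovery tests therefore establishes that the analysis is correct and
well-conditioned at realistic signal levels — not that it would be robust
to every artefact of real tetrode data.

## Problem sizes used in validation

Recovery tests use the experiment's own scale — three 600 s sessions at
50 Hz tracking, cohorts of 20 units (40 + 9 for classification), 20 seeds
for the remapping cohort, 5 for the stability null — chosen as the smallest
sizes at which the cohort statistics are stable.  Classification accuracy
on the simulated cohort is typically 88–98 % and occasionally dips to
~76 % on coverage-unlucky trajectories: every error is a true place cell
whose single-session mean rate falls below the 0.25 Hz floor, a selection
effect a threshold-defined real cohort cannot exhibit by construction.

## Known limitations

* The Skaggs bias (above) makes bits-per-spike values at sub-hertz rates
  systematically high; comparisons across conditions remain valid because
  the bias is shared, but absolute values should not be read as information
  in the channel-capacity sense.
* The L1DL2 angle collapses the full 2-D remap into one number and is
  undefined for zero displacement; the COM distances carry the
  complementary information and should be read together.
* Welch/Simpson band power assumes stationarity within a session; no
  artifact rejection is implemented.
* Rate-map statistics are bin-size dependent; all defaults are exposed and
  logged by the CLI so a sensitivity analysis is one config file away.
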