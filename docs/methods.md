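# Methods

This note documents the models, estimators and numerical choices behind
`halotrack`, and what the synthetic data do and do not establish about
real recordings.

## Motion models

**Run-and-tumble.** A swimmer alternates straight runs with instantaneous
reorientations. Run durations are i.i.d. exponential with mean
`mean_run_duration` (default 1.0 s, the classic *E. coli* value); tumble
angles are drawn uniformly in ±[`tumble_angle_min`, `tumble_angle_max`]
(default ±[30°, 180°], so that every true tumble exceeds the 30°
significance threshold of the direction-change metric; both bounds are
configurable). Each cell draws a single speed from
N(`mean_speed` = 10.6 µm/s, `speed_sd` = 4.0 µm/s) truncated at zero -
between-cell variation dominates observed speed histograms - plus a small
within-run multiplicative jitter (`within_run_speed_jitter` = 0.1) applied
per frame interval. The continuous path is integrated exactly across
tumble events inside each interval and sampled at `frame_rate` (default
7.0 Hz) for `duration` (default 10 s).

Motion is simulated in 2-D: a 10 µm deep counting chamber keeps the
sample quasi-planar, and out-of-plane excursions are ignored. Boundaries
reflect (the sampled path is folded back at the field edges), so the
number of cells in a recording is constant - a deliberate simplification;
real cells drift in and out of the field of view.

**Brownian.** Non-motile cells take i.i.d. Gaussian steps with per-axis SD
`sqrt(2 D dt)` (default D = 0.4 µm²/s), the exact finite-time law of
isotropic diffusion, so the net mean-squared displacement is 4Dt.

## Scene rendering

Cells appear as isotropic Gaussian spots (`spot_sigma_um` = 0.5 µm,
matching rods of ~2 x 1 µm imaged near the diffraction limit) of
amplitude 150 on a constant background of 20, with additive Gaussian
noise (SD 2) and clipping to [0, 255]. The default geometry is
2560 x 1920 px over 141 µm x 106 µm (0.0551 µm/px); pipeline scenes
default to 640 x 480 px over the same field (0.2203 µm/px) to keep
desk-scale runs fast - the field, cell counts and motion statistics, not
the pixel budget, carry the science. Anisotropic pixel scales (x and y
differing by more than 5%) are rejected.

Not modelled: phase-contrast halos and point-spread asymmetries, cell
division, collisions (cells pass through each other), chemotactic
gradients, illumination drift. Consequences: detection on real data will
need retuned thresholds, and the tracker sees more (and harsher) spot
overlaps here than a repulsive-cell world would produce.

## Detection, MHI, linking

Per frame, background is the median and noise the robust SD
(1.4826 x MAD) - both immune to the sparse bright spots; pixels above
background + `k_sigma` (5) x SD form the candidate mask. In noise-free
frames (robust SD = 0) the threshold falls back to 5% of the dynamic
range. Connected components within [`min_area_px`, `max_area_px`] become
detections; a component containing several intensity peaks (minimum
separation 3 px on a lightly smoothed copy) is split by watershed, so two
cells whose spots touch keep separate identities until their peaks truly
fuse (closer than ~2 spot sigmas). Centroids are intensity-weighted on
background-subtracted intensities, giving sub-pixel (~0.05 px) accuracy
on clean spots.

The motion history image thresholds absolute frame-to-frame differences at
6 x the robust SD of the signed difference image (computed on the first
frame pair; the folded absolute difference would bias the MAD low) and
stamps each active pixel with the time of the later frame; later activity
overwrites earlier. An optional window keeps only the trailing seconds.

Linking is greedy nearest neighbour on *predicted* positions: each track
carries an exponentially smoothed velocity (weight 0.5 on the newest
step), candidate pairs are ranked by distance from the constant-velocity
prediction, and both the predicted and the raw last-position distance must
fall within the gate `(gap+1) x max_speed / frame_rate`
(`max_speed` = 30 µm/s, above the fastest observed speed bin of
23-25 µm/s; ~4.3 µm/frame at 7 Hz). Unmatched tracks coast up to
`max_gap` = 5 frames (bridged linearly on reacquisition); a stitching pass
then joins fragments separated by up to `stitch_max_gap` = 7 frames within
the same speed gate, and tracks shorter than `min_track_frames` = 7 (~one
mean run at 7 Hz) are dropped. The velocity memory, the 5-frame gap and
the stitching exist because a swimmer crossing a static cell merges blobs
for ~0.3-0.5 s (~3 frames): without them such crossings fragment tracks
and corrupt the motile-track count. A per-frame optimal bipartite
assignment was evaluated and rejected: with sub-pixel centroids the
correct pair costs ~0 and greedy locks it first, whereas the global
optimum will trade it away whenever a tumbling cell's prediction degrades
- empirically it produced more identity swaps, not fewer.

Known limitation: if a cell tumbles during the 1-2 frames in which its
spot is fused with another cell's, no frame-local tracker can keep the
identities straight. Such exchanges are rare (a few per hundred crossing
events) and do not move positions - localization RMSE stays ~0.4 px - but
a static/motile exchange can split one swimmer across two motile-classified
tracks, which is why recovered motile counts on dense 100-cell scenes are
accurate to ±2-3 rather than exact.

## Track metrics

Mean speed is path length over duration (robust to gap-bridged points;
identical to the mean of instantaneous speeds under uniform sampling).
Speed dynamic is the sample SD (n-1) of instantaneous speeds; it needs
>= 3 points and is otherwise NaN with a reason code. Turning angles use
`atan2(cross, dot)` of successive displacement vectors (numerically stable
near 0° and 180°, unlike `acos`); a junction only counts when both steps
exceed `min_step` = 0.3 µm (2 x a ~0.15 µm localization noise SD), so
jitter on a stationary cell cannot mint fake >30° events - a track whose
steps are all below `min_step` reports rate 0 with a `noise_dominated`
flag. Straightness is clamped to [0, 1] against rounding. All metrics are
invariant under rigid motions to 1e-9 and are reported together with the
frame rate they were computed at (straightness and direction-change rate
are sampling-rate dependent by nature). Whether the >30° criterion should
apply per frame pair or per smoothed segment is underdetermined for this
kind of data; per frame pair with the `min_step` guard is this package's
choice.

## Motility classification and calibration

A track is motile iff net displacement >= `d_min` AND mean speed >=
`v_min` AND duration >= `t_min` (uncalibrated defaults 5 µm, 2 µm/s, 1 s).
These defaults are deliberately loose: at D = 0.4 µm²/s and 10 s a
Brownian track exceeds 5 µm net displacement with probability ~0.21, and
its mean sampled speed (~3 µm/s at 7 Hz) clears 2 µm/s, so the defaults
alone cannot separate the classes. `calibrate_motility_criteria`
simulates a Brownian ensemble at the scene's D and sets `v_min` to
mean + 4 SD of the Brownian mean speeds (beyond the 99.99th percentile -
the mean of ~70 Rayleigh step speeds is nearly Gaussian, so 4 sigma keeps
the false-positive rate well under the 1% requirement with a margin the
99th percentile itself would not give) and `d_min` to half the Brownian
RMS net displacement `sqrt(4DT)` (a floor against noise tracks that a
10 µm/s swimmer fails with probability ~2e-3; a 5 µm gate would already
cost ~1.5% of genuine swimmers, since an unbiased run-and-tumble walk
revisits its origin). The speed gate carries the discrimination.

Note the Brownian "speed" is a sampling artifact: it scales as
`sqrt(4 D frame_rate / pi)`, so the calibration must be redone per frame
rate and D - which is exactly what the calibration routine does.

## Parameter recovery

Estimating the generator parameters back from sampled tracks needs
estimators that respect the sampling: at 7 Hz, naive inversion of the
>30° event rate is biased 10-20% because a tumble inside a frame interval
splits into two junction angles (sometimes both above threshold,
sometimes neither) and adjacent tumbles merge.

*Mean run duration*: a junction is "straight" when its turning angle is
below a tiny epsilon (default 0.001°; the simulator's within-run headings
are exact, so any genuine tumble registers). With Poisson run switching,
a junction is straight exactly when no tumble fell in its two supporting
intervals, so the straight fraction estimates `exp(-2 dt / tau)` and
`tau = -2 dt / ln(p)` - unbiased up to the 1/ln nonlinearity. On measured
tracks the epsilon must be raised above the localization angular noise.

*Mean speed*: the mean of within-run step speeds, censoring steps adjacent
to a turning junction (a tumble inside an interval shortens the chord by
~23% on average, a ~3% bias at 1/s tumbling) and steps within 3 µm of a
field edge (a mirror reflection bends the path exactly like a tumble).
Each track contributes its mean; the condition estimate averages tracks,
matching the between-cell speed model. With 200 tracks and a 4 µm/s
between-cell SD the estimator's relative SE is ~2.7% - the dominant
uncertainty; its bias is below 1%.

## Viability statistics

CFU/mL = colonies x dilution / plated volume (default 0.05 mL).
Survivability divides mean sample CFU/mL by mean control CFU/mL at the
same timepoint; values above 1 are preserved. The SEM of a replicate mean
uses the Poisson plug-in variance (variance = mean count) by default:
with n = 3 replicates an empirical-SD SEM behaves like a t-interval with
~4 degrees of freedom (a ±2 SEM interval covers only ~88%), while counts
are Poisson by construction here and to good approximation on real
plates; the empirical option (`error_model="sample"`) remains available.
Ratio SEMs combine relative errors in quadrature. Aggregation order:
technical triplicates average within each biological replicate, condition
values average the biological replicates, and SEMs are computed across
biological replicates.

Motile-among-survivors = sample motile fraction / survivability, under
the assumption that all control cells are alive. It is the only capped
quantity (a fraction of a population cannot exceed 100%); capping events
are logged and the uncapped value retained. Survivability 0 with motile
tracks present is reported as an inconsistency flag (it does occur in
campaigns: a condition can plate to zero colonies while a recording still
shows a motile cell) rather than silently clipped. The 0.01 h timepoint
is treated as exactly t = 0.01 h, including on log-scaled time axes.

The campaign's survival curves are plateau-exponentials
`S(t) = p + (1-p) exp(-k c t)` and the motility response adds a transient
stimulation pulse peaking at 1 h; both encode only the qualitative
ordering (chloride least harmful, perchlorate most; short-lived
hypermotility under oxidising salts) and make no claim to fit measured
values - published absolute tables cannot be reconstructed from published
summaries alone, since control motile fractions are reported only as
ranges.

## Statistics

Group comparisons default to Welch's unequal-variance two-sided t-test
(the equal-variance Student variant is available and every result records
which was used, with Welch-Satterthwaite degrees of freedom). Raw
p-values are reported; Benjamini-Hochberg adjustment exists but is off by
default, matching the raw-p reporting convention of this kind of study.
Degenerate inputs (both groups constant) give t = 0, p = 1 on equal means
and raise otherwise. Speed histograms use 2 µm/s bins anchored at odd
integers (3-5, 9-11, 23-25 µm/s, ...), half-open on the right, normalized
to relative frequencies.

## Reproducibility and problem sizes

Every generator is a pure function of (parameters, seed); campaign seeds
derive from SHA-256 of the master seed plus the (salt, concentration,
timepoint, replicate, stage) coordinates, so adding a condition never
perturbs another's data. Reports are JSON with sorted keys; tracks CSVs
are reloaded with round-trip float parsing, so a campaign's exported
tracks re-analyzed from disk reproduce the campaign's outputs
byte-identically.

Default problem sizes (chosen to make desk-scale runs complete in
minutes): 640 x 480 px renderings; 100 cells per scene; 1,000-track
ensembles for classifier calibration checks; 10,000 tracks for the
Brownian MSD check; 200 tracks per condition for parameter recovery; 500
replications for survivability coverage; 10,000 simulations for the Welch
type-I error. Full-resolution 2560 x 1920 rendering is available through
`SceneSpec` but is opt-in.
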