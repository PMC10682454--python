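# Methods

This note documents the models, the numerical choices, and what the
synthetic sessions do and do not establish.

## The pipeline's model of a session

A session is three blocks over a fixed neuron set: REST1, RUN, REST2.
Activity is non-negative deconvolved event rates at ~19 Hz; behaviour
is position/velocity on a 150 cm circular belt with four visuo-tactile
cues; an optional LFP channel at 2.6 kHz accompanies the rest blocks.
Movement epochs inside rest are masked and excluded from correlation,
standardization and envelope statistics.

## Spatial selectivity

Tuning curves use 50 half-open 3 cm bins, with the belt treated as
periodic everywhere (tuning, wavelets, segment wrapping): this is the
natural geometry of a looped belt and avoids edge artifacts at the
reward line.  Spatial information uses occupancy-weighted bin means;
empty bins are excluded from the sum rather than imputed.  The shuffle
null circularly rotates the activity trace 1000 times by default,
excluding rotations shorter than 1 s so the null stays conservative
(small shifts barely decorrelate activity from position).  SI is
computed on deconvolved rates, not binarized events.

Place fields come from a Ricker CWT (PyWavelets `mexh`) of the
circularly extended tuning curve at scales 1..50.  Two operational
choices were needed where the rule "local maxima above 3 MAD of the
scale-1 coefficients; narrower maxima nested in wider ones are
discarded" is underdetermined:

1. a candidate must be a local maximum along the scale axis as well
   (a ridge peak), so a bump is detected at the scale its wavelet
   response prefers rather than at the widest supra-threshold scale;
2. the width constraint (5–80 % of the track, measured between the
   zero crossings of the wavelet response at the detected scale) is
   applied *before* overlap suppression, because an invalid-width
   response — e.g. the wrap-around artifact at scales comparable to
   the track length — cannot be a field and must not swallow real
   candidates;
3. overlapping candidates compete by wavelet-response magnitude rather
   than strictly by scale.  On a 50-bin circle any two bumps admit a
   merged coarse-scale envelope within the 80 % width cap, so a
   strict widest-wins rule could never report a multi-field cell; a
   bump's matched-scale response exceeds both its coarse-scale echo
   and the merged envelope, so single bumps still give exactly one
   field while separated bumps give one each.

Retained fields must further have in-field mean ≥ 2.5× the out-of-field
mean and contain the per-lap activity peak in ≥ 1/3 of laps; sessions
with fewer than 10 laps are rejected.

## Ensembles and labels

Rest traces are Gaussian-smoothed (σ = 200 ms), z-scored, correlated,
and clustered with average linkage on d = 1 − r, cut at 0.75 (average
within-cluster r of 0.25); clusters below 5 members are dropped.
Segment extraction normalizes each spatially-selective member's tuning
curve to [0, 1] and unions the supra-0.5 bins per member ("any ensemble
neuron"); circular runs of that union are segments, discarded unless
≥ 3 members contribute.  A segment < 30 cm containing a cue centre
(inclusive endpoints) makes the ensemble *cue*; the rule is cue-first
when both qualifying and long segments coexist.  The encoding-bias
models are Poisson over 3 cm bins with occupancy exposure: a circular
Gaussian tuning model (baseline, amplitude, centre, width; L-BFGS-B
with multi-start over the centre) versus a closed-form per-cue-rate
model; the reported statistic is the log-likelihood difference.

## Seeded PCA–ICA

The rest matrix is standardized per neuron on quiet frames; the same
statistics standardize RUN for projection (the alternative —
re-standardizing each block — would make strengths incomparable across
blocks).  The residual after removing the seed subspace is
eigendecomposed as a correlation matrix (covariance available as an
option); eigenvectors above λ₊ = (1+√(N/T))² are retained.

Reconstruction ICA minimizes the reconstruction-plus-log-cosh objective
over the projection of X onto the concatenated basis, starting from the
identity (deterministic — no seed enters the optimizer).  Numerical
choices:

- the leading 1/N of the objective is implemented as a mean over time
  frames (the rows of the projected matrix), the only reading that
  makes the first term an average; the `penalty_weight` parameter
  (default 1) rescales the trade-off in any case;
- the projected matrix is divided by one global RMS so the penalty
  scale is independent of recording length and amplitude; a per-column
  scaling would distort the relative variances of ensemble projections,
  which carry information;
- gradient descent with Armijo backtracking; convergence is declared on
  the gradient norm (‖∇‖ < tol·max(1, |J|), tol = 1e-6, max 500
  iterations).  A relative-objective-change criterion was tried first
  and stalls during the slow rotation phase with sources still mixed —
  the gradient there is small per step but far from zero;
- the final neuron-space components are the first M columns of W′W.
  With the row-vector convention of the objective, the separated
  coordinates are x W, so W′W are the filters; the transposed form
  (which column-vector notation would suggest) applies the inverse
  rotation and demonstrably re-mixes planted sources;
- components are unit-normalized and sign-fixed so the
  largest-magnitude weight is positive.

Reactivation events are excursions of a strength series above
mean + 3 SD, extended outward to 25 % of that threshold; overlapping
extended events merge, and an excursion with no rising flank
(onset = peak, a single-frame spike) is discarded — a transient with a
~180 ms envelope always crosses the boundary threshold before it
peaks, whereas barely-supra-threshold noise does not.  Strength
z-scoring is per block, not per event window.

## Ripples

400-order FIR bandpass 150–250 Hz applied forward–backward, 8 ms RMS
envelope, threshold mean + 3 SD with onset/offset at 75 % of threshold.
The ≥ 3 cycles minimum duration (3/200 s = 15 ms at band centre) is
measured on the supra-threshold **core** of an event by default.  The
alternative — measuring it on the extended 75 % bounds — lets brief
envelope-noise excursions pass (their extensions routinely span
15 ms), producing hundreds of false events per 10 min of noise-only
LFP, whereas the core reading leaves ~1; planted 5 SD bursts keep a
core well above 15 ms either way.  `duration_on="extended"` restores
the literal-bounds reading.  Events starting within 250 ms of the
previous event are merged into it by default (pure discard available).
Envelope statistics can be restricted to non-movement samples via a
mask mapped from the imaging frames.

## Coupling statistics

Peri-event averages z-score the series over the block and average
event-centred windows (edge events dropped).  Lags come from a
four-parameter Gaussian fit to the unbiased-normalized
cross-correlation (fallback: argmax, flagged); the sign convention is
positive when the second series lags the first, and reported lags carry
the ±dwell/3 ≈ ±17 ms scanning bound plus one frame period.  Coupled
cue–trajectory pairs compare the peak |cross-correlation| within ±1 s
with the one-tailed 95 % bound of a circular-shift surrogate null
(500 shifts, minimum shift 1 s); the reported pair lag is the mean lag
weighted by the positive part of the coefficient curve.  The
SWR-association window defaults to ±500 ms on event onsets (the
"any-overlap" alternative is a one-line change and both conventions are
reported in the output metadata).  Explained variance is the squared
partial correlation of upper-triangle pairwise-correlation vectors,
(RUN, REST2 | REST1)·100, and rev swaps the rest blocks.  Ensemble
persistence is the maximum Jaccard index over partner ensembles, with
significance from a one-tailed Fisher exact test on the overlap table
(α = 0.001).

## Hopfield pattern completion

Features are binarized at 0.5 of their min–max range into ±1 vectors
over the 50 spatial bins (bins, not neurons, since features are the
stated input space).  Hebbian outer-product weights, zero diagonal;
asynchronous updates in fixed index order with ties (zero local field)
keeping the current bit, which guarantees energy descent.  A trial
stores one coupled and one uncoupled trajectory pattern, probes with
the coupled pair's cue pattern, and succeeds when the settled state is
strictly nearer (Hamming) to the coupled pattern; ties are reported as
indeterminate and excluded from the success fraction.

## The synthetic generator

The generator emulates the study conditions: ~19 Hz frames, 2.6 kHz
LFP, 150 cm belt with four cues, 8 min RUN between two 10 min rests,
constant-speed laps (15 cm/s with jitter and a 1 s reward pause, ≥ 40
laps), Gaussian place fields (σ = 6 cm), narrow cue responses, and
~180 ms half-Gaussian-rise/decay reactivation transients with ±20 %
member-amplitude jitter (so ICA weighting is non-degenerate).
Background activity is sparse independent events (0.1 Hz, exponential
amplitudes) plus truncated Gaussian noise — the event statistics of
real quiet rest are not pinned down by the experimental protocol, so
they are configuration, not constants.  Defaults plant 3 ensembles
(one cue, two trajectory, 6–10 members), 0.05 Hz reactivations, 0.1 Hz
SWRs, and couple 20 % of reactivations to SWRs, matching the ~18–20 %
SWR-association fractions the analysis reports on such data.

Two deliberate structural choices mirror the phenomenon under study:
trajectory ensemble *k* is paired with cue ensemble *k* — its spatial
segment spans that cue's location, and the pair couples to the same
SWR subset (cue onset at `cue_lag_ms` = 50, trajectory at
`traj_lag_ms` = 180 after SWR onset) — while unpaired ensembles draw
independent SWR subsets.  Event placement enforces a minimum separation
within an ensemble only, so paired ensembles can co-reactivate around
one SWR.

The LFP is 1/f-amplitude noise; each planted SWR is a 50 ms
flat-topped (Tukey) 200 Hz burst whose peak ripple-band RMS envelope
sits a configurable number of envelope SDs above the background mean.
The burst *replaces* the local ripple-band background inside its window
— with plain superposition, random-phase interference erases a
noticeable fraction of nominally 5 SD bursts, making the planted SD
multiple a fiction.

What the generator does **not** emulate: biophysical calcium dynamics
and indicator kinetics, motion artifacts, ROI cross-talk, non-Poisson
burst statistics, theta/spindle structure in the LFP, behavioural state
changes within a block, and across-day drift.  Passing recovery tests
therefore demonstrates the internal consistency and statistical
calibration of the pipeline under its own assumptions, not performance
on real recordings.

## Problem sizes

The test suite and the acceptance script run sessions of 100 neurons
with 8 min RUN / 10 min rests (20 min rest for the clustering-recovery
check), 200 shuffle rotations for significance tests, 100–500 surrogate
shifts for coupling nulls, and 50–100 seeds for distribution-level
checks; these sizes give stable statistics for every recovery property
while keeping a full run in the minutes range on one CPU.

## Known limitations

- The Marčenko–Pastur bound is asymptotic: for i.i.d. Gaussian
  residuals at N = 50, T = 5000 the top correlation eigenvalue exceeds
  λ₊ in roughly one seed in ten (finite-size Tracy–Widom fluctuation),
  so a single spurious component above the bound is expected
  occasionally; downstream, such a component only adds one residual
  dimension to the ICA basis and does not perturb the seeded ensemble
  components.
- The Gaussian lag fit assumes a single dominant cross-correlation
  peak; multi-peaked structures fall back to the argmax with a flag.
- Hierarchical clustering merges ensembles whose reactivations are
  strongly and consistently co-timed (after 200 ms smoothing their
  traces correlate above the cut-off); this is a property of the
  method, visible in the generator when SWR coupling is pushed to 1.
- The encoding-bias Poisson likelihood treats deconvolved rates as
  counts; this is a quasi-likelihood, adequate for the sign and ranking
  of the bias statistic but not for absolute likelihood values.
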