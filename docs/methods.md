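# Methods

## Scope

`foragekit` re-implements, as a reusable pipeline, the quantitative analyses
used to characterize *C. elegans* off-food foraging: segmentation of
tracker state arrays into behavioral events, reversal parameterization,
local/global-search frequency statistics with effect-size-gated
distribution comparisons, optogenetic pulse-aligned response
quantification, and ON/OFF state calling for AVA-type calcium traces.  No
recorded data ship with the package; a synthetic-data generator with
planted ground truth stands in for tracker output so every stage is
testable end to end.

## Behavioral generative model

Locomotion is simulated as a semi-Markov process over the states
{forward, reversal, omega turn, pause}:

- **Reversal hazard.** Forward runs are terminated by a reversal hazard
  λ(t) (events/min of wall-clock time) that holds at `lambda_local`
  (default 3.5/min) until `hazard_hold_s` (default 480 s) and then relaxes
  exponentially toward `lambda_global` (default 0.8/min) with time constant
  `tau_decay_s` (default 420 s).  The plateau-then-decay shape reproduces
  the empirical local-to-global search transition: the rate is
  approximately constant across the minute 4–8 analysis window and has
  essentially reached the global rate by minute 36.  A single exponential
  from t = 0 cannot be near `lambda_local` at minutes 4–8 *and* near
  `lambda_global` at minutes 36–40 for any time constant, which is why the
  hold parameter exists.
- **Dead-time compensation.** The hazard is only active during forward
  movement, so a naive simulator would exhibit an observed onset rate
  ~20–25% below λ(t) (time spent reversing, turning, and pausing is
  "dead").  The generator therefore inflates the forward-state hazard by
  the renewal correction λ/(1 − λ·E[dead time per maneuver] − pause duty),
  with E[dead] computed analytically from the length mixture, reversal
  speed, coupling probability (Gauss–Hermite quadrature over the mixture)
  and omega duration.  The planted λ is thus the *measured wall-clock
  onset frequency*, exact in expectation for constant hazard and accurate
  to a few percent across the decay.  Sampling uses Poisson thinning
  against the t = 0 hazard bound.
- **Reversal lengths** are drawn from a two-component lognormal mixture in
  body-length units: 60% short (median 0.25 bl, σ_log 0.3) and 40% long
  (median 1.5 bl, σ_log 0.3).  The components sit clearly on either side
  of the 0.5 bl short/long class boundary (< 1.1% of mass crosses it), so
  mixture-weight recovery tests probe the pipeline rather than component
  overlap.  Per-frame reversal displacements are jittered but renormalized
  so the summed path equals the drawn length exactly.
- **Omega coupling.** Each reversal is followed by an omega turn with
  probability logistic(slope·(length − midpoint)), defaults slope 4 /bl,
  midpoint 0.6 bl — long reversals couple, short ones mostly do not.
  Omega turns reorient the heading by a planted ±(120–180)° step.
- **Path model.** Forward motion has angular diffusion (0.3 rad/√s) and
  speed noise around 0.15 mm/s; reversals retrace straight backward at
  ~0.18 mm/s; pauses are stationary; omega turns are nearly in-place.
  These speeds are plausible placeholders for off-food crawling — the
  source analyses report distributions only graphically, so simulator
  speed/duration defaults are *not* calibrated to any particular strain.
- **Event snapping.** All event durations are snapped to whole frames
  (3 fps default) and every event spans ≥ 1 frame, so the emitted state
  sequence segments back into exactly the planted event list and ground
  truth tiles the recording without gaps.

Optogenetic simulations multiply the instantaneous hazard by
`hazard_boost` inside light pulses, but only when `retinal` is true; with
`retinal=False` the generator consumes the identical random stream and the
output is bit-identical to the base simulation — the natural control for
channelrhodopsin experiments without the obligatory cofactor.  The default
schedule is three 20 s pulses separated by 100 s gaps starting at 600 s.

Calcium traces are an exact continuous-time two-state telegraph process
(OFF→ON rate 1/30 s⁻¹, ON→OFF 1/20 s⁻¹ → stationary ON fraction 0.4, mean
ON epoch 20 s), initialized at stationarity and sampled at 10 fps for
40 min.  The hidden state drives fluorescence through first-order
indicator kinetics (rise τ 0.5 s, decay τ 2 s; τ = 0 degenerates to an
instantaneous copy), scaled as F = F₀·(1 + a·c(t)) with a = 1.0, plus
optional linear bleaching and white Gaussian noise of 0.2·F₀ (trace
SNR ≈ 5).

**What the generator does not emulate:** posture, head oscillations,
tracker segmentation errors, collisions and track fragmentation,
plate-edge behavior, photophysics (light intensity is metadata only), and
correlated/photon-limited imaging noise.  Passing recovery tests therefore
demonstrates correctness of the analysis code under the stated model, not
robustness to every artifact of real recordings.

## Event analysis

Events are maximal runs of identical state; runs shorter than
`min_event_frames` (default 1, i.e. no smoothing — tracker calls are taken
at face value) are absorbed into the preceding event.  Per event:

- duration = frames/rate (events are half-open in frames and tile the
  track exactly);
- reversal/forward path length = Σ successive centroid displacements over
  the event's frames ÷ worm length (single-frame events have length 0);
- speed = (mean + median of frame speeds)/2, using the tracker's speed
  column rather than recomputing from positions.

Reversals are SHORT below 0.5 body lengths, LONG otherwise (a tie at
exactly 0.5 goes LONG; the boundary is measure-zero on real data).
Coupling: a reversal is a reversal-omega maneuver if an omega turn starts
within `max_gap_s` of its end (default 0 — immediately adjacent), a pure
reversal if the next event is a forward run; reversals followed by pauses
or shallow turns are unclassified and omega turns without a preceding
reversal are flagged uncoupled (they fall in the ethogram's "other"
category).  Turn angles compare net-displacement headings over 1 s windows
before reversal onset and after turn end, wrapped to [0°, 180°]; windows
not fully covered by the track disqualify the maneuver.

Forward-run duration analyses keep runs ≥ 2 s.  Parameter analyses exclude
tracks shorter than 5 min, tracks flagged near the arena barrier, and
tracks without at least one complete (boundary-free) reversal or forward
run.

## Frequency statistics

Frequencies count event *onsets* inside half-open windows — local search
[240, 480) s and global search [2160, 2400) s after removal from food —
divided by window length in minutes (wall-clock; paused time is not
excluded).  Only tracks continuously covering the whole window are
eligible.  Per-track frequencies are averaged within each assay plate and
the plate means are the unit for group statistics: Mann–Whitney U for two
groups, Kruskal–Wallis plus Dunn's post hoc against a designated control
(z on pooled mean ranks with tie correction, Bonferroni family adjustment)
for more.  The per-minute timecourse applies the same per-bin eligibility
rule and reports mean ± SEM (SEM set to 0 with a warning for single-track
bins).

Distribution comparisons use the two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`): D is the exact maximum ECDF gap over the pooled
points; the p-value is asymptotic by default with an exact small-sample
option (the exact null distribution is the permutation distribution over
all label splits).  p-values are Bonferroni-adjusted by an explicit,
caller-supplied family size — family composition is an analysis decision,
never inferred.  A comparison is flagged *discussable* only when the
adjusted p < 0.05 **and** D ≥ 0.15; the flag annotates reports and never
filters computed output.

## Optogenetic quantification

Tracks are aligned around each pulse into 120 s segments with light at
[50, 70) s of segment time; partially covered segments are dropped.  The
evoked response is Δ = (reversal onsets in the 18 s window [50, 68)) −
(onsets in the 18 s window [32, 50)), each scaled to events/min.  The
source convention fixes only the 18 s durations; we place both windows
adjacent to light onset (the most conservative reading) and expose both
offsets.  Reversals straddling onset count by onset time.  Reversal
parameters are scored only for the first reversal of duration ≥ 0.5 s
beginning during the light; its absence is a valid outcome.

## Calcium state calling

1. Boxcar-smooth raw fluorescence over 1 s (centered; even windows span
   w/2 frames left and w/2 − 1 right; edges truncate and renormalize).
2. F₀ = median of the samples at or below the 10th percentile of the
   smoothed trace (a mean-of-lowest-decile option exists; the two differ
   negligibly); ΔF/F₀ = (F_smoothed − F₀)/F₀.
3. Traces whose peak ΔF/F₀ never exceeds 10% are non-qualifying and stay
   OFF regardless of thresholds.  Qualifying traces get an initial binary
   assignment: ON wherever ΔF/F₀ > 50% of its maximum (Fmax is the max of
   smoothed ΔF/F₀ — a raw-F maximum would be gain-dependent).
4. dF/dt is the central-difference derivative of ΔF/F₀, boxcar-smoothed
   over 3 s; per-trace transition thresholds are ±0.25 × the derivative's
   extrema.  The factor is configurable; on reference simulations the
   frame-wise calls move by < 2% across factors 0.15–0.35.
5. The 50%-Fmax boundaries lag the true transitions by the indicator
   kinetics (≈ τ·ln 2 on each flank), so each initial ON epoch is refined
   to where the corresponding derivative excursion *begins*: the start is
   walked back to the first frame of the rise-threshold excursion
   containing it, and the end is walked back to the first frame of the
   fall-threshold excursion containing it — the moment the decay starts,
   which is when the state turns off.  Refinement never crosses a
   neighboring initial epoch; overlapping refined epochs merge; refined
   epochs shorter than 1 s are dropped as flicker.

Because F₀, Fmax and the thresholds all derive from the trace itself,
state calls are invariant to a multiplicative gain on the raw
fluorescence (bit-exactly so for power-of-two gains, to floating-point
rounding otherwise).

Metrics per analysis window (defaults: 0–5 min and 30–35 min after the
conditioned-media switch): fraction of time ON, OFF→ON transition count,
and mean duration of ON epochs, with transitions/epochs attributed to the
window containing their onset.  On the reference cohort (50 traces,
40 min, 10 fps, planted ON fraction 0.4, SNR ≈ 5) the pipeline recovers
~96% frame accuracy, fraction-ON within ±0.01, and ~93% of true OFF→ON
transitions (short true epochs below the 1 s flicker floor account for
most of the deficit).

## Numerical and design choices

- Half-open interval convention `[start, end)` everywhere (windows,
  events, pulses); times in seconds from removal from food (behavior) or
  recording start with `media_switch_s` (calcium); positions in mm, path
  lengths in body lengths.
- Fixed seed ⇒ bit-identical output: per-track streams derive from the
  master seed via `SeedSequence([seed, crc32(plate_id), index])`, so
  plates can be generated in any order or in parallel.
- CSV serialization at 12 significant digits keeps round-trip error below
  1e-9 relative; readers validate uniform sampling (1e-6 s tolerance), the
  closed state vocabulary, and positive fluorescence, reporting row
  numbers, and never impute gaps.
- Degenerate inputs: zero hazard → one forward run; empty tracks,
  zero-length windows, empty samples, groups of < 2 plates → typed errors;
  flat derivative → (0, 0) thresholds flagged degenerate; single-frame
  events → zero path length.
- Test and acceptance problem sizes (24 plates × 13 animals, 50 seed
  replicates, 500+ pulses, 30–50 calcium traces) were chosen to put
  Monte-Carlo error well inside each tolerance while keeping a laptop run
  in minutes.

## Known limitations

- The simulator is a calibration instrument, not a worm model: no posture,
  no sensory feedback, no speed/duration calibration to recorded strains.
- The derivative-threshold construction for calcium transitions is the
  least constrained part of the published procedure; our symmetric
  fractional-extrema rule is one defensible choice, with the factor
  exposed and a documented robustness sweep.
- Dunn's post hoc is implemented against a single designated control (the
  common design in this assay family), not all-pairs.
- The track reader consumes the package's own documented CSV schema; it
  does not parse the original MATLAB tracker containers.
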