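# Methods

This note documents the models behind `poregram`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter.

## Signal model

A single-channel recording is modelled as an alternation of open-pore
stretches and translocation events. The open pore carries current
`I_open` (default 100 pA at +140 mV) with white Gaussian noise (default sd
1.5 pA, specified pre-filter). Captures follow a Poisson process with rate
`k·C` (`k` in s⁻¹µM⁻¹, `C` the analyte concentration in µM); the capture
clock runs only while the pore is unoccupied, and events never overlap
(single-channel assumption).

Each event is, in time order:

1. a **spike** near 0 pA — depth drawn uniformly on 0–2 % of `I_open`,
   duration fixed at 0.5 ms. The depth distribution and duration are
   declared defaults, not inferred quantities; recordings only constrain
   the spike to be brief and deep.
2. for each of the remaining `n − 1` units, one three-level feature:
   **A** (C-first; default I_res% levels 15 / 30 / 3.5) or **B** (N-first;
   21 / 40 / 7). The direction is drawn once per event
   (default P(C-first) = 10/11, the octamer value; 2:1 applies with a
   C-terminal linker). B-level percentages are package defaults chosen
   distinct from A; they are calibration inputs, not measured constants.
3. dwell times: A1 and A2 are single-exponential (defaults 10 ms and 5 ms;
   single-exponential is an assumption, not an observation). A3 follows a
   two-component exponential mixture — fast 0.69 ms, slow 320 ms — with
   slow-component weight 3 % for features before the last and 25 % for the
   final feature, reproducing the long-lived final A3. The final-feature
   mixture is a separate field (`dwell_A3_mixture_final`) because a single
   shared mixture cannot produce that contrast.

A PTM on unit `u` (the spike consumes unit 1, so feature `f` carries unit
`f + 1`) lowers that unit's A1 by `delta_ires` percentage points of
`I_open` and adds `rms_boost` pA of white noise in quadrature. The shipped
presets (P: 1.2 pts / 3 pA / 80 Da, GSH: 2.2 / 4 / 305.3,
SLN: 3.8 / 5.5 / 656.6) rise with modification mass, as real blockades do;
the absolute values are synthetic calibration defaults because no published
per-species table is available.

The assembled piecewise-constant signal plus noise passes through a 4-pole
low-pass Bessel filter (magnitude-normalized, default 10 kHz) emulating a
patch-clamp amplifier's analog filter, and is sampled at 50 kHz.
Ground-truth boundaries are shifted by the filter's low-frequency group
delay so they index the recorded trace. All randomness flows through one
`numpy` generator in a documented draw order (wait, direction, spike
depth, per-feature dwells, then per-segment noise), so a fixed seed gives
bit-identical traces.

**Not emulated:** 1/f or device noise (no noise spectrum to match), gating
artifacts, baseline drift, retro-translocations or failed captures beyond
end-of-trace truncation, and any physics of electro-osmosis or unfolding —
chaotrope and voltage exist only as metadata re-parameterizing rates.
Passing tests therefore demonstrate correctness of the *analysis* under
the stated statistical model, not robustness to every artifact of bilayer
recordings.

## Idealization

Event detection is threshold-with-hysteresis: an event opens below
0.9 × baseline and closes above 0.95 × baseline. The baseline is the mean
of the samples within ±6 robust-sd of the 97th percentile — the open-pore
population is the topmost current mode, and all event levels sit far
below it, so the estimate tolerates ≥30 % event occupancy.

Segmentation minimizes within-segment sum of squared deviations plus a
per-change-point penalty (Gaussian homoscedastic cost), solved exactly by
PELT; ties are broken toward the earliest indices. The default penalty is
`c·σ²·log N` with `c = 10` and σ a *marginal* robust noise sd (MAD of the
residual around a 0.5 ms rolling median). A first-difference σ estimator
would underestimate the noise because the analog filter correlates
adjacent samples, which in turn oversplits; the rolling-median residual
does not. Adjacent segments whose means differ by <3σ are merged; segments
shorter than 0.2 ms (the dead time) are kept but flagged, and the parser
treats flagged segments as filter-edge artifacts.

Two performance notes. PELT's pruning is ineffective *inside* a long
constant level, so very long windows are cut at "quiet points" — midpoints
of runs whose block means agree to within a small multiple of the block
sem — and the pieces segmented independently; a change point can never be
optimal strictly inside such a verified-constant run at these penalties,
and the merge pass rejoins the halves. The dynamic program is
numba-compiled when numba is importable, with an identical pure-numpy
fallback.

Idealization runs on the acquisition-bandwidth trace. The 2 kHz zero-phase
post-filter (4-pole Bessel, forward–backward) is applied **only** for rms
noise measurement: a 2 kHz zero-phase filter destroys the 0.5 ms spike and
the 0.69 ms fast A3, while rms statistics are defined on the filtered
signal. Zero-phase filtering is used so level boundaries are not biased in
time; the cost is non-causality, acceptable offline.

## Per-level statistics

`I_res% = level mean / baseline × 100`. Level means are measured with a
0.1 ms edge guard (transition samples are smeared by the analog filter);
rms is measured on the 2 kHz-filtered trace with a 0.3 ms guard. The
corrected noise is `sqrt(max(rms_level² − rms_open², 0))`, clipped to zero
and flagged (never silent) when the open-pore noise exceeds the level
noise — the raw formula would be imaginary there.

A quadrature-corrected rms measured after filtering is an *attenuated*
image of an injected white-noise boost: with the boost entering before the
analog filter, `rms_corr = sqrt(a) × boost`, where `a` is the variance
transfer of the 10 kHz analog filter followed by the squared-magnitude
2 kHz post-filter. `noise_attenuation_factor` computes `a` from the filter
frequency responses and `estimate_rms_boost` divides it back out, so the
reported boost is on the same (pre-filter) scale as the generator
parameter. For the default chain `sqrt(a) ≈ 0.245`.

ΔI_res% of a candidate feature is the mean A1 I_res% of the *other*
features of the same event minus the candidate's — always within one
event. The <1 ms exclusion applies to A3/B3 levels as stated (undersampling
of the fast population); A1/A2 are never dwell-excluded. Each level row
also carries the standard error of its mean, computed as
`sd × sqrt(inflation / n)` where the inflation factor
`|H(0)|²/mean|H|²` accounts for noise correlation introduced by the analog
filter (≈2.6 at 10 kHz/50 kHz).

## Grammar parsing

Levels are classified by I_res% bands (defaults matched to the generator;
a 1-D k-means calibration from the level histogram is available, and an
explicit band table overrides both). Bands are checked for interior
overlap; a value on a shared boundary belongs to the lower band.

Parsing is greedy and deterministic. The optional spike is taken from the
levels preceding the first X1 anchor — filtering can lift a true spike out
of its nominal band, so short terminal-band/unassigned leading levels
qualify. Features are anchored on a full-size X1, or a full-size X2 when
the X1 itself was undersampled (X2 cannot occur outside a repeat);
sub-dead-time segments inside a feature are recorded as residue and
skipped rather than ending the feature, because at acquisition bandwidth
they are almost always transition artifacts. A feature missing an
undersampled X2/X3 is kept and flagged; an (X1) or (X1, X2) prefix at the
end of a trace-truncated event is kept with the event marked incomplete —
the long-lived final A3 makes end-of-trace truncation likely, so
discarding would bias the census. Unparseable levels are reported as
residue, never dropped. Direction: all-A → C-first, all-B → N-first, a
B-block strictly after an A-block → mixed (disulfide-linked double
constructs), anything else unknown.

## Kinetics

Dwell-time fitting is maximum likelihood for k-component exponential
mixtures left-truncated at the dead time (default 0.2 ms = 10 samples),
via EM with five quantile-spread initializations, convergence at
log-likelihood change <1e-8 or 500 iterations, and a monotonicity
assertion every iteration. This deliberately simplifies full
missed-event interval-likelihood (MIL) fitting: the dwells come from
already-idealized levels, so no hidden-Markov missed-event correction is
applied. For k=1 the EM fixed point equals the closed form
`mean − dead_time`. Model selection returns the smallest k whose BIC is
within 2 of the minimum. Bootstrap percentile CIs (500 seeded resamples
when enabled) are opt-in rather than default, because 500 EM refits is a
poor cost to impose on every call.

The capture rate is `events / (open time × concentration)` with a
Garwood (Poisson-exact) 95 % interval, covering the zero-event case.

## PTM calling

The modified unit is found by a leave-one-out outlier test on within-event
A1 residual currents: `z = (mean(others) − own) / sqrt(max(robust_sd²,
median_sem²) + sem_own²)`, calling the maximum-z feature when z > 3 and the
blockade is deeper than the others' mean. Flooring the between-unit spread
at the per-level measurement error guards the small-sample MAD; adding the
candidate's own sem makes the test honest for short A1 levels, and A1
levels under 1 ms are not candidates at all — a mean over a handful of
filtered samples is biased toward the neighbouring levels. The original
experiments identified the modified unit by construct design; the
leave-one-out test generalizes this to unknown positions, which a reusable
caller needs.

Species assignment is generative: per-species 2-D Gaussians in the
(ΔI_res%, corrected rms) plane, fitted on labelled calibration events
(class models are inputs, not shipped constants). The call is maximum
likelihood, with an explicit **ambiguous** outcome when the top-two
likelihood ratio is below 3 — overlapping species clouds (phosphate vs
glutathione) are a property of the data and forced calls would be
meaningless. Threading order: feature 1 is the C-terminal-most unit in
C-first events, reversed for N-first.

## Problem sizes and determinism

Tests and the acceptance script use seconds-long simulated recordings
(tens to hundreds of events per cohort) — large enough for the stated
tolerances, chosen once as representative of single-pore experiment
scales. Every stochastic step takes an explicit seed; CLI stages are
byte-reproducible for fixed seed and config.

## Known limitations

* Equivalence with commercial idealization software cannot be asserted —
  only oracle equivalence (exhaustive enumeration) and recovery on
  synthetic data.
* The exclusion, band, penalty and dead-time defaults are declared package
  choices where the recording literature leaves settings unstated.
* No absolute calibration of I_res% or per-species Δ to published
  supplementary values; class models must be fitted to calibration data.
* Optional ABF ingestion is not provided; traces enter as CSV or raw
  float32 + JSON sidecar.
* The simulator's noise is white and Gaussian per level; conclusions about
  1/f-dominated recordings require caution.
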