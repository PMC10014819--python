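# Methods

`warpkit` studies *perceptual warping* in speech categorization: the
context-dependent displacement of a listener's category boundary when a
vowel continuum is presented in serial rather than random order, and how
that warping interacts with speech-shaped masking noise. The package has
three layers: stimulus synthesis, a generative observer that emulates the
behavioral and mouse-tracking structure of such an experiment, and the
analysis chain (psychometrics, trajectory geometry, condition-level
statistics) that measures warping. This note records the models, the
defaults and their rationale, and the numerical choices.

## Stimuli

**Vowel continuum.** Seven 100 ms tokens span /u/ to /a/ by varying only
F1 in exactly equal steps from 430 to 730 Hz; F0 (100 Hz), F2 (1090 Hz)
and F3 (2350 Hz) are shared, with 10 ms raised-cosine on/off ramps and a
48,828 Hz sample rate. Synthesis is a cascade (Klatt-style) source-filter:
an impulse train at F0 through three second-order resonators in series.
Formant bandwidths are not part of the continuum parameterization; we use
the standard Klatt defaults 60/90/150 Hz (B1–B3), which shape timbre but
not the F1 gradient. No formants above F3 are synthesized. All tokens are
RMS-normalized (normalization is idempotent to 1e−12).

Synthesis accuracy is verified by independent measurement: Burg-method LPC
(order 10 at a ~10 kHz analysis rate, no pre-emphasis) recovers every
token's F1 within ±15 Hz and the shared F2 within ±25 Hz; the
autocorrelation-method fundamental is within ±2 Hz. The Burg lattice was
chosen over autocorrelation-method LPC because the latter shows
harmonic-sampling bias of up to ~±22 Hz on short 100 Hz-periodic segments.

**Speech-shaped masker.** The long-term power spectrum (LTPS) target is
the 1/3-octave-smoothed envelope of the concatenated vowel set's Welch PSD
(4096-sample segments, 50% overlap). Seeded white Gaussian noise is shaped
in the frequency domain (zero-phase multiplication by the square root of
the envelope interpolated onto the FFT grid), so the masker's band
spectrum matches the vowel LTPS by construction (verified within ±3 dB in
1/3-octave bands, 100–8000 Hz). The smoothed envelope — rather than the
raw PSD — is the operative definition of a speech-shaped masker here: the
raw spectrum of an isolated periodic vowel set is a 100 Hz harmonic comb
whose deep valleys no finite filter reproduces, and a masker that imitated
the comb would not behave like the continuous speech-spectrum noise the
paradigm calls for.

**SNR mixing.** `mix_at_snr` rescales a masker segment (offset selectable:
the masker is conceptually continuous) so that
`20·log10(RMS_speech/RMS_noise)` equals the request exactly (1e−9 dB);
speech RMS is untouched. If the sum would clip, the whole mixture is
rescaled globally and the factor recorded — a global rescale preserves the
ratio, so SNR audits still pass. The experiment's noise condition uses
0 dB SNR.

## Experiment design

Six blocks fully cross masking {clean, 0 dB} with order {random, forward
Tk1→Tk7, reverse Tk7→Tk1}; 30 trials per token per block (210 per block),
block order shuffled per subject. Random order is drawn as 30 balanced
passes (each a permutation of 1..7) so per-token counts are exact by
construction; unconstrained sampling would only approximate them. Trial
logs are long-format CSV, one row per 100 Hz cursor sample; the cursor
convention is a unit screen with y increasing upward, trial onset at the
invisible threshold line y = 1/8 and termination inside a 15%×15% corner
response box ("u" left, "a" right).

## The synthetic observer

No public dataset accompanies this paradigm, so the generator *is* the
study condition; its defaults were fixed once, a priori, to values typical
of vowel categorization studies, and all randomness descends from one root
seed through spawned per-subject substreams (with trajectory noise on a
separate substream so trajectory-free simulations reproduce identical
responses).

**Responses.** P(/a/) follows a logistic in token index with subject
boundary β0 ~ N(4.0, 0.4) and slope β1 ~ N(1.5, 0.3) (clipped to sane
ranges). Serial passes displace the effective boundary by a signed,
subject-fixed `warp` ~ N(1.0, 0.75) in the pass direction — positive warp
is hysteresis (the percept lags the stimulus). The large between-subject
SD with within-subject constancy reproduces the qualitative picture of
strong individual differences alongside high split-half repeatability.
Hysteresis is conditioned on pass direction, not on the previous response,
which keeps the model identifiable from block-level fits.

**Reaction times.** Median structure
`rt_base + rt_ambiguity_gain·exp(−β1²(token−b_eff)²/2)` minus a serial
facilitation and a small noise speed-up, times lognormal(0, 0.25) trial
noise. Defaults: 700 ms base, 300 ms ambiguity peak (an inverted-V over
tokens, collective RTs ≈ 800 ms midrange), 80 ms serial facilitation,
40 ms noise speed-up. The noise speed-up is a free parameter, not a
mechanistic claim — the direction of SNR effects on RT is unsettled — and
it defaults to a small positive value.

**Trajectories.** A two-phase kinematic sketch, not a decision-process
fit: the analysis needs geometry with the right ordinal structure only.
The path follows the straight chord from (0.5, 1/8) to the chosen corner,
plus a lateral excursion toward the competing side whose amplitude
(`traj_deviation`·h) and duration (`traj_curvature_gain`·h of the trial)
grow with ambiguity h = 1 − |2p − 1|; during the excursion the cursor also
falls behind the constant-speed schedule along the chord (it rises
vertically instead of progressing diagonally), which is what depresses
proximity-to-target mid-trial. The excursion decays at `traj_attraction`
per unit of *normalized* time. Two deliberate choices here:

* *Curvature is driven by ambiguity relative to the nominal boundary*
  (β0), while the binary response uses the warped boundary. If curvature
  tracked the warped probability, hysteresis would make the lagging
  endpoint token *more* ambiguous under serial order and curvature would
  rise for serial-in-noise — the opposite of the phenomenon the analysis
  must detect. Keeping the drivers separate makes "warping straightens
  paths in noise" an explicit, controllable effect
  (`curvature_noise_reduction_serial`, default 0.5, applied only under
  serial order in noise) rather than an emergent artifact.
* *Geometry is invariant to trial duration*: the excursion decays in
  normalized time, and cursor jitter is band-limited (~110 ms Hann-smoothed,
  SD 0.004 screen units). Wall-clock decay or white per-sample jitter
  would couple measured path area to RT — serial trials are faster — and
  manufacture spurious order effects in *clean* listening, which the
  generative model defines as order-invariant.

What the generator does **not** emulate: response-history (trial-to-trial)
dependence, lapses/guessing, endpoint-token curvature beyond what
ambiguity induces (real endpoint tracks bow more than these), velocity
structure within a movement, or any SNR effect on identification accuracy
(masking at 0 dB leaves categorization largely intact, and the model takes
that literally). Passing tests therefore show the analysis chain recovers
the structure this model encodes, not that real data look like this model.

## Analysis chain

**Psychometrics.** Per subject × SNR × order, the /a/ proportions over
tokens are fit with P = 1/(1+e^(−β1(x−β0))) by bounded trust-region least
squares (β0 ∈ [0, 8], β1 ∈ (0, 20], start (4, 1), tolerances 1e−12) —
deterministic given data, with basin coverage for 7-point curves. Constant
proportions are flagged non-identifiable (no exception); decreasing curves
fit as-is with a warning. Forward and reverse blocks are additionally
pooled into a "serial" condition before fitting (the per-direction fits
remain for signed-shift analyses). Fits are unweighted across tokens by
default because the design guarantees equal per-token n. RTs outside the
closed interval [250, 2500] ms are excluded; medians are per token over
retained trials. Split-half reliability splits every block at its temporal
midpoint and correlates per-subject β0 (pooled across orders and SNRs)
between halves.

**Trajectory geometry.** Pixel coordinates normalize to the unit square;
trials resample to T = 101 normalized-time points (the mouse-tracking
convention; the endpoint samples are preserved exactly). Left-target
trials reflect across the vertical midline so all trials reference the
right target; endpoint tokens pool as mean(Tk1 mirrored, Tk7). The area
under the curve (a.u.c.) is the shoelace area of the polygon closed by
the start–end chord, reported in normalized units² (resolution-independent;
a pixel rescale is a multiplication the caller can apply), signed positive
when the path bows away from the target, plus a cancellation-free
absolute variant (∫|lateral| d(along)). Proximity is 1 − d/max d toward
the response-box center with max taken per trial (a per-condition max is
available; the scope is genuinely ambiguous and per-trial is the default
because the start point is typically the farthest sample). Condition
curves average trial → subject → grand, so the running paired t-test
(two-tailed, α = 0.01 per sample, all maximal runs reported, min-run
length configurable, default 1) operates on subject-level curves. A
zero-variance sample yields p = 1 for identically-zero differences and
p = 0 for an exactly constant nonzero difference (logged).

**Statistics.** On this balanced within-subject design, classical
repeated-measures ANOVA on subject × condition cell means is used (with
partial η² = SS_effect/(SS_effect+SS_error) and each effect tested against
its own effect-by-subject interaction); subjects with missing cells drop
listwise with a log entry. This is a deliberate substitution for
trial-level mixed models: it tests the same hypotheses on cell means
without an REML dependency, at the cost of different (smaller) denominator
degrees of freedom — trial-level F statistics from mixed-model analyses
are therefore not comparable and are not targeted. Pairwise contrasts use
Holm step-down adjustment (exactly implementable; raw p always reported
alongside) rather than studentized-range-based corrections. Warping–
trajectory coupling is the Pearson correlation, per SNR stratum, between
per-subject |Δβ0| (serial − random) and the magnitude of the a.u.c. change
on pooled endpoint tokens; the RT correlation restricts to token 4, where
categories are most ambiguous.

## Problem sizes and verification

The test suite verifies: exact design arithmetic; the β0 = 50%-point
identity (1e−9); stimulus fidelity by LPC/autocorrelation measurement;
1e−9 dB SNR exactness; closed-form geometry oracles (shoelace vs
fine-grid rasterization within 1%, straight-line zero, the ½·0.5·1 = 0.25
right-angle toy path, mirror antisymmetry, proximity = t* for a
constant-speed straight approach); parameter recovery at the design's 30
trials/token (100 simulated subjects: median |β0 error| ≤ 0.15 token
units, median |β1 relative error| ≤ 20%, a generating warp of 1.0
recovered within ±0.15); monotonicity of the fitted shift in the
generating warp over {0, 0.5, 1.0, 1.5}; running-t-test type-I calibration
(1.0% ± 0.3% per sample over 2,000 null simulations of 29 subjects); and
the headline qualitative pattern at the full 29-subject scale (a.u.c.
reduction for serial order in noise but not clean, with a reliable
SNR × order interaction, and proximity divergence that starts earlier and
lasts longer in noise). Stochastic checks are seeded; simulation sizes
(100 subjects for recovery, 29 for the end-to-end pattern, 2,000 null
replicates) were chosen to keep Monte-Carlo error well inside each
asserted band.

## Known limitations

* The observer is a measurement model, not a process model: no evidence
  accumulation, no motor dynamics, no response-history effects.
* Endpoint-token trajectories are nearly straight (curvature is purely
  ambiguity-driven), so absolute a.u.c. magnitudes are smaller than
  typical human tracks; only ordinal condition structure is calibrated.
* The cell-mean ANOVA reproduces hypotheses, not trial-level degrees of
  freedom, of mixed-model analyses.
* Audio is synthesized at full scale but perceptual calibration (dB SPL,
  hardware) is out of scope.
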