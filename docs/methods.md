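# Methods

## The asymmetry statistic

For a right-hemisphere channel ch1 and a left-hemisphere channel ch2, the
per-epoch asymmetry in a frequency band is the mean over in-band frequency
bins of the natural-log ratio of one-sided Welch power spectral densities:

    Asym_band(ch1, ch2) = mean_{f in band} [ ln P_ch1(f) − ln P_ch2(f) ].

Two readings of the "mean" are possible — over frequency bins of the
per-bin log-density difference, or over time segments of scalar band-power
log-ratios; they coincide for flat in-band spectra. The per-bin reading is
implemented (it matches a per-frequency power-spectrum formulation and is
stable for narrow bands); band-edge bins are included when
f_low ≤ f ≤ f_high on the discrete grid. Bins with zero density in either
channel are excluded from the mean; an epoch with no valid bins is a
degenerate-epoch error. Because the statistic is a ratio, any gain common
to both channels — amplifier gain, filter roll-off at the band edges —
cancels exactly, and the log-density biases of the Welch estimator cancel
between the two channels, so the per-epoch statistic is unbiased for the
true log-power ratio.

Key numerical choices:

* Epochs are the 10 s window ending at each rating, samples
  `[round((t−10)·fs), round(t·fs))`. Reports whose window does not fit in
  the run are skipped, not zero-padded — padding would bias the PSD.
* Welch: 256-sample (2 s) Hanning windows with 50% overlap, density
  scaling, so a 1280-sample epoch yields 9 averaged periodograms at 0.5 Hz
  resolution and the delta band (0.5–3 Hz) still contains 6 bins.
* Band edges are clipped to [0.5 Hz, 0.95 × Nyquist] before filter design;
  at fs = 128 the gamma and "non" upper edges become 60.8 Hz (the nominal
  100 Hz bound is unreachable). An empty clipped band is an error.
* The default route band-pass filters the epoch (zero-phase 4th-order
  Butterworth, `sosfiltfilt`) before the PSD and then selects in-band bins;
  `prefilter=False` selects bins of the broadband PSD directly. Both are
  exposed because either could have been used upstream; results differ
  negligibly since the ratio cancels the filter response.

Quadrant signals are sample-wise means of the non-bad member channels
(left/right anterior: AF3 F3 F7 FC5 / AF4 F4 F8 FC6; left/right posterior:
T7 P7 O1 / T8 P8 O2) and enter the same statistic in place of ch1/ch2.

## Preprocessing

Detrending removes each channel's least-squares line (idempotent).
Re-referencing subtracts a chosen channel (AF3 or F3) from the posterior
sensor set only, mirroring a headset whose native reference sits close to
the posterior sensors; it is deliberately not idempotent and is refused
when the reference channel is flagged bad (the affected run is skipped and
logged).

Bad channels are detected with a probability criterion run twice: each
channel is robustly standardized (median / 1.4826·MAD), its samples'
negative mean log-likelihood is evaluated under a binned Gaussian-kernel
density (Silverman bandwidth, grid refined to at most half a bandwidth per
bin) of the *other* surviving channels pooled, and the measures are
z-scored across channels with flagging at |z| > 3. Zero-variance channels
are always flagged. Two design points deserve emphasis:

* *Leave-one-out pooling.* Evaluating a channel under a density fit to
  itself lets the fit explain away its own outliers; sparse ±500 µV spikes
  then never reach the threshold. Against the pooled density of the other
  channels they do.
* *Gain invariance.* Channels are standardized before pooling, so the
  measure responds to distribution shape (spikes, clipping, bimodality),
  not to a static gain. This is intentional: a pure gain multiplies the
  PSD uniformly, which shifts Asym by an additive constant and cannot bias
  its slope on the rating. A 50×-amplitude but otherwise Gaussian channel
  is therefore *not* flagged — and also not harmful to the inference. It
  also means genuine, sustained asymmetry (the very effect under study)
  is not mistaken for an artifact.

Wavelet-ICA and automated artifact-component classification are not
reimplemented (they form a separately published pipeline built around a
trained classifier); `run_analysis` accepts a `cleaner` callable as a hook
where such a step can be inserted. The synthetic generator produces
artifact-free data, with an injector (`flat`, `high_variance`, `spikes`)
for exercising the detector.

## Inference

Per participant and test, ratings reported fewer than 3 times are dropped
with their samples; a participant with fewer than 3 distinct surviving
ratings is excluded from that test (globally, pooled over runs, for cohort
selection; per test for the analysis, since bad channels differ per run
and pair). Left-handed participants are excluded up front.

SMOTE is reimplemented in its original form on the 1-D Asym feature:
every rating class is oversampled to the majority count by emitting
x + u·(x′ − x), u ~ U(0,1), where x′ is a uniformly chosen one of the
k = min(5, class size − 1) nearest same-class neighbours; originals are
always retained, so synthetics stay inside each class's [min, max]. The
balance-and-fit step is repeated 10× with seed-derived children and the
OLS slopes/intercepts averaged. The regression orientation is a config
switch; the default regresses SWB on Asym. Repeats with zero predictor
variance are skipped with a warning; a participant with no usable repeat
is dropped for that test.

The group test is a two-sided one-sample t-test of participant mean slopes
against zero with CI mean ± t(0.975, n−1)·SE; it requires ≥ 2 participants
and non-zero slope variance, otherwise the row is emitted with status
`insufficient_data` and kept out of the FDR family. Benjamini–Yekutieli
adjustment (statsmodels, `fdr_by`; validated against a brute-force
step-up oracle) is applied across the family of one run — one pair
universe, one band set, one reference scheme — at α = 0.1. p-values of
exactly 0 cannot arise from a t distribution; no epsilon flooring is
applied. All randomness flows from one master seed through deterministic
per-(test, participant) seed children; reruns are byte-identical.

Test families: anterior contralateral pairs (right {AF4, F4, F8, FC6} ×
left {AF3, F3, F7, FC5} = 16), posterior contralateral pairs
(right {T8, P8, O2} × left {T7, P7, O1} = 9), the two quadrant pairs, and
an expert "all" universe of every right×left sensor pair (49). Anterior ×
posterior cross pairs are never formed. Re-referencing is only accepted
for posterior/quadrant analyses, since only posterior sensors are
re-referenced.

## The synthetic generator

Each channel is a sum over bands of independent band-limited Gaussian
noise: complex standard-normal rFFT coefficients on the in-band bins, zero
elsewhere — white noise through an ideal band-pass — scaled to a per-band
RMS amplitude (defaults 20/10/10/5/2 µV for δ/θ/α/β/γ, a generic
resting-state profile). Frequency-domain synthesis gives an exactly flat
in-band spectrum, making the expected Asym of a coupled pair closed-form,
and costs one inverse FFT per band instead of a long filtering pass.

A coupling (chR, chL, band, γ) ties that pair's expected asymmetry to the
rating: within each 30 s inter-report segment with rating s, the band
component of chR is scaled by exp(+(γs+e)/4) and chL by exp(−(γs+e)/4),
e ~ N(0, asym_noise_sd), so the pair's expected Asym is exactly γs + e.
The scaling is split between the two channels rather than loaded on chR
alone: any single-channel scaling leaks the *full* slope into every pair
containing that channel, making the injected pair indistinguishable in
expectation from its neighbours; with the split, pairs sharing one coupled
channel inherit exactly half the slope and the injected pair is uniquely
strongest — visible in the README example, where the runner-up rows all
contain AF4 or F7. The scaling applies to the whole 30 s segment, not just
the 10 s analysis window, so the window always sees the intended ratio.

Ratings are i.i.d. from a configurable distribution; the default
{6: .28, 7: .28, 8: .18, 5: .10, 9: .06, 4: .04, 3: .03, 2: .01, 1: .01,
10: .01} concentrates mass on 6–8 the way comfortable participants report.
Handedness is assigned to exactly round(fraction·n) participants. One
master seed spawns per-(participant, run) children; generation is
bit-reproducible. Datasets round-trip through a documented directory
layout (per-run wide CSV — lossless — or 16-bit EDF via a minimal writer
read back with MNE; reports as TSV; metadata with seed provenance).

What the generator does *not* emulate: 1/f background spectra, volume
conduction and cross-channel correlation, ocular/muscle artifacts,
non-stationarity beyond the injected segment scaling, and
temperature–humidity covariates. Passing tests therefore demonstrate that
the inference machinery recovers what it is pointed at under a known,
well-behaved signal model — not that the effect exists in, or would
survive the artifact structure of, real recordings.

## Validation studies and sizes

Two Monte-Carlo studies exercise the pipeline end to end at desk scale on
one CPU (sizes are the package's own defaults; both synthesize only the
analyzed bands, since uncoupled out-of-family bands cannot influence
in-band asymmetries under the independent-band model):

* *Null calibration*: 200 replicates of 8 participants × 2 runs × 18
  epochs with no coupling, posterior universe × {alpha, beta}. The pooled
  fraction of raw group-test p-values below 0.05 is checked against the
  exact central 95% binomial interval. Tests within a replicate share
  channels and are positively dependent, which inflates the variance of
  the pooled fraction somewhat relative to the binomial reference; the
  check is kept in its exact-binomial form regardless.
* *Parameter recovery*: 50 replicates of 27 right-handed participants ×
  2 runs, γ = 0.3 on (AF4, F7, alpha), coupling noise SD 0.05, anterior
  universe × {alpha, beta}. The injected row must attain the smallest
  BY-adjusted p (ties at the minimum count — the step-up running minimum
  routinely equalizes the lowest ranks) with positive mean slope in ≥ 90%
  of replicates. Separately, pooling 288 epochs at zero coupling noise,
  the OLS slope of per-epoch Asym on the rating recovers γ; 288 epochs put
  the Monte-Carlo SD of that estimate near 3% of γ, so a ±10% check is a
  three-sigma margin.

## Known limitations

* The probability-based detector is blind to pure gain anomalies by
  design (see above); a criterion targeting amplitude would be needed if
  gain faults mattered for a different downstream statistic.
* Averaged-then-tested: the t-test sees only participant mean slopes, not
  the 10 per-repeat fits; repeat-level variance is deliberately collapsed
  first.
* The regression orientation (SWB on Asym vs Asym on SWB) changes the
  slope's units and attenuation behaviour; it is a single config switch,
  and reported CIs are in the units of the chosen orientation.
* EDF export quantizes to 16 bits over the recording's physical range;
  round trips are exact only in the CSV dialect.
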