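# Methods

This note documents the models implemented in `neurocode`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not establish about real recordings.

## Data model

All population analyses run on a trial tensor of shape
`(trials, neurons, time_bins)` with per-trial stimulus and session labels
(`containers.Ensemble`). Responses are rate-like and baseline-subtracted.
Feature vectors are built in two modes: *spatiotemporal* (every neuron's full
time course concatenated, N·K entries) and *spatial* (each neuron's
time-averaged rate, N entries). Synthetic ensembles carry their noise-free
templates and true pairwise correlations so estimators can be validated
against ground truth.

## Noise-corrected correlation

Trial noise attenuates the Pearson correlation between trial-averaged
population vectors. With R trials per stimulus the correlation of the
noise-free representations is estimated as the mean cross-stimulus
single-trial correlation divided by the geometric mean of the within-stimulus
across-trial correlations (ordered pairs r ≠ r′; the value is identical for
unordered pairs). Properties and conventions:

- The estimator is unbiased as the feature dimension grows; single estimates
  can fall outside [−1, 1] and are reported as-is, never clipped.
- Stimuli whose within-stimulus mean across-trial correlation is below 0.01
  are noise-dominated (the denominator approaches zero) and excluded before
  RSA; the comparison is strict (`< 0.01` excluded).
- Pearson correlations involving zero-variance vectors are undefined; such
  pairs are dropped from the means with a logged count.
- Within-trial noise correlations across simultaneously recorded neurons
  reduce the effective dimension; `popcode.shuffle_trials` removes them by
  permuting trial identity independently per neuron, preserving each neuron's
  marginal trial set exactly.
- Template generation (`synthio.make_correlated_templates`) orthonormalizes
  centered Gaussian draws (Gram–Schmidt) and mixes them with the Cholesky
  factor of the equicorrelation matrix, so realized template correlations
  match the request to < 1e−6.

Inference uses a session bootstrap: the statistic is recomputed on 100
resamples of sessions with replacement; p-values are two-sided and floored at
1/n_boot (0.01 at the default).

**Matrix-level dissimilarity.** The structural dissimilarity between two RSA
matrices is 1 minus the Pearson correlation of their upper triangles (range
[0, 2]). Because entry-level noise decorrelates two matrices even when their
latent structure is identical, `corrected_matrix_dissimilarity` mirrors the
trial-level correction at the matrix level: matrices are computed on disjoint
random trial halves, and the across-source upper-triangle correlation is
divided by the geometric mean of the within-source across-half correlations,
averaged over splits. This split-half construction is this package's own
definition (the matrix-level correction is not otherwise standardized) and is
validated on synthetic "areas" sharing latent structure but differing in
noise. Note that the attenuation correction is undefined when the latent
upper triangle is (near-)constant — with equicorrelated templates the
statistic is driven entirely by noise; heterogeneous latent structure is
required.

## Decoding

`decode.split_half` draws, independently for every unit and stimulus, a
random half of trials for training and the complement for testing (odd counts
put the extra trial in the train half). Each test-half average is assigned
the stimulus whose train-half average has the highest Pearson correlation;
exact ties go to the lowest stimulus index (counted and logged). Accuracy
curves average over 20 split seeds by default in the pipeline (5 in the small
configs); the seed list is recorded.

**Timescale restriction.** Each neuron's K-bin response is decomposed into
discrete Fourier coefficients C_n = Σ_k ν(k)·exp(−2πi·k·n/K) for
n = 0 … K/2 (the Nyquist limit). Band-n features are the per-neuron
real/imaginary pairs (2N entries); cumulative features concatenate bands
0 … n. The DFT sign/normalization convention is immaterial to a
correlation-based decoder; the band-0 coefficient is stored as the plain
time average (the same code path as spatial featurization), which makes
"spatial decoder ≡ band-0 decoder" an exact, bit-level identity rather than
a numerical approximation. No temporal pre-filtering is applied. For the
standard 750-ms response window this gives 24 bins of 31.25 ms at imaging
frame rates and 96 bins of 7.8125 ms for electrophysiology.

A caution discovered while testing: with templates that carry *no* feature
difference at all, half-split template decoding is not pinned at chance for a
single noise realization — which half of the trials each unit contributes
biases the correlations — so chance-level claims are asserted over fresh
ensemble constructions, not over split seeds of one ensemble.

## Reinforcement-learning model

The decision circuit is a Go unit with plastic excitatory weights w_E and an
inhibitory partner with weights w_I, both nonnegative. Per time bin,
y(t) = θ(w_E·X(t) − w_I·X(t) − ξ) with θ the Heaviside step (θ(0) = 0) and
ξ ~ N(0, ξ_sd²) drawn once per trial; the response is Go when ⟨y⟩ > 0.2 over
the 0.5-s window. Outcomes are R = +1 for a hit and −1 otherwise. Weights
update as δw_E = λ·f(e)·ElTr, δw_I = −δw_E, with prediction error
e = R − σ·(w_E − w_I)·ElTr and f(u) = u for u < 0, ν·u for u ≥ 0 (ν > 1:
unexpected rewards teach faster than omissions). Weights are clipped at 0.
An optional weight-proportional ("multiplicative") scaling of the step is
available behind a switch and off by default.

**Eligibility trace.** Synapses active coincidentally with the output are
tagged and the tag is read out at reward time through a gating kernel D(u)
(gamma-shaped, peak 1 s, support [0, 2] s, unit integral — a documented
stand-in for the measured striatal dopamine-gating window). Because D varies
over seconds while the response window is 0.5 s, the kernel acts within a
trial as a single gain at the trial's coincidence-to-reward lag:
ElTr = D(lag)·Σ_k X(k)·y(k)·dt. This is a deliberate design choice: applying
D bin-by-bin inside the window weights late bins more than early ones and
thereby opens a slow temporal matched-filter channel through which the model
can eventually discriminate time-shuffled patterns — contrary to the model's
purpose. Gating the integrated coincidence makes the rule structurally
rate-based: the seconds-long trace averages out pre/post timing inside the
window.

**Parameters.** λ = 0.002, ν = 3, σ = 0.5, ξ_sd = 0.5, threshold 0.2,
w_init = 0.01, reward delay 1 s. λ, ν, σ and ξ_sd have no canonical values;
they were chosen once so that the model (i) escapes the absorbing always-NoGo
state (zero output → zero trace → frozen weights, which occurs when decision
noise is far smaller than the learned drive), and (ii) reproduces the
qualitative ordering — spatial and rate differences learned within hundreds
to ~1500 trials, purely temporal differences never within 10,000. σ matters
for blindness: it sets the weight-norm equilibrium, and at σ = 0.5 the drive
saturates within trials (y constant per trial), closing the residual
temporal channel on every tested seed. All quantitative claims about this
module are property-based (ordering, blindness, monotonicity), never
absolute trial counts.

Learning curves are fractions correct per 150-trial block, averaged over 3
independent repeats; trials-to-criterion is the end of the first block whose
averaged accuracy reaches 80%, with sentinel max_trials + 1 when never
reached. The global activity difference between two patterns is
GAD = |ϑ₁ − ϑ₂| / (ϑ₁ + ϑ₂). Blank trials are not included in the trial
stream.

## Synthetic generators

`make_pattern_pair` builds 1000-neuron × 25-bin nonnegative patterns: each
entry uniform(0, 1) times a per-neuron gain uniform(0.5, 2) (both ranges are
package defaults; nothing canonical fixes them). The NoGo pattern derives
from the Go pattern by (i) per-neuron time-bin shuffling in a chosen fraction
of neurons — exactly mean-preserving, so it moves only spatiotemporal
similarity; (ii) resampling activity in a chosen fraction — moves spatial
(and necessarily spatiotemporal) similarity, leaves GAD ≈ 0 in expectation;
(iii) a global additive offset — moves only GAD (Pearson similarities are
exactly invariant to a common additive constant). Negative activities after a
negative offset are clipped at 0 and logged. Realized similarity metrics are
recorded next to the requested knobs.

`make_noisy_ensemble` standardizes templates to zero mean and unit SD so the
noise scale is in signal-SD units; trials are template + independent Gaussian
noise, and session labels partition trials evenly.

`make_fluorescence` is the forward model inverted by preprocessing:
rate convolved with exp(−t/τ), plus baseline, neuropil contamination, and
white noise.

**What the generators do not emulate:** correlated noise across neurons
(except where constructed explicitly), non-Gaussian and multiplicative
calcium noise, slow drifts and motion artifacts, overdispersed spike counts,
and realistic stimulus-dependent response manifolds. Passing tests therefore
establish the estimators' and models' mathematical behavior, not performance
on any particular real dataset.

## Preprocessing

ΔF/F uses a sliding 3rd-percentile baseline of a Gaussian-filtered trace
(window 60 s, pre-filter SD 1 s — both configurable; the window length is
not canonical). Deconvolution is the linear operator r = f′ + f/τ with
τ = 2 s and central differences (one-sided at edges), followed by Gaussian
smoothing (σ = 31 ms, kernel truncated at ±4σ and renormalized). Linearity
holds to 1e−9 before smoothing; the exp(−t/τ) cancellation identity holds up
to the O(dt²) finite-difference truncation error.

The reproducibility index of a neuron is the mean pairwise across-trial
correlation of its response, averaged over stimuli (undefined pairs from
zero-variance responses are dropped; a neuron with no defined pair scores 0).
Units below 0.12 are flagged non-responsive. The population-level index per
stimulus uses the full concatenated population sequence.

Cluster reduction groups neurons by Ward agglomerative clustering (standard
for Euclidean profile distances) on their full temporal responses to all
stimuli, and selects the smallest cluster count whose cluster-mean RSA matrix
explains ≥ 95% of the variance of the full-population RSA matrix, where
"variance explained" is the squared Pearson correlation of upper triangles
(a package definition; no canonical one exists). This quantity is *not*
monotone in cluster count at small counts, so the selection scans counts
upward and returns the first that reaches the target.

## Auditory periphery layout

CFs are geometrically spaced at 12 IHCs/octave from 5 kHz (40 IHCs);
positions follow x = −56.5 + 82.5·log₁₀(CF) (base-10: it reproduces the 1.2%
apex position and 2.07% increment, natural log does not). Fibers per IHC
follow the quadratic N = −0.0038x² + 0.375x + 7.9 with nearest-integer
rounding per IHC; both the rounded and unrounded totals are 590 on the
default grid. Spontaneous rates are sampled log-uniformly in [0.5, 95]
spikes/s (the sampling distribution is a package default) and mapped to
calcium clearance constants by inverting SR = 91.1·τ_Ca^2.66. The grid's
last CF is 47.6 kHz and its base position 81.9%, slightly short of a
nominal 50-kHz/83.9% endpoint — an internal inconsistency of the printed
constants that the package resolves in favor of the formulas.

## E/I integrate-and-fire motif

Two LIF neurons (V_m = −65, V_T = −50, V_R = −70 mV, τ_M = 10 ms): E is
driven by pulse-train input A (J_A = 0.09) and inhibited (J_I = 0.04, delay
τ_I = 2 ms) by neuron I, which is driven by input B (J_B = 0.09). The leak
is the standard form τ_M·dV/dt = −(V − V_m) + inputs. Input pulses are
rectangular with amplitude 250 (so J·amplitude = 22.5 mV of drive,
suprathreshold from rest — the amplitude scale is a package choice; unit
pulses with the printed J values would never reach threshold); each
inhibitory spike produces a 5-ms rectangular IPSP. Integration is fixed-step
Euler–Maruyama (dt = 0.05 ms, guarded to ≤ 0.1·τ_I); no refractory period
beyond reset is imposed. Zero-noise runs are deterministic, and the
constant-drive inter-spike interval matches the closed form
τ_M·ln((V∞ − V_R)/(V∞ − V_T)) within 2%.

The order experiment drives A-then-B and B-then-A with 225-ms, 20-Hz pulse
trains at varying onset lags: with overlap the B-driven inhibition truncates
E spiking asymmetrically between orders (a relative-timing cue becomes a
rate cue); at a 250-ms lag the orders produce identical counts, and removing
the synapse (J_I = 0) abolishes the effect exactly. The deterministic order
effect is on the order of one spike, so noisy-regime claims use the signed
count difference with a bootstrap CI over seeds.

## Problem sizes

Test-suite and acceptance runs use the sizes the analyses were designed
around where they are cheap (N = 2000 features, 15 trials, 200 seeds for
estimator recovery; 1000 × 25 patterns and 10,000-trial runs for the RL
blindness property) and scaled-down ensembles (tens of neurons, ~10 trials)
for structural identities that hold at any size.

## Known limitations

- The RL model's blindness to temporal structure is structural given the
  trace definition, but the learning-speed numbers depend on the unprinted
  (λ, ν, σ, ξ_sd) and are meaningful only as orderings.
- The corrected estimator assumes noise independent across trials; slow
  drifts shared by neighboring trials bias the within-stimulus terms.
- The matrix-level dissimilarity correction is a package construction, not a
  community standard.
- The periphery module builds layouts only; no transduction cascade or spike
  generation is included.
- `pipeline.run_all` is an orchestration convenience for synthetic flows; it
  does not implement ingestion of real recording formats.
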