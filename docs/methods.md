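# Methods

This note documents the models, parameter choices and numerical conventions
behind `nirsdmst`, and what its validation on simulated data does and does
not establish about real recordings.

## Task and design generation

The delayed-matching-to-sample trial is S1 → 6 s silent delay → S2 → 3 s
response window → 5–9 s uniformly jittered silence. Items last 500 ms with a
100 ms inter-stimulus silence (600 ms SOA), so an n-item trial spans
`2·(600·n − 100) + 6000` ms (11800 ms for five items). Blocks hold 16 slots;
slots 1, 6, 11 and 16 are long silent trials (22.8–26.8 s in the 2×2 design,
26.4–30.4 s in the load design) that let the hemodynamic signal return to
baseline and serve as the implicit baseline of the FIR model.

Sequences draw from six-item inventories. The musical inventory is ordered
by pitch (C2 < E2 < G2 < B2 < D3 < F3); a sequence's *contour* is its
up/down pattern of successive intervals. Construction rules:

* 2×2 design (five items): all items distinct; musical sequences contain at
  least one rising and one falling interval. "Different" S2s replace the
  item at position 2, 3 or 4 (balanced) with the single unused inventory
  item; for musical material the replacement must change the contour —
  positions where it would not are rejected and the S1 redrawn.
* Load design (4–8 items): repeats allowed, but never of the first item,
  never with fewer than two intervening items, at most three occurrences per
  item, and no repeated 3- or 4-item sub-pattern. "Different" S2s swap two
  adjacent items (never the first; swap positions balanced over admissible
  indices, remainder randomly assigned), which necessarily flips one
  interval and hence the musical contour.
* Perception-task S2s control only the final item pair (identical in half
  the pool; when different, musical final pairs span at most three pitch
  ranks). When the final pair is identical, the distinctness and contour
  rules exempt only that pair.

Ordering constraints (≤3 consecutive same/different, ≤3 consecutive of one
load, ≤4 of one material) are enforced by rejection sampling with a 10,000
retry cap; the constraint set is loose, so rejection is cheap and exact.
A run constraint is applied only when a block actually mixes levels of that
factor. Block order across participants follows the Williams construction:
for an even number of conditions a single Latin square in which every
ordered condition pair is adjacent exactly once; for odd numbers the square
plus its mirror (2n rows).

## Forward simulation

The hemodynamic response is a double gamma, `g(t; 6, 1) − g(t; 16, 1)/6`,
peak-normalized, peaking at 5 s. Each condition's expected response is the
convolution of that kernel with a boxcar spanning S1 onset to S2 offset,
peak-normalized and scaled by the condition's effect size in µM HbO
(HbR = −0.3 × HbO, a typical empirical ratio).

The simulator injects this response *piecewise-constant over the 1-second
FIR bins* (the smooth convolution sampled at bin centers and held within
each bin). This is deliberate: the injected signal then lies exactly in the
span of the FIR design matrix, so on noiseless data ordinary least squares
must return the ground-truth bin heights to machine precision, and any
discrepancy is an implementation defect rather than discretization error.
The acceptance suite verifies recovery below 1e-6 µM; measured error is
~1e-14. The corollary is that FIR-recovery tests validate the estimator's
algebra, not its behavior under model mismatch (real responses are smooth,
not binned); the band-pass/TDDR distortion of real hemodynamics is likewise
outside what these tests certify.

Systemic physiology is a four-component latent signal — cardiac (1.2 Hz),
respiratory (0.25 Hz), Mayer waves (0.1 Hz) and slow drift (0.008 Hz) —
shared across all channels with per-channel gains drawn uniformly from
[0.5, 1.5]; short (0.8 cm) channels carry only systemic signal and noise.
This low-dimensional shared structure is precisely the premise of
short-channel regression. Cardiac and respiratory components fall outside
the analysis band and are removed by the filter; the Mayer component falls
inside it and is what the nuisance regressors must absorb. HbR receives the
systemic signal scaled by +0.3 (systemic fluctuations co-vary positively
across chromophores). Sensor noise is white Gaussian in concentration and
optionally multiplicative log-normal on intensity (photon-count-like,
keeping intensities positive). Motion artifacts are Poisson-timed
exponential spikes (0.25 s decay) and step baseline shifts in the
optical-density domain, each logged.

The montage is schematic: 22 long channels with separations spread over
2.9–4.1 cm and 8 short channels at 0.8 cm, with synthetic positions on a
frontal arc. Eighteen long channels are assigned to five ROIs (lIFG 3,
rIFG 3, ldlPFC 4, rdlPFC 4, SFG 4); four are recorded but unanalyzed,
mirroring typical channel exclusions. Geometry carries no anatomical
meaning; only separations, short flags and ROI membership matter downstream.

Behavior follows an equal-variance SDT model: a different-trial is answered
"different" with probability Φ(d′/2 − c), a same-trial with Φ(−d′/2 − c);
response times are log-normal around a per-cell median, and draws beyond the
3 s window are recorded as missed.

## Preprocessing

Fixed order, asserted via provenance flags: intensity → optical density
(`−ln(I/mean I)`; the DC concentration level is therefore unidentifiable,
and round-trip checks compare mean-centered series) → TDDR → band-pass →
Beer–Lambert inversion.

TDDR splits each series at 0.5 Hz (3rd-order zero-phase Butterworth),
robustly re-estimates the location of the low-frequency temporal derivative
with Tukey biweight weights (tuning constant 4.685, scale 1.4826·MAD,
convergence 1e-8, ≤50 iterations), rescales derivative deviations by their
final weights, re-integrates anchored at the first sample, and restores the
high-frequency part. One deliberate difference from the published reference
implementation: the robust mean derivative is retained
(`μ + w·(deriv − μ)`) rather than removed, so drift-free inputs such as
linear ramps pass through unchanged; the reference subtracts the mean slope.
The two outputs differ only by a linear trend, which the band-pass removes,
and agree to ~1e-8 RMS after detrending. TDDR strongly suppresses step
artifacts (~98%, matching the reference) but only partially suppresses
sub-second spikes, whose energy lies above the 0.5 Hz split by construction
— a property of the algorithm, not of this implementation.

The band-pass is a zero-phase (forward–backward) Butterworth of order 5 per
pass, 0.01–0.2 Hz. Order 5 is the smallest meeting the attenuation contract
with margin at this sampling rate: the two-pass response is −21.9 dB at
0.25 Hz (respiratory), −167 dB at 1.2 Hz (cardiac), and flat (±0.01 dB) at
0.05 Hz; order 3 would reach only −14.5 dB at 0.25 Hz.

Beer–Lambert inversion solves the per-channel 2×2 system with extinction
coefficients from the standard compiled tables (760 nm: 1.4866/3.8437,
850 nm: 2.5264/1.7986, in 1/(mM·cm), HbO/HbR) and DPF 6.0 at both
wavelengths, all overridable. The partial-volume factor is fixed at 1, so
concentrations are in a µM·(effective pathlength) convention; only relative
betas matter downstream.

## FIR GLM

For each participant, all blocks are fitted jointly in one concatenated OLS
GLM per channel and chromophore. The design holds 36 one-second boxcar
regressors per condition anchored on S1 onset (2×2 design, window start
−5 s) or delay onset (load design, start −9 s, since S1 duration varies
with load); one boxcar per block (no global intercept — block regressors
absorb offsets and would be collinear with an intercept); and the
preprocessed short-channel series (8 channels × 2 chromophores), reduced to
an orthonormal basis. Orthonormalization cannot change the FIR estimates
(OLS is invariant to invertible recombination within a regressor block); it
only conditions the solve, and the suite asserts the invariance.

Bin convention: 36 bins labeled by integer start offsets from the window
start, so the supported range is [start, start + 36) seconds around the
anchor — [−5, +31) and [−9, +27) for the two designs. This convention is
recorded in the design metadata. A sample belongs to the bin containing its
timestamp (half-open intervals); at 7.81 Hz a bin holds 7 or 8 samples and
no fractional weighting is used. Overlapping FIR support within a condition
is summed with a warning (events are far apart by design). ROI betas are
unweighted channel means.

## Bayes-factor statistics

The JZS t-test BF places a Cauchy(0, √2/2 by default) prior on the
standardized effect and integrates the g-representation by adaptive
quadrature; it matches an independent fine-grid oracle to <0.1% and an
external implementation to ~1e-4.

The repeated-measures ANOVA BF follows the default mixed-model g-prior
construction: the response is centered; each effect term (fixed factors,
their interaction, participant intercepts, per-factor participant slopes)
receives orthonormal sum-to-zero coding and its own g with
InvGamma(1/2, h²/2) prior — h = 0.5 for fixed terms, 1.0 for random terms.
In a balanced within-subject design all term subspaces are mutually
orthogonal (asserted numerically, not assumed), so the marginal likelihood
reduces to sums over per-term eigenvalues and data projections; models with
one g integrate by quadrature (log-space, mode-shifted), multi-g models by
Monte-Carlo over g draws (default 100,000; 20,000 per bin in the
time-course loop) with common random numbers for terms shared across
models and a delta-method standard error on the log BF. Per-(ROI, bin)
seeds derive deterministically from the master seed. Models within one
combined standard error of the best are flagged as tied. Unbalanced tables
are rejected; zero-variance responses raise and are recorded as undefined
bins by the time-course driver rather than crashing it.

The candidate set for factors (A, B) is {A, B, A+B, A+B+A:B} against the
random-effects-only null; the best model is reported when its BF10 exceeds
1. Inclusion BFs use matched models under equal prior probabilities.
Post-hoc cascades: a best model containing the task-by-material interaction
triggers per-material paired t-tests of the task effect; a best model with
the load-by-material interaction triggers per-material one-factor load
ANOVAs (participant intercepts only, as in the behavioral analyses) and,
where those show a load effect, pairwise load t-tests.

Two parameterizations of the participant term are supported. The default
places a g-prior on participant intercepts and per-factor slopes. The
alternative (`participant_prior="flat"`) integrates participant intercepts
out with a flat prior (restricted likelihood, with the corresponding
degrees-of-freedom reduction); for a single two-level factor this reduces
*exactly* to the paired JZS t-test on within-participant differences at the
same scale, which is how the correspondence between the two routes is
verified.

### Calibration of the random-slopes model

A consequence worth stating plainly: with one observation per participant
and cell, participant-slope variance and residual variance are confounded.
Under the g-prior the slope terms adaptively absorb contrast variance,
deflating the implicit residual and making fixed-effect BFs
anticonservative. On null simulations (n = 16, 24 bins × 5 ROIs), ~13% of
cells show a task-containing best model at BF10 > 1 and ~11% of cells reach
BF10 > 3 under the random-slopes default, versus ~9% and ~4.6% with
intercept-only random effects — the latter matching paired-t theory
(P(BF10 > 1 | null) = 10.5% at scale 0.5, n = 16). This was verified against
a brute-force dense-covariance computation of the same marginals, so it is a
property of the model, not of the implementation. The time-course default
keeps the random-slopes parameterization (it is the published analysis
form), every result table records which parameterization was used, and the
acceptance script reports both calibration numbers. Users wanting
BF-threshold calibration closer to the nominal intuition should prefer
`random_slopes=False` or raise the evidence threshold.

## Behavioral statistics

Hits are "different" responses on different trials; false alarms are
"different" responses on same trials; missed (timed-out) responses are
excluded everywhere. The log-linear correction is applied unconditionally to
every cell — H = (hits + 0.5)/(n_signal + 1) and likewise for false alarms —
so d′ = z(H) − z(F) and c = −(z(H) + z(F))/2 are always finite. The
correction shrinks extreme cells toward chance: with few trials per cell the
estimator is visibly biased at high d′ (at 6 + 6 trials, true d′ = 2.5 is
recovered near 2.1), which is a property of the corrected estimator, not a
defect. Recovery validation therefore uses 120 trials per trial type, where
the residual shrinkage is small (d′ recovered within ±0.04 at d′ ≤ 2.5 over
200 simulated participants); consistency is asymptotic in trial count. RT
summaries average correct, non-missed trials per requested cell.

## Problem sizes and reproducibility

Validation problem sizes: noiseless FIR recovery uses 16 participants × 4
blocks; short-channel efficacy 20 independent seeds of one participant;
time-course recovery n = 16 (2×2) and n = 24 (load design) with effects at
twice the noise standard deviation; null calibration 100 replicates of the
full 5-ROI × 24-bin grid at 2,000 Monte-Carlo samples per model (BF
thresholds are insensitive to the remaining ~2% Monte-Carlo error); SDT
recovery 200 participants × 120 trials per type. Every random quantity in
the package and in `scripts/acceptance.py` derives from a single master
seed through SHA-256-based stage seeds; deterministic stages reproduce
bit-for-bit, as the run-manifest checksums assert.

## Known limitations

* The simulator generates FIR-form (binned) neural responses and
  low-dimensional sinusoidal systemics; passing tests demonstrate correct
  estimation under the model's own assumptions, not robustness to smooth
  responses, non-stationary physiology, serially correlated noise (no
  prewhitening is implemented) or real optode-coupling artifacts.
* Verbal items are opaque labels; no phonological distance is modeled.
* Channel pruning by coupling quality, wavelet/spline motion correction,
  and anatomical (photon-transport) forward models are out of scope.
* The SNIRF writer/reader covers the subset of the format the pipeline
  produces (continuous-wave intensity, one data block), not arbitrary files.
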