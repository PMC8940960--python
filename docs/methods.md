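# Methods

This note records the models, conventions and design choices behind
`hrvfatigue`, and what the synthetic cohort does and does not establish.

## Analysis conventions

**Time domain.** All standard deviations (SDNN, SDSD) use the population
convention (1/N) by default, with a `ddof` switch for the sample
convention; RMSSD always divides by the number of successive differences.
meanHR is 60000/meanRR — the rate of the mean interval — not the mean of
per-beat rates; the two differ by Jensen's inequality and conflating them
is a classic HRV pitfall. CV is reported as the dimensionless fraction
SDNN/meanRR. The pNNx thresholds are strict inequalities (|ΔRR| > x ms),
normalized by N−1 pairs.

**Spectral analysis.** The RR tachogram is unevenly sampled by nature, so
it is cubic-spline interpolated (not-a-knot) onto a uniform 4 Hz grid —
comfortably above twice the 0.4 Hz HF edge — with each interval attached
to the time of the beat that ends it. The default PSD is Welch with a
single full-record (300 s) Hann window and linear detrend. A conventional
choice of shorter (e.g. 120 s) detrended segments was rejected after
measurement: VLF components have periods up to 333 s, longer than such a
segment, so per-segment detrending annihilates them, and segment
averaging roughly doubled the realization scatter of band powers on
5-min records without improving bias (for band-integrated power the
effective number of degrees of freedom is bounded by bandwidth × record
length either way). Segment length remains a parameter. Band powers are
trapezoidal integrals over VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz;
ULF is excluded because it is meaningless on 5-min epochs. Normalized
powers use the LF+HF denominator, the standard short-term convention that
makes LFnorm + HFnorm ≡ 1. When HF power is exactly zero LF/HF is
reported as NaN (an undefined marker), never infinity. The Burg AR
spectrum (default order 16) is offered as an alternative estimator on the
same grid.

**Poincaré descriptors.** SD1/SD2 are computed as the population SDs of
the point cloud projected across/along the identity line. The closed
forms SD1 = (√2/2)·SDSD and SD2 = √(2·SDNN² − SDSD²/2) are exact only
when the variances are taken over the lag-1 pair ensemble (the first and
last N−1 intervals and their covariance); with SDNN over all N intervals
they hold to O(1/N). Every call cross-checks the projection route against
the pair-ensemble closed form at 1e-9 relative tolerance and raises on
disagreement, so the two derivations guard each other. A negative SD2
radicand is impossible under consistent definitions and is treated as an
internal error, not clamped silently.

**Sample entropy.** Template vectors use delay embedding (dimension m,
delay τ; defaults m = 2, τ = 1). Both orders are evaluated over the same
N − m·τ templates so the statistic is a genuine conditional probability;
distances are Chebyshev, the comparison is ≤ r, self-matches are
excluded, and the default tolerance is r = 0.2 × series SD (the
conventional point in the 0.1–0.25 SD range). A constant series resolves
r against a tiny absolute floor and yields entropy 0; absence of any
match at order m+1 yields NaN, never an exception or infinity, so cohort
tables can carry it as missing. The implementation is vectorized but is
pinned, on every random series up to n = 200, to a literal double-loop
oracle written independently in the test suite.

**Entropy panel.** Three channels per record: RR intervals,
instantaneous HR, and the R-peak amplitude series when amplitudes are
available (they are absent-marked otherwise, e.g. for RR-only input
files).

**Cohort contrast.** The normality screen is Lilliefors' corrected K–S
test — parameters are always estimated from the data here, so the plain
K–S null would be anticonservative; reports label it accordingly. The
paired-state association is Spearman ρ over within-subject
(nonfatigue, fatigue) pairs. Location differences use the two-sided
Mann–Whitney U: an own exact enumeration over all C(n_a+n_b, n_a)
group assignments (handles ties; limited to 20 observations total) and
the tie/continuity-corrected normal approximation via scipy for larger
groups; the two agree within 0.02 in p for groups of ≥ 8 without heavy
ties. Stars follow the ** p < 0.001 / * p < 0.05 convention. No
multiple-testing correction is applied in the primary tables — the
protocol reports per-feature tests — but a clearly-labelled supplementary
Holm–Bonferroni column is emitted alongside. KDE summaries use Gaussian
kernels (Silverman bandwidth) renormalized to integrate to exactly 1 on
their grid.

**FS-14.** 14 Likert items in 1–5; the physical/mental partition is
configuration (defaults: items 1–8 physical, 9–14 mental, matching the
8/6 split of the instrument). Totals are sums; no reverse-coded items are
assumed.

## Synthetic cohort model

The generator emulates the paired field design: 38 male and 27 female
subjects by default, each with a rested and an end-of-shift 5-min RR
series, R-peak amplitudes and FS-14 responses.

**Tachogram.** RR(t) = mean_rr + Σ_band s_band(t) + ε, evaluated at the
running cumulative beat times (so the series is irregularly sampled by
construction, as real tachograms are), with ε per-beat Gaussian jitter.
Each band process s_band is a random-phase multisine: equal-amplitude
cosines on the record's Fourier grid (spacing 3/T, inset 2/T from the
band edges) whose phases are drawn from the seeded generator and whose
amplitudes sum to exactly the configured band variance. With dozens of
components this is an asymptotically Gaussian band-limited process, but —
unlike filtered white noise, which was tried first — its in-band power is
deterministic: the 3/T spacing makes Hann-windowed components exactly
orthogonal over the record, so the spectral module recovers configured
band powers within a few percent on every seed, rather than with the
~25–35% realization scatter that any stochastic-envelope process exhibits
at bandwidth × 300 s degrees of freedom. Intervals are floored at 250 ms;
optional ectopic beats are isolated halvings/doublings, which exercise
the artifact filter. The R-peak amplitude channel is a stationary AR(1)
process around 1 mV.

**State calibration.** Defaults encode the fatigue contrast the package
is designed to detect: mean RR 845 → 698 ms; band variances
(VLF, LF, HF) = (2000, 1450, 483) → (880, 782, 131) ms², giving SDNN
≈ 64 → ≈ 44 ms; beat jitter 5 → 10 ms (a more erratic rhythm when
fatigued, which is also what raises RR/iHR sample entropy); amplitude
AR(1) coefficient 0.92 → 0.80 (rougher amplitude series, higher
amplitude entropy). The fatigue HF variance is set so that the *measured*
LF/HF — which includes the broadband floor the beat jitter contributes to
every band — lands near 4.8 against the rested ≈ 3.0. Per-subject
heterogeneity is a multiplicative lognormal jitter (SD 0.08) on mean RR,
each band power and the jitter scale, shared between the two states so
the design is genuinely paired; gender scales mean RR per state by a few
percent (females rest slower and fatigue faster in the default
calibration). FS-14 items are round-and-clip Gaussians whose latent means
are solved numerically (Brent on the discretized-normal expectation) so
cohort-level subtotals hit physical 12.6/34.2 and mental 9.0/15.2 —
the discretization bias near the scale ends makes naive mean-setting
land visibly off target.

**ECG rendering.** One Gaussian template per beat (width 80 ms ≈ a QRS
complex, vanishing at ±3σ), 500 ms lead-in/out so boundary beats are
detectable, default 256 Hz. This supports the detector round-trip
contract (intervals recovered within one sample period) and noise
benchmarks; it is not a morphological ECG model.

**What passing tests show — and don't.** The synthetic cohort has, by
construction, stationary band-limited modulation, Gaussian tails,
no respiration–cardiac coupling, no transients, no electrode artifacts
beyond injected ectopics, and a schematic QRS. Green tests therefore
demonstrate that the *pipeline* is correct (formulas, conventions,
estimators, statistics, plumbing) and that effect directions propagate
end to end; they do not validate physiological claims about real worker
ECG, nor detector performance on pathological morphologies.

## ECG processing choices

Band-pass: cascade of Butterworth high-pass (0.5 Hz) and low-pass
(40 Hz), order 6 each, applied forward–backward (zero phase). A single
band-pass SOS section over edges two orders of magnitude apart was
numerically fragile; the cascade leaves a 50 Hz mains tone below 5% of
its input amplitude and is flat in band. The R-peak detector is a
derivative–squared–integrate design with an adaptive threshold (30% of
the 98th energy percentile), a 200 ms refractory period, and refinement
to the raw-trace maximum within ±100 ms; any detector meeting the
round-trip and SNR-10 dB recall/precision ≥ 0.95 contracts would be
acceptable. Artifact filtering drops intervals outside 300–2000 ms or
jumping more than 30% from the previous accepted interval (conventional
thresholds for adult HRV); removing more than 20% of a record flags a
quality failure without discarding the series — exclusion is a reported,
never silent, decision at the cohort level.

## Problem sizes

Default records are 300 s (≈ 350–430 beats), the canonical short-term
HRV epoch; the entropy panel is O(n²) in beats and the full 65-subject
end-to-end run completes in well under a minute on one core. The exact
Mann–Whitney enumeration is capped at 20 observations because C(20,10)
assignments is the practical enumeration limit and the corrected normal
approximation is already accurate there.

## Known limitations

- The surrogate tachogram's comb-like in-band spectrum (0.01 Hz tooth
  spacing) is an idealization; real LF/HF peaks are broader and drift.
- Sample entropy of the iHR channel is nearly redundant with the RR
  channel on clean data (the transform is monotone); it differs mainly
  under artifacts.
- The exact Mann–Whitney p is defined by distance from the null mean of
  U; other two-sided conventions (doubling the smaller tail) can differ
  slightly in heavily tied data.
- `ecg_files` mode assumes a positive R deflection; inverted leads should
  be negated on ingest.
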