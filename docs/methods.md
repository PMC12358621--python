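# Methods

## Montage and pair enumeration

The montage is fixed at eight channels on a 2×4 grid, ordered frontal
right, temporal right, parietal right, occipital right, occipital left,
parietal left, temporal left, frontal left. Regions carry
anterior-posterior ranks (frontal = 1 … occipital = 4); an unordered pair
is graded by the absolute rank difference ("diagonal grade") and assigned
H(1 + grade) when the channels sit on opposite hemispheres, V(grade)
otherwise. This one rule reproduces the seven groups and their sizes
(H1 = 4, H2 = 6, H3 = 4, H4 = 2, V1 = 6, V2 = 4, V3 = 2) and fixes the
membership of H4 — the two fully diagonal interhemispheric pairs
(fr/ol and or/fl) — which the grading implies even though only lower
grades are usually spelled out. Pair indices are lexicographic on
(smaller channel, larger channel); this puts the occipital mirror pair at
index 19 and the right occipitotemporal pair at index 9, the two pairs
where the guest-box effects concentrate. The scheme is deliberately
specific to this montage: arbitrary channel counts or 10–20 coordinate
geometry are out of scope.

## Recordings, units and segment selection

Signals are (8 × n) arrays in µV at fs = 1000 Hz nominal; indexing is
0-based half-open everywhere. EDF files are read (via mne, physical units
converted to µV, channels reordered by label); the writable interchange
format is a plain TSV matrix plus a YAML sidecar, which keeps fixtures and
simulated cohorts text-only and diffable. Artifact screening on real data
is expert work; the package substitutes a transparent rule — maximal runs
where every channel stays within 200 µV of its own median, at least 10 s
long — and accepts pre-annotated segments so an expert selection can be
injected instead. Analyses concatenate the per-segment results (each
segment is filtered on its own, avoiding transients across joins) and the
segment list is recorded alongside outputs rather than assuming any fixed
duration per night.

## Band decomposition

Five bands: delta 0–4 Hz as a pure lowpass (the acquisition is full-band
DC, and sustained potentials are part of the delta-band signal), theta
4–8, alpha 8–13, beta 13–30 and gamma 30–120 Hz as bandpasses. All are
3rd-order Butterworth designs with normalized cutoffs Wn = f/(fs/2),
applied forward-backward, so the net phase shift is zero and the
effective gain is |H(f)|² — exactly ½ at a band edge. Edge transients are
suppressed by scipy's odd-reflection padding (3·max(len(a), len(b))
samples per end; for the order-3 lowpass this equals the conventional
3·(order+1) pad). No mains notch is applied by default — segments with
line noise are meant to be excluded, mirroring the screening rule — but a
50 Hz notch helper exists for data where exclusion is impractical. Band
definitions are overridable wherever a band argument is accepted
(name, (low, high) tuple, or BandSpec).

## Rank-biserial pair correlation

The per-pair statistic is the two-sample rank-biserial correlation
r = 2U/(n₁n₂) − 1 with ties counted ½, computed by the rank-sum identity
(O(n log n)) and validated in the tests against an O(n²) counting oracle.
Interpretation matters here: r measures stochastic dominance of one
channel's amplitude distribution over the other's, not waveform
covariance — two identical series score exactly 0, while a sustained
offset between sites drives r toward ±1. On full-band DC recordings the
delta band (which retains such offsets) is therefore the band where
interhemispheric potential asymmetries — the occipital FNE signature —
show up; mean-free bandpass bands stay near zero. The shared-variance
coupling that moves Pearson-type statistics leaves r's expectation at
zero, which is why the synthetic guest presets encode the pair-19 effect
as a slow-potential asymmetry (below) rather than as coupling.

Bootstrap intervals are percentile intervals over n_boot = 3000 resamples
of time indices with replacement, drawn independently for the two
channels; a paired mode (one index draw for both) and a moving-block mode
(for honesty about autocorrelation, which the default treats as absent)
are available behind config flags but off by default. Intervals are
deterministic given the seed. Cohort aggregation is the element-wise
median over subjects per condition, and condition comparison is the
home − guest difference map; the 0.8 significance threshold on the median
map is strict (>).

## Coherence

Welch magnitude-squared coherence with Hann window of 2000 samples,
overlap 100, nfft 1000 at fs = 1000 Hz. Because the window exceeds the
transform length, each tapered, mean-removed segment is wrapped modulo
nfft and summed before the FFT — the time-aliasing behaviour of
MATLAB-style estimators, reproduced here deliberately so the stated
parameters mean what they say; a conventional nperseg = nfft mode is the
cross-check route (the two agree exactly when the window fits the
transform, which the tests verify against scipy). The one-sided grid runs
0–500 Hz in 1 Hz bins. Estimates from fewer than two segments are
rejected as degenerate (one segment gives MSC ≡ 1) rather than returned.
The small-sample bias of the estimator — mean coherence ≈ 1/K for K
windows of independent noise — is asserted in the tests.

The cross-frequency variant correlates the delta-filtered series of one
channel with the raw series of the other; both orientations (A→B, B→A)
are computed, since nothing fixes which one a given analysis used — on
the synthetic cohorts they are indistinguishable. Within-delta coherence
is the same spectrum read at bins ≤ 4 Hz. Cohort results live in a
frequency × pair × subject cube; subjects without analysable segments are
NaN columns, the median view ignores them, and the 0.8 mask is strict.

## Grouped zero-lag connectivity

Zero-lag normalized cross-correlation (mean-removed inner product over
the product of norms) per band-filtered pair; zero-variance inputs are an
error, not a silent 0. Per group, the normalized count is
(pairs with r ≥ 0.8)/(group size) — inclusive at the threshold for this
statistic, in contrast to the strict coherence mask; the two conventions
are kept distinct on purpose. Delta is excluded from the grouped analysis
by default: a broadly shared slow source saturates every group's count
(asserted on a synthetic fixture), so the band has no discriminative
value there. Differences are home − guest per subject. The rank-sum test
uses the exact null distribution when both samples have ≤ 10 values and
no ties, and the normal approximation with tie and continuity corrections
otherwise; the two paths agree within 0.02 in p at n = 10 (calibration
property in the tests). No multiple-testing correction is applied by
default, matching the descriptive use of the 28 (band × group) tests; a
Benjamini-Hochberg flag exists.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline must detect:

* **Background**: per-channel 1/f noise (exponent 1.0, SD 4 µV) plus a
  white floor (SD 2 µV), giving ~10–50 µV peak-to-peak — a realistic
  resting-EEG range.
* **Shared band-limited sources**: within a source band, target channels
  carry √c·shared + √(1−c)·private, both generated by the pipeline's own
  band filters from white noise, so generator and analyser share one band
  definition and the shared-variance fraction c is, in closed form, the
  expected zero-lag correlation (and c² the in-band coherence). The
  background's band content is first carved out of target channels by
  three subtraction passes of the same zero-phase filter (residual band
  power < 1%), and each injection is scaled to the original background's
  band power, so overlapping sources combine by variance addition exactly
  as `ground_truth` predicts. Sinusoid sources are supported for
  line-spectrum checks.
* **Slow-potential shifts**: per-channel sustained offsets expressed in
  units of that channel's delta-band SD. These emulate the
  interhemispheric DC asymmetry a full-band DC acquisition picks up in an
  unfamiliar environment; they move the rank-biserial statistic
  (expectation 2Φ(Δk/√2) − 1 for a shift difference of Δk SDs) without
  touching mean-removed correlations or nonzero-frequency coherence.
* **Heterogeneity**: per-subject coupling jitter, uniform ±0.05, seeded.

Generation is deterministic: every (seed, population, condition, subject)
tuple seeds its own stream, and identical specs are byte-identical.

The default presets encode the qualitative study structure: in the guest
box both populations get a strong (c = 0.95) 0–3.5 Hz source on channels
(2, 4) — suprathreshold 1–3 Hz coherence at pair 9 — and a ±1.3 SD
occipital slow-potential asymmetry on channels (4, 5) — a delta
rank-biserial median above 0.8 at pair 19 and nowhere else. The pair-9
source is a lowpass (0–3.5 Hz) rather than a narrow band because
uncarved sub-Hz background would otherwise leak through the Hann mainlobe
into the 1 Hz bin and dilute its coherence. Non-sport animals
additionally recruit a strong interhemispheric alpha source (channels
1, 4, 5, 8; c = 0.9) only in the guest box, spreading their home − guest
group-count differences over H1, H4 and V3; sport animals keep the same
weak alpha coupling in both boxes (habituation), so their differences
stay near zero — the reduced-variability pattern. No global "delta
everywhere" source is in the presets (it would blur the pair-9 contrast);
the delta-saturation behaviour has its own dedicated fixture in the tests.

Default cohort sizes are 5 subjects per population and 60 s of signal per
recording — enough for ~30 Welch windows and a delta-band effective
sample size of a few hundred, which keeps all preset effects several
standard errors clear of their thresholds; parameter-recovery experiments
use 6 subjects. What the generator does **not** emulate: volume
conduction and reference effects, sleep microstructure (spindles,
K-complexes, stage transitions), movement artifacts, and nonstationarity
within a night. Passing tests therefore demonstrate that the pipeline
measures what it claims on signals with known structure — not that real
horse EEG satisfies that structure.

## Numerical conventions

Coherence values are clipped into [0, 1] only within floating-point
tolerance; correlation outputs are clipped into [−1, 1] the same way.
Percentiles use linear interpolation (the numpy default, frozen in the
tests against a manual order-statistic oracle). Median over an even
number of subjects is the mean of the central order statistics. Degenerate
inputs fail loudly: zero variance, empty samples, too-short series for a
filter pad or a second Welch window, seven-channel files, inconsistent
sampling rates, mixed bands in a median.

## Known limitations

* EDF is read-only (no EDF writer dependency); the text matrix+sidecar
  format is the round-trip format.
* The rank-biserial bootstrap treats samples as exchangeable; with
  autocorrelated EEG its intervals are anti-conservative unless the
  block mode is enabled.
* The amplitude rule for clean segments is a stand-in for expert artifact
  screening and will pass low-amplitude artifacts (e.g. subtle chewing
  rhythms) that an expert would reject.
* Group-count contrasts at n = 5 per population have limited power and
  heavily tied data; the exact rank-sum path rarely applies there and the
  tie-corrected approximation is used instead.
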