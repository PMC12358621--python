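# equiconn

EEG functional-connectivity analysis for the equine **First Night Effect**
(FNE) — the degraded, asymmetric sleep animals (and people) show in an
unfamiliar environment. The package targets sleep researchers and
veterinary neurophysiologists working with multichannel EEG from large
animals: it implements the full analysis chain from raw 8-channel
recordings (home-box vs guest-box nights, sport vs non-sport populations)
to connectivity maps, coherence spectra and group-level statistics, plus a
synthetic cohort generator so every stage can be validated against known
ground truth.

## The montage and the statistics

Recordings use a 2×4 bilateral grid — frontal, temporal, parietal and
occipital sites on each hemisphere — numbered 1–8 (frontal right → …
→ occipital right, occipital left → … → frontal left), sampled at
1000 Hz with full-band DC acquisition. All C(8,2) = 28 channel pairs are
enumerated lexicographically; pair 19 is the occipital interhemispheric
pair (4, 5) and pair 9 the right occipitotemporal pair (2, 4). Pairs are
partitioned into seven spatial groups by hemisphere crossing and
anterior-posterior distance: H1–H4 (interhemispheric) and V1–V3
(intrahemispheric), with sizes (4, 6, 4, 2, 6, 4, 2).

Three connectivity statistics are computed per band (delta 0–4 Hz lowpass;
theta 4–8, alpha 8–13, beta 13–30, gamma 30–120 Hz bandpass; zero-phase
3rd-order Butterworth filters):

* **Rank-biserial correlation** r = 2U/(n₁n₂) − 1, with U the
  Mann-Whitney statistic between the two band-filtered channel series —
  a stochastic-dominance measure sensitive to sustained potential offsets
  between sites. Percentile bootstrap intervals (default 3000 resamples),
  median maps per cohort/condition and home − guest differences.
* **Magnitude-squared coherence** |S_xy|²/(S_xx·S_yy) by Welch averaging
  (Hann window of 2000 samples, overlap 100, nfft 1000 — windows longer
  than the transform are wrapped modulo nfft before the FFT), including
  the cross-frequency variant coherence(delta-filtered A, raw B), stored
  as a frequency × pair × subject cube with median-over-subject views and
  a strict 0.8 threshold mask.
* **Zero-lag normalized cross-correlation** per pair, counted per spatial
  group as (pairs ≥ 0.8)/(group size), differenced home − guest per
  subject, and compared with two-sided Wilcoxon rank-sum tests (exact for
  n ≤ 10 without ties) between populations and between conditions.

## Worked example

Simulate the default guest-box cohort and run the delta-band analyses:

```python
import equiconn as eq

spec = eq.default_presets(seed=7)
guest = [eq.generate_recording(spec, i, "non-sport", "guest") for i in range(5)]

med = eq.median_map([eq.correlation_map(r, "delta") for r in guest])
print(max(med, key=med.get), round(med[19], 3))
print(eq.threshold_pairs(med, 0.8))

cube = eq.build_cube(guest)                    # delta-vs-raw coherence
median = eq.median_coherence(cube)
print([round(median[f, 8], 3) for f in (1, 2, 3)])  # pair 9, 1-3 Hz bins
```

prints

```
19 0.944
[19]
[0.927, 0.937, 0.919]
```

i.e. the guest-box condition produces a median rank-biserial of 0.944 at
the occipital interhemispheric pair — the only pair above the 0.8
significance threshold (at home the same pair sits at −0.011) — and
suprathreshold 1–3 Hz coherence at the occipitotemporal pair 9. Running
`eq.condition_contrast` on the alpha-band group counts of the non-sport
cohort rejects the home = guest null for the interhemispheric groups H1
and H4 (and V3), each at p = 0.004, while the habituated sport cohort
shows no rejection — the FNE pattern the presets encode.

The same pipeline runs from the shell:

```
equiconn simulate --out cohort/ --seed 7
equiconn analyze cohort/ --out results/
```

`analyze` accepts real recordings too: EDF files, or plain TSV matrices
with a YAML sidecar (sampling rate, channel labels, subject, population,
condition, optional artifact-free segment annotations).

## Layout

```
src/equiconn/
  montage.py           channels, 28-pair table, H/V group scheme
  recordings.py        EDF / matrix+sidecar IO, clean-segment selection
  filtering.py         zero-phase Butterworth band decomposition
  pair_correlation.py  rank-biserial maps, bootstrap, medians, differences
  coherence.py         wrap-mode Welch MSC, cross-frequency cube, masks
  grouped.py           zero-lag correlation counts, rank-sum contrasts
  synthetic.py         cohort generator with analytic ground truth
  cli.py               `equiconn simulate | analyze | export-montage`
```

See `docs/methods.md` for the model, parameter choices and limitations.
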