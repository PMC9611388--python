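# eegconn — occipital-seeded EEG phase-locking connectivity

`eegconn` re-implements, as a reusable and tested Python pipeline, a
sensor-space EEG analysis used to study how the brain responds to seeing
manipulable objects and hand–object interactions: dynamic functional
connectivity between the visual cortex and the rest of the scalp, screened
for significance against the pre-stimulus baseline, together with
time–frequency power analysis (mu-rhythm ERD/ERS) and an ERP-lateralization
contrast. It is aimed at EEG researchers who want a transparent,
dependency-light implementation of this analysis whose every stage can be
validated on synthetic data with known ground truth.

## The analysis

**Phase-locking value (PLV).** Epochs are band-filtered (delta 1–3, theta
4–7, alpha 8–13, beta 14–30 Hz) and a virtual *occipital seed* is formed as
the signal-level average of Oz, O1, O2, POz, PO3 and PO4. With θ<sub>i,k,t</sub>
the Hilbert instantaneous phase of region *i* in epoch *k* at time *t*, the
connectivity between the seed *i* and an electrode *j* over *n* epochs is

    PLV_{i,j,t} = [ 1/n Σ_k cos(θ_{i,k,t} − θ_{j,k,t}) ]² + [ 1/n Σ_k sin(θ_{i,k,t} − θ_{j,k,t}) ]²

— the *squared* resultant length of the phase differences, whose null
expectation is 1/n (the conventional square-root form is available via
`convention="sqrt"`; the screening below is invariant to that monotone
choice).

**Effective PLV (ePLV).** Even noise yields nonzero PLVs, so each
(electrode, time) point is screened against baseline: per participant, the
pre-stimulus PLVs are bootstrap-averaged into a grand mean; then at each
time point the across-participant PLVs are paired against those grand means
with a one-tailed paired bootstrap test — resample the paired differences
with replacement 10,000 times, sort the resampled means ascending, and with
`index` the rank of the first mean strictly greater than zero, p′ =
index/10,000. Points with p′ ≤ α are ePLVs.

**Resampling tests.** The independent-samples analogue is a Monte-Carlo
permutation test: v₀ = mean(A) − mean(B); the pooled sample is randomly
re-split 10,000 times, the null differences sorted, and p = 1 −
location/10,000 with `location` the rank of the first null value strictly
above v₀ (p := 0 when none is). An exhaustive-enumeration oracle validates
the Monte-Carlo engine on small samples.

**ERSP.** Each epoch gets a continuous Morlet wavelet transform; with
u<sub>i,j</sub> the coefficient magnitude at time *i* and frequency *j* and
baseline<sub>j</sub> its pre-stimulus average, ERSP<sub>i,j</sub> = 10·log₁₀(u<sub>i,j</sub>/baseline<sub>j</sub>),
averaged across epochs. A Hjorth finite-difference surface Laplacian (each
channel minus the inverse-distance-weighted mean of its 4 nearest
neighbours) sharpens the resulting topographies. Mu-rhythm (8–13 Hz)
ERD/ERS is read off ROI-averaged ERSP time courses.

**ERP lateralization.** Grand-average ERPs at PO7 and PO8 per condition,
their (left − right) difference waveform, window means over 246–300 ms, and
a one-way ANOVA with Tukey pairwise comparison across conditions.

Because the study's participant data are private, everything is exercised
on a synthetic-EEG generator (`eegconn.synth`) that emulates the recording's
statistical structure — 500 Hz, 64-channel 10-10 montage, 4 conditions with
jittered trial timing, pink-noise background, von-Mises phase coupling from
the occipital seed, band-power gain windows (ERD/ERS), asymmetric ERPs,
blink artifacts and >100 µV outlier trials — with machine-readable ground
truth for scoring.

## Worked example

```
python analysis/01_simulate.py      --seed 0   # cohort + ground-truth tables
python analysis/02_preprocess.py    --seed 0   # one participant through the chain
python analysis/03_run_pipeline.py  --seed 0   # full run + truth scoring
python analysis/04_summarize.py                # condensed summary.json
```

On the demo cohort (7 participants × 32 trials) this prints, among others:

```
[pipeline] band theta: peak 16 connections at 280 ms
[pipeline] ERS window (0.1, 0.2): interactions - objects = +0.82 dB, permutation p = 0.0020
[pipeline] theta ePLV vs truth: sensitivity 87.2% on ['C3', 'C4', 'P4'] × (0.15, 0.4) s, false-positive cell rate 10.5%
[summary] mu condition D: ERD -2.21 dB at 502 ms, ERS +0.45 dB at 156 ms
```

Reading: the injected theta coupling (occipital → C3/C4/P4, 150–400 ms) is
recovered — the theta connection count peaks at 280 ms and 87% of the
injected (electrode, time) cells pass the ePLV screen, while ~10% of
uninjected cells fire at α = 0.05 (the screen's calibrated false-positive
level plus reference leakage; see `docs/methods.md`). The mu-rhythm ERD
injected at 0.30–0.70 s appears as a −2.2 dB trough near 500 ms, and the
interaction-only early ERS (gain 1.8, 0.10–0.20 s) appears at 156 ms and
survives the between-condition permutation test (p = 0.002). Larger cohorts
sharpen everything; `--participants 19` reproduces the study's sample size.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the complete pipeline end-to-end from the given seed (synthesis,
preprocessing, band-wise ePLV screening, mu ERSP, ERP lateralization) and
writes the results JSON. The source study reports its outcomes on a private
dataset, so there are no printed quantities to recompute; the package's
quantitative guarantees (analytic PLV recovery, test calibration, detection
sensitivity/specificity, ERSP gain recovery, source separation, determinism)
are property-based and enforced by `tests/test_acceptance.py`.
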