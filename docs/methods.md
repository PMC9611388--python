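# Methods

This note documents the models, estimators and numerical choices behind
`eegconn`, what the synthetic-data generator does and does not emulate, and
the known limitations. Units: potentials in µV, time in seconds, frequency
in Hz, phases in radians.

## Signal model and preprocessing

Continuous recordings are channel × time arrays with stimulus-onset events.
The preprocessing chain is fixed in order: common-average re-reference →
zero-phase bandpass (1–30 Hz) → AMUSE blind source separation with
EOG-component removal → epoching (−0.2 … +1.0 s, t = 0 on the grid) →
amplitude rejection (strictly above 100 µV) → band splitting.

* **Zero-phase bandpass** is a frequency-domain mask: unity in the passband,
  raised-cosine roll-off over 0.5 Hz at each edge, zero outside. Group delay
  is exactly zero; a passband sinusoid keeps amplitude within 1% and phase
  within 0.01 rad. The 0.5 Hz transition avoids the ringing of a brick-wall
  mask.
* **AMUSE** whitens via the eigendecomposition of the zero-lag covariance and
  rotates by the eigenvectors of the symmetrized lag-1 covariance of the
  whitened data ((C_τ + C_τᵀ)/2, lag exposed). A common-average reference
  removes exactly one spatial dimension, so the whitener silently drops one
  null direction; losing *more* than one dimension signals duplicated or
  flat channels and raises an error naming the offenders. Reconstruction
  with no components removed is the identity to 1e−9.
* **EOG removal** flags components whose |Pearson r| with any frontal-pole
  channel (Fp1/Fpz/Fp2 — the recordings carry no dedicated EOG channel, so
  frontal electrodes act as proxies) reaches 0.7 (exposed). Flagging every
  component is treated as misconfiguration and raises.
* **Amplitude rejection** applies post-ICA to the band-limited signal,
  matching the stated processing order; the 100 µV criterion is a strict
  inequality. Every epoch ever dropped is recorded in a rejection log with
  its reason, so kept + dropped always equals the original count.
* **Band splitting and epoching commute.** Epoch sets keep a link to the
  continuous recording they were cut from; band filtering re-filters the
  continuous data and re-cuts the same epochs, so epoch-edge filter
  transients never enter analysis windows. Standalone epoch arrays fall
  back to per-epoch filtering with 200 ms mirror padding.

## Resampling tests

Both engines rank the observed statistic inside a resampled null with the
same "first sorted value strictly greater" rule:

* **Independent samples (permutation):** v₀ = mean(A) − mean(B); each of N
  (default 10,000) resamples pools A∪B and randomly re-splits into the
  original sizes. With G = #{null > v₀}: p = (G − 1)/N for G > 0 and p := 0
  for G = 0 (the formula's limit; an optional conservative floor 1/(N+1) is
  available). One-tailed, H₀: mean(A) ≤ mean(B).
* **Paired samples (bootstrap):** P = C − D is resampled with replacement;
  with G = #{resampled means > 0}: p′ = (N − G + 1)/N for G > 0 and p′ := 1
  for G = 0 (the C ≡ D degenerate case).
* **Tie handling:** "strictly greater" uses an ulp-scale guard
  (ε = 10⁻⁹·(1 + |v₀|)). Resamples that recreate the observed grouping can
  differ from v₀ by a few ulp depending on summation order; without the
  guard the Monte-Carlo engine and the exhaustive-enumeration oracle drift
  apart on tied data.
* **Calibration:** under H₀ the permutation p satisfies P(p ≤ α) = α + O(1/N);
  the suite verifies a 5% ± 1.5% empirical rejection rate at n = 19.
* The **one-way ANOVA** with Tukey pairwise comparison delegates to
  scipy/statsmodels — it is a standard step, not this package's
  contribution.

All randomness flows from explicit integer seeds; there is no global state.

## PLV and the ePLV screen

PLV is implemented exactly as the squared resultant length (sum of squared
cosine and sine means of the across-epoch phase differences), so identical
phases give 1, uniform phases give expectation 1/n, and von Mises(Δ, κ)
differences give (I₁(κ)/I₀(κ))² asymptotically — the parameter-recovery
tests check this curve at κ ∈ {0, 1, 2, 4, 8}. The conventional resultant
(`convention="sqrt"`) is a monotone transform and does not change the
screen's decisions.

Instantaneous phase is the angle of the analytic signal of *band-limited*
input; each epoch is mirror-padded 200 ms per side before the Hilbert
transform (pads discarded) so edge transients stay out of the baseline
window. Constant input has no defined phase and raises.

The screen forms, per participant and electrode, a baseline level: the
grand mean of 10,000 bootstrap averages of the pre-stimulus PLVs (by the
central-limit theorem a tight estimate of the baseline mean). At each
(electrode, time), the across-participant PLVs are paired against these
levels with the one-tailed paired bootstrap (PLV > baseline); the ePLV mask
is p′ ≤ α. Design points:

* The test sample is **across participants at each time point** (the
  per-participant construction is the natural reading of one PLV series per
  subject); at least 2 participants are required.
* One-tailed for **increase** only; no multiple-comparison correction across
  electrodes or time is applied (none is used upstream), so the per-cell
  false-positive rate is α by construction. Expect isolated false cells;
  detection claims should be read at the cell-rate level, not as
  "electrode ever flagged".
* **Reference leakage:** after common-average referencing, −1/64 of every
  injected (or genuine) seed oscillation reappears in all channels. Coupling
  amplitudes around the in-band noise level keep this leak below the group
  screen's detection floor; much stronger sources would make "uncoupled
  electrode" physically ill-defined under this montage/reference.
* PLV time series are smooth at the band's timescale, so the pipeline
  screens on a decimated time grid (default every 5th sample = 10 ms at
  500 Hz) for runtime; `plv_decim=1` restores the full grid.

## ERSP, surface Laplacian, ERD/ERS, ERP lateralization

Morlet wavelets use n_cycles ramping linearly from 3 at 1 Hz to 8 at 30 Hz
(balanced time–frequency resolution over the analyzed range; exposed).
Kernels are scaled so a unit-amplitude sinusoid at the wavelet's frequency
yields magnitude 1.

**Edge handling** matters because the 200 ms baseline sits at the epoch
edge. When the epoch set retains its source link (the pipeline's normal
path), the transform convolves wider segments cut from the continuous
recording and crops, so no artificial edge exists inside the epoch at all.
For standalone epoch arrays the fallback is zero padding with envelope-
coverage normalization — exact for deterministic narrowband signals,
approximate (√coverage) for noise — and samples within one wavelet
half-width (4σ_t) of an edge are flagged.

ERSP follows the magnitude form literally: 10·log₁₀(u/baseline_j) per epoch
with baseline_j the pre-stimulus average of u at that frequency, then
averaged across epochs (`convention="power"` squares u first, doubling the
dB values). Zero baselines produce NaN with a warning. For stationary input
the baseline window averages to 0 dB within ±0.5 dB; injected envelope
gains g are recovered as ≈ 10·log₁₀(g) with a dilution toward 0 dB from
out-of-band wavelet leakage — at gain 2 on alpha noise, about 2.5–2.9 dB of
the nominal 3.01 depending on n_cycles.

The surface Laplacian is the Hjorth finite difference: each channel minus
the 1/distance-weighted mean of its k = 4 nearest montage neighbours
(available neighbours with a warning if fewer). It annihilates spatially
uniform maps exactly, strongly attenuates linear gradients away from the
rim, and maps a one-channel hotspot to positive centre / negative
neighbours. It is applied to ERSP topographies (ERSP values replace
potentials in the operator).

Mu ERD/ERS is the ROI- and band-averaged ERSP time course (default ROI: the
left somatosensory group C5/CP3/CP5; band 8–13 Hz); the most negative and
most positive post-stimulus excursions are reported with their times, and
two conditions are compared at a window by the permutation test on
per-participant window means. ERP lateralization baseline-corrects epochs
(pre-stimulus mean subtracted — the difference plot presupposes
zero-centred pre-stimulus activity), grand-averages per condition at PO7
and PO8, reports the (left − right) window mean ± SE (window 0.246–0.300 s,
exposed), counts |difference| peaks above a 0.5 µV prominence, and compares
conditions by one-way ANOVA with Tukey flags.

Topography snapshots are taken at a single sample (default 400 ms) rather
than a window average; the choice is configurable.

## The synthetic generator (and what a green test does not establish)

The generator emulates the *statistical structure* of the recordings: one
or more sessions of 4 conditions × n trials (default 35/condition/session ≈
140 per session) in randomized order, 1 s fixation, 1 s stimulus (duration
unstated upstream; 1 s chosen), 1–2 s jittered inter-trial interval; 500 Hz
and a 64-channel schematic 10-10 montage on the unit disc (both defaults,
not facts of the source study, which states neither). The background is
1/f^α pink noise (α = 1, 15 µV RMS per channel). Injected effects:

* **Coupling** — a sinusoidal burst (default 5 µV, ≈ in-band noise level;
  large enough to detect, small enough that the −1/64 common-average leak
  into other channels stays below the screen's detection floor) added to
  the six seed channels, with a per-trial uniform carrier phase; each
  target channel receives a copy with fixed lag plus von Mises(0, κ) jitter
  drawn per trial and target; 50 ms raised-cosine window ramps.
* **Power modulation** — the channel's band-limited noise component is
  multiplicatively scaled by g inside the window (g < 1 ERD, g > 1 ERS).
* **ERPs** — Gaussian-windowed deflections, per-channel amplitudes for
  lateral asymmetry, optionally condition-specific.
* **Artifacts** — 400 ms raised-cosine blinks (120 µV at the frontal pole,
  spatial gain e^(−d/0.35); rank-1 in space so second-order separation can
  isolate them) at 6/min, and 2% outlier trials carrying a ±180 µV Gaussian
  transient (σ = 60 ms, so it survives the 1–30 Hz filter above 100 µV) —
  matching the upstream report that over 97.5% of trials survived cleaning.

Identical configurations (including the seed) produce bit-identical
recordings.

What the generator does **not** emulate: volume conduction and realistic
source mixing (beyond the rank-1 blink), head geometry, non-stationary or
heavy-tailed background, muscle/line artifacts, inter-participant variance
beyond independent noise realizations, or any neurocognitive content. A
green end-to-end test therefore establishes that the estimators and screens
recover *this* class of injected structure at the stated SNR — it does not
validate the neuroscientific interpretation of any real-data result.

## Numerical and design choices

* PLV is the squared resultant (the printed form); the square root is an
  option. All downstream screening is invariant to the choice.
* p := 0 when no null value exceeds v₀ (limit of the rank formula);
  conservative floor available but off by default.
* Seed fusion is time-domain averaging before phase extraction — not phase
  averaging, not PLV averaging.
* Pipeline seeds: participant i draws its generator seed as
  (1009·seed + 7919·(i+1)) mod 2³¹; the screen and group tests use fixed
  offsets of the run seed. The manifest records all of them.
* Group tables are written with fixed float rounding so re-runs are
  byte-identical; per-participant intermediates are cached as NPZ under the
  output directory and reused when present.
* EDF output is 16-bit with a symmetric digital range (±32767), one shared
  physical range, 1 s records, and the true sample count stashed in the
  reserved header field; events travel in a TSV sidecar.

## Limitations

* The exhaustive permutation oracle is bounded at 10⁶ splits.
* The paired bootstrap at very small n (< ~8 participants) is only roughly
  calibrated — its false-positive rate can exceed α noticeably; the
  demonstration cohort of 7 sits at that edge, the study-scale 19 does not.
* The Hjorth Laplacian is a local finite difference, not a spherical-spline
  current source density; rim electrodes keep gradient residue.
* The EDF reader supports the subset of EDF this package writes (single
  sampling rate, µV units).
* No multiple-comparison correction in the ePLV screen (faithful to the
  upstream analysis); interpret masks at the cell level.
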