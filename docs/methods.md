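# Methods

## Scope and data model

The package analyses multichannel recordings made simultaneously from a
coronary-sinus (CS) catheter (bipoles CS 1-2 … CS 9-10) and a surface
ECG lead during atrial fibrillation, in two phases per patient (pre-
and post-ablation). The unit of analysis is the 50 s window: each
recording is cut into consecutive, non-overlapping 50 s windows from its
start (at most five; trailing partial data is discarded). All entropy
and RR-interval quantities are computed per window; per-patient values
are window means.

## Entropy of atrial electrograms

**Shannon entropy (ShEn)** is computed on the amplitude distribution of
the full 50 s trace: 64 equal-width bins spanning the trace's own
[min, max], empirical probabilities over occupied bins, log base 2. A
constant trace scores 0. The fixed bin count keeps values comparable
across windows; binning over the window's own range makes the measure
amplitude-scale invariant. The bin count is configurable.

**Sample entropy (SampEn)** uses template length `m = 2` and tolerance
`r = 0.2` times the analysed segment's standard deviation — the de
facto standard parameterization. Both `A` and `B` counts run over the
same `N − m` templates, self-matches excluded, Chebyshev distance. Each
50 s window is split into five 10 s sub-segments; SampEn is computed per
sub-segment with `r` referenced to that sub-segment's own SD (keeping
the match criterion adaptive to local signal scale) and the five values
are averaged. A sub-segment with zero matches at length `m` or `m + 1`
has undefined SampEn; such sub-segments are dropped with a logged count,
and the window value is undefined only when all five fail. A constant
sub-segment is treated as perfectly regular (SampEn 0).

The pair counting is exact (integer counts). The default path is a
branch-free compiled double loop specialized for `m = 2`; electrogram
segments concentrate most samples in a baseline cluster where nearly
every first-coordinate pair matches, which defeats tree- and
sort-pruning counting strategies, whereas the straight-line counted
loop vectorizes well. A generic kernel covers other `m`. Both are
checked against independent brute-force enumerations to 1e−12.

No detrending or filtering is applied to electrograms before entropy
computation.

## Ventricular response

R waves are detected with the Hamilton algorithm: band-pass 8–16 Hz
(zero-phase, 2nd-order Butterworth), differentiation, rectification,
80 ms moving-average integration; candidate peaks at least 200 ms apart
are classified QRS or noise by an adaptive threshold
`noise + 0.3125 (qrs − noise)` maintained from running means of the
last eight QRS and noise peak heights; when the current RR gap exceeds
1.5 times the running mean RR, a search-back accepts the largest
rejected peak above half threshold. Detections are refined to the local
maximum of the raw trace within ±60 ms. Detected beat times become RR
intervals by successive differencing; intervals outside a 200–3000 ms
plausibility band are dropped (no interpolation or ectopy correction
beyond this filter).

Per window, seven metrics: mean absolute successive RRI difference
normalized by the mean RRI ("normalized mean RRI difference" —
implemented as mean |ΔRRI| / mean RRI, the reading consistent with its
grouping under time-domain variability and the stated normalization
rule); SD RRI (sample, n−1, denominator) and normalized SD RRI; rMSSD;
pNN50 with a strict "> 50 ms" rule; SampEn of the interval series
(`m = 2`, `r = 0.2·SD`, independently configurable from the electrogram
setting) and normalized SampEn. Normalization always divides by the
mean RRI to remove the effect of heart rate itself.

## Cohort statistics

Pre/post comparisons use a two-sided paired t-test on per-patient
values, restricted to patients with PVI completion ≥ 0.70 (inclusive)
and both phases recorded; patients below the threshold contribute
pre-ablation data only. Normality is assessed with the
D'Agostino–Pearson omnibus K² test (flagged unreliable below n = 20)
for reporting; the t-test is applied regardless. Entropy–RRI
associations are computed per 50 s window, treating windows as
independent observations (a patient-clustered analysis is deliberately
not the default); Pearson for the variability metrics, Spearman for
SampEn and normalized SampEn; no multiplicity correction. Significance
stars: * < 0.05, ** < 0.01, *** < 0.001; rendered tables floor small
p-values at "< 0.001" while machine outputs keep raw values.
Zero-variance paired differences are handled explicitly (identical
pairs: t = 0, p = 1; constant nonzero shift: flagged degenerate, p at
the machine floor). Constant input to a correlation leaves r undefined
(NaN, flagged).

## Synthetic cohort

The generator grades atrial activity with a single disorganization
parameter θ ∈ [0, 1] (0 = fully organized, 1 = maximally disorganized)
and produces:

1. **Activation trains.** Inter-activation intervals are
   gamma-distributed with mean 170 ms (rapid AF cycle length) and CV
   `θ · 0.35`, floored at a physiological 80 ms; θ = 0 degenerates to
   an exactly periodic train.
2. **Electrograms.** Each activation places a biphasic deflection
   (first derivative of a Gaussian, 4 ms width parameter). θ scales
   three disorganization effects: a bounded uniform amplitude
   multiplier with CV `θ · 0.4`; Poisson-many extra delayed deflections
   per activation (expectation `θ · 2.5`, delays 10–150 ms, relative
   amplitude 0.25–0.6, random polarity) representing fractionation; and
   a continuous broadband fibrillatory component with SD `θ · 0.1`
   replacing the quiet diastolic baseline of organized rhythms.
   Additive recording noise (SD 0.02) is θ-independent. The bounded
   amplitude law and the attenuated fractionation amplitudes keep the
   histogram range stable across windows; the fibrillatory component is
   what drives sample entropy upward with disorganization at any
   sampling rate, and places SampEn values in the clinically reported
   magnitude range (≈ 0.15 at θ = 0 to ≈ 1.2 at θ = 1).
3. **Ventricular response.** Atrial impulses are filtered through an
   AV-node model: an impulse arriving after the refractory period
   conducts (ventricular beat 60 ms later; new refractory period 400 ms
   plus Gaussian jitter, SD 10 ms), while an impulse arriving inside it
   is blocked but extends the running refractory period by 70 ms —
   concealed conduction. Conducted plus blocked impulses always equal
   the atrial count. With a 170 ms cycle this yields mean RR ≈ 650 ms
   (≈ 90 bpm), and RR irregularity that increases monotonically with θ.
4. **ECG.** A fixed QRST template (Gaussian R wave with Q/S side lobes
   and a T wave) is placed at each ventricular beat time; ground-truth
   beat times are kept alongside for detector validation.

A cohort draws per-patient θ_pre uniformly from [0.4, 0.95]
(persistent-AF population spanning the middle-to-disorganized
spectrum); θ_post = θ_pre − effect (clipped at 0), with effect 0.3 as
the default post-ablation organization shift. Channels receive
independent Gaussian θ jitter (SD 0.05, clipped to [0, 1]) to create
realistic inter-channel spread; the ventricular response is driven by
the phase-level θ. Ten percent of patients are "cardioverted early"
(PVI completion drawn below 0.7) and contribute a pre-ablation
recording only. All randomness derives from one root seed through
deterministic spawn keys per patient/phase/channel, so any single
recording is regenerable in isolation.

**What the generator does not emulate:** anatomically realistic atrial
propagation, autonomic (vagal/sympathetic) modulation of the AV node,
anesthesia effects, catheter-contact and positioning variability,
ectopy, or drift/powerline artifacts on the ECG. Passing tests
demonstrate that the analysis pipeline recovers the statistical
structure this mechanism generates — a monotone organization–entropy
link and an AV-node-mediated organization–irregularity link — not that
real AF obeys the model quantitatively. In particular the mapping from
θ to absolute entropy values is a modelling choice, not a measured
calibration.

## Numerical and protocol choices

- Sampling rates are configurable with a 250 Hz floor for signal
  synthesis and detection; the library default is 1 kHz. Simulation
  studies in the test suite and acceptance script run at 250 Hz with
  one or two 50 s windows per phase — problem sizes chosen so the
  behaviour under test (effect direction, correlation signs, detector
  operating point) is measured with comfortable statistical margin
  while keeping runs brisk; the 50 s window and 5 × 10 s SampEn
  protocol are never scaled.
- Window counting uses `min(5, floor(duration / 50 s))` with a small
  epsilon guard against floating-point duration round-off.
- SampEn tolerances use the population SD (ddof = 0) of the segment;
  the SD RRI *metric* uses the sample SD (ddof = 1).
- The eligibility threshold comparison is inclusive (`>= 0.70`).
- Recordings round-trip losslessly through CSV (`%.17g` writing,
  round-trip float parsing); analysis tables are written at 10
  significant digits. Outputs carry the configuration digest (a hash
  of the analysis-relevant settings, excluding the output path), and
  identical configuration plus seeds reproduce every machine output
  byte for byte.
- In windows of highly irregular RR series (~75 intervals), RRI SampEn
  occasionally has no length-3 template matches and is undefined; such
  windows are dropped from SampEn correlations (logged). Because RRI
  SampEn saturates across the disorganized half of the θ range, its
  window-level correlation with atrial entropy is weak when a cohort
  spans only θ ∈ [0.4, 0.95] (pre-ablation) and clearly positive across
  the wider post-ablation range — an instance of the general pattern
  that rank correlations vanish on a plateau of the response curve.

## Known limitations

- The Hamilton detector is validated on synthetic ECG only; its
  constants are the published reference values and have not been tuned
  to clinical noise morphologies.
- Window-level correlations ignore within-patient clustering by design
  (matching the study protocol); standard errors would be conservative
  under clustering.
- The organization parameter is scalar; real AF organization is
  spatially heterogeneous, which per-channel θ jitter only caricatures.
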