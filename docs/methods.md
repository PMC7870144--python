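# Methods

`ineuron` re-implements, as a tested pipeline over synthetic ground truth,
the quantitative workflow used to compare the maturation of ape and human
induced neurons (iNs): neurite morphometry from traced reconstructions,
whole-cell patch-clamp feature extraction, single-cell differential
expression with gene-set enrichment, and the group statistics that tie the
arms together. This note documents the models, estimators, parameter
defaults and numerical choices, and what the synthetic generators do and do
not emulate.

## Morphometry

A reconstruction is a soma centroid plus a forest of rooted neurite trees
(`Neurite`: nodes in topological order, each non-root node with one parent).
Readers exist for 7-column SWC (soma nodes of type 1 are collapsed to their
centroid; each soma-attached subtree becomes one neurite) and for the HOC
dialect emitted by Imaris exports (`create`/`connect`/`pt3dadd` only; other
statements are ignored with a warning). Both readers produce the same
in-memory tree for the same geometry, which the format-equivalence tests
exercise on generated trees serialized both ways.

Metrics:

* **Total neurite length** — sum of parent–child Euclidean distances, in µm.
* **Axon** — operationally the longest neurite (the study validated this
  with axonal-marker staining); length ties break to the lowest neurite
  index so the choice is deterministic. **Dendrite length** is total minus
  axon, i.e. all neurites excluding the longest one.
* **Polarity** — count of primary neurites (total length ≥
  `min_primary_length`, default 5 µm): 1 unipolar, 2 bipolar, ≥ 3
  multipolar. The threshold is a package choice: the source classification
  was visual and never defined numerically. Unipolar cells are classified
  but flagged, and the pipeline excludes them from group statistics, as the
  study disregarded them.
* **Sholl profile** — crossings of concentric spheres centred on the soma
  at radii `step, 2·step, …` (default step 10 µm; the original Imaris
  increment is not published). Spheres in 3-D rather than planar circles,
  because the reconstructions are 3-D Z-stacks; this is configurable
  reasoning, not a measured fact. A straight segment's distance to the
  centre is convex along the segment, so it crosses a sphere 0, 1 or 2
  times; we count exactly: once when the endpoint distances straddle the
  radius (near < r ≤ far), twice when both endpoints lie outside but the
  closest approach dips inside. A dense-resampling oracle (0.01 µm steps,
  sign changes of distance − r) verifies the counts on generated trees.
* **Batch normalisation** — each axon length divided by the mean of the
  ape-group values in its differentiation batch, making the ape per-batch
  mean exactly 1 (to double-precision rounding, ~1e-16; tests assert 1e-12).
  A batch with no ape cells is an error naming the batch.

## Electrophysiology

Units: mV, pA, MΩ, pF, ms (so MΩ·pF = µs and mV/MΩ = nA). The cell model
throughout is the standard whole-cell recording circuit: access resistance
`Rs` in series with the membrane (`Rcell` parallel `Ccell`) resting at
`Vrmp`. Rs is read from recording metadata (the amplifier reports it);
50 % compensation is assumed applied upstream.

**Capacitance from the fast transient.** After an uncompensated voltage
step the clamp current decays with τ_fast = (Rs‖Rcell)·Ccell. We fit
I(t) = A·exp(−t/τ) + I_ss over the first 500 µs after onset, skipping the
first 2 samples (anti-alias filter artifacts at the 2.5 kHz recording
filter). Because the window can be shorter than τ, a free steady-state term
is poorly identified under noise; when the trace is long enough the I_ss
term is pinned to the measured plateau (10 ms mean starting 20 ms after
onset) and only A and τ are fitted. Fits with τ outside (10 µs, 10 ms) are
flagged as failures. The naive conversion Ccell = τ/Rs carries a systematic
Rs/(Rs+Rcell) bias (up to ~20 % at low input resistance); when the plateau
Rcell estimate is available the exact relation
Ccell = τ·(Rs+Rcell)/(Rs·Rcell) is inverted instead, and the full per-cell
workup (`extract_passive`) always does so.

**Input resistance.** (1) Plateau route: the steady currents of the
four-step family (−80 to −95/−85/−75/−65 mV) regressed on the step
voltages give Rs+Rcell; the known Rs is subtracted. (2) Ramp route: the
inverse current slope over the command window −75…−65 mV of a
−90→+60 mV/800 ms ramp, likewise series-corrected.

**Resting potential.** The zero-current crossing of the ramp. At the
crossing the membrane is by definition unclamped, so the raw crossing is
displaced from Vrmp by the capacitive ramp current — about
τ_m·(dV/dt)·Rcell/(Rs+Rcell), which is 3–17 mV at the protocol's
0.1875 mV/ms for plausible cells and therefore cannot be ignored. The
estimator locates the crossing on a lightly smoothed trace (2 ms boxcar),
refines it with a local linear fit (±5 mV window, removing the
first-crossing noise bias), and adds the correction
Ccell·k·Rcell²/(Rs+Rcell) using the step-derived Ccell. When the current
is non-monotonic between the slope window and the crossing (a subthreshold
sodium conductance distorting the trace), the zero of the slope-window
linear fit is used instead, with the same correction.

**Consolidation.** Per quantity, estimates from the different routes are
averaged when every estimate lies within 10 % of their mean; otherwise the
median is taken and a disagreement flag raised. (The pairwise reading of
"agreement within 10 %" would put the canonical 100/105/95 example exactly
on the boundary; deviation-from-mean is used.) τ is reported as
Rcell·Ccell in ms. Recording QC flags: Rs > 25 MΩ, Rs risen by more than
5 MΩ, or any of Rcell/Ccell/Vrmp drifted > 20 % from the initial workup.

**Action potentials** are upward crossings of −20 mV in current clamp,
with a 1 ms refractory between counted crossings (not specified at source;
prevents double counts on noisy threshold touches; configurable).

**Spontaneous EPSCs** are detected by scaled-template matching with a
triangular kernel (linear rise over `max_rise` = 1.5 ms, linear decay over
`max_fall` = 6 ms, unit peak) on the sign-flipped, inward-positive trace.
At every offset the kernel is least-squares fitted with free scale and
offset; the detection statistic is scale / SE(scale) with the residual SD
estimated per window. Candidates require the statistic above
`detection_criterion` and fitted amplitude above `noise_sd` (14 pA);
overlapping candidates merge to the local criterion maximum. An event is
rejected when either its fitted scale or its measured (smoothed,
baseline-subtracted) data peak exceeds `max_amplitude` = 500 pA — the
fitted scale of an imperfectly matching template underestimates the true
peak — and detections inside the decay of a rejected oversized event are
suppressed until it returns to the noise floor at the template's fall
rate. The four kernel/acceptance parameters are the published recording
settings; the detection criterion and merge rule of the original software
are unpublished. The default criterion of **5.0** was set by
constant-false-alarm-rate calibration on the null condition (pure 14 pA
Gaussian noise at 10 kHz): it yields ~0.01 Hz of false alarms — an order
of magnitude under the 0.1 Hz design bound — while a 30 pA event sits at
~5.7 standard errors and is detected with high probability; a criterion of
3 admits several hertz of noise crossings under the same conditions.
Event frequency is counted over the 60-s trace; the downstream group
statistic uses log10(frequency), and zero-event cells are flagged and
excluded from the transformed series (their transform is undefined; the
source treatment is unstated).

## Transcriptomics

The count matrix is an `AnnData` (cells × genes, raw integer counts) with
species/line/day/batch/cluster cell annotations and a boolean
mitochondrial gene flag (default: symbols starting `MT-`). Filters: cells
with 500–6000 genes detected and mitochondrial fraction ≤ 5 %; genes whose
mean count exceeds 0.1 in at least one batch. Both filters are idempotent.

Differential expression between two cell groups (neurons vs progenitors)
uses a two-sided Wilcoxon rank-sum per gene on counts-per-10k, log1p
values — a deliberate substitution for the model-based normalisation of
the original third-party pipeline, which is out of scope; rank tests are
insensitive to monotone per-cell scalings beyond depth, so CP10K is
sufficient here. p-values are Benjamini–Hochberg adjusted (the adjustment
method was unstated at source; BH is the de-facto default and is
configurable), and a gene is a DEG when adjusted p < 0.05 and log2 fold
change > 0.25 with the higher level in the first group. The fold change is
computed on CP10K means with a 1e-9 pseudo-count.

Gene-set enrichment of the DEG list against the detected-gene background:

* **Binomial route** — one-sided exact binomial upper tail,
  p = P(X ≥ k), X ~ Binomial(n, K/N), flagged at raw p < 0.05;
* **Fisher route** — one-sided hypergeometric tail on the 2×2 table with
  BH FDR, flagged at FDR < 0.05 (the SynGO-style analysis).

Terms with no background genes are skipped with a warning. Enrichment
profiles across groups are compared by Pearson correlation of −log10 p by
default (raw-p mode available; the source's scale is unstated) with the
0.7 reporting threshold; zero-variance profiles yield NaN.

## Group statistics

Mann–Whitney U is exact for group sizes up to 8: the full conditional null
(all C(n_a+n_b, n_a) assignments on pooled midranks, hence valid with
ties) is enumerated in-repo, with two-sided p = 2·min(tails) capped at 1.
Larger samples use the tie-corrected normal approximation with continuity
correction. Welch's t uses Satterthwaite degrees of freedom with the
convention p = 1 for two zero-variance groups with equal means. The
day × species (and batch) two-way ANOVA uses type-II sums of squares —
appropriate for the unbalanced per-day cell counts; on balanced designs
type II equals types I/III, which is property-tested. Shapiro–Wilk screens
normality (3 ≤ n ≤ 5000, non-constant). Significance stars: p < 0.05 `*`,
p < 0.01 `**`, p < 0.001 `***`. Summary tables report n, mean, median, SD
and SEM per group per day ("SMEM" in the source's supplementary tables is
read as the standard error of the mean).

## Synthetic data

Every generator is deterministic given a seed and records ground truth for
round-trip testing. Defaults are the study conditions where those are
stated, and field-realistic choices otherwise:

* **Morphology** — stochastic branching trees with direction-persistent
  growth; primary-neurite counts drawn 1–5 with weights (0.06, 0.31, 0.26,
  0.21, 0.16) to emulate the observed polarity mix; arbor size scales as
  `elongation_per_day^(day−7)` (default 1.06, ≈5× from day 7 to 35) times
  species and batch factors. Truth records per-neurite lengths, node and
  branch counts.
* **Membrane** — the single-compartment circuit above, integrated
  analytically piece by piece (exact exponential response per linear
  command segment); the optional subthreshold sodium conductance is
  sub-stepped Euler. Current-clamp spikes are stylized 2-ms triangular
  waveforms inserted at known times, with the passive response saturated
  at spike threshold (a real cell fires instead of charging past it);
  waveform realism is irrelevant because only threshold crossings are
  counted.
* **EPSC trains** — homogeneous Poisson events with biexponential kernels
  (0.5 ms rise, 4 ms decay: inside the template's acceptance window),
  log-normal amplitudes (median 55 pA, σ_ln 0.3 — bulk mass 30–100 pA) in
  Gaussian noise of SD 14 pA over 60 s at 10 kHz.
* **Counts** — negative-binomial (dispersion 2) over log-normal gene
  means, log-normal library sizes, planted 4-fold DEGs (100 of 2000 by
  default), `MT-*` genes tuned to ~3 % baseline mitochondrial fraction
  with planted high-mito and low-depth QC violations, and gene-set
  collections with planted enrichment (80 % DEG members vs background).

What the generators do **not** emulate: real tracing artifacts (gaps,
z-compression, diameter errors), electrode drift and seal instability,
biophysically detailed spiking, correlated or bursty synaptic input,
ambient RNA, doublets, and batch-specific expression structure beyond a
scalar scale. Passing tests therefore demonstrate estimator correctness
under the stated statistical conditions, not robustness to every artifact
of real recordings.

## Problem sizes and numerical choices

The packaged analyses and the reproduction script use 100 simulated cells
for passive-property recovery, 100 current-clamp families, 20 EPSC traces
(plus 20 noise-only traces), 50 trees for the geometric oracles, 2000
genes × 400 cells for DEG recovery with 20 null replicates, and a reduced
end-to-end study for the determinism check — sizes chosen so the full
reproduction completes in well under a minute per arm on one core while
keeping Monte-Carlo standard errors far from the acceptance margins.
Optimizer settings: the transient fit bounds τ to (1 µs, 20 ms) during
optimisation and flags results outside (10 µs, 10 ms); template matching
uses FFT convolution; degenerate inputs (zero-amplitude steps, identical
step targets, constant samples, zero-variance profiles, empty groups or
batches) raise typed errors rather than returning silently wrong numbers.
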