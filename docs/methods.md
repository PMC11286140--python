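# Methods

This note documents the models, parameters and design choices behind the
package, and what the synthetic experiments do and do not establish.

## 1. Synthetic vocalizations (`zebrarep.synth`)

Each call type is a parametric signal model chosen to reproduce the
features the extraction stage measures, not perceptual realism:

| type | model | key defaults |
|---|---|---|
| squeal | harmonic stack (6 harmonics, −6 dB/oct rolloff) on an F0 contour with ±2% vibrato at 5 Hz; shallow sinusoidal AM | F0 base 1200 Hz; AM 8 s⁻¹, 6 dB |
| quagga quagga | 3–6 tonal units with symmetric dip-and-return F0 contours, alternating loud/soft, separated by 60–120 ms silent gaps | unit F0 700 Hz |
| snort | spectrally tilted Gaussian noise with a raised-cosine pulse train envelope | tilt −3 dB/oct; pulse rate 25 s⁻¹, 12 dB deep |
| soft snort | tilted noise under a single smooth breath-like hump, 12 dB below the snort | tilt −6 dB/oct |

Durations are uniform per type (squeal 0.3–0.8 s, quagga 0.7–1.2 s,
snort 0.4–1.0 s, soft snort 0.4–0.9 s), all ≤ 1.25 s so the repertoire
length rule never bites at defaults. Pink-ish background noise is added
at 30 dB SNR — enough that the high-pass filters matter, low enough that
expected feature values are unchanged.

**Individual signatures.** For each individual and call type, offsets on
(F0, AM rate, spectral tilt) are drawn once from
N(0, `individual_sd`) — defaults 120 Hz, 4 s⁻¹, 2 dB/oct — and each call
adds N(0, `within_sd`) jitter (40 Hz, 1.5 s⁻¹, 1 dB/oct). Sex adds a
configurable shift to males; location adds a shift per step along the
location list (both default 0). Setting every `individual_sd` to 0 gives
the null model used for type-I-error calibration.
`draw_call_parameter_table` exposes this parameter model without audio
synthesis, which is what the large replicate simulations use.

**What the generator does not emulate:** reverberation and distance
effects, overlapping sounds, graded/intermediate call types, recording
chain variation, or realistic SNR statistics (the source material reports
none). Passing tests therefore show the *pipeline* is correct and
well-calibrated, not that field data would be classified equally well.

## 2. Feature extraction (`zebrarep.features`)

High-pass: zero-phase forward–backward 4th-order Butterworth (so envelope
metrics are not phase-distorted), cutoffs 30 Hz (snort, soft snort),
500 Hz (squeal), 600 Hz (quagga quagga).

F0: frame-wise normalized autocorrelation, 40 ms frames, 10 ms hop,
voicing threshold 0.45, parabolic peak interpolation, search ranges
squeal [400, 4000] Hz and quagga [400, 3000] Hz. Among autocorrelation
peaks within 90% of the best one, the smallest lag wins — vibrato and AM
can raise the 2-period peak marginally above the true-period peak, and
this guard removes those octave-down errors (observed before the guard:
~5% of frames; after: none). The reference tool's exact pitch heuristics
(octave costs, transition costs) are not replicated; these are declared
defaults.

Spectrum: one rectangular-window DFT of the whole filtered call; quartile
q_p is the first bin where cumulative energy reaches p of the total; peak
frequency is the maximum-power bin.

Amplitude: frame-RMS intensity contour (10 ms frames, 5 ms hop) in dB.
Amplitude variation = Σ|ΔdB| / duration. AM cycles are intensity maxima
with prominence ≥ 3 dB; AM rate = count/duration, AM extent = mean
prominence, missing when no cycle qualifies (such calls are excluded from
the feature-based repertoire set, mirroring the handling of missing AM
extent). The count/duration definition carries an irreducible ±1-cycle
quantization, so AM-rate recovery is assessed on the snort (≈ 17 cycles
per call) where the median error stays well under 10%; at the squeal's
8 s⁻¹ over ~0.5 s the same tolerance would be unattainable by
construction, not by defect.

`range_f0 = max_f0 − min_f0` holds exactly by construction. Because it is
an exact linear combination of two other features, it is excluded from
correlation-based screening (`INDIVIDUALITY_FIELDS`); a correlation
matrix containing it is singular for any dataset.

## 3. Spectrogram preparation (`zebrarep.specprep`)

Mel-spectrograms: STFT (512-sample Hann window, 256 hop), 128 triangular
mel bands from 30 Hz to Nyquist, log-power in dB relative to the call
maximum with a −80 dB floor. "Zero padding" is zero *power*, i.e. the dB
floor — literal zeros on a dB scale would inject mid-level energy. Calls
longer than 1.25 s are rejected with the exclusion recorded. Alignment
shifts each call so its energy onset (first frame > floor + 10 dB) sits
at frame 0.

The time-shift distance is the Frobenius distance minimized over integer
shifts in ±`max_shift` (default 25% of the frame count), vacated frames
at the floor. The directed distance is asymmetric only through which
call's frames get truncated; the pairwise routine (FFT cross-correlation
over all shifts at once, algebraically identical to the definition and
tested for equality at 1e-8) offers `symmetrize="min"` for embedding
methods. For clustering, spectrograms are block-mean downsampled to
32 × 64 before the distance matrix — at 720 calls the full-resolution
matrix would dominate runtime without changing cluster structure.

## 4. Repertoire analyses (`zebrarep.repertoire`, `zebrarep.cnn`)

**Importance screen.** A gradient-boosted tree classifier is fit on all
eight repertoire features and exact TreeSHAP attributions are averaged
(|value|, over samples and classes). The screening threshold is
configurable; mean-|SHAP| is in log-odds units and its scale is
dataset-dependent, so the analysis scripts use 0.1 — a weak screen that
removes only near-zero-attribution features (on the default synthetic
dataset: the two redundant upper quartiles).

**Supervised.** Features: XGBoost, 70/30 stratified split, random search
(default 20 trials) over learning rate (log-uniform 0.01–0.5), depth
(2–8) and trees (50–300) with 5-fold CV on the training split; the report
(accuracy, per-class precision/recall/f1, confusion matrix) uses the test
split only. Spectrograms: a from-scratch numpy convolutional network —
two 3×3 conv + ReLU + 2×2 max-pool blocks (8 and 16 filters), one dense
layer (width 32, dropout 0.25), softmax — trained with Adam (1e-3, batch
32) and early stopping (patience 8) on the 21% validation split of a
49/21/30 split, inputs block-downsampled to 32×32 and min–max scaled over
the dataset. All randomness (init, batch order, dropout) flows from one
generator, so fixed seeds give bit-identical reports on CPU. The
architecture is deliberately small: the call types differ in coarse
time–frequency structure, and a few thousand parameters suffice (and keep
the dual-representation comparison honest at this data scale).

**Unsupervised.** 2-D embedding by UMAP with the large-data parameters
n_neighbors = 200 and local_connectivity = 150 (each clamped to n − 1
with a warning when n is small; these parameters presume hundreds of
calls and wash out structure on toy-sized fixtures, where tests pass
smaller values explicitly). Spectrogram mode feeds the symmetrized
time-shift distance matrix as a precomputed metric with min_dist = 0.
k-means runs for k = 1..k_max (default 8) on the embedding (configurable
to the original space).

**Elbow rule.** k grows while each added cluster cuts the within-cluster
sum of squares by at least 40% (`stop_ratio` 0.6). Rationale: bisecting a
single isotropic 2-D Gaussian reduces WSS by only ~32% (the split axis
falls from variance 1 to 1 − 2/π), so an unstructured blob stops at
k = 1, while every genuine split clears the bar. The more common
max-second-difference rule was rejected because embedded call types are
hierarchically separated (tonal vs non-tonal super-groups first), and on
such curves the second difference always elects the super-split (k = 2)
even when k-means at k = 4 reproduces the types almost exactly. The
stopping rule picks 4 equal blobs → 4, one blob → 1, two blobs → 2, and
the synthetic embedding → 4.

Within/between diagnostics: Euclidean pairwise distances in the
clustering representation, sampled to ≤ 50 000 per group (seeded),
summarized by a 60-bin histogram overlap coefficient (0 = disjoint).

## 5. Individuality chain (`zebrarep.individuality`)

KMO: MSA_j = Σr²/(Σr² + Σq²) with anti-image partial correlations
q_jk = −R⁻¹_jk/√(R⁻¹_jj R⁻¹_kk); features kept at MSA ≥ 0.5. A
correlation matrix with condition number > 1e10 (duplicated or exactly
dependent columns) is rejected naming the collinear pair. PCA is on the
correlation matrix (centered, unit-scaled variables), components kept at
eigenvalue > 1 (strict), loading signs fixed so each vector's largest
entry is positive. The DFA solves the generalized eigenproblem
S_b w = λ S_w w (ridge 1e-8 on S_w), reports percent discriminative
variance per function and DF–PC correlations flagged at |r| ≥ 0.5.

**Nested pDFA.** Derivation size per individual =
max(2, ⌊0.6 × minimum per-individual call count⌋). For each of
`n_selections` draws (default 100; simulations and acceptance use 10–20),
an equal number of calls per individual is sampled, a linear DFA is fit
on the derivation set, and the withheld calls are classified by
Mahalanobis distance to group centroids under the pooled within-group
covariance (equal priors; ties broken toward the lowest individual
index); the statistic is the mean correct count. The null shuffles the
call-to-individual assignment within restriction levels only (per-
individual counts preserved); each permutation re-averages over fresh
selections. p = (#permutations with count ≥ observed)/N with the observed
dataset counted, so min p = 1/N (0.001 at the default N = 1000). The
chance level (`expected_correct`) averages the true permutations only. A
restriction level containing a single individual contributes nothing to
the null and triggers a warning; a single level reduces to an
unrestricted pDFA.

Validity at the defaults, verified by the acceptance suite: exact p-floor
under strong signatures; type-I error of 0.045 over 200 null replicates
(200 permutations each); median observed-correct monotone in signature
strength.

## 6. Inclusion rules and boundaries (`zebrarep.workbench`)

Repertoire mode drops calls strictly longer than 1.25 s (a 1.25 s call is
kept). Individuality mode drops, per call type, individuals with fewer
than 5 calls of that type (5 is kept). Calls with missing AM extent are
excluded from the feature-based repertoire set. Every exclusion is logged
with its rule; kept + excluded = input by construction.

## 7. Problem sizes

Default study conditions: 12 individuals (4 per location at 3 locations,
sexes alternating), 15 calls per individual per type = 720 calls, 44.1 kHz.
Simulation studies (null calibration, power) run on the parameter model
at 8 individuals × 10 calls with 200 permutations × 10 selections and
200 replicates. These sizes were chosen so the complete suite and the
acceptance script each run in minutes on a single CPU while keeping
every statistical check adequately powered.

## 8. Known limitations

- The synthetic types are more separable than field recordings; the
  near-perfect classifier accuracies bound the pipeline's correctness,
  not real-world performance.
- The F0 tracker is a plain autocorrelation tracker; strongly graded or
  biphonic calls would need the full cost-based tracking it omits.
- The AM-rate definition quantizes at ±1 cycle per call (see §2).
- KMO screening penalizes informative but mutually uncorrelated features
  (visible on synthetic snorts, where it keeps only the correlated
  quartile block); this is a property of the method, reproduced
  faithfully rather than corrected.
- The spectrogram clustering route merges the two noise-based types at
  default settings — time-shift Euclidean distance is weakly informative
  for noise-on-noise comparisons.
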