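# Methods

This note documents the models, parameter choices and numerical conventions
behind `sliscreen`, and what the synthetic data can and cannot show.

## Scope and assumptions

The pipeline screens children aged 4–12 for Specific Language Impairment
from (a) audio of a fixed speaking-task battery and (b) human transcriptions
of what the child actually said.  It assumes mono 16-bit PCM recordings at
16 or 44.1 kHz, one child per recording, and target/realized phoneme
sequences produced by the shared tokenizer.  Automatic speech recognition is
deliberately out of scope: realized phoneme sequences are inputs.

Graphemes stand in for phonemes throughout.  Czech orthography is close to
phonemic; the single correction applied is that the digraph "ch" is one
token.  The speaking-task battery has 12 categories (T1–T11, T13; there is
no T12) totalling 57 target patterns, from isolated vowels to a sentence.

## Utterance tests (penalty score)

Target and realization are aligned by minimal-cost global alignment over the
(m+1)×(n+1) edit array, with unit costs for substitution/deletion/insertion
and 0 for a match.  The penalty score `PS = wp + up + mp` decomposes the
distance into wrong (substituted), unspoken (deleted) and missing (inserted)
phonemes.  Two conventions are fixed rather than discovered:

* **unspoken ↦ deletion, missing ↦ insertion.**  Both quantities describe
  absences; the mapping is isolated in `penalty_score` and can be flipped
  without touching anything else.  `PS` itself is invariant.
* **Tie-break** among equal-cost alignments: during backtracking prefer
  substitution over deletion over insertion, right to left.  This makes the
  (wp, up, mp) split deterministic; `PS` is tie-invariant (it always equals
  the unit-cost Levenshtein distance, which the tests verify against an
  independent DP oracle and against `edlib`).

Per speaker, PS is summed within each of the 12 task categories, giving the
12-component error vector used by the classifiers, plus its total.

## Formant analysis

* Pre-emphasis 0.97; 25 ms Hamming frames with 10 ms hop.
* LPC by the autocorrelation method (Levinson via a Toeplitz solve), order
  `2 + fs/1000` (18 at 16 kHz) — the standard rule of thumb.
* Polynomial roots above the real axis become candidate resonances
  `f = θ·fs/2π` with bandwidth `−fs/π·ln|r|`; candidates below 90 Hz
  (F0/DC leakage) or broader than 400 Hz are discarded; the lowest three
  survivors per frame are kept and the per-formant **median over frames**
  is reported.  Frames with fewer than three valid resonances are skipped;
  fewer than three usable frames raises an explicit error.
* F0 by framewise normalized autocorrelation in 60–500 Hz (children's
  range), parabolic peak interpolation, voicing threshold 0.45; unvoiced
  frames carry 0.

The vocalic triangle is the map vowel → (F1, F2) over exactly /a e i o u/,
tagged `isolated` or `in_word`.  Comparison of the two contexts yields
per-vowel Euclidean displacement in the (F1, F2) plane, a misplacement flag
at a configurable threshold (default **100 Hz** — the visual "wrong place"
judgment needs a numeric stand-in), and the in-word/isolated shoelace-area
ratio.  In-word vowel segments are located from the manifest's phoneme
timing (synthetic data records it exactly); forced alignment of real audio
is out of scope.  The middle 60% of each vowel segment is analyzed to avoid
onset/offset ramps.

## Audio preprocessing

Canonical internal rate **16 kHz** (the analysis uses at most the 0–8 kHz
band); 44.1 kHz input is polyphase-downsampled.  Stereo folds to the channel
mean.  Level unification is **RMS** normalization to **−23 dBFS** (a common
broadcast reference; peak normalization would be hostage to single clicks).
Silence trimming uses 25 ms frame energy at −40 dB relative to the loudest
frame; a recording trimmed to nothing is returned flagged, not raised.  The
in-pipeline preprocessing skips trimming because it would invalidate the
manifest's segment timing and synthetic audio carries no padding.

## The 1,582-feature set

Framing as above.  The 34 base low-level descriptors are: loudness
(framewise RMS normalized to the loudest frame, raised to the power 0.3),
MFCC 0–14 (26-triangle mel bank over 0–8 kHz, log floor 1e-10, orthonormal
DCT-II), log power of 8 mel bands over 0–8 kHz, 8 line spectral pair
frequencies from an order-8 LPC fit (uniformly spaced LSFs are substituted
in the flat-spectrum/unstable limit), the median-of-5 smoothed F0 contour
with unvoiced gaps held at the last voiced value, and the unclipped
normalized-autocorrelation voicing probability.  Regression deltas over ±2
frames with edge replication double the set to 68 contours.

The 21 functionals follow their textual definitions exactly: positions in
frames (first occurrence on ties), least-squares line fit over frame index
(slope, offset, mean absolute and mean squared residual), population
standard deviation, skewness and **raw (non-excess) kurtosis** as 3rd/4th
standardized moments (0 on constant contours), linearly interpolated
quartiles/percentiles, the three inter-quartile ranges, the 1–99 percentile
range, and `upleveltimeX` = percent of frames **strictly above**
`min + X%·range` (a constant contour therefore scores 0).

The pitch block applies the 21 functionals minus the two position
functionals (19) to four pitch contours and their deltas: F0, local jitter
(mean absolute consecutive-period difference over mean period), DDP jitter
(mean absolute second difference of periods over mean period) and local
shimmer (same construction on peak amplitudes).  Periods come from
F0-guided peak picking; per frame the statistics are computed over periods
within ±50 ms.  The enumeration of the four pitch contours and the
19-functional reduction are documented configuration, not discoveries: the
descriptor set's published structure fixes only the counts (4 × 2 × 19 =
152).  Appended: the number of unvoiced→voiced transitions in the F0
contour (a leading voiced frame counts) and the duration in seconds.
Totals: 68 × 21 = 1,428, plus 152, plus 2 = **1,582**.

No attempt is made to be bit-compatible with any external feature
extractor; the contract is the documented structure (names, counts,
definitions), which the tests pin against brute-force oracles.

## Classifiers

* **HM (hand-made thresholds).**  Per group and feature, the observed
  [min, max] box on training data.  A sample inside exactly one box takes
  that group.  Otherwise it is flagged and resolved by the signed box
  margin (positive = distance to the nearest face from inside, negative =
  Euclidean distance to the box from outside): the larger margin wins, so
  "inside both" goes to the box the sample is deeper in, and "outside
  both" to the nearer box.
* **Supervised SOM.**  8×8 grid, 200 epochs, learning rate decaying
  0.5→0.01 and Gaussian neighborhood radius max(rows,cols)/2→1, both
  exponentially; inputs z-scored with training statistics; presentation
  order reshuffled per epoch; fully seeded.  Unit labels by majority of
  captured training samples; unlabeled units inherit the nearest labeled
  unit's label on the grid.  The three initializations: small random
  values; the two groups' per-feature min/max vectors interleaved across
  the grid; the two group means tiled with small jitter.  All SOM defaults
  are package choices — no published values exist for them.
* **Spearman voting.**  Per word, each feature's |Spearman ρ| against the
  0/1 group label ranks the features; the top 30 are selected (per word by
  default; a pooled mode exists).  Constant features get ρ = 0, never NaN;
  ties break by feature name.  Each selected feature of the evaluated
  speaker is assigned to the group whose per-feature training **median**
  is nearer; the speaker goes to the group with the larger tally over all
  words and features.  This "assign to nearer group reference, tally,
  argmax" reading is the package's operationalization of coefficient-based
  ranking, isolated in `vote_classify` so it can be replaced.

Evaluation is **leave-one-speaker-out** (selection and references refitted
per fold; resubstitution available for comparison).  Ties everywhere
resolve to "case": a screening instrument should err toward sensitivity.

## Synthetic cohorts

The generator reproduces the structures the analysis depends on:

* Two groups with severity grades 1–3 for cases (mix 0.40/0.35/0.25).
  Error rates are per phoneme, i.i.d., applied as substitutions, then
  deletions, then insertions; defaults: controls (0.01, 0.005, 0.005),
  severity-1 cases (0.10, 0.05, 0.03), scaled by the severity grade.
  Exact applied counts are recorded as ground truth, so the minimal edit
  distance is bounded by (and usually equals) their sum.
* One RNG stream per speaker, keyed by (seed, speaker id): enlarging a
  cohort does not reshuffle existing speakers.
* Vowel audio is source–filter synthesis: a band-limited pulse train with
  a −6 dB/oct glottal tilt, ±5% vibrato at 5 Hz and a −25 dB aspiration
  noise floor, through a cascade of three two-pole resonators (bandwidths
  80/100/140 Hz) at canonical Czech vowel formants (a 850/1400, e
  600/1700, i 300/2300, o 500/900, u 350/700 Hz; F3 2200–3000 Hz).  The
  vibrato and aspiration are what make LPC recovery well-posed at
  child-like F0 (the harmonics sweep through and fill in the spectral
  envelope); without them LPC locks onto individual harmonics and the
  round trip degrades sharply above ~200 Hz.  Cohort F0 defaults to
  210 ± 20 Hz, where the round-trip error stays within ±60 Hz.
* Words are concatenations of vowel segments (180 ms) and low-level noise
  bursts for consonants (60 ms), with exact per-phoneme timing recorded.
  Case speakers' **in-word** vowels are displaced by the configured
  (F1, F2) shift, default (150, 150) Hz; isolated vowels are never
  shifted; controls are never shifted.  Audio is generated for the five
  isolated vowels and three words jointly covering all five vowels
  ("různobarevný", "pivo", "kouzelný měšec"); all 57 patterns get phoneme
  realizations regardless.

What the generator does **not** emulate: naturalistic child voices,
prosody, coarticulation, background-noise corpora (only white noise at a
configured SNR), therapist/child overlap, or recording-channel variety.
Consequently, passing tests demonstrate that the pipeline's mathematics and
plumbing are correct and that its statistics behave as designed under
controlled group differences — not that the screen reaches any particular
accuracy on real clinical recordings.  The published headline rates on the
clinical corpus are in the 65–97% range depending on method; the synthetic
cohorts at default rates are more separable than real children, and the
four threshold/SOM methods often tie near 100% there.

## Problem sizes and numerical choices

Reference experiments use 40-speaker cohorts (20 per arm), 20 seeds for
classifier-recovery summaries in the test suite and 10 in the acceptance
script, 2,000 random pairs for the edit-distance oracle, 1,000 random
contours × 21 functionals (tolerance 1e-9 relative), and 4+4-speaker
double runs for byte-determinism.  The acceptance script seeds every RNG
from its `--seed` argument.

Degenerate inputs are contracts, not crashes: empty audio payloads,
all-zero signals, all-silent trims, single-group cohorts, empty-realization
speakers, constant features and unstable LPC polynomials all have specified
behavior (explicit error or flagged result), covered by tests.

## Known limitations

* Grapheme-level scoring under-counts errors a phonetic transcription
  would reveal (e.g. voicing assimilation) and cannot represent sub-token
  distortions.
* LPC formant estimation is biased at high F0 regardless of
  implementation; above ~250 Hz the ±60 Hz round-trip contract is not
  guaranteed.
* Jitter/shimmer contours rely on peak picking and are meaningful only on
  strongly periodic material; on real noisy recordings they would need a
  robust pitch-mark algorithm.
* The SOM is trained on 12-dimensional penalty vectors by default; using
  the full 1,582-feature vectors with an 8×8 grid and cohort-sized n would
  need dimensionality reduction first.
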