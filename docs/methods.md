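# Methods

## Workflow representation

A FESS navigation workflow is a sequence of timed endoscope states.  Each
state records a step count, the main cavity, the landmark group, the set of
simultaneously visible landmarks (1–3 of them; narrow pathways make
combinations common) and a movement direction.  Directions are derived
from a depth-ranked spatial ontology: moving to a combination whose
deepest member ranks deeper than the previous one is `inwards`, shallower
is `outwards`, equal is `dwell`; the first state of a workflow dwells.

The published description gives only the *spatially follows/precedes*
relation, not a full ordering, so the shipped depth ranks encode the
anterior-to-posterior surgical approach as configuration
(`out_of_patient`=0, `middle_nasal_concha`=1, `middle_nasal_meatus`=2,
`uncinate_process_of_ethmoid`=`ethmoidal_bulla`=3,
`maxillary_sinus_orifice`=4, `spheno_ethmoidal_recess`=5) and can be
overridden from a JSON ontology file.  The representative rank of a
combination is the maximum member rank — the deepest visible landmark
determines progress.

Annotation exports are read from a minimal documented CSV/JSON schema
(the native format of the annotation tool used in the original study is
not public).  Consecutive records with identical landmark combinations are
merged into one state: an annotation interval means continuous visibility,
so one combination visit is one step.  This makes derivation idempotent.

## Sentences and classes

States are verbalized with a fixed-slot template
`step <count> <cavity> <group> <lm_1..lm_k> <direction>` (6–8 tokens,
within the 6–10-word band of the original annotations).  The exact surface
wording was not published; a deterministic, invertible template was chosen
so that sentences round-trip to states and every evaluation slot is
recoverable.  Landmark tokens are emitted in depth-rank order
(alphabetical tie-break) so exact-match metrics see one canonical form;
any order is accepted on decode.  Step-count numerals are vocabulary
tokens capped at 999 (observed maxima are ≈860); larger numbers map to
UNK.  The vocabulary reserves PAD=0, SOS=1, EOS=2, UNK=3.

Class-level models see each distinct landmark combination as an integer
class id assigned in first-seen corpus order.

## Synthetic corpus

No clinical data ship with the package.  The simulator is a first-order
Markov chain over 12 landmark-combination states with zero self-transition
probability (a transition is a new combination visit, matching the merge
rule).  Per-workflow step counts are truncated-normal (mean 167, sd 60,
bounds [20, 500]), matching the reported mean of ≈167 steps; dwell times
are log-normal with median 9 s and log-sd 0.5, putting the mean visibility
duration in the reported ≈10 s band.  Dwell times decorate states but
carry no predictive information.

The chain is calibrated so that its stationary distribution, accumulated
per landmark, reproduces the reported observation fractions (concha 0.51,
meatus 0.27, maxillary ostium 0.18, out-of-patient 0.13, uncinate 0.06,
bulla 0.04, recess 0.01).  Two remarks on that calibration:

* The published per-landmark counts are not jointly consistent with a
  single state count (the in-combination mentions are fewer than twice the
  number of combination states they imply), so exact simultaneous matching
  of individual and in-combination fractions is impossible.  The simulator
  targets the *accumulated* fractions and absorbs the normalization excess
  in the individual states whose fractions have the most slack
  (out-of-patient 0.17, maxillary ostium 0.20, meatus 0.287 at
  stationarity — all within ±0.05 of the reported values).
* The transition matrix is found by a deterministic fixed-point iteration:
  row *i* proportional to a weight vector `q` restricted to `j ≠ i`, with
  `q` adjusted until the stationary distribution matches the target to
  ~1e-10.

One master seed derives per-workflow seeds by a fixed offset; identical
seeds give bit-identical corpora.  The simulator reproduces only the
aggregate statistics above.  It does not model surgeon-specific pathway
strategies, higher-order temporal dependence, lens-cleaning excursion
dynamics (beyond the out-of-patient state), or patient anatomy variation —
so passing calibration tests says the pipeline handles realistically
imbalanced FESS-like data, not that predictions transfer to real
recordings.

## Predictors

All four predictors share a next-step contract: sentence translators
expose `p(next word | source, prefix)`, class models
`p(next class | history)`.

* **GRU encoder-decoder (S2S).**  Two stacked GRU layers in encoder and
  decoder; 512 units and embedding 256 at full scale, a 64/32 desk preset
  for CPU-scale runs.  The embedding size is not stated in the original
  description; 256 is adopted as a conventional companion to 512 hidden
  units.
* **Transformer (TRF).**  Standard base configuration
  (d_model 512, 8 heads, 6 layers, FFN 2048, dropout 0.1) as the `paper`
  preset and 64/4/2/256 as the `desk` preset.  Post-layer-norm residual
  blocks, sinusoidal positional encodings, scaled dot-product attention
  with exportable per-layer weight matrices for inspection.
* **LSTM class baseline.**  Two layers, 200 units (64 desk), input window
  fixed at 6 class ids, left-padded with a dedicated PAD class that has no
  output slot and therefore can never be predicted.
* **Gaussian HMM.**  12 hidden states by default, univariate Gaussian
  emissions over the integer class encoding, Baum-Welch with per-step
  scaling, convergence at Δ log-likelihood < 0.01 or 500 iterations.  The
  original description specifies Gaussian emissions over categorical data
  without naming an encoding; mapping class id *k* to the real value *k*
  is the simplest faithful reading and is isolated in `encode_classes`
  for replacement.  Next-step prediction advances the filtering
  distribution one transition and emits the class maximizing the
  predictive density (greedy; ties to the lowest class id).

The neural models run on an in-repo reverse-mode autodiff engine
(`fessnav.models.autodiff`) verified against finite differences to 1e-6.

## Training

Adam (β = (0.9, 0.98), ε = 1e-9) with the warm-up schedule
`lr(n) = d_model^(−1/2) · min(n^(−1/2), n · n_warmup^(−3/2))`,
n_warmup = 200.  The formula as printed in the source publication scales
by √d_model, which yields learning rates above 1 and diverges; this is
presumed a typographical slip of the cited reference's schedule, so the
`standard` d_model^(−1/2) form is the default and the literal variant is
retained behind `mode="paper_literal"`.

S2S and LSTM train with cross-entropy for 10 epochs by default; the
transformer trains with the label-smoothed KL loss (smoothing 0.1) for 40.
The smoothed target puts 1−s on the true token and s/(V−2) on every other
non-PAD token; the loss identity KL = cross-entropy − entropy(target)
holds to 1e-6 and is asserted in tests.  Batches of 20 are reassembled and
reshuffled each epoch.  Source sentences can be augmented with random swap
(1 swap) and random deletion (p = 0.1) — conventional strengths for these
operations; the step-count slot is exempt from deletion so source and
target stay alignable, and sentences never shrink below 2 tokens.

Evaluation uses leave-one-workflow-out cross-validation; the left-in pairs
are shuffled and split 9:1 (validation = ⌊n/10⌋).

## Decoding

Beam search with beam 4 (the vocabulary is small), maximum sentence length
10, termination on EOS; ties break to the shorter hypothesis, then
lexicographic token order.  Candidate scores are rescored by the
recurrence decay `d(y) = 1 − e^(−r_y/r_mean(y))`: `r_y` counts the
consecutive preceding sentences of the series containing y (slot
persistence and containment coincide because tokens live in fixed slots),
and `r_mean(y)` is the mean training run length, floored at 1.

The published score `s = log p · (1 − d)` *rewards* recurring tokens when
log p < 0, contradicting its stated penalization intent, so the default
applies the decay to the probability itself:
`s = log p + log(1 − d)` (candidates with d = 1 are eliminated).  The
literal product form is kept behind `score_mode="paper_literal"`; neither
is presented as the certainly intended formula.  Multi-step rollout feeds
each generated sentence back as the next source, incrementing recurrence
counts for persisting tokens and resetting them on absence.

## Metrics

BLEU-1 is clipped unigram precision times the brevity penalty; ROUGE-L
recall is LCS length over reference length; `F1_BR` is their harmonic mean
(0 when both are 0); Jaccard distance is 1 − |∩|/|∪| over token sets.
Slot-level scores macro-average multi-class precision/recall per template
slot, with the landmark-combination slot compared as a set; the overall
row is the unweighted mean across slots and the accuracy is the harmonic
mean of overall precision and recall.  Landmark-level scores count a
predicted landmark occurrence (individual or in-combination) as a true
positive iff it occurs in the aligned target combination; the overall row
is the unweighted macro mean, and landmarks never predicted and never
present are excluded (their precision is undefined).  Reports round
half-up to 2 decimals; full precision is kept internally, which is why a
few published overall/F1 cells differ by ±0.01 from recomputation over
their rounded neighbours.

Corpus statistics treat a size-1 combination as an *individual*
observation of its landmark and a size-≥2 combination as an
*in-combination* observation of each member; accumulated = individual +
in-combination, and all fractions share the total state count as
denominator.

## Numerical choices

* HMM: variance floor 1e-3; start/transition probabilities floored at
  1e-10 after each M-step so filtering never collapses on observations
  outside the training support.  EM monotonicity is asserted to 1e-6.
* Beam search: zero-probability candidates (including EOS) are never
  expanded; a decode that cannot terminate returns the best partial
  hypothesis, flagged.
* Autodiff: float64 throughout; log-softmax via the max-shift identity.
* Rounding for reports: half-up (ties away from zero), matching the
  published tables.

## Problem sizes in the test suite

The suites run at desk scale by choice: transformer/S2S overfit checks use
cyclic corpora of ≤12 distinct sentences and the 64-dimensional desk
presets; HMM recovery uses 5 000 simulated observations; simulator
calibration uses the default 22-workflow corpus (≈3 700 states) and the
law-of-large-numbers transition check a 400-workflow corpus (≈68 000
states, so even the rarest combination state is visited a few hundred
times).  Full-scale presets (512-dimensional models, 40-epoch training)
are configuration, exercised only through the same code paths.

## Known limitations

Predictive accuracy on real recordings cannot be validated here; the
simulator's first-order Markov assumption matches the baselines' modeling
assumption, which flatters them relative to data with longer-range
structure.  The HMM's scalar class encoding imposes an artificial metric
on classes (adjacent ids look similar to a Gaussian); this mirrors the
underspecified original setup and is the documented seam to replace.
Beam search recomputes the full prefix at each expansion (no incremental
decoding cache), which is fine at sentence lengths ≤ 10.
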