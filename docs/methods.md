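# Methods

## Problem and model

`phonealign` solves text-independent forced alignment: given a frame-level
phone recogniser's output and an unsupervised segmenter's boundary list,
assign a phone label and exact time span to every segment of an utterance,
without assuming the canonical transcript. The aligner is deterministic
and purely geometric — all learning lives in the (external) frontends.

**Timestamping.** A sequence of `T` frame labels over an utterance of
`seconds = n_samples / sampling_rate` is stamped uniformly: token `i`
(0-based) gets time `(2i + 1) · seconds / (2T)`, i.e. the centre of its
equal share of the timeline. Every frame — including `[pad]`, `[unk]` and
the word delimiter `|` — is stamped; the specials are removed afterwards
with their times intact. For a fixed-stride frontend (e.g. 20 ms frames)
this uniform rule coincides with the physical frame centres.

**Class regions.** Successive surviving impulses at `t₁ < t₂` are
separated by the biased boundary `(1 − β)t₁ + βt₂`. The first region is
anchored at 0 and the last at the utterance duration, so the regions
partition `[0, duration)` exactly for every β ∈ [0, 1]; β = 0.5 is the
nearest-neighbour midpoint rule. β is a single global parameter (default
0.5); equal impulse times are rejected rather than tie-broken, since the
uniform timestamping rule cannot produce them.

**Labelling.** Each segment receives the label whose regions overlap it
most, with overlap pooled per phone across that phone's regions. Intervals
are half-open; a shared endpoint contributes zero. Ties are broken toward
the label whose contribution starts earliest within the segment — an
explicit temporal rule rather than dictionary insertion order, so results
are reproducible across implementations. Overlaps within 1 ns are treated
as tied, so floating-point rounding cannot decide between genuinely equal
contributions.

**Cleaning.** The CTC-collapsed token string (merge runs, then drop
specials — in that order, so a pad-separated repeat survives) yields the
permissible transitions: its adjacent label pairs. *Hard* cleaning merges
every adjacent same-label segment pair whose `(p, p)` is not permissible,
repeating to a fixed point; it is idempotent and position-blind. *Soft*
cleaning makes one left-to-right pass synchronised with the transition
list: realising the expected transition advances the transition cursor,
an unlicensed duplicate of the expected source phone is merged (also
advancing), anything else advances the segment cursor — so only the first
duplicate pair of a run is amalgamated per pass. A repeated-to-fixed-point
soft variant is available but not the default. Merged segments keep the
shared label and span `[first.start, second.end)`.

The published pseudocode for both cleans contains defects a direct
transcription would inherit (the hard-clean loop never terminates and the
soft clean indexes the transition list inconsistently and never removes
the absorbed segment); the implementations here are the minimal repairs
consistent with the documented behaviour, and the transition-realisation
check is ordered before the duplicate-merge check so a licensed `(p, p)`
expected at the cursor is preserved.

**VAD.** The voice-activity detector computes framewise RMS energy
(window 0.025 s, hop 0.01 s, nFFT 2048, threshold 0.5 by default),
min–max normalised to [0, 1] per utterance. It is a deliberately simple,
fully documented energy detector behind a `FrameProbabilities` interface,
so a model-based detector can be substituted. Frame `i` covers
`[i·hop, i·hop + window)`; speech runs become rising/falling edge pairs
using frame start times, a trailing run closing at the total duration.
Filtering deletes boundary *points* that fall outside every speech region
(region edges count as speech), so segments wholly inside silence
disappear. VAD is off by default: ablations favour hard cleaning without
VAD, and per-utterance min–max normalisation is meaningless on
silence-free audio.

## Evaluation protocols

The midpoint protocol counts a hit when `pred.start ≤ truth.midpoint ≤
pred.end` and the labels agree; proportions over truth and prediction
counts are combined with the harmonic mean `2/(a⁻¹ + b⁻¹)` (defined as 0
when either argument is 0, its limit value). The nested truth×prediction
comparison is kept verbatim — one truth segment may hit several
predictions and vice versa — because the published scores depend on that
counting; a one-to-one variant (`unique_matching=True`) is available for
comparison. Timing errors are recorded as absolute differences per hit;
tolerance tables report the fraction strictly below each threshold
(20/40/60 ms defaults). A `match_fraction` (midpoint matches ignoring
labels) accompanies the label-checked scores.

The onset protocol matches predicted to true segment starts within a
tolerance (default 20 ms) greedily by increasing time difference, one to
one — the standard convention for boundary F1, adopted here because the
protocol's matching multiplicity is otherwise unspecified.

Per-phone error rates are `1 −` (fraction of that phone's truth segments
with at least one midpoint hit). Counting raw multi-match hits instead
could exceed the segment count and produce negative rates, so
distinct-truth counting is used.

## Synthetic data generator

The generator emulates a 16 kHz corpus with a 50 frames/s (20 ms stride)
CTC recogniser and an unsupervised segmenter. Ground truth draws phone
labels uniformly from the TIMIT 61-phone inventory and durations uniformly
from 0.05–0.18 s (typical phone durations), quantised to whole samples as
in PHN annotations. Error modes, each with an explicit rate or standard
deviation and driven by one integer seed:

- impulse timing jitter (Gaussian, seconds);
- label substitution (uniform over the utterance's other phones);
- **overfit double-fires**: with probability `duplicate_rate` a phone
  fires a second impulse frame *adjacent* to the first (so CTC collapse
  removes the repeat and the transition list does not license `(p, p)`)
  while the segmenter simultaneously drops a spurious boundary between
  the two impulses. This jointly produces the adjacent unlicensed
  duplicate segments that cleaning exists to remove. Genuine licensed
  repeats need no knob: a ground truth that repeats a phone yields
  pad-separated impulses whose repeat survives collapse;
- boundary jitter, boundary deletion, and uniform spurious boundaries
  (over-segmentation);
- leading/trailing silence (pad frames; speech-edge boundaries).

With zero corruption the pipeline recovers the ground truth *exactly*:
impulses sit at phone centres, so the region boundary between phones `i`
and `i+1` lies within `0.25·|dᵢ − dᵢ₊₁|` of the true boundary, a
neighbouring region can intrude at most `0.25·dᵢ + 10 ms` into segment
`i` (10 ms = worst-case frame quantisation at 50 frames/s), and with
minimum duration > 40 ms the phone's own region always dominates — hence
the 0.05 s duration floor. Timing errors are identically zero because
ground-truth boundaries are sample-quantised and passed through to the
segmenter unchanged.

What the generator does **not** model: acoustic confusability (substitutions
are uniform, not phonetically structured), recogniser deletions/insertions
beyond double-fires, correlated errors between frontends other than the
overfit event, coarticulation-dependent boundary bias, and real audio
(only noise-burst fixtures for the VAD). Passing tests therefore
demonstrate the aligner's correctness given frontend outputs with these
statistical shapes, not recogniser/segmenter quality on real speech.

## Numerical and I/O choices

- Sample indices are 0-based, intervals half-open, TIMIT-style; seconds
  via `t = n/f`.
- PHN sample-rate repair multiplies indices by `new_rate/old_rate` and
  rounds half away from zero (a fixed rule for reproducibility); an entry
  collapsing to zero length raises.
- Files that are empty or contain only the placeholder strings `.jpg` or
  `xxx` (a known corpus defect) raise a dedicated `UnusablePhnError`.
- The frontend interchange format is JSON (`frame_labels`, `n_samples`,
  `sampling_rate`, `boundaries_s`, optional `audio_path`), decoupling the
  aligner from any specific model runtime.
- The phone→emoji codepoint map (U+1F600…) exists only as tokenizer
  metadata for character-level frontends; all APIs use ARPABET strings.
- TextGrid export writes a single `phones` interval tier, gaps filled with
  empty labels; WAV I/O uses 16-bit PCM mono via `scipy.io.wavfile`.

## Problem sizes

The test suite and acceptance checks use 12-phone utterances; property
suites run 300–1000 random instances against brute-force oracles (0.1 ms
grid counting for labelling, quadratic nested loops for midpoint scoring);
parameter recovery and cleaning-efficacy checks use 50 seeded utterances;
the bias sweep uses 200 utterances over a 0.1-spaced grid. These sizes
give stable statistics (the sweep's argmax at β = 0.5 is reproducible
across disjoint seed blocks) while keeping the whole suite to a few
seconds.

## Known limitations

- The uniform timestamp rule ignores any non-uniform relation between
  token index and acoustic time; frontends with variable stride should
  supply boundaries already in seconds and may need a different stamping
  rule.
- Hard cleaning licenses a duplicate pair *globally*: one genuine `(p, p)`
  anywhere in the collapsed string preserves every adjacent `p`-duplicate
  in the utterance. That is inherent to the position-blind rule; soft
  cleaning is the position-aware alternative.
- The energy VAD assumes silence is low-energy relative to speech within
  the utterance; it will misbehave on constant-level noise or on audio
  with no silence at all (min–max normalisation then amplifies noise).
- Midpoint-protocol proportions can exceed 1 under multi-match counting
  in degenerate cases (many predictions containing one truth midpoint);
  this mirrors the protocol as published and is left uncorrected, with
  the one-to-one variant available.
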