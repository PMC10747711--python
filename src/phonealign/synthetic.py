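"""Synthetic utterances and corrupted frontend outputs.

The aligner consumes two model outputs it has no control over: a per-frame
phone label sequence (recogniser) and an unlabelled boundary list
(segmenter).  This module generates ground-truth phone alignments and
emulates both frontends with controllable error modes, so the whole
pipeline is testable without any speech corpus:

* recogniser errors — Gaussian timing jitter of each phone's impulse,
  overfitted double-fires (see below), and label substitutions;
* segmenter errors — Gaussian boundary jitter, spurious extra boundaries
  (over-segmentation) and dropped true boundaries (under-segmentation);
* leading/trailing silence, emitted as pad frames by the recogniser and
  flanked by speech-edge boundaries from the segmenter.

An *overfit event* (``duplicate_rate``) models a phone whose acoustics
double-fire both frontends at once: the recogniser emits a second impulse
frame adjacent to the first — so CTC collapse merges the repeat and the
transition list does **not** license a ``(p, p)`` pair — and the segmenter
drops a spurious boundary between the two impulses.  The labelling stage
then produces two adjacent same-label segments that are not a permissible
transition: precisely what the cleaning stage amalgamates.  Genuine
licensed repeats need no knob — they arise whenever the ground truth
itself repeats a phone, whose pad-separated impulses survive collapse and
put ``(p, p)`` into the transition list.

Defaults emulate a 16 kHz recording frontend with a 50 frames/s (20 ms
stride) recogniser and phone durations uniform on 0.05–0.18 s.  A single
integer seed drives every random draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from phonealign.types import (
    FrontendBundle,
    LabeledSegment,
    PhoneInventory,
    PAD_TOKEN,
    default_inventory,
)

__all__ = [
    "CorruptionConfig",
    "GroundTruthUtterance",
    "DEFAULT_DURATION_MODEL",
    "DEFAULT_FRAME_RATE",
    "emulate_recognizer",
    "emulate_segmenter",
    "generate_ground_truth",
    "make_bundle",
    "noise_burst_audio",
]

DEFAULT_DURATION_MODEL = (0.05, 0.18)
DEFAULT_FRAME_RATE = 50.0
DEFAULT_SAMPLING_RATE = 16000


@dataclass(frozen=True)
class GroundTruthUtterance:
    """A contiguous phone alignment covering ``[0, duration)``."""

    phones: tuple[LabeledSegment, ...]
    duration: float
    sampling_rate: int

    def __post_init__(self) -> None:
        if not self.phones:
            raise ValueError("utterance must contain at least one phone")
        if self.phones[0].start != 0.0:
            raise ValueError("first phone must start at 0")
        for a, b in zip(self.phones, self.phones[1:]):
            if abs(a.end - b.start) > 1e-12:
                raise ValueError("phones must be contiguous")
        if abs(self.phones[-1].end - self.duration) > 1e-9:
            raise ValueError("last phone must end at duration")

    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.phones)

    def interior_boundaries(self) -> tuple[float, ...]:
        return tuple(p.end for p in self.phones[:-1])


@dataclass(frozen=True)
class CorruptionConfig:
    """Error-mode knobs for the emulated frontends.

    All rates are probabilities in [0, 1]; standard deviations are in
    seconds.  ``silence_pad`` adds that much silence before and after the
    utterance (pad frames from the recogniser, speech-edge boundaries from
    the segmenter).  ``seed`` drives all randomness.
    """

    timing_jitter_sd: float = 0.0
    duplicate_rate: float = 0.0
    substitution_rate: float = 0.0
    boundary_jitter_sd: float = 0.0
    over_segmentation_rate: float = 0.0
    deletion_rate: float = 0.0
    silence_pad: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "substitution_rate",
                     "over_segmentation_rate", "deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("timing_jitter_sd", "boundary_jitter_sd", "silence_pad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def generate_ground_truth(
    n_phones: int,
    inventory: PhoneInventory | None = None,
    duration_model: tuple[float, float] = DEFAULT_DURATION_MODEL,
    seed: int = 0,
    sampling_rate: int = DEFAULT_SAMPLING_RATE,
) -> GroundTruthUtterance:
    """Random contiguous alignment: uniform labels, uniform durations."""
    if n_phones < 1:
        raise ValueError("n_phones must be >= 1")
    lo, hi = duration_model
    if not 0 < lo <= hi:
        raise ValueError("duration_model must satisfy 0 < min <= max")
    inventory = inventory or default_inventory()
    rng = np.random.default_rng(seed)
    phones = rng.choice(sorted(inventory.phones), size=n_phones)
    # durations quantised to whole samples, as in PHN ground truth
    sample_durs = np.maximum(
        np.round(rng.uniform(lo, hi, size=n_phones) * sampling_rate), 1
    ).astype(int)
    edges = np.concatenate([[0], np.cumsum(sample_durs)])
    segments = [
        LabeledSegment(label=str(label), start=b / sampling_rate, end=e / sampling_rate)
        for label, b, e in zip(phones, edges, edges[1:])
    ]
    return GroundTruthUtterance(
        phones=tuple(segments),
        duration=int(edges[-1]) / sampling_rate,
        sampling_rate=sampling_rate,
    )


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _overfit_flags(gt: GroundTruthUtterance, cfg: CorruptionConfig) -> np.ndarray:
    """Which phones double-fire.  Drawn from a dedicated substream so the
    recogniser and segmenter emulators see the same events."""
    rng = _substream(cfg.seed, 2)
    return rng.random(len(gt.phones)) < cfg.duplicate_rate


def emulate_recognizer(
    gt: GroundTruthUtterance,
    cfg: CorruptionConfig,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> list[str]:
    """Per-frame labels emulating a CTC recogniser on this utterance.

    Every ground-truth phone fires a single-frame impulse at (roughly) its
    temporal centre, surrounded by pad frames.  Per ``cfg``: the impulse
    time is jittered, the label substituted, and — on an overfit event —
    a second impulse frame emitted adjacent to the first, so the repeat
    collapses away in the CTC string.  With zero corruption,
    CTC-collapsing the output recovers the ground-truth phone string
    exactly; that identity also holds under pure duplicate corruption.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    rng = _substream(cfg.seed, 0)
    total = gt.duration + 2 * cfg.silence_pad
    n_frames = max(int(round(total * frame_rate)), 1)
    frames = [PAD_TOKEN] * n_frames
    alphabet = sorted({p.label for p in gt.phones})
    overfit = _overfit_flags(gt, cfg)

    last_idx = -2
    for phone, doubled in zip(gt.phones, overfit):
        centre = cfg.silence_pad + phone.midpoint
        if cfg.timing_jitter_sd > 0:
            centre += rng.normal(0.0, cfg.timing_jitter_sd)
        label = phone.label
        if cfg.substitution_rate > 0 and rng.random() < cfg.substitution_rate:
            others = [p for p in alphabet if p != label] or [label]
            label = others[rng.integers(len(others))]
        # nearest frame centre, forced past the previous impulse with a pad gap
        idx = int(round(centre * n_frames / total - 0.5))
        idx = max(idx, last_idx + 2)
        if idx > n_frames - 1:
            continue  # jitter pushed the impulse off the end; drop it
        frames[idx] = label
        last_idx = idx
        if doubled and idx + 1 <= n_frames - 1:
            frames[idx + 1] = label
            last_idx = idx + 1
    return frames


def emulate_segmenter(
    gt: GroundTruthUtterance, cfg: CorruptionConfig
) -> list[float]:
    """Unlabelled boundary times emulating an unsupervised segmenter.

    Starts from the ground-truth interior boundaries (plus the speech
    edges when silence padding is present), then jitters, deletes and
    over-segments per ``cfg``.  Overfit events (shared with the
    recogniser emulator) each contribute one spurious boundary just past
    the affected phone's centre, splitting it into the duplicate segment
    pair the cleaning stage exists for.  Output is strictly increasing
    within the open interval ``(0, total_duration)``.
    """
    rng = _substream(cfg.seed, 1)
    total = gt.duration + 2 * cfg.silence_pad
    true_boundaries = [cfg.silence_pad + b for b in gt.interior_boundaries()]
    if cfg.silence_pad > 0:
        true_boundaries = [
            cfg.silence_pad,
            *true_boundaries,
            cfg.silence_pad + gt.duration,
        ]
    # split each double-fired phone between its two impulse frames
    splits = [
        cfg.silence_pad + phone.midpoint + min(0.01, phone.length / 4)
        for phone, doubled in zip(gt.phones, _overfit_flags(gt, cfg))
        if doubled
    ]

    out: list[float] = list(splits)
    for b in true_boundaries:
        if cfg.deletion_rate > 0 and rng.random() < cfg.deletion_rate:
            continue
        if cfg.boundary_jitter_sd > 0:
            b += rng.normal(0.0, cfg.boundary_jitter_sd)
        out.append(b)
    if cfg.over_segmentation_rate > 0 and true_boundaries:
        n_spurious = rng.binomial(len(true_boundaries), cfg.over_segmentation_rate)
        out.extend(rng.uniform(0.0, total, size=n_spurious))

    eps = 1e-6
    out = sorted(b for b in out if eps < b < total - eps)
    deduped: list[float] = []
    for b in out:
        if not deduped or b > deduped[-1] + eps:
            deduped.append(b)
    return deduped


def make_bundle(
    gt: GroundTruthUtterance,
    cfg: CorruptionConfig,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> tuple[FrontendBundle, list[LabeledSegment]]:
    """Emulate both frontends and pack them as a FrontendBundle.

    Returns the bundle and the ground-truth segments on the bundle's
    timeline (shifted by the leading silence pad), ready for evaluation.
    """
    total = gt.duration + 2 * cfg.silence_pad
    n_samples = int(round(total * gt.sampling_rate))
    bundle = FrontendBundle(
        frame_labels=tuple(emulate_recognizer(gt, cfg, frame_rate)),
        n_samples=n_samples,
        sampling_rate=gt.sampling_rate,
        boundaries_s=tuple(emulate_segmenter(gt, cfg)),
    )
    truth = [
        LabeledSegment(p.label, p.start + cfg.silence_pad, p.end + cfg.silence_pad)
        for p in gt.phones
    ]
    return bundle, truth


def noise_burst_audio(
    duration: float,
    bursts: list[tuple[float, float]],
    sampling_rate: int = DEFAULT_SAMPLING_RATE,
    amplitude: float = 0.9,
    seed: int = 0,
) -> np.ndarray:
    """Digital silence with full-scale white-noise bursts — a minimal
    speech/silence fixture for exercising the energy VAD."""
    rng = np.random.default_rng(seed)
    signal = np.zeros(int(round(duration * sampling_rate)))
    for start, end in bursts:
        lo, hi = int(start * sampling_rate), int(end * sampling_rate)
        signal[lo:hi] = amplitude * rng.uniform(-1.0, 1.0, size=hi - lo)
    return signal
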