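"""The forced-aligner backbone: frontend bundle in, labelled segments out.

Stage order: stamp every frame label with its time; optionally delete
segment boundaries lying in VAD silence; drop CTC special tokens; build
biased class regions from the surviving impulses; bracket the boundary
list with 0 and the utterance duration; label each segment by maximum
region overlap; amalgamate impermissible duplicate segments (soft or hard
cleaning, driven by the transitions of the CTC-collapsed token string).

Defaults are the configuration that performs best in ablations: bias 0.5,
hard cleaning, no VAD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from phonealign import vad_filter
from phonealign.class_regions import decision_boundary_calc
from phonealign.cleaning import hard_clean, soft_clean
from phonealign.evaluation import harmonic_mean, midpoint_evaluate
from phonealign.segment_labeling import boundaries_to_segments, max_contribution
from phonealign.token_stream import (
    ctc_collapse,
    derive_transitions,
    filter_special,
    tokens_to_timed_tokens,
)
from phonealign.types import (
    FrontendBundle,
    LabeledSegment,
    PhoneInventory,
    default_inventory,
)

__all__ = ["AlignConfig", "align", "bias_sweep"]

logger = logging.getLogger(__name__)

CLEAN_MODES = ("none", "soft", "hard")


@dataclass(frozen=True)
class AlignConfig:
    """Aligner configuration (defaults = best ablation setting)."""

    bias: float = 0.5
    clean: str = "hard"
    soft_clean_fixed_point: bool = False
    vad: bool = False
    vad_nfft: int = vad_filter.DEFAULT_NFFT
    vad_window: float = vad_filter.DEFAULT_WINDOW
    vad_hop: float = vad_filter.DEFAULT_HOP
    vad_threshold: float = vad_filter.DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")
        if self.clean not in CLEAN_MODES:
            raise ValueError(f"clean must be one of {CLEAN_MODES}")


def align(
    bundle: FrontendBundle,
    cfg: AlignConfig | None = None,
    inventory: PhoneInventory | None = None,
) -> list[LabeledSegment]:
    """Run the full aligner on one frontend bundle.

    Raises ``ValueError`` when the bundle contains no non-special tokens
    (nothing was recognised, so no labels can be assigned).
    """
    cfg = cfg or AlignConfig()
    inventory = inventory or default_inventory()
    duration = bundle.duration

    timed = tokens_to_timed_tokens(
        bundle.frame_labels, bundle.n_samples, bundle.sampling_rate
    )

    boundaries = list(bundle.boundaries_s)
    if cfg.vad:
        if bundle.audio_path is None:
            raise ValueError("VAD filtering requested but bundle has no audio_path")
        probs = vad_filter.compute_vad(
            bundle.audio_path,
            n_fft=cfg.vad_nfft,
            window=cfg.vad_window,
            hop=cfg.vad_hop,
            threshold=cfg.vad_threshold,
        )
        regions = vad_filter.probabilities_to_regions(probs)
        kept = vad_filter.filter_segments(boundaries, regions)
        logger.info("VAD: %d -> %d boundaries", len(boundaries), len(kept))
        boundaries = kept

    filtered = filter_special(timed, inventory)
    if not filtered:
        raise ValueError("nothing recognised: bundle has no non-special tokens")

    partition = decision_boundary_calc(filtered, duration, cfg.bias)
    segments = boundaries_to_segments(
        [b for b in boundaries if 0.0 < b < duration], duration
    )
    labeled = max_contribution(segments, partition)
    logger.info("labelled %d segments from %d impulses", len(labeled), len(filtered))

    if cfg.clean != "none":
        transitions = derive_transitions(ctc_collapse(bundle.frame_labels, inventory))
        if cfg.clean == "hard":
            cleaned = hard_clean(labeled, transitions)
        else:
            cleaned = soft_clean(
                labeled, transitions, to_fixed_point=cfg.soft_clean_fixed_point
            )
        logger.info("cleaning (%s): %d -> %d segments", cfg.clean, len(labeled), len(cleaned))
        labeled = cleaned
    return labeled


def bias_sweep(
    corpus: Sequence[tuple[FrontendBundle, Sequence[LabeledSegment]]],
    biases: Sequence[float],
    cfg: AlignConfig | None = None,
    inventory: PhoneInventory | None = None,
) -> list[tuple[float, float]]:
    """Midpoint-protocol harmonic mean per bias over a corpus.

    Hits and segment counts are pooled over all utterances before the
    proportions and their harmonic mean are taken (micro-average), the
    natural aggregation for corpora of uneven utterance lengths.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    cfg = cfg or AlignConfig()
    rows: list[tuple[float, float]] = []
    for bias in biases:
        hits = n_truth = n_pred = 0
        for bundle, truth in corpus:
            pred = align(bundle, replace(cfg, bias=bias), inventory)
            report = midpoint_evaluate(list(truth), pred)
            hits += report.hits
            n_truth += report.n_truth
            n_pred += report.n_pred
        hm = harmonic_mean(hits / n_truth, hits / n_pred)
        rows.append((bias, hm))
    return rows
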