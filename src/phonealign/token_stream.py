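"""Timed token impulses, CTC collapse, and permissible transitions.

A frame-level recogniser emits one token per frame (phones plus the CTC
blank/pad, unknown, and word-delimiter tokens).  Each frame is stamped with
the centre time of its equal share of the utterance: frame ``i`` of ``T``
gets ``(2i + 1) * seconds / (2T)``.  CTC collapse (merge runs, then drop
specials) recovers the spoken phone string; a genuine repeat separated by a
pad frame survives as a duplicate pair — the behaviour that makes words
like "cackal" expressible and that the cleaning stage must respect.
"""

from __future__ import annotations

from typing import Sequence

from phonealign.types import PhoneInventory, TimedToken

__all__ = [
    "ctc_collapse",
    "derive_transitions",
    "filter_special",
    "tokens_to_timed_tokens",
]


def tokens_to_timed_tokens(
    frame_labels: Sequence[str], n_samples: int, sampling_rate: int
) -> list[TimedToken]:
    """Stamp every frame label (specials included) with its centre time.

    With ``seconds = n_samples / sampling_rate`` and ``T`` frames, token
    ``i`` (0-based) receives time ``(2i + 1) * seconds / (2T)`` — i.e. the
    spacing ``delta = seconds / (2T)`` with the first token at ``delta``
    and successive tokens ``2 * delta`` apart.
    """
    if not frame_labels:
        raise ValueError("frame label sequence is empty")
    if n_samples <= 0 or sampling_rate <= 0:
        raise ValueError("n_samples and sampling_rate must be positive")
    seconds = n_samples / sampling_rate
    delta = seconds / (2 * len(frame_labels))
    return [
        TimedToken(label=label, time=(2 * i + 1) * delta)
        for i, label in enumerate(frame_labels)
    ]


def filter_special(
    timed: Sequence[TimedToken], inventory: PhoneInventory
) -> list[TimedToken]:
    """Drop pad/unknown/delimiter tokens, keeping original times."""
    return [t for t in timed if not inventory.is_special(t.label)]


def ctc_collapse(
    frame_labels: Sequence[str], inventory: PhoneInventory
) -> list[str]:
    """Collapse a frame label sequence to the spoken phone string.

    Standard CTC order: merge consecutive identical labels first, then
    remove special tokens — so a repeat separated by a pad frame survives
    as a duplicate pair, while an uninterrupted run collapses to one.
    """
    merged: list[str] = []
    for label in frame_labels:
        if not merged or merged[-1] != label:
            merged.append(label)
    return [label for label in merged if not inventory.is_special(label)]


def derive_transitions(collapsed: Sequence[str]) -> list[tuple[str, str]]:
    """Adjacent label pairs of the collapsed string, in order.

    These are the transitions the recogniser asserts actually occurred;
    a duplicate pair like ``(k, k)`` appears exactly when the collapsed
    string genuinely repeats a phone, and licenses the cleaning stage to
    keep the corresponding duplicate segments.
    """
    return list(zip(collapsed, collapsed[1:]))
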