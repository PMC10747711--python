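"""Label unlabelled segments by maximum class-region overlap.

Every segment receives the phone whose class regions overlap it the most
(overlap summed per phone across all that phone's regions, as intervals —
a shared endpoint contributes zero).  Because the regions partition the
timeline, the per-segment overlaps always sum to the segment length, so a
label always exists.
"""

from __future__ import annotations

from typing import Sequence

from phonealign.types import LabeledSegment, RegionPartition, Segment

__all__ = ["boundaries_to_segments", "max_contribution"]


def boundaries_to_segments(
    boundaries: Sequence[float], duration: float
) -> list[Segment]:
    """Bracket interior boundaries with 0 and ``duration``.

    Boundaries ``[b1 < ... < bk]`` become segments ``[0, b1), [b1, b2),
    ..., [bk, duration)``; an empty list yields the single segment
    ``[0, duration)``.
    """
    prev = 0.0
    for b in boundaries:
        if not 0.0 < b < duration:
            raise ValueError(f"boundary {b} outside (0, {duration})")
        if b <= prev and prev > 0.0:
            raise ValueError("boundaries must be strictly increasing")
        prev = b
    cuts = [0.0, *boundaries, duration]
    return [Segment(start=a, end=b) for a, b in zip(cuts, cuts[1:])]


def max_contribution(
    segments: Sequence[Segment], partition: RegionPartition
) -> list[LabeledSegment]:
    """Assign each segment the label with the greatest overlap.

    Overlap is accumulated per phone label (several regions of the same
    phone pool their contributions).  Ties between labels with equal
    maximal overlap go to the label whose contribution starts earliest
    within the segment — a deterministic temporal rule.
    """
    eps = 1e-9
    labeled: list[LabeledSegment] = []
    for seg in segments:
        if seg.start < -eps or seg.end > partition.duration + eps:
            raise ValueError(
                f"segment [{seg.start}, {seg.end}) outside partition span "
                f"[0, {partition.duration})"
            )
        overlap: dict[str, float] = {}
        first_start: dict[str, float] = {}
        for region in partition.regions:
            lo = max(region.start, seg.start)
            hi = min(region.end, seg.end)
            if hi <= lo:
                continue
            overlap[region.label] = overlap.get(region.label, 0.0) + (hi - lo)
            first_start.setdefault(region.label, lo)
        if not overlap:  # impossible when regions partition the timeline
            raise ValueError(f"segment [{seg.start}, {seg.end}) overlaps no region")
        # overlaps within 1 ns are treated as tied so float rounding cannot
        # decide between genuinely equal contributions
        top = max(overlap.values())
        best = min(
            (lab for lab in overlap if overlap[lab] >= top - 1e-9),
            key=lambda lab: first_start[lab],
        )
        labeled.append(LabeledSegment(label=best, start=seg.start, end=seg.end))
    return labeled
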