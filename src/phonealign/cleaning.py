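"""Amalgamation of overfitted duplicate segments.

A frame-level recogniser sometimes fires twice for one phone, and the
labelling stage then produces two adjacent segments with the same label.
Cleaning merges such pairs — unless the collapsed token string says the
repeat is real, i.e. the ``(label, label)`` pair appears in the
permissible-transition list (a word genuinely containing a doubled sound,
like "ca-ck-ck-al").

Two strategies:

* ``hard_clean`` ignores *where* a permissible duplicate transition occurs:
  if ``(p, p)`` is permissible anywhere, every adjacent ``p``/``p`` pair is
  kept; otherwise all are merged, repeatedly, to a fixed point.
* ``soft_clean`` walks segments and transitions together in one
  left-to-right pass, so a duplicate is only merged where the transition
  list is currently expecting that phone; only the first duplicate pair of
  a run is amalgamated per pass.
"""

from __future__ import annotations

from typing import Sequence

from phonealign.types import LabeledSegment

__all__ = ["hard_clean", "soft_clean"]

Transition = tuple[str, str]


def _merge(a: LabeledSegment, b: LabeledSegment) -> LabeledSegment:
    return LabeledSegment(label=a.label, start=a.start, end=b.end)


def hard_clean(
    segments: Sequence[LabeledSegment], transitions: Sequence[Transition]
) -> list[LabeledSegment]:
    """Merge every adjacent equal-label pair not licensed by ``transitions``.

    Merging repeats until no impermissible duplicate pair remains, so the
    result is a fixed point (idempotent).  Permissible duplicate pairs are
    preserved wherever they occur.
    """
    permitted = set(transitions)
    segs = list(segments)
    ceiling = len(segs) - 2
    jj = 0
    while jj <= ceiling:
        a, b = segs[jj], segs[jj + 1]
        if a.label == b.label and (a.label, b.label) not in permitted:
            segs[jj] = _merge(a, b)
            del segs[jj + 1]
            ceiling -= 1
            jj = max(jj - 1, 0)
        else:
            jj += 1
    return segs


def soft_clean(
    segments: Sequence[LabeledSegment],
    transitions: Sequence[Transition],
    to_fixed_point: bool = False,
) -> list[LabeledSegment]:
    """Single synchronised pass over segments and expected transitions.

    For each expected transition in turn, scan forward through the
    segments: a pair realising the expected transition advances to the
    next transition; an adjacent duplicate of the transition's source
    phone that does *not* realise it is merged (and also advances to the
    next transition, so only the first duplicate pair of a run is
    amalgamated); anything else advances the segment cursor.

    With ``to_fixed_point=True`` the pass is repeated until the segment
    list stops changing.
    """
    segs = list(segments)
    while True:
        before = len(segs)
        segs = _soft_pass(segs, transitions)
        if not to_fixed_point or len(segs) == before:
            return segs


def _soft_pass(
    segs: list[LabeledSegment], transitions: Sequence[Transition]
) -> list[LabeledSegment]:
    segs = list(segs)
    index = 0
    for expected in transitions:
        while index < len(segs) - 1:
            a, b = segs[index], segs[index + 1]
            if (a.label, b.label) == expected:
                index += 1
                break
            if a.label == b.label and a.label == expected[0]:
                segs[index] = _merge(a, b)
                del segs[index + 1]
                break
            index += 1
        else:
            break  # ran out of segments; remaining transitions unmatched
    return segs
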