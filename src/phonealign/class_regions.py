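"""Biased nearest-neighbour class regions.

Each recognised token impulse at time ``t_i`` owns a class region of the
timeline; the boundary between the regions of successive impulses at
``t1 < t2`` is ``(1 - beta) * t1 + beta * t2``.  ``beta = 0.5`` is the
plain midpoint; ``beta -> 0`` pulls every boundary towards the earlier
impulse and ``beta -> 1`` towards the later one, compensating recognisers
whose impulses sit systematically early or late within the true phone.
The first region starts at 0 and the last ends at the utterance duration,
so the regions always partition ``[0, duration)``.
"""

from __future__ import annotations

from typing import Sequence

from phonealign.types import ClassRegion, RegionPartition, TimedToken

__all__ = ["biased_boundary", "decision_boundary_calc"]


def biased_boundary(t1: float, t2: float, bias: float) -> float:
    """Boundary between two successive impulses: ``(1 - bias)*t1 + bias*t2``."""
    if not t1 < t2:
        raise ValueError(f"impulse times must satisfy t1 < t2, got {t1} >= {t2}")
    if not 0.0 <= bias <= 1.0:
        raise ValueError(f"bias must lie in [0, 1], got {bias}")
    return (1.0 - bias) * t1 + bias * t2


def decision_boundary_calc(
    tokens: Sequence[TimedToken], duration: float, bias: float = 0.5
) -> RegionPartition:
    """Partition ``[0, duration)`` into one class region per token.

    Region ``i`` spans from the biased boundary with its predecessor to the
    biased boundary with its successor; the first region is anchored at 0
    and the last at ``duration``.
    """
    if not tokens:
        raise ValueError("cannot build class regions from an empty token list")
    times = [t.time for t in tokens]
    for a, b in zip(times, times[1:]):
        if not a < b:
            raise ValueError("token times must be strictly increasing")
    if times[-1] >= duration:
        raise ValueError("all token times must be < duration")

    cuts = [0.0]
    cuts += [biased_boundary(a, b, bias) for a, b in zip(times, times[1:])]
    cuts.append(duration)
    regions = tuple(
        ClassRegion(label=tok.label, start=lo, end=hi)
        for tok, lo, hi in zip(tokens, cuts, cuts[1:])
    )
    return RegionPartition(regions=regions, duration=duration, bias=bias)
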