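"""Shared domain types.

All time intervals are half-open ``[start, end)`` in seconds; sample-index
intervals are half-open ``[begin, end)`` with 0-based indices (TIMIT
convention).  Conversion between the two is ``t = n / f`` with ``f`` the
sampling rate in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: TIMIT's full 61-symbol ARPABET phone set (vowels, stops and their
#: closures, affricates, fricatives, nasals, semivowels, and the
#: silence/juncture symbols pau, epi, h#).
TIMIT_PHONES: tuple[str, ...] = (
    # vowels
    "iy", "ih", "eh", "ey", "ae", "aa", "aw", "ay", "ah", "ao",
    "oy", "ow", "uh", "uw", "ux", "er", "ax", "ix", "axr", "ax-h",
    # stops and flaps
    "b", "d", "g", "p", "t", "k", "dx", "q",
    # stop closures
    "bcl", "dcl", "gcl", "pcl", "tcl", "kcl",
    # affricates
    "jh", "ch",
    # fricatives
    "s", "sh", "z", "zh", "f", "th", "v", "dh", "hh", "hv",
    # nasals
    "m", "n", "ng", "em", "nx", "en", "eng",
    # semivowels and laterals
    "l", "r", "w", "y", "el",
    # silence / juncture
    "pau", "epi", "h#",
)

PAD_TOKEN = "[pad]"
UNK_TOKEN = "[unk]"
DELIMITER_TOKEN = "|"


@dataclass(frozen=True)
class PhoneInventory:
    """The phone label set plus the recogniser's CTC special tokens.

    ``codepoint_map`` assigns each phone a unique Unicode codepoint starting
    at U+1F600.  It exists only as tokenizer metadata (single-codepoint
    tokens survive character-level tokenizers); all public APIs speak
    ARPABET strings.
    """

    phones: frozenset[str]
    special_tokens: frozenset[str] = frozenset({PAD_TOKEN, UNK_TOKEN, DELIMITER_TOKEN})
    codepoint_map: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.phones & self.special_tokens:
            raise ValueError("special tokens must not appear in the phone set")
        if not self.codepoint_map:
            mapping = {
                phone: chr(0x1F600 + i) for i, phone in enumerate(sorted(self.phones))
            }
            object.__setattr__(self, "codepoint_map", mapping)
        if len(set(self.codepoint_map.values())) != len(self.codepoint_map):
            raise ValueError("codepoint_map must be a bijection")

    def is_special(self, label: str) -> bool:
        return label in self.special_tokens

    @classmethod
    def timit(cls) -> "PhoneInventory":
        return cls(phones=frozenset(TIMIT_PHONES))


def default_inventory() -> PhoneInventory:
    """The TIMIT 61-phone inventory with standard CTC special tokens."""
    return PhoneInventory.timit()


@dataclass(frozen=True)
class PhoneticAnnotation:
    """A TIMIT-style phone-level annotation: sample intervals plus labels."""

    entries: tuple[tuple[int, int, str], ...]
    sampling_rate: int

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        prev_begin = -1
        prev_end = 0
        for begin, end, phone in self.entries:
            if begin < 0 or begin >= end:
                raise ValueError(f"invalid interval [{begin}, {end}) for {phone!r}")
            if begin < prev_begin:
                raise ValueError("entries must be sorted by begin sample")
            if begin < prev_end:
                raise ValueError("entries must not overlap")
            prev_begin, prev_end = begin, end

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def duration(self) -> float:
        """End of the last entry in seconds (0.0 when empty)."""
        if not self.entries:
            return 0.0
        return self.entries[-1][1] / self.sampling_rate


@dataclass(frozen=True)
class TimedToken:
    """A recogniser token with its single impulse time in seconds."""

    label: str
    time: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("token time must be non-negative")


@dataclass(frozen=True)
class Segment:
    """An unlabelled half-open time interval from the segmenter."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment must satisfy start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class LabeledSegment:
    """A phone-labelled half-open time interval."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment must satisfy start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class ClassRegion:
    """The labelled interval of the timeline owned by one token impulse."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("class region must satisfy start < end")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class RegionPartition:
    """Contiguous class regions covering exactly ``[0, duration)``."""

    regions: tuple[ClassRegion, ...]
    duration: float
    bias: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")
        if not self.regions:
            raise ValueError("partition must contain at least one region")
        if self.regions[0].start != 0.0:
            raise ValueError("first region must start at 0")
        if abs(self.regions[-1].end - self.duration) > 1e-12:
            raise ValueError("last region must end at duration")
        for a, b in zip(self.regions, self.regions[1:]):
            if a.end != b.start:
                raise ValueError("regions must be contiguous")

    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.regions)


@dataclass(frozen=True)
class SpeechRegion:
    """A rising/falling edge pair from voice activity detection."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("speech region must satisfy start < end")


@dataclass(frozen=True)
class FrontendBundle:
    """Interchange payload produced by an acoustic frontend.

    Carries a per-frame label sequence (including pad/unknown/delimiter
    tokens), the audio extent as ``(n_samples, sampling_rate)``, the
    segmenter's unlabelled boundary times, and an optional path to the
    source WAV for VAD.
    """

    frame_labels: tuple[str, ...]
    n_samples: int
    sampling_rate: int
    boundaries_s: tuple[float, ...] = ()
    audio_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.sampling_rate <= 0:
            raise ValueError("n_samples and sampling_rate must be positive")
        dur = self.duration
        prev = -1.0
        for b in self.boundaries_s:
            if not 0.0 <= b <= dur:
                raise ValueError(f"boundary {b} outside [0, {dur}]")
            if b <= prev:
                raise ValueError("boundaries must be strictly increasing")
            prev = b

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def validate_sorted_segments(segments: Sequence[LabeledSegment]) -> None:
    """Raise if segments are unsorted or overlapping."""
    for a, b in zip(segments, segments[1:]):
        if b.start < a.end - 1e-12:
            raise ValueError(
                f"segments overlap or are unsorted: [{a.start}, {a.end}) then [{b.start}, {b.end})"
            )


def total_span(segments: Iterable[LabeledSegment]) -> float:
    return sum(s.length for s in segments)
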