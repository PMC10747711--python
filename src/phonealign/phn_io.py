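"""TIMIT-style PHN annotation I/O, sample-rate repair, frontend-bundle
interchange, and Praat TextGrid export.

PHN files are whitespace-delimited ``BEGIN_SAMPLE END_SAMPLE PHONE`` lines,
one phone per line, with 0-based half-open sample intervals.  Some corpora
(notably the array-microphone portion of TORGO) ship PHN files whose sample
indices refer to the original 44.1 kHz recordings while the audio was
downsampled to 16 kHz; :func:`rescale_phn` repairs the mismatch.  A second
corpus defect — placeholder files that are empty or contain only ``.jpg``
or ``xxx`` — is rejected at read time as :class:`UnusablePhnError`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

from phonealign.types import (
    FrontendBundle,
    LabeledSegment,
    PhoneticAnnotation,
    validate_sorted_segments,
)

__all__ = [
    "PhnParseError",
    "UnusablePhnError",
    "annotation_to_segments",
    "export_textgrid",
    "read_bundle",
    "read_phn",
    "rescale_phn",
    "segments_to_annotation",
    "write_bundle",
    "write_phn",
]

_PLACEHOLDER_CONTENT = {".jpg", "xxx"}


class PhnParseError(ValueError):
    """A PHN line could not be parsed or failed validation."""


class UnusablePhnError(PhnParseError):
    """The file is empty or a known placeholder (''.jpg'' / ''xxx'')."""


def read_phn(path: str | Path, sampling_rate: int) -> PhoneticAnnotation:
    """Read a PHN file, validating and sorting its entries.

    Parameters
    ----------
    path
        PHN file with lines ``begin end phone``.
    sampling_rate
        Rate (Hz) the sample indices refer to; PHN files do not store it.

    Raises
    ------
    UnusablePhnError
        Empty file, or content that is solely a placeholder string.
    PhnParseError
        A malformed line (reported with its 1-based line number) or an
        entry with ``begin >= end``.
    """
    text = Path(path).read_text()
    stripped = text.strip()
    if not stripped or stripped in _PLACEHOLDER_CONTENT:
        raise UnusablePhnError(f"{path}: empty or placeholder PHN file")

    entries: list[tuple[int, int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            raise PhnParseError(f"{path}:{lineno}: blank line inside PHN file")
        parts = line.split()
        if len(parts) != 3:
            raise PhnParseError(
                f"{path}:{lineno}: expected 'begin end phone', got {line!r}"
            )
        try:
            begin, end = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise PhnParseError(f"{path}:{lineno}: non-integer sample index") from exc
        if begin >= end:
            raise PhnParseError(
                f"{path}:{lineno}: begin sample {begin} must be < end sample {end}"
            )
        entries.append((begin, end, parts[2]))

    entries.sort(key=lambda e: e[0])
    return PhoneticAnnotation(entries=tuple(entries), sampling_rate=sampling_rate)


def write_phn(ann: PhoneticAnnotation, path: str | Path) -> None:
    """Write an annotation as PHN; refuses an empty annotation."""
    if not ann.entries:
        raise ValueError("refusing to write an empty PHN file")
    lines = [f"{b} {e} {p}" for b, e, p in sorted(ann.entries, key=lambda x: x[0])]
    Path(path).write_text("\n".join(lines) + "\n")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def rescale_phn(
    ann: PhoneticAnnotation, old_rate: int, new_rate: int
) -> PhoneticAnnotation:
    """Recompute sample indices for audio resampled ``old_rate → new_rate``.

    Each index is multiplied by ``new_rate / old_rate`` and rounded to the
    nearest integer (half away from zero).  Raises if rounding collapses an
    entry to zero length.
    """
    if old_rate <= 0 or new_rate <= 0:
        raise ValueError("sampling rates must be positive")
    ratio = new_rate / old_rate
    entries = []
    for begin, end, phone in ann.entries:
        nb, ne = _round_half_away(begin * ratio), _round_half_away(end * ratio)
        if nb >= ne:
            raise ValueError(
                f"rescaling produced degenerate interval [{nb}, {ne}) for {phone!r}"
            )
        entries.append((nb, ne, phone))
    return PhoneticAnnotation(entries=tuple(entries), sampling_rate=new_rate)


def annotation_to_segments(ann: PhoneticAnnotation) -> list[LabeledSegment]:
    """Convert sample-indexed entries to labelled segments in seconds."""
    f = ann.sampling_rate
    return [LabeledSegment(p, b / f, e / f) for b, e, p in ann.entries]


def segments_to_annotation(
    segments: Sequence[LabeledSegment], sampling_rate: int
) -> PhoneticAnnotation:
    """Convert labelled segments (seconds) to a sample-indexed annotation."""
    entries = tuple(
        (_round_half_away(s.start * sampling_rate), _round_half_away(s.end * sampling_rate), s.label)
        for s in segments
    )
    return PhoneticAnnotation(entries=entries, sampling_rate=sampling_rate)


def export_textgrid(
    segments: Sequence[LabeledSegment], duration: float, path: str | Path
) -> None:
    """Write segments as a Praat long-format TextGrid.

    A single interval tier named ``phones`` covers ``[0, duration]``; gaps
    between segments (and before/after them) become empty-label intervals.
    """
    segments = sorted(segments, key=lambda s: s.start)
    validate_sorted_segments(segments)
    if segments and (segments[0].start < 0 or segments[-1].end > duration + 1e-9):
        raise ValueError("segments must lie within [0, duration]")

    intervals: list[tuple[float, float, str]] = []
    cursor = 0.0
    for seg in segments:
        if seg.start > cursor + 1e-12:
            intervals.append((cursor, seg.start, ""))
        intervals.append((seg.start, seg.end, seg.label))
        cursor = seg.end
    if cursor < duration - 1e-12 or not intervals:
        intervals.append((cursor, duration, ""))

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {duration:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        '        name = "phones"',
        "        xmin = 0",
        f"        xmax = {duration:.6f}",
        f"        intervals: size = {len(intervals)}",
    ]
    for i, (xmin, xmax, text) in enumerate(intervals, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {xmin:.6f}",
            f"            xmax = {xmax:.6f}",
            f'            text = "{text}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_textgrid(path: str | Path) -> list[LabeledSegment]:
    """Read labelled intervals from a Praat long-format TextGrid.

    Returns the non-empty-label intervals of the first interval tier.
    Understands the subset of the format that :func:`export_textgrid`
    writes (which is also what most tools emit for a single tier).
    """
    import re

    text = Path(path).read_text()
    pattern = re.compile(
        r"xmin\s*=\s*([0-9.eE+-]+)\s*\n\s*xmax\s*=\s*([0-9.eE+-]+)\s*\n\s*"
        r'text\s*=\s*"([^"]*)"'
    )
    segments = [
        LabeledSegment(label=m.group(3), start=float(m.group(1)), end=float(m.group(2)))
        for m in pattern.finditer(text)
        if m.group(3)
    ]
    if not segments:
        raise ValueError(f"{path}: no labelled intervals found")
    return segments


def read_bundle(path: str | Path) -> FrontendBundle:
    """Read a frontend interchange JSON file.

    Expected keys: ``frame_labels`` (list of token strings), ``n_samples``,
    ``sampling_rate``, ``boundaries_s`` (optional), ``audio_path``
    (optional).
    """
    data = json.loads(Path(path).read_text())
    try:
        return FrontendBundle(
            frame_labels=tuple(data["frame_labels"]),
            n_samples=int(data["n_samples"]),
            sampling_rate=int(data["sampling_rate"]),
            boundaries_s=tuple(float(b) for b in data.get("boundaries_s", [])),
            audio_path=data.get("audio_path"),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing interchange key {exc}") from exc


def write_bundle(bundle: FrontendBundle, path: str | Path) -> None:
    """Write a frontend interchange JSON file (round-trips read_bundle)."""
    payload = {
        "frame_labels": list(bundle.frame_labels),
        "n_samples": bundle.n_samples,
        "sampling_rate": bundle.sampling_rate,
        "boundaries_s": list(bundle.boundaries_s),
    }
    if bundle.audio_path is not None:
        payload["audio_path"] = bundle.audio_path
    Path(path).write_text(json.dumps(payload))
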