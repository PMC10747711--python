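"""Energy-based voice activity detection and silence-boundary removal.

The detector frames the signal (window 25 ms, hop 10 ms, nFFT 2048 by
default), computes framewise RMS energy over each window, and min–max
normalises the energies to ``[0, 1]`` over the utterance; thresholding at
0.5 yields a binary speech/non-speech sequence.  Runs of speech frames
become rising/falling edge pairs (speech regions), and any segment
boundary lying strictly inside a non-speech gap is deleted — so segments
wholly contained in silence disappear.  The detector sits behind a plain
``FrameProbabilities`` interface, so a model-based VAD can be swapped in.

Frame-time convention: frame ``i`` covers ``[i*hop, i*hop + window)``;
region edges use frame start times, and a speech run extending to the last
frame closes at the total duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile

from phonealign.types import SpeechRegion

__all__ = [
    "FrameProbabilities",
    "compute_vad",
    "filter_segments",
    "probabilities_to_regions",
    "read_wav",
]

DEFAULT_NFFT = 2048
DEFAULT_WINDOW = 0.025
DEFAULT_HOP = 0.01
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class FrameProbabilities:
    """Per-frame speech probabilities with the framing parameters used."""

    values: tuple[float, ...]
    hop: float
    window: float
    n_fft: int
    threshold: float
    duration: float

    def __post_init__(self) -> None:
        if self.hop <= 0:
            raise ValueError("hop must be positive")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ValueError("probabilities must lie in [0, 1]")

    def binary(self) -> np.ndarray:
        """Thresholded speech/non-speech decisions (1 = speech)."""
        return (np.asarray(self.values) >= self.threshold).astype(int)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV as float64 in [-1, 1] plus its sampling rate."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return data, rate


def compute_vad(
    wav: np.ndarray | str | Path,
    sampling_rate: int | None = None,
    n_fft: int = DEFAULT_NFFT,
    window: float = DEFAULT_WINDOW,
    hop: float = DEFAULT_HOP,
    threshold: float = DEFAULT_THRESHOLD,
) -> FrameProbabilities:
    """Framewise RMS-energy VAD, min–max normalised to ``[0, 1]``.

    ``wav`` is either a 1-D float array (``sampling_rate`` required) or a
    path to a mono PCM WAV file.  Raises if the audio is shorter than one
    analysis window.
    """
    if isinstance(wav, (str, Path)):
        signal, sampling_rate = read_wav(wav)
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate is required with array input")
        signal = np.asarray(wav, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("audio is empty")

    win_n = int(round(window * sampling_rate))
    hop_n = int(round(hop * sampling_rate))
    if signal.size < win_n:
        raise ValueError(
            f"audio ({signal.size} samples) shorter than one window ({win_n})"
        )

    starts = np.arange(0, signal.size - win_n + 1, hop_n)
    # RMS over each window via cumulative sum of squares
    csq = np.concatenate([[0.0], np.cumsum(signal**2)])
    energy = np.sqrt((csq[starts + win_n] - csq[starts]) / win_n)

    lo, hi = energy.min(), energy.max()
    probs = np.zeros_like(energy) if hi - lo < 1e-12 else (energy - lo) / (hi - lo)
    return FrameProbabilities(
        values=tuple(float(p) for p in probs),
        hop=hop,
        window=window,
        n_fft=n_fft,
        threshold=threshold,
        duration=signal.size / sampling_rate,
    )


def probabilities_to_regions(probs: FrameProbabilities) -> list[SpeechRegion]:
    """Convert thresholded frame decisions to rising/falling edge pairs.

    A region opens at the start time of the first speech frame of a run
    and closes at the start time of the first non-speech frame after it;
    a run reaching the last frame closes at the total duration.
    """
    binary = probs.binary()
    regions: list[SpeechRegion] = []
    open_at: float | None = None
    for i, flag in enumerate(binary):
        if flag and open_at is None:
            open_at = i * probs.hop
        elif not flag and open_at is not None:
            regions.append(SpeechRegion(start=open_at, end=i * probs.hop))
            open_at = None
    if open_at is not None:
        regions.append(SpeechRegion(start=open_at, end=probs.duration))
    return regions


def filter_segments(
    boundaries: Sequence[float], regions: Sequence[SpeechRegion]
) -> list[float]:
    """Delete boundary points lying strictly inside non-speech gaps.

    A boundary is kept when it falls inside (or exactly on the edge of)
    some speech region.  Both delimiting boundaries of a segment wholly
    contained in silence are removed, so the segment disappears.  With no
    regions at all, everything is treated as non-speech and all boundaries
    are dropped.
    """
    prev = None
    for b in boundaries:
        if prev is not None and b <= prev:
            raise ValueError("boundaries must be strictly increasing")
        prev = b
    return [
        b for b in boundaries if any(r.start <= b <= r.end for r in regions)
    ]
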