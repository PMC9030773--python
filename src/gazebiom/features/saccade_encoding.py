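"""Saccade micropattern encoding (wordbook n-gram counts).

Each saccade becomes one character from its direction sector and amplitude
class: 8 sectors counter-clockwise from rightward mapped to
``r e u f l g d h`` (so up on screen is ``u``), lowercase for amplitudes
below a threshold and uppercase at or above it.  A 4-sector variant
(``r u l d``) is available.  Sliding windows of lengths 1-3 over the
per-segment string yield micropatterns; a wordbook of the 40 most frequent
micropatterns in the *training* partition (ties broken lexicographically)
defines the feature slots, and a segment's features are its wordbook-entry
counts normalized by its string length.

The amplitude threshold defaults to the median saccade amplitude of the
training partition (fixed-degree thresholds are unusable without angular
calibration), so both the threshold and the wordbook must be refit inside
every cross-validation training fold — :class:`SaccadeEncoder` bundles the
two fitted artifacts to make that discipline easy to audit.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

# sector order is counter-clockwise starting at rightward
_CHARS_8 = "reuflgdh"
_CHARS_4 = "ruld"

SACCADE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"sacc_ngram_{i:02d}" for i in range(40))


@dataclass(frozen=True)
class EncodingConfig:
    n_direction_bins: int = 8
    amplitude_threshold: float | None = None  # px; training-partition median
    ngram_lengths: tuple[int, ...] = (1, 2, 3)
    wordbook_size: int = 40

    def __post_init__(self) -> None:
        if self.n_direction_bins not in (4, 8):
            raise ValueError("n_direction_bins must be 4 or 8")
        if self.wordbook_size < 1:
            raise ValueError("wordbook_size must be positive")


@dataclass(frozen=True)
class Wordbook:
    """Ordered micropattern vocabulary frozen at training time."""

    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("wordbook entries must be unique")

    def __len__(self) -> int:
        return len(self.entries)


def _char_for(direction: float, amplitude: float,
              config: EncodingConfig) -> str:
    chars = _CHARS_8 if config.n_direction_bins == 8 else _CHARS_4
    width = 2 * math.pi / config.n_direction_bins
    sector = int(math.floor(direction / width + 0.5)) % config.n_direction_bins
    c = chars[sector]
    return c.upper() if amplitude >= config.amplitude_threshold else c


def encode_saccades(saccades, config: EncodingConfig) -> str:
    """One character per saccade; direction 0 rad = rightward, CCW positive.

    ``saccades`` is either a sequence of Saccade events or a pair of
    (amplitudes, directions) arrays.
    """
    if config.amplitude_threshold is None:
        raise ValueError("amplitude_threshold must be set before encoding")
    if isinstance(saccades, tuple) and len(saccades) == 2:
        amps, dirs = (np.asarray(a, dtype=float) for a in saccades)
    else:
        amps = np.array([s.amplitude for s in saccades], dtype=float)
        dirs = np.array([s.direction for s in saccades], dtype=float)
    return "".join(_char_for(d, a, config) for a, d in zip(amps, dirs))


def count_micropatterns(string: str, ngram_lengths=(1, 2, 3)) -> Counter:
    """Overlapping sliding-window substring counts for each length."""
    counts: Counter = Counter()
    for length in ngram_lengths:
        for i in range(len(string) - length + 1):
            counts[string[i:i + length]] += 1
    return counts


def build_wordbook(training_strings, config: EncodingConfig) -> Wordbook:
    """Top-``wordbook_size`` micropatterns by total training count.

    Ties are broken lexicographically; deterministic for a fixed corpus.
    """
    total: Counter = Counter()
    for s in training_strings:
        total.update(count_micropatterns(s, config.ngram_lengths))
    ranked = sorted(total.items(), key=lambda kv: (-kv[1], kv[0]))
    return Wordbook(tuple(p for p, _ in ranked[:config.wordbook_size]))


def encoding_features(segment_string: str, wordbook: Wordbook) -> np.ndarray:
    """Wordbook-entry counts in the string, normalized by string length.

    Entries absent from the wordbook contribute nothing; an empty string (or
    a wordbook shorter than its nominal size) zero-fills.
    """
    out = np.zeros(40 if len(wordbook) <= 40 else len(wordbook))
    if not segment_string:
        return out
    counts = count_micropatterns(
        segment_string, sorted({len(e) for e in wordbook.entries}))
    for i, entry in enumerate(wordbook.entries):
        out[i] = counts.get(entry, 0) / len(segment_string)
    return out


class SaccadeEncoder:
    """Training-fold-fitted amplitude threshold + wordbook, applied per segment."""

    def __init__(self, config: EncodingConfig | None = None):
        self.config = config or EncodingConfig()
        self.fitted_config: EncodingConfig | None = None
        self.wordbook: Wordbook | None = None

    def fit(self, segments_saccades) -> "SaccadeEncoder":
        """``segments_saccades``: per-training-segment (amplitudes, directions)."""
        all_amps = np.concatenate(
            [np.asarray(a, dtype=float) for a, _ in segments_saccades]
            or [np.array([])])
        threshold = (self.config.amplitude_threshold
                     if self.config.amplitude_threshold is not None
                     else float(np.median(all_amps)) if len(all_amps) else 0.0)
        self.fitted_config = EncodingConfig(
            n_direction_bins=self.config.n_direction_bins,
            amplitude_threshold=threshold,
            ngram_lengths=self.config.ngram_lengths,
            wordbook_size=self.config.wordbook_size,
        )
        strings = [encode_saccades(pair, self.fitted_config)
                   for pair in segments_saccades]
        self.wordbook = build_wordbook(strings, self.fitted_config)
        return self

    def transform(self, segments_saccades) -> np.ndarray:
        if self.fitted_config is None or self.wordbook is None:
            raise RuntimeError("encoder must be fit on a training partition first")
        rows = [encoding_features(encode_saccades(pair, self.fitted_config),
                                  self.wordbook)
                for pair in segments_saccades]
        return np.vstack(rows) if rows else np.zeros((0, 40))


__all__ = [
    "SACCADE_FEATURE_NAMES", "EncodingConfig", "Wordbook", "SaccadeEncoder",
    "encode_saccades", "count_micropatterns", "build_wordbook",
    "encoding_features",
]
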