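"""Within-genome sliding-window composition scanning.

A genome is cut into overlapping windows (2000 bp / 500 bp step by default —
wide enough to sample most of the 256 tetranucleotide space, narrow enough
to localize a few-kb anomaly). Each window is normalized to its *own*
nucleotide composition, exactly as a whole genome would be, so a window's
usage-deviation vector reflects word preferences rather than local GC.
Pairwise Euclidean distances between window vectors form a heatmap in which
a horizontally acquired segment shows up as a self-similar block that is
distant from everything else; entries between physically overlapping
windows are masked because shared sequence makes them trivially similar.

:func:`call_outlier_windows` turns visual heatmap inspection into a
reproducible caller: windows whose mean unmasked distance exceeds a robust
(median + z * scaled-MAD) threshold are flagged and merged into intervals.
Single-word tracks (:func:`word_track`) profile one word, e.g. GATC, along
the genome in larger windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer_core import (
    UsageVector,
    canonicalize,
    composition,
    expected_count,
    usage_deviation,
)
from .sequence_io import Genome, StrandPair, ValidationError, extend_with_revcomp, revcomp


@dataclass(frozen=True)
class WindowInterval:
    """0-based half-open genomic interval, flagged if shorter than requested."""

    start: int
    end: int
    truncated: bool = False


def sliding_windows(
    genome: Genome, window_size: int = 2000, step: int = 500
) -> list[WindowInterval]:
    """Window start coordinates [s, s+window_size) for s = 0, step, 2*step, ...

    Windows run while they fit entirely inside the genome; a trailing partial
    window is dropped because a short window under-samples the word space.
    If the whole genome is shorter than one window, a single truncated
    interval [0, L) is returned.
    """
    if window_size <= 0 or step <= 0:
        raise ValidationError("window_size and step must be positive")
    L = genome.length
    if L < window_size:
        return [WindowInterval(0, L, truncated=True)]
    return [
        WindowInterval(s, s + window_size)
        for s in range(0, L - window_size + 1, step)
    ]


@dataclass
class WindowProfile:
    """Ordered per-window usage vectors for one genome at fixed window/step."""

    source_id: str
    k: int
    window_size: int
    step: int
    starts: list[int]
    vectors: list[UsageVector]
    truncated: bool = False


def window_profile(
    genome: Genome, k: int = 4, window_size: int = 2000, step: int = 500
) -> WindowProfile:
    """Usage-deviation vector of every sliding window.

    Each window subsequence is treated as an independent mini-genome:
    extended by its own reverse complement, counted, and normalized to its
    own composition. No cross-collection universality filter applies within
    a genome.
    """
    if genome.length < k:
        raise ValidationError(
            f"genome {genome.id!r} (length {genome.length}) is shorter than k={k}"
        )
    intervals = sliding_windows(genome, window_size, step)
    vectors = []
    for iv in intervals:
        sub = Genome(
            id=f"{genome.id}:{iv.start}-{iv.end}",
            sequence=genome.sequence[iv.start : iv.end],
        )
        vectors.append(usage_deviation(sub, k))
    return WindowProfile(
        source_id=genome.id,
        k=k,
        window_size=window_size,
        step=step,
        starts=[iv.start for iv in intervals],
        vectors=vectors,
        truncated=any(iv.truncated for iv in intervals),
    )


@dataclass
class WindowHeatmap:
    """Pairwise window distances with an overlap mask.

    ``overlap_mask[i, j]`` is True when windows i and j share any sequence
    (|start_i - start_j| < window_size); masked entries are excluded from
    downstream outlier statistics.
    """

    source_id: str
    window_size: int
    step: int
    starts: list[int]
    distances: np.ndarray
    overlap_mask: np.ndarray


def window_heatmap(profile: WindowProfile) -> WindowHeatmap:
    """All-pairs Euclidean distances between canonicalized window vectors.

    For each window pair, only words with nonzero expected count in both
    windows enter the distance — a word unattainable in a short window (a
    needed nucleotide absent) should not contribute spurious distance.
    """
    if len(profile.vectors) < 2:
        raise ValidationError("heatmap requires at least 2 windows")
    canon = [v if v.canonicalized else canonicalize(v) for v in profile.vectors]
    dev = np.vstack([v.deviation_array() for v in canon])
    attainable = np.vstack(
        [np.array([v.expected[w] > 0 for w in v.words], dtype=bool) for v in canon]
    )
    n = len(canon)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = attainable[i] & attainable[j]
            diff = (dev[i] - dev[j])[usable]
            D[i, j] = D[j, i] = float(np.sqrt((diff**2).sum()))
    starts = np.array(profile.starts)
    mask = np.abs(starts[:, None] - starts[None, :]) < profile.window_size
    return WindowHeatmap(
        source_id=profile.source_id,
        window_size=profile.window_size,
        step=profile.step,
        starts=list(profile.starts),
        distances=D,
        overlap_mask=mask,
    )


@dataclass
class WordTrack:
    """Per-window usage deviation of a single word along one genome."""

    source_id: str
    word: str
    window_size: int
    step: int
    starts: list[int]
    deviation: list[float]


def _count_occurrences(haystack: str, needle: str) -> int:
    # overlapping occurrences (str.count is non-overlapping)
    count = 0
    pos = haystack.find(needle)
    while pos != -1:
        count += 1
        pos = haystack.find(needle, pos + 1)
    return count


def word_track(
    genome: Genome, word: str, window_size: int = 5000, step: int = 1000
) -> WordTrack:
    """Track one word's usage deviation in sliding windows.

    Per window: observed = occurrences of the word over both strands of the
    extended window; expected = zero-order model expectation under the
    window's own composition; deviation = observed / expected (0 when the
    expectation is 0).
    """
    word = word.upper()
    if not word or any(ch not in "ACGT" for ch in word):
        raise ValidationError(f"word must be a nonempty string over ACGT, got {word!r}")
    if len(word) > window_size:
        raise ValidationError("word longer than window_size")
    intervals = sliding_windows(genome, window_size, step)
    starts, devs = [], []
    for iv in intervals:
        sub = Genome(id=f"{genome.id}:{iv.start}", sequence=genome.sequence[iv.start : iv.end])
        pair = extend_with_revcomp(sub)
        obs = _count_occurrences(pair.forward, word) + _count_occurrences(pair.reverse, word)
        exp = expected_count(word, composition(pair))
        starts.append(iv.start)
        devs.append(obs / exp if exp > 0 else 0.0)
    return WordTrack(
        source_id=genome.id,
        word=word,
        window_size=window_size,
        step=step,
        starts=starts,
        deviation=devs,
    )


def group_mean_track(tracks: list[WordTrack], group_name: str = "group") -> WordTrack:
    """Element-wise mean of several tracks, truncated at the shortest.

    Genomes of different lengths are aligned by window index from the genome
    start; the mean stops where the shortest genome's track ends.
    """
    if not tracks:
        raise ValidationError("group_mean_track requires at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.word, t.window_size, t.step) != (first.word, first.window_size, first.step):
            raise ValidationError("tracks must share word, window_size and step")
    n = min(len(t.deviation) for t in tracks)
    mean = np.vstack([t.deviation[:n] for t in tracks]).mean(axis=0)
    return WordTrack(
        source_id=group_name,
        word=first.word,
        window_size=first.window_size,
        step=first.step,
        starts=list(first.starts[:n]),
        deviation=[float(v) for v in mean],
    )


def call_outlier_windows(
    heatmap: WindowHeatmap, z: float = 3.0
) -> list[tuple[int, int]]:
    """Flag compositionally anomalous windows and merge them into intervals.

    Each window's mean distance to all non-overlapping windows is computed;
    windows at or above median + z * 1.4826 * MAD of those means are
    flagged (the robust threshold tolerates the heavy tail that repeat
    blocks and genuine transfers create). Runs of adjacent flagged windows
    are merged; returned intervals are 0-based half-open in genome
    coordinates.
    """
    unmasked = ~heatmap.overlap_mask
    n = heatmap.distances.shape[0]
    iu = np.triu_indices(n, k=1)
    if int(unmasked[iu].sum()) < 5:
        raise ValidationError("need at least 5 unmasked window pairs to call outliers")
    means = np.full(n, np.nan)
    for i in range(n):
        sel = unmasked[i]
        if sel.any():
            means[i] = heatmap.distances[i, sel].mean()
    valid = ~np.isnan(means)
    med = float(np.median(means[valid]))
    mad = float(np.median(np.abs(means[valid] - med)))
    threshold = med + z * 1.4826 * mad
    flagged = valid & (means >= threshold)
    intervals: list[tuple[int, int]] = []
    for i in range(n):
        if not flagged[i]:
            continue
        start = heatmap.starts[i]
        end = heatmap.starts[i] + heatmap.window_size
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], end))
        else:
            intervals.append((start, end))
    return intervals
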