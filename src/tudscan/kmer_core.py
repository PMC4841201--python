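"""Word counting and usage-deviation vectors under a zero-order Markov model.

The central statistic is the usage deviation of a word W of length k —
for k = 4 the tetranucleotide usage deviation, TUD:

    TUD(W) = N(W) / E(W),        E(W) = A^a * T^t * C^c * G^g * N

where N(W) is the observed count of W over both strands of the extended
sequence, A/T/C/G are the mononucleotide frequencies of the extended
sequence, a/t/c/g the counts of each nucleotide in W, and N the extended
sequence length. A value of 1 means the word occurs exactly as often as a
zero-order (mononucleotide shuffle) model predicts; a value of 2 means twice
as often. Normalizing by E(W) removes the trivial enrichment of GC-rich
words in GC-rich genomes, so deviation vectors are comparable across genomes
of different base composition.

Because counting runs over both strands, a word and its reverse complement
always receive identical deviations; :func:`canonicalize` drops one member of
each redundant pair before distance computations. :func:`filter_universal`
additionally removes words absent from at least one genome of a collection,
so log transforms and ratios stay well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .sequence_io import Genome, StrandPair, ValidationError, extend_with_revcomp, revcomp

MAX_K = 8  # 4^8 words; larger k would be memory-hostile and is out of scope

ALPHABET = "ACGT"

# byte -> 2-bit code; N (and anything else) -> -1, masking the window
_CODES = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _CODES[ord(_c)] = _i


@dataclass(frozen=True)
class Word:
    """A k-mer over {A,C,G,T} with its nucleotide composition."""

    text: str

    @property
    def k(self) -> int:
        return len(self.text)

    @property
    def composition(self) -> tuple[int, int, int, int]:
        """Counts (a, t, c, g) of each nucleotide in the word."""
        return word_composition(self.text)

    @property
    def canonical(self) -> str:
        return canonical_word(self.text)


def word_composition(word: str) -> tuple[int, int, int, int]:
    """Counts (a, t, c, g) of each nucleotide in ``word``."""
    return word.count("A"), word.count("T"), word.count("C"), word.count("G")


def canonical_word(word: str) -> str:
    """Lexicographic minimum of a word and its reverse complement."""
    return min(word, revcomp(word))


def enumerate_words(k: int) -> list[str]:
    """All 4^k words of length k in lexicographic (A < C < G < T) order."""
    if not 1 <= k <= MAX_K:
        raise ValidationError(f"k must be in [1, {MAX_K}], got {k}")
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def _encode(sequence: str) -> np.ndarray:
    return _CODES[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _count_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Occurrence counts of every k-mer (indexed by base-4 code) in one strand.

    Windows containing any N contribute nothing.
    """
    n = codes.size
    if n < k:
        return np.zeros(4**k, dtype=np.int64)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        col = codes[j : j + m]
        vals = vals * 4 + col
        ok &= col >= 0
    return np.bincount(vals[ok], minlength=4**k)


def count_words(pair: StrandPair, k: int) -> dict[str, int]:
    """Count each k-mer over both strands of an extended sequence.

    Every enumerated word gets an entry (possibly 0). Any window containing
    an N is skipped entirely.
    """
    if not 1 <= k <= MAX_K:
        raise ValidationError(f"k must be in [1, {MAX_K}], got {k}")
    if k > len(pair.forward):
        raise ValidationError(
            f"k={k} exceeds sequence length {len(pair.forward)} for {pair.source_id!r}"
        )
    counts = _count_codes(_encode(pair.forward), k) + _count_codes(_encode(pair.reverse), k)
    words = enumerate_words(k)
    return {w: int(c) for w, c in zip(words, counts)}


@dataclass(frozen=True)
class NucleotideComposition:
    """Mononucleotide frequencies of an extended sequence.

    ``n_total`` is the combined length of both strands (the formula's N);
    ``n_effective`` counts only A/C/G/T characters, over which the
    frequencies are computed. On an extended strand pair freq_a == freq_t and
    freq_c == freq_g exactly, because every A on one strand is a T on the
    other.
    """

    freq_a: float
    freq_t: float
    freq_c: float
    freq_g: float
    n_effective: int
    n_total: int


def composition(pair: StrandPair) -> NucleotideComposition:
    """Mononucleotide frequencies over the ACGT characters of both strands."""
    counts = np.zeros(4, dtype=np.int64)
    for strand in (pair.forward, pair.reverse):
        codes = _encode(strand)
        counts += np.bincount(codes[codes >= 0], minlength=4)
    n_eff = int(counts.sum())
    if n_eff == 0:
        raise ValidationError(f"sequence {pair.source_id!r} contains no A/C/G/T characters")
    freqs = counts / n_eff
    return NucleotideComposition(
        freq_a=float(freqs[0]),
        freq_c=float(freqs[1]),
        freq_g=float(freqs[2]),
        freq_t=float(freqs[3]),
        n_effective=n_eff,
        n_total=len(pair.forward) + len(pair.reverse),
    )


def expected_count(word: str | Word, comp: NucleotideComposition) -> float:
    """Expected count of a word under the zero-order model: A^a T^t C^c G^g N.

    The A/T and C/G factors are grouped before multiplying so that a word and
    its reverse complement (which swap a<->t and c<->g) produce bit-identical
    results whenever freq_a == freq_t and freq_c == freq_g.
    """
    text = word.text if isinstance(word, Word) else word
    a, t, c, g = word_composition(text)
    at = (comp.freq_a**a) * (comp.freq_t**t)
    cg = (comp.freq_c**c) * (comp.freq_g**g)
    return at * cg * comp.n_total


@dataclass
class UsageVector:
    """Observed, expected and deviation values for every retained word.

    ``words`` is the ordered list of retained words (all 4^k before
    canonicalization/filtering); the three maps are keyed by those words.
    ``undefined_words`` lists words observed but with zero expectation
    (possible only when a nucleotide is entirely absent); their deviation is
    reported as 0.
    """

    source_id: str
    k: int
    words: tuple[str, ...]
    observed: dict[str, int]
    expected: dict[str, float]
    deviation: dict[str, float]
    canonicalized: bool = False
    undefined_words: tuple[str, ...] = ()

    @property
    def filtered_words(self) -> tuple[str, ...]:
        return self.words

    def deviation_array(self) -> np.ndarray:
        return np.array([self.deviation[w] for w in self.words], dtype=float)

    def observed_array(self) -> np.ndarray:
        return np.array([self.observed[w] for w in self.words], dtype=np.int64)


def usage_deviation(
    genome: Genome,
    k: int = 4,
    expected_denominator: str = "length",
) -> UsageVector:
    """Usage-deviation vector of one genome at word length k.

    Pipeline: extend with the reverse complement, count words over both
    strands, compute mononucleotide frequencies, and divide observed by
    expected counts. Deviation is 0 for unobserved words.

    ``expected_denominator`` selects the N in E(W): ``"length"`` (default)
    uses the extended sequence length; ``"positions"`` uses the number of
    word start positions, 2*(L-k+1). The two differ by a factor of
    order k/L.
    """
    if expected_denominator not in ("length", "positions"):
        raise ValidationError(
            f"expected_denominator must be 'length' or 'positions', got {expected_denominator!r}"
        )
    if genome.length < k:
        raise ValidationError(
            f"genome {genome.id!r} (length {genome.length}) is shorter than k={k}"
        )
    pair = extend_with_revcomp(genome)
    observed = count_words(pair, k)
    comp = composition(pair)
    if expected_denominator == "positions":
        comp = NucleotideComposition(
            freq_a=comp.freq_a,
            freq_t=comp.freq_t,
            freq_c=comp.freq_c,
            freq_g=comp.freq_g,
            n_effective=comp.n_effective,
            n_total=2 * (genome.length - k + 1),
        )
    words = tuple(enumerate_words(k))
    expected = {w: expected_count(w, comp) for w in words}
    deviation: dict[str, float] = {}
    undefined: list[str] = []
    for w in words:
        e = expected[w]
        o = observed[w]
        if o == 0:
            deviation[w] = 0.0
        elif e > 0:
            deviation[w] = o / e
        else:
            deviation[w] = 0.0
            undefined.append(w)
    return UsageVector(
        source_id=genome.id,
        k=k,
        words=words,
        observed=observed,
        expected=expected,
        deviation=deviation,
        canonicalized=False,
        undefined_words=tuple(undefined),
    )


def canonicalize(vector: UsageVector) -> UsageVector:
    """Drop the redundant member of each reverse-complement word pair.

    Double-strand counting makes deviation(W) == deviation(revcomp(W)), so
    one of the two is removed — the lexicographically larger. Palindromes are
    kept once. Values of retained words are unchanged.
    """
    if vector.canonicalized:
        raise ValidationError(f"vector {vector.source_id!r} is already canonicalized")
    kept = tuple(w for w in vector.words if w <= revcomp(w))
    return UsageVector(
        source_id=vector.source_id,
        k=vector.k,
        words=kept,
        observed={w: vector.observed[w] for w in kept},
        expected={w: vector.expected[w] for w in kept},
        deviation={w: vector.deviation[w] for w in kept},
        canonicalized=True,
        undefined_words=tuple(w for w in vector.undefined_words if w in set(kept)),
    )


def filter_universal(vectors: list[UsageVector]) -> list[UsageVector]:
    """Remove words not observed at least once in every vector.

    All vectors must share k, canonicalization state and word list; the
    returned vectors share one identical ordered word list. After this
    filter every retained deviation is strictly positive, which makes the
    vectors safe to log-transform.
    """
    if not vectors:
        raise ValidationError("filter_universal requires at least one vector")
    first = vectors[0]
    for v in vectors[1:]:
        if v.k != first.k:
            raise ValidationError(f"mixed k: {first.k} vs {v.k}")
        if v.canonicalized != first.canonicalized:
            raise ValidationError("mixed canonicalization state")
        if v.words != first.words:
            raise ValidationError("vectors must share an identical word list")
    kept = tuple(w for w in first.words if all(v.observed[w] > 0 for v in vectors))
    out = []
    for v in vectors:
        out.append(
            replace(
                v,
                words=kept,
                observed={w: v.observed[w] for w in kept},
                expected={w: v.expected[w] for w in kept},
                deviation={w: v.deviation[w] for w in kept},
                undefined_words=tuple(w for w in v.undefined_words if w in set(kept)),
            )
        )
    return out
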