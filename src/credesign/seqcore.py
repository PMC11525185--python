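"""Sequence encodings, motif models and scoring primitives.

DNA sequences are represented as L x 4 one-hot matrices with column order
A, C, G, T.  Unknown bases (N) encode as all-zero rows, so every downstream
dot product treats them as contributing nothing.  Coordinates are 0-based,
half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_COMPLEMENT_ORDER = np.array([3, 2, 1, 0])  # A<->T, C<->G column swap

_ENCODING = {}
for _i, _b in enumerate(BASES):
    _row = np.zeros(4, dtype=np.float32)
    _row[_i] = 1.0
    _ENCODING[_b] = _row
    _ENCODING[_b.lower()] = _row
_ENCODING["N"] = np.zeros(4, dtype=np.float32)
_ENCODING["n"] = np.zeros(4, dtype=np.float32)

# Constant reporter-backbone flanks used to pad 200-nt inserts to the model
# input length.  These are a fixed, arbitrary-but-documented default; users
# with the true vector sequence can override them in the model config.
DEFAULT_FLANK_5 = (
    "TCGCGATTTCGACTACTGTTCAGCTTAGATTTCAGCCGGGGTAGGGCCCCAGAGATAAATACTTCGCGAT"
    "TGCCTCGTCGGGGTGAGACAGACTACGGGTCCCGCGAGGTCTCCACTATGTGTAATGAATCTTTCTTTTC"
    "GATCGCGCTCTTAGACATGTACATTTAGAGTATGCTGGCACAGACTGCGTGACCTTAATG"
)
DEFAULT_FLANK_3 = (
    "CGCCCACAGTACCTCTTATGGCGGCCCTCGTCCCTTCCCATCAAGGTAAGGGTGGAATGCCCAATGCACG"
    "ACTATGACACATTTAGCCCGATGGGCATTATGTGTACCTATTGCGGCAGGAAACGGACGGCGATGAAATC"
    "CATTCAGTCTCGTGTACTAGTTTTGCCGTTGGCTTCGCACATGGCCGCCCCGCCAAGTGT"
)


@dataclass
class OneHotSequence:
    """A DNA sequence as an L x 4 one-hot matrix (rows sum to 0 or 1)."""

    matrix: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError(f"one-hot matrix must be L x 4 with L >= 1, got {self.matrix.shape}")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.length

    def decode(self) -> str:
        return decode_onehot(self.matrix)


def encode_onehot(seq: str, name: str = "") -> OneHotSequence:
    """Encode a DNA string over {A,C,G,T,N} (case-insensitive) as one-hot.

    A -> [1,0,0,0], C -> [0,1,0,0], G -> [0,0,1,0], T -> [0,0,0,1],
    N -> [0,0,0,0].  Any other character is rejected with its position.
    """
    rows = np.empty((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq):
        try:
            rows[i] = _ENCODING[ch]
        except KeyError:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}") from None
    return OneHotSequence(rows, name=name)


def decode_onehot(matrix: np.ndarray) -> str:
    matrix = np.asarray(matrix)
    out = []
    for row in matrix:
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(BASES[int(np.argmax(row))])
    return "".join(out)


def reverse_complement(x: OneHotSequence | np.ndarray) -> OneHotSequence | np.ndarray:
    """Reverse the position axis and swap complementary base columns.

    All-zero (N) rows stay all-zero.  Accepts either an OneHotSequence or a
    bare (..., L, 4) array; returns the same type.
    """
    if isinstance(x, OneHotSequence):
        return OneHotSequence(reverse_complement(x.matrix), name=x.name)
    arr = np.asarray(x)
    return np.ascontiguousarray(arr[..., ::-1, :][..., _COMPLEMENT_ORDER])


def pad_with_flanks(
    x: OneHotSequence,
    flank5: OneHotSequence,
    flank3: OneHotSequence,
) -> OneHotSequence:
    """Concatenate flank5 || insert || flank3 (reporter-backbone padding)."""
    mat = np.concatenate([flank5.matrix, x.matrix, flank3.matrix], axis=0)
    return OneHotSequence(mat, name=x.name)


@dataclass
class MotifModel:
    """A motif as a PPM / PWM pair, optionally with a contribution-space CWM.

    The PWM is the log2-odds form against a uniform 0.25 background (a small
    pseudocount keeps scores finite).  ``consensus_score`` is the maximum
    attainable PWM match score, i.e. the per-position column maxima summed.
    """

    ppm: np.ndarray
    id: str = "motif"
    cwm: np.ndarray | None = None
    source: str = "supplied"
    pseudocount: float = 1e-3
    pwm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4:
            raise ValueError("ppm must be w x 4")
        w = self.ppm.shape[0]
        if not 1 <= w:
            raise ValueError("motif width must be >= 1")
        if np.any(self.ppm < 0):
            raise ValueError("ppm entries must be non-negative")
        rowsums = self.ppm.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            raise ValueError("ppm rows must sum to 1")
        p = (self.ppm + self.pseudocount) / (1 + 4 * self.pseudocount)
        self.pwm = np.log2(p / 0.25)
        if self.cwm is not None:
            self.cwm = np.asarray(self.cwm, dtype=np.float64)
            if self.cwm.shape != self.ppm.shape:
                raise ValueError("cwm shape must match ppm")

    @property
    def width(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus_score(self) -> float:
        return float(self.pwm.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    def reverse_complement(self) -> "MotifModel":
        rc_ppm = self.ppm[::-1, _COMPLEMENT_ORDER]
        rc_cwm = None if self.cwm is None else self.cwm[::-1, _COMPLEMENT_ORDER]
        return MotifModel(rc_ppm, id=self.id, cwm=rc_cwm, source=self.source,
                          pseudocount=self.pseudocount)

    def patser_threshold(self, precision: int = 10**4) -> float:
        """Patser-style score threshold (type-I/II error balance) under the
        uniform background, computed with Biopython's score distribution."""
        from Bio import motifs as bio_motifs

        counts = {b: (self.ppm[:, i] * 1000).tolist() for i, b in enumerate(BASES)}
        m = bio_motifs.Motif(counts=counts)
        m.pseudocounts = {b: 1000 * self.pseudocount for b in BASES}
        dist = m.pssm.distribution(background=m.background, precision=precision)
        return float(dist.threshold_patser())


@dataclass
class ScoredMatch:
    """A scored motif occurrence on a sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    motif_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _window_scores(pwm: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """PWM match score of every window of `matrix` (L-w+1 scores)."""
    w = pwm.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(matrix, w, axis=0)
    # windows: (L-w+1, 4, w); pwm: (w, 4)
    return np.einsum("nbw,wb->n", windows, pwm)


def pwm_scan(motif: MotifModel, x: OneHotSequence, threshold: float) -> list[ScoredMatch]:
    """All windows on both strands scoring >= threshold, sorted by
    (start, strand with '+' first, score)."""
    if motif.width > x.length:
        return []
    fwd = _window_scores(motif.pwm, x.matrix)
    rev = _window_scores(motif.reverse_complement().pwm, x.matrix)
    hits = []
    for start in range(len(fwd)):
        if fwd[start] >= threshold:
            hits.append(ScoredMatch(x.name, start, start + motif.width, "+",
                                    float(fwd[start]), motif.id))
        if rev[start] >= threshold:
            hits.append(ScoredMatch(x.name, start, start + motif.width, "-",
                                    float(rev[start]), motif.id))
    hits.sort(key=lambda h: (h.start, h.strand, h.score))
    return hits


def sample_onehot(ppm: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n one-hot arrays (n, w, 4) from per-position categoricals."""
    ppm = np.asarray(ppm, dtype=np.float64)
    if np.any(ppm < 0):
        raise ValueError("ppm entries must be non-negative")
    w = ppm.shape[0]
    cdf = np.cumsum(ppm / ppm.sum(axis=1, keepdims=True), axis=1)
    u = rng.random((n, w, 1))
    idx = (u > cdf[None]).sum(axis=2)
    out = np.zeros((n, w, 4), dtype=np.float32)
    np.put_along_axis(out, idx[:, :, None], 1.0, axis=2)
    return out


def sample_from_ppm(ppm: np.ndarray, n: int, seed: int | np.random.Generator) -> list[OneHotSequence]:
    """Sample n sequences i.i.d. per position from a PPM; seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = sample_onehot(ppm, n, rng)
    return [OneHotSequence(a, name=f"sample_{i}") for i, a in enumerate(arr)]


def random_sequences(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform-random one-hot sequences, shape (n, length, 4)."""
    return sample_onehot(np.full((length, 4), 0.25), n, rng)


def default_flanks(length: int = 200) -> tuple[OneHotSequence, OneHotSequence]:
    """The package's constant reporter-backbone flank pair, trimmed to
    ``length`` (5' flank keeps its 3' end, 3' flank its 5' end, so the
    sequence adjacent to the insert is stable as length varies)."""
    if not 1 <= length <= 200:
        raise ValueError("default flanks support lengths 1..200")
    return (
        encode_onehot(DEFAULT_FLANK_5[200 - length:], name="flank5"),
        encode_onehot(DEFAULT_FLANK_3[:length], name="flank3"),
    )
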