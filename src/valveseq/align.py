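"""Local alignment under the demultiplexer's scoring parameterization.

Reads are matched to designs with BLASTN-like scoring: match +2, mismatch -3,
and affine gaps where a gap of length k costs ``gap_open + k * gap_extend``
(defaults 5 and 2).  Ranking uses the raw local-alignment score: at a fixed
scoring scheme the bitscore is a fixed affine transform of the raw score
(bitscore = (lambda * S - ln K) / ln 2 with constants lambda and K), so
best-hit ranking and tie detection are identical and no Karlin-Altschul
parameter estimation is needed.

Two aligners are provided: :func:`local_align_dp`, the exact full dynamic
program (the oracle), and :func:`seeded_align`, which finds exact ``word_size``
seeds and extends them with a banded version of the same DP.  A seeded score
is always a valid alignment score and therefore never exceeds the oracle's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import gotoh_local, kmer_codes, seed_diagonals

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 base codes (A=0, C=1, G=2, T=3)."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring; defaults mirror the tuned demultiplexing parameters."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 4
    min_score: int = 30
    band_width: int = 16
    # reads are sense-strand RNA and dRNA-seq is strand-specific, so only the
    # forward strand is searched unless this is set
    search_reverse_strand: bool = False

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        if self.word_size < 1:
            raise ValueError("word size must be >= 1")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment: raw score plus half-open query/reference intervals."""

    score: int
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    design_id: str | None = None


class ReferenceIndex:
    """A reference sequence with a sorted exact-word index for seeding."""

    def __init__(self, sequence: str, word_size: int = 4, design_id: str | None = None):
        if not sequence:
            raise ValueError("empty reference sequence")
        self.design_id = design_id
        self.sequence = sequence
        self.codes = encode(sequence)
        self.word_size = word_size
        km = kmer_codes(self.codes, word_size)
        order = np.argsort(km, kind="stable")
        self.kmer_sorted = km[order]
        self.pos_sorted = order.astype(np.int64)


def local_align_dp(query: str, reference: str, scoring: ScoringScheme = DEFAULT_SCORING) -> AlignmentHit:
    """Optimal local affine-gap alignment (exact DP; the seeding oracle)."""
    if not query or not reference:
        raise ValueError("empty sequence")
    q = encode(query)
    r = encode(reference)
    score, qs, qe, rs, re = gotoh_local(
        q, r, scoring.match, scoring.mismatch,
        scoring.gap_open + scoring.gap_extend, scoring.gap_extend,
        -len(query), len(reference),
    )
    return AlignmentHit(int(score), int(qs), int(qe), int(rs), int(re))


def _diagonal_groups(diags: np.ndarray, counts: np.ndarray, band: int, prune: bool):
    """Cluster seed diagonals into extension bands.

    With ``prune``, single-hit diagonals are dropped whenever some diagonal
    carries >= 4 seed hits — noise suppression for pool-scale demultiplexing
    where spurious 4-mer matches scatter across the whole matrix.
    """
    if prune and counts.max() >= 4:
        keep = counts >= 2
        diags = diags[keep]
    groups = []
    start = 0
    for t in range(1, len(diags) + 1):
        if t == len(diags) or diags[t] - diags[t - 1] > band:
            groups.append((int(diags[start]) - band, int(diags[t - 1]) + band))
            start = t
    return groups


def seeded_align(
    query: str,
    reference,
    scoring: ScoringScheme = DEFAULT_SCORING,
    prune: bool = False,
) -> list[AlignmentHit]:
    """Seed-and-extend local alignment.

    Finds exact ``word_size`` matches, clusters their diagonals, and runs the
    banded affine DP over each cluster (band half-width ``band_width``).
    Overlapping hits are merged keeping the higher score; hits below
    ``min_score`` are not reported.  Hits are sorted by descending score, then
    lowest reference start, then lowest query start.
    """
    if not query:
        raise ValueError("empty sequence")
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(
        reference, scoring.word_size
    )
    q = encode(query)
    if len(query) < scoring.word_size:
        return []
    qk = kmer_codes(q, scoring.word_size)
    raw = seed_diagonals(qk, index.kmer_sorted, index.pos_sorted)
    if raw.size == 0:
        return []
    diags, counts = np.unique(raw, return_counts=True)
    gap_oe = scoring.gap_open + scoring.gap_extend
    hits = []
    for dlo, dhi in _diagonal_groups(diags, counts, scoring.band_width, prune):
        score, qs, qe, rs, re = gotoh_local(
            q, index.codes, scoring.match, scoring.mismatch, gap_oe, scoring.gap_extend,
            dlo, dhi,
        )
        if score >= scoring.min_score:
            hits.append(AlignmentHit(int(score), int(qs), int(qe), int(rs), int(re),
                                     design_id=index.design_id))
    hits.sort(key=lambda h: (-h.score, h.ref_start, h.query_start))
    merged: list[AlignmentHit] = []
    for h in hits:
        if all(h.ref_end <= k.ref_start or h.ref_start >= k.ref_end for k in merged):
            merged.append(h)
    return merged


def best_hit(query: str, reference, scoring: ScoringScheme = DEFAULT_SCORING,
             prune: bool = False) -> AlignmentHit | None:
    hits = seeded_align(query, reference, scoring, prune=prune)
    return hits[0] if hits else None
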