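"""Assign reads to designs by best local alignment over the design library.

Each read is aligned against every design's cassette reference (never the
plasmid backbone); the design with the highest raw alignment score wins.
Reads with no alignment reaching ``min_score`` are reported as
``unassigned_no_hit``; reads whose maximum score is shared by two or more
designs are ``unassigned_tie`` and excluded, which makes the assignment fully
invariant to the order designs are supplied in.

At pool scale a BLAST-like screening heuristic keeps this tractable: for each
read the designs are ranked by their densest seed-diagonal window and only
the strongest candidates (ties included, so duplicated designs are never
separated) are extended with the banded affine DP.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import assign_scores, kmer_codes
from .align import DEFAULT_SCORING, ReferenceIndex, ScoringScheme, encode
from .parts import Design


class AssignmentStatus(str, enum.Enum):
    ASSIGNED = "assigned"
    NO_HIT = "unassigned_no_hit"
    TIE = "unassigned_tie"


@dataclass(frozen=True)
class Assignment:
    read_id: str
    status: AssignmentStatus
    design_id: str | None = None
    score: int = 0

    def __post_init__(self):
        if (self.design_id is not None) != (self.status is AssignmentStatus.ASSIGNED):
            raise ValueError("design_id must be present iff status is assigned")


class DesignLibrary:
    """Seed indexes over a set of design references, built once per pool."""

    def __init__(self, designs, scoring: ScoringScheme = DEFAULT_SCORING, top_k: int = 8):
        self.scoring = scoring
        self.top_k = top_k
        self.design_ids: list[str] = []
        self.indexes: list[ReferenceIndex] = []
        seen = set()
        for d in designs:
            did, seq = (d.id, d.reference_sequence) if isinstance(d, Design) else d
            if did in seen:
                raise ValueError(f"duplicate design id {did}")
            seen.add(did)
            self.design_ids.append(did)
            self.indexes.append(ReferenceIndex(seq, scoring.word_size, design_id=did))
        if not self.indexes:
            raise ValueError("design library is empty")
        # CSR layout over all designs for the screening kernel
        self.csr_codes = np.concatenate([ix.kmer_sorted for ix in self.indexes])
        self.csr_pos = np.concatenate([ix.pos_sorted for ix in self.indexes])
        self.csr_offsets = np.zeros(len(self.indexes) + 1, np.int64)
        self.ref_offsets = np.zeros(len(self.indexes) + 1, np.int64)
        for t, ix in enumerate(self.indexes):
            self.csr_offsets[t + 1] = self.csr_offsets[t] + ix.kmer_sorted.size
            self.ref_offsets[t + 1] = self.ref_offsets[t] + ix.codes.size
        self.ref_codes = np.concatenate([ix.codes for ix in self.indexes])

    def __len__(self):
        return len(self.indexes)


def _pool_scores(sequence: str, library: DesignLibrary) -> np.ndarray | None:
    sc = library.scoring
    q = encode(sequence)
    qk = kmer_codes(q, sc.word_size)
    if qk.size == 0:
        return None
    return assign_scores(
        q, qk,
        library.csr_codes, library.csr_pos, library.csr_offsets,
        library.ref_codes, library.ref_offsets,
        sc.match, sc.mismatch, sc.gap_open + sc.gap_extend, sc.gap_extend,
        sc.band_width, library.top_k,
    )


def assign_read(read_id: str, sequence: str, library: DesignLibrary) -> Assignment:
    """Best-score assignment with tie exclusion."""
    from .parts import reverse_complement

    scores = _pool_scores(sequence, library)
    if scores is None:
        return Assignment(read_id, AssignmentStatus.NO_HIT)
    if library.scoring.search_reverse_strand:
        rc = _pool_scores(reverse_complement(sequence), library)
        if rc is not None:
            scores = np.maximum(scores, rc)
    best = int(scores.max())
    if best < library.scoring.min_score:
        return Assignment(read_id, AssignmentStatus.NO_HIT)
    winners = np.flatnonzero(scores == best)
    if winners.size > 1:
        return Assignment(read_id, AssignmentStatus.TIE, score=best)
    return Assignment(read_id, AssignmentStatus.ASSIGNED,
                      library.design_ids[int(winners[0])], best)


def demultiplex_pool(reads, designs, scoring: ScoringScheme = DEFAULT_SCORING):
    """Demultiplex a pool of reads against a design library.

    Parameters
    ----------
    reads : iterable of (read_id, sequence)
        E.g. ``valveseq.io.read_fastq(path)`` or simulated reads via
        ``[(r.id, r.sequence) for r in pool]``.
    designs : list of Design or (id, sequence), or a prebuilt DesignLibrary.

    Returns
    -------
    (table, per_design, summary)
        ``table`` is a DataFrame (read_id, status, design_id, score);
        ``per_design`` maps design id -> list of assigned read ids; ``summary``
        counts reads per status and, for assigned reads, per design, with
        design frequencies relative to the total number of assigned reads.
    """
    library = designs if isinstance(designs, DesignLibrary) else DesignLibrary(designs, scoring)
    rows = []
    per_design: dict[str, list[str]] = {did: [] for did in library.design_ids}
    status_counts = {s.value: 0 for s in AssignmentStatus}
    for read_id, seq in reads:
        a = assign_read(read_id, seq, library)
        rows.append((a.read_id, a.status.value, a.design_id, a.score))
        status_counts[a.status.value] += 1
        if a.status is AssignmentStatus.ASSIGNED:
            per_design[a.design_id].append(a.read_id)
    table = pd.DataFrame(rows, columns=["read_id", "status", "design_id", "score"])
    n_assigned = status_counts[AssignmentStatus.ASSIGNED.value]
    summary = {
        "n_reads": len(rows),
        "status_counts": status_counts,
        "design_counts": {d: len(v) for d, v in per_design.items()},
        "design_frequencies": {
            d: (len(v) / n_assigned if n_assigned else 0.0) for d, v in per_design.items()
        },
    }
    return table, per_design, summary
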