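"""Read depth profiles: mapping, read filtering, normalization and Δ-profiles.

Demultiplexed reads are mapped back onto their design's reference by local
alignment; the alignment span contributes pileup-style coverage.  Reads that
do not contain the full design cassette AND end between the start of the
spacer and a small margin into the core terminator are removed — such reads
are indistinguishable from 5' truncation artifacts, whereas genuinely
terminated reads end deep inside the terminator's U-tract and read-through
reads span the whole design.

The normalized profile is N(x) = depth(x) / depth(x_s) and the Δ (drop)
profile is D(x) = N(x-1) - N(x), positive where coverage falls; the summed
drop across the valve telescopes exactly to the termination efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, ReferenceIndex, ScoringScheme, seeded_align
from .parts import Design, Role


@dataclass
class MappedRead:
    read_id: str
    design_id: str
    ref_start: int
    ref_end: int
    contains_full_design: bool
    score: int = 0

    @property
    def end_position(self) -> int:
        """3'-most covered reference position + 1 (half-open span end)."""
        return self.ref_end


@dataclass
class DepthProfile:
    design_id: str
    depth: np.ndarray
    n_reads: int
    normalized: np.ndarray | None = None


def map_read(read_id: str, sequence: str, design: Design | ReferenceIndex,
             scoring: ScoringScheme = DEFAULT_SCORING, end_slack: int = 5,
             cassette: tuple[int, int] | None = None,
             prune: bool = True) -> MappedRead | None:
    """Map one read onto its assigned design; ``None`` if unmappable.

    ``contains_full_design`` is true iff the alignment span covers the whole
    design cassette interval within ``end_slack`` nt at each end.
    """
    if isinstance(design, Design):
        index = ReferenceIndex(design.reference_sequence, scoring.word_size, design_id=design.id)
        cassette = design.cassette
    else:
        index = design
        if cassette is None:
            raise ValueError("cassette interval required when mapping to a raw index")
    hits = seeded_align(sequence, index, scoring, prune=prune)
    if not hits:
        return None
    h = hits[0]
    cs, ce = cassette
    full = h.ref_start <= cs + end_slack and h.ref_end >= ce - end_slack
    return MappedRead(read_id, index.design_id or "", h.ref_start, h.ref_end, full, h.score)


def map_pool(assignments: pd.DataFrame, reads_by_id: dict[str, str], designs,
             scoring: ScoringScheme = DEFAULT_SCORING, end_slack: int = 5):
    """Map every assigned read to its design; returns mapped reads per design
    plus a count of unmappable reads."""
    by_id = {d.id: d for d in designs}
    index_cache: dict[str, ReferenceIndex] = {}
    cassette_cache: dict[str, tuple[int, int]] = {}
    mapped: dict[str, list[MappedRead]] = {d.id: [] for d in designs}
    unmappable = 0
    assigned = assignments[assignments["status"] == "assigned"]
    for read_id, design_id in zip(assigned["read_id"], assigned["design_id"]):
        d = by_id[design_id]
        if design_id not in index_cache:
            index_cache[design_id] = ReferenceIndex(d.reference_sequence, scoring.word_size,
                                                    design_id=design_id)
            cassette_cache[design_id] = d.cassette
        mr = map_read(read_id, reads_by_id[read_id], index_cache[design_id], scoring,
                      end_slack, cassette=cassette_cache[design_id])
        if mr is None:
            unmappable += 1
        else:
            mapped[design_id].append(mr)
    return mapped, unmappable


def filter_reads(mapped_reads: list[MappedRead], design: Design,
                 terminator_margin: int = 20,
                 window: tuple[int, int] | None = None):
    """Apply the truncation-artifact filter.

    A read is removed iff it does NOT contain the full design sequence and its
    end position falls in ``[spacer start, terminator start + margin)``.  All
    other reads (full-design spans, genuine terminations deeper in the
    terminator, read-throughs) are kept.  Returns ``(kept, removal_log)``
    where the log is a DataFrame (read_id, reason).
    """
    if window is None:
        if Role.SPACER not in design.intervals or Role.TERMINATOR not in design.intervals:
            raise ValueError(f"design {design.id} lacks spacer/terminator annotation; "
                             "pass an explicit window")
        lo = design.intervals[Role.SPACER][0]
        hi = design.intervals[Role.TERMINATOR][0] + terminator_margin
    else:
        lo, hi = window
    kept, removed = [], []
    for mr in mapped_reads:
        if not mr.contains_full_design and lo <= mr.end_position < hi:
            removed.append((mr.read_id, "partial design ending in truncation window"))
        else:
            kept.append(mr)
    return kept, pd.DataFrame(removed, columns=["read_id", "reason"])


def build_depth_profile(mapped_reads: list[MappedRead], reference_length: int,
                        design_id: str = "") -> DepthProfile:
    """Pileup depth: depth[x] = number of spans containing position x."""
    diff = np.zeros(reference_length + 1, dtype=np.int64)
    for mr in mapped_reads:
        if not (0 <= mr.ref_start < mr.ref_end <= reference_length):
            raise ValueError(f"span [{mr.ref_start}, {mr.ref_end}) outside reference")
        diff[mr.ref_start] += 1
        diff[mr.ref_end] -= 1
    depth = np.cumsum(diff[:-1])
    return DepthProfile(design_id or (mapped_reads[0].design_id if mapped_reads else ""),
                        depth, len(mapped_reads))


def normalize_and_delta(profile: DepthProfile, x_s: int):
    """Normalized profile N(x) = depth(x)/depth(x_s) and drops D(x) = N(x-1) - N(x).

    D(0) is defined as 0.  Raises if there is no coverage at the valve start.
    """
    depth = profile.depth
    if depth[x_s] <= 0:
        raise ValueError("no coverage at valve start")
    normalized = depth / float(depth[x_s])
    drop = np.zeros_like(normalized)
    drop[1:] = normalized[:-1] - normalized[1:]
    profile.normalized = normalized
    return normalized, drop


def profile_table(profile: DepthProfile, x_s: int) -> pd.DataFrame:
    normalized, drop = normalize_and_delta(profile, x_s)
    return pd.DataFrame(
        {
            "position": np.arange(len(profile.depth)),
            "depth": profile.depth,
            "normalized": normalized,
            "drop": drop,
        }
    )
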