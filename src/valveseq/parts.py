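"""Combinatorial transcriptional-valve libraries: parts, designs and sequence generators.

A transcriptional valve is a ``modifier + core terminator`` cassette placed
downstream of an upstream "spacer" element that stands in for variable genetic
context.  Spacer, modifier and terminator parts are combinatorially assembled
into designs; each design's reference sequence is the exact concatenation

    5' flank + spacer + modifier + terminator + 3' flank

and the valve interval ``[x_s, x_e)`` runs from the start of the modifier (or
the terminator, if no modifier is present) to the end of the terminator.  All
coordinates are 0-based half-open; GFF3 output converts to 1-based inclusive.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np

DNA_ALPHABET = "ACGT"
_DNA_SET = frozenset(DNA_ALPHABET)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Recognition sites scanned by the padding-sequence filter.  The insert
#: cloning strategy is directional, so only the given strand is scanned by
#: default; set ``both_strands=True`` to also scan the reverse complement.
RESTRICTION_SITES = {
    "EcoRI": "GAATTC",
    "SpeI": "ACTAGT",
    "AatII": "GACGTC",
}

#: Base-composition presets for the spacer generator.  ``uniform`` is the
#: default; ``ecoli_coding`` approximates the average base composition of
#: E. coli coding regions (slightly GC-rich on the sense strand).
COMPOSITION_PRESETS = {
    "uniform": {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
    "ecoli_coding": {"A": 0.24, "C": 0.26, "G": 0.29, "T": 0.21},
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_empty: bool = False) -> str:
    if not allow_empty and not seq:
        raise ValueError("sequence is empty")
    bad = set(seq) - _DNA_SET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


class Role(str, enum.Enum):
    SPACER = "spacer"
    MODIFIER = "modifier"
    TERMINATOR = "terminator"


#: Assembly order of roles along a design, 5' to 3'.
ROLE_ORDER = (Role.SPACER, Role.MODIFIER, Role.TERMINATOR)


@dataclass(frozen=True)
class Part:
    """One spacer / modifier / core-terminator DNA part."""

    id: str
    role: Role
    sequence: str
    description: str = ""

    def __post_init__(self):
        validate_dna(self.sequence)
        object.__setattr__(self, "role", Role(self.role))


class PartSet:
    """Parts grouped by role, with unique ids."""

    def __init__(self, parts):
        self.by_role: dict[Role, list[Part]] = {r: [] for r in ROLE_ORDER}
        seen: set[str] = set()
        for p in parts:
            if p.id in seen:
                raise ValueError(f"duplicate part id: {p.id}")
            seen.add(p.id)
            self.by_role[p.role].append(p)
        self._index = {p.id: p for role in ROLE_ORDER for p in self.by_role[role]}

    def __len__(self):
        return len(self._index)

    def __getitem__(self, part_id: str) -> Part:
        return self._index[part_id]

    def counts(self) -> dict[Role, int]:
        return {r: len(v) for r, v in self.by_role.items()}

    @property
    def parts(self):
        return list(self._index.values())


@dataclass
class Design:
    """An assembled construct: ordered part intervals on a reference sequence.

    ``intervals`` maps a role to its 0-based half-open span on the reference.
    ``x_s``/``x_e`` bound the transcriptional valve; ``cassette`` spans all
    variable parts (the "design sequence" used by the full-design filter).
    """

    id: str
    part_ids: dict[Role, str]
    reference_sequence: str
    intervals: dict[Role, tuple[int, int]]
    x_s: int
    x_e: int

    def __post_init__(self):
        validate_dna(self.reference_sequence)
        if not (0 <= self.x_s < self.x_e <= len(self.reference_sequence)):
            raise ValueError(f"invalid valve bounds [{self.x_s}, {self.x_e})")
        last = 0
        for role in ROLE_ORDER:
            if role not in self.intervals:
                continue
            s, e = self.intervals[role]
            if not (last <= s < e <= len(self.reference_sequence)):
                raise ValueError(f"interval for {role.value} out of order or range")
            last = e

    @property
    def cassette(self) -> tuple[int, int]:
        starts = [s for s, _ in self.intervals.values()]
        ends = [e for _, e in self.intervals.values()]
        return min(starts), max(ends)

    def part_sequence(self, role: Role) -> str:
        s, e = self.intervals[role]
        return self.reference_sequence[s:e]


def enumerate_designs(parts: PartSet, fixed_flanks: tuple[str, str] = ("", "")) -> list[Design]:
    """Enumerate the full Cartesian product spacer x modifier x terminator.

    Roles with zero parts are skipped (not multiplied by zero).  Design ids
    are the underscore-joined constituent part ids, missing roles omitted.

    Raises
    ------
    ValueError
        If the part set contains no terminators ("no terminators").
    """
    flank5, flank3 = fixed_flanks
    validate_dna(flank5, allow_empty=True)
    validate_dna(flank3, allow_empty=True)
    if not parts.by_role[Role.TERMINATOR]:
        raise ValueError("no terminators")
    pools = [parts.by_role[r] or [None] for r in ROLE_ORDER]
    designs = []
    for combo in itertools.product(*pools):
        chosen = [(role, p) for role, p in zip(ROLE_ORDER, combo) if p is not None]
        design_id = "_".join(p.id for _, p in chosen)
        seq_parts = [flank5]
        intervals: dict[Role, tuple[int, int]] = {}
        pos = len(flank5)
        for role, p in chosen:
            intervals[role] = (pos, pos + len(p.sequence))
            seq_parts.append(p.sequence)
            pos += len(p.sequence)
        seq_parts.append(flank3)
        if Role.MODIFIER in intervals:
            x_s = intervals[Role.MODIFIER][0]
        else:
            x_s = intervals[Role.TERMINATOR][0]
        x_e = intervals[Role.TERMINATOR][1]
        designs.append(
            Design(
                id=design_id,
                part_ids={role: p.id for role, p in chosen},
                reference_sequence="".join(seq_parts),
                intervals=intervals,
                x_s=x_s,
                x_e=x_e,
            )
        )
    return designs


def generate_spacer(length: int = 33, seed: int = 0, composition=None, part_id=None) -> Part:
    """Draw a random spacer whose final three bases are forced to ``TAA``.

    ``composition`` is a base->frequency map or the name of a preset in
    :data:`COMPOSITION_PRESETS`; the default is uniform.
    """
    if length < 3:
        raise ValueError("spacer length must be >= 3 (must fit the TAA stop codon)")
    comp = _resolve_composition(composition)
    rng = np.random.default_rng(seed)
    probs = [comp[b] for b in DNA_ALPHABET]
    body = "".join(rng.choice(list(DNA_ALPHABET), size=length - 3, p=probs))
    seq = body + "TAA"
    return Part(id=part_id or f"S_{seed}", role=Role.SPACER, sequence=seq)


def _resolve_composition(composition):
    if composition is None:
        composition = "uniform"
    if isinstance(composition, str):
        composition = COMPOSITION_PRESETS[composition]
    total = sum(composition.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"base composition sums to {total}, expected 1")
    return composition


def _has_homopolymer(seq: str, min_run: int = 4) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= min_run:
            return True
    return min_run <= 1 and len(seq) >= 1


def _has_hairpin(seq: str, stem: int = 4, min_loop: int = 3) -> bool:
    """Minimal-hairpin surrogate for a folding test.

    True iff the sequence contains two disjoint reverse-complementary segments
    of length >= ``stem`` separated by at least ``min_loop`` nt.
    """
    n = len(seq)
    for i in range(n - stem + 1):
        probe = reverse_complement(seq[i : i + stem])
        j = seq.find(probe, i + stem + min_loop)
        if j != -1:
            return True
    return False


def passes_padding_filters(
    seq: str,
    *,
    max_homopolymer: int = 3,
    stem: int = 4,
    min_loop: int = 3,
    both_strands: bool = False,
) -> tuple[bool, list[str]]:
    """Check a candidate padding sequence against the design filters.

    A sequence passes iff it has (a) no homopolymer run of length
    ``max_homopolymer + 1`` or more, (b) no EcoRI/SpeI/AatII recognition site,
    and (c) no minimal hairpin (two disjoint reverse-complementary segments of
    length >= ``stem`` separated by >= ``min_loop`` nt), a self-contained
    surrogate for "predicted structure-free".

    Returns ``(ok, reasons)`` where ``reasons`` lists every failed filter.
    """
    validate_dna(seq)
    reasons = []
    if _has_homopolymer(seq, max_homopolymer + 1):
        reasons.append("homopolymer")
    targets = [seq]
    if both_strands:
        targets.append(reverse_complement(seq))
    for name, site in RESTRICTION_SITES.items():
        if any(site in t for t in targets):
            reasons.append("restriction site")
            break
    if _has_hairpin(seq, stem=stem, min_loop=min_loop):
        reasons.append("structure")
    return (not reasons, reasons)


def generate_padding(length: int, seed: int = 0, max_attempts: int = 10_000, **filter_kwargs) -> str:
    """Rejection-sample a random DNA sequence passing the padding filters."""
    if length < 1:
        raise ValueError("padding length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = list(DNA_ALPHABET)
    for _ in range(max_attempts):
        seq = "".join(rng.choice(bases, size=length))
        ok, _reasons = passes_padding_filters(seq, **filter_kwargs)
        if ok:
            return seq
    raise RuntimeError(f"no passing sequence of length {length} after {max_attempts} attempts")


def predict_design_frequencies(part_freqs: dict, designs: list[Design]) -> dict[str, float]:
    """Predict design frequencies as the product of constituent part frequencies.

    ``part_freqs`` maps role -> (part id -> frequency); each role present must
    sum to 1 (within 1e-9).  Over a full product library the output sums to 1.
    """
    norm = {Role(r): dict(v) for r, v in part_freqs.items()}
    for role, freqs in norm.items():
        if any(f < 0 for f in freqs.values()):
            raise ValueError(f"negative frequency in role {role.value}")
        total = sum(freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"frequencies for role {role.value} sum to {total}, expected 1")
    out = {}
    for d in designs:
        f = 1.0
        for role, pid in d.part_ids.items():
            if role not in norm or pid not in norm[role]:
                raise ValueError(f"part {pid!r} (role {role.value}) missing from part_freqs")
            f *= norm[role][pid]
        out[d.id] = f
    return out


# ---------------------------------------------------------------------------
# gRNA arrays: several transcription units separated by valves
# ---------------------------------------------------------------------------


@dataclass
class GuideArray:
    """A gRNA array: ordered guide units separated by transcriptional valves.

    ``units`` and ``valves`` are 0-based half-open intervals on the reference;
    unit i's relative abundance is the product of read-through fractions of
    the valves upstream of it.
    """

    id: str
    reference_sequence: str
    units: list[tuple[int, int]]
    valves: list[tuple[int, int]]

    def __post_init__(self):
        validate_dna(self.reference_sequence)
        if len(self.valves) != len(self.units) - 1:
            raise ValueError("an array of k units needs k-1 valves")


def build_guide_array(array_id: str, guides: list[str], valves: list[Design | str],
                      flanks: tuple[str, str] = ("", "")) -> GuideArray:
    """Assemble guide and valve sequences into a :class:`GuideArray`.

    ``valves`` entries may be :class:`Design` objects (their cassette sequence
    is used and valve bounds are taken from ``x_s``/``x_e``) or raw sequences
    (the whole insert is the valve).
    """
    if len(valves) != len(guides) - 1:
        raise ValueError("an array of k guides needs k-1 valves")
    flank5, flank3 = flanks
    seq = [flank5]
    pos = len(flank5)
    units, valve_spans = [], []
    for i, g in enumerate(guides):
        validate_dna(g)
        units.append((pos, pos + len(g)))
        seq.append(g)
        pos += len(g)
        if i < len(valves):
            v = valves[i]
            if isinstance(v, Design):
                cs, ce = v.cassette
                insert = v.reference_sequence[cs:ce]
                valve_spans.append((pos + (v.x_s - cs), pos + (v.x_e - cs)))
            else:
                insert = validate_dna(v)
                valve_spans.append((pos, pos + len(insert)))
            seq.append(insert)
            pos += len(insert)
    seq.append(flank3)
    return GuideArray(array_id, "".join(seq), units, valve_spans)
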