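"""Synthetic direct-RNA-seq reads with ground truth.

Each design's pool is a mixture of two transcript isoforms: with probability
``true_te`` a polymerase terminates at a position drawn from the design's
termination-position distribution (the read is the reference prefix ending
there), otherwise it reads through to the 3' end of the reference.  A poly(A)
tail is appended (the library-prep polyadenylation step), random nucleotide
substitutions are applied at a configurable per-base rate (default 0.15,
matching the error level the pipeline was tuned against), and reads can
optionally lose a random 5' prefix to emulate truncation artifacts introduced
during library preparation.

Reads are emitted in the DNA alphabet, as basecallers emit them.  Every
design draws from its own RNG substream derived from ``(seed, design id)``,
so adding or reordering designs does not perturb the reads of others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .parts import Design, GuideArray, Role

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _stable_hash(text: str) -> int:
    """Order-independent 62-bit integer from a string (stable across runs)."""
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big") >> 2


def design_rng(seed: int, design_id: str) -> np.random.Generator:
    """Per-design RNG substream keyed on ``(seed, design id)``."""
    return np.random.default_rng([seed, _stable_hash(design_id)])


@dataclass
class TruthModel:
    """Ground-truth termination behavior for one design."""

    design_id: str
    true_te: float
    termination_weights: dict[int, float]
    polyA_length: int = 30

    def __post_init__(self):
        if not 0.0 <= self.true_te <= 1.0:
            raise ValueError("true_te must lie in [0, 1]")
        if self.polyA_length < 0:
            raise ValueError("polyA_length must be >= 0")
        total = sum(self.termination_weights.values())
        if self.termination_weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"termination weights sum to {total}, expected 1")


def default_truth_model(design: Design, true_te: float, polyA_length: int = 30) -> TruthModel:
    """Single termination position at the middle of the terminator's 3' half.

    A terminated read's ``termination_position`` p is an exclusive end: the
    final transcribed nucleotide is position p - 1 of the reference.
    """
    ts, te_ = design.intervals[Role.TERMINATOR]
    pos = ts + (3 * (te_ - ts)) // 4
    return TruthModel(design.id, true_te, {pos: 1.0}, polyA_length)


@dataclass
class SimulatedRead:
    id: str
    sequence: str
    design_id: str
    is_terminated: bool
    termination_position: int | None = None
    truncation_position: int | None = None


@dataclass
class SimulationConfig:
    substitution_rate: float = 0.15
    truncation_prob: float = 0.0
    indel_rate: float = 0.0  # optional extension; the base error model is substitution-only
    reads_per_design: int | dict = 100
    seed: int = 0
    min_keep: int = 50
    design_frequency_mode: str = "uniform"
    part_freqs: dict | None = None
    total_reads: int | None = None

    def __post_init__(self):
        for name in ("substitution_rate", "truncation_prob", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.design_frequency_mode not in ("uniform", "from_part_freqs"):
            raise ValueError(f"unknown design_frequency_mode {self.design_frequency_mode!r}")


def _validate_model(design: Design, model: TruthModel) -> None:
    ts, _ = design.intervals[Role.TERMINATOR]
    for pos in model.termination_weights:
        if not ts < pos <= design.x_e:
            raise ValueError(
                f"termination position {pos} outside terminator ({ts}, {design.x_e}] "
                f"for design {design.id}"
            )


def simulate_transcript(design: Design, model: TruthModel, rng: np.random.Generator) -> SimulatedRead:
    """One error-free read: terminated prefix or full-length read-through."""
    _validate_model(design, model)
    ref = design.reference_sequence
    tail = "A" * model.polyA_length
    if model.termination_weights and rng.random() < model.true_te:
        positions = sorted(model.termination_weights)
        weights = np.array([model.termination_weights[p] for p in positions])
        p = int(positions[rng.choice(len(positions), p=weights / weights.sum())])
        return SimulatedRead("", ref[:p] + tail, design.id, True, termination_position=p)
    return SimulatedRead("", ref + tail, design.id, False)


def apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``.

    A substituted base becomes one of the three other bases, uniformly; the
    length is preserved (the error model is substitution-only).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = np.searchsorted(_BASES, arr)
    hit = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, size=arr.size)
    codes[hit] = (codes[hit] + shift[hit]) % 4
    return _BASES[codes].tobytes().decode("ascii")


def apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Optional indel extension: per base, delete or insert with equal odds.

    Each position is hit with probability ``rate``; a hit is a deletion of
    that base or an insertion of a random base before it (50/50).  Off by
    default — the core error model is substitution-only — but useful for
    stress-testing the aligner's gap handling.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0 or not seq:
        return seq
    out = []
    for ch in seq:
        if rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append("ACGT"[rng.integers(4)])  # insertion
        out.append(ch)
    return "".join(out)


def apply_truncation(read: SimulatedRead, prob: float, rng: np.random.Generator,
                     min_keep: int = 50) -> SimulatedRead:
    """With probability ``prob``, drop a random-length 5' prefix.

    The cut length is uniform on ``[1, len(read) - min_keep]``; if that range
    is empty the read is returned unchanged.  The 3' end is never altered.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must lie in [0, 1]")
    hi = len(read.sequence) - min_keep
    if prob == 0.0 or hi < 1 or rng.random() >= prob:
        return read
    cut = int(rng.integers(1, hi + 1))
    return replace(read, sequence=read.sequence[cut:], truncation_position=cut)


def _read_counts(designs: list[Design], config: SimulationConfig) -> dict[str, int]:
    if config.design_frequency_mode == "from_part_freqs":
        from .parts import predict_design_frequencies

        if config.part_freqs is None or config.total_reads is None:
            raise ValueError("from_part_freqs mode needs part_freqs and total_reads")
        freqs = predict_design_frequencies(config.part_freqs, designs)
        ids = sorted(freqs)
        rng = np.random.default_rng([config.seed, _stable_hash("design_counts")])
        p = np.array([freqs[i] for i in ids])
        counts = rng.multinomial(config.total_reads, p / p.sum())
        return dict(zip(ids, (int(c) for c in counts)))
    if isinstance(config.reads_per_design, dict):
        return {d.id: int(config.reads_per_design[d.id]) for d in designs}
    return {d.id: int(config.reads_per_design) for d in designs}


def simulate_pool(
    designs: list[Design],
    models: dict[str, TruthModel],
    config: SimulationConfig,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate a pooled sequencing run; returns reads and the truth table.

    Reads are interleaved across designs (round-robin) as in a pooled run.
    The truth table has one row per read: read_id, design_id, is_terminated,
    termination_position, truncation_position.
    """
    for d in designs:
        if d.id not in models:
            raise ValueError(f"no truth model for design {d.id}")
    counts = _read_counts(designs, config)
    per_design: dict[str, list[SimulatedRead]] = {}
    for d in designs:
        rng = design_rng(config.seed, d.id)
        model = models[d.id]
        reads = []
        for k in range(counts[d.id]):
            read = simulate_transcript(d, model, rng)
            read.id = f"{d.id}|r{k}"
            read = apply_truncation(read, config.truncation_prob, rng, config.min_keep)
            read.sequence = apply_substitutions(read.sequence, config.substitution_rate, rng)
            if config.indel_rate > 0:
                read.sequence = apply_indels(read.sequence, config.indel_rate, rng)
            reads.append(read)
        per_design[d.id] = reads
    pool: list[SimulatedRead] = []
    queues = [per_design[d.id] for d in designs]
    depth = max((len(q) for q in queues), default=0)
    for k in range(depth):
        for q in queues:
            if k < len(q):
                pool.append(q[k])
    return pool, truth_table(pool)


def truth_table(reads: list[SimulatedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.id for r in reads],
            "design_id": [r.design_id for r in reads],
            "is_terminated": [r.is_terminated for r in reads],
            "termination_position": [r.termination_position for r in reads],
            "truncation_position": [r.truncation_position for r in reads],
        }
    )


# ---------------------------------------------------------------------------
# gRNA arrays: sequential valves along one transcript
# ---------------------------------------------------------------------------


@dataclass
class ArrayTruthModel:
    """Per-valve termination behavior for a guide array."""

    array_id: str
    valve_te: list[float]
    valve_weights: list[dict[int, float]]
    polyA_length: int = 30


def default_array_truth_model(array: GuideArray, valve_te: list[float],
                              polyA_length: int = 30) -> ArrayTruthModel:
    if len(valve_te) != len(array.valves):
        raise ValueError("one true_te per valve required")
    weights = []
    for (vs, ve) in array.valves:
        weights.append({vs + (3 * (ve - vs)) // 4: 1.0})
    return ArrayTruthModel(array.id, list(valve_te), weights, polyA_length)


def simulate_array_pool(
    array: GuideArray,
    model: ArrayTruthModel,
    n_reads: int,
    config: SimulationConfig,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate reads from a guide array: valves are passed 5' to 3'.

    At each valve the polymerase terminates with that valve's probability;
    otherwise it continues, so the expected abundance of unit i is the product
    of upstream read-through fractions.  The truth table's
    ``termination_position`` names the terminating valve's drawn position (or
    none for full-length reads).
    """
    rng = design_rng(config.seed, array.id)
    ref = array.reference_sequence
    tail = "A" * model.polyA_length
    reads = []
    for k in range(n_reads):
        end = None
        for te, weights in zip(model.valve_te, model.valve_weights):
            if rng.random() < te:
                positions = sorted(weights)
                w = np.array([weights[p] for p in positions])
                end = int(positions[rng.choice(len(positions), p=w / w.sum())])
                break
        if end is None:
            read = SimulatedRead(f"{array.id}|r{k}", ref + tail, array.id, False)
        else:
            read = SimulatedRead(f"{array.id}|r{k}", ref[:end] + tail, array.id, True,
                                 termination_position=end)
        read = apply_truncation(read, config.truncation_prob, rng, config.min_keep)
        read.sequence = apply_substitutions(read.sequence, config.substitution_rate, rng)
        reads.append(read)
    return reads, truth_table(reads)


# ---------------------------------------------------------------------------
# Synthetic part libraries (study-scale fixtures built at run time)
# ---------------------------------------------------------------------------


def synthetic_terminator(part_id: str, seed: int, stem: int = 8, loop: int = 4,
                         u_tract: int = 8, pad5: int = 8, pad3: int = 12):
    """A synthetic intrinsic terminator: hairpin then U-tract.

    Layout: 5' pad, ``stem`` nt, ``loop`` nt, reverse-complement stem, a run
    of ``u_tract`` T's (the U-tract on the DNA sense strand), 3' pad.  The
    default 48-nt part places the default termination position (middle of the
    3' half) exactly at the end of the U-tract.
    """
    from .parts import Part, reverse_complement

    rng = np.random.default_rng([seed, _stable_hash(part_id)])
    bases = list("ACGT")

    def draw(n):
        return "".join(rng.choice(bases, size=n))

    stem_seq = draw(stem)
    seq = draw(pad5) + stem_seq + draw(loop) + reverse_complement(stem_seq) + "T" * u_tract + draw(pad3)
    return Part(id=part_id, role=Role.TERMINATOR, sequence=seq)


def synthetic_part_set(n_spacers: int, n_modifiers: int, n_terminators: int, seed: int = 0,
                       modifier_length: int = 30):
    """Random spacer/modifier/terminator parts for simulation studies."""
    from .parts import Part, PartSet, generate_spacer

    rng = np.random.default_rng([seed, _stable_hash("modifiers")])
    bases = list("ACGT")
    parts = []
    for i in range(n_spacers):
        parts.append(generate_spacer(33, seed=int(rng.integers(2**31)), part_id=f"S{i + 1}"))
    for i in range(n_modifiers):
        seq = "".join(rng.choice(bases, size=modifier_length))
        parts.append(Part(id=f"M{i + 1}", role=Role.MODIFIER, sequence=seq))
    for i in range(n_terminators):
        parts.append(synthetic_terminator(f"T{i + 1}", seed))
    return PartSet(parts)
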