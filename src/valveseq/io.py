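"""File interfaces: part/design FASTA, design GFF3, read FASTQ and truth tables.

Parts travel as multi-FASTA with headers ``id|role``.  Designs travel as a
multi-FASTA of reference sequences plus a GFF3 with ``spacer`` / ``modifier`` /
``terminator`` / ``valve`` features (the valve feature spans ``[x_s, x_e)``).
GFF3 uses 1-based inclusive coordinates; everything in memory is 0-based
half-open.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .parts import Design, Part, PartSet, Role


def write_parts_fasta(parts, path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=f"{p.id}|{p.role.value}", description=p.description)
        for p in (parts.parts if isinstance(parts, PartSet) else parts)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_parts_fasta(path) -> PartSet:
    parts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            pid, role = rec.id.split("|", 1)
        except ValueError as exc:
            raise ValueError(f"part header {rec.id!r} is not 'id|role'") from exc
        desc = rec.description.split(None, 1)[1] if " " in rec.description else ""
        parts.append(Part(id=pid, role=Role(role), sequence=str(rec.seq).upper(), description=desc))
    return PartSet(parts)


def write_designs_fasta(designs: list[Design], path) -> None:
    records = [SeqRecord(Seq(d.reference_sequence), id=d.id, description="") for d in designs]
    SeqIO.write(records, str(path), "fasta")


def write_designs_gff3(designs: list[Design], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for d in designs:
            fh.write(f"##sequence-region {d.id} 1 {len(d.reference_sequence)}\n")
            for role, (s, e) in d.intervals.items():
                pid = d.part_ids[role]
                fh.write(
                    f"{d.id}\tvalveseq\t{role.value}\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={d.id}:{role.value};Name={pid}\n"
                )
            fh.write(
                f"{d.id}\tvalveseq\tvalve\t{d.x_s + 1}\t{d.x_e}\t.\t+\t.\tID={d.id}:valve\n"
            )


def read_designs(fasta_path, gff3_path) -> list[Design]:
    """Rebuild :class:`Design` objects from a reference FASTA + GFF3 pair."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    feats: dict[str, dict] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, *_rest, attrs = cols
            entry = feats.setdefault(seqid, {"intervals": {}, "part_ids": {}, "valve": None})
            span = (int(start) - 1, int(end))
            if ftype == "valve":
                entry["valve"] = span
            else:
                role = Role(ftype)
                entry["intervals"][role] = span
                attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                entry["part_ids"][role] = attr_map.get("Name", f"{seqid}:{ftype}")
    designs = []
    for seqid, entry in feats.items():
        if seqid not in seqs:
            raise ValueError(f"GFF3 sequence {seqid!r} missing from FASTA")
        if entry["valve"] is None:
            raise ValueError(f"design {seqid!r} has no valve feature")
        x_s, x_e = entry["valve"]
        designs.append(
            Design(
                id=seqid,
                part_ids=entry["part_ids"],
                reference_sequence=seqs[seqid],
                intervals=entry["intervals"],
                x_s=x_s,
                x_e=x_e,
            )
        )
    return designs


def write_fastq(reads, path, quality: int = 40) -> None:
    """Write ``(read_id, sequence)`` pairs (or SimulatedReads) as 4-line FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            rid, seq = (r.id, r.sequence) if hasattr(r, "sequence") else r
            fh.write(f"@{rid}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastq(path):
    """Yield ``(read_id, sequence)`` from a FASTQ file."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence in FASTQ record {i} ({rec.id})")
        yield rec.id, seq


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
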