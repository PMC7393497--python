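"""FASTA / GFF3 / TSV input-output.

FASTA goes through Biopython's SeqIO. GFF3 is written and read directly as
the 9-column text it is, so that writer -> reader -> writer round-trips are
byte-identical (a property the test suite relies on).
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """id -> sequence; raises with file context on parse trouble."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot parse FASTA file {path}: {exc}") from exc
    if not records and path.stat().st_size > 0:
        raise ValueError(f"{path} does not look like FASTA (no records parsed)")
    return {r.id: str(r.seq).upper() for r in records}


def read_fasta_with_desc(path) -> dict[str, tuple[str, str]]:
    """id -> (sequence, full description line)."""
    return {
        r.id: (str(r.seq).upper(), r.description)
        for r in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path, width: int = 70, descriptions=None) -> None:
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(s), id=name, description=descriptions.get(name, ""))
        for name, s in seqs.items()
    ]
    with open(path, "w") as f:
        writer = SeqIO.FastaIO.FastaWriter(f, wrap=width)
        writer.write_file(records)


def parse_desc_keyvals(description: str) -> dict[str, str]:
    """Extract key=value tokens from a FASTA description line."""
    out = {}
    for tok in description.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            out[k] = v
    return out


class Gff3Feature:
    __slots__ = ("seqid", "source", "ftype", "start", "end", "score", "strand", "phase", "attributes")

    def __init__(self, seqid, source, ftype, start, end, score, strand, phase, attributes):
        self.seqid = seqid
        self.source = source
        self.ftype = ftype
        self.start = int(start)  # 1-based inclusive, as in the file
        self.end = int(end)
        self.score = score
        self.strand = strand
        self.phase = phase
        self.attributes = attributes  # dict, insertion-ordered

    def line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items())
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.ftype,
                str(self.start),
                str(self.end),
                self.score,
                self.strand,
                self.phase,
                attrs,
            ]
        )

    @classmethod
    def from_line(cls, line: str) -> "Gff3Feature":
        p = line.rstrip("\n").split("\t")
        if len(p) != 9:
            raise ValueError(f"malformed GFF3 line ({len(p)} columns): {line!r}")
        attrs = {}
        for item in p[8].split(";"):
            if item:
                k, _, v = item.partition("=")
                attrs[k] = v
        return cls(p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], attrs)


def write_gff3(features: list[Gff3Feature], path) -> None:
    with open(path, "w") as f:
        f.write("##gff-version 3\n")
        for feat in features:
            f.write(feat.line() + "\n")


def read_gff3(path) -> list[Gff3Feature]:
    out = []
    with open(path) as f:
        for line in f:
            if line.startswith("#") or not line.strip():
                continue
            out.append(Gff3Feature.from_line(line))
    return out
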