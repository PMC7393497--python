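"""Small sequence utilities shared across the package.

Coordinates are 0-based half-open throughout the library; GFF3 emission
converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

#: the 20 standard residues in the conventional (PAML) order
AA20 = "ARNDCQEGHILKMFPSTWYV"

#: scoring alphabet: 20 standard residues + ambiguity codes + stop
AA_EXTENDED = AA20 + "BZX*"

STOP = "*"

DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string, frame 0, standard code.

    Codons containing N (or any ambiguity) become ``X``; stop codons are
    rendered as ``*``. A trailing partial codon is dropped.
    """
    n = len(seq) - len(seq) % 3
    if n == 0:
        return ""
    return str(Seq(seq[:n]).translate())


def sanitize_protein(protein: str) -> str:
    """Map any residue outside the scoring alphabet to X."""
    return "".join(c if c in AA_EXTENDED else "X" for c in protein.upper())


#: amino acid -> list of synonymous codons (standard code), plus stops
CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in CODONS_FOR:
    CODONS_FOR[_aa].sort()
STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))


@dataclass
class Scaffold:
    """A named nucleotide sequence; the search and annotation substrate.

    Assembly gaps (runs of >= ``min_gap_run`` N) are derivable from the
    sequence itself via :meth:`assembly_gaps`.
    """

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)

    def assembly_gaps(self, min_gap_run: int = 10) -> list[tuple[int, int]]:
        return [
            m.span() for m in re.finditer("N{%d,}" % min_gap_run, self.seq.upper())
        ]
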