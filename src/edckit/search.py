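"""Protein-vs-genome translated homology search.

This is the pipeline's stand-in for tBLASTn: every scaffold is translated in
all six reading frames and each protein query is aligned locally against each
frame translation. In keeping with how the original searches were run, no
low-complexity filtering is applied by default (EDC proteins are themselves
low-complexity, so masking would suppress the very signal being sought).

Scores are raw substitution-matrix scores (BLOSUM62, gap 11/1 by default),
not E-values: at the scaffold sizes this package targets, a raw-score
threshold is deterministic and sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import align
from .seqs import revcomp, translate

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class SearchParams:
    """Knobs for the translated search.

    word_size only gates the minimum usable query length; the search itself
    runs full dynamic programming per frame, so reported scores are exact.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    word_size: int = 3
    score_threshold: float = 50.0
    low_complexity_filter: bool = False
    max_hsps_per_frame: int = 16

    def matrix(self):
        return align.load_matrix(self.substitution_matrix)


@dataclass
class Hsp:
    """High-scoring pair between a protein query and a translated scaffold.

    query_range is in residues, scaffold_range in forward-strand nucleotides;
    both 0-based half-open.
    """

    query_id: str
    scaffold_id: str
    frame: int
    query_range: tuple[int, int]
    scaffold_range: tuple[int, int]
    score: float
    identity: float
    path: list = field(default_factory=list, repr=False)

    @property
    def query_span(self) -> int:
        return self.query_range[1] - self.query_range[0]


def six_frame_translate(sequence: str) -> dict[int, str]:
    """Translate a scaffold in all six frames.

    Frames +1..+3 read the forward strand with offsets 0..2; frames -1..-3
    read the reverse complement likewise. Stops are ``*``, N-containing
    codons are ``X``.
    """
    if not sequence:
        raise ValueError("cannot translate an empty sequence")
    seq = sequence.upper()
    rc = revcomp(seq)
    out = {}
    for f in (1, 2, 3):
        out[f] = translate(seq[f - 1:])
        out[-f] = translate(rc[f - 1:])
    return out


def frame_to_scaffold(frame: int, aa_start: int, aa_end: int, length: int) -> tuple[int, int]:
    """Map a half-open residue range in a frame translation to forward-strand
    nucleotide coordinates."""
    f = abs(frame)
    if frame > 0:
        return (f - 1 + 3 * aa_start, f - 1 + 3 * aa_end)
    return (length - (f - 1) - 3 * aa_end, length - (f - 1) - 3 * aa_start)


def search(
    query: str,
    scaffold_seq: str,
    params: SearchParams | None = None,
    query_id: str = "query",
    scaffold_id: str = "scaffold",
) -> list[Hsp]:
    """All HSPs of a protein query against the six-frame translation of a
    scaffold, sorted by descending score.

    Per frame, the optimal local alignment is exact (full affine-gap
    Smith-Waterman); further non-overlapping HSPs are extracted by masking
    the matched span and re-aligning.
    """
    params = params or SearchParams()
    if len(query) < params.word_size:
        raise ValueError(
            f"query length {len(query)} is below word_size {params.word_size}"
        )
    frames = six_frame_translate(scaffold_seq)
    matrix = params.matrix()
    L = len(scaffold_seq)
    hsps: list[Hsp] = []
    for frame in FRAMES:
        ft = frames[frame]
        if not ft:
            continue
        for aln in align.local_alignments(
            query,
            ft,
            matrix,
            params.gap_open,
            params.gap_extend,
            min_score=params.score_threshold,
            max_hits=params.max_hsps_per_frame,
        ):
            srange = frame_to_scaffold(frame, aln.t_start, aln.t_end, L)
            hsps.append(
                Hsp(
                    query_id=query_id,
                    scaffold_id=scaffold_id,
                    frame=frame,
                    query_range=(aln.q_start, aln.q_end),
                    scaffold_range=srange,
                    score=aln.score,
                    identity=aln.identity,
                    path=aln.path,
                )
            )
    hsps.sort(key=lambda h: (-h.score, abs(h.frame), h.frame < 0, h.scaffold_range))
    return hsps


def search_all(
    queries: dict[str, str],
    scaffolds: dict[str, str],
    params: SearchParams | None = None,
) -> list[Hsp]:
    """Search every query against every scaffold; flat HSP list."""
    params = params or SearchParams()
    out: list[Hsp] = []
    for sid, seq in scaffolds.items():
        for qid, q in queries.items():
            out.extend(search(q, seq, params, query_id=qid, scaffold_id=sid))
    return out


def validate_expression(
    proteins: dict[str, str],
    transcripts: dict[str, str],
    params: SearchParams | None = None,
    min_coverage: float = 0.5,
) -> dict[str, str]:
    """Mark each protein expressed iff some transcript yields an HSP above
    the score threshold covering at least ``min_coverage`` of the protein.

    Mirrors transcriptome-based validation of predicted gene models: a
    transcript contig is treated as a mini-scaffold and searched with the
    protein in all six frames.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    params = params or SearchParams()
    table: dict[str, str] = {}
    for pid, prot in proteins.items():
        status = "not_detected"
        for tid, tseq in transcripts.items():
            if len(tseq) < 3:
                continue
            hits = search(prot, tseq, params, query_id=pid, scaffold_id=tid)
            if any(h.query_span / len(prot) >= min_coverage for h in hits):
                status = "expressed"
                break
        table[pid] = status
    return table


HSP_TSV_HEADER = (
    "query_id\tscaffold_id\tframe\tq_start\tq_end\ts_start\ts_end\tscore\tidentity"
)


def write_hsp_tsv(hsps: list[Hsp], path) -> None:
    with open(path, "w") as f:
        f.write(HSP_TSV_HEADER + "\n")
        for h in hsps:
            f.write(
                f"{h.query_id}\t{h.scaffold_id}\t{h.frame}"
                f"\t{h.query_range[0]}\t{h.query_range[1]}"
                f"\t{h.scaffold_range[0]}\t{h.scaffold_range[1]}"
                f"\t{h.score:g}\t{h.identity:.4f}\n"
            )


def read_hsp_tsv(path) -> list[Hsp]:
    out = []
    with open(path) as f:
        header = f.readline()
        if header.strip() != HSP_TSV_HEADER.replace("\t", "\t").strip():
            pass  # tolerate reordered copies; columns are positional below
        for line in f:
            p = line.rstrip("\n").split("\t")
            out.append(
                Hsp(
                    query_id=p[0],
                    scaffold_id=p[1],
                    frame=int(p[2]),
                    query_range=(int(p[3]), int(p[4])),
                    scaffold_range=(int(p[5]), int(p[6])),
                    score=float(p[7]),
                    identity=float(p[8]),
                )
            )
    return out
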