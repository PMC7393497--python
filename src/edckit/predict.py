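"""Homology-anchored gene-model prediction for EDC loci.

EDC genes follow a rigid grammar that makes ab initio modelling
unnecessary: SEDC genes have one non-coding exon and one exon holding the
entire coding sequence, SFTP genes have one non-coding and two coding
exons, and CBP genes are SEDC-shaped. Prediction therefore reduces to open
reading frame scanning inside regions flagged by the translated search,
plus canonical GT..AG splice-site placement, plus pseudogene flagging when
the best alignment to a homolog is interrupted by stops or frameshifts.

All internal coordinates are 0-based half-open on the forward strand;
minus-strand features are stored on forward coordinates with a strand flag.
CDS intervals include the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import align
from .features import PSSM
from .io import Gff3Feature
from .search import Hsp, SearchParams, search
from .seqs import STOP_CODONS, Scaffold, revcomp, translate


@dataclass
class Lesion:
    kind: str  # "stop" | "frameshift"
    position: int  # forward-strand nt coordinate


@dataclass
class GeneModel:
    gene_id: str
    scaffold_id: str
    strand: str
    gene_class: str  # SEDC | SFTP | CBP | pseudogene | unclassified
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    protein: str = ""
    evidence: list[str] = field(default_factory=list)
    complete: bool = False
    flags: list[str] = field(default_factory=list)
    lesions: list[Lesion] = field(default_factory=list)

    @property
    def start(self) -> int:
        coords = self.exons or self.cds
        return min(s for s, _ in coords) if coords else 0

    @property
    def end(self) -> int:
        coords = self.exons or self.cds
        return max(e for _, e in coords) if coords else 0


# ------------------------------------------------------------- orientation


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def _to_forward(iv: tuple[int, int], L: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return iv
    s, e = iv
    return (L - e, L - s)


def _pos_to_forward(p: int, L: int, strand: str) -> int:
    return p if strand == "+" else L - 1 - p


# --------------------------------------------------------------- ORF scan


def scan_orfs(
    scaffold: Scaffold,
    region: tuple[int, int],
    strand: str = "+",
    min_length: int = 30,
) -> list[tuple[int, int]]:
    """All maximal ATG..stop ORFs of >= min_length residues on one strand.

    Maximal means the ORF starts at the first in-frame ATG after the
    previous in-frame stop. Returned intervals are forward-strand 0-based
    half-open and include the stop codon; sorted by start.
    """
    s, e = region
    if s < 0 or e > len(scaffold.seq) or s >= e:
        raise ValueError(f"region {region} outside scaffold {scaffold.id}")
    sub = _oriented(scaffold.seq[s:e], strand)
    n = len(sub)
    out = []
    for f in range(3):
        current = None
        for p in range(f, n - 2, 3):
            codon = sub[p:p + 3]
            if codon in STOP_CODONS:
                if current is not None:
                    residues = (p - current) // 3
                    if residues >= min_length:
                        out.append((current, p + 3))
                    current = None
            elif codon == "ATG" and current is None:
                current = p
    fwd = []
    for iv in out:
        a, b = _to_forward(iv, n, strand)
        fwd.append((s + a, s + b))
    fwd.sort()
    return fwd


# ------------------------------------------------------------ SEDC models


def _find_utr_intron(
    oseq: str,
    cds_start: int,
    search_window: int,
    min_intron: int,
    utr_exon_len: int,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Place a non-coding first exon upstream of an oriented CDS start.

    The acceptor AG must directly precede the coding exon (the coding exon
    is taken to begin at the start codon); the donor GT is the nearest one
    at least min_intron upstream, searched within search_window.
    """
    if cds_start < min_intron + 2:
        return None
    if oseq[cds_start - 2:cds_start] != "AG":
        return None
    lo = max(0, cds_start - search_window)
    for d in range(cds_start - min_intron, lo - 1, -1):
        if oseq[d:d + 2] == "GT":
            exon1 = (max(0, d - utr_exon_len), d)
            return exon1, (d, cds_start)
    return None


def predict_sedc(
    scaffold: Scaffold,
    orf: tuple[int, int],
    strand: str = "+",
    search_window: int = 5000,
    min_intron: int = 60,
    utr_exon_len: int = 100,
    gene_id: str = "gene",
    evidence: list[str] | None = None,
) -> GeneModel:
    """Single-coding-exon gene model from an ORF, with UTR-intron placement."""
    L = len(scaffold.seq)
    cds_seq = _oriented(scaffold.seq[orf[0]:orf[1]], strand)
    if not cds_seq.startswith("ATG"):
        raise ValueError(f"{gene_id}: ORF does not begin with ATG")
    prot = translate(cds_seq)
    if "*" in prot[:-1]:
        raise ValueError(f"{gene_id}: ORF contains an internal stop")
    model = GeneModel(
        gene_id=gene_id,
        scaffold_id=scaffold.id,
        strand=strand,
        gene_class="SEDC",
        cds=[orf],
        protein=prot.rstrip("*"),
        evidence=list(evidence or []),
        complete=prot.endswith("*"),
    )
    oseq = _oriented(scaffold.seq, strand)
    ostart = orf[0] if strand == "+" else L - orf[1]
    found = _find_utr_intron(oseq, ostart, search_window, min_intron, utr_exon_len)
    coding_exon = orf
    if found is None:
        model.exons = [coding_exon]
        model.flags.append("no_utr_intron")
    else:
        exon1, _intron = found
        model.exons = sorted([_to_forward(exon1, L, strand), coding_exon])
    return model


# ------------------------------------------------------------ SFTP models


@dataclass
class SftpParams:
    min_exon1: int = 150  # nt of coding exon 1
    max_exon1: int = 450
    min_intron: int = 60
    max_intron: int = 2000
    min_protein: int = 90  # residues
    tail_extension: int = 3000  # nt scanned past the region for the stop
    support_weight: float = 0.2


def predict_sftp(
    scaffold: Scaffold,
    region: tuple[int, int],
    strand: str,
    s100_profile: PSSM,
    params: SftpParams | None = None,
    gene_id: str = "gene",
    support_protein: str | None = None,
    search_window: int = 5000,
    utr_exon_len: int = 100,
    evidence: list[str] | None = None,
) -> GeneModel:
    """Two-coding-exon (S100 fused-type) gene model inside a flagged region.

    Candidate structures are enumerated exhaustively: every ATG, every GT
    donor within the allowed first-exon range before the first in-frame
    stop, every AG acceptor at a legal intron length. A candidate survives
    if its spliced translation is stop-free and ends at a stop codon; it is
    scored by the S100 profile match at the protein start plus (when a
    supporting homolog is given) the Smith-Waterman score against it. Ties
    prefer the shortest intron.
    """
    params = params or SftpParams()
    L = len(scaffold.seq)
    oseq = _oriented(scaffold.seq, strand)
    oregion = region if strand == "+" else (L - region[1], L - region[0])
    rs, re_ = oregion
    scan_end = min(len(oseq), re_ + params.tail_extension)

    width = s100_profile.width
    best = None  # (score, -intron_len, structure)
    saw_donor = False
    for a in range(rs, re_ - 30):
        if oseq[a:a + 3] != "ATG":
            continue
        # first in-frame stop limits the donor range
        stop_limit = min(a + params.max_exon1, len(oseq)) + 3
        p = a
        while p + 3 <= len(oseq) and p < a + params.max_exon1:
            if oseq[p:p + 3] in STOP_CODONS:
                stop_limit = p + 2
                break
            p += 3
        d_hi = min(a + params.max_exon1, stop_limit, len(oseq) - 2)
        for d in range(a + params.min_exon1, d_hi):
            if oseq[d:d + 2] != "GT":
                continue
            saw_donor = True
            e_lo = d + params.min_intron
            e_hi = min(d + params.max_intron, scan_end)
            for e in range(e_lo, e_hi):
                if oseq[e - 2:e] != "AG":
                    continue
                structure = _try_structure(oseq, a, d, e, scan_end, params)
                if structure is None:
                    continue
                protein, stop_end = structure
                if len(protein) < max(params.min_protein, width):
                    continue
                score = s100_profile.score_at(protein, 0)
                if support_protein:
                    score += params.support_weight * align.smith_waterman(
                        support_protein, protein
                    ).score
                else:
                    score += 0.01 * len(protein)
                key = (score, -(e - d))
                if best is None or key > best[0]:
                    best = (key, (a, d, e, stop_end, protein))
    if best is None:
        model = GeneModel(
            gene_id=gene_id,
            scaffold_id=scaffold.id,
            strand=strand,
            gene_class="unclassified",
            evidence=list(evidence or []),
        )
        model.flags.append("no_donor" if not saw_donor else "no_two_exon_structure")
        return model

    a, d, e, stop_end, protein = best[1]
    cds1 = _to_forward((a, d), L, strand)
    cds2 = _to_forward((e, stop_end), L, strand)
    model = GeneModel(
        gene_id=gene_id,
        scaffold_id=scaffold.id,
        strand=strand,
        gene_class="SFTP",
        cds=sorted([cds1, cds2]),
        protein=protein,
        evidence=list(evidence or []),
        complete=True,
    )
    exons = [cds1, cds2]
    found = _find_utr_intron(oseq, a, search_window, params.min_intron, utr_exon_len)
    if found is None:
        model.flags.append("no_utr_intron")
    else:
        exon1, _ = found
        exons.append(_to_forward(exon1, L, strand))
    model.exons = sorted(exons)
    return model


def _try_structure(oseq, a, d, e, scan_end, params):
    """Translate a spliced (ATG..donor) + (acceptor..) structure; return
    (protein, oriented stop end) or None if no clean stop is reached."""
    exon1 = oseq[a:d]
    phase = len(exon1) % 3
    protein = translate(exon1[: len(exon1) - phase])
    if "*" in protein:
        return None
    carry = exon1[len(exon1) - phase:]
    p = e
    while True:
        if len(carry) == 3:
            aa = translate(carry)
            if aa == "*":
                stop_end = p
                return protein, stop_end
            protein += aa
            carry = ""
        if p >= scan_end:
            return None
        carry += oseq[p]
        p += 1


# ------------------------------------------------------------- pseudogenes


@dataclass
class PseudogeneVerdict:
    is_pseudogene: bool
    lesions: list[Lesion]
    hsps: list[Hsp]
    aligned_span: tuple[int, int] | None = None  # forward-strand coords
    chain_score: float = 0.0  # summed scores of the alignment chain


def flag_pseudogene(
    scaffold: Scaffold,
    region: tuple[int, int],
    strand: str,
    homolog: str,
    params: SearchParams | None = None,
) -> PseudogeneVerdict:
    """Pseudogene call: is the best alignment of the region's translation to
    an intact homolog interrupted by stops or frameshifts?

    The homolog is aligned against the coding-strand translations of the
    region; consecutive alignment fragments along the homolog reveal either
    a reading-frame change (frameshift) or an in-frame stop codon in the
    gap between them (premature stop). Lesion coordinates are forward-strand.
    """
    if not homolog:
        raise ValueError("homolog protein must be non-empty")
    params = params or SearchParams(score_threshold=25.0)
    s, e = region
    sub = _oriented(scaffold.seq[s:e], strand)
    n = len(sub)
    hits = [h for h in search(homolog, sub, params) if h.frame > 0]
    # score-ordered greedy chain: an HSP joins only if it explains a part of
    # the homolog not already covered (repeat-rich queries spawn spurious
    # shifted-frame HSPs over ground already covered by the main alignment)
    hits.sort(key=lambda h: (-h.score, h.query_range))
    covered: set[int] = set()
    chain: list[Hsp] = []
    for h in hits:
        qspan = set(range(*h.query_range))
        if len(qspan - covered) < 10:
            continue
        chain.append(h)
        covered |= qspan
    chain.sort(key=lambda h: h.query_range)
    # require scaffold-order consistency with query order
    pruned: list[Hsp] = []
    for h in chain:
        if pruned and h.scaffold_range[0] < pruned[-1].scaffold_range[0]:
            continue
        pruned.append(h)
    chain = pruned
    # premature stops: in-frame stop codons inside an aligned span (the
    # aligner bridges a stop with a gap pair rather than pairing it, so the
    # alignment stays in one piece) or in the gap between same-frame pieces
    stop_positions: set[int] = set()
    for h in chain:
        f = h.frame - 1
        lo, hi = h.scaffold_range
        start = lo + ((f - lo) % 3)
        for p in range(start, hi - 2, 3):
            if sub[p:p + 3] in STOP_CODONS:
                stop_positions.add(p)
    lesions: list[Lesion] = []
    for h1, h2 in zip(chain, chain[1:]):
        gap_lo = h1.scaffold_range[1]
        gap_hi = h2.scaffold_range[0]
        if h1.frame != h2.frame:
            pos = _region_pos_to_forward(gap_lo, s, n, strand)
            lesions.append(Lesion("frameshift", pos))
        else:
            f = h1.frame - 1
            start = gap_lo + ((f - gap_lo) % 3)
            for p in range(start, max(start, gap_hi - 2), 3):
                if sub[p:p + 3] in STOP_CODONS:
                    stop_positions.add(p)
    for p in sorted(stop_positions):
        lesions.append(Lesion("stop", _region_pos_to_forward(p, s, n, strand)))
    lesions.sort(key=lambda l: l.position)
    span = None
    if chain:
        lo = min(h.scaffold_range[0] for h in chain)
        hi = max(h.scaffold_range[1] for h in chain)
        a = _region_pos_to_forward(lo, s, n, strand)
        b = _region_pos_to_forward(hi - 1, s, n, strand)
        span = (min(a, b), max(a, b) + 1)
    return PseudogeneVerdict(
        bool(lesions), lesions, chain, span, sum(h.score for h in chain)
    )


def _region_pos_to_forward(p: int, region_start: int, n: int, strand: str) -> int:
    return region_start + (p if strand == "+" else n - 1 - p)


# ----------------------------------------------------------- region merge


def merge_hsp_regions(
    hsps: list[Hsp],
    pad: int = 600,
    merge_distance: int = 300,
) -> list[dict]:
    """Group HSPs into candidate gene regions per (scaffold, strand).

    Each region records its extent (padded), the supporting HSPs, and the
    best-scoring query. Used by the pipeline to decide what to predict
    where.
    """
    by_key: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        strand = "+" if h.frame > 0 else "-"
        by_key.setdefault((h.scaffold_id, strand), []).append(h)
    regions = []
    for (sid, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.scaffold_range)
        current: list[Hsp] = []
        for h in group:
            if current and h.scaffold_range[0] > max(
                x.scaffold_range[1] for x in current
            ) + merge_distance:
                regions.append(_close_region(sid, strand, current, pad))
                current = []
            current.append(h)
        if current:
            regions.append(_close_region(sid, strand, current, pad))
    return regions


def _close_region(sid, strand, hsps, pad):
    lo = min(h.scaffold_range[0] for h in hsps)
    hi = max(h.scaffold_range[1] for h in hsps)
    best = max(hsps, key=lambda h: h.score)
    return {
        "scaffold_id": sid,
        "strand": strand,
        "span": (max(0, lo - pad), hi + pad),
        "hsps": hsps,
        "best_query": best.query_id,
        "best_score": best.score,
    }


# ---------------------------------------------------------------- GFF3 I/O


def models_to_gff3(models: list[GeneModel], source: str = "edckit") -> list[Gff3Feature]:
    feats = []
    for m in sorted(models, key=lambda x: (x.scaffold_id, x.start)):
        attrs = {
            "ID": m.gene_id,
            "gene_class": m.gene_class,
            "complete": str(m.complete).lower(),
        }
        if m.flags:
            attrs["flags"] = ",".join(m.flags)
        if m.lesions:
            attrs["lesions"] = ",".join(f"{l.kind}:{l.position}" for l in m.lesions)
        if m.evidence:
            attrs["evidence"] = ",".join(m.evidence)
        if m.protein:
            attrs["protein"] = m.protein
        feats.append(
            Gff3Feature(
                m.scaffold_id, source, "gene", m.start + 1, m.end, ".",
                m.strand, ".", attrs,
            )
        )
        feats.append(
            Gff3Feature(
                m.scaffold_id, source, "mRNA", m.start + 1, m.end, ".",
                m.strand, ".", {"ID": m.gene_id + ".t1", "Parent": m.gene_id},
            )
        )
        for (xs, xe) in sorted(m.exons):
            feats.append(
                Gff3Feature(
                    m.scaffold_id, source, "exon", xs + 1, xe, ".", m.strand,
                    ".", {"Parent": m.gene_id + ".t1"},
                )
            )
        coding = sorted(m.cds)
        order = coding if m.strand == "+" else list(reversed(coding))
        acc = 0
        for cs, ce in order:
            phase = (3 - acc % 3) % 3
            acc += ce - cs
            feats.append(
                Gff3Feature(
                    m.scaffold_id, source, "CDS", cs + 1, ce, ".", m.strand,
                    str(phase), {"Parent": m.gene_id + ".t1"},
                )
            )
    return feats


def models_from_gff3(features: list[Gff3Feature]) -> list[GeneModel]:
    models: dict[str, GeneModel] = {}
    for f in features:
        if f.ftype == "gene":
            m = GeneModel(
                gene_id=f.attributes["ID"],
                scaffold_id=f.seqid,
                strand=f.strand,
                gene_class=f.attributes.get("gene_class", "unclassified"),
                complete=f.attributes.get("complete", "false") == "true",
                protein=f.attributes.get("protein", ""),
            )
            if "flags" in f.attributes:
                m.flags = f.attributes["flags"].split(",")
            if "lesions" in f.attributes:
                for item in f.attributes["lesions"].split(","):
                    kind, _, pos = item.partition(":")
                    m.lesions.append(Lesion(kind, int(pos)))
            if "evidence" in f.attributes:
                m.evidence = f.attributes["evidence"].split(",")
            models[m.gene_id] = m
        elif f.ftype == "exon":
            gid = f.attributes["Parent"].removesuffix(".t1")
            models[gid].exons.append((f.start - 1, f.end))
        elif f.ftype == "CDS":
            gid = f.attributes["Parent"].removesuffix(".t1")
            models[gid].cds.append((f.start - 1, f.end))
    for m in models.values():
        m.exons.sort()
        m.cds.sort()
    return list(models.values())


def model_summary_table(models: list[GeneModel]):
    import pandas as pd

    rows = []
    for m in sorted(models, key=lambda x: (x.scaffold_id, x.start)):
        rows.append(
            {
                "gene_id": m.gene_id,
                "scaffold_id": m.scaffold_id,
                "strand": m.strand,
                "gene_class": m.gene_class,
                "start": m.start,
                "end": m.end,
                "n_exons": len(m.exons),
                "n_cds": len(m.cds),
                "protein_length": len(m.protein),
                "complete": m.complete,
                "flags": ",".join(m.flags) or "-",
                "lesions": ",".join(f"{l.kind}:{l.position}" for l in m.lesions) or "-",
            }
        )
    return pd.DataFrame(rows)
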