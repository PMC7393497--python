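"""Cross-species orthology by reciprocal best hits, refined by synteny.

Orthology between two species' EDC gene sets is assigned the way it is done
for real EDC loci: reciprocal best protein-protein alignment hits, with
1-to-many co-ortholog groups for lineage-specific duplications, plus a
gene-order (synteny) chain over the two locus maps. Locus maps mirror the
comparative figures of EDC papers: genes in cluster order with strand
arrows, "§" between scaffolds and "//" at within-scaffold assembly gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import align


# ---------------------------------------------------------------- locus map


@dataclass
class LocusMapEntry:
    gene_id: str
    family: str
    strand: str
    scaffold_id: str
    start: int
    at_gap: bool = False  # gene abuts/spans an assembly gap


@dataclass
class LocusMap:
    species: str
    entries: list[LocusMapEntry] = field(default_factory=list)
    # within-scaffold assembly gaps: scaffold_id -> list of gap start coords
    gaps: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.entries.sort(key=lambda e: (e.scaffold_id, e.start))

    def order(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def entry(self, gene_id: str) -> LocusMapEntry:
        for e in self.entries:
            if e.gene_id == gene_id:
                return e
        raise KeyError(gene_id)


def locus_map_from_models(species: str, models, scaffolds=None) -> LocusMap:
    """Build a LocusMap from GeneModel-like objects (gene_id, scaffold_id,
    strand, gene_class, start attributes)."""
    gaps: dict[str, list[int]] = {}
    if scaffolds:
        for s in scaffolds.values() if isinstance(scaffolds, dict) else scaffolds:
            g = [a for a, _ in s.assembly_gaps()]
            if g:
                gaps[s.id] = g
    entries = [
        LocusMapEntry(
            gene_id=m.gene_id,
            family=m.gene_class,
            strand=m.strand,
            scaffold_id=m.scaffold_id,
            start=m.start,
        )
        for m in models
    ]
    return LocusMap(species=species, entries=entries, gaps=gaps)


# --------------------------------------------------------------------- RBH


def all_vs_all_scores(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> pd.DataFrame:
    """Smith-Waterman score matrix, rows = species A genes, cols = B."""
    matrix = align.load_matrix()
    data = {
        b: [
            align.smith_waterman(sa, sb, matrix, gap_open, gap_extend).score
            for sa in proteins_a.values()
        ]
        for b, sb in proteins_b.items()
    }
    return pd.DataFrame(data, index=list(proteins_a))


@dataclass
class RbhResult:
    pairs: list[tuple[str, str]]
    ambiguous_a: list[str]
    ambiguous_b: list[str]
    scores: pd.DataFrame


def reciprocal_best_hits(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    *extra,
    scores: pd.DataFrame | None = None,
) -> RbhResult:
    """(a, b) pairs where b is a's unique best hit and vice versa.

    Score ties leave both partners unpaired and flagged ambiguous. Strictly
    pairwise: passing a third protein set is an error.
    """
    if extra:
        raise ValueError("reciprocal_best_hits is pairwise; got extra protein sets")
    if not proteins_a or not proteins_b:
        raise ValueError("protein sets must be non-empty")
    S = scores if scores is not None else all_vs_all_scores(proteins_a, proteins_b)
    pairs = []
    ambiguous_a, ambiguous_b = [], []
    best_b_of_a, amb_a = _unique_argmax(S)
    best_a_of_b, amb_b = _unique_argmax(S.T)
    ambiguous_a = sorted(amb_a)
    ambiguous_b = sorted(amb_b)
    for a, b in best_b_of_a.items():
        if b in best_a_of_b and best_a_of_b[b] == a:
            pairs.append((a, b))
    return RbhResult(sorted(pairs), ambiguous_a, ambiguous_b, S)


def _unique_argmax(S: pd.DataFrame):
    best = {}
    ambiguous = []
    for idx, row in S.iterrows():
        m = row.max()
        winners = row.index[row == m]
        if len(winners) == 1:
            best[idx] = winners[0]
        else:
            ambiguous.append(idx)
    return best, ambiguous


# --------------------------------------------------------------- relations


@dataclass
class OrthologyMap:
    pairs: list[tuple[str, str, str]]  # (geneA, geneB, relation)
    unmatched_a: list[str]
    unmatched_b: list[str]
    ambiguous_a: list[str] = field(default_factory=list)
    ambiguous_b: list[str] = field(default_factory=list)
    scores: pd.DataFrame | None = None
    synteny: "SyntenyChain | None" = None

    def as_table(self) -> dict[str, list[str]]:
        """source gene -> sorted list of partners (empty when unmatched)."""
        out: dict[str, list[str]] = {a: [] for a in self.unmatched_a}
        for a, b, _rel in self.pairs:
            out.setdefault(a, []).append(b)
        for a in out:
            out[a].sort()
        return out


def resolve_families(
    rbh: RbhResult,
    clustering_threshold: float = 0.9,
    min_score: float = 50.0,
) -> OrthologyMap:
    """Expand RBH pairs into 1:1 / 1:many / many:1 relations.

    A B gene joins gene a's co-ortholog group when a is its unique closest
    A gene and its score to a is within clustering_threshold of that B
    gene's own best hit; a group of size >1 is a 1:many relation
    (symmetrically for many:1). Genes without any partner above min_score
    are unmatched. Anchoring the relative threshold at each candidate's own
    best score keeps the grouping stable when independently diverged
    co-orthologs drift apart at different speeds.
    """
    S = rbh.scores
    best_a_of_b, _ = _unique_argmax(S.T)
    best_b_of_a, _ = _unique_argmax(S)
    rbh_set = set(rbh.pairs)
    pairs: list[tuple[str, str, str]] = []
    matched_a, matched_b = set(), set()
    for a in S.index:
        row = S.loc[a]
        best = row.max()
        if best < min_score:
            continue
        cands = [
            b
            for b in S.columns
            if best_a_of_b.get(b) == a
            and row[b] >= clustering_threshold * S[b].max()
            and row[b] >= min_score
        ]
        if not cands:
            continue
        if len(cands) == 1:
            b = cands[0]
            if (a, b) in rbh_set:
                pairs.append((a, b, "1:1"))
                matched_a.add(a)
                matched_b.add(b)
        else:
            for b in sorted(cands):
                pairs.append((a, b, "1:many"))
                matched_a.add(a)
                matched_b.add(b)
    # many:1 — several A genes collapsing onto one B gene
    for b in S.columns:
        col = S[b]
        best = col.max()
        if best < min_score or b in matched_b:
            continue
        cands = [
            a
            for a in S.index
            if best_b_of_a.get(a) == b
            and col[a] >= clustering_threshold * S.loc[a].max()
            and col[a] >= min_score
        ]
        if len(cands) > 1:
            for a in sorted(cands):
                pairs.append((a, b, "many:1"))
                matched_a.add(a)
                matched_b.add(b)
    unmatched_a = sorted(set(S.index) - matched_a)
    unmatched_b = sorted(set(S.columns) - matched_b)
    return OrthologyMap(
        pairs=sorted(pairs),
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        ambiguous_a=rbh.ambiguous_a,
        ambiguous_b=rbh.ambiguous_b,
        scores=S,
    )


# ----------------------------------------------------------------- synteny


@dataclass
class SyntenyChain:
    chain: list[tuple[str, str, bool]]  # (geneA, geneB, inverted)
    breakpoints: list[tuple[str, str]]  # matched pairs off the chain

    def __len__(self) -> int:
        return len(self.chain)


def synteny_chain(
    map_a: LocusMap,
    map_b: LocusMap,
    relations: OrthologyMap,
    exclude_gap_genes: bool = True,
) -> SyntenyChain:
    """Maximal common subsequence of matched genes respecting gene order.

    One representative pair per gene (the highest-scoring one for 1:many
    groups) enters the chain computation; the chain is the longest strictly
    order-increasing set of pairs in both species. A matched gene whose
    strand differs between species stays in the chain with an inversion
    flag. Genes flagged as spanning assembly gaps are excluded from chain
    scoring but remain on the maps.
    """
    pos_a = {g: i for i, g in enumerate(map_a.order())}
    pos_b = {g: i for i, g in enumerate(map_b.order())}
    S = relations.scores
    # one representative pair per A gene and per B gene, by score
    reps: dict[str, tuple[str, str]] = {}
    used_b: set[str] = set()
    scored = sorted(
        relations.pairs,
        key=lambda p: (-(S.loc[p[0], p[1]] if S is not None else 0), p[0], p[1]),
    )
    for a, b, _rel in scored:
        if a in reps or b in used_b:
            continue
        if a not in pos_a or b not in pos_b:
            continue
        if exclude_gap_genes and (
            map_a.entry(a).at_gap or map_b.entry(b).at_gap
        ):
            continue
        reps[a] = (a, b)
        used_b.add(b)
    pairs = sorted(reps.values(), key=lambda p: pos_a[p[0]])
    # longest increasing subsequence on the B positions
    n = len(pairs)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if pos_b[pairs[j][1]] < pos_b[pairs[i][1]] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    chain_idx: list[int] = []
    if n:
        i = max(range(n), key=lambda k: (best_len[k], -k))
        while i >= 0:
            chain_idx.append(i)
            i = prev[i]
        chain_idx.reverse()
    in_chain = set(chain_idx)
    chain = []
    for i in chain_idx:
        a, b = pairs[i]
        inverted = map_a.entry(a).strand != map_b.entry(b).strand
        chain.append((a, b, inverted))
    breakpoints = [pairs[i] for i in range(n) if i not in in_chain]
    return SyntenyChain(chain=chain, breakpoints=breakpoints)


# --------------------------------------------------------------- rendering


def render_locus_map(maps: list[LocusMap], relations: OrthologyMap | None = None) -> str:
    """Deterministic text rendering of one or more locus maps.

    Genes appear as ``name(strand)`` in cluster order; "§" separates
    scaffolds and "//" marks within-scaffold assembly gaps falling between
    consecutive genes.
    """
    if not maps:
        raise ValueError("need at least one locus map")
    lines = []
    for lm in maps:
        tokens: list[str] = []
        prev: LocusMapEntry | None = None
        for e in lm.entries:
            if prev is not None:
                if e.scaffold_id != prev.scaffold_id:
                    tokens.append("§")
                else:
                    for gap in lm.gaps.get(e.scaffold_id, []):
                        if prev.start < gap < e.start:
                            tokens.append("//")
                            break
            tokens.append(f"{e.gene_id}({e.strand})")
            prev = e
        lines.append(f"{lm.species}: " + " ".join(tokens))
    if relations is not None and relations.synteny is not None:
        rendered = " ".join(
            f"{a}={b}{'*' if inv else ''}" for a, b, inv in relations.synteny.chain
        )
        lines.append("chain: " + rendered)
    return "\n".join(lines) + "\n"


LOCUS_TSV_HEADER = "species\trow_type\tgene_id\tfamily\tstrand\tscaffold_id\tstart"


def write_locus_map_tsv(lm: LocusMap, path) -> None:
    with open(path, "w") as f:
        f.write(LOCUS_TSV_HEADER + "\n")
        for e in lm.entries:
            f.write(
                f"{lm.species}\tgene\t{e.gene_id}\t{e.family}\t{e.strand}"
                f"\t{e.scaffold_id}\t{e.start}\n"
            )
        for sid in sorted(lm.gaps):
            for gap in lm.gaps[sid]:
                f.write(f"{lm.species}\tgap\t-\t-\t.\t{sid}\t{gap}\n")


def read_locus_map_tsv(path) -> LocusMap:
    entries = []
    gaps: dict[str, list[int]] = {}
    species = ""
    with open(path) as f:
        f.readline()
        for line in f:
            p = line.rstrip("\n").split("\t")
            species = p[0]
            if p[1] == "gene":
                entries.append(
                    LocusMapEntry(
                        gene_id=p[2], family=p[3], strand=p[4],
                        scaffold_id=p[5], start=int(p[6]),
                    )
                )
            else:
                gaps.setdefault(p[5], []).append(int(p[6]))
    return LocusMap(species=species, entries=entries, gaps=gaps)


def write_orthology_tsv(om: OrthologyMap, path) -> None:
    S = om.scores
    chain_pairs = (
        {(a, b) for a, b, _ in om.synteny.chain} if om.synteny is not None else set()
    )
    with open(path, "w") as f:
        f.write("geneA\tgeneB\trelation\tscore_ab\tscore_ba\tin_chain\n")
        for a, b, rel in om.pairs:
            sab = f"{S.loc[a, b]:g}" if S is not None else "."
            f.write(f"{a}\t{b}\t{rel}\t{sab}\t{sab}\t{int((a, b) in chain_pairs)}\n")
        for a in om.unmatched_a:
            f.write(f"{a}\t-\tunmatched_A\t.\t.\t0\n")
        for b in om.unmatched_b:
            f.write(f"-\t{b}\tunmatched_B\t.\t.\t0\n")
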