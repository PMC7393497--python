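"""Synthetic genomes with planted EDC-like genes and full ground truth.

The generator emulates the substrate of lepidosaurian EDC annotation:
scaffolds carrying clustered single-coding-exon (SEDC) genes whose proteins
are glycine/serine/proline/cysteine-biased and tandem-repeat-rich,
three-exon SFTP-like genes whose first coding exon encodes an S100-like
domain, corneous beta-protein (CBP) genes carrying 1 or 4 copies of a
34-residue beta-sheet motif, pseudogenes with planted frameshifts or
premature stops, and derived "species" produced by substitutions,
duplications, losses and strand inversions.

Every planted locus comes with exact coordinates, so downstream stages can
be scored against truth. All randomness flows from explicit seeds and output
is byte-deterministic.

Gene anatomy on the coding strand::

    [non-coding exon] [intron GT..TAG] [coding exon = ATG..stop]      SEDC
    [non-coding exon] [intron GT..TAG] [CDS part 1] [intron GT..AG] [CDS part 2]  SFTP

The first intron deliberately ends in ``TAG``: its last two bases are the
canonical acceptor AG and the triplet is an in-frame stop immediately
upstream of the ATG, which pins the open reading frame to the planted start
codon (no upstream in-frame extension is possible).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .io import Gff3Feature, write_fasta, write_gff3
from .seqs import AA20, CODONS_FOR, STOP_CODONS, Scaffold, revcomp, translate

GENE_CLASSES = ("SEDC", "SFTP", "CBP1B", "CBP4B", "pseudogene")

_NT = np.array(list("ACGT"))
_AA = np.array(list(AA20))


class ValidationError(ValueError):
    """A GeneSpec or parameter set violates a stated invariant."""


def _load_seed(name: str) -> dict[str, str]:
    text = resources.files("edckit.data").joinpath(name).read_text()
    rows: dict[str, str] = {}
    rid = None
    for line in text.splitlines():
        if line.startswith(">"):
            rid = line[1:].split()[0]
            rows[rid] = ""
        elif rid:
            rows[rid] += line.strip()
    return rows


def beta_seed_alignment() -> dict[str, str]:
    """The shipped (synthetic) 34-column beta-motif seed alignment."""
    return _load_seed("beta_motif_seed.synthetic.fasta")


def beta_consensus() -> str:
    rows = list(beta_seed_alignment().values())
    cons = []
    for col in range(len(rows[0])):
        chars = [r[col] for r in rows]
        cons.append(max(sorted(set(chars)), key=chars.count))
    return "".join(cons)


def s100_seed_alignment() -> dict[str, str]:
    """The shipped (synthetic) S100-like first-coding-exon seed alignment."""
    return _load_seed("s100_seed.synthetic.fasta")


def s100_consensus() -> str:
    rows = list(s100_seed_alignment().values())
    cons = []
    for col in range(len(rows[0])):
        chars = [r[col] for r in rows]
        cons.append(max(sorted(set(chars)), key=chars.count))
    return "".join(cons)


@dataclass
class GeneSpec:
    """Blueprint for one planted gene.

    nterm_arm_length counts residues before the first beta motif, including
    the initial methionine (CBP classes only). composition_bias maps residue
    letters to target fractions; the remainder of the distribution is spread
    uniformly over the other residues.
    """

    name: str
    gene_class: str = "SEDC"
    protein_length: int = 120
    composition_bias: dict[str, float] = field(default_factory=dict)
    repeat_motif: str | None = None
    repeat_count: int | None = None
    n_beta_motifs: int = 0
    nterm_arm_length: int = 8
    strand: str = "+"
    utr_intron: bool = True
    cterm_motif: str | None = None
    lesion_types: tuple[str, ...] = ("stop",)

    def __post_init__(self):
        if self.gene_class == "CBP4B" and self.n_beta_motifs == 0:
            self.n_beta_motifs = 4
        if self.gene_class == "CBP1B" and self.n_beta_motifs == 0:
            self.n_beta_motifs = 1

    def validate(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(
                f"{self.name}: gene_class {self.gene_class!r} not in {GENE_CLASSES}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"{self.name}: strand must be '+' or '-'")
        bias_sum = sum(self.composition_bias.values())
        if bias_sum > 1.0 + 1e-9:
            raise ValidationError(
                f"{self.name}: composition_bias fractions sum to {bias_sum:.3f} > 1"
            )
        if self.n_beta_motifs not in (0, 1, 4):
            raise ValidationError(
                f"{self.name}: n_beta_motifs must be 0, 1 or 4"
            )
        if self.gene_class == "CBP4B" and self.n_beta_motifs != 4:
            raise ValidationError(f"{self.name}: CBP4B requires n_beta_motifs=4")
        if self.repeat_motif is not None:
            count = self.repeat_count or 0
            if count * len(self.repeat_motif) > self.protein_length:
                raise ValidationError(
                    f"{self.name}: repeat block ({count} x {len(self.repeat_motif)}) "
                    f"exceeds protein_length {self.protein_length}"
                )
        fixed = self._fixed_length()
        if fixed > self.protein_length:
            raise ValidationError(
                f"{self.name}: fixed elements need {fixed} residues but "
                f"protein_length is {self.protein_length}"
            )
        for lt in self.lesion_types:
            if lt not in ("stop", "frameshift"):
                raise ValidationError(f"{self.name}: unknown lesion type {lt!r}")

    def _fixed_length(self) -> int:
        n = 1  # initial Met
        if self.n_beta_motifs:
            n = self.nterm_arm_length + self.n_beta_motifs * 34
            n += (self.n_beta_motifs - 1) * 5
        if self.gene_class == "SFTP":
            n = len(s100_consensus())
        if self.repeat_motif and self.repeat_count:
            n += self.repeat_count * len(self.repeat_motif)
        if self.cterm_motif:
            n += len(self.cterm_motif)
        return n


@dataclass
class LocusBlock:
    """A planted gene in block-local coding-strand coordinates."""

    spec: GeneSpec
    seq: str
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    protein: str
    lesions: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class PlantedLocus:
    """Ground truth for one planted gene in forward scaffold coordinates."""

    scaffold_id: str
    gene: GeneSpec
    exon_coords: list[tuple[int, int]]
    intron_coords: list[tuple[int, int]]
    cds_coords: list[tuple[int, int]]
    protein: str
    span: tuple[int, int]
    lesions: list[tuple[str, int]] = field(default_factory=list)
    block: LocusBlock | None = field(default=None, repr=False)

    @property
    def name(self) -> str:
        return self.gene.name

    @property
    def strand(self) -> str:
        return self.gene.strand


@dataclass
class EvolutionParams:
    """Events applied when deriving a second species from a cluster."""

    substitution_rate: float = 0.05
    duplication_events: list[tuple[str, int]] = field(default_factory=list)
    loss_events: list[str] = field(default_factory=list)
    inversion_events: list[str] = field(default_factory=list)
    rng_seed: int = 0

    def validate(self, known_genes) -> None:
        if self.substitution_rate < 0:
            raise ValidationError("substitution_rate must be >= 0")
        known = set(known_genes)
        for name, n in self.duplication_events:
            if name not in known:
                raise ValidationError(f"duplication of unknown gene {name!r}")
            if n < 1:
                raise ValidationError(f"duplication count for {name!r} must be >= 1")
        for name in list(self.loss_events) + list(self.inversion_events):
            if name not in known:
                raise ValidationError(f"event names unknown gene {name!r}")


@dataclass
class EvolvedCluster:
    scaffold: Scaffold
    loci: list[PlantedLocus]
    orthologs: dict[str, list[str]]


# ---------------------------------------------------------------- sequences


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.45) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NT, size=n, p=p))


def _biased_residues(n: int, bias: dict[str, float], rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    probs = np.zeros(20)
    rest = [i for i, a in enumerate(AA20) if a not in bias]
    for a, frac in bias.items():
        probs[AA20.index(a)] = frac
    remainder = 1.0 - probs.sum()
    if rest:
        probs[rest] = remainder / len(rest)
    probs = probs / probs.sum()
    return "".join(rng.choice(_AA, size=n, p=probs))


def build_protein(spec: GeneSpec, rng: np.random.Generator) -> str:
    """Deterministically assemble the planted protein for a spec."""
    spec.validate()
    bias = spec.composition_bias
    parts: list[str] = []
    if spec.n_beta_motifs:
        arm = "M" + _biased_residues(spec.nterm_arm_length - 1, bias, rng)
        parts.append(arm)
        motif = beta_consensus()
        for i in range(spec.n_beta_motifs):
            if i:
                parts.append(_biased_residues(5, bias, rng))
            parts.append(motif)
    elif spec.gene_class == "SFTP":
        parts.append(s100_consensus())
    else:
        parts.append("M")
    repeat_block = ""
    if spec.repeat_motif and spec.repeat_count:
        repeat_block = spec.repeat_motif * spec.repeat_count
    tail_motif = spec.cterm_motif or ""
    filler = spec.protein_length - sum(len(p) for p in parts)
    filler -= len(repeat_block) + len(tail_motif)
    prefix = filler // 3
    parts.append(_biased_residues(prefix, bias, rng))
    parts.append(repeat_block)
    parts.append(_biased_residues(filler - prefix, bias, rng))
    parts.append(tail_motif)
    protein = "".join(parts)
    assert len(protein) == spec.protein_length
    return protein


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein: uniform synonymous codons, plus a stop codon."""
    codons = []
    for aa in protein:
        options = CODONS_FOR[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


# -------------------------------------------------------------- locus block


def build_block(
    spec: GeneSpec,
    rng: np.random.Generator,
    utr_exon_len: int = 120,
    gc: float = 0.45,
) -> LocusBlock:
    spec.validate()
    protein = build_protein(spec, rng)
    cds = reverse_translate(protein, rng)

    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    cds_coords: list[tuple[int, int]] = []
    pos = 0

    def emit(s: str) -> tuple[int, int]:
        nonlocal pos
        pieces.append(s)
        span = (pos, pos + len(s))
        pos += len(s)
        return span

    if spec.utr_intron:
        exons.append(emit(random_dna(utr_exon_len, rng, gc)))
        ilen = int(rng.integers(90, 160))
        # intron ends in TAG: canonical AG acceptor whose triplet is an
        # in-frame stop pinning the downstream ATG
        introns.append(emit("GT" + random_dna(ilen - 5, rng, gc) + "TAG"))
    else:
        emit(random_dna(17, rng, gc) + "TAA")

    lesions: list[tuple[str, int]] = []
    if spec.gene_class == "SFTP":
        k = 3 * len(s100_consensus())
        span1 = emit(cds[:k])
        exons.append(span1)
        cds_coords.append(span1)
        ilen2 = int(rng.integers(90, 160))
        introns.append(emit("GT" + random_dna(ilen2 - 4, rng, gc) + "AG"))
        span2 = emit(cds[k:])
        exons.append(span2)
        cds_coords.append(span2)
    elif spec.gene_class == "pseudogene":
        mutated, lesions = _apply_lesions(cds, spec.lesion_types, rng)
        span = emit(mutated)
        exons.append(span)
        cds_coords.append(span)
        lesions = [(kind, span[0] + p) for kind, p in lesions]
    else:
        span = emit(cds)
        exons.append(span)
        cds_coords.append(span)

    return LocusBlock(
        spec=spec,
        seq="".join(pieces),
        exons=exons,
        introns=introns,
        cds=cds_coords,
        protein=protein,
        lesions=lesions,
    )


def _apply_lesions(cds: str, lesion_types, rng) -> tuple[str, list[tuple[str, int]]]:
    """Plant premature stops and/or frameshifts at interior codons.

    Positions are uniform over internal codons, excluding 8 codons at each
    terminus: a lesion in the extreme termini leaves no alignable fragment on
    one side and is undetectable by homology in principle.
    """
    ncod = len(cds) // 3 - 1  # exclude the genuine stop
    lo, hi = 8, ncod - 8
    if hi <= lo:
        raise ValidationError("pseudogene parent CDS too short for a lesion")
    idx = sorted(
        rng.choice(np.arange(lo, hi), size=len(lesion_types), replace=False),
        reverse=True,
    )
    seq = cds
    recorded = []
    for codon_i, kind in zip(idx, reversed(list(lesion_types))):
        p = 3 * int(codon_i)
        if kind == "stop":
            stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
            seq = seq[:p] + stop + seq[p + 3:]
        else:  # frameshift: single-base deletion
            seq = seq[:p] + seq[p + 1:]
        recorded.append((kind, p))
    recorded.reverse()
    return seq, recorded


# ----------------------------------------------------------------- assembly


def _map_interval(iv, offset, blen, strand):
    s, e = iv
    if strand == "+":
        return (offset + s, offset + e)
    return (offset + blen - e, offset + blen - s)


def _embed(block: LocusBlock, offset: int, scaffold_id: str) -> PlantedLocus:
    strand = block.spec.strand
    blen = len(block.seq)
    mapiv = lambda iv: _map_interval(iv, offset, blen, strand)  # noqa: E731
    lesions = []
    for kind, p in block.lesions:
        fp = offset + p if strand == "+" else offset + blen - 1 - p
        lesions.append((kind, fp))
    return PlantedLocus(
        scaffold_id=scaffold_id,
        gene=block.spec,
        exon_coords=sorted(mapiv(iv) for iv in block.exons),
        intron_coords=sorted(mapiv(iv) for iv in block.introns),
        cds_coords=sorted(mapiv(iv) for iv in block.cds),
        protein=block.protein,
        span=(offset, offset + blen),
        lesions=sorted(lesions, key=lambda x: x[1]),
        block=block,
    )


def _assemble(
    blocks: list[LocusBlock],
    intergenic: list[str],
    scaffold_id: str,
) -> tuple[Scaffold, list[PlantedLocus]]:
    """Interleave intergenic segments (len(blocks)+1 of them) with blocks."""
    assert len(intergenic) == len(blocks) + 1
    pieces = [intergenic[0]]
    pos = len(intergenic[0])
    loci = []
    for i, block in enumerate(blocks):
        bseq = block.seq if block.spec.strand == "+" else revcomp(block.seq)
        loci.append(_embed(block, pos, scaffold_id))
        pieces.append(bseq)
        pos += len(bseq)
        pieces.append(intergenic[i + 1])
        pos += len(intergenic[i + 1])
    return Scaffold(scaffold_id, "".join(pieces)), loci


def generate_locus(
    spec: GeneSpec,
    flank: int = 1000,
    rng_seed: int = 0,
    gc: float = 0.45,
) -> tuple[Scaffold, PlantedLocus]:
    """One scaffold containing exactly one gene conforming to ``spec``."""
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    rng = np.random.default_rng(rng_seed)
    block = build_block(spec, rng, gc=gc)
    scaffold, loci = _assemble(
        [block],
        [random_dna(flank, rng, gc), random_dna(flank, rng, gc)],
        scaffold_id=f"syn_{spec.name}",
    )
    return scaffold, loci[0]


def generate_edc_cluster(
    specs: list[GeneSpec],
    spacing: int = 2000,
    rng_seed: int = 0,
    gc: float = 0.45,
    scaffold_id: str = "syn_edc",
    flank: int = 1000,
) -> tuple[Scaffold, list[PlantedLocus]]:
    """A scaffold with the given genes planted in order, ``spacing`` nt apart."""
    if not specs:
        raise ValidationError("at least one GeneSpec is required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("gene names must be unique within a cluster")
    rng = np.random.default_rng(rng_seed)
    blocks = [build_block(s, rng, gc=gc) for s in specs]
    intergenic = [random_dna(flank, rng, gc)]
    for _ in range(len(blocks) - 1):
        intergenic.append(random_dna(spacing, rng, gc))
    intergenic.append(random_dna(flank, rng, gc))
    return _assemble(blocks, intergenic, scaffold_id)


# ---------------------------------------------------------------- evolution


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. per-site substitution model: each site mutates with probability
    ``rate`` to a uniformly chosen different base. N sites are left alone.

    This raw model (no site protection) is what the analytic identity
    expectation in the test suite targets.
    """
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        b = arr[i].decode()
        if b == "N":
            continue
        others = [c for c in "ACGT" if c != b]
        arr[i] = others[rng.integers(3)].encode()
    return arr.tobytes().decode()


def expected_aa_identity(cds: str, rate: float) -> float:
    """Closed-form expected amino-acid identity after mutate_sequence.

    Each codon independently: P(aa unchanged) = sum over the 64 mutated-codon
    outcomes of their probability times [same amino acid]. Exact under the
    i.i.d. per-site model.
    """
    from itertools import product

    p_same = 1 - rate
    p_other = rate / 3
    total = 0.0
    ncod = 0
    for k in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[k:k + 3]
        aa = translate(codon)
        if aa == "*":
            continue
        ncod += 1
        prob_keep = 0.0
        for alt in product("ACGT", repeat=3):
            p = 1.0
            for b0, b1 in zip(codon, alt):
                p *= p_same if b0 == b1 else p_other
            if translate("".join(alt)) == aa:
                prob_keep += p
        total += prob_keep
    return total / ncod if ncod else 1.0


def _cds_positions(block: LocusBlock) -> list[int]:
    pos = []
    for s, e in block.cds:
        pos.extend(range(s, e))
    return pos


def _mutate_block(block: LocusBlock, rate: float, rng: np.random.Generator) -> LocusBlock:
    """Substitutions on a locus block, preserving its gene anatomy.

    Protected: splice dinucleotides, the start codon, the terminal stop, and
    the 3 nt frame-guard immediately upstream of the CDS. Substitutions that
    would create an in-frame stop inside the (spliced) CDS are resampled, so
    non-pseudogene truth stays translatable.
    """
    if rate <= 0:
        return block
    seq = list(block.seq)
    protected: set[int] = set()
    for s, e in block.introns:
        protected.update((s, s + 1, e - 2, e - 1))
    cpos = _cds_positions(block)
    if block.spec.gene_class != "pseudogene":
        protected.update(cpos[:3])  # ATG
        protected.update(cpos[-3:])  # stop codon
    else:
        protected.update(cpos[:3])
        protected.update(p for _, p in block.lesions)
    cds_start = block.cds[0][0]
    protected.update(range(max(0, cds_start - 3), cds_start))
    in_cds = {p: i for i, p in enumerate(cpos)}
    pseudo = block.spec.gene_class == "pseudogene"

    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        i = int(i)
        if i in protected or seq[i] == "N":
            continue
        others = [c for c in "ACGT" if c != seq[i]]
        j = int(rng.integers(3))
        if i in in_cds and not pseudo:
            ci = in_cds[i]
            codon_slots = cpos[ci - ci % 3: ci - ci % 3 + 3]
            ok = []
            for cand in others:
                codon = "".join(
                    cand if p == i else seq[p] for p in codon_slots
                )
                if codon not in STOP_CODONS:
                    ok.append(cand)
            if not ok:
                continue
            seq[i] = ok[j % len(ok)]
        else:
            seq[i] = others[j]
    new_seq = "".join(seq)
    if pseudo:
        protein = block.protein  # truth stays the parent protein
    else:
        spliced = "".join(new_seq[s:e] for s, e in block.cds)
        protein = translate(spliced).rstrip("*")
        assert "*" not in protein
    return dataclasses.replace(block, seq=new_seq, protein=protein)


_COPY_SUFFIX = "abcdefghijklmnopqrstuvwxyz"


def evolve_species(
    cluster: tuple[Scaffold, list[PlantedLocus]],
    params: EvolutionParams,
    scaffold_id: str | None = None,
) -> EvolvedCluster:
    """Derive a second species from a planted cluster.

    Order of events: losses, duplications (tandem copies named ``<gene>a``,
    ``<gene>b``, ...), strand inversions, then substitutions applied
    independently to every surviving block and intergenic segment. Returns
    the derived scaffold, derived truth, and the source->derived ortholog
    table (lost genes map to an empty list).
    """
    scaffold, loci = cluster
    loci = sorted(loci, key=lambda l: l.span[0])
    params.validate([l.name for l in loci])
    rng = np.random.default_rng(params.rng_seed)
    dup = dict(params.duplication_events)
    lost = set(params.loss_events)
    inverted = set(params.inversion_events)

    # carve the source scaffold into intergenic pieces around locus spans
    intergenic: list[str] = []
    cursor = 0
    for locus in loci:
        intergenic.append(scaffold.seq[cursor:locus.span[0]])
        cursor = locus.span[1]
    intergenic.append(scaffold.seq[cursor:])

    new_blocks: list[LocusBlock] = []
    new_intergenic: list[str] = [intergenic[0]]
    orthologs: dict[str, list[str]] = {}
    for i, locus in enumerate(loci):
        block = locus.block
        if block is None:
            raise ValidationError(
                f"locus {locus.name} carries no block record; evolve_species "
                "requires generator-produced truth"
            )
        if locus.name in lost:
            orthologs[locus.name] = []
            new_intergenic[-1] += intergenic[i + 1]
            continue
        n_copies = dup.get(locus.name, 1)
        names = (
            [locus.name]
            if n_copies == 1
            else [locus.name + _COPY_SUFFIX[k] for k in range(n_copies)]
        )
        orthologs[locus.name] = names
        for k, name in enumerate(names):
            spec = dataclasses.replace(block.spec, name=name)
            if locus.name in inverted:
                spec = dataclasses.replace(
                    spec, strand="-" if spec.strand == "+" else "+"
                )
            b = dataclasses.replace(block, spec=spec)
            new_blocks.append(_mutate_block(b, params.substitution_rate, rng))
            if k < len(names) - 1:
                new_intergenic.append(random_dna(200, rng))
        new_intergenic.append(
            mutate_sequence(intergenic[i + 1], params.substitution_rate, rng)
        )
    new_intergenic[0] = mutate_sequence(
        new_intergenic[0], params.substitution_rate, rng
    )
    sid = scaffold_id or scaffold.id + "_derived"
    scaffold2, loci2 = _assemble(new_blocks, new_intergenic, sid)
    return EvolvedCluster(scaffold2, loci2, orthologs)


# ----------------------------------------------------- family expansions


def mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    out = list(protein)
    hit = rng.random(len(out)) < rate
    for i in np.flatnonzero(hit):
        others = [a for a in AA20 if a != out[i]]
        out[int(i)] = others[rng.integers(19)]
    return "".join(out)


def simulate_family_expansion(
    copies_per_clade,
    within_rate: float,
    between_rate: float,
    rng_seed: int = 0,
    n_clades: int = 2,
    protein_length: int = 120,
    clade_labels: tuple[str, ...] | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Independent gene-family expansions after an ancestral split.

    Each clade receives its own ancestor (the shared ancestor mutated at
    ``between_rate``) and then its copies as independent ``within_rate``
    mutants of that clade ancestor, so per-clade monophyly is true by
    construction. Returns (proteins, clade-of-protein).
    """
    if not (between_rate > within_rate > 0):
        raise ValidationError("require between_rate > within_rate > 0")
    if isinstance(copies_per_clade, int):
        copies = [copies_per_clade] * n_clades
    else:
        copies = list(copies_per_clade)
        n_clades = len(copies)
    if any(c <= 0 for c in copies):
        raise ValidationError("copies per clade must be positive")
    labels = clade_labels or tuple(
        "clade" + chr(ord("A") + i) for i in range(n_clades)
    )
    rng = np.random.default_rng(rng_seed)
    ancestor = "M" + "".join(rng.choice(_AA, size=protein_length - 1))
    proteins: dict[str, str] = {}
    clades: dict[str, str] = {}
    for lab, ncop in zip(labels, copies):
        clade_anc = mutate_protein(ancestor, between_rate, rng)
        for i in range(ncop):
            name = f"{lab}_{i + 1}"
            proteins[name] = mutate_protein(clade_anc, within_rate, rng)
            clades[name] = lab
    return proteins, clades


# ------------------------------------------------------------------ output


def extract_cds(scaffold: Scaffold, locus: PlantedLocus) -> str:
    """Spliced CDS on the coding strand, by truth coordinates."""
    concat = "".join(scaffold.seq[s:e] for s, e in locus.cds_coords)
    return concat if locus.strand == "+" else revcomp(concat)


def locus_protein_from_scaffold(scaffold: Scaffold, locus: PlantedLocus) -> str:
    return translate(extract_cds(scaffold, locus)).rstrip("*")


def _phases(cds_lengths: list[int]) -> list[int]:
    phases = []
    acc = 0
    for ln in cds_lengths:
        phases.append((3 - acc % 3) % 3)
        acc += ln
    return phases


def truth_gff3_features(
    scaffold: Scaffold, loci: list[PlantedLocus], source: str = "edckit_synthetic"
) -> list[Gff3Feature]:
    feats = []
    for locus in sorted(loci, key=lambda l: l.span[0]):
        gid = locus.name
        strand = locus.strand
        s, e = locus.span
        attrs = {"ID": gid, "gene_class": locus.gene.gene_class}
        if locus.lesions:
            attrs["lesions"] = ",".join(f"{k}:{p}" for k, p in locus.lesions)
        feats.append(
            Gff3Feature(scaffold.id, source, "gene", s + 1, e, ".", strand, ".", attrs)
        )
        feats.append(
            Gff3Feature(
                scaffold.id, source, "mRNA", s + 1, e, ".", strand, ".",
                {"ID": gid + ".t1", "Parent": gid},
            )
        )
        for (xs, xe) in locus.exon_coords:
            feats.append(
                Gff3Feature(
                    scaffold.id, source, "exon", xs + 1, xe, ".", strand, ".",
                    {"Parent": gid + ".t1"},
                )
            )
        cds = locus.cds_coords
        coding_order = cds if strand == "+" else list(reversed(cds))
        phases = _phases([e0 - s0 for s0, e0 in coding_order])
        for (cs, ce), ph in zip(coding_order, phases):
            feats.append(
                Gff3Feature(
                    scaffold.id, source, "CDS", cs + 1, ce, ".", strand, str(ph),
                    {"Parent": gid + ".t1"},
                )
            )
    return feats


def write_truth(outdir, scaffold: Scaffold, loci: list[PlantedLocus]) -> None:
    """FASTA + GFF3 + protein FASTA + TSV truth bundle for one species."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta({scaffold.id: scaffold.seq}, outdir / "genome.fasta")
    write_gff3(truth_gff3_features(scaffold, loci), outdir / "truth.gff3")
    write_fasta(
        {l.name: l.protein for l in sorted(loci, key=lambda l: l.span[0])},
        outdir / "proteins.fasta",
        descriptions={
            l.name: f"class={l.gene.gene_class} strand={l.strand}" for l in loci
        },
    )
    with open(outdir / "truth.tsv", "w") as f:
        f.write("gene\tclass\tstrand\tcds_coords\tprotein_length\tlesions\n")
        for l in sorted(loci, key=lambda x: x.span[0]):
            coords = ";".join(f"{s}-{e}" for s, e in l.cds_coords)
            lesions = ";".join(f"{k}:{p}" for k, p in l.lesions) or "-"
            f.write(
                f"{l.name}\t{l.gene.gene_class}\t{l.strand}\t{coords}"
                f"\t{len(l.protein)}\t{lesions}\n"
            )


def specs_from_yaml(path) -> list[GeneSpec]:
    """Load a gene-spec list from a YAML file (a list of mappings whose
    keys are GeneSpec field names)."""
    import yaml

    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, list):
        raise ValidationError("spec file must contain a list of gene specs")
    known = {f.name for f in dataclasses.fields(GeneSpec)}
    specs = []
    for item in data:
        unknown = set(item) - known
        if unknown:
            raise ValidationError(
                f"unknown GeneSpec keys {sorted(unknown)} in {item.get('name')}"
            )
        if "lesion_types" in item:
            item["lesion_types"] = tuple(item["lesion_types"])
        spec = GeneSpec(**item)
        spec.validate()
        specs.append(spec)
    return specs


def specs_to_yaml(specs: list[GeneSpec], path) -> None:
    import yaml

    data = []
    for s in specs:
        d = dataclasses.asdict(s)
        d["lesion_types"] = list(d["lesion_types"])
        data.append(d)
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=False)


def write_ortholog_table(orthologs: dict[str, list[str]], path) -> None:
    with open(path, "w") as f:
        f.write("source_gene\tderived_genes\trelation\n")
        for src in sorted(orthologs):
            der = orthologs[src]
            rel = "lost" if not der else ("1:1" if len(der) == 1 else f"1:{len(der)}")
            f.write(f"{src}\t{','.join(der) or '-'}\t{rel}\n")
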