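"""Characterization of predicted EDC proteins.

Covers the feature stack used to classify EDC gene products: amino-acid
composition (ProtParam-style percentages), compositional-bias labels
(glycine/serine/proline/cysteine enrichment), tandem amino-acid repeat
detection, position-specific scoring-matrix (PSSM) construction and
scanning for the 34-residue corneous beta-protein motif, CBP typing by
motif count and amino-terminal arm length, and family-specific terminal
motif detection (e.g. the cornulin / scaffoldin-1 carboxy-terminal motifs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import AA20
from .synthetic import beta_seed_alignment

_AA_IDX = {a: i for i, a in enumerate(AA20)}


# ------------------------------------------------------------- composition


@dataclass
class CompositionProfile:
    """Per-residue percentages over the 20 standard residues."""

    percent: dict[str, float]
    length: int

    def __getitem__(self, residue: str) -> float:
        return self.percent[residue]

    @property
    def total(self) -> float:
        return sum(self.percent.values())


def composition(protein: str) -> CompositionProfile:
    """Percentage of each standard residue, 100 * count / length.

    X (and any other non-standard letter) is excluded from the denominator.
    """
    if not protein:
        raise ValueError("cannot profile an empty protein")
    counts = {a: 0 for a in AA20}
    n = 0
    for c in protein.upper():
        if c in counts:
            counts[c] += 1
            n += 1
    if n == 0:
        raise ValueError("protein contains no standard residues")
    return CompositionProfile(
        percent={a: 100.0 * counts[a] / n for a in AA20}, length=len(protein)
    )


DEFAULT_BIAS_THRESHOLDS = {
    "single": 15.0,  # any single residue at or above this is X-rich
    "C": 10.0,       # cysteine flags at a lower bar
    "GS": 40.0,      # combined glycine+serine
}


def bias_class(
    profile: CompositionProfile,
    thresholds: dict[str, float] | None = None,
) -> set[str]:
    """Compositional-bias labels; thresholds are inclusive at the boundary."""
    th = dict(DEFAULT_BIAS_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    labels = set()
    for a in AA20:
        cutoff = th.get(a, th["single"])
        if profile.percent[a] >= cutoff:
            labels.add(f"{a}-rich")
    if profile.percent["G"] + profile.percent["S"] >= th["GS"]:
        labels.add("GS-rich")
    return labels


# ------------------------------------------------------------ tandem repeats


@dataclass
class RepeatCall:
    """A maximal tandem array of an amino-acid motif."""

    motif: str
    count: int
    span: tuple[int, int]
    max_mismatches_per_unit: int
    partial_tail: bool = False

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0]


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_tandem_repeats(
    protein: str,
    motif_len_range: tuple[int, int] = (2, 12),
    max_mismatches_per_unit: int = 1,
) -> list[RepeatCall]:
    """Maximal tandem repeat arrays, best call first.

    A unit copy counts if it differs from the array's first unit by at most
    ``max_mismatches_per_unit`` substitutions. "Best" means greatest copy
    count, ties broken by longest span, then leftmost start, then shortest
    motif. A trailing partial copy covering at least half the motif is
    flagged, not counted.
    """
    lo, hi = motif_len_range
    if lo < 2 or hi > 30 or lo > hi:
        raise ValueError("motif_len_range must lie within [2, 30]")
    L = len(protein)
    raw: list[RepeatCall] = []
    for m in range(lo, hi + 1):
        for i in range(0, L - 2 * m + 1):
            unit = protein[i:i + m]
            k = i
            count = 0
            while k + m <= L and _mismatches(protein[k:k + m], unit) <= max_mismatches_per_unit:
                count += 1
                k += m
            if count < 2:
                continue
            tail = protein[k:k + m]
            half = (m + 1) // 2
            partial = (
                len(tail) >= half
                and _mismatches(tail, unit[: len(tail)]) <= max_mismatches_per_unit
            )
            raw.append(
                RepeatCall(unit, count, (i, k), max_mismatches_per_unit, partial)
            )
    raw.sort(key=lambda c: (-c.count, -c.span_length, c.span[0], len(c.motif)))
    kept: list[RepeatCall] = []
    for c in raw:
        dominated = any(
            d.span[0] <= c.span[0] and c.span[1] <= d.span[1] and d.count >= c.count
            for d in kept
        )
        if not dominated:
            kept.append(c)
    return kept


# -------------------------------------------------------------------- PSSM


@dataclass
class PSSM:
    """Position-specific scoring matrix, log2-odds over a background."""

    matrix: np.ndarray  # width x 20
    background: np.ndarray
    threshold: float
    name: str = "pssm"

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(AA20[j] for j in self.matrix.argmax(axis=1))

    def self_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def score_at(self, protein: str, start: int) -> float:
        s = 0.0
        for k in range(self.width):
            j = _AA_IDX.get(protein[start + k])
            if j is not None:  # X and friends contribute 0
                s += self.matrix[k, j]
        return s

    def scan(self, protein: str) -> list[tuple[int, float]]:
        """(start, score) for every window, in order."""
        return [
            (i, self.score_at(protein, i))
            for i in range(0, len(protein) - self.width + 1)
        ]


def build_pssm(
    rows: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    threshold_fraction: float = 0.6,
    name: str = "pssm",
) -> PSSM:
    """Log-odds PSSM from a gapless alignment.

    The reporting threshold defaults to ``threshold_fraction`` of the
    consensus self-score.
    """
    if not rows:
        raise ValueError("seed alignment is empty")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("seed alignment is ragged: all rows must share one length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = background if background is not None else np.full(20, 1 / 20)
    counts = np.zeros((width, 20))
    for r in rows:
        for k, c in enumerate(r.upper()):
            j = _AA_IDX.get(c)
            if j is None:
                raise ValueError(f"non-standard residue {c!r} in seed alignment")
            counts[k, j] += 1
    # pseudocount applied to per-column residue proportions, so the matrix
    # is invariant to duplicating the seed rows
    props = counts / len(rows)
    freqs = (props + pseudocount * bg) / (1.0 + pseudocount)
    matrix = np.log2(freqs / bg)
    pssm = PSSM(matrix=matrix, background=bg, threshold=0.0, name=name)
    pssm.threshold = threshold_fraction * pssm.self_score()
    return pssm


def build_beta_pssm(
    seed_alignment: list[str] | None = None,
    pseudocount: float = 0.5,
    threshold_fraction: float = 0.6,
) -> PSSM:
    """PSSM for the 34-residue beta-sheet motif of corneous beta-proteins."""
    rows = seed_alignment if seed_alignment is not None else list(
        beta_seed_alignment().values()
    )
    if any(len(r) != 34 for r in rows):
        raise ValueError("beta-motif seed alignment must have exactly 34 columns")
    return build_pssm(
        rows, pseudocount, threshold_fraction=threshold_fraction, name="beta34"
    )


# -------------------------------------------------------------- CBP typing


@dataclass
class CbpCall:
    """Motif content and type assignment for one candidate CBP."""

    protein_id: str
    n_motifs: int
    motif_spans: list[tuple[int, int]] = field(default_factory=list)
    nterm_arm: int = 0
    cbp_type: str = "not_cbp"  # 4B | type1 | type2 | not_cbp | unclassified
    anomalous: bool = False


def scan_cbp(
    protein: str,
    pssm: PSSM,
    protein_id: str = "protein",
    arm_cutoff: int = 15,
) -> CbpCall:
    """Detect beta motifs and assign the CBP type.

    Motif placements are greedy best-first and non-overlapping. Types:
    4 motifs -> 4B; 1 motif with an amino-terminal arm of at most
    ``arm_cutoff`` residues -> type1, longer arm -> type2; 0 motifs ->
    not_cbp; 2-3 motifs is flagged anomalous and left unclassified.
    """
    hits = [
        (start, score)
        for start, score in (pssm.scan(protein) if len(protein) >= pssm.width else [])
        if score >= pssm.threshold
    ]
    hits.sort(key=lambda h: (-h[1], h[0]))
    spans: list[tuple[int, int]] = []
    for start, _score in hits:
        span = (start, start + pssm.width)
        if all(span[1] <= s or span[0] >= e for s, e in spans):
            spans.append(span)
    spans.sort()
    n = len(spans)
    call = CbpCall(protein_id=protein_id, n_motifs=n, motif_spans=spans)
    if n == 0:
        call.cbp_type = "not_cbp"
        return call
    call.nterm_arm = spans[0][0]
    if n == 4:
        call.cbp_type = "4B"
    elif n == 1:
        call.cbp_type = "type1" if call.nterm_arm <= arm_cutoff else "type2"
    else:
        call.cbp_type = "unclassified"
        call.anomalous = True
    return call


# ------------------------------------------------------- terminal motifs


@dataclass
class TerminalMotifCall:
    present: bool
    score: float
    span: tuple[int, int] | None = None


def detect_terminal_motif(
    protein: str,
    family_profile: PSSM,
    terminus: str = "C",
    window: int = 50,
) -> TerminalMotifCall:
    """Scan only the terminal window for a family-specific motif.

    Used for the carboxy-terminal motifs that distinguish cornulin and
    scaffoldin-1 from scaffoldin-2: the motif must lie entirely within the
    last (or first) ``window`` residues.
    """
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    if window > len(protein):
        raise ValueError("window exceeds protein length")
    w = family_profile.width
    if w > window:
        raise ValueError("profile is wider than the terminal window")
    offset = 0 if terminus == "N" else len(protein) - window
    region = protein[offset:offset + window]
    best = None
    for i in range(0, len(region) - w + 1):
        score = family_profile.score_at(region, i)
        if best is None or score > best[1]:
            best = (i, score)
    if best is None:
        return TerminalMotifCall(False, float("-inf"))
    start = offset + best[0]
    return TerminalMotifCall(
        present=best[1] >= family_profile.threshold,
        score=best[1],
        span=(start, start + w),
    )


# ----------------------------------------------------------- feature table


def feature_table(
    proteins: dict[str, str],
    beta_pssm: PSSM | None = None,
    terminal_profiles: dict[str, PSSM] | None = None,
    bias_thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One row per protein: length, 20 composition columns, bias labels,
    top repeat motif and count, beta-motif count, CBP type, terminal flags."""
    pssm = beta_pssm or build_beta_pssm()
    rows = []
    for pid, seq in proteins.items():
        prof = composition(seq)
        labels = sorted(bias_class(prof, bias_thresholds))
        repeats = find_tandem_repeats(seq)
        top = repeats[0] if repeats else None
        call = scan_cbp(seq, pssm, protein_id=pid)
        row = {
            "protein_id": pid,
            "length": len(seq),
            **{f"pct_{a}": round(prof.percent[a], 2) for a in AA20},
            "bias_labels": ",".join(labels) or "-",
            "top_repeat_motif": top.motif if top else "-",
            "top_repeat_count": top.count if top else 0,
            "n_beta_motifs": call.n_motifs,
            "cbp_type": call.cbp_type,
        }
        for fam, profile in (terminal_profiles or {}).items():
            try:
                hit = detect_terminal_motif(seq, profile)
                row[f"cterm_{fam}"] = int(hit.present)
            except ValueError:
                row[f"cterm_{fam}"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------- PSSM text format


def write_pssm(pssm: PSSM, path) -> None:
    """Plain-text position x residue matrix (MEME-like)."""
    with open(path, "w") as f:
        f.write(f"# PSSM {pssm.name}\n")
        f.write(f"width {pssm.width}\n")
        f.write(f"threshold {pssm.threshold:.6f}\n")
        f.write("background " + " ".join(f"{x:.6f}" for x in pssm.background) + "\n")
        f.write("residues " + " ".join(AA20) + "\n")
        for k in range(pssm.width):
            f.write(" ".join(f"{x:.6f}" for x in pssm.matrix[k]) + "\n")


def read_pssm(path) -> PSSM:
    rows = []
    meta: dict[str, str] = {}
    name = "pssm"
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                name = line.split()[-1]
                continue
            key = line.split()[0]
            if key in ("width", "threshold", "background", "residues"):
                meta[key] = line.partition(" ")[2]
            else:
                rows.append([float(x) for x in line.split()])
    matrix = np.array(rows)
    return PSSM(
        matrix=matrix,
        background=np.array([float(x) for x in meta["background"].split()]),
        threshold=float(meta["threshold"]),
        name=name,
    )
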