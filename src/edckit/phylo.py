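"""Family alignment, distance trees, bootstrap and monophyly tests.

The question this module answers for EDC gene families is a clade-membership
question: did a family (say, the small proline-rich EDSPRs) expand before or
after two lineages split? That is decided by whether each species' paralogs
are monophyletic, with bootstrap support on the defining edge.

Machinery: a deterministic progressive aligner (p-distance neighbor-joining
guide tree, profile-profile global alignment with affine gaps), pairwise
distances under a Poisson correction or the empirical JTT model (maximum
likelihood, 1-D optimization), neighbor joining with a lexicographic
tie-break, and nonparametric bootstrap over alignment columns. Full
maximum-likelihood tree search is deliberately out of scope: at the
divergences involved, distance NJ recovers the clade structure the
monophyly verdicts rest on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import align
from .seqs import AA20

# ---------------------------------------------------------------- alignment


@dataclass
class Alignment:
    """Rows of equal length; ungapping a row recovers the input sequence."""

    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace("-", "")

    def columns(self, keep: list[int]) -> "Alignment":
        return Alignment(
            {rid: "".join(s[c] for c in keep) for rid, s in self.rows.items()}
        )

    def write_fasta(self, path) -> None:
        with open(path, "w") as f:
            for rid, s in self.rows.items():
                f.write(f">{rid}\n{s}\n")

    def write_phylip(self, path) -> None:
        with open(path, "w") as f:
            f.write(f" {len(self.rows)} {self.length}\n")
            for rid, s in self.rows.items():
                f.write(f"{rid}  {s}\n")

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        rows: dict[str, str] = {}
        rid = None
        with open(path) as f:
            for line in f:
                line = line.strip()
                if line.startswith(">"):
                    rid = line[1:].split()[0]
                    rows[rid] = ""
                elif rid is not None:
                    rows[rid] += line
        return cls(rows)

    @classmethod
    def read_phylip(cls, path) -> "Alignment":
        rows: dict[str, str] = {}
        with open(path) as f:
            f.readline()
            for line in f:
                if line.strip():
                    name, seq = line.split(None, 1)
                    rows[name] = seq.strip()
        return cls(rows)


def unambiguous_columns(
    alignment: Alignment,
    max_gap_fraction: float = 0.2,
    min_agreement: float = 0.5,
) -> list[int]:
    """Columns considered unambiguously aligned: gap fraction below
    ``max_gap_fraction`` and the modal residue at or above ``min_agreement``
    of non-gap rows. A stand-in for the manual column selection that
    published motif phylogenies rely on; an explicit mask can be supplied
    instead wherever this is used."""
    keep = []
    rows = list(alignment.rows.values())
    n = len(rows)
    for c in range(alignment.length):
        col = [r[c] for r in rows]
        gaps = col.count("-")
        if gaps / n >= max_gap_fraction and gaps > 0:
            continue
        residues = [x for x in col if x != "-"]
        if not residues:
            continue
        modal = max(set(residues), key=residues.count)
        if residues.count(modal) / len(residues) >= min_agreement:
            keep.append(c)
    return keep


# ---------------------------------------------------------- progressive MSA

_B62_20 = None


def _blosum20() -> np.ndarray:
    global _B62_20
    if _B62_20 is None:
        full = align.load_matrix()
        idx = [align._AA_INDEX[a] for a in AA20]
        _B62_20 = full[np.ix_(idx, idx)]
    return _B62_20


def _profile(rows: list[str]) -> np.ndarray:
    idx = {a: i for i, a in enumerate(AA20)}
    L = len(rows[0])
    P = np.zeros((L, 20))
    for r in rows:
        for c, ch in enumerate(r):
            j = idx.get(ch)
            if j is not None:
                P[c, j] += 1
    P /= len(rows)
    return P


def progressive_align(
    sequences: dict[str, str],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Progressive multiple alignment.

    Guide tree: neighbor joining on p-distances from pairwise global
    alignments. Merging: profile-profile global alignment with affine gaps,
    expected BLOSUM62 score between columns. Deterministic: sequences are
    processed in lexicographic id order, so input order does not matter.
    """
    if len(sequences) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = sorted(sequences)
    if len(ids) == 2:
        a, b = ids
        _, ga, gb = align.needleman_wunsch(
            sequences[a], sequences[b], None, gap_open, gap_extend
        )
        return Alignment({a: ga, b: gb})
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ga, gb = align.needleman_wunsch(
                sequences[ids[i]], sequences[ids[j]], None, gap_open, gap_extend
            )
            ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
            D[i, j] = D[j, i] = 1.0 - ident / len(ga)
    order = _merge_order(D, ids)
    clusters: dict[str, dict[str, str]] = {rid: {rid: sequences[rid]} for rid in ids}
    matrix = _blosum20()
    for left, right, new in order:
        c1, c2 = clusters.pop(left), clusters.pop(right)
        p1 = _profile(list(c1.values()))
        p2 = _profile(list(c2.values()))
        sim = p1 @ matrix @ p2.T
        path = align.global_profile_path(sim, gap_open, gap_extend)
        merged: dict[str, str] = {}
        for rid, row in c1.items():
            merged[rid] = "".join(row[i] if i >= 0 else "-" for i, _ in path)
        for rid, row in c2.items():
            merged[rid] = "".join(row[j] if j >= 0 else "-" for _, j in path)
        clusters[new] = merged
    final = clusters.popitem()[1]
    return Alignment({rid: final[rid] for rid in ids})


def _merge_order(D: np.ndarray, ids: list[str]) -> list[tuple[str, str, str]]:
    """Agglomeration order from a guide NJ run (join order of the NJ loop)."""
    labels = list(ids)
    D = D.copy()
    order = []
    k = 0
    while len(labels) > 1:
        n = len(labels)
        if n == 2:
            i, j = 0, 1
        else:
            r = D.sum(axis=1)
            best = None
            for i0 in range(n):
                for j0 in range(i0 + 1, n):
                    q = (n - 2) * D[i0, j0] - r[i0] - r[j0]
                    if best is None or q < best[0] - 1e-12:
                        best = (q, i0, j0)
            _, i, j = best
        new = f"__node{k}__"
        k += 1
        order.append((labels[i], labels[j], new))
        dnew = [(D[i, t] + D[j, t] - D[i, j]) / 2 for t in range(n) if t not in (i, j)]
        keep = [t for t in range(n) if t not in (i, j)]
        labels = [labels[t] for t in keep] + [new]
        D2 = np.zeros((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D2[n - 2, : n - 2] = dnew
        D2[: n - 2, n - 2] = dnew
        D = D2
    return order


# ---------------------------------------------------------------- distances

POISSON_CAP = 10.0


@lru_cache(maxsize=1)
def _jtt() -> tuple[np.ndarray, np.ndarray]:
    """(equilibrium frequencies, symmetric exchangeabilities) of JTT."""
    text = resources.files("edckit.data").joinpath("jtt.txt").read_text()
    freqs: list[float] = []
    exch: list[float] = []
    section = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line
            continue
        vals = [float(x) for x in line.split()]
        if section == "[frequencies]":
            freqs.extend(vals)
        else:
            exch.extend(vals)
    pi = np.array(freqs)
    S = np.zeros((20, 20))
    k = 0
    for j in range(19):
        for i in range(j + 1, 20):
            S[i, j] = S[j, i] = exch[k]
            k += 1
    return pi, S


@lru_cache(maxsize=1)
def _jtt_eigen():
    pi, S = _jtt()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    Q = Q / mu  # one expected substitution per unit time
    sp = np.sqrt(pi)
    B = (Q * sp[:, None]) / sp[None, :]
    lam, U = np.linalg.eigh((B + B.T) / 2)
    left = U.T * sp[None, :]
    right = U / sp[:, None]
    return pi, lam, right, left


def jtt_stationary() -> np.ndarray:
    return _jtt_eigen()[0].copy()


def jtt_transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt) under the JTT model, Q scaled to 1 sub/site/unit."""
    _, lam, right, left = _jtt_eigen()
    P = (right * np.exp(lam * t)[None, :]) @ left
    return np.clip(P, 1e-300, None)


def _pairwise_sites(row_a: str, row_b: str) -> tuple[int, int, list[tuple[int, int]]]:
    """Pairwise-deletion comparison; returns (compared, mismatches, pairs)."""
    idx = {a: i for i, a in enumerate(AA20)}
    compared = 0
    mism = 0
    pairs = []
    for x, y in zip(row_a, row_b):
        i, j = idx.get(x), idx.get(y)
        if i is None or j is None:
            continue
        compared += 1
        if i != j:
            mism += 1
        pairs.append((i, j))
    return compared, mism, pairs


def _jtt_ml_distance(pairs: list[tuple[int, int]]) -> float:
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    pi = jtt_stationary()
    if np.all(ii == jj):
        return 0.0

    def neg_loglik(t):
        P = jtt_transition_matrix(t)
        return -np.log(pi[ii] * P[ii, jj]).sum()

    res = minimize_scalar(neg_loglik, bounds=(1e-6, 20.0), method="bounded")
    return float(res.x)


def distance_matrix(alignment: Alignment, model: str = "poisson_corrected") -> pd.DataFrame:
    """Pairwise distances with pairwise deletion of gap columns.

    poisson_corrected: d = -ln(1 - p) for p-distance p (capped with a
    warning when p >= 1). jtt_like: maximum-likelihood distance under the
    shipped JTT matrix (1-D optimization).
    """
    if model not in ("poisson_corrected", "jtt_like"):
        raise ValueError(f"unknown model {model!r}")
    ids = alignment.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 rows")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared, mism, pairs = _pairwise_sites(
                alignment.rows[ids[i]], alignment.rows[ids[j]]
            )
            if compared == 0:
                d = POISSON_CAP
            elif model == "poisson_corrected":
                p = mism / compared
                if p >= 1.0:
                    warnings.warn(
                        f"p-distance {p:.3f} >= 1 between {ids[i]} and {ids[j]}; "
                        f"capping at {POISSON_CAP}"
                    )
                    d = POISSON_CAP
                else:
                    d = -np.log(1.0 - p)
            else:
                d = _jtt_ml_distance(pairs)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=ids, columns=ids)


# ----------------------------------------------------------------- NJ trees


def nj_tree(matrix: pd.DataFrame) -> dendropy.Tree:
    """Standard neighbor joining; deterministic (lowest (i, j) pair wins
    Q-matrix ties). Negative branch lengths are clamped to zero. On additive
    matrices the tree's path-length metric reproduces the input exactly."""
    ids = list(matrix.index)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = matrix.to_numpy(dtype=float).copy()
    nodes = [f"'{t}'" if " " in t else t for t in ids]
    while len(nodes) > 2:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.12g},{nodes[j]}:{lj:.12g})"
        dnew = [(D[i, t] + D[j, t] - D[i, j]) / 2 for t in range(n) if t not in (i, j)]
        keep = [t for t in range(n) if t not in (i, j)]
        nodes = [nodes[t] for t in keep] + [new]
        D2 = np.zeros((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D2[n - 2, : n - 2] = dnew
        D2[: n - 2, n - 2] = dnew
        D = D2
    newick = f"({nodes[0]}:{max(D[0, 1], 0.0):.12g},{nodes[1]}:0)"
    tree = dendropy.Tree.get(
        data=newick + ";", schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(M, index=labels, columns=labels)


def tree_splits(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions as leaf-label frozensets (child side)."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            out[side] = node
    return out


def _canonical_splits(tree: dendropy.Tree) -> set[frozenset]:
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_leaves)
    canon = set()
    for side in tree_splits(tree):
        canon.add(side if ref not in side else all_leaves - side)
    return canon


# ---------------------------------------------------------------- bootstrap


@dataclass
class FamilyTree:
    """Tree + per-internal-edge bootstrap supports (percent) + provenance."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_replicates: int = 0
    degenerate: bool = False
    model: str = "poisson_corrected"

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def bootstrap_support(
    alignment: Alignment,
    model: str = "poisson_corrected",
    n_replicates: int = 100,
    rng_seed: int = 0,
) -> FamilyTree:
    """NJ tree with column-resampling bootstrap supports.

    Supports are the percentage of replicates whose NJ tree contains each
    internal split of the tree built from the full alignment; they are
    written onto the internal node labels. An alignment with no variable
    columns yields a degenerate star-like signal: the tree is returned
    flagged degenerate with all supports zero.
    """
    if alignment.length < 2:
        raise ValueError("alignment must have at least 2 columns")
    D = distance_matrix(alignment, model)
    tree = nj_tree(D)
    ref = min(alignment.ids)
    all_leaves = frozenset(alignment.ids)

    def canon(side: frozenset) -> frozenset:
        return side if ref not in side else all_leaves - side

    targets = {canon(s): node for s, node in tree_splits(tree).items()}
    counts = {s: 0 for s in targets}
    variable = any(
        len({r[c] for r in alignment.rows.values()}) > 1
        for c in range(alignment.length)
    )
    rng = np.random.default_rng(rng_seed)
    if variable:
        for _ in range(n_replicates):
            cols = rng.integers(0, alignment.length, size=alignment.length)
            rep = alignment.columns([int(c) for c in cols])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rd = distance_matrix(rep, model)
            rsplits = _canonical_splits(nj_tree(rd))
            for s in counts:
                if s in rsplits:
                    counts[s] += 1
    supports = {
        s: (100.0 * c / n_replicates if variable else 0.0)
        for s, c in counts.items()
    }
    for s, node in targets.items():
        node.label = f"{supports[s]:g}"
    return FamilyTree(
        tree=tree,
        supports=supports,
        n_replicates=n_replicates,
        degenerate=not variable,
        model=model,
    )


# ---------------------------------------------------------------- monophyly


def test_monophyly(ft: FamilyTree | dendropy.Tree, leaf_subset) -> dict:
    """Is ``leaf_subset`` a clade (some edge bipartitions leaves into
    exactly this subset vs the rest)? Returns the defining edge's bootstrap
    support when available."""
    tree = ft.tree if isinstance(ft, FamilyTree) else ft
    supports = ft.supports if isinstance(ft, FamilyTree) else {}
    subset = frozenset(leaf_subset)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if not subset <= all_leaves:
        raise ValueError(f"unknown leaves: {sorted(subset - all_leaves)}")
    if len(subset) < 2 or len(subset) >= len(all_leaves):
        raise ValueError("leaf subset must be non-trivial (>=2 and < all leaves)")
    ref = min(all_leaves)
    canon_subset = subset if ref not in subset else all_leaves - subset
    for side in tree_splits(tree):
        canon = side if ref not in side else all_leaves - side
        if canon == canon_subset:
            support = supports.get(canon)
            return {"monophyletic": True, "support": support}
    # the complement of a size-(n-1) subset is a single leaf: always a clade
    if len(subset) == len(all_leaves) - 1:
        return {"monophyletic": True, "support": None}
    return {"monophyletic": False, "support": None}
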