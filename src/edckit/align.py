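"""Affine-gap pairwise alignment kernels.

The package's homology searches all funnel through two dynamic-programming
kernels (local Smith-Waterman and global Needleman-Wunsch), jit-compiled with
numba and operating on a precomputed position-by-position similarity matrix.
That lets the same kernels serve residue-vs-residue alignment (similarity =
substitution-matrix lookup) and profile-vs-profile alignment during
progressive multiple alignment (similarity = expected substitution score).

Gap convention: a gap of length k costs ``gap_open + k * gap_extend``
(the NCBI convention, so the BLOSUM62 11/1 defaults mean a 1-column gap
costs 12).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqs import AA_EXTENDED, sanitize_protein

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

#: score assigned to any pairing with a stop codon; low enough that no
#: alignment ever crosses an in-frame stop
STOP_PENALTY = -1000.0


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return a len(AA_EXTENDED) x len(AA_EXTENDED) float score matrix."""
    m = substitution_matrices.load(name)
    k = len(AA_EXTENDED)
    out = np.zeros((k, k), dtype=np.float64)
    for i, a in enumerate(AA_EXTENDED):
        for j, b in enumerate(AA_EXTENDED):
            if a == "*" or b == "*":
                out[i, j] = STOP_PENALTY
            else:
                try:
                    out[i, j] = m[a, b]
                except KeyError:
                    out[i, j] = m["X", "X"]
    return out


_AA_INDEX = {c: i for i, c in enumerate(AA_EXTENDED)}


def encode(protein: str) -> np.ndarray:
    """Encode a protein string as indices into the scoring alphabet."""
    idx = _AA_INDEX
    x = idx["X"]
    return np.array([idx.get(c, x) for c in protein], dtype=np.int64)


def similarity(a: str, b: str, matrix: np.ndarray | None = None) -> np.ndarray:
    """Precomputed similarity matrix sim[i, j] = score(a[i], b[j])."""
    if matrix is None:
        matrix = load_matrix()
    ea, eb = encode(sanitize_protein(a)), encode(sanitize_protein(b))
    return matrix[np.ix_(ea, eb)]


NEG = -1.0e18


@njit(cache=True)
def _local_kernel(sim, gap_open, gap_extend):  # pragma: no cover - jit
    n, m = sim.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop 1 diag 2 up(E) 3 left(F)
    pe = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 => E extended
    pf = np.zeros((n + 1, m + 1), dtype=np.int8)
    oe = gap_open + gap_extend
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - oe
            e_ext = E[i - 1, j] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i, j - 1] - oe
            f_ext = F[i, j - 1] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
            d = H[i - 1, j - 1] + sim[i - 1, j - 1]
            h = 0.0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, ptr, pe, pf, best, bi, bj


@njit(cache=True)
def _global_kernel(sim, gap_open, gap_extend):  # pragma: no cover - jit
    n, m = sim.shape
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    pe = np.zeros((n + 1, m + 1), dtype=np.int8)
    pf = np.zeros((n + 1, m + 1), dtype=np.int8)
    oe = gap_open + gap_extend
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        E[i, 0] = -(gap_open + i * gap_extend)
        H[i, 0] = E[i, 0]
        ptr[i, 0] = 2
        pe[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        F[0, j] = -(gap_open + j * gap_extend)
        H[0, j] = F[0, j]
        ptr[0, j] = 3
        pf[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - oe
            e_ext = E[i - 1, j] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i, j - 1] - oe
            f_ext = F[i, j - 1] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
            d = H[i - 1, j - 1] + sim[i - 1, j - 1]
            h = d
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
    return H, ptr, pe, pf


def _traceback(ptr, pe, pf, i, j, local: bool):
    """Recover the aligned-pair path ending at (i, j); returns list of
    (qi, tj) with -1 marking a gap, ordered 5'->3'."""
    path = []
    state = 0  # 0 in H, 1 in E, 2 in F
    while i > 0 or j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                if local:
                    break
                # global: only at origin
                break
            if p == 1:
                path.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 3
        elif state == 1:
            path.append((i - 1, -1))
            ext = pe[i, j]
            i -= 1
            state = 1 if ext else 0
        else:
            path.append((-1, j - 1))
            ext = pf[i, j]
            j -= 1
            state = 3 if ext else 0
    path.reverse()
    return path


@dataclass
class LocalAlignment:
    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    path: list  # list of (qi, tj) pairs, -1 = gap
    n_identical: int = 0
    n_columns: int = 0

    @property
    def identity(self) -> float:
        return self.n_identical / self.n_columns if self.n_columns else 0.0


def smith_waterman(
    query: str,
    target: str,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> LocalAlignment:
    """Best local alignment of two protein strings."""
    sim = similarity(query, target, matrix)
    return _best_local(sim, query, target, gap_open, gap_extend)


def _best_local(sim, query, target, gap_open, gap_extend) -> LocalAlignment:
    H, ptr, pe, pf, best, bi, bj = _local_kernel(sim, gap_open, gap_extend)
    if best <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, [])
    path = _traceback(ptr, pe, pf, bi, bj, local=True)
    qpos = [p[0] for p in path if p[0] >= 0]
    tpos = [p[1] for p in path if p[1] >= 0]
    nid = sum(
        1
        for qi, tj in path
        if qi >= 0 and tj >= 0 and query[qi] == target[tj]
    )
    return LocalAlignment(
        float(best), qpos[0], qpos[-1] + 1, tpos[0], tpos[-1] + 1,
        path, nid, len(path),
    )


def local_alignments(
    query: str,
    target: str,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    min_score: float = 0.0,
    max_hits: int = 32,
) -> list[LocalAlignment]:
    """Non-overlapping local alignments, best first.

    The optimal alignment is found, its target span is masked out, and the
    DP is rerun until the best score drops below ``min_score``. The top hit
    is therefore always the exact Smith-Waterman optimum.
    """
    if matrix is None:
        matrix = load_matrix()
    sim = similarity(query, target, matrix)
    hits: list[LocalAlignment] = []
    for _ in range(max_hits):
        aln = _best_local(sim, query, target, gap_open, gap_extend)
        if aln.score < min_score or aln.n_columns == 0:
            break
        hits.append(aln)
        sim[:, aln.t_start:aln.t_end] = STOP_PENALTY
    return hits


def needleman_wunsch(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, str, str]:
    """Global alignment; returns (score, gapped_a, gapped_b)."""
    sim = similarity(a, b, matrix)
    H, ptr, pe, pf = _global_kernel(sim, gap_open, gap_extend)
    path = _traceback(ptr, pe, pf, len(a), len(b), local=False)
    ga = "".join(a[qi] if qi >= 0 else "-" for qi, _ in path)
    gb = "".join(b[tj] if tj >= 0 else "-" for _, tj in path)
    return float(H[len(a), len(b)]), ga, gb


def global_profile_path(
    sim: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> list:
    """Global alignment path over a precomputed profile-profile similarity
    matrix; used by the progressive aligner."""
    H, ptr, pe, pf = _global_kernel(sim, gap_open, gap_extend)
    return _traceback(ptr, pe, pf, sim.shape[0], sim.shape[1], local=False)
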