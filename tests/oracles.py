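"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately written as plain, slow, transparent code
with no dependence on the package's own algorithmic paths.
"""

from __future__ import annotations


def sw_score(query: str, target: str, score, gap_open: float, gap_extend: float) -> float:
    """Full affine-gap Smith-Waterman score, textbook three-matrix DP.

    ``score(a, b)`` is a callable; a gap of length k costs
    gap_open + k * gap_extend.
    """
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    oe = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Ei1 = E[i], E[i - 1]
        Fi = F[i]
        qi = query[i - 1]
        for j in range(1, m + 1):
            e = max(Hi1[j] - oe, Ei1[j] - gap_extend)
            f = max(Hi[j - 1] - oe, Fi[j - 1] - gap_extend)
            h = max(0.0, Hi1[j - 1] + score(qi, target[j - 1]), e, f)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > best:
                best = h
    return best


GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def orf_bruteforce(seq: str, min_length: int) -> list[tuple[int, int]]:
    """All maximal ATG..stop spans in the 3 forward frames of ``seq``.

    Maximal: the ORF starts at the first ATG after the previous in-frame
    stop. Intervals include the stop codon; min_length counts residues
    excluding the stop.
    """
    out = []
    for f in range(3):
        start = None
        for p in range(f, len(seq) - 2, 3):
            codon = seq[p:p + 3]
            aa = GENETIC_CODE.get(codon)
            if aa == "*":
                if start is not None and (p - start) // 3 >= min_length:
                    out.append((start, p + 3))
                start = None
            elif codon == "ATG" and start is None:
                start = p
    return sorted(out)


def repeat_bruteforce(protein: str, lo: int, hi: int, max_mm: int):
    """Best tandem array over all motif lengths and phases.

    Returns (count, span_len, start, motif) maximizing count, then span
    length, then leftmost start, then shortest motif — or None.
    """
    best = None
    L = len(protein)
    for m in range(lo, hi + 1):
        for i in range(0, L - 2 * m + 1):
            unit = protein[i:i + m]
            k = i
            count = 0
            while k + m <= L:
                mm = sum(1 for a, b in zip(unit, protein[k:k + m]) if a != b)
                if mm > max_mm:
                    break
                count += 1
                k += m
            if count >= 2:
                cand = (count, k - i, i, unit)
                if best is None or (
                    (-cand[0], -cand[1], cand[2], len(cand[3]))
                    < (-best[0], -best[1], best[2], len(best[3]))
                ):
                    best = cand
    return best


def rbh_bruteforce(scores) -> list[tuple[str, str]]:
    """Reciprocal unique-argmax pairs from a pandas score matrix."""
    pairs = []
    for a in scores.index:
        row = scores.loc[a]
        mx = row.max()
        winners = [b for b in scores.columns if row[b] == mx]
        if len(winners) != 1:
            continue
        b = winners[0]
        col = scores[b]
        mxc = col.max()
        cw = [x for x in scores.index if col[x] == mxc]
        if cw == [a]:
            pairs.append((a, b))
    return sorted(pairs)


def lcs_length(a: list, b: list) -> int:
    """Classic longest-common-subsequence DP on two sequences."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                dp[i][j] = dp[i - 1][j - 1] + 1
            else:
                dp[i][j] = max(dp[i - 1][j], dp[i][j - 1])
    return dp[n][m]


def least_squares_topology(D, taxa) -> frozenset:
    """Best 4-taxon unrooted topology by ordinary least squares.

    Returns the cherry pair of the winning split, e.g. frozenset({A, B})
    for ((A,B),(C,D)). D is a dict (or DataFrame) of pairwise distances.
    """
    import itertools

    import numpy as np

    a, b, c, d = taxa

    def dist(x, y):
        try:
            return float(D.loc[x, y])
        except AttributeError:
            return float(D[(x, y)] if (x, y) in D else D[(y, x)])

    best = None
    for (p, q), (r, s) in [
        ((a, b), (c, d)),
        ((a, c), (b, d)),
        ((a, d), (b, c)),
    ]:
        # five-edge tree: fit by least squares over all 6 distances
        # design matrix rows: pq, pr, ps, qr, qs, rs
        pairs = [(p, q), (p, r), (p, s), (q, r), (q, s), (r, s)]
        y = np.array([dist(x, z) for x, z in pairs])
        # edges: ep, eq, er, es, em (internal)
        A = np.zeros((6, 5))
        names = {p: 0, q: 1, r: 2, s: 3}
        for row, (x, z) in enumerate(pairs):
            A[row, names[x]] = 1
            A[row, names[z]] = 1
            same_side = {x, z} in ({p, q}, {r, s})
            if not same_side:
                A[row, 4] = 1
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ coef - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, frozenset({p, q}))
    return best[1]
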