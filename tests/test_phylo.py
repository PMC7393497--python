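"""Alignment, distances, neighbor joining, bootstrap, monophyly."""

import numpy as np
import pandas as pd
import pytest

from edckit import phylo
from edckit.phylo import (
    Alignment,
    bootstrap_support,
    distance_matrix,
    jtt_stationary,
    jtt_transition_matrix,
    nj_tree,
    path_length_matrix,
    progressive_align,
    test_monophyly as check_monophyly,
    unambiguous_columns,
)
from edckit.seqs import AA20
from edckit.synthetic import simulate_family_expansion

from .oracles import least_squares_topology


class TestProgressiveAlign:
    def test_identical_pair_gapless(self):
        aln = progressive_align({"a": "MKWCHDE", "b": "MKWCHDE"})
        assert aln.rows == {"a": "MKWCHDE", "b": "MKWCHDE"}

    def test_single_gap_placed_opposite_deletion(self):
        aln = progressive_align({"x": "ACDEF", "y": "ACEF"})
        assert aln.rows["x"] == "ACDEF"
        assert aln.rows["y"] == "AC-EF"

    def test_ungapping_recovers_inputs(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list(AA20), int(rng.integers(40, 60))))
            for i in range(5)
        }
        aln = progressive_align(seqs)
        for k, v in seqs.items():
            assert aln.ungapped(k) == v

    def test_identical_pairs_cluster_first(self):
        seqs = {
            "a1": "MKWCHDEFRYGASP" * 3,
            "a2": "MKWCHDEFRYGASP" * 3,
            "b1": "PLIVTNQHKRWYED" * 3,
            "b2": "PLIVTNQHKRWYED" * 3,
        }
        aln = progressive_align(seqs)
        D = distance_matrix(aln)
        assert D.loc["a1", "a2"] == 0.0
        assert D.loc["b1", "b2"] == 0.0
        assert D.loc["a1", "b1"] > 0.0

    def test_input_order_irrelevant(self):
        seqs = {"c": "MKWCHDE", "a": "MKWCIDE", "b": "MKWCHDEF"}
        a1 = progressive_align(seqs)
        a2 = progressive_align(dict(reversed(list(seqs.items()))))
        assert a1.rows == a2.rows

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": "MK"})


class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment({"a": "MKWC", "b": "MKWC"})
        assert distance_matrix(aln).loc["a", "b"] == 0.0
        assert distance_matrix(aln, "jtt_like").loc["a", "b"] == 0.0

    def test_poisson_closed_form(self):
        # p = 0.1 -> -ln(0.9) = 0.10536
        row_a = "A" * 100
        row_b = "A" * 90 + "C" * 10
        d = distance_matrix(Alignment({"a": row_a, "b": row_b})).loc["a", "b"]
        assert d == pytest.approx(0.1053605, abs=1e-6)

    def test_saturated_pair_capped_with_warning(self):
        aln = Alignment({"a": "AAAA", "b": "CCCC"})
        with pytest.warns(UserWarning, match="capping"):
            d = distance_matrix(aln).loc["a", "b"]
        assert d == phylo.POISSON_CAP

    def test_gap_columns_pairwise_deleted(self):
        aln = Alignment({"a": "MK-C", "b": "MKWC", "c": "MKAC"})
        D = distance_matrix(aln)
        assert D.loc["a", "b"] == 0.0  # gap column ignored
        assert D.loc["b", "c"] > 0.0

    def test_jtt_ml_distance_consistency(self, rng):
        """Estimated JTT distances on pairs simulated at t=0.3 average to
        the truth within 3 standard errors (10 kb sites per pair)."""
        pi = jtt_stationary()
        P = jtt_transition_matrix(0.3)
        ests = []
        for _ in range(5):
            anc = rng.choice(20, size=10_000, p=pi)
            child = np.array([rng.choice(20, p=P[a]) for a in anc])
            row_a = "".join(AA20[i] for i in anc)
            row_b = "".join(AA20[i] for i in child)
            d = distance_matrix(Alignment({"a": row_a, "b": row_b}), "jtt_like")
            ests.append(d.loc["a", "b"])
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.3) < 3 * se + 0.01

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(Alignment({"a": "MK", "b": "MK"}), "gtr")


def _additive_matrix_4taxa():
    # ((A,B),(C,D)) with leaf edges 2,3,4,5 and internal edge 1
    ids = ["A", "B", "C", "D"]
    D = pd.DataFrame(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
        index=ids, columns=ids, dtype=float,
    )
    return ids, D


class TestNeighborJoining:
    def test_additive_4taxa_exact_and_split_recovered(self):
        ids, D = _additive_matrix_4taxa()
        tree = nj_tree(D)
        M = path_length_matrix(tree)
        assert np.abs(M.loc[ids, ids].to_numpy() - D.to_numpy()).max() < 1e-9
        assert least_squares_topology(D, ids) in (
            frozenset({"A", "B"}), frozenset({"C", "D"}),
        )
        splits = phylo._canonical_splits(tree)
        all_leaves = frozenset(ids)
        want = frozenset({"C", "D"})  # canonical side not containing "A"
        assert want in splits

    def test_additive_5taxa_exact(self):
        # caterpillar tree (((A,B),C),(D,E)) with known edge lengths
        ids = ["A", "B", "C", "D", "E"]
        edges = {"A": 2, "B": 3, "C": 4, "D": 2, "E": 1}
        internal_ab = 2
        internal_de = 3
        D = pd.DataFrame(0.0, index=ids, columns=ids)
        def plen(x, y):
            if {x, y} == {"A", "B"}:
                return edges["A"] + edges["B"]
            if {x, y} <= {"A", "B", "C"}:
                other = ({"A", "B"} & {x, y}).pop()
                return edges[other] + internal_ab + edges["C"]
            if {x, y} == {"D", "E"}:
                return edges["D"] + edges["E"]
            left = ({"A", "B", "C"} & {x, y}).pop()
            right = ({"D", "E"} & {x, y}).pop()
            base = edges[left] + (internal_ab if left in "AB" else 0)
            return base + internal_de + edges[right]
        for i in ids:
            for j in ids:
                if i != j:
                    D.loc[i, j] = plen(i, j)
        tree = nj_tree(D)
        M = path_length_matrix(tree)
        assert np.abs(M.loc[ids, ids].to_numpy() - D.to_numpy()).max() < 1e-9

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        D = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]], index=ids, columns=ids, dtype=float
        )
        tree = nj_tree(D)
        M = path_length_matrix(tree)
        assert np.abs(M.loc[ids, ids].to_numpy() - D.to_numpy()).max() < 1e-9

    def test_matches_reference_nj_topology(self, rng):
        """Cross-check against scikit-bio's neighbor joining on a random
        (noisy-additive) matrix: identical unrooted topology."""
        skbio = pytest.importorskip("skbio")
        ids = [f"t{i}" for i in range(7)]
        base = rng.random((7, 7)) * 0.2
        D = base + base.T + 1.0
        np.fill_diagonal(D, 0.0)
        Ddf = pd.DataFrame(D, index=ids, columns=ids)
        mine = nj_tree(Ddf)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        ref_dendropy = phylo.dendropy.Tree.get(
            data=str(ref), schema="newick", preserve_underscores=True
        )
        assert phylo._canonical_splits(mine) == phylo._canonical_splits(ref_dendropy)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(pd.DataFrame([[0.0, 1], [1, 0.0]], index=["a", "b"], columns=["a", "b"]))


class TestBootstrap:
    def test_saturated_two_clades_full_support(self, rng):
        block_a = "".join(rng.choice(list(AA20), 200))
        block_b = "".join(rng.choice(list(AA20), 200))
        aln = Alignment({"a1": block_a, "a2": block_a, "b1": block_b, "b2": block_b})
        ft = bootstrap_support(aln, n_replicates=100, rng_seed=1)
        v = check_monophyly(ft, ["a1", "a2"])
        assert v["monophyletic"] and v["support"] == 100.0

    def test_all_identical_alignment_degenerate(self):
        aln = Alignment({k: "MKWCHDEF" * 5 for k in ["a", "b", "c", "d"]})
        ft = bootstrap_support(aln, n_replicates=10, rng_seed=0)
        assert ft.degenerate
        assert all(s == 0.0 for s in ft.supports.values())

    def test_supports_in_range_and_seed_deterministic(self, rng):
        prots, _ = simulate_family_expansion(3, 0.1, 0.4, rng_seed=5)
        aln = progressive_align(prots)
        f1 = bootstrap_support(aln, n_replicates=50, rng_seed=7)
        f2 = bootstrap_support(aln, n_replicates=50, rng_seed=7)
        assert f1.supports == f2.supports
        assert all(0.0 <= s <= 100.0 for s in f1.supports.values())

    def test_supports_invariant_to_leaf_relabeling(self):
        prots, _ = simulate_family_expansion(3, 0.05, 0.5, rng_seed=9)
        aln = progressive_align(prots)
        ft = bootstrap_support(aln, n_replicates=50, rng_seed=3)
        mapping = {k: f"x{i}" for i, k in enumerate(sorted(aln.rows))}
        aln2 = Alignment({mapping[k]: v for k, v in aln.rows.items()})
        ft2 = bootstrap_support(aln2, n_replicates=50, rng_seed=3)
        def relabel(supports):
            return {
                frozenset(mapping[x] for x in s): v for s, v in supports.items()
            }
        # canonicalization side may flip; compare split-or-complement
        leaves2 = frozenset(aln2.rows)
        s1 = {min(s, leaves2 - s, key=sorted): v for s, v in relabel(ft.supports).items()}
        s2 = {min(s, leaves2 - s, key=sorted): v for s, v in ft2.supports.items()}
        assert s1 == s2


class TestMonophyly:
    def test_planted_expansion_recovered(self):
        prots, clades = simulate_family_expansion(
            (9, 2), within_rate=0.05, between_rate=0.5, rng_seed=2
        )
        aln = progressive_align(prots)
        ft = bootstrap_support(aln, n_replicates=100, rng_seed=0)
        A = [k for k, v in clades.items() if v == "cladeA"]
        B = [k for k, v in clades.items() if v == "cladeB"]
        va, vb = check_monophyly(ft, A), check_monophyly(ft, B)
        assert va["monophyletic"] and vb["monophyletic"]
        assert va["support"] >= 95

    def test_trivial_subset_rejected(self):
        prots, _ = simulate_family_expansion(2, 0.05, 0.5, rng_seed=3)
        aln = progressive_align(prots)
        ft = bootstrap_support(aln, n_replicates=10, rng_seed=0)
        with pytest.raises(ValueError):
            check_monophyly(ft, ["cladeA_1"])
        with pytest.raises(ValueError):
            check_monophyly(ft, list(prots))

    def test_interleaved_subset_not_monophyletic(self):
        prots, clades = simulate_family_expansion(3, 0.05, 0.5, rng_seed=4)
        aln = progressive_align(prots)
        ft = bootstrap_support(aln, n_replicates=10, rng_seed=0)
        mixed = ["cladeA_1", "cladeB_1"]
        assert not check_monophyly(ft, mixed)["monophyletic"]


def test_unambiguous_columns_masks_gappy_disagreeing_sites():
    aln = Alignment({
        "a": "MK-WAC",
        "b": "MKAWCC",
        "c": "MK-WGC",
        "d": "MKAWTC",
    })
    keep = unambiguous_columns(aln, max_gap_fraction=0.2, min_agreement=0.5)
    assert 2 not in keep  # 50% gaps
    assert 4 not in keep  # all four residues disagree
    assert {0, 1, 3, 5} <= set(keep)


def test_alignment_io_roundtrip(tmp_path):
    aln = Alignment({"a": "MK-W", "b": "MKAW"})
    f, p = tmp_path / "a.fasta", tmp_path / "a.phy"
    aln.write_fasta(f)
    aln.write_phylip(p)
    assert Alignment.read_fasta(f).rows == aln.rows
    assert Alignment.read_phylip(p).rows == aln.rows
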