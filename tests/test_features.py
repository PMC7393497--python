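"""Protein feature stack: composition, bias, repeats, PSSM, CBP typing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edckit.features import (
    bias_class,
    build_beta_pssm,
    build_pssm,
    composition,
    detect_terminal_motif,
    feature_table,
    find_tandem_repeats,
    read_pssm,
    scan_cbp,
    write_pssm,
)
from edckit.seqs import AA20
from edckit.synthetic import GeneSpec, build_protein, beta_consensus

from .oracles import repeat_bruteforce


class TestComposition:
    def test_simple_cases(self):
        prof = composition("GGSS")
        assert prof["G"] == 50.0 and prof["S"] == 50.0
        assert sum(v for k, v in prof.percent.items() if k not in "GS") == 0.0
        assert composition("P")["P"] == 100.0

    def test_random_protein_matches_letter_counts(self, rng):
        seq = "".join(rng.choice(list(AA20), 1000))
        prof = composition(seq)
        for a in AA20:
            assert prof[a] == pytest.approx(100.0 * seq.count(a) / 1000)
        assert prof.total == pytest.approx(100.0, abs=0.1)

    def test_x_excluded_from_denominator(self):
        prof = composition("GGXX")
        assert prof["G"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composition("")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.permutations(list("GASPCQKLMN")))
    def test_permutation_invariance(self, letters):
        prof = composition("".join(letters))
        assert prof["G"] == 10.0 and prof.total == pytest.approx(100.0)


class TestBiasClass:
    def test_gs_rich_at_61_percent(self):
        # loricrin-like: G+S above 60% must classify GS-rich
        seq = "G" * 31 + "S" * 30 + "A" * 39
        assert "GS-rich" in bias_class(composition(seq))

    def test_uniform_profile_unlabeled(self):
        seq = AA20  # 5% each
        assert bias_class(composition(seq)) == set()

    def test_threshold_boundary_inclusive(self):
        seq = "P" * 15 + "A" * 85
        assert "P-rich" in bias_class(composition(seq))
        seq_c = "C" * 10 + "A" * 90
        assert "C-rich" in bias_class(composition(seq_c))


class TestTandemRepeats:
    def test_seventeen_exact_copies_top_call(self):
        seq = "MA" + "KCVPVCPP" * 17 + "GW"
        calls = find_tandem_repeats(seq, (2, 12), max_mismatches_per_unit=0)
        top = calls[0]
        assert top.motif == "KCVPVCPP" and top.count == 17

    def test_homopolymer_degenerate(self):
        seq = "A" * 21
        top = find_tandem_repeats(seq, (2, 12), 0)[0]
        assert top.motif == "AA"
        assert top.count == 10  # floor(21 / 2)

    def test_partial_tail_flagged_not_counted(self):
        seq = "KCVPVCPP" * 3 + "KCVPV"
        top = find_tandem_repeats(seq, (8, 8), 0)[0]
        assert top.count == 3 and top.partial_tail

    def test_exact_mode_matches_bruteforce(self, rng):
        for _ in range(5):
            n = int(rng.integers(60, 200))
            seq = "".join(rng.choice(list("ACGPS"), n))  # repeat-prone alphabet
            calls = find_tandem_repeats(seq, (2, 8), 0)
            oracle = repeat_bruteforce(seq, 2, 8, 0)
            if oracle is None:
                assert calls == []
            else:
                top = calls[0]
                assert (top.count, top.span_length, top.span[0], top.motif) == oracle

    def test_range_validation(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("AAAA", (1, 5))


class TestPssm:
    def test_single_row_seed_best_match_is_itself(self, rng):
        row = "".join(rng.choice(list(AA20), 34))
        pssm = build_beta_pssm([row])
        scores = dict(pssm.scan(row + "".join(rng.choice(list(AA20), 30))))
        assert max(scores, key=scores.get) == 0
        assert pssm.consensus() == row

    def test_duplicate_rows_idempotent(self):
        rows = list(__import__("edckit.synthetic", fromlist=["x"]).beta_seed_alignment().values())
        p1 = build_beta_pssm([rows[0], rows[1]])
        p2 = build_beta_pssm([rows[0], rows[0], rows[1], rows[1]])
        assert np.allclose(p1.matrix, p2.matrix)

    def test_all_g_column_scores_g_highest(self):
        rows = ["G" + "A" * 33] * 3
        pssm = build_beta_pssm(rows)
        g = AA20.index("G")
        assert pssm.matrix[0].argmax() == g

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged|34"):
            build_beta_pssm(["GG", "G"])

    def test_text_serialization_roundtrip(self, tmp_path, beta_pssm):
        p = tmp_path / "beta.pssm"
        write_pssm(beta_pssm, p)
        back = read_pssm(p)
        assert np.allclose(back.matrix, beta_pssm.matrix, atol=1e-6)
        assert back.threshold == pytest.approx(beta_pssm.threshold, abs=1e-5)


class TestCbpTyping:
    def test_type1_short_arm(self, beta_pssm, rng):
        spec = GeneSpec("c", "CBP1B", 120, nterm_arm_length=8)
        prot = build_protein(spec, np.random.default_rng(1))
        call = scan_cbp(prot, beta_pssm)
        assert call.n_motifs == 1 and call.nterm_arm == 8
        assert call.cbp_type == "type1"

    def test_type2_long_arm(self, beta_pssm):
        spec = GeneSpec("c", "CBP1B", 160, nterm_arm_length=60)
        prot = build_protein(spec, np.random.default_rng(2))
        assert scan_cbp(prot, beta_pssm).cbp_type == "type2"

    def test_4b_four_motifs(self, beta_pssm):
        spec = GeneSpec("c", "CBP4B", 200, nterm_arm_length=10)
        prot = build_protein(spec, np.random.default_rng(3))
        call = scan_cbp(prot, beta_pssm)
        assert call.n_motifs == 4 and call.cbp_type == "4B"

    def test_motif_free_random_protein(self, beta_pssm, rng):
        prot = "".join(rng.choice(list(AA20), 150))
        call = scan_cbp(prot, beta_pssm)
        assert call.n_motifs == 0 and call.cbp_type == "not_cbp"

    def test_count_invariant_under_motif_free_flanks(self, beta_pssm, rng):
        core = "M" + "A" * 7 + beta_consensus()
        n0 = scan_cbp(core, beta_pssm).n_motifs
        flank = "".join(rng.choice(list("DEKR"), 40))  # charged, motif-free
        n1 = scan_cbp(flank + core + flank, beta_pssm).n_motifs
        assert n0 == n1 == 1

    def test_classification_consistency_over_random_specs(self, beta_pssm):
        """Planted (n_motifs, arm) specs map back to {4B, type1, type2}
        correctly for at least 95% of 200 seeded random specs."""
        rng = np.random.default_rng(99)
        ok = 0
        for i in range(200):
            if rng.random() < 0.25:
                spec = GeneSpec("c", "CBP4B", 200 + int(rng.integers(0, 60)),
                                nterm_arm_length=int(rng.integers(7, 14)))
                want = "4B"
            elif rng.random() < 0.5:
                arm = int(rng.integers(7, 11))
                spec = GeneSpec("c", "CBP1B", 120 + int(rng.integers(0, 60)),
                                nterm_arm_length=arm)
                want = "type1"
            else:
                arm = int(rng.integers(40, 100))
                spec = GeneSpec("c", "CBP1B", 160 + int(rng.integers(0, 80)),
                                nterm_arm_length=arm)
                want = "type2"
            prot = build_protein(spec, rng)
            if scan_cbp(prot, beta_pssm).cbp_type == want:
                ok += 1
        assert ok >= 190


@pytest.fixture(scope="module")
def crnn_profile():
    return build_pssm(["QQEQLERQHDQF"], name="crnn_cterm")


class TestTerminalMotif:
    def test_present_at_terminus(self, crnn_profile, rng):
        prot = "".join(rng.choice(list(AA20), 120)) + "QQEQLERQHDQF"
        hit = detect_terminal_motif(prot, crnn_profile, "C", 50)
        assert hit.present and hit.span[1] == len(prot)

    def test_motif_outside_window_absent(self, crnn_profile, rng):
        prot = "QQEQLERQHDQF" + "".join(rng.choice(list("AGSPV"), 120))
        assert not detect_terminal_motif(prot, crnn_profile, "C", 50).present
        assert detect_terminal_motif(prot, crnn_profile, "N", 50).present

    def test_scfn2_like_lacks_motif(self, crnn_profile, rng):
        scfn1 = "".join(rng.choice(list(AA20), 100)) + "QQEQLERQHDQF"
        scfn2 = "".join(rng.choice(list("AGSPV"), 112))  # motif deleted
        assert detect_terminal_motif(scfn1, crnn_profile).present
        assert not detect_terminal_motif(scfn2, crnn_profile).present

    def test_window_larger_than_protein_rejected(self, crnn_profile):
        with pytest.raises(ValueError):
            detect_terminal_motif("MKL", crnn_profile, "C", 50)


def test_feature_table_shape(beta_pssm):
    rng = np.random.default_rng(5)
    prots = {
        "p1": build_protein(GeneSpec("p1", "CBP1B", 120, nterm_arm_length=8), rng),
        "p2": "".join(rng.choice(list(AA20), 80)),
    }
    df = feature_table(prots, beta_pssm)
    assert list(df["protein_id"]) == ["p1", "p2"]
    assert df.loc[0, "cbp_type"] == "type1"
    assert df.loc[1, "cbp_type"] == "not_cbp"
    pct_cols = [c for c in df.columns if c.startswith("pct_")]
    assert len(pct_cols) == 20
    assert df[pct_cols].sum(axis=1).round(1).tolist() == [100.0, 100.0]
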