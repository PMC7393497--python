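"""Generator invariants: planted truth must be exactly what it claims."""

import numpy as np
import pytest

from edckit import synthetic
from edckit.seqs import STOP_CODONS, revcomp, translate
from edckit.synthetic import (
    EvolutionParams,
    GeneSpec,
    ValidationError,
    evolve_species,
    expected_aa_identity,
    generate_edc_cluster,
    generate_locus,
    mutate_sequence,
    simulate_family_expansion,
)


class TestGeneSpecValidation:
    def test_repeat_longer_than_protein_rejected(self):
        spec = GeneSpec("g", "SEDC", 50, repeat_motif="KCVPVCPP", repeat_count=10)
        with pytest.raises(ValidationError, match="repeat"):
            spec.validate()

    def test_bias_fractions_over_one_rejected(self):
        spec = GeneSpec("g", "SEDC", 100, {"G": 0.7, "S": 0.5})
        with pytest.raises(ValidationError, match="composition_bias"):
            spec.validate()

    def test_cbp4b_motif_count_forced(self):
        assert GeneSpec("g", "CBP4B", 200).n_beta_motifs == 4
        with pytest.raises(ValidationError):
            GeneSpec("g", "CBP4B", 200, n_beta_motifs=1).validate()

    def test_invalid_flank_rejected(self):
        with pytest.raises(ValidationError, match="flank"):
            generate_locus(GeneSpec("g"), flank=-1)


class TestGenerateLocus:
    def test_planted_repeats_appear_exactly(self):
        spec = GeneSpec("g", "SEDC", 100, repeat_motif="KCVPVCPP", repeat_count=10)
        _, locus = generate_locus(spec, flank=300, rng_seed=1)
        assert locus.protein.count("KCVPVCPP") == 10
        assert "KCVPVCPP" * 10 in locus.protein

    def test_cbp4b_carries_four_seed_motifs(self, beta_motif):
        spec = GeneSpec("g", "CBP4B", 200, nterm_arm_length=10)
        _, locus = generate_locus(spec, flank=200, rng_seed=2)
        assert locus.protein.count(beta_motif) == 4

    def test_pseudogene_truncates_longest_orf(self):
        spec = GeneSpec("g", "pseudogene", 100, lesion_types=("stop",))
        scaf, locus = generate_locus(spec, flank=200, rng_seed=3)
        cds = synthetic.extract_cds(scaf, locus)
        prot = translate(cds)
        first = prot.split("*")[0]
        assert len(first) < 100
        assert locus.lesions and locus.lesions[0][0] == "stop"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_truth_consistency(self, strand):
        """Extracting CDS by truth coordinates reproduces the protein."""
        spec = GeneSpec("g", "SEDC", 120, {"P": 0.15}, strand=strand)
        scaf, locus = generate_locus(spec, flank=400, rng_seed=4)
        assert synthetic.locus_protein_from_scaffold(scaf, locus) == locus.protein
        cds = synthetic.extract_cds(scaf, locus)
        assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS

    def test_introns_canonical_gt_ag(self, small_cluster):
        scaf, loci = small_cluster
        for locus in loci:
            for s, e in locus.intron_coords:
                piece = scaf.seq[s:e]
                if locus.strand == "-":
                    piece = revcomp(piece)
                assert piece.startswith("GT") and piece.endswith("AG")

    def test_exon_counts_by_class(self, small_cluster):
        _, loci = small_cluster
        by_name = {l.name: l for l in loci}
        assert len(by_name["gA"].cds_coords) == 1  # SEDC: one coding exon
        assert len(by_name["gA"].exon_coords) == 2  # plus one non-coding exon
        assert len(by_name["gD"].cds_coords) == 2  # SFTP: two coding exons
        assert len(by_name["gD"].exon_coords) == 3


class TestCluster:
    def test_order_and_spacing(self):
        specs = [GeneSpec(f"g{i}", "SEDC", 80) for i in range(5)]
        _, loci = generate_edc_cluster(specs, spacing=2000, rng_seed=5)
        assert [l.name for l in loci] == [f"g{i}" for i in range(5)]
        for a, b in zip(loci, loci[1:]):
            assert b.span[0] - a.span[1] >= 2000

    def test_zero_spacing_non_overlapping(self):
        specs = [GeneSpec(f"g{i}", "SEDC", 80) for i in range(3)]
        _, loci = generate_edc_cluster(specs, spacing=0, rng_seed=6)
        for a, b in zip(loci, loci[1:]):
            assert b.span[0] >= a.span[1]

    def test_minus_strand_cds_is_valid_orf(self):
        specs = [GeneSpec("g", "SEDC", 90, strand="-")]
        scaf, loci = generate_edc_cluster(specs, rng_seed=7)
        cds = synthetic.extract_cds(scaf, loci[0])
        assert cds.startswith("ATG")
        assert "*" not in translate(cds)[:-1]

    def test_byte_determinism(self):
        specs = [GeneSpec("g1", "SEDC", 80), GeneSpec("g2", "CBP1B", 120)]
        s1, l1 = generate_edc_cluster(specs, rng_seed=42)
        s2, l2 = generate_edc_cluster(specs, rng_seed=42)
        assert s1.seq == s2.seq
        assert [l.cds_coords for l in l1] == [l.cds_coords for l in l2]

    def test_gff3_truth_roundtrip(self, small_cluster, tmp_path):
        from edckit.io import read_gff3, write_gff3

        scaf, loci = small_cluster
        feats = synthetic.truth_gff3_features(scaf, loci)
        p1 = tmp_path / "a.gff3"
        write_gff3(feats, p1)
        feats2 = read_gff3(p1)
        p2 = tmp_path / "b.gff3"
        write_gff3(feats2, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestEvolveSpecies:
    def test_identity_when_no_events(self, small_cluster):
        ev = evolve_species(small_cluster, EvolutionParams(substitution_rate=0.0))
        assert ev.scaffold.seq == small_cluster[0].seq
        assert [l.name for l in ev.loci] == [l.name for l in small_cluster[1]]

    def test_duplication_gives_one_to_two(self, small_cluster):
        ev = evolve_species(
            small_cluster,
            EvolutionParams(substitution_rate=0.0, duplication_events=[("gA", 2)]),
        )
        assert ev.orthologs["gA"] == ["gAa", "gAb"]
        names = [l.name for l in ev.loci]
        assert "gAa" in names and "gAb" in names

    def test_loss_and_inversion(self, small_cluster):
        ev = evolve_species(
            small_cluster,
            EvolutionParams(
                substitution_rate=0.0,
                loss_events=["gB"],
                inversion_events=["gA"],
            ),
        )
        assert ev.orthologs["gB"] == []
        derived = {l.name: l for l in ev.loci}
        assert "gB" not in derived
        assert derived["gA"].strand == "-"
        # inverted gene still carries a valid truth protein
        assert (
            synthetic.locus_protein_from_scaffold(ev.scaffold, derived["gA"])
            == derived["gA"].protein
        )

    def test_unknown_event_gene_rejected(self, small_cluster):
        with pytest.raises(ValidationError, match="unknown gene"):
            evolve_species(small_cluster, EvolutionParams(loss_events=["nope"]))

    def test_derived_truth_stays_translatable(self, small_cluster):
        ev = evolve_species(small_cluster, EvolutionParams(substitution_rate=0.08, rng_seed=3))
        for locus in ev.loci:
            if locus.gene.gene_class == "pseudogene":
                continue
            assert (
                synthetic.locus_protein_from_scaffold(ev.scaffold, locus)
                == locus.protein
            )
            assert "*" not in locus.protein

    def test_substitution_identity_matches_analytic_expectation(self, rng):
        """Observed aa identity under the raw i.i.d. model agrees with the
        exact per-codon expectation within 3 Monte-Carlo standard errors."""
        from edckit.synthetic import reverse_translate

        protein = "M" + "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 3999))
        cds = reverse_translate(protein, rng)[:-3]  # drop stop
        rate = 0.05
        expected = expected_aa_identity(cds, rate)
        mutated = mutate_sequence(cds, rate, rng)
        p1, p2 = translate(cds), translate(mutated)
        obs = np.array([a == b for a, b in zip(p1, p2) if a != "*"], dtype=float)
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert abs(obs.mean() - expected) < 3 * se + 1e-12


class TestFamilyExpansion:
    def test_copy_counts_and_labels(self):
        prots, clades = simulate_family_expansion(3, 0.05, 0.5, rng_seed=1)
        assert len(prots) == 6
        assert sorted(set(clades.values())) == ["cladeA", "cladeB"]

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValidationError):
            simulate_family_expansion(3, 0.5, 0.1, rng_seed=1)
        with pytest.raises(ValidationError):
            simulate_family_expansion(0, 0.1, 0.5, rng_seed=1)

    def test_tiny_within_rate_keeps_copies_near_identical(self):
        prots, clades = simulate_family_expansion(3, 1e-9, 0.5, rng_seed=2)
        a = [p for k, p in prots.items() if clades[k] == "cladeA"]
        assert a[0] == a[1] == a[2]

    def test_within_distance_below_between_distance(self):
        prots, clades = simulate_family_expansion(4, 0.05, 0.4, rng_seed=3)
        def pdist(x, y):
            return sum(1 for a, b in zip(x, y) if a != b) / len(x)
        within, between = [], []
        names = list(prots)
        for i, x in enumerate(names):
            for y in names[i + 1:]:
                (within if clades[x] == clades[y] else between).append(
                    pdist(prots[x], prots[y])
                )
        assert np.mean(within) < np.mean(between)
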