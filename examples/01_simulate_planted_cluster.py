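"""Plant a small EDC-like cluster and inspect its ground truth.

Builds a scaffold carrying a GS-rich loricrin-like gene, a proline-rich
repeat gene, a single-beta-motif CBP and a pseudogene, then prints the
planted coordinates and checks that translating the truth CDS reproduces
the stored protein.
"""

from edckit.synthetic import (
    GeneSpec,
    generate_edc_cluster,
    locus_protein_from_scaffold,
)

specs = [
    GeneSpec("LOR", "SEDC", 180, {"G": 0.35, "S": 0.28}),
    GeneSpec("EDSPR", "SEDC", 120, {"P": 0.2}, repeat_motif="KCVPVCPP", repeat_count=8),
    GeneSpec("CBP", "CBP1B", 125, nterm_arm_length=8, strand="-"),
    GeneSpec("psiX", "pseudogene", 100, lesion_types=("stop",)),
]
scaffold, loci = generate_edc_cluster(specs, spacing=1500, rng_seed=42)

print(f"scaffold {scaffold.id}: {len(scaffold)} nt, {len(loci)} planted genes\n")
for locus in loci:
    if locus.gene.gene_class == "pseudogene":
        consistency = "n/a (lesioned by design)"
    else:
        ok = locus_protein_from_scaffold(scaffold, locus) == locus.protein
        consistency = f"truth-consistent={ok}"
    print(
        f"{locus.name:7s} {locus.gene.gene_class:10s} strand {locus.strand} "
        f"cds={locus.cds_coords} protein={len(locus.protein)} aa {consistency}"
    )
    if locus.lesions:
        print(f"        planted lesions: {locus.lesions}")

# Each line gives a planted gene's exact CDS coordinates (0-based,
# half-open, stop codon included) and confirms the stored protein matches
# what the scaffold actually encodes — the invariant every downstream
# stage is scored against. The pseudogene intentionally fails to translate
# cleanly: its planted stop is recorded as a lesion instead.
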