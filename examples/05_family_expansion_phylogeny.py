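"""Did a gene family expand before or after two lineages split?

Simulates independent expansions (9 copies in one clade, 2 in the other,
after a deep split), aligns the family, builds a bootstrap NJ tree, and
tests per-clade monophyly — the "independent expansion" verdict.
"""

from edckit.phylo import bootstrap_support, progressive_align, test_monophyly
from edckit.synthetic import simulate_family_expansion

proteins, clades = simulate_family_expansion(
    copies_per_clade=(9, 2),
    within_rate=0.05,
    between_rate=0.5,
    rng_seed=1,
    clade_labels=("tuatara", "lizard"),
)
alignment = progressive_align(proteins)
tree = bootstrap_support(alignment, model="jtt_like", n_replicates=100, rng_seed=0)

for clade in ("tuatara", "lizard"):
    members = [k for k, v in clades.items() if v == clade]
    verdict = test_monophyly(tree, members)
    print(
        f"{clade}: {len(members)} paralogs, monophyletic="
        f"{verdict['monophyletic']}, bootstrap support={verdict['support']}"
    )
print("\nnewick:", tree.newick())

# Both species' paralogs come out monophyletic with high support on the
# defining edge: the tree says each family expanded independently after
# the split, which is exactly how the proteins were simulated.
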