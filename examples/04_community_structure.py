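"""Shared/unique OTUs, taxonomy stacks and dominant taxa.

Simulates a staged community with one genus planted to dominate the final
stage at 95% relative abundance, then runs the presence/Venn analysis
(mean tag count > 1 defines presence in a stage), builds the top-10 genus
stack with Others/unclassified bands, and recovers the planted dominant.
"""

import fermflavor as ff

design = ff.StageDesign()
params = ff.CommunitySimParams(
    n_otus=100,
    library_size_mean=6000,
    planted_dominants=[("HT9", 12, 0.95)],
)
otus, tax = ff.generate_otu_experiment(design, params, seed=7)

presence = ff.group_presence(otus)  # per-stage OTU presence sets
venn = ff.venn_counts(presence)
print(f"OTUs present in every stage (core): {venn['core']}")
print(f"unique OTUs per stage: {venn['unique']}\n")

comp = ff.aggregate_taxonomy(otus, tax, rank="genus")
stage_comp = ff.collapse_to_stages(comp, otus)
stack = ff.top_taxa_stack(stage_comp, k=10)
print("top-10 genus stack (first three stages shown):")
print(stack[["HT1", "HT2", "HT9"]].round(3), "\n")

taxon, abundance = ff.dominant_taxon(stage_comp, "HT9")
print(f"dominant genus at HT9: {taxon} at {abundance:.1%} relative abundance")
print("(the generator planted OTU_0013's genus at 95% in HT9)")
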