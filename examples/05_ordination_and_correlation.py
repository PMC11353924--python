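"""PCA ordination and taxa x compound correlation with a planted link.

Simulates a community plus a flavor experiment in which one compound's
stage-mean content tracks the most abundant OTU's trajectory with target
Pearson r = 0.95, then (a) ordinates the samples by PCA on relative
abundance and (b) computes the taxa x compound correlation grid on stage
means (n = 9), starring significant cells.
"""

import fermflavor as ff

design = ff.StageDesign()
otus, tax = ff.generate_otu_experiment(
    design,
    ff.CommunitySimParams(n_otus=60, library_size_mean=5000,
                          unclassified_fraction=0.0),
    seed=3,
)

res = ff.pca(otus, transform="relative", n_components=2)
evr = res.explained_variance_ratio
print(f"PCA: PC1 explains {evr['PC1']:.1%}, PC2 {evr['PC2']:.1%} of variance")
print("HT1 vs HT9 mean PC1 score:",
      f"{res.scores.iloc[:3, 0].mean():.3f} vs {res.scores.iloc[-3:, 0].mean():.3f}\n")

# link compound_003 to the most abundant OTU so its genus carries the signal
rel = otus.relative_abundance()
top_otu = int(rel.mean(axis=1).argmax())
top_genus = tax.rank("genus")[otus.otu_ids[top_otu]]
peaks, thresholds, truth = ff.generate_flavor_experiment(
    design, otus,
    ff.FlavorSimParams(n_compounds=8, noise_sd=2.0,
                       linked_pairs=[(top_otu, 2, 0.95)]),
    seed=4,
)
content = ff.compute_absolute_content(
    peaks, ff.QuantParams(c1=1.0, v=1.0, m=3.0), design
)

phylum = ff.collapse_to_stages(ff.aggregate_taxonomy(otus, tax, "phylum"), otus)
genus = ff.collapse_to_stages(ff.aggregate_taxonomy(otus, tax, "genus"), otus)
taxa, compounds = ff.build_feature_sets(
    phylum, genus, content, n_phyla=3, n_genera=10
)
grid = ff.correlation_grid(taxa, compounds)
starred = grid.long_format().query("stars != ''")
print(f"correlation grid: {grid.r.shape[0]} taxa x {grid.r.shape[1]} compounds, "
      f"n = {grid.n} stages per cell")
print("significant cells (* p<0.05, ** p<0.01):")
print(starred[["taxon", "compound", "r", "p", "stars"]].round(3).to_string(index=False))
print(
    f"\nThe planted pair — {top_genus} (genus of {otus.otu_ids[top_otu]}) vs "
    "compound_003 — carries the strongest positive correlation; its phylum "
    "echoes the signal, and taxa competing with the dominant OTU pick up "
    "negative correlations. Stars elsewhere are chance at the 5% level."
)
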