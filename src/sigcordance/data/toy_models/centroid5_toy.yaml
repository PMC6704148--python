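# TOY nearest-centroid subtype model for synthetic cohorts.
# NON-CLINICAL: parameters are self-consistent with the bundled generator's
# axis structure, not any published centroid set.
name: centroid5_toy
family: centroid_subtype
centroids: centroid5_centroids.tsv
classes: [LumA, LumB, HER2E, Basal, Normal]
correlation_method: spearman
centering: reference_set
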