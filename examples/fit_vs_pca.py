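"""Compare how well PCA-derived distances explain observed genetic
dissimilarities as the number of components grows.

Population-level expected distances are squared Euclidean distances
between per-population medians of the first k PC scores; the fit statistic
is the Pearson correlation over all population pairs.
"""

import migscape as ms

graph = ms.build_grid((0, 0, 600, 550), spacing_km=100.0, mode="planar")
field = ms.make_rate_field(graph)  # pure isolation by distance
cfg = ms.SimConfig(seed=21, n_sampled_per_deme=10, deme_size=30,
                   n_generations=300)
geno = ms.simulate_wf_genotypes(field, cfg)
print(f"simulated {geno.n_samples} individuals on {graph.n_vertices} demes; "
      f"panel FST = {ms.fst_empirical(geno, geno.samples['pop'].to_numpy()):.3f}")

D = ms.observed_dissimilarity(geno)
pops = geno.samples["pop"].to_numpy()
observed, _ = ms.population_mean_matrix(D, pops)

pca = ms.pca_decompose(geno, 100)
for k in (2, 10, 100):
    expected, _ = ms.expected_distance_from_pcs(pca.scores, pops, k)
    fit = ms.fit_correlation(expected, observed, method=f"pca-{k}")
    print(f"  k = {k:3d} PCs: Pearson r = {fit.pearson_r:.3f}")
# r grows with k: more components recover more of the pairwise structure
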