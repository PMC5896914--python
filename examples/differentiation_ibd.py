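"""Differentiation and isolation by distance under stepping-stone gene flow.

AMOVA partitions the molecular variance among/within sites into an
overall Fst; the Fst ceilings show how far below 1 the attainable range
really is for highly polymorphic markers; the Mantel tests ask whether
genetic distance increases with geographic distance.
"""

import msatnet as mn

config = mn.stepping_stone_preset(seed=1)
table, _ = mn.simulate_stepping_stone(config)

res = mn.amova(table, n_perm=999, seed=0)
print(f"overall Fst = {res.fst:.4f} (permutation p = {res.p_value:.3f})")

bounds = mn.fst_upper_bounds(mn.allele_frequencies(table), K=2)
print(f"Fst ceilings (two-deme theory): from M = {bounds.mean_bound_M:.3f}, "
      f"from total homozygosity = {bounds.mean_bound_HT:.3f}")
# the observed Fst should be judged against these ceilings, not against 1

fst, _ = mn.pairwise_fst(table, n_perm=0)
geo = mn.geographic_distances(config.site_table())
m1 = mn.mantel_test(mn.linearize_fst(fst), geo, n_perm=999, seed=0)

graph = mn.fit_population_graph(table, bonferroni=True)
cgd = mn.conditional_genetic_distance(graph)
m2 = mn.mantel_test(cgd, geo, n_perm=999, seed=0)

print(f"Mantel r (linearised Fst vs km): {m1.statistic:.2f}, p = {m1.p_value:.3f}")
print(f"Mantel r (cGD vs km):            {m2.statistic:.2f}, p = {m2.p_value:.3f}")
# both positive and significant = isolation by distance detected through
# pairwise and through whole-network genetic distances alike
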