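"""Per-site diversity: the classical survey table.

For each sampling site: sample size n, mean alleles per locus N, private
alleles per locus Np, rarefied allelic richness AR (comparable across
unequal sample sizes), observed/expected heterozygosity Ho/He and the
fixation index F = (He - Ho)/He (positive = heterozygote deficit).
"""

import msatnet as mn

table, _ = mn.simulate_hierarchical(mn.study_preset(seed=1))
summary = mn.diversity_table(table)

print(summary.with_mean_row().round(3).to_string())
print(f"\nrarefaction used g = {summary.g} gene copies "
      "(twice the smallest site x locus sample)")

# Hardy-Weinberg check for one site x locus cell
site_rows = table.site_index()[table.sites[0]]
res = mn.hwe_exact_test(table.calls[site_rows, 0, :], n_reps=10_000, seed=0)
print(f"HWE exact test, {table.sites[0]} x {table.locus_names[0]}: p = {res.p_value:.3f}")
# p close to uniform is expected: the generator draws genotypes in
# Hardy-Weinberg proportions within sites.
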