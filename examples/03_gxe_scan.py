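"""Genome-wide G-by-E scan: joint multivariate GREML across environment
groups, all pairwise genetic correlations, Wald tests against r_G = 1 and
a permutation check of the most significant contrast.

A self-contained small simulation (K=2 for speed) with genuine G-by-E:
true r_G = 0.3 between the two environments.
"""

import envgreml as eg

n_per_group, m = 350, 1100
G = eg.simulate_genotypes(2 * n_per_group, m, seed=21)
cfg = eg.gxe_config([n_per_group] * 2, h2=[0.5, 0.5], r_g=0.3, n_snps=m, seed=22)
cohort = eg.simulate_gxe_cohort(G, cfg)
A = eg.compute_grm(G)

scan = eg.gxe_scan(cohort, A, group_col="group", n_traits=1, min_group=50)
print(scan.to_frame().to_string(index=False))
print(f"\nBonferroni threshold over {scan.n_tests} test(s): {scan.threshold:.4g}")
# Rows labelled 'a' are per-group SNP-heritabilities tested against 0;
# rows labelled 'b' are cross-environment genetic correlations tested
# against 1 — a significant departure from 1 is the G-by-E signal.

pair = scan.pairs[0]
print(f"\nr_G({pair.labels[0]}, {pair.labels[1]}) = {pair.r_g:.3f} "
      f"(SE {pair.se:.3f}), Wald p vs 1 = {pair.p_vs_1:.2e}")

perm = eg.permutation_test(cohort, A, pair.labels, n_perm=100, seed=23)
print(f"permutation p (100 shuffles, statistic |r_G - 1|): {perm.p_value:.4f}")
# The permutation p is exact under the null (r_G = 1) and ranks datasets
# consistently with the Wald p, but under strong true G-by-E it is
# conservative at desk scale: shuffled pseudo-groups are mixtures that
# retain interaction structure, widening the null spread of r_G-hat.
# With n_perm=100 the smallest attainable value is 1/101.
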