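"""Genotype QC, GRM construction and relatedness pruning.

Reads PLINK files (run 01_simulate_cohort.py first, or point the prefix at
your own data), applies the standard marker/sample filters, builds the
allele-frequency standardized genomic relationship matrix and prunes
related individuals.
"""

import numpy as np

import envgreml as eg

G = eg.read_plink("scratch/example_cohort")
print(f"loaded {G.n_samples} samples x {G.n_variants} SNPs")

# biobank-style thresholds: MAF > 0.01, HWE p >= 1e-4, missingness <= 5%
G_clean, report = eg.qc_filter(G, maf_min=0.01, hwe_p_min=1e-4,
                               var_miss_max=0.05, sample_miss_max=0.05)
print(report.to_frame().to_string(index=False))

A = eg.compute_grm(G_clean)
diag = np.diag(A.values)
off = A.values[np.triu_indices(A.n, k=1)]
print(f"\nGRM: mean diagonal {diag.mean():.4f} (expect ~1), "
      f"off-diagonal sd {off.std():.4f} (expect ~1/sqrt(M) = {1/np.sqrt(G_clean.n_variants):.4f})")

# individuals with pairwise relationship > 0.05 are greedily pruned
kept = eg.prune_related(A, threshold=0.05)
print(f"relatedness pruning retained {len(kept)}/{A.n} samples")

eg.write_gcta_grm(A.subset(kept), "scratch/example_cohort_grm")
print("wrote GCTA-format GRM to scratch/example_cohort_grm.grm.*")
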