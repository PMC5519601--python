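"""PLINK I/O, Hardy-Weinberg testing, QC filters, GRM construction and
relatedness pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import envgreml as eg
from envgreml.exceptions import DomainError, FormatError, ModelError

from conftest import hand_grm


def _geno(dosages, samples=None):
    n, m = dosages.shape
    samples = samples or [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "snp": [f"v{j}" for j in range(m)],
            "cm": 0.0,
            "pos": np.arange(1, m + 1),
            "a1": "A",
            "a2": "G",
        }
    )
    return eg.GenotypeMatrix(samples, variants, np.asarray(dosages, dtype=float))


class TestPlinkIO:
    def test_roundtrip_identity(self, tmp_path):
        G = eg.simulate_genotypes(5, 8, (0.1, 0.5), missing_rate=0.2, seed=1)
        eg.write_plink(G, tmp_path / "t")
        G2 = eg.read_plink(tmp_path / "t")
        assert G2.samples == G.samples
        assert np.array_equal(G.dosages, G2.dosages, equal_nan=True)
        assert list(G2.variants["snp"]) == list(G.variants["snp"])

    def test_handbuilt_bed_bytes_decode_exactly(self, tmp_path):
        """2 samples x 2 SNPs with manually packed 2-bit codes:
        SNP1: s1 hom-A1 (00), s2 het (10) -> byte 0b00001000
        SNP2: s1 missing (01), s2 hom-A2 (11) -> byte 0b00001101
        """
        (tmp_path / "h.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b1000, 0b1101]))
        (tmp_path / "h.fam").write_text("f1 s1 0 0 0 -9\nf2 s2 0 0 0 -9\n")
        (tmp_path / "h.bim").write_text("1\tv1\t0\t1\tA\tG\n1\tv2\t0\t2\tA\tG\n")
        G = eg.read_plink(tmp_path / "h")
        expected = np.array([[2.0, np.nan], [1.0, 0.0]])
        assert np.array_equal(G.dosages, expected, equal_nan=True)

    def test_duplicate_fam_ids_rejected(self, tmp_path):
        G = eg.simulate_genotypes(4, 3, seed=2)
        eg.write_plink(G, tmp_path / "d")
        fam = (tmp_path / "d.fam").read_text().splitlines()
        fam[1] = fam[0]
        (tmp_path / "d.fam").write_text("\n".join(fam) + "\n")
        with pytest.raises(FormatError):
            eg.read_plink(tmp_path / "d")

    def test_bad_magic_and_truncation_rejected(self, tmp_path):
        G = eg.simulate_genotypes(4, 3, seed=3)
        eg.write_plink(G, tmp_path / "b")
        raw = (tmp_path / "b.bed").read_bytes()
        (tmp_path / "b.bed").write_bytes(b"\x00" + raw[1:])
        with pytest.raises(FormatError, match="magic"):
            eg.read_plink(tmp_path / "b")
        (tmp_path / "b.bed").write_bytes(raw[:-1])
        with pytest.raises(FormatError, match="bytes"):
            eg.read_plink(tmp_path / "b")


class TestHWE:
    def test_exact_hw_proportions_give_p_one(self):
        assert eg.hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_maximal_disequilibrium(self):
        assert eg.hwe_test(50, 0, 50) < 1e-10

    def test_matches_independent_chisquare_oracle(self):
        n_aa, n_ab, n_bb = 30, 40, 30
        n = 100
        p = (2 * n_aa + n_ab) / (2 * n)
        exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_aa, n_ab, n_bb])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p_oracle = stats.chi2.sf(chi2, 1)
        assert eg.hwe_test(n_aa, n_ab, n_bb) == pytest.approx(p_oracle, abs=1e-6)

    def test_zero_counts_raise(self):
        with pytest.raises(DomainError):
            eg.hwe_test(0, 0, 0)


class TestQCFilter:
    def test_clean_matrix_untouched(self):
        G = eg.simulate_genotypes(100, 30, (0.2, 0.5), seed=4)
        out, report = eg.qc_filter(G)
        assert out.dosages.shape == G.dosages.shape
        assert (report.removed_maf, report.removed_hwe,
                report.removed_var_missing, report.removed_sample_missing) == (0, 0, 0, 0)

    def test_hand_counted_toy_fixture(self):
        """6 samples x 4 SNPs: v0 monomorphic (MAF filter), v1 60% missing
        (variant-missingness filter), v2/v3 clean; sample 5 is missing 100%
        of the surviving SNPs (sample filter).  Survivors: 2 SNPs, 5 samples."""
        nan = np.nan
        dos = np.array(
            [
                # v0  v1   v2   v3
                [0.0, 1.0, 1.0, 2.0],
                [0.0, nan, 0.0, 1.0],
                [0.0, nan, 1.0, 1.0],
                [0.0, 2.0, 2.0, 0.0],
                [0.0, nan, 1.0, 1.0],
                [0.0, nan, nan, nan],
            ]
        )
        out, report = eg.qc_filter(_geno(dos), maf_min=0.01, hwe_p_min=1e-4,
                                   var_miss_max=0.5, sample_miss_max=0.5)
        assert report.removed_maf == 1
        assert report.removed_var_missing == 1
        assert report.removed_sample_missing == 1
        assert out.dosages.shape == (5, 2)
        # removals sum to input - output
        assert report.n_variants_out == 2 and report.n_samples_out == 5

    def test_hwe_filter_removes_disequilibrium(self):
        v0 = np.array([2.0] * 30 + [0.0] * 30)  # no hets: strong disequilibrium
        v1 = np.array([2.0] * 15 + [1.0] * 30 + [0.0] * 15)  # exact HW proportions
        dos = np.column_stack([v0, v1])
        out, report = eg.qc_filter(_geno(dos), hwe_p_min=1e-4)
        assert report.removed_hwe == 1
        assert out.n_variants == 1

    def test_invalid_threshold_raises(self):
        G = eg.simulate_genotypes(10, 5, seed=5)
        with pytest.raises(DomainError):
            eg.qc_filter(G, maf_min=0.6)

    def test_idempotent(self):
        G = eg.simulate_genotypes(60, 40, (0.05, 0.5), missing_rate=0.03, seed=6)
        once, _ = eg.qc_filter(G)
        twice, rep2 = eg.qc_filter(once)
        assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)

    def test_all_variants_removed_flags_not_raises(self):
        dos = np.zeros((6, 3))  # all monomorphic
        out, report = eg.qc_filter(_geno(dos))
        assert report.empty_output and out.n_variants == 0


class TestGRM:
    def test_identical_genotypes_identical_relationship(self):
        dos = np.array([[0.0, 1, 2, 1], [0.0, 1, 2, 1], [2.0, 1, 0, 1]])
        A = eg.compute_grm(_geno(dos))
        assert A.values[0, 1] == pytest.approx(A.values[0, 0])
        assert A.values[0, 1] == pytest.approx(A.values[1, 1])

    def test_hand_evaluated_toy(self):
        dos = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        A = eg.compute_grm(_geno(dos))
        assert A.values[0, 2] == pytest.approx(-2.0, abs=1e-12)
        assert np.allclose(A.values, hand_grm(dos), atol=1e-10)

    def test_mean_diagonal_near_one_under_hwe(self):
        G = eg.simulate_genotypes(500, 5000, (0.05, 0.5), seed=7)
        A = eg.compute_grm(G)
        assert abs(np.diag(A.values).mean() - 1.0) < 0.02

    def test_equals_standardized_crossproduct_on_complete_data(self):
        G = eg.simulate_genotypes(80, 200, (0.1, 0.5), seed=8)
        A = eg.compute_grm(G)
        z = G.standardized()
        assert np.allclose(A.values, z @ z.T / G.n_variants, atol=1e-10)

    def test_permutation_exchangeability(self):
        G = eg.simulate_genotypes(40, 100, seed=9)
        A = eg.compute_grm(G)
        perm = np.random.default_rng(0).permutation(40)
        A2 = eg.compute_grm(G.subset(sample_idx=perm))
        assert np.allclose(A2.values, A.values[np.ix_(perm, perm)], atol=1e-12)

    def test_monomorphic_snps_skipped(self):
        dos = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 0.0], [0.0, 1.0]])
        A = eg.compute_grm(_geno(dos))
        assert (A.n_snps_used == 1).all()

    def test_all_monomorphic_raises(self):
        with pytest.raises(ModelError):
            eg.compute_grm(_geno(np.ones((4, 3)) * 2))

    def test_gcta_binary_roundtrip(self, tmp_path):
        G = eg.simulate_genotypes(25, 80, missing_rate=0.05, seed=10)
        A = eg.compute_grm(G)
        eg.write_gcta_grm(A, tmp_path / "g")
        A2 = eg.read_gcta_grm(tmp_path / "g")
        assert A2.samples == A.samples
        assert np.allclose(A2.values, A.values, atol=1e-6)  # float32 storage
        assert np.allclose(A2.n_snps_used, A.n_snps_used, atol=0.5)


class TestPruneRelated:
    def _grm(self, values, ids=None):
        n = values.shape[0]
        ids = ids or [f"s{i}" for i in range(n)]
        return eg.GRM(ids, values, np.full((n, n), 100.0))

    def test_unrelated_all_retained(self):
        vals = np.eye(6) + 0.01
        assert eg.prune_related(self._grm(vals), 0.05) == [f"s{i}" for i in range(6)]

    def test_duplicate_pair_loses_exactly_one(self):
        vals = np.eye(5) * 1.0
        vals[1, 3] = vals[3, 1] = 0.98
        kept = eg.prune_related(self._grm(vals), 0.05)
        assert len(kept) == 4 and ("s1" in kept) != ("s3" in kept)

    def test_planted_conflicts_resolved_greedily(self):
        rng = np.random.default_rng(1)
        n = 40
        vals = np.eye(n) + rng.normal(0, 0.005, (n, n))
        vals = (vals + vals.T) / 2
        pairs = [(0, 1), (0, 2), (0, 3), (5, 6), (7, 8), (9, 10),
                 (11, 12), (12, 13), (20, 30), (25, 35)]
        for i, j in pairs:
            vals[i, j] = vals[j, i] = 0.2
        grm = self._grm(vals)
        kept = eg.prune_related(grm, 0.05)
        idx = grm.index_of(kept)
        off = vals[np.ix_(idx, idx)].copy()
        np.fill_diagonal(off, 0)
        assert off.max() <= 0.05
        # independent greedy re-computation
        conflict = vals > 0.05
        np.fill_diagonal(conflict, False)
        active = set(range(n))
        while True:
            deg = {i: sum(conflict[i, j] for j in active if j != i) for i in active}
            worst = max(deg.values())
            if worst == 0:
                break
            active.discard(max(i for i in active if deg[i] == worst))
        assert kept == [f"s{i}" for i in sorted(active)]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ModelError):
            eg.prune_related(self._grm(np.eye(3)), 0.0)
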