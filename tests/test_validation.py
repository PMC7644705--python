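"""Panel partitioning, sensitivity, AF correlation, PCA, dosage accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import niptpool as nt
from niptpool.core import NiptpoolError


class TestPartition:
    def test_study_scale_percentages(self):
        # partition of 8,054,515 calls: 7,390,020 / 67,153 / 517,020 / 80,322
        q = np.arange(8_054_515)
        panels = [("khv", np.arange(7_390_020)),
                  ("eas", np.arange(7_390_020, 7_390_020 + 67_153)),
                  ("db", np.arange(7_457_173, 7_457_173 + 517_020))]
        part = nt.partition_callset(q, panels)
        pct = part.percentages
        assert round(pct["khv"], 1) == 91.8
        assert round(pct["eas"], 1) == 0.8
        assert round(pct["db"], 1) == 6.4
        assert round(pct["novel"], 1) == 1.0
        assert round(100 - pct["khv"], 1) == 8.2
        assert sum(part.counts.values()) == part.total

    def test_all_panels_empty_all_novel(self):
        part = nt.partition_callset([1, 2, 3], [("a", []), ("b", [])])
        assert part.counts == {"a": 0, "b": 0, "novel": 3}
        assert part.percentages["novel"] == 100.0

    def test_query_subset_of_first_panel(self):
        part = nt.partition_callset([1, 2], [("a", [1, 2, 3]), ("b", [1, 2])])
        assert part.counts["a"] == 2 and part.counts["b"] == 0

    def test_precedence_first_match_wins(self):
        part = nt.partition_callset([1], [("a", [1]), ("b", [1])])
        assert part.counts == {"a": 1, "b": 0, "novel": 0}

    def test_duplicate_query_rejected(self):
        with pytest.raises(NiptpoolError):
            nt.partition_callset([1, 1], [("a", [1])])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_counts_sum_and_internal_order_invariance(self, q, a, b):
        query = sorted(q)
        p1 = nt.partition_callset(query, [("a", sorted(a)), ("b", sorted(b))])
        p2 = nt.partition_callset(query, [("a", sorted(a, reverse=True)), ("b", list(b))])
        assert p1.counts == p2.counts
        assert sum(p1.counts.values()) == len(query)
        if query:
            assert sum(p1.percentages.values()) == pytest.approx(100.0)


class TestSensitivity:
    def test_study_scale_ratio(self):
        # 6,889,016 of 7,609,526 common SNPs recovered -> 90.5%
        common = np.arange(7_609_526)
        called = np.arange(6_889_016)
        assert nt.sensitivity_from_sites(common, called) == pytest.approx(0.9053, abs=1e-4)

    def test_small_arithmetic(self):
        assert nt.sensitivity_from_sites(range(10), range(7)) == pytest.approx(0.7)

    def test_empty_common_set_signalled(self):
        with pytest.raises(NiptpoolError):
            nt.sensitivity_from_sites([], [1])

    def test_full_recovery_from_genotypes(self, toy_af, toy_genome):
        gm = nt.simulate_genotypes(toy_af, "main", 30, genome=toy_genome, seed=1)
        callset = gm.sites[["chrom", "pos", "ref", "alt"]].copy()
        assert nt.common_snp_sensitivity(gm, callset, min_carriers=2) == 1.0

    def test_min_carriers_boundary(self):
        sites = pd.DataFrame({"chrom": ["c"] * 3, "pos": [1, 2, 3], "ref": list("AAA"),
                              "alt": list("GGG"), "chrom_cls": ["autosome"] * 3})
        dosage = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.int8)
        meta = pd.DataFrame({"population": ["p"] * 3, "sex": ["F"] * 3})
        gm = nt.GenotypeMatrix(dosage, sites, meta)
        callset = sites.iloc[[0]]
        # only site 1 has >= 2 carriers; it is called -> sensitivity 1.0
        assert nt.common_snp_sensitivity(gm, callset, min_carriers=2) == 1.0


class TestAFCorrelation:
    def test_identical_and_reversed(self):
        x = np.array([0.1, 0.2, 0.5, 0.9])
        assert nt.af_correlation(x, x) == pytest.approx(1.0)
        assert nt.af_correlation(x, 1 - x) == pytest.approx(-1.0)

    def test_matches_two_pass_oracle(self):
        x = np.array([0.05, 0.2, 0.33, 0.71, 0.9])
        y = np.array([0.11, 0.18, 0.40, 0.65, 0.88])
        r = nt.af_correlation(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(NiptpoolError):
            nt.af_correlation([0.5, 0.5], [0.1, 0.2])


class TestGenotypesFromAF:
    def test_zero_af_all_zero(self):
        sites = pd.DataFrame({"chrom": ["c"] * 4, "pos": [1, 2, 3, 4], "ref": list("ACGT"),
                              "alt": list("GTAC")})
        gm = nt.simulate_genotypes_from_af(sites, np.zeros(4), n_individuals=20, seed=2)
        assert gm.dosage.sum() == 0

    def test_default_panel_size_and_af_recovery(self):
        rng = np.random.default_rng(3)
        m = 400
        af = rng.uniform(0.05, 0.95, size=m)
        sites = pd.DataFrame({"chrom": ["c"] * m, "pos": np.arange(1, m + 1),
                              "ref": ["A"] * m, "alt": ["G"] * m})
        gm = nt.simulate_genotypes_from_af(sites, af, seed=4)
        assert gm.n_individuals == 100
        emp = gm.allele_frequency()
        se = np.sqrt(af * (1 - af) / 200)
        assert (np.abs(emp - af) < 4 * se + 1e-9).mean() > 0.99


class TestPCA:
    @staticmethod
    def _two_pop_matrices(f, n_sites=1500, n_ind=60, seed=5):
        genome = nt.ToyGenome.random([("chr1", 500_000, "autosome")], seed=seed)
        af = nt.simulate_population_afs(genome, n_sites, {"A": f, "B": f}, seed=seed + 1)
        ga = nt.simulate_genotypes(af, "A", n_ind, seed=seed + 2)
        gb = nt.simulate_genotypes(af, "B", n_ind, seed=seed + 3)
        return af, ga, gb

    def test_diverged_populations_separate(self):
        from sklearn.metrics import silhouette_score

        _, ga, gb = self._two_pop_matrices(0.1)
        res = nt.pca_genotypes([ga, gb], k=2)
        labels = res.coords["population"]
        score = silhouette_score(res.coords[["PC1", "PC2"]], labels)
        assert score > 0.5

    def test_identical_populations_do_not_separate(self):
        from sklearn.metrics import silhouette_score

        _, ga, gb = self._two_pop_matrices(0.0)
        res = nt.pca_genotypes([ga, gb], k=2)
        score = silhouette_score(res.coords[["PC1", "PC2"]], res.coords["population"])
        assert abs(score) < 0.1

    def test_pseudo_individuals_cocluster_with_source(self):
        af, ga, gb = self._two_pop_matrices(0.1)
        pseudo = nt.simulate_genotypes_from_af(ga.sites, af.af("A"), n_individuals=60, seed=9)
        shared = nt.restrict_to_shared_sites([ga, gb, pseudo])
        res = nt.pca_genotypes(shared, k=2)
        cent = res.coords.groupby("population")[["PC1", "PC2"]].mean()
        d_a = np.linalg.norm(cent.loc["pooled_sim"] - cent.loc["A"])
        d_b = np.linalg.norm(cent.loc["pooled_sim"] - cent.loc["B"])
        assert d_a < d_b

    def test_monomorphic_only_rejected(self):
        sites = pd.DataFrame({"chrom": ["c"], "pos": [1], "ref": ["A"], "alt": ["G"],
                              "chrom_cls": ["autosome"]})
        gm = nt.GenotypeMatrix(np.zeros((4, 1), np.int8), sites,
                               pd.DataFrame({"population": ["p"] * 4, "sex": ["F"] * 4}))
        with pytest.raises(NiptpoolError):
            nt.pca_genotypes([gm])

    def test_explained_variance_monotone(self):
        _, ga, gb = self._two_pop_matrices(0.05, n_sites=400, n_ind=30)
        res = nt.pca_genotypes([ga, gb], k=5)
        assert (np.diff(res.explained) <= 1e-12).all()
        assert res.explained.min() >= 0 and res.explained.max() <= 1


class TestSexDosage:
    def test_male_data_fraction_study_values(self):
        assert nt.male_data_fraction(0.10, 0.5) == pytest.approx(0.05)
        assert nt.male_data_fraction(0.0, 0.7) == 0.0
        assert nt.male_data_fraction(0.08, 1.0) == pytest.approx(0.08)

    def test_predicted_y_depth_ratio(self):
        assert nt.predicted_y_depth_ratio(0.084, 0.5) == pytest.approx(0.021)
        assert nt.predicted_y_depth_ratio(0.1, 0.0) == 0.0

    def test_empirical_matches_prediction(self, toy_genome, toy_af):
        cohort = nt.simulate_nipt_cohort(toy_af, "main", 150, genome=toy_genome,
                                         fetal_fraction=0.084, p_male=0.5, depth=0.3, seed=31)
        reads = nt.simulate_cohort_reads(cohort, toy_genome, toy_af, seed=32)
        ratio = nt.y_depth_ratio(reads, toy_genome)
        m = np.mean([s.fetal_sex == "M" for s in cohort])
        # dosage-weight oracle conditioned on the realised male fraction
        g = toy_genome
        lx = g["chrX"].length
        ly = g["chrY"].length
        la = g.total_length - lx - ly
        ff = 0.084
        w_male = 2 * la + (2 - ff) * lx + ff * ly
        expected = m * ff * g.total_length / w_male
        n_y = (reads.df["chrom"] == "chrY").sum()
        assert ratio == pytest.approx(expected, abs=3 * expected / max(np.sqrt(n_y), 1))

    def test_no_y_reads_when_all_female(self, toy_genome, toy_af):
        cohort = nt.simulate_nipt_cohort(toy_af, "main", 20, genome=toy_genome, p_male=0.0, seed=33)
        reads = nt.simulate_cohort_reads(cohort, toy_genome, toy_af, seed=34)
        assert nt.y_depth_ratio(reads, toy_genome) == 0.0

    def test_zero_depth_signalled(self, toy_genome):
        with pytest.raises(NiptpoolError):
            nt.y_depth_ratio(nt.ReadSet.empty(), toy_genome)


class TestCarrierFrequency:
    def test_study_value_one_in_five(self):
        # AF 13.40% -> carrier frequency 2pq = 0.2321 ~ "1 in 5"
        cf = nt.carrier_frequency(0.134)
        assert cf == pytest.approx(0.2321, abs=1e-4)
        assert 1 / cf == pytest.approx(4.31, abs=0.01)

    def test_extremes_and_maximum(self):
        assert nt.carrier_frequency(0.0) == 0.0
        assert nt.carrier_frequency(0.5) == 0.5

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.0, 1.0))
    def test_symmetry(self, af):
        assert nt.carrier_frequency(af) == pytest.approx(nt.carrier_frequency(1 - af))
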