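"""Pooled pileup, binomial-error calling, filters, Ti/Tv, VCF round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import niptpool as nt
from niptpool.caller import COUNT_COLUMNS, call_pileup, call_site, default_alpha_site
from niptpool.core import BASES, NiptpoolError
from conftest import make_readset


def make_column(ref="A", n=None, **counts):
    """Build a pileup column dict; counts like A_fwd=3, G_rev=1."""
    col = {"chrom": "chr1", "pos": 100, "ref": ref}
    for c in COUNT_COLUMNS:
        col[c] = counts.get(c, 0)
    col["n"] = sum(col[c] for c in COUNT_COLUMNS) if n is None else n
    return col


def columns_frame(rows):
    return pd.DataFrame(rows)


class TestPileup:
    def test_counting_example(self, toy_genome):
        # 3 reads with bases A, A, G at one position (ref A)
        pos = 1 + int(np.argmax(toy_genome["chr1"].seq == 0))  # a reference A
        rows = [(f"s{i}", "chr1", pos, pos + 74) for i in range(3)]
        rs = make_readset(rows, mismatches=[(2, "chr1", pos, "G")])
        pile = nt.pileup(rs, toy_genome, sites=[("chr1", pos)])
        col = pile[pile["pos"] == pos].iloc[0]
        assert col["ref"] == "A"
        assert col["A_fwd"] == 2 and col["G_fwd"] == 1 and col["n"] == 3

    def test_uncovered_requested_site_has_zero_depth(self, toy_genome):
        pile = nt.pileup(nt.ReadSet.empty(), toy_genome, sites=[("chr1", 500)])
        assert len(pile) == 1 and pile.iloc[0]["n"] == 0

    def test_unrequested_reference_only_positions_absent(self, toy_genome):
        rs = make_readset([("s", "chr1", 1, 75)])
        pile = nt.pileup(rs, toy_genome)
        assert len(pile) == 0

    def test_pooled_counts_equal_sum_of_per_sample_pileups(self, toy_reads, toy_genome, toy_af):
        sites = list(zip(toy_af.df["chrom"], toy_af.df["pos"]))
        site_idx = pd.MultiIndex.from_tuples(sites)
        pooled = nt.pileup(toy_reads, toy_genome, sites=sites)
        total = None
        for sample in toy_reads.samples:
            ids = toy_reads.df.index[toy_reads.df["sample"] == sample]
            sub = nt.pileup(toy_reads.subset(ids), toy_genome, sites=sites)
            counts = sub.set_index(["chrom", "pos"])[COUNT_COLUMNS + ["n"]]
            total = counts if total is None else total.add(counts, fill_value=0)
        # compare at the explicitly requested sites (every per-sample pileup
        # materializes those columns; error positions appear only in their
        # own sample's frame)
        merged = pooled.set_index(["chrom", "pos"])[COUNT_COLUMNS + ["n"]].loc[site_idx]
        pd.testing.assert_frame_equal(
            merged.sort_index(), total.loc[site_idx].sort_index().astype(np.int64)[merged.columns],
            check_dtype=False,
        )

    def test_distinct_samples_equals_depth_after_preprocessing(self, toy_reads, toy_genome, toy_af):
        filtered = nt.deduplicate_overlaps(nt.filter_mapq(toy_reads))
        sites = list(zip(toy_af.df["chrom"], toy_af.df["pos"]))
        pile = nt.pileup(filtered, toy_genome, sites=sites, distinct_samples=True)
        assert (pile["n_samples"] == pile["n"]).all()

    def test_strand_split_counts(self, toy_reads, toy_genome):
        pile = nt.pileup(toy_reads, toy_genome)
        fwd = sum(pile[f"{b}_fwd"] for b in BASES)
        rev = sum(pile[f"{b}_rev"] for b in BASES)
        assert ((fwd + rev) == pile["n"]).all()


class TestCallSite:
    def test_no_alt_reads_no_calls(self):
        assert call_site(make_column(ref="A", A_fwd=50)) == []

    def test_single_read_tail_probability(self):
        # n=300, k=1, e=0.003: P(X>=1) = 1 - 0.999^300 ~ 0.259 -> no call at 1e-8
        col = make_column(ref="A", A_fwd=299, G_fwd=1)
        assert call_site(col, alpha_site=1e-8) == []
        p = float(stats.binom.sf(0, 300, 0.001))
        assert p == pytest.approx(0.2593, abs=5e-4)
        calls = call_site(col, alpha_site=0.5)
        assert len(calls) == 1 and calls[0].p_value == pytest.approx(p)

    def test_strong_signal_called_with_af(self):
        col = make_column(ref="A", A_fwd=324, G_fwd=40)
        calls = call_site(col, alpha_site=1e-8)
        assert len(calls) == 1
        c = calls[0]
        assert c.k == 40 and c.n == 364
        assert c.af == pytest.approx(40 / 364)
        assert c.is_pass

    def test_weak_evidence_flag(self):
        col = make_column(ref="A", A_fwd=10, G_fwd=2)
        calls = call_site(col, alpha_site=1.0, min_alt=3)
        assert calls and calls[0].filters == {"weak_evidence"}

    def test_multi_allelic_site(self):
        col = make_column(ref="A", A_fwd=100, G_fwd=30, T_rev=20)
        calls = call_site(col, alpha_site=1e-8)
        assert sorted(c.alt for c in calls) == ["G", "T"]

    def test_error_rate_validated(self):
        with pytest.raises(NiptpoolError):
            call_site(make_column(ref="A", G_fwd=1), error_rate=0.7)


class TestCallPileup:
    def test_matches_per_column_enumerator(self, toy_reads, toy_genome):
        """Vectorized calls equal the brute-force per-column rule on a toy set."""
        filtered = nt.deduplicate_overlaps(nt.filter_mapq(toy_reads))
        pile = nt.pileup(filtered, toy_genome)
        alpha = 1e-4  # permissive so both call paths fire
        calls = call_pileup(pile, alpha_site=alpha)
        expected = []
        for _, col in pile.iterrows():
            for c in call_site(col, alpha_site=alpha):
                expected.append((c.chrom, c.pos, c.ref, c.alt, c.k, c.n))
        got = [tuple(r) for r in calls[["chrom", "pos", "ref", "alt", "k", "n"]].itertuples(index=False)]
        assert sorted(got) == sorted(expected)

    def test_type_one_error_controlled_on_null_sites(self):
        """~10^6 monomorphic columns at ~100x: PASS false calls <= 3.n.alpha
        with Poisson slack."""
        n_sites, depth, e = 1_000_000, 100, 0.003
        rng = np.random.default_rng(99)
        ref_codes = rng.integers(0, 4, n_sites)
        n_err = rng.binomial(depth, e, size=n_sites)
        # split errors uniformly over the three non-ref bases
        k1 = rng.binomial(n_err, 1 / 3)
        k2 = rng.binomial(n_err - k1, 0.5)
        k3 = n_err - k1 - k2
        cols = {c: np.zeros(n_sites, dtype=np.int64) for c in COUNT_COLUMNS}
        bases = list(BASES)
        for r in range(4):
            sel = ref_codes == r
            others = [b for j, b in enumerate(bases) if j != r]
            cols[f"{bases[r]}_fwd"][sel] = depth - n_err[sel]
            for kk, b in zip((k1, k2, k3), others):
                cols[f"{b}_fwd"][sel] = kk[sel]
        pile = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n_sites + 1),
                             "ref": np.array(bases, dtype=object)[ref_codes], **cols})
        pile["n"] = depth
        alpha = default_alpha_site(1_000_000)
        calls = call_pileup(pile, error_rate=e, alpha_site=alpha)
        passing = calls[calls["filter"] == "PASS"]
        expected = n_sites * 3 * alpha
        assert len(passing) <= expected + 5 * np.sqrt(expected) + 3

    def test_sensitivity_monotone_in_depth_and_af(self):
        rng = np.random.default_rng(7)
        m = 2000
        alpha = 1e-6
        rates = {}
        for n in (30, 100, 300):
            for q in (0.02, 0.05, 0.1, 0.2):
                k = rng.binomial(n, q, size=m)
                pv = stats.binom.sf(np.maximum(k, 1) - 1, n, 0.001)
                rates[(n, q)] = float(np.mean((k >= 1) & (pv <= alpha)))
        for q in (0.02, 0.05, 0.1, 0.2):
            assert rates[(30, q)] <= rates[(100, q)] + 0.02 <= rates[(300, q)] + 0.04
        for n in (30, 100, 300):
            assert rates[(n, 0.02)] <= rates[(n, 0.05)] + 0.02 <= rates[(n, 0.1)] + 0.04

    def test_af_estimator_unbiased_with_binomial_rmse(self):
        # conditional on calling, mean(k/n) -> q and RMSE ~ sqrt(q(1-q)/n)
        rng = np.random.default_rng(8)
        n, q, m = 1000, 0.1, 20_000
        k = rng.binomial(n, q, size=m)
        called = k >= 5  # essentially all draws at this depth
        af = k[called] / n
        assert abs(af.mean() - q) < 0.002
        rmse = np.sqrt(np.mean((af - q) ** 2))
        assert rmse == pytest.approx(np.sqrt(q * (1 - q) / n), rel=0.2)


class TestStrandBias:
    @pytest.mark.parametrize(
        "ref_f,ref_r,alt_f,alt_r,flagged",
        [
            (100, 100, 5, 5, False),  # balanced
            (100, 100, 20, 0, True),  # one-sided and significant
            (2, 2, 1, 0, False),  # one-sided but Fisher p above threshold
        ],
    )
    def test_examples_against_hypergeometric_oracle(self, ref_f, ref_r, alt_f, alt_r, flagged):
        calls = pd.DataFrame([{"chrom": "chr1", "pos": 100, "ref": "A", "alt": "G",
                               "k": alt_f + alt_r, "n": ref_f + ref_r + alt_f + alt_r,
                               "af": 0.1, "p_value": 1e-12, "filter": "PASS"}])
        pile = pd.DataFrame([make_column(ref="A", A_fwd=ref_f, A_rev=ref_r, G_fwd=alt_f, G_rev=alt_r)])
        out = nt.strand_bias_filter(calls, pile, p_threshold=1e-3)
        assert ("strand_bias" in out.iloc[0]["filter"]) == flagged
        # oracle: two-sided Fisher p from the hypergeometric distribution
        table = np.array([[ref_f, ref_r], [alt_f, alt_r]])
        n_tot, n_row, n_col = table.sum(), table[1].sum(), table[:, 0].sum()
        hg = stats.hypergeom(n_tot, n_row, n_col)
        p_obs = hg.pmf(alt_f)
        p_two = sum(hg.pmf(x) for x in range(n_row + 1) if hg.pmf(x) <= p_obs * (1 + 1e-9))
        assert (p_two < 1e-3 and max(alt_f, alt_r) / (alt_f + alt_r) >= 0.9) == flagged


class TestTiTv:
    def test_counting_example(self):
        assert nt.titv_ratio([("A", "G"), ("C", "T"), ("A", "C")]) == pytest.approx(2.0)

    def test_zero_transversions_signalled(self):
        with pytest.raises(NiptpoolError):
            nt.titv_ratio([("A", "G"), ("G", "A")])

    def test_uniform_random_alts_give_half(self):
        rng = np.random.default_rng(11)
        refs = np.array(list(BASES))[rng.integers(0, 4, 100_000)]
        pairs = []
        for r in refs:
            others = [b for b in BASES if b != r]
            pairs.append((r, others[rng.integers(0, 3)]))
        assert nt.titv_ratio(pairs) == pytest.approx(0.5, abs=0.02)


class TestCallsetVCF:
    def test_round_trip(self, small_report, tmp_path):
        calls = small_report.calls
        path = tmp_path / "c.vcf"
        nt.write_callset(calls, path, genome=small_report.sim.genome)
        back = nt.read_callset(path)
        for col in ("chrom", "pos", "ref", "alt", "k", "n", "filter"):
            assert list(back[col]) == list(calls[col])
        assert np.allclose(back["af"], calls["af"], atol=1e-6)

    def test_empty_callset(self, toy_genome, tmp_path):
        empty = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "k", "n", "af", "p_value", "filter"])
        path = tmp_path / "e.vcf"
        nt.write_callset(empty, path, genome=toy_genome)
        assert len(nt.read_callset(path)) == 0

    def test_multiallelic_split_style(self, toy_genome, tmp_path):
        calls = pd.DataFrame(
            [("chr1", 10, "A", "G", 5, 50, 0.1, 1e-9, "PASS"),
             ("chr1", 10, "A", "T", 4, 50, 0.08, 1e-8, "PASS"),
             ("chr1", 99, "C", "T", 6, 40, 0.15, 1e-9, "PASS")],
            columns=["chrom", "pos", "ref", "alt", "k", "n", "af", "p_value", "filter"],
        )
        path = tmp_path / "m.vcf"
        nt.write_callset(calls, path, genome=toy_genome)
        back = nt.read_callset(path)
        assert len(back) == 3
        assert list(back["alt"]) == ["G", "T", "T"]

    def test_unsorted_rejected(self, toy_genome, tmp_path):
        calls = pd.DataFrame(
            [("chr1", 99, "C", "T", 6, 40, 0.15, 1e-9, "PASS"),
             ("chr1", 10, "A", "G", 5, 50, 0.1, 1e-9, "PASS")],
            columns=["chrom", "pos", "ref", "alt", "k", "n", "af", "p_value", "filter"],
        )
        with pytest.raises(NiptpoolError):
            nt.write_callset(calls, tmp_path / "u.vcf", genome=toy_genome)


class TestTiTvContrast:
    def test_true_calls_near_two_false_calls_near_half(self):
        """With truth Ti/Tv = 2 and uniform errors, calls at truth sites keep
        Ti/Tv ~ 2 while error-driven false calls drift to ~ 0.5."""
        rng = np.random.default_rng(12)
        genome = nt.ToyGenome.random([("chr1", 400_000, "autosome")], seed=13)
        af = nt.simulate_population_afs(genome, 4000, {"p": 0.0}, titv=2.0, seed=14)
        truth_pairs = list(zip(af.df["ref"], af.df["alt"]))
        assert nt.titv_ratio(truth_pairs) == pytest.approx(2.0, abs=0.25)
        # error-only false calls: uniform alt among 3 non-ref bases
        n_sites = 300_000
        refs = np.array(list(BASES))[rng.integers(0, 4, n_sites)]
        n_err = rng.binomial(60, 0.003, size=n_sites)
        false_pairs = []
        for i in np.flatnonzero(n_err >= 3):
            # >=3 same-base errors would be needed to call; approximate the
            # winning alt by a uniform pick, matching the uniform error model
            others = [b for b in BASES if b != refs[i]]
            false_pairs.append((refs[i], others[rng.integers(0, 3)]))
        assert len(false_pairs) > 100
        assert nt.titv_ratio(false_pairs) == pytest.approx(0.5, abs=0.15)
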