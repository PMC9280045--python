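import math

import numpy as np
import pytest

from woxkit import codon_usage as cu
from woxkit import synthetic_data as sim
from woxkit.io_formats import SequenceRecord


@pytest.fixture(scope="module")
def families():
    return cu.synonymous_families()


@pytest.fixture(scope="module")
def printed_tables():
    return cu.load_fixture_usage_tables()


@pytest.fixture(scope="module")
def printed_ratios():
    return cu.load_fixture_ratio_tables()


class TestFamilies:
    def test_partition_covers_64(self, families):
        codons = [c for f in families for c in f.codons]
        assert len(codons) == 64 == len(set(codons))

    def test_ter_family_size(self, families):
        ter = next(f for f in families if f.amino_acid == "TER")
        assert set(ter.codons) == {"UAA", "UAG", "UGA"}


class TestCountCodons:
    def test_single_gene(self):
        counts = cu.count_codons([SequenceRecord("a", "ATGTAA")])
        assert counts.counts["AUG"] == 1 and counts.counts["UAA"] == 1
        assert counts.n_total == 2

    def test_ambiguous_triplet_skipped(self):
        counts = cu.count_codons([SequenceRecord("a", "ATGNNGTAA")])
        assert counts.counts["AUG"] == 1 and counts.counts["UAA"] == 1
        assert counts.n_skipped == 1

    def test_additivity(self):
        rec = SequenceRecord("a", "ATGGCAGCATAA")
        counts = cu.count_codons([rec, rec])
        assert counts.counts["GCA"] == 4
        assert counts.counts["AUG"] == 2 and counts.counts["UAA"] == 2

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            cu.count_codons([SequenceRecord("a", "ATGT")])


class TestComputeUsage:
    def test_two_codon_family_forced_arithmetic(self):
        # 3 AAA vs 1 AAG (Lys, k=2)
        recs = [SequenceRecord("a", "AAA" * 3 + "AAG")]
        table = cu.compute_usage(cu.count_codons(recs))
        assert table.df.loc["AAA", "rscu"] == pytest.approx(1.5)
        assert table.df.loc["AAG", "rscu"] == pytest.approx(0.5)
        assert table.df.loc["AAA", "rfsc"] == pytest.approx(75.0)
        assert table.df.loc["AAA", "high_frequency"] == True  # noqa: E712
        assert table.df.loc["AAG", "high_frequency"] == False  # noqa: E712

    def test_published_gca_row(self, printed_tables):
        row = printed_tables["JcWOX"].df.loc["GCA"]
        assert row["rscu"] == 2.09 and row["rfsc"] == 52.26 and row["k"] == 4
        assert row["bias"] == "positive"
        assert row["high_frequency"] == True  # noqa: E712

    def test_published_acu_exact_boundary(self, printed_tables):
        # RFSC 37.50 = 1.5 * (100/4): the >= clause must include the boundary
        row = printed_tables["HbWOX"].df.loc["ACU"]
        assert row["rfsc"] == 37.50
        assert row["high_frequency"] == True  # noqa: E712

    def test_single_codon_family_never_classified(self, printed_tables):
        for table in printed_tables.values():
            assert table.df.loc["AUG", "rfsc"] == 100.0
            assert table.df.loc["AUG", "high_frequency"] is cu.pd.NA
            assert table.df.loc["UGG", "high_frequency"] is cu.pd.NA

    def test_unobserved_family_undefined(self):
        counts = cu.count_codons([SequenceRecord("a", "ATGTAA")])
        table = cu.compute_usage(counts)
        assert table.df.loc["AAA", "bias"] == "undefined"
        assert math.isnan(table.df.loc["AAA", "rscu"])

    def test_family_identities_on_simulated_sets(self, families):
        records, _ = sim.simulate_cds_set(30, 120, dirichlet_alpha=0.8, seed=4)
        table = cu.compute_usage(cu.count_codons(records))
        for fam in families:
            sub = table.df.loc[list(fam.codons)]
            if sub["count"].sum() == 0:
                continue
            assert sub["rscu"].sum() == pytest.approx(fam.k, abs=1e-9)
            assert sub["rfsc"].sum() == pytest.approx(100.0, abs=1e-9)
            np.testing.assert_allclose(
                sub["rfsc"], sub["rscu"] * 100.0 / fam.k, atol=1e-9
            )

    def test_rscu_converges_to_k_times_p(self):
        # Ala codon probabilities fixed; 4e5 codons drive RSCU -> k*p
        probs = {"A": {"GCT": 0.5, "GCC": 0.3, "GCA": 0.15, "GCG": 0.05}}
        records, _ = sim.simulate_cds_set(400, 1000, family_probs=probs, seed=9)
        table = cu.compute_usage(cu.count_codons(records))
        for codon, p in [("GCU", 0.5), ("GCC", 0.3), ("GCA", 0.15), ("GCG", 0.05)]:
            assert table.df.loc[codon, "rscu"] == pytest.approx(4 * p, abs=0.05)


class TestBiasPartition:
    def test_sums_to_universe(self, printed_tables):
        parts = cu.bias_partition(list(printed_tables.values()))
        assert sum(parts) == 64

    def test_identical_tables(self, printed_tables):
        table = printed_tables["JcWOX"]
        npos, nneg, nnone, ndiff = cu.bias_partition([table, table])
        assert ndiff == 0
        assert npos + nneg + nnone == 64

    def test_single_flip_moves_one_codon(self, printed_tables):
        import copy

        tables = [copy.deepcopy(t) for t in printed_tables.values()]
        base = cu.bias_partition(tables)
        # GCC is negative in all four species; flip one across the 1.0 line
        tables[0].df.loc["GCC", "bias"] = "positive"
        flipped = cu.bias_partition(tables)
        assert flipped[3] == base[3] + 1
        assert flipped[1] == base[1] - 1


class TestConsensusHighFrequency:
    def test_single_table_identity(self, printed_tables):
        table = printed_tables["MeWOX"]
        assert cu.consensus_high_frequency([table]) == table.high_frequency_set()

    def test_disjoint_sets_empty(self, printed_tables):
        import copy

        a = copy.deepcopy(printed_tables["JcWOX"])
        b = copy.deepcopy(printed_tables["JcWOX"])
        a.df["high_frequency"] = False
        a.df.loc["GCA", "high_frequency"] = True
        b.df["high_frequency"] = False
        b.df.loc["GAU", "high_frequency"] = True
        assert cu.consensus_high_frequency([a, b]) == set()


class TestCodonFrequency:
    def test_degenerate_and_uniform(self):
        counts = cu.count_codons([SequenceRecord("a", "ATGATGATG")])
        freq = cu.codon_frequency(counts)
        assert freq["AUG"] == 1000.0 and freq["GCA"] == 0.0

    def test_scale_invariance_and_total(self):
        rec = SequenceRecord("a", "ATGGCAGCTTGGTAA")
        f1 = cu.codon_frequency(cu.count_codons([rec]))
        f2 = cu.codon_frequency(cu.count_codons([rec, rec]))
        assert f1 == f2
        assert sum(f1.values()) == pytest.approx(1000.0, abs=1e-9)

    def test_empty_set_rejected(self):
        counts = cu.CodonCounts("empty", {c: 0 for c in f1_codons()})
        with pytest.raises(ValueError):
            cu.codon_frequency(counts)


def f1_codons():
    return [c for f in cu.synonymous_families() for c in f.codons]


class TestRatioCompare:
    def test_identical_maps_all_similar(self):
        freq = {c: 1000.0 / 64 for c in f1_codons()}
        table = cu.ratio_compare(freq, freq)
        assert (table.df["ratio"] == 1.0).all()
        assert (table.df["class"] == "similar").all()

    def test_band_inclusive_at_both_ends(self):
        freq_ref = {c: 10.0 for c in f1_codons()}
        freq_set = dict(freq_ref)
        freq_set["GCA"] = 20.0  # ratio 2.00
        freq_set["GCU"] = 5.0   # ratio 0.50
        table = cu.ratio_compare(freq_set, freq_ref)
        assert table.df.loc["GCA", "class"] == "divergent"
        assert table.df.loc["GCU", "class"] == "divergent"

    def test_zero_reference_rules(self):
        freq_ref = {c: 10.0 for c in f1_codons()}
        freq_set = {c: 10.0 for c in f1_codons()}
        freq_ref["UAG"] = 0.0
        freq_set["UGA"] = 0.0
        freq_ref["UGA"] = 0.0
        table = cu.ratio_compare(freq_set, freq_ref)
        assert table.df.loc["UAG", "class"] == "divergent"
        assert table.df.loc["UGA", "class"] == "undefined"

    def test_reciprocal_symmetry(self, rng):
        freqs = rng.uniform(0.1, 50.0, size=(2, 64))
        a = dict(zip(f1_codons(), freqs[0]))
        b = dict(zip(f1_codons(), freqs[1]))
        ab = cu.ratio_compare(a, b)
        ba = cu.ratio_compare(b, a)
        assert ab.divergent_set() == ba.divergent_set()

    def test_published_jc_at_column(self, printed_ratios):
        table = printed_ratios["JcWOX/At"]
        assert table.divergent_set() == {"GCU", "CGC", "UCG", "UAA", "UAG", "UGA"}


class TestRankHosts:
    def test_identical_candidate_first(self):
        freq = {c: 1000.0 / 64 for c in f1_codons()}
        other = dict(freq)
        other["GCA"] = freq["GCA"] * 3
        ranked = cu.rank_hosts(freq, {"same": dict(freq), "far": other})
        assert ranked[0][0] == "same" and ranked[0][1] == 0

    def test_ordering_by_divergent_count(self, printed_ratios):
        # reconstruct per-host divergence orders from the published ratios
        div = {k: t.n_divergent for k, t in printed_ratios.items() if k.startswith("JcWOX")}
        assert div["JcWOX/At"] < div["JcWOX/Os"]

    def test_tie_broken_by_mean_log_ratio(self):
        freq = {c: 10.0 for c in f1_codons()}
        near = dict(freq)
        far = dict(freq)
        for c in ("GCA", "GCU"):
            near[c] = 11.0   # |log2 r| small, not divergent
            far[c] = 19.0    # |log2 r| large, still inside the band
        ranked = cu.rank_hosts(freq, {"zfar": far, "anear": near})
        assert [r[0] for r in ranked] == ["anear", "zfar"]
        assert ranked[0][1] == ranked[1][1] == 0
        assert ranked[0][2] < ranked[1][2]
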