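"""Screen scoring: read counting, empirical-null thresholding, gene calls, RIGER."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurotf import screen_scoring as ss
from neurotf.screen_scoring import ADAPTER


@pytest.fixture()
def tiny_manifest():
    # sequences pairwise distant (Hamming > 2) so 1-mismatch matching is unambiguous
    return pd.DataFrame({
        "guide_id": ["g1", "g2", "g3", "ntc1"],
        "gene": ["TFA", "TFA", "TFB", pd.NA],
        "is_ntc": [False, False, False, True],
        "sequence": ["A" * 20, "C" * 20, "G" * 20, "T" * 20],
    })


class TestReadCounting:
    def test_exact_match_after_adapter_trim(self, tiny_manifest):
        reads = [ADAPTER + "A" * 20]
        counts, stats = ss.count_guides_from_reads(reads, tiny_manifest)
        assert counts["g1"] == 1 and stats["matched"] == 1

    def test_one_substitution_still_matches(self, tiny_manifest):
        reads = [ADAPTER + "A" * 10 + "C" + "A" * 9]
        counts, _ = ss.count_guides_from_reads(reads, tiny_manifest)
        assert counts["g1"] == 1

    def test_two_substitutions_do_not_match(self, tiny_manifest):
        reads = [ADAPTER + "CC" + "A" * 18]
        counts, stats = ss.count_guides_from_reads(reads, tiny_manifest)
        assert counts.sum() == 0 and stats["unmatched"] == 1

    def test_short_remainder_after_trim_discarded(self, tiny_manifest):
        reads = [ADAPTER + "A" * 12]
        _, stats = ss.count_guides_from_reads(reads, tiny_manifest)
        assert stats["too_short"] == 1

    def test_read_without_adapter_discarded(self, tiny_manifest):
        reads = ["ACGT" * 12]
        _, stats = ss.count_guides_from_reads(reads, tiny_manifest)
        assert stats["no_adapter"] == 1

    def test_adapter_with_mismatches_within_tolerance(self, tiny_manifest):
        mutated = "AA" + ADAPTER[2:]  # 2 errors <= floor(0.2 * 24)
        reads = [mutated + "G" * 20]
        counts, _ = ss.count_guides_from_reads(reads, tiny_manifest)
        assert counts["g3"] == 1

    def test_partial_adapter_at_read_start(self, tiny_manifest):
        reads = [ADAPTER[-8:] + "C" * 20]  # 8-base suffix overlap
        counts, _ = ss.count_guides_from_reads(reads, tiny_manifest)
        assert counts["g2"] == 1

    def test_ambiguous_one_mismatch_hit_discarded(self):
        # two guides at Hamming distance 2: their midpoint is ambiguous
        man = pd.DataFrame({
            "guide_id": ["g1", "g2"],
            "gene": ["TFA", "TFB"],
            "is_ntc": [False, False],
            "sequence": ["A" * 20, "CC" + "A" * 18],
        })
        probe = "CA" + "A" * 18  # one mismatch from both
        _, stats = ss.count_guides_from_reads([ADAPTER + probe], man)
        assert stats["ambiguous"] == 1

    def test_empty_stream_warns_and_returns_zeros(self, tiny_manifest):
        with pytest.warns(UserWarning, match="empty read stream"):
            counts, _ = ss.count_guides_from_reads([], tiny_manifest)
        assert (counts == 0).all()

    def test_fastq_file_input(self, tiny_manifest, tmp_path):
        fq = tmp_path / "reads.fastq"
        read = ADAPTER + "A" * 20
        fq.write_text(f"@r1\n{read}\n+\n{'I' * len(read)}\n")
        counts, _ = ss.count_guides_from_reads(str(fq), tiny_manifest)
        assert counts["g1"] == 1


class TestGuideEnrichment:
    @pytest.fixture()
    def counts(self):
        return pd.DataFrame({"num": [900, 100, 0], "den": [100, 900, 0]},
                            index=["a", "b", "c"])

    def test_equal_rpm_gives_zero(self):
        counts = pd.DataFrame({"x": [10, 30], "y": [20, 60]}, index=["a", "b"])
        enr = ss.guide_enrichment(counts, "x", "y")
        assert np.allclose(enr, 0.0)

    def test_zero_vs_zero_is_exactly_zero(self, counts):
        enr = ss.guide_enrichment(counts, "num", "den")
        assert enr["c"] == 0.0

    def test_hand_computed_rpm_ratio(self):
        # counts chosen so RPM = 900 vs 100 per guide with depth 1e6
        counts = pd.DataFrame({"num": [900] * 1000 + [100] * 1000,
                               "den": [100] * 1000 + [900] * 1000})
        enr = ss.guide_enrichment(counts, "num", "den")
        assert enr.iloc[0] == pytest.approx(math.log2(901 / 101), abs=1e-12)

    def test_zero_depth_population_rejected(self, counts):
        counts = counts.assign(empty=0)
        with pytest.raises(ValueError, match="zero total"):
            ss.guide_enrichment(counts, "num", "empty")

    @given(st.integers(0, 2**20), st.integers(1, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_antisymmetric_at_equal_depth(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 1000, n)
        b = rng.integers(0, 1000, n)
        # equalize depths so RPM pseudocounts mirror exactly
        pad = abs(int(a.sum()) - int(b.sum()))
        counts = pd.DataFrame({"x": np.append(a, [pad if a.sum() < b.sum() else 0]),
                               "y": np.append(b, [pad if b.sum() > a.sum() else 0])})
        counts = counts[counts.sum(axis=1) > 0]
        if counts["x"].sum() == 0 or counts["y"].sum() == 0:
            return
        fwd = ss.guide_enrichment(counts, "x", "y")
        rev = ss.guide_enrichment(counts, "y", "x")
        assert np.allclose(fwd, -rev, atol=1e-9)


class TestEmpiricalThreshold:
    def make(self, ntc_values, targeting_values=()):
        n_t = len(targeting_values)
        man = pd.DataFrame({
            "guide_id": [f"t{i}" for i in range(n_t)]
            + [f"n{i}" for i in range(len(ntc_values))],
            "gene": ["TF"] * n_t + [pd.NA] * len(ntc_values),
            "is_ntc": [False] * n_t + [True] * len(ntc_values),
        })
        enr = pd.Series(list(targeting_values) + list(ntc_values),
                        index=man["guide_id"].to_numpy(), dtype=float)
        return man, enr

    def test_nearest_rank_on_one_to_ten(self):
        man, enr = self.make(range(1, 11))
        thr = ss.empirical_threshold(enr, man, q=0.9)
        assert thr == 9.0
        assert (enr[man.loc[man["is_ntc"], "guide_id"]] > thr).sum() == 1

    def test_all_identical_ntc_enriches_nothing(self):
        man, enr = self.make([2.0] * 50)
        thr = ss.empirical_threshold(enr, man)
        assert thr == 2.0
        assert (enr > thr).sum() == 0

    def test_exactly_ten_percent_of_distinct_ntcs_above(self):
        rng = np.random.default_rng(0)
        man, enr = self.make(rng.standard_normal(1000))
        thr = ss.empirical_threshold(enr, man, q=0.9)
        ntc_vals = enr[man.loc[man["is_ntc"], "guide_id"]]
        assert (ntc_vals > thr).sum() == 100

    def test_requires_nontargeting_guides(self):
        man, enr = self.make([1.0] * 5, targeting_values=[0.0] * 5)
        with pytest.raises(ValueError):
            ss.empirical_threshold(enr, man)


class TestGeneCalls:
    @pytest.fixture()
    def screen_calls(self, small_screen):
        manifest, truth, counts = small_screen
        enr_a = ss.guide_enrichment(counts, "sorted_negative", "unsorted_iN")
        enr_b = ss.guide_enrichment(counts, "sorted_negative", "sorted_positive")
        return manifest, truth, enr_a, enr_b

    def test_two_enriched_guides_trigger_call(self):
        man = pd.DataFrame({
            "guide_id": ["g1", "g2", "g3"] + [f"n{i}" for i in range(20)],
            "gene": ["TFA"] * 3 + [pd.NA] * 20,
            "is_ntc": [False] * 3 + [True] * 20,
        })
        vals = [3.0, 2.5, 0.1] + list(np.linspace(0, 2.0, 20))
        enr = pd.Series(vals, index=man["guide_id"].to_numpy())
        calls = ss.call_netfs(enr, enr, man)
        assert calls.loc["TFA", "n_enriched_a"] == 2
        assert bool(calls.loc["TFA", "is_netf"])

    def test_single_comparison_call_is_not_intersection(self):
        man = pd.DataFrame({
            "guide_id": ["g1", "g2"] + [f"n{i}" for i in range(20)],
            "gene": ["TFA"] * 2 + [pd.NA] * 20,
            "is_ntc": [False] * 2 + [True] * 20,
        })
        high = pd.Series([5.0, 5.0] + list(np.linspace(0, 1, 20)),
                         index=man["guide_id"].to_numpy())
        low = pd.Series([0.0, 0.0] + list(np.linspace(0, 1, 20)),
                        index=man["guide_id"].to_numpy())
        calls = ss.call_netfs(high, low, man)
        assert bool(calls.loc["TFA", "called_a"])
        assert not bool(calls.loc["TFA", "is_netf"])

    def test_planted_essentials_recovered(self, screen_calls):
        manifest, truth, enr_a, enr_b = screen_calls
        calls = ss.call_netfs(enr_a, enr_b, manifest)
        assert truth.essential_tfs <= set(calls.index[calls["is_netf"]])

    def test_raising_min_guides_never_adds_genes(self, screen_calls):
        manifest, _, enr_a, enr_b = screen_calls
        previous = None
        for k in (1, 2, 3, 4):
            called = set(ss.call_netfs(enr_a, enr_b, manifest, min_guides=k)
                         .query("is_netf").index)
            if previous is not None:
                assert called <= previous
            previous = called

    def test_intersection_is_subset_of_each_comparison(self, screen_calls):
        manifest, _, enr_a, enr_b = screen_calls
        calls = ss.call_netfs(enr_a, enr_b, manifest)
        netf = set(calls.query("is_netf").index)
        assert netf <= set(calls.query("called_a").index)
        assert netf <= set(calls.query("called_b").index)

    def test_unknown_guide_rejected(self, tiny_manifest):
        enr = pd.Series([1.0], index=["mystery"])
        with pytest.raises(ValueError, match="absent from manifest"):
            ss.call_netfs(enr, enr, tiny_manifest)

    def test_ntc_false_call_rate_bounded_by_construction(self):
        # iid scores: targeting NTC-lookalikes must be called at <= 10% + noise
        rng = np.random.default_rng(3)
        man = pd.DataFrame({
            "guide_id": [f"x{i}" for i in range(5000)],
            "gene": [pd.NA if i < 1000 else f"G{i // 5}" for i in range(5000)],
            "is_ntc": [i < 1000 for i in range(5000)],
        })
        enr = pd.Series(rng.standard_normal(5000), index=man["guide_id"].to_numpy())
        thr = ss.empirical_threshold(enr, man)
        ntc_rate = (enr[man["is_ntc"].to_numpy()] > thr).mean()
        assert ntc_rate <= 0.1


class TestRiger:
    @pytest.fixture()
    def tiny(self):
        man = pd.DataFrame({
            "guide_id": ["a1", "a2", "b1", "b2", "c1", "c2"],
            "gene": ["G1", "G1", "G2", "G2", "G3", "G3"],
            "is_ntc": [False] * 6,
        })
        enr = pd.Series([6, 5, 4, 3, 2, 1], dtype=float,
                        index=man["guide_id"].to_numpy())
        return man, enr

    def test_hand_computed_score_for_best_gene(self, tiny):
        man, enr = tiny
        res = ss.riger(enr, man, exact=True).set_index("gene")
        assert res.loc["G1", "score"] == pytest.approx(0.5 * (1 / 6) + 0.5 * (2 / 6))

    def test_exact_p_matches_full_permutation_enumeration(self, tiny):
        man, enr = tiny
        res = ss.riger(enr, man, exact=True).set_index("gene")
        # independent oracle: enumerate all 6! label permutations literally
        ranks = np.array([1, 2, 3, 4, 5, 6]) / 6
        obs = {"G1": 0.5 * (ranks[0] + ranks[1]),
               "G2": 0.5 * (ranks[2] + ranks[3]),
               "G3": 0.5 * (ranks[4] + ranks[5])}
        for gene, slot in (("G1", 0), ("G2", 1), ("G3", 2)):
            hits = total = 0
            for perm in itertools.permutations(range(6)):
                mine = sorted(ranks[list(perm[2 * slot:2 * slot + 2])])
                score = 0.5 * (mine[0] + mine[1])
                hits += score <= obs[gene] + 1e-12
                total += 1
            assert res.loc[gene, "perm_p"] == pytest.approx(hits / total)

    def test_minimal_score_gene_gets_smallest_possible_p(self):
        # the gene holding the library's two best guides reaches the minimal
        # score; with a large library no permutation ties it, so p = 1/(n+1)
        rng = np.random.default_rng(4)
        n_genes = 200
        man = pd.DataFrame({
            "guide_id": [f"g{i}_{j}" for i in range(n_genes) for j in (1, 2)],
            "gene": [f"G{i}" for i in range(n_genes) for _ in (1, 2)],
            "is_ntc": [False] * 2 * n_genes,
        })
        vals = rng.standard_normal(2 * n_genes)
        vals[0], vals[1] = 50.0, 49.0  # G0 owns the top two ranks
        enr = pd.Series(vals, index=man["guide_id"].to_numpy())
        res = ss.riger(enr, man, n_perm=999, seed=0).set_index("gene")
        assert res.loc["G0", "perm_p"] == pytest.approx(1 / 1000)

    def test_score_ignores_guides_below_top_two(self):
        man = pd.DataFrame({
            "guide_id": [f"g{i}" for i in range(6)] + ["o1", "o2"],
            "gene": ["G1"] * 6 + ["G2"] * 2,
            "is_ntc": [False] * 8,
        })
        base = pd.Series([8, 7, 3, 2, 1, 0.5, 6, 5], dtype=float,
                         index=man["guide_id"].to_numpy())
        shuffled = base.copy()
        shuffled[["g2", "g3", "g4", "g5"]] = [0.5, 1, 2, 3]  # permute below top 2
        s1 = ss.riger(base, man, n_perm=10, seed=0).set_index("gene")["score"]
        s2 = ss.riger(shuffled, man, n_perm=10, seed=0).set_index("gene")["score"]
        assert s1.equals(s2)

    def test_monte_carlo_p_consistent_with_exact(self, tiny):
        man, enr = tiny
        exact = ss.riger(enr, man, exact=True).set_index("gene")["perm_p"]
        mc = ss.riger(enr, man, n_perm=4000, seed=1).set_index("gene")["perm_p"]
        for gene in exact.index:
            se = math.sqrt(exact[gene] * (1 - exact[gene]) / 4000)
            assert abs(mc[gene] - exact[gene]) < 3 * se + 1 / 4000

    def test_single_guide_gene_excluded_with_warning(self):
        man = pd.DataFrame({
            "guide_id": ["a1", "a2", "b1"],
            "gene": ["G1", "G1", "G2"],
            "is_ntc": [False] * 3,
        })
        enr = pd.Series([3, 2, 1], dtype=float, index=man["guide_id"].to_numpy())
        with pytest.warns(UserWarning, match="< 2 guides"):
            res = ss.riger(enr, man, n_perm=10, seed=0)
        assert set(res["gene"]) == {"G1"}

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(12)
        n_genes = 400
        man = pd.DataFrame({
            "guide_id": [f"g{i}_{j}" for i in range(n_genes) for j in (1, 2)],
            "gene": [f"G{i}" for i in range(n_genes) for _ in (1, 2)],
            "is_ntc": [False] * 2 * n_genes,
        })
        enr = pd.Series(rng.standard_normal(2 * n_genes),
                        index=man["guide_id"].to_numpy())
        res = ss.riger(enr, man, n_perm=500, seed=2)
        assert kstest(res["perm_p"], "uniform").pvalue > 0.01


class TestQcAndDepletion:
    def test_uniform_counts_have_unit_percentile_ratio(self):
        counts = pd.DataFrame({"pop": [57] * 100})
        qc = ss.library_qc(counts, "pop")
        assert qc["percentile_ratio_90_10"] == 1.0
        assert qc["zero_fraction"] == 0.0

    def test_constructed_percentile_ratio(self):
        # nearest-rank p90 = 569, p10 = 99; pseudocount 1 gives exactly 5.7
        vals = [99] * 50 + [300] * 39 + [569] * 11
        qc = ss.library_qc(pd.DataFrame({"pop": vals}), "pop")
        assert qc["percentile_ratio_90_10"] == pytest.approx(5.7)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            ss.library_qc(pd.DataFrame({"pop": [0, 0]}), "pop")
        with pytest.raises(KeyError):
            ss.library_qc(pd.DataFrame({"pop": [1]}), "missing")

    def test_depletion_requires_both_populations(self, small_screen):
        _, _, counts = small_screen
        with pytest.raises(KeyError):
            ss.guide_enrichment(counts, "plasmid", "not_a_population")
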