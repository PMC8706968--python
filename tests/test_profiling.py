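"""Activity profiling: PAM summaries, pathways, correlations, stats."""

import numpy as np
import pytest
from scipy import stats as sps

import paircut as pc
from paircut.calling import IndelEvent, PairEditingProfile, RepairType

from oracles import oracle_mwu_exact_p, oracle_u_statistic


def _pair(pid, pam, target=None):
    if target is None:
        target = pam + "ACGTACGTACGTACGTACGTACG" + "GCATCGTACGTGACA"[:15]
    return pc.GuideTargetPair(pid, target[4:27], "", target, pam)


class TestPamSummaries:
    def test_single_pair_group(self):
        lib = [_pair("p1", "TTTA")]
        out = pc.summarize_by_pam({"p1": 0.4}, lib, ["TTTV"])
        assert len(out) == 1
        assert out[0].mean_frequency == pytest.approx(0.4)
        assert out[0].n_targets == 1

    def test_group_mean(self):
        lib = [_pair("p1", "TTTA"), _pair("p2", "TTTC")]
        out = pc.summarize_by_pam({"p1": 0.2, "p2": 0.4}, lib, ["TTTV"])
        assert out[0].mean_frequency == pytest.approx(0.3)

    def test_empty_group_missing(self):
        lib = [_pair("p1", "TTTA")]
        out = pc.summarize_by_pam({"p1": 0.4}, lib, ["TTCV"])
        assert out == []

    def test_order_invariance_and_recombination(self):
        lib = [_pair(f"p{i}", "TTTA") for i in range(6)]
        freqs = {f"p{i}": v for i, v in enumerate([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])}
        fwd = pc.summarize_by_pam(freqs, lib, ["TTTA"])[0]
        rev = pc.summarize_by_pam(dict(reversed(freqs.items())), lib[::-1],
                                  ["TTTA"])[0]
        assert fwd.mean_frequency == pytest.approx(rev.mean_frequency)
        # weighted recombination of subgroup means gives the full mean
        a = pc.summarize_by_pam({k: freqs[k] for k in ["p0", "p1"]}, lib, ["TTTA"])[0]
        b = pc.summarize_by_pam({k: freqs[k] for k in ["p2", "p3", "p4", "p5"]},
                                lib, ["TTTA"])[0]
        recombined = (a.mean_frequency * a.n_targets + b.mean_frequency * b.n_targets) / 6
        assert recombined == pytest.approx(fwd.mean_frequency)


class TestPathwayClassification:
    def test_repeat_collapse_is_mmej(self):
        ref = "TTTA" + "GCATCGTCGAT" + "ACGTAC" + "GG" + "ACGTAC" + "TTGACCATGCAAG"
        rt = RepairType((IndelEvent("deletion", 15, 8),), 5)
        assert pc.classify_pathway(rt, ref) == "MMEJ"

    def test_insertion_is_nhej(self):
        ref = "TTTA" + "A" * 38
        rt = RepairType((IndelEvent("insertion", 22, 2, "GT"),), 3)
        assert pc.classify_pathway(rt, ref) == "NHEJ"

    def test_repeat_free_deletion_is_nhej(self):
        rng = np.random.default_rng(8)
        ref = "".join(rng.choice(list("ACGT"), size=42))
        rt_hits = {(s, d) for s, d, _ in pc.find_microhomologies(ref, min_len=2)}
        for start in (5, 20, 30):
            rt = RepairType((IndelEvent("deletion", start, 4),), 1)
            expected = "MMEJ" if (start, 4) in rt_hits else "NHEJ"
            assert pc.classify_pathway(rt, ref) == expected

    def test_agrees_with_microhomology_search(self):
        """Cross-module consistency on every microhomology deletion."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            ref = "".join(rng.choice(list("ACGT"), size=42))
            for s, d, k in pc.find_microhomologies(ref, min_len=2):
                rt = RepairType((IndelEvent("deletion", s, d),), 1)
                assert pc.classify_pathway(rt, ref) == "MMEJ"


class TestSpectrum:
    def _profile(self, counts):
        prof = PairEditingProfile("p")
        for i, n in enumerate(counts):
            prof.edited_types[(IndelEvent("deletion", 20 + i, 2),)] = n
        return prof

    def test_single_type(self):
        spec = pc.repair_type_spectrum(self._profile([7]))
        assert [round(p, 6) for _, p in spec] == [1.0]

    def test_proportions(self):
        spec = pc.repair_type_spectrum(self._profile([30, 70]))
        assert [p for _, p in spec] == pytest.approx([0.7, 0.3])

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            counts = rng.integers(1, 50, size=8)
            spec = pc.repair_type_spectrum(self._profile(list(counts)))
            assert sum(p for _, p in spec) == pytest.approx(1.0)

    def test_empty_spectrum(self):
        assert pc.repair_type_spectrum(self._profile([])) == []


class TestReplicateCorrelation:
    def test_identity_gives_r_one(self):
        f = {f"p{i}": v for i, v in enumerate([0.1, 0.3, 0.5, 0.7])}
        assert pc.replicate_correlation(f, f).statistic == pytest.approx(1.0)

    def test_negation_gives_r_minus_one(self):
        a = {f"p{i}": v for i, v in enumerate([0.1, 0.3, 0.5])}
        b = {f"p{i}": 0.6 - v for i, v in enumerate([0.1, 0.3, 0.5])}
        assert pc.replicate_correlation(a, b).statistic == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        a = {f"p{i}": v for i, v in enumerate([1, 2, 3, 4])}
        b = {f"p{i}": v for i, v in enumerate([2, 4, 5, 9])}
        x, y = np.array([1, 2, 3, 4.0]), np.array([2, 4, 5, 9.0])
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pc.replicate_correlation(a, b).statistic == pytest.approx(expected)

    def test_too_few_shared(self):
        with pytest.raises(ValueError, match="shared"):
            pc.replicate_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


class TestMannWhitney:
    def test_identical_multisets_p_near_one(self):
        res = pc.compare_two([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value >= 0.99

    def test_complete_separation_u_zero(self):
        res = pc.compare_two([10, 11, 12], [1, 2, 3])
        # U for the larger group is n_a*n_b; for the smaller it is 0
        assert pc.compare_two([1, 2, 3], [10, 11, 12]).statistic == 0.0
        assert res.statistic == 9.0

    @pytest.mark.parametrize("a,b", [
        ([1, 2, 3], [4, 5, 6, 7]),
        ([1.5, 2.5, 2.5], [2.5, 3.5]),       # ties across groups
        ([0.1, 0.2, 0.3, 0.4], [0.25, 0.35, 0.45]),
        ([5, 5, 5], [5, 5, 6]),              # heavy ties
    ])
    def test_exact_p_matches_permutation_oracle(self, a, b):
        res = pc.compare_two(a, b)
        assert res.statistic == pytest.approx(oracle_u_statistic(a, b))
        assert res.p_value == pytest.approx(oracle_mwu_exact_p(a, b))

    def test_tie_free_exact_matches_scipy(self):
        a, b = [1, 4, 6, 9], [2, 3, 7, 11, 13]
        res = pc.compare_two(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pc.compare_two([], [1.0])


class TestKruskalDunn:
    def test_identical_groups(self):
        groups = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        res = pc.compare_many(groups)
        assert res[0].test == "kruskal_wallis"
        assert res[0].statistic == pytest.approx(0.0, abs=1e-9)
        assert all(r.p_value > 0.05 for r in res[1:])

    def test_tie_corrected_h_formula(self):
        groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0, 4.0], "c": [5.0, 5.0, 6.0]}
        res = pc.compare_many(groups)
        pooled = sorted(v for g in groups.values() for v in g)
        ranks = {}
        vals = np.array(pooled)
        rk = sps.rankdata(vals)
        n = len(pooled)
        # hand evaluation of the tie-corrected statistic
        rank_of = dict(zip(vals.tolist(), rk.tolist()))  # ties share midrank
        r_sums = {k: sum(rank_of[v] for v in g) for k, g in groups.items()}
        h = (12 / (n * (n + 1))) * sum(r ** 2 / 3 for r in r_sums.values()) - 3 * (n + 1)
        _, counts = np.unique(vals, return_counts=True)
        h /= 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
        assert res[0].statistic == pytest.approx(h)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(0)
        groups = {"a": list(rng.normal(0, 1, 30)),
                  "b": list(rng.normal(0, 1, 30)),
                  "c": list(rng.normal(8, 1, 30))}
        res = pc.compare_many(groups)
        dunn = {r.groups: r for r in res[1:]}
        assert dunn[("a", "c")].p_value < 0.05
        assert dunn[("b", "c")].p_value < 0.05
        assert dunn[("a", "b")].p_value > 0.05

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="compare_two"):
            pc.compare_many({"a": [1], "b": [2]})


class TestRanking:
    def test_high_low_split(self):
        ranked = pc.rank_effectors({"As": 0.39, "Mb": 0.07})
        assert [(r.effector, r.category) for r in ranked] == [
            ("As", "high"), ("Mb", "low")]

    def test_all_low(self):
        ranked = pc.rank_effectors({"a": 0.05, "b": 0.1}, threshold=0.2)
        assert all(r.category == "low" for r in ranked)

    def test_stable_tie_ordering(self):
        ranked = pc.rank_effectors({"b": 0.3, "a": 0.3, "c": 0.3})
        assert [r.effector for r in ranked] == ["a", "b", "c"]
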