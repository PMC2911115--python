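import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g1snet.datatypes import BindingCallSet
from g1snet.errors import ValidationError
from g1snet.reports import (
    DivergentPair,
    benchmark_location_dataset,
    consensus_ccr,
    divergent_pair_mcc,
    functional_enrichment,
    motif_position_summary,
    overlap_report,
    peak_phase_distribution,
    rescore_without,
)
from g1snet.thresholds import Classification


class TestConsensusCCR:
    def test_membership_rule(self):
        lists = [[f"G{i}" for i in range(10)] for _ in range(3)]
        lists.append([f"G{i}" for i in range(5)])
        lists.append(["X1", "X2"])
        ccr = consensus_ccr(lists, top_n=8, min_lists=3)
        assert "G0" in ccr and "G4" in ccr
        assert "G9" not in ccr  # beyond top_n in all three long lists
        assert "X1" not in ccr  # only one list

    def test_duplicate_within_list_rejected(self):
        with pytest.raises(ValidationError):
            consensus_ccr([["A", "B", "A"]], top_n=5, min_lists=1)

    def test_matches_bruteforce_counting(self, rng):
        genes = [f"G{i:03d}" for i in range(150)]
        lists = [list(rng.permutation(genes))[:100] for _ in range(5)]
        got = consensus_ccr(lists, top_n=40, min_lists=3)
        counts = {}
        for lst in lists:
            for g in lst[:40]:
                counts[g] = counts.get(g, 0) + 1
        assert got == {g for g, c in counts.items() if c >= 3}


class TestOverlapReport:
    def test_paper_structure_counts(self):
        shared = {f"S{i}" for i in range(36)}
        mbf = shared | {f"M{i}" for i in range(75)}
        sbf = shared | {f"B{i}" for i in range(58)}
        rep = overlap_report({"MBF": mbf, "SBF": sbf})
        rep = rep.set_index("region")
        assert rep.loc["MBF&SBF", "intersection_size"] == 36
        assert rep.loc["MBF", "exclusive_size"] == 75
        total = rep.loc[["MBF", "SBF"], "exclusive_size"].sum() + 36
        assert total == 169  # union of 111 and 94 with 36 shared

    def test_disjoint_sets(self):
        rep = overlap_report({"A": {"X1"}, "B": {"Y1"}}).set_index("region")
        assert rep.loc["A&B", "intersection_size"] == 0

    def test_three_sets_match_bruteforce(self, rng):
        genes = [f"G{i:03d}" for i in range(60)]
        sets = {k: set(rng.choice(genes, size=25, replace=False)) for k in "ABC"}
        rep = overlap_report(sets).set_index("region")
        a, b, c = sets["A"], sets["B"], sets["C"]
        assert rep.loc["A&B&C", "exclusive_size"] == len(a & b & c)
        assert rep.loc["A&B", "exclusive_size"] == len((a & b) - c)
        assert rep.loc["A", "exclusive_size"] == len(a - b - c)


class TestPeakPhase:
    def test_single_bin_and_nd(self, dataset):
        from g1snet.datatypes import CellCyclePeakMap

        peaks = CellCyclePeakMap(pd.Series({"A1": 20.0, "A2": 22.0}))
        h = peak_phase_distribution({"A1", "A2"}, peaks, bin_width=5.0)
        assert h["counts"].sum() == 2 and h["counts"].max() == 2
        peaks_nd = CellCyclePeakMap(pd.Series({"A1": np.nan}))
        h2 = peak_phase_distribution({"A1"}, peaks_nd, bin_width=5.0)
        assert h2["n_nd"] == 1 and h2["counts"].sum() == 0

    def test_mbf_targets_peak_near_generator_mode(self, dataset):
        h = peak_phase_distribution(dataset.truth.mbf_targets, dataset.cc_peaks,
                                    bin_width=5.0)
        mode_start = h["bin_edges"][int(np.argmax(h["counts"]))]
        assert mode_start in (15.0, 20.0, 25.0)  # within one bin of 20%

    def test_ccr_fraction(self, dataset):
        ccr = set(list(dataset.truth.mbf_targets)[:50])
        h = peak_phase_distribution(dataset.truth.mbf_targets, dataset.cc_peaks,
                                    bin_width=5.0, ccr_genes=ccr)
        assert h["ccr_fraction"] == pytest.approx(50 / 111)


class TestMotifPositions:
    def test_zone_accounting(self):
        from g1snet.datatypes import PromoterRecord, PromoterSet

        ps = PromoterSet(max_length=1000)
        # one motif at exactly position 200 (inclusive zone-1 boundary)
        seq = ["A"] * 1000
        seq[1000 - 200: 1000 - 200 + 5] = list("ACGCG")
        ps.add(PromoterRecord(gene="Z1", sequence="".join(seq)))
        summ = motif_position_summary({"Z1"}, ps, "ACGCG")
        np.testing.assert_allclose(summ["zone_fractions"], [1.0, 0.0, 0.0])
        assert summ["gene_fractions"]["proximal"] == 1.0

    def test_proximal_gene_fraction_within_binomial_ci(self, dataset):
        summ = motif_position_summary(dataset.truth.sbf_targets, dataset.promoters,
                                      "CRCGAA", boundaries=(400, 700))
        n = summ["n_genes"]
        observed = round(summ["gene_fractions"]["proximal"] * n)
        # planted at 0.78 plus background chance hits can only raise it
        lo, _ = stats.binom.interval(0.99, n, 0.78)
        assert observed >= lo


class TestRescoreWithout:
    def test_decomposition_identity(self, synthetic_run):
        _, _, _, results = synthetic_run
        res = results["Mbp1"]
        for clf in ("motif", "binding", "cc_peak"):
            sub = rescore_without(clf, res.matrix, res.specs, res.thresholds,
                                  res.weights, "Mbp1")
            expected = res.scores["SUM"] - res.scores[clf]
            np.testing.assert_allclose(
                sub["SUM"].reindex(res.scores.index), expected, atol=1e-9
            )

    def test_zero_weight_classifier_changes_nothing(self, synthetic_run):
        _, _, _, results = synthetic_run
        res = results["Mbp1"]
        zeroed = type(res.weights)(
            weights={**res.weights.weights,
                     "motif": {k: 0.0 for k in res.weights.weights["motif"]}},
            pseudocount=0.5, n_positives=1, n_negatives=1,
        )
        from g1snet.integration import total_scores

        full = total_scores(res.matrix, res.specs, res.thresholds, zeroed, "Mbp1")
        sub = rescore_without("motif", res.matrix, res.specs, res.thresholds,
                              zeroed, "Mbp1")
        np.testing.assert_allclose(sub["SUM"], full["SUM"].reindex(sub.index), atol=1e-12)

    def test_inactive_classifier_rejected(self, synthetic_run):
        _, _, _, results = synthetic_run
        res = results["Mbp1"]
        with pytest.raises(ValidationError):
            rescore_without("av40_60_wt", res.matrix, res.specs, res.thresholds,
                            res.weights, "Mbp1")


class TestLocationBenchmark:
    def test_perfect_calls_give_unit_mcc(self):
        ranked = [f"G{i:03d}" for i in range(100)]
        calls = BindingCallSet(study_id="lee", tf="Mbp1",
                               bound_genes=frozenset(ranked[:30]))
        curve = benchmark_location_dataset(calls, ranked, cutoffs=[30])
        assert curve["mcc"].iloc[0] == pytest.approx(1.0)

    def test_empty_call_set_gives_missing(self):
        ranked = [f"G{i:03d}" for i in range(50)]
        calls = BindingCallSet(study_id="lee", tf="Mbp1", bound_genes=frozenset())
        curve = benchmark_location_dataset(calls, ranked, cutoffs=[10])
        assert math.isnan(curve["mcc"].iloc[0])

    def test_known_sensitivity_matches_analytic_expectation(self, rng):
        n, k, sens, fpr = 2000, 400, 0.8, 0.05
        ranked = [f"G{i:04d}" for i in range(n)]
        truth = set(ranked[:k])
        bound = {g for g in ranked
                 if rng.random() < (sens if g in truth else fpr)}
        calls = BindingCallSet(study_id="iyer", tf="Swi4", bound_genes=frozenset(bound))
        curve = benchmark_location_dataset(calls, ranked, cutoffs=[k])
        tp, fp = sens * k, fpr * (n - k)
        fn, tn = k - tp, (n - k) - fp
        expected = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert curve["mcc"].iloc[0] == pytest.approx(expected, abs=0.04)


class TestDivergentPairs:
    def _classification(self, targets, universe):
        ranked = sorted(targets) + sorted(set(universe) - set(targets))
        return Classification(tf="Mbp1", ranked=ranked, cutoff=len(targets),
                              metrics={}, constrained=True)

    def test_all_correct_gives_unit_mcc(self):
        pairs = [DivergentPair("A1", "A2", "regulated", "not_regulated"),
                 DivergentPair("B1", "B2", "regulated", "not_regulated")]
        cls = self._classification({"A1", "B1"}, {"A1", "A2", "B1", "B2"})
        m = divergent_pair_mcc(pairs, cls)
        assert m["mcc"] == pytest.approx(1.0)

    def test_unknown_labels_contribute_nothing(self):
        pairs = [DivergentPair("A1", "A2", "unknown", "unknown")]
        cls = self._classification({"A1"}, {"A1", "A2"})
        with pytest.raises(ValidationError):
            divergent_pair_mcc(pairs, cls)  # no labeled genes at all

    def test_random_predictions_give_near_zero_mcc(self, rng):
        genes = [f"G{i:03d}" for i in range(500)]
        labels = rng.random(500) < 0.5
        targets = set(rng.choice(genes, size=150, replace=False))
        cls = self._classification(targets, genes)
        mccs = []
        for _ in range(1000):
            perm = rng.permutation(labels)
            pairs = [
                DivergentPair(genes[i], genes[i + 1],
                              "regulated" if perm[i] else "not_regulated",
                              "regulated" if perm[i + 1] else "not_regulated")
                for i in range(0, 500, 2)
            ]
            mccs.append(divergent_pair_mcc(pairs, cls)["mcc"])
        assert np.mean(np.abs(mccs)) < 0.05


class TestFunctionalEnrichment:
    def test_targets_equal_universe_gives_p_one(self):
        universe = [f"G{i}" for i in range(30)]
        classes = {g: ("DNA RRR" if i < 10 else "others") for i, g in enumerate(universe)}
        out = functional_enrichment(universe, classes, universe).set_index("class")
        assert out["p_value"].tolist() == pytest.approx([1.0] * len(out))

    def test_matches_hypergeometric_enumeration(self):
        universe = [f"G{i:03d}" for i in range(100)]
        classes = {g: ("cell cycle" if i < 10 else "others") for i, g in enumerate(universe)}
        targets = universe[:10] + universe[20:30]  # overlap 10 of the class
        out = functional_enrichment(targets, classes, universe).set_index("class")
        # two-tailed exact p by direct enumeration over the hypergeometric support
        N, K, n, a = 100, 10, 20, 10
        pmf = [math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
               for k in range(0, min(K, n) + 1)]
        p_expected = sum(p for p in pmf if p <= pmf[a] * (1 + 1e-9))
        assert out.loc["cell cycle", "p_value"] == pytest.approx(p_expected, rel=1e-9)

    def test_empty_class_skipped_and_symmetry(self):
        universe = [f"G{i}" for i in range(40)]
        classes = {g: ("SPB" if i < 8 else "others") for i, g in enumerate(universe)}
        out = functional_enrichment(universe[:12], classes, universe)
        assert "cytoskeleton" not in set(out["class"])
        # Fisher p symmetric under swapping rows and columns of the 2x2 table
        a, b, c, d = 6, 6, 2, 26
        p1 = stats.fisher_exact([[a, b], [c, d]])[1]
        p2 = stats.fisher_exact([[a, c], [b, d]])[1]
        assert p1 == pytest.approx(p2)
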