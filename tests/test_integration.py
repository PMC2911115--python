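import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g1snet.classifiers import classifier_specs
from g1snet.errors import ParameterError, ValidationError
from g1snet.integration import (
    MISSING_BIN,
    BinThresholds,
    ControlSet,
    assign_bin,
    bin_matrix,
    build_control_sets,
    derive_bin_thresholds,
    estimate_lls_weights,
    total_scores,
)


class TestBinThresholds:
    def test_forced_single_draw_gives_order_statistics(self):
        values = pd.Series(np.arange(1.0, 41.0), index=[f"G{i:03d}" for i in range(40)])
        th = derive_bin_thresholds(values, n_sets=1, set_size=40, seed=0)
        assert th.cuts == (10.0, 20.0, 30.0)

    def test_constant_values_collapse(self):
        values = pd.Series(3.14, index=[f"G{i:03d}" for i in range(60)])
        th = derive_bin_thresholds(values, seed=1)
        assert th.cuts == (3.14, 3.14, 3.14)
        assert assign_bin(3.14, th) == 1  # half-open rule puts everything in bin 1

    def test_reimplementation_oracle_same_seed(self, rng):
        values = pd.Series(rng.normal(size=120), index=[f"G{i:03d}" for i in range(120)])
        th = derive_bin_thresholds(values, seed=11)
        # independent re-execution of draw -> sort -> average with the same stream
        check = np.random.default_rng(11)
        avail = values.dropna().loc[sorted(values.index)].to_numpy()
        expect = np.zeros(3)
        for _ in range(3):
            draw = check.choice(len(avail), size=40, replace=False)
            ordered = np.sort(avail[draw])
            expect += [ordered[9], ordered[19], ordered[29]]
        np.testing.assert_allclose(th.cuts, expect / 3)

    def test_too_few_values_rejected(self):
        values = pd.Series([1.0] * 10 + [np.nan] * 50,
                           index=[f"G{i:03d}" for i in range(60)])
        with pytest.raises(ParameterError):
            derive_bin_thresholds(values, set_size=40, seed=0)

    def test_unordered_cuts_rejected(self):
        with pytest.raises(ValidationError):
            BinThresholds(cuts=(3.0, 2.0, 1.0))


class TestAssignBin:
    TH = BinThresholds(cuts=(1.0, 2.0, 3.0))

    def test_boundaries_are_half_open(self):
        assert assign_bin(1.0, self.TH) == 1  # value == t1 -> bin 1
        assert assign_bin(1.0001, self.TH) == 2
        assert assign_bin(3.0, self.TH) == 3
        assert assign_bin(3.001, self.TH) == 4
        assert assign_bin(float("nan"), self.TH) == MISSING_BIN
        assert assign_bin(None, self.TH) == MISSING_BIN

    @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
    @settings(max_examples=300, derandomize=True)
    def test_bins_partition_the_line(self, v):
        b = assign_bin(v, self.TH)
        assert b in (1, 2, 3, 4)
        t1, t2, t3 = self.TH.cuts
        expected = 1 if v <= t1 else 2 if v <= t2 else 3 if v <= t3 else 4
        assert b == expected


class TestLLSWeights:
    def _controls(self, n_pos=40, n_neg=200):
        return ControlSet(
            tf="Mbp1",
            positives=frozenset(f"P{i}" for i in range(n_pos)),
            negatives=frozenset(f"N{i}" for i in range(n_neg)),
        )

    def _binned(self, pos_bins, neg_bins):
        genes = [f"P{i}" for i in range(len(pos_bins))] + [f"N{i}" for i in range(len(neg_bins))]
        spec = classifier_specs("Mbp1")[1]  # value20_wt, continuous
        return pd.DataFrame({spec.id: pos_bins + neg_bins}, index=genes), [spec]

    def test_analytic_ln2(self):
        binned, specs = self._binned(["bin1"] * 20 + ["bin2"] * 20,
                                     ["bin1"] * 50 + ["bin2"] * 150)
        ctr = self._controls(40, 200)
        w = estimate_lls_weights(binned, specs, ctr, pseudocount=0.0)
        assert w.weight("value20_wt", "bin1") == pytest.approx(math.log(2.0))

    def test_equal_frequencies_give_zero(self):
        # 25%/75% split in both classes -> zero evidence without smoothing
        binned, specs = self._binned(["bin1"] * 10 + ["bin2"] * 30,
                                     ["bin1"] * 50 + ["bin2"] * 150)
        w = estimate_lls_weights(binned, specs, self._controls(), pseudocount=0.0)
        assert w.weight("value20_wt", "bin1") == pytest.approx(0.0)
        assert w.weight("value20_wt", "bin2") == pytest.approx(0.0)
        # bins empty in both classes carry no evidence either
        assert w.weight("value20_wt", "bin4") == 0.0

    def test_smoothing_formula_empty_negative_bin(self):
        # 10/40 positives in bin, 0/200 negatives, pseudocount 1, 4 bins
        binned, specs = self._binned(["bin2"] * 10 + ["bin1"] * 30, ["bin1"] * 200)
        w = estimate_lls_weights(binned, specs, self._controls(), pseudocount=1.0)
        expected = math.log((11 / 44) / (1 / 204))
        assert w.weight("value20_wt", "bin2") == pytest.approx(expected)

    def test_missing_pseudo_bin_weight_is_zero(self):
        binned, specs = self._binned(["bin1"] * 39 + [MISSING_BIN],
                                     ["bin1"] * 199 + [MISSING_BIN])
        w = estimate_lls_weights(binned, specs, self._controls(), pseudocount=0.5)
        assert w.weight("value20_wt", MISSING_BIN) == 0.0

    def test_monotone_in_positive_count(self):
        ctr = self._controls(40, 200)
        prev = -np.inf
        for k in range(0, 41, 8):
            binned, specs = self._binned(["bin4"] * k + ["bin1"] * (40 - k),
                                         ["bin4"] * 20 + ["bin1"] * 180)
            w = estimate_lls_weights(binned, specs, ctr, pseudocount=0.5)
            cur = w.weight("value20_wt", "bin4")
            assert cur > prev
            prev = cur

    @given(st.integers(0, 40), st.integers(0, 200), st.floats(0.1, 5.0))
    @settings(max_examples=60, derandomize=True)
    def test_pseudocount_keeps_weights_finite(self, kp, kn, pc):
        binned, specs = self._binned(["bin2"] * kp + ["bin1"] * (40 - kp),
                                     ["bin2"] * kn + ["bin1"] * (200 - kn))
        w = estimate_lls_weights(binned, specs, self._controls(), pseudocount=pc)
        for b in ("bin1", "bin2", "bin3", "bin4"):
            assert math.isfinite(w.weight("value20_wt", b))


class TestTotalScores:
    def test_oracle_equivalence_on_synthetic_run(self, synthetic_run, rng):
        dataset, _, _, results = synthetic_run
        res = results["Mbp1"]
        picks = rng.choice(dataset.genes, size=50, replace=False)
        binned = bin_matrix(res.matrix, res.specs, res.thresholds, "Mbp1")
        for g in picks:
            expected = sum(
                res.weights.weight(s.id, binned.loc[g, s.id]) for s in res.specs
            )
            assert res.scores.loc[g, "SUM"] == pytest.approx(expected, abs=1e-9)

    def test_missing_classifier_in_weights_rejected(self, synthetic_run):
        _, _, _, results = synthetic_run
        res = results["Mbp1"]
        broken = type(res.weights)(
            weights={k: v for k, v in res.weights.weights.items() if k != "motif"},
            pseudocount=0.5, n_positives=40, n_negatives=100,
        )
        with pytest.raises(ValidationError):
            total_scores(res.matrix, res.specs, res.thresholds, broken, "Mbp1")

    def test_ranks_dense_and_tie_broken_lexicographically(self, synthetic_run):
        _, _, _, results = synthetic_run
        scores = results["Mbp1"].scores
        assert list(scores["rank"]) == list(range(1, len(scores) + 1))
        by_rank = scores.sort_values("rank")
        sums = by_rank["SUM"].to_numpy()
        names = list(by_rank.index)
        for i in range(len(sums) - 1):
            assert sums[i] > sums[i + 1] or (
                sums[i] == sums[i + 1] and names[i] < names[i + 1]
            )

    def test_targets_score_above_background_by_permutation(self, synthetic_run, rng):
        dataset, _, _, results = synthetic_run
        scores = results["Mbp1"].scores["SUM"]
        is_target = np.array([g in dataset.truth.mbf_targets for g in scores.index])
        observed = scores[is_target].mean() - scores[~is_target].mean()
        vals = scores.to_numpy()
        exceed = 0
        for _ in range(2000):
            perm = rng.permutation(is_target)
            exceed += (vals[perm].mean() - vals[~perm].mean()) >= observed
        assert exceed / 2000 < 0.001


class TestBuildControlSets:
    def _priors(self):
        a = {"Mbp1": [f"M{i}" for i in range(60)], "Swi4": [f"S{i}" for i in range(50)]}
        b = {"Mbp1": [f"M{i}" for i in range(5, 70)], "Swi4": [f"S{i}" for i in range(3, 55)]}
        return a, b

    def _universe(self):
        return ([f"M{i}" for i in range(70)] + [f"S{i}" for i in range(55)]
                + [f"X{i}" for i in range(200)])

    def test_intersection_sufficient_uses_only_intersection(self):
        a, b = self._priors()
        out = build_control_sets(self._universe(), a, b, set(), {"Mbp1": 40, "Swi4": 32}, seed=5)
        inter = set(a["Mbp1"]) & set(b["Mbp1"])
        assert out["Mbp1"].positives <= inter

    def test_dual_and_other_tf_excluded(self):
        a, b = self._priors()
        a["Swi4"] = a["Swi4"] + ["M10", "M11"]  # make two genes dual-regulated
        other = {"M12", "M13"}
        out = build_control_sets(self._universe(), a, b, other, {"Mbp1": 40, "Swi4": 32}, seed=5)
        assert not out["Mbp1"].positives & {"M10", "M11", "M12", "M13"}

    def test_negative_draws_merged_and_disjoint(self):
        a, b = self._priors()
        out = build_control_sets(self._universe(), a, b, set(), {"Mbp1": 40, "Swi4": 32}, seed=5)
        for tf, n in (("Mbp1", 40), ("Swi4", 32)):
            cs = out[tf]
            assert len(cs.negatives) <= 5 * n
            assert not cs.negatives & cs.positives
            annotated = set(a[tf]) | set(b[tf])
            assert not cs.negatives & annotated

    def test_shortfall_reported(self):
        a = {"Mbp1": ["M1", "M2"], "Swi4": ["S1", "S2"]}
        b = {"Mbp1": ["M1"], "Swi4": ["S1"]}
        with pytest.raises(ParameterError, match="short"):
            build_control_sets(self._universe(), a, b, set(), {"Mbp1": 40, "Swi4": 32}, seed=5)
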