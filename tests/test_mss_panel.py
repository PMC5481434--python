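import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from glycotma import mss_panel as mp
from glycotma import synthetic_data as sd

# ---------------------------------------------------------------------------
# brute-force oracle for 1-marker search
# ---------------------------------------------------------------------------


def one_marker_search_oracle(values, y, min_sens, min_spec):
    """Every (midpoint threshold, majority state table) pair meeting the gate."""

    values = np.asarray(values, float)
    y = np.asarray(y, bool)
    u = np.unique(values)
    out = set()
    for thr in (u[:-1] + u[1:]) / 2:
        states = (values > thr).astype(int)
        table = []
        for s in (0, 1):
            ncase = np.sum(y & (states == s))
            nctrl = np.sum(~y & (states == s))
            table.append(ncase > nctrl)
        pred = np.array([table[s] for s in states])
        tp = np.sum(pred & y)
        tn = np.sum(~pred & ~y)
        sens = tp / y.sum()
        spec = tn / (~y).sum()
        if sens >= min_sens - 1e-12 and spec >= min_spec - 1e-12:
            out.add((round(float(thr), 12), tuple(table)))
    return out


class TestCandidateThresholds:
    def test_midpoints(self):
        assert mp.candidate_thresholds([1, 2, 3]).tolist() == [1.5, 2.5]

    def test_duplicates_collapse(self):
        assert mp.candidate_thresholds([5, 5, 9]).tolist() == [7.0]

    def test_count_is_n_minus_one(self, rng):
        vals = rng.permutation(np.arange(30.0))
        assert mp.candidate_thresholds(vals).size == 29

    def test_cap_for_large_n(self, rng):
        vals = rng.uniform(0, 100, 500)
        cand = mp.candidate_thresholds(vals, max_candidates=50)
        assert cand.size <= 50
        assert np.all(np.diff(cand) > 0)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            mp.candidate_thresholds([4, 4, 4])

    def test_no_observed_value_equals_threshold(self, rng):
        vals = rng.integers(0, 20, 40).astype(float)
        cand = mp.candidate_thresholds(vals)
        assert not np.isin(cand, np.unique(vals)).any()


class TestBinarize:
    def test_strictly_above(self):
        assert mp.binarize([[10.0]], [7.0])[0, 0] == 1
        assert mp.binarize([[7.0]], [7.0])[0, 0] == 0

    def test_monotone_in_threshold(self, rng):
        vals = rng.uniform(0, 10, (20, 1))
        lo = mp.binarize(vals, [3.0])
        hi = mp.binarize(vals, [6.0])
        assert not np.any((hi == 1) & (lo == 0))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            mp.binarize([[1.0, 2.0]], [1.0])


class TestFitStateRule:
    def test_majority_state(self):
        states = np.ones((10, 3), dtype=int)
        y = np.array([True] * 9 + [False])
        table = mp.fit_state_rule(states, y)
        assert table[7]  # (1,1,1) -> case

    def test_tie_goes_to_control(self):
        states = np.zeros((4, 1), dtype=int)
        y = np.array([True, True, False, False])
        assert not mp.fit_state_rule(states, y)[0]

    def test_unobserved_states_control(self):
        states = np.array([[1, 1]])
        table = mp.fit_state_rule(states, [True])
        assert table.tolist() == [False, False, False, True]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mp.fit_state_rule(np.zeros((0, 2)), [])

    def test_majority_rule_is_trainwise_optimal(self, rng):
        """classify(fit_state_rule(X, y)) beats any single-threshold
        single-marker rule on the same markers."""

        for _ in range(10):
            x = rng.uniform(0, 10, 30)
            y = rng.random(30) < 0.5
            if y.all() or not y.any():
                continue
            thr = mp.candidate_thresholds(x)
            best_fit = 0
            best_single = 0
            for t in thr:
                states = (x > t).astype(int)[:, None]
                table = mp.fit_state_rule(states, y)
                pred = table[states[:, 0]]
                best_fit = max(best_fit, np.mean(pred == y))
                for direction in (states[:, 0] == 1, states[:, 0] == 0):
                    best_single = max(best_single, np.mean(direction == y))
            assert best_fit >= best_single - 1e-12


class TestClassifyAndRule:
    def reference_rule(self):
        """case iff dual low, or all three high (first marker = MSB)."""

        markers = ("ca199_only", "stra_only", "dual")
        table = [False] * 8
        for s in range(8):
            bits = [(s >> (2 - i)) & 1 for i in range(3)]
            if bits[2] == 0 or all(bits):
                table[s] = True
        return mp.PanelRule(markers=markers, thresholds=(10.0, 10.0, 5.0),
                            state_to_case=tuple(table))

    def test_low_dual_is_case(self):
        rule = self.reference_rule()
        assert mp.classify(rule, {"ca199_only": 0.0, "stra_only": 99.0, "dual": 1.0})

    def test_all_high_is_case(self):
        rule = self.reference_rule()
        assert mp.classify(rule, {"ca199_only": 20.0, "stra_only": 20.0, "dual": 20.0})

    def test_other_patients_control(self):
        rule = self.reference_rule()
        assert not mp.classify(rule, {"ca199_only": 20.0, "stra_only": 2.0, "dual": 20.0})

    def test_missing_marker_value_rejected(self):
        rule = self.reference_rule()
        with pytest.raises(KeyError):
            mp.classify(rule, {"ca199_only": 1.0, "dual": 2.0})

    def test_rule_family_representable_by_wildcard_rows(self):
        """The published-style family {(X,X,0) -> case, (1,1,1) -> case,
        else control} induces exactly this rule's state table."""

        rule = self.reference_rule()
        def covered(pattern, s):
            bits = format(s, "03b")
            return all(p in ("X", b) for p, b in zip(pattern, bits))
        for s in range(8):
            expect = covered("XX0", s) or covered("111", s)
            assert rule.state_to_case[s] == expect
        # and the compact form uses wildcards (not just raw minterms)
        assert any("X" in row for row, _ in rule.compact_rows())

    def test_compact_rows_cover_exactly_case_states(self):
        rule = self.reference_rule()
        covered = set()
        for pattern, _ in rule.compact_rows():
            free = [i for i, ch in enumerate(pattern) if ch == "X"]
            for bits in itertools.product("01", repeat=len(free)):
                full = list(pattern)
                for i, b in zip(free, bits):
                    full[i] = b
                covered.add(int("".join(full), 2))
        assert covered == {s for s, c in enumerate(rule.state_to_case) if c}


class TestEvaluatePanel:
    def test_confusion_counts_fractions(self):
        perf = mp.PanelPerformance.from_counts(tp=27, fn=3, fp=3, tn=12)
        assert perf.sensitivity == pytest.approx(0.90)
        assert perf.specificity == pytest.approx(0.80)
        assert perf.accuracy == pytest.approx(39 / 45)

    def test_perfect_rule(self):
        x = pd.DataFrame({"m": [1.0, 2.0, 8.0, 9.0]})
        rule = mp.PanelRule(markers=("m",), thresholds=(5.0,), state_to_case=(False, True))
        perf = mp.evaluate_panel(rule, x, [False, False, True, True])
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0

    def test_constant_case_rule(self):
        x = pd.DataFrame({"m": [1.0, 9.0]})
        rule = mp.PanelRule(markers=("m",), thresholds=(5.0,), state_to_case=(True, True))
        perf = mp.evaluate_panel(rule, x, [False, True])
        assert perf.sensitivity == 1.0 and perf.specificity == 0.0


class TestSearchPanels:
    def test_separable_single_marker_found(self):
        x = pd.DataFrame({"m": [1, 2, 3, 10, 11, 12.0]})
        y = [False, False, False, True, True, True]
        panels = mp.search_panels(x, labels=y, markers=["m"])
        assert panels
        assert panels[0].performance.accuracy == 1.0

    def test_matches_one_marker_brute_force_oracle(self, rng):
        for trial in range(10):
            n = 12
            x = rng.uniform(0, 10, n)
            y = rng.random(n) < 0.5
            if y.sum() < 2 or (~y).sum() < 2:
                continue
            min_sens, min_spec = 0.6, 0.6
            panels = mp.search_panels(
                x[:, None], labels=y, markers=["m"], min_sens=min_sens,
                min_spec=min_spec, max_markers=1,
            )
            got = {(round(p.thresholds[0], 12), p.state_to_case) for p in panels}
            assert got == one_marker_search_oracle(x, y, min_sens, min_spec)

    def test_null_labels_usually_no_panels(self):
        counts = []
        trials = 10
        for seed in range(trials):
            r = np.random.default_rng(seed)
            x = r.uniform(0, 100, (45, 3))
            y = np.array([True] * 30 + [False] * 15)
            counts.append(len(mp.search_panels(x, labels=y, markers=list("abc"))))
        # typically zero panels at 80/80 when labels are independent of markers
        assert np.median(counts) == 0
        assert sum(c == 0 for c in counts) >= trials // 2

    def test_planted_rule_recovered_on_large_cohort(self):
        t = sd.generate_cohort(sd.CohortSpec(n_patients=200, seed=1))
        markers = ["ca199_only", "stra_only", "dual"]
        y = (t["class_label"] == "short").to_numpy()
        panels = mp.search_panels(t[markers], labels=y, markers=markers)
        perfect = [p for p in panels if p.performance.accuracy == 1.0]
        assert perfect  # planted labels perfectly recovered on observed states
        three = [p for p in perfect if len(p.markers) == 3]
        assert three
        pred = mp.classify(three[0], t[markers])
        assert np.array_equal(pred, y)

    def test_requires_two_per_class(self):
        with pytest.raises(ValueError, match="two patients"):
            mp.search_panels(np.arange(5.0)[:, None], labels=[True, False, False, False, False],
                             markers=["m"])

    def test_deterministic_ordering(self):
        t = sd.generate_cohort(sd.CohortSpec(n_patients=45, seed=5))
        markers = ["ca199_only", "stra_only", "dual"]
        y = (t["class_label"] == "short").to_numpy()
        a = mp.search_panels(t[markers], labels=y, markers=markers)
        b = mp.search_panels(t[markers], labels=y, markers=markers)
        assert a[:50] == b[:50]
        accs = [p.performance.accuracy for p in a]
        assert accs == sorted(accs, reverse=True)


class TestCVReportArithmetic:
    ROUND2 = [53, 88, 42, 80, 53, 100, 55, 88, 88, 80]

    def test_round2_median(self):
        assert mp.round_median(self.ROUND2) == 80.0

    def test_average_of_printed_medians(self):
        avg = mp.average_of_medians([71, 80, 73, 80, 84])
        assert round(avg) == 78

    def test_absent_round_median(self):
        assert mp.round_median([None] * 10) is None
        report = mp.CVReport(accuracies=[[None] * 10, self.ROUND2])
        assert report.round_medians == [None, 80.0]
        assert report.overall_average == 80.0

    def test_dash_semantics_in_frame(self):
        report = mp.CVReport(accuracies=[[None, 50.0]])
        frame = report.to_frame(human_dash=True)
        assert frame.loc[0, "Split1"] == "—"
        machine = report.to_frame()
        assert pd.isna(machine.loc[0, "Split1"])


class TestCrossValidation:
    def _planted(self, n=45, seed=0):
        t = sd.generate_cohort(sd.CohortSpec(n_patients=n, seed=seed))
        markers = ["ca199_only", "stra_only", "dual"]
        return t[markers], (t["class_label"] == "short").to_numpy(), markers

    def test_reproducible_from_seed(self):
        X, y, markers = self._planted()
        a = mp.cross_validate(X, labels=y, markers=markers, rounds=2, seed=4)
        b = mp.cross_validate(X, labels=y, markers=markers, rounds=2, seed=4)
        assert a.accuracies == b.accuracies

    def test_planted_structure_scores_high(self):
        X, y, markers = self._planted()
        report = mp.cross_validate(X, labels=y, markers=markers, rounds=2, seed=1)
        assert report.overall_average is not None
        assert report.overall_average > 75.0

    def test_k_larger_than_n_rejected(self):
        X, y, markers = self._planted(n=5)
        with pytest.raises(ValueError):
            mp.cross_validate(X, labels=y, markers=markers, k=10)

    def test_null_reproducible_and_mostly_empty(self):
        X, y, markers = self._planted()
        a = mp.random_label_null(X, labels=y, markers=markers, rounds=2, seed=5)
        b = mp.random_label_null(X, labels=y, markers=markers, rounds=2, seed=5)
        assert a.accuracies == b.accuracies
        present = sum(v is not None for row in a.accuracies for v in row)
        assert present <= 5

    def test_report_shape(self):
        X, y, markers = self._planted()
        report = mp.cross_validate(X, labels=y, markers=markers, rounds=3, k=5, seed=2)
        assert len(report.accuracies) == 3
        assert all(len(row) == 5 for row in report.accuracies)
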