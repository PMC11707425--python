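import numpy as np
import pandas as pd
import pytest

from idicss.evaluate import (
    baseline_scores,
    classification_metrics,
    concordance_index,
    dichotomize_response,
    drug_screen,
    km_logrank,
    response_auc,
    time_dependent_auc,
)
from idicss.io import GeneExpressionMatrix


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def cindex_oracle(scores, times, events):
    conc = comp = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / comp


def auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def logrank_oracle(times, events, groups):
    """Two-group log-rank chi-square via the O-E / hypergeometric-V formula."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestConcordanceIndex:
    def test_perfect_concordance(self):
        times = np.array([5.0, 3.0, 9.0, 1.0])
        assert concordance_index(-times, times, np.ones(4)) == 1.0

    def test_constant_scores_give_half(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(np.zeros(4), times, np.ones(4)) == 0.5

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(3, 9))
            times = rng.integers(1, 6, n).astype(float)
            events = rng.integers(0, 2, n)
            scores = rng.integers(0, 4, n).astype(float)
            try:
                expected = cindex_oracle(scores, times, events)
            except ZeroDivisionError:
                with pytest.raises(ValueError):
                    concordance_index(scores, times, events)
                continue
            assert concordance_index(scores, times, events) == pytest.approx(
                expected, abs=1e-12
            )

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(1)
        times = rng.exponential(10, 100)
        events = rng.integers(0, 2, 100)
        events[0] = 1
        scores = rng.normal(size=100)
        ours = concordance_index(scores, times, events)
        theirs = ll_cindex(times, -scores, events)
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestResponseAuc:
    def test_perfect_separation(self):
        scores = np.array([3.0, 4.0, 1.0, 2.0])
        labels = np.array([1, 1, 0, 0])
        assert response_auc(scores, labels) == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            n = int(rng.integers(3, 9))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 4, n).astype(float)
            assert response_auc(scores, labels) == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12
            )

    def test_flip_symmetry_without_ties(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert response_auc(scores, labels) + response_auc(-scores, labels) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert response_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            response_auc(np.ones(4), np.ones(4))


class TestKmLogrank:
    def test_four_subject_hand_calculation(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        groups = np.array(["g1", "g1", "g2", "g2"])
        comp = km_logrank(times, events, groups)
        assert comp.statistic == pytest.approx(
            logrank_oracle(times, events, groups), abs=1e-10
        )
        # survival curves are valid step functions
        for curve in comp.curves.values():
            s = curve["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
            assert ((s >= 0) & (s <= 1)).all()

    def test_identical_groups_null(self):
        times = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        comp = km_logrank(times, events, groups)
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0, abs=1e-12)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="events"):
            km_logrank(
                np.array([1.0, 2.0, 3.0, 4.0]),
                np.zeros(4, int),
                np.array(["a", "a", "b", "b"]),
            )

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 9))
            times = rng.integers(1, 6, n).astype(float)
            events = rng.integers(0, 2, n)
            groups = np.where(rng.integers(0, 2, n) == 1, "a", "b")
            if len(set(groups)) < 2 or events.sum() == 0:
                continue
            expected = logrank_oracle(times, events, groups)
            if not np.isfinite(expected):
                continue
            comp = km_logrank(times, events, groups)
            assert comp.statistic == pytest.approx(expected, abs=1e-8)
            checked += 1


class TestClassificationMetrics:
    def test_all_correct(self):
        scores = np.array([0.0, 0.0, 1.0, 1.0])
        labels = np.array([1, 1, 0, 0])
        m = classification_metrics(scores, labels, threshold=0.5)
        for key in ("sensitivity", "specificity", "ppv", "npv", "f1", "accuracy"):
            assert m[key] == 1.0

    def test_stated_confusion_matrix(self):
        # TP=2, FP=1, FN=1, TN=6
        scores = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 1], float)
        labels = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
        m = classification_metrics(scores, labels, threshold=0.5)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (2, 1, 1, 6)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(6 / 7)
        assert m["ppv"] == pytest.approx(2 / 3)
        assert m["npv"] == pytest.approx(6 / 7)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_label_flip_swaps_sensitivity_specificity(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        m = classification_metrics(scores, labels, threshold=0.0)
        flipped = classification_metrics(scores, 1 - labels, threshold=0.0, positive_below=False)
        assert m["sensitivity"] == pytest.approx(flipped["specificity"])
        assert m["specificity"] == pytest.approx(flipped["sensitivity"])

    def test_degenerate_cells_reported_as_none(self):
        m = classification_metrics(np.array([1.0, 2.0]), np.array([0, 0]), threshold=0.0)
        assert m["sensitivity"] is None
        assert m["accuracy"] is not None


class TestTimeDependentAuc:
    def test_perfect_risk_ordering(self):
        times = np.arange(1.0, 101.0)
        events = np.ones(100, int)
        aucs = time_dependent_auc(-times, times, events, [25.0, 50.0, 75.0])
        for v in aucs.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_censoring_free_reduction_to_binary_auc(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(10, 200)
        events = np.ones(200, int)
        scores = -times + rng.normal(0, 3, 200)
        horizon = float(np.median(times))
        auc = time_dependent_auc(scores, times, events, [horizon])[horizon]
        binary = response_auc(scores, times <= horizon)
        assert auc == pytest.approx(binary, abs=1e-9)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, 500)
        events = np.ones(500, int)
        scores = rng.normal(size=500)
        auc = time_dependent_auc(scores, times, events, [float(np.median(times))])
        assert list(auc.values())[0] == pytest.approx(0.5, abs=0.05)

    def test_horizon_beyond_follow_up_rejected(self):
        times = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            time_dependent_auc(np.zeros(3), times, np.ones(3, int), [10.0])


class TestBaselines:
    def _expr(self):
        rng = np.random.default_rng(9)
        return GeneExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(3, 6)),
                index=["CD274", "PDCD1", "TCF7"],
                columns=[f"s{i}" for i in range(6)],
            )
        )

    def test_single_gene_baseline_is_zscored_row(self):
        from idicss.profile import zscore_rows

        expr = self._expr()
        table = baseline_scores(expr, single_genes={"PD-L1": "CD274"})
        expected = zscore_rows(expr.data.loc[["CD274"]]).iloc[0]
        np.testing.assert_allclose(table["PD-L1"], expected)

    def test_missing_gene_skipped(self):
        table = baseline_scores(self._expr(), single_genes={"X": "NOPE"})
        assert "X" not in table.columns

    def test_pair_score_counts_and_is_bounded(self):
        expr = self._expr()
        pairs = [("CD274", "PDCD1"), ("TCF7", "PDCD1")]
        table = baseline_scores(expr, gene_pairs={"PAIRS": pairs})
        vals = table["PAIRS"].to_numpy()
        assert ((vals >= 0) & (vals <= len(pairs))).all()
        manual = (
            (expr.data.loc["CD274"] > expr.data.loc["PDCD1"]).astype(float)
            + (expr.data.loc["TCF7"] > expr.data.loc["PDCD1"]).astype(float)
        )
        np.testing.assert_allclose(vals, manual)


class TestDrugScreen:
    def _panel(self, n_lines=30, seed=10):
        rng = np.random.default_rng(seed)
        lines = [f"cl{i}" for i in range(n_lines)]
        scores = pd.Series(rng.normal(size=n_lines), index=lines)
        return lines, scores, rng

    def test_monotone_drug_is_candidate(self):
        lines, scores, rng = self._panel()
        ic50 = pd.DataFrame(
            {
                "mono": np.exp(scores.to_numpy()),
                "null": rng.normal(size=len(lines)),
            },
            index=lines,
        ).T
        table = drug_screen(scores, ic50)
        assert table.loc["mono", "rho"] == pytest.approx(1.0)
        assert bool(table.loc["mono", "candidate"])

    def test_constant_ic50_flagged_degenerate(self):
        lines, scores, rng = self._panel()
        ic50 = pd.DataFrame(
            {"flat": np.ones(len(lines)), "ok": np.exp(scores.to_numpy())}, index=lines
        ).T
        table = drug_screen(scores, ic50)
        assert bool(table.loc["flat", "degenerate"])
        assert not bool(table.loc["flat", "candidate"])

    def test_null_drugs_rarely_candidates(self):
        lines, scores, rng = self._panel(seed=11)
        ic50 = pd.DataFrame(
            rng.normal(size=(100, len(lines))),
            index=[f"d{i}" for i in range(100)],
            columns=lines,
        )
        table = drug_screen(scores, ic50, rho_min=0.3)
        assert table["candidate"].mean() <= 0.10

    def test_too_few_lines_rejected(self):
        lines, scores, rng = self._panel(n_lines=5)
        ic50 = pd.DataFrame(rng.normal(size=(3, 5)), index=list("abc"), columns=lines)
        with pytest.raises(ValueError, match="cell lines"):
            drug_screen(scores, ic50)


def test_dichotomize_response():
    resp = pd.Series(["CR", "PR", "SD", "PD", "responder", "non-responder"])
    assert list(dichotomize_response(resp)) == [True, True, False, False, True, False]
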