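import random

import pytest

from dompred import (
    BenchmarkSet,
    auc_pr_step,
    coverage,
    evaluate_cafa,
    fmax,
    naive_baseline,
    pooled_pr_curve,
    ppp_evaluate,
    precision_recall_at,
    smin,
)
from dompred.ontology import TermIC
from dompred.predict import PredictionRecord, PredictionSet


def pset_from(scores: dict[str, dict[str, float]]) -> PredictionSet:
    records = [
        PredictionRecord(p, t, frozenset(), s, s, "test")
        for p, terms in scores.items()
        for t, s in terms.items()
    ]
    return PredictionSet(records=records, predicted_proteins=set(scores))


@pytest.fixture
def two_term_instance():
    """Single protein: truth {A,B}, predictions {A:0.9, C:0.8}."""
    predictions = pset_from({"P1": {"A": 0.9, "C": 0.8}})
    benchmark = BenchmarkSet(truth={"P1": {"A", "B"}})
    return predictions, benchmark


class TestPrecisionRecall:
    def test_perfect_prediction(self):
        preds = pset_from({"P1": {"A": 0.7, "B": 0.7}})
        bench = BenchmarkSet(truth={"P1": {"A", "B"}})
        assert precision_recall_at(preds, bench, 0.5, "full") == (1.0, 1.0)

    def test_threshold_excludes_low_scores(self, two_term_instance):
        preds, bench = two_term_instance
        assert precision_recall_at(preds, bench, 0.9, "full") == (1.0, 0.5)
        assert precision_recall_at(preds, bench, 0.8, "full") == (0.5, 0.5)

    def test_full_mode_penalizes_uncovered_proteins(self):
        preds = pset_from({"P1": {"A": 0.9}})
        bench = BenchmarkSet(truth={"P1": {"A"}, "P2": {"B"}})
        _, rc_full = precision_recall_at(preds, bench, 0.5, "full")
        _, rc_partial = precision_recall_at(preds, bench, 0.5, "partial")
        assert rc_full == 0.5 and rc_partial == 1.0

    def test_threshold_domain_checked(self, two_term_instance):
        preds, bench = two_term_instance
        with pytest.raises(ValueError):
            precision_recall_at(preds, bench, 0.0, "full")
        with pytest.raises(ValueError):
            precision_recall_at(preds, bench, 1.5, "full")


class TestFmax:
    def test_hand_worked_two_term_instance(self, two_term_instance):
        preds, bench = two_term_instance
        f, tau = fmax(preds, bench, "full")
        assert f == pytest.approx(2 / 3, abs=1e-12)
        assert tau == pytest.approx(0.9)

    def test_perfect_predictions_give_one(self):
        preds = pset_from({"P1": {"A": 1.0}, "P2": {"B": 0.9}})
        bench = BenchmarkSet(truth={"P1": {"A"}, "P2": {"B"}})
        assert fmax(preds, bench, "full")[0] == 1.0

    def test_no_predictions_full_mode_zero(self):
        preds = pset_from({})
        bench = BenchmarkSet(truth={"P1": {"A"}})
        assert fmax(preds, bench, "full")[0] == 0.0

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkSet(truth={"P1": set()})
        preds = pset_from({})
        with pytest.raises(ValueError):
            fmax(preds, BenchmarkSet(truth={}), "full")

    @staticmethod
    def random_instance(rng):
        terms = [f"t{i}" for i in range(6)]
        truth = {}
        scores = {}
        for i in range(rng.randint(1, 6)):
            prot = f"p{i}"
            truth[prot] = set(rng.sample(terms, rng.randint(1, 4)))
            if rng.random() < 0.8:
                # scores drawn on the 0.01 grid so exact thresholds align with it
                scores[prot] = {
                    t: rng.randint(1, 100) / 100.0
                    for t in rng.sample(terms, rng.randint(1, 5))
                }
        return pset_from(scores), BenchmarkSet(truth=truth)

    def test_grid_matches_bruteforce_over_distinct_scores(self):
        # independent oracle: maximize F over thresholds at every distinct score
        rng = random.Random(3)
        for _ in range(100):
            preds, bench = self.random_instance(rng)
            grid_f, _ = fmax(preds, bench, "full")
            distinct = sorted({r.normalized for r in preds.records})
            brute = 0.0
            for tau in distinct:
                pr, rc = precision_recall_at(preds, bench, tau, "full")
                brute = max(brute, 2 * pr * rc / (pr + rc) if pr + rc else 0.0)
            assert grid_f == pytest.approx(brute, abs=1e-12)

    def test_partial_mode_at_least_full_mode(self):
        rng = random.Random(5)
        for _ in range(50):
            preds, bench = self.random_instance(rng)
            assert fmax(preds, bench, "partial")[0] >= fmax(preds, bench, "full")[0] - 1e-12


class TestSmin:
    def test_perfect_predictions_give_zero(self):
        preds = pset_from({"P1": {"A": 1.0, "B": 1.0}})
        bench = BenchmarkSet(truth={"P1": {"A", "B"}})
        ic = TermIC(ia={"A": 1.0, "B": 2.0})
        assert smin(preds, bench, ic, "full")[0] == 0.0

    def test_no_predictions_gives_average_truth_information(self):
        preds = pset_from({})
        bench = BenchmarkSet(truth={"P1": {"A"}, "P2": {"A", "B"}})
        ic = TermIC(ia={"A": 1.0, "B": 3.0})
        s, _ = smin(preds, bench, ic, "full")
        assert s == pytest.approx((1.0 + 4.0) / 2)

    def test_single_missed_term(self):
        preds = pset_from({"P1": {"A": 1.0}})
        bench = BenchmarkSet(truth={"P1": {"A", "B"}})
        ic = TermIC(ia={"A": 0.5, "B": 1.0})
        s, _ = smin(preds, bench, ic, "full")
        assert s == pytest.approx(1.0)

    def test_wrong_prediction_cannot_decrease_smin(self):
        bench = BenchmarkSet(truth={"P1": {"A"}})
        ic = TermIC(ia={"A": 1.0, "B": 2.0})
        base = smin(pset_from({"P1": {"A": 0.9}}), bench, ic, "full")[0]
        with_wrong = smin(pset_from({"P1": {"A": 0.9, "B": 0.9}}), bench, ic, "full")[0]
        assert with_wrong >= base


class TestCoverage:
    def test_fraction_of_predicted_proteins(self):
        preds = pset_from({"P1": {"A": 0.5}, "P2": {"A": 0.5}, "P3": {"A": 0.5}})
        bench = BenchmarkSet(truth={f"P{i}": {"A"} for i in range(1, 5)})
        assert coverage(preds, bench) == 0.75

    def test_extremes(self):
        bench = BenchmarkSet(truth={"P1": {"A"}})
        assert coverage(pset_from({"P1": {"A": 0.5}}), bench) == 1.0
        assert coverage(pset_from({}), bench) == 0.0


class TestPPP:
    def test_all_correct_gives_perfect_curve(self):
        preds = pset_from({"P1": {"A": 0.9}, "P2": {"B": 0.8}})
        report = ppp_evaluate(preds, {"P1": {"A"}, "P2": {"B"}})
        assert report.auc_pr == pytest.approx(1.0)
        assert report.fmax == pytest.approx(1.0)

    def test_all_wrong_gives_zero_precision(self):
        preds = pset_from({"P1": {"A": 0.9}})
        report = ppp_evaluate(preds, {"P1": {"B"}})
        assert all(pr == 0.0 for _, pr, _ in report.pr_points)
        assert report.fmax == 0.0

    def test_ranked_list_hand_enumeration(self):
        # 4 pooled pairs; the two correct ones hold the top scores
        preds = pset_from({"P1": {"A": 0.9, "C": 0.6}, "P2": {"B": 0.8, "D": 0.5}})
        report = ppp_evaluate(preds, {"P1": {"A"}, "P2": {"B"}})
        # thresholds at 0.9, 0.8, 0.6, 0.5
        assert report.pr_points == [
            (0.9, 1.0, 0.5),
            (0.8, 1.0, 1.0),
            (0.6, pytest.approx(2 / 3), 1.0),
            (0.5, 0.5, 1.0),
        ]
        assert report.auc_pr == pytest.approx(0.5 * 1.0 + 0.5 * 1.0)

    def test_auc_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = random.Random(9)
        for _ in range(30):
            pairs = [(rng.randint(1, 50) / 50.0, rng.random() < 0.4) for _ in range(40)]
            if not any(label for _, label in pairs):
                continue
            mine = auc_pr_step(pooled_pr_curve(pairs))
            ref = average_precision_score(
                [int(l) for _, l in pairs], [s for s, _ in pairs]
            )
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_recall_non_increasing_in_threshold(self):
        rng = random.Random(13)
        pairs = [(rng.random(), rng.random() < 0.5) for _ in range(50)]
        points = pooled_pr_curve(pairs)
        recalls = [rc for _, _, rc in points]  # points ordered by decreasing threshold
        assert all(a <= b for a, b in zip(recalls, recalls[1:]))
        assert all(0 <= pr <= 1 and 0 <= rc <= 1 for _, pr, rc in points)


class TestNaiveBaseline:
    def test_term_frequency_scores(self):
        training = {f"p{i}": {"A"} for i in range(50)}
        training.update({f"q{i}": {"B"} for i in range(50)})
        pset = naive_baseline(training, ["x1", "x2"])
        scores = pset.by_protein()
        assert scores["x1"]["A"] == pytest.approx(0.5)
        assert scores["x2"]["B"] == pytest.approx(0.5)

    def test_universal_term_scores_one(self):
        training = {"p1": {"A"}, "p2": {"A"}}
        pset = naive_baseline(training, ["x"])
        assert pset.by_protein()["x"]["A"] == 1.0

    def test_full_coverage_by_construction(self):
        training = {"p1": {"A"}}
        bench = BenchmarkSet(truth={"x1": {"A"}, "x2": {"B"}})
        pset = naive_baseline(training, bench.truth)
        assert coverage(pset, bench) == 1.0


class TestEvaluateCafa:
    def test_report_consistency(self, two_term_instance):
        preds, bench = two_term_instance
        ic = TermIC(ia={"A": 1.0, "B": 1.0, "C": 1.0})
        report = evaluate_cafa(preds, bench, ic=ic, mode="full")
        assert report.fmax == pytest.approx(2 / 3, abs=1e-12)
        assert report.fmax_threshold == pytest.approx(0.9)
        assert report.coverage == 1.0
        assert report.smin is not None and report.smin >= 0
        # fmax equals the max F over the stored PR points
        best = max(2 * p * r / (p + r) if p + r else 0.0 for _, p, r in report.pr_points)
        assert report.fmax == pytest.approx(best, abs=1e-12)

    def test_benchmark_subset_restriction(self, two_term_instance):
        preds, bench = two_term_instance
        bench2 = BenchmarkSet(truth=dict(bench.truth, P9={"Z"}))
        restricted = bench2.restrict(["P1"], subset_tag="no-knowledge")
        assert restricted.truth == bench.truth
        assert restricted.subset_tag == "no-knowledge"
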