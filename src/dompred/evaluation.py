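"""Protein-centric evaluation of function predictions.

Two complementary procedures are implemented:

* CAFA-style protein-centric metrics over a held-out benchmark: ``Fmax`` (the
  maximum over score thresholds of the harmonic mean of protein-averaged
  precision and recall), ``Smin`` (the minimum over thresholds of
  ``sqrt(ru^2 + mi^2)``, remaining uncertainty and misinformation weighted by
  per-term information accretion) and coverage (the fraction of benchmark
  proteins receiving at least one prediction).  In *full* mode recall (and the
  Smin averages) are taken over every benchmark protein, penalizing proteins
  the method cannot predict; in *partial* mode only proteins with at least one
  prediction enter the denominators.

* A pooled precision-recall procedure for self-prediction ("pathway
  prediction performance"): predictions for the proteins used to build the
  network are labelled true/false positives by whether they match the original
  annotation, and the ranked score list yields a PR curve, its Fmax and a
  step-interpolated AUC-PR.  Unlike GO-based evaluation this needs no
  ontology, so it extends validation to pathway vocabularies such as KEGG and
  Reactome.

A frequency ("naive") baseline predictor is included: every query protein
receives every training term, scored by the term's training-corpus frequency.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .ontology import TermIC
from .predict import PredictionRecord, PredictionSet

logger = logging.getLogger(__name__)

MODES = ("full", "partial")

#: CAFA threshold grid: 0.01, 0.02, ..., 1.00
TAU_GRID = tuple(round(i / 100.0, 2) for i in range(1, 101))


@dataclass
class BenchmarkSet:
    """Ground-truth term sets for benchmark proteins (propagated, root-free)."""

    truth: dict[str, set[str]]
    subset_tag: str = "all"  # e.g. "no-knowledge", "limited-knowledge"
    ontology_tag: str = ""

    def __post_init__(self) -> None:
        if any(not terms for terms in self.truth.values()):
            raise ValueError("every benchmark protein must have a non-empty truth set")

    def restrict(self, proteins: Iterable[str], subset_tag: str) -> "BenchmarkSet":
        """Benchmark restricted to a caller-supplied protein list (e.g. a
        no-knowledge/limited-knowledge classification)."""
        keep = set(proteins)
        return BenchmarkSet(
            truth={p: t for p, t in self.truth.items() if p in keep},
            subset_tag=subset_tag,
            ontology_tag=self.ontology_tag,
        )


@dataclass
class EvaluationReport:
    mode: str = "full"
    fmax: float | None = None
    fmax_threshold: float | None = None
    smin: float | None = None
    smin_threshold: float | None = None
    coverage: float | None = None
    pr_points: list[tuple[float, float, float]] = field(default_factory=list)  # (tau, pr, rc)
    auc_pr: float | None = None

    def as_dict(self) -> dict[str, float | str | None]:
        return {
            "mode": self.mode,
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "smin": self.smin,
            "smin_threshold": self.smin_threshold,
            "coverage": self.coverage,
            "auc_pr": self.auc_pr,
        }


def _score_map(predictions: PredictionSet | Mapping[str, Mapping[str, float]]) -> dict[str, dict[str, float]]:
    if isinstance(predictions, PredictionSet):
        return predictions.by_protein()
    return {p: dict(terms) for p, terms in predictions.items()}


def precision_recall_at(
    predictions: PredictionSet | Mapping[str, Mapping[str, float]],
    benchmark: BenchmarkSet,
    tau: float,
    mode: str = "full",
) -> tuple[float, float]:
    """Protein-averaged precision and recall at score threshold ``tau``.

    Precision averages ``|pred & truth| / |pred|`` over benchmark proteins
    with at least one prediction scoring >= tau; recall averages
    ``|pred & truth| / |truth|`` over all benchmark proteins (full mode) or
    over proteins with at least one prediction at any threshold (partial).
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {tau}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not benchmark.truth:
        raise ValueError("empty benchmark")
    scores = _score_map(predictions)

    precisions: list[float] = []
    recalls: list[float] = []
    n_covered = 0
    for prot, truth in benchmark.truth.items():
        pred_all = scores.get(prot, {})
        if pred_all:
            n_covered += 1
        pred_tau = {t for t, s in pred_all.items() if s >= tau}
        hits = len(pred_tau & truth)
        if pred_tau:
            precisions.append(hits / len(pred_tau))
        recalls.append(hits / len(truth))

    precision = sum(precisions) / len(precisions) if precisions else 0.0
    if mode == "full":
        recall = sum(recalls) / len(benchmark.truth)
    else:
        recall = sum(recalls) / n_covered if n_covered else 0.0
    return precision, recall


def _f1(pr: float, rc: float) -> float:
    return 2.0 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0


def fmax(
    predictions: PredictionSet | Mapping[str, Mapping[str, float]],
    benchmark: BenchmarkSet,
    mode: str = "full",
) -> tuple[float, float]:
    """Maximum F-measure over the 0.01-step threshold grid.

    Ties take the largest threshold achieving the maximum (the most selective
    prediction set with maximal F), so the reported threshold marks where the
    score list should be cut.
    """
    best_f, best_tau = 0.0, TAU_GRID[0]
    for tau in TAU_GRID:
        pr, rc = precision_recall_at(predictions, benchmark, tau, mode)
        f = _f1(pr, rc)
        if f >= best_f:
            best_f, best_tau = f, tau
    return best_f, best_tau


def smin(
    predictions: PredictionSet | Mapping[str, Mapping[str, float]],
    benchmark: BenchmarkSet,
    ic: TermIC,
    mode: str = "full",
) -> tuple[float, float]:
    """Minimum semantic distance ``sqrt(ru^2 + mi^2)`` over the threshold grid.

    ``ru`` (remaining uncertainty) averages the accretion of truth terms the
    prediction misses; ``mi`` (misinformation) averages the accretion of
    predicted terms not in the truth.  Terms missing from ``ic`` contribute
    the zero default (a warning is logged once).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not benchmark.truth:
        raise ValueError("empty benchmark")
    scores = _score_map(predictions)

    missing = {
        t
        for prot, truth in benchmark.truth.items()
        for t in truth | set(scores.get(prot, {}))
        if t not in ic.ia
    }
    if missing:
        logger.warning("%d terms missing from information-accretion table (ia=0 used)", len(missing))

    covered = [p for p in benchmark.truth if scores.get(p)]
    denom_proteins = list(benchmark.truth) if mode == "full" else covered
    if not denom_proteins:
        return math.nan, TAU_GRID[0]

    best_s, best_tau = math.inf, TAU_GRID[0]
    for tau in TAU_GRID:
        ru_sum = 0.0
        mi_sum = 0.0
        for prot in denom_proteins:
            truth = benchmark.truth[prot]
            pred_tau = {t for t, s in scores.get(prot, {}).items() if s >= tau}
            ru_sum += sum(ic.get(t) for t in truth - pred_tau)
            mi_sum += sum(ic.get(t) for t in pred_tau - truth)
        n = len(denom_proteins)
        s = math.hypot(ru_sum / n, mi_sum / n)
        if s < best_s:
            best_s, best_tau = s, tau
    return best_s, best_tau


def coverage(
    predictions: PredictionSet | Mapping[str, Mapping[str, float]],
    benchmark: BenchmarkSet,
) -> float:
    """Fraction of benchmark proteins with at least one retained prediction."""
    if not benchmark.truth:
        raise ValueError("empty benchmark")
    scores = _score_map(predictions)
    return sum(1 for p in benchmark.truth if scores.get(p)) / len(benchmark.truth)


def evaluate_cafa(
    predictions: PredictionSet | Mapping[str, Mapping[str, float]],
    benchmark: BenchmarkSet,
    ic: TermIC | None = None,
    mode: str = "full",
) -> EvaluationReport:
    """Full protein-centric report: Fmax, optional Smin, coverage, PR points."""
    report = EvaluationReport(mode=mode)
    report.pr_points = [
        (tau, *precision_recall_at(predictions, benchmark, tau, mode)) for tau in TAU_GRID
    ]
    best = max(report.pr_points, key=lambda p: (_f1(p[1], p[2]), p[0]))
    report.fmax, report.fmax_threshold = _f1(best[1], best[2]), best[0]
    if ic is not None:
        report.smin, report.smin_threshold = smin(predictions, benchmark, ic, mode)
    report.coverage = coverage(predictions, benchmark)
    return report


def pooled_pr_curve(
    scored_pairs: list[tuple[float, bool]],
) -> list[tuple[float, float, float]]:
    """PR points of a pooled ranked list, one per distinct score threshold.

    Pairs are ranked by descending score; at each distinct score ``tau`` the
    retained set is every pair scoring >= ``tau``.  Recall is relative to the
    positives present in the list.
    """
    if not scored_pairs:
        return []
    n_pos = sum(1 for _, label in scored_pairs if label)
    ordered = sorted(scored_pairs, key=lambda x: -x[0])
    points: list[tuple[float, float, float]] = []
    tp = 0
    n_ret = 0
    i = 0
    while i < len(ordered):
        tau = ordered[i][0]
        while i < len(ordered) and ordered[i][0] == tau:
            tp += ordered[i][1]
            n_ret += 1
            i += 1
        precision = tp / n_ret
        recall = tp / n_pos if n_pos else 0.0
        points.append((tau, precision, recall))
    return points


def auc_pr_step(points: list[tuple[float, float, float]]) -> float:
    """Step-interpolated area under a PR curve: ``sum dR * P`` over thresholds."""
    area = 0.0
    prev_recall = 0.0
    for _, precision, recall in points:
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def ppp_evaluate(
    predictions: PredictionSet,
    original_annotations: Mapping[str, set[str]],
) -> EvaluationReport:
    """Self-prediction precision-recall over the training proteins.

    Every prediction record is labelled a true positive if its function is in
    the protein's original annotation and a false positive otherwise; the
    pooled ranked list gives the PR curve, its Fmax, and the AUC-PR.  Matching
    is against the annotation sets exactly as given (propagate them first to
    score against the ancestor closure).
    """
    pooled = [
        (r.normalized, r.function_id in original_annotations.get(r.protein_id, set()))
        for r in predictions.records
    ]
    points = pooled_pr_curve(pooled)
    report = EvaluationReport(mode="full", pr_points=points)
    if points:
        best = max(points, key=lambda p: (_f1(p[1], p[2]), p[0]))
        report.fmax, report.fmax_threshold = _f1(best[1], best[2]), best[0]
        report.auc_pr = auc_pr_step(points)
    else:
        report.fmax, report.auc_pr = 0.0, 0.0
    return report


def naive_baseline(
    training_annotations: Mapping[str, set[str]],
    benchmark_proteins: Iterable[str],
) -> PredictionSet:
    """Frequency baseline: every query gets every training term, scored by the
    fraction of training proteins annotated with it."""
    n_train = len(training_annotations)
    if n_train == 0:
        raise ValueError("empty training annotation corpus")
    counts: dict[str, int] = {}
    for terms in training_annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    freq = {t: c / n_train for t, c in counts.items()}

    pset = PredictionSet()
    for prot in benchmark_proteins:
        pset.predicted_proteins.add(prot)
        for t, s in freq.items():
            pset.records.append(
                PredictionRecord(
                    protein_id=prot,
                    function_id=t,
                    domains=frozenset(),
                    raw=s,
                    normalized=s,
                    method_tag="naive",
                )
            )
    return pset
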