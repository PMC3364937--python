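"""Release differencing: per-term reliability, coverage, and summaries.

The evaluation exploits change between two annotation releases. Every
(gene, term) closure pair of the *evaluated* stratum (by default: electronic
annotations) in the older release receives exactly one label against the newer
release:

* ``rejected_explicit`` — the newer release gained an experimental NOT
  assertion at exactly that term (NOT never propagates);
* ``confirmed`` — a new experimental annotation to the term or any of its
  descendants arrived (the descendant implies the term; conversely a new, less
  specific experimental annotation confirms only the ancestral pairs it
  implies, leaving deeper pairs untouched);
* ``removed`` — the pair vanished from the newer release's evaluated closure
  (implicit rejection; replacement by a more specific annotation keeps the
  pair in the closure, so specialization is *not* a removal);
* ``uninformative`` — still present, neither confirmed nor contradicted.

Per term, reliability = confirmed / (confirmed + rejected + removed), and
coverage = predicted / (predicted + missed) over the newer release's *new*
experimental closure pairs, where a pair is predicted when the older release's
evaluated closure already implied it. Ratios with empty denominators are
undefined and reported as missing, never as 0 or 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .annotations import (
    AnnotationCorpus,
    Selector,
    drop_contradictory_pairs,
    filter_corpus,
)
from .ontology import OntologyGraph, shared_terms
from .propagation import (
    AnnotationClosure,
    build_closure,
    closure_difference,
    information_content,
    term_frequency,
)

log = logging.getLogger(__name__)

CONFIRMED = "confirmed"
REJECTED_EXPLICIT = "rejected_explicit"
REMOVED = "removed"
UNINFORMATIVE = "uninformative"
LABELS = (CONFIRMED, REJECTED_EXPLICIT, REMOVED, UNINFORMATIVE)


@dataclass(frozen=True)
class EvaluationConfig:
    """Thresholds and strata for a release-pair evaluation.

    A term is *reportable* when it has at least ``min_old_annotations``
    evaluated closure pairs in the old release and ``min_new_experimental``
    reference closure pairs in the new release (both default 10).
    """

    min_old_annotations: int = 10
    min_new_experimental: int = 10
    evaluated_category: Selector = field(
        default_factory=lambda: Selector.of(categories={"electronic"})
    )
    reference_category: Selector = field(
        default_factory=lambda: Selector.of(categories={"experimental"})
    )

    def __post_init__(self) -> None:
        if self.min_old_annotations < 1 or self.min_new_experimental < 1:
            raise ValueError("thresholds must be >= 1")


def classify_pairs(
    old_eval: AnnotationClosure,
    new_eval: AnnotationClosure,
    new_ref: AnnotationClosure,
    graph: OntologyGraph | None = None,
) -> dict[tuple[str, str], str]:
    """Label every old evaluated closure pair against the newer release.

    ``new_ref`` must hold only the *new* reference (experimental) closure
    pairs — those absent from the old reference closure (see
    :func:`annotrack.propagation.closure_difference`) — and the NOT
    assertions added in the newer release. Explicit rejection takes
    precedence over confirmation: a curator's exact-term NOT outweighs a
    simultaneous experimental descendant elsewhere in the DAG.
    """
    graphs = {id(c.graph) for c in (old_eval, new_eval, new_ref) if c.graph is not None}
    if graph is not None:
        graphs.add(id(graph))
    if len(graphs) > 1:
        raise ValueError("closures were built on different ontologies")
    out: dict[tuple[str, str], str] = {}
    empty: frozenset[str] = frozenset()
    for gene, terms in old_eval.positive.items():
        ref_not = new_ref.negated.get(gene, empty)
        ref_pos = new_ref.positive.get(gene, empty)
        eval_pos = new_eval.positive.get(gene, empty)
        for t in terms:
            if t in ref_not:
                out[(gene, t)] = REJECTED_EXPLICIT
            elif t in ref_pos:
                out[(gene, t)] = CONFIRMED
            elif t not in eval_pos:
                out[(gene, t)] = REMOVED
            else:
                out[(gene, t)] = UNINFORMATIVE
    return out


class TermReliability(NamedTuple):
    n_confirmed: int
    n_rejected_explicit: int
    n_removed: int
    reliability: float | None


def reliability_by_term(
    classifications: dict[tuple[str, str], str],
) -> dict[str, TermReliability]:
    """Aggregate pair labels per term; uninformative pairs never enter the ratio."""
    conf: dict[str, int] = {}
    rej: dict[str, int] = {}
    rem: dict[str, int] = {}
    terms: set[str] = set()
    for (_gene, t), label in classifications.items():
        terms.add(t)
        if label == CONFIRMED:
            conf[t] = conf.get(t, 0) + 1
        elif label == REJECTED_EXPLICIT:
            rej[t] = rej.get(t, 0) + 1
        elif label == REMOVED:
            rem[t] = rem.get(t, 0) + 1
    out: dict[str, TermReliability] = {}
    for t in terms:
        c, r, m = conf.get(t, 0), rej.get(t, 0), rem.get(t, 0)
        denom = c + r + m
        out[t] = TermReliability(c, r, m, c / denom if denom else None)
    return out


class TermCoverage(NamedTuple):
    n_predicted: int
    n_missed: int
    coverage: float | None


def coverage_by_term(
    old_eval: AnnotationClosure,
    old_ref: AnnotationClosure,
    new_ref: AnnotationClosure,
) -> dict[str, TermCoverage]:
    """Fraction of new experimental closure pairs anticipated per term.

    ``new_ref`` here is the *full* newer-release reference closure; pairs
    already implied by ``old_ref`` are not new and are skipped. A new pair is
    predicted when the old evaluated closure contains it, else missed.
    """
    pred: dict[str, int] = {}
    miss: dict[str, int] = {}
    empty: frozenset[str] = frozenset()
    for gene, terms in new_ref.positive.items():
        old_known = old_ref.positive.get(gene, empty)
        old_pred = old_eval.positive.get(gene, empty)
        for t in terms:
            if t in old_known:
                continue
            if t in old_pred:
                pred[t] = pred.get(t, 0) + 1
            else:
                miss[t] = miss.get(t, 0) + 1
    out: dict[str, TermCoverage] = {}
    for t in set(pred) | set(miss):
        p, m = pred.get(t, 0), miss.get(t, 0)
        out[t] = TermCoverage(p, m, p / (p + m) if p + m else None)
    return out


TERM_QUALITY_COLUMNS = [
    "term", "namespace", "name", "specificity",
    "n_confirmed", "n_rejected_explicit", "n_removed", "reliability",
    "n_predicted", "n_missed", "coverage",
    "n_old_electronic", "n_new_experimental", "reportable",
]


def evaluate_release_pair(
    old_corpus: AnnotationCorpus,
    new_corpus: AnnotationCorpus,
    graph: OntologyGraph,
    graph_old: OntologyGraph | None = None,
    config: EvaluationConfig | None = None,
    source_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full pipeline: one TermQuality row per term touched by the release pair.

    Both releases are propagated on ``graph`` (the analysis ontology, normally
    the newer release's); when ``graph_old`` is given the term universe is
    first restricted to the terms shared by both ontology releases.
    Specificity is the IC of the term in the *old* release's evaluated
    stratum. Rows failing the thresholds are retained with ``reportable``
    False; the reportable view is ``df[df.reportable]``.
    """
    config = config or EvaluationConfig()
    shared = shared_terms(graph_old, graph) if graph_old is not None else None

    old_corpus, dropped_old = drop_contradictory_pairs(old_corpus)
    new_corpus, dropped_new = drop_contradictory_pairs(new_corpus)
    if dropped_old or dropped_new:
        log.info(
            "dropped contradictory NOT/positive pairs: %d old, %d new",
            len(dropped_old), len(dropped_new),
        )

    def closure(corpus: AnnotationCorpus, sel: Selector, label: str) -> AnnotationClosure:
        sub = filter_corpus(corpus, sel, graph=graph, source_map=source_map)
        return build_closure(sub, graph, stratum=label, terms=shared)

    old_eval = closure(old_corpus, config.evaluated_category, "old-evaluated")
    new_eval = closure(new_corpus, config.evaluated_category, "new-evaluated")
    old_ref = closure(old_corpus, config.reference_category, "old-reference")
    new_ref = closure(new_corpus, config.reference_category, "new-reference")

    if not old_eval.positive:
        log.warning("evaluated stratum of the old release is empty")

    new_ref_new = closure_difference(new_ref, old_ref)
    classifications = classify_pairs(old_eval, new_eval, new_ref_new, graph)
    rel = reliability_by_term(classifications)
    cov = coverage_by_term(old_eval, old_ref, new_ref)

    table = term_frequency(old_eval, graph) if old_eval.positive else None
    if table is not None:
        information_content(table)

    n_old: dict[str, int] = {}
    for _g, t in old_eval.pairs():
        n_old[t] = n_old.get(t, 0) + 1
    n_new_exp: dict[str, int] = {}
    for _g, t in new_ref.pairs():
        n_new_exp[t] = n_new_exp.get(t, 0) + 1

    rows = []
    for t in sorted(set(rel) | set(cov)):
        r = rel.get(t, TermReliability(0, 0, 0, None))
        c = cov.get(t, TermCoverage(0, 0, None))
        nold = n_old.get(t, 0)
        nnew = n_new_exp.get(t, 0)
        rows.append({
            "term": t,
            "namespace": graph.namespace.get(t, ""),
            "name": graph.name.get(t, ""),
            "specificity": table.ic.get(t, np.nan) if table else np.nan,
            "n_confirmed": r.n_confirmed,
            "n_rejected_explicit": r.n_rejected_explicit,
            "n_removed": r.n_removed,
            "reliability": np.nan if r.reliability is None else r.reliability,
            "n_predicted": c.n_predicted,
            "n_missed": c.n_missed,
            "coverage": np.nan if c.coverage is None else c.coverage,
            "n_old_electronic": nold,
            "n_new_experimental": nnew,
            "reportable": (
                nold >= config.min_old_annotations
                and nnew >= config.min_new_experimental
            ),
        })
    return pd.DataFrame(rows, columns=TERM_QUALITY_COLUMNS)


def pooled_reliability(
    classifications: dict[tuple[str, str], str],
    pairs: Iterable[tuple[str, str]] | None = None,
) -> float | None:
    """Confirmed / (confirmed + rejected + removed) pooled over pairs.

    With ``pairs`` given, only those (gene, term) pairs enter the pool — e.g.
    the directly annotated pairs, which are the independent units when
    recovering event rates from a simulation (ancestor pairs of one gene are
    correlated through shared terms).
    """
    if pairs is None:
        labels = list(classifications.values())
    else:
        labels = [classifications[p] for p in pairs if p in classifications]
    conf = sum(1 for l in labels if l == CONFIRMED)
    bad = sum(1 for l in labels if l in (REJECTED_EXPLICIT, REMOVED))
    denom = conf + bad
    return conf / denom if denom else None


# -- summaries -----------------------------------------------------------------


class DistributionSummary(NamedTuple):
    q1: float
    median: float
    q3: float
    mean: float
    outliers: tuple[float, ...]
    n: int


def summarize_distribution(values: Iterable[float]) -> DistributionSummary:
    """Boxplot statistics: quartiles by linear interpolation, mean, and
    outliers farther than 1.5 IQR from the nearest quartile."""
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_distribution needs at least one defined value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(v) for v in arr[(arr < lo) | (arr > hi)])
    return DistributionSummary(
        float(q1), float(med), float(q3), float(arr.mean()), outliers, int(arr.size)
    )


class IntervalComparison(NamedTuple):
    u: float
    p: float
    significant: bool


def compare_intervals(
    values_a: Iterable[float], values_b: Iterable[float], alpha: float = 0.05
) -> IntervalComparison:
    """Two-sided Mann-Whitney U test between two per-term measure samples.

    The U statistic is reported for the first sample. The null distribution
    is exact for small tie-free samples and a tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples need at least one defined value")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return IntervalComparison(float(res.statistic), float(res.pvalue),
                              bool(res.pvalue < alpha))
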