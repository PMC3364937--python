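"""True-path propagation of annotations and information-content specificity.

Annotating a gene product to a term implies every ancestor of that term over
is_a/part_of, so all accounting works on the *closure*: the per-gene set of
implied (gene, term) pairs. NOT annotations are exact-term assertions of
absence and are never propagated.

A term's specificity is its information content, IC(t) = -log2 freq(t), where
freq is the inheritance-aware annotation frequency normalized per namespace so
that the namespace root has frequency 1 (hence IC 0). Frequencies count genes,
not records: a gene contributes at most one closure pair per term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, TextIO

import pandas as pd

from .annotations import AnnotationCorpus
from .ontology import OntologyGraph


class ClosureError(Exception):
    """Corpus terms that cannot be resolved against the ontology."""


@dataclass
class AnnotationClosure:
    """Per-gene propagated positive term sets and unpropagated NOT term sets."""

    positive: dict[str, frozenset[str]] = field(default_factory=dict)
    negated: dict[str, frozenset[str]] = field(default_factory=dict)
    stratum: str = ""
    graph: OntologyGraph | None = field(default=None, repr=False, compare=False)

    def pairs(self) -> Iterator[tuple[str, str]]:
        """All positive closure (gene, term) pairs."""
        for gene, terms in self.positive.items():
            for t in terms:
                yield gene, t

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.positive.values())


def build_closure(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    stratum: str = "",
    terms: set[str] | None = None,
) -> AnnotationClosure:
    """Propagate a corpus over the DAG.

    Positive annotations expand to their full ancestor set (reflexive); NOT
    annotations are kept verbatim at the asserted term. When ``terms`` is
    given (e.g. the cross-release shared set), annotations outside it are
    dropped and closure sets are intersected with it.
    """
    positive: dict[str, set[str]] = {}
    negated: dict[str, set[str]] = {}
    bad: list[str] = []
    for r in corpus.records:
        canon = graph.resolve_or_none(r.term)
        if canon is None or canon in graph.obsolete:
            bad.append(f"{r.gene} -> {r.term}")
            continue
        if terms is not None and canon not in terms:
            continue
        if r.negated:
            negated.setdefault(r.gene, set()).add(canon)
        else:
            anc = graph.ancestors(canon)
            if terms is not None:
                anc = anc & terms
            positive.setdefault(r.gene, set()).update(anc)
    if bad:
        raise ClosureError(
            "annotations to unknown/obsolete terms: " + "; ".join(bad[:10])
        )
    return AnnotationClosure(
        positive={g: frozenset(v) for g, v in positive.items()},
        negated={g: frozenset(v) for g, v in negated.items()},
        stratum=stratum,
        graph=graph,
    )


def closure_difference(
    minuend: AnnotationClosure, subtrahend: AnnotationClosure
) -> AnnotationClosure:
    """Pairs of ``minuend`` absent from ``subtrahend`` — the *new* annotations.

    Applied separately to positive closure pairs and to NOT assertions.
    """
    positive = {}
    for g, terms in minuend.positive.items():
        diff = terms - subtrahend.positive.get(g, frozenset())
        if diff:
            positive[g] = diff
    negated = {}
    for g, terms in minuend.negated.items():
        diff = terms - subtrahend.negated.get(g, frozenset())
        if diff:
            negated[g] = diff
    return AnnotationClosure(
        positive=positive,
        negated=negated,
        stratum=f"{minuend.stratum}-new",
        graph=minuend.graph,
    )


@dataclass
class TermFrequencyTable:
    """Gene-level closure counts, per-namespace frequencies and IC in bits."""

    count: dict[str, int] = field(default_factory=dict)
    freq: dict[str, float] = field(default_factory=dict)
    ic: dict[str, float] = field(default_factory=dict)
    namespace: dict[str, str] = field(default_factory=dict)
    total: dict[str, int] = field(default_factory=dict)  # namespace -> root count

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "namespace": self.namespace.get(t, ""),
                "count": self.count[t],
                "freq": self.freq[t],
                "ic": self.ic.get(t, float("nan")),
            }
            for t in sorted(self.count)
        ]
        return pd.DataFrame(
            rows, columns=["term", "namespace", "count", "freq", "ic"]
        )

    def to_tsv(self, dest: str | TextIO) -> None:
        self.to_frame().to_csv(dest, sep="\t", index=False)


def term_frequency(
    closure: AnnotationClosure, graph: OntologyGraph
) -> TermFrequencyTable:
    """Count genes per term in the closure and normalize per namespace root.

    Every gene annotated in a namespace carries that namespace's root in its
    closure, so the root count is the number of genes annotated there and
    freq(root) = 1. Namespaces without annotations are absent from the table.
    """
    table = TermFrequencyTable()
    for _gene, term in closure.pairs():
        table.count[term] = table.count.get(term, 0) + 1
    roots = graph.roots()
    for ns, root in roots.items():
        if root in table.count:
            table.total[ns] = table.count[root]
    for term, n in table.count.items():
        ns = graph.namespace[term]
        table.namespace[term] = ns
        table.freq[term] = n / table.total[ns]
    return table


def information_content(table: TermFrequencyTable) -> dict[str, float]:
    """Fill and return IC(t) = -log2 freq(t); zero-frequency terms are omitted.

    Every closure containing a child also contains its parents, so a child's
    count is at most its parent's and IC is monotone non-decreasing from root
    to leaves.
    """
    table.ic = {
        t: -math.log2(f) for t, f in table.freq.items() if f > 0
    }
    return table.ic
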