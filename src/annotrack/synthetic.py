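"""Synthetic ontologies and release pairs with known ground-truth event rates.

The generator builds a random rooted DAG per namespace, annotates genes with
direct electronic (IEA) annotations plus an experimental background, and then
derives a newer release by drawing one event per electronic annotation:

* ``confirm``   — a new experimental annotation arrives at the term (or, with
  probability ``p_descendant_confirm``, at a random strict descendant);
* ``reject``    — the annotation is dropped and an exact-term experimental NOT
  assertion is added;
* ``remove``    — the annotation silently disappears;
* ``specialize``— the electronic annotation is replaced by one at a strict
  descendant (no descendant: kept unchanged, tallied as a fallback);
* ``unchanged`` — copied verbatim.

Independently, *novel* experimental annotations unrelated to any event are
injected into the newer release so coverage has its own ground truth. Events
are drawn per direct annotation; closure-level consequences (ancestor pairs)
emerge only through the evaluation engine, which is what makes the simulator
an independent check of the DAG semantics. A single NumPy random stream,
fully determined by ``seed``, drives both structure and events.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .annotations import (
    DEFAULT_SOURCE_MAP,
    AnnotationCorpus,
    AnnotationRecord,
    write_gaf,
)
from .ontology import NAMESPACES, OntologyGraph, write_obo

OLD_RELEASE_LABEL = "2008-01-16"
NEW_RELEASE_LABEL = "2011-01-11"

_EVENTS = ("confirm", "reject", "remove", "specialize", "unchanged")


@dataclass(frozen=True)
class SimulationConfig:
    """Sizes and ground-truth event probabilities for a simulated release pair.

    Defaults describe the reference simulation: 150 terms per namespace with
    up to 3 parents each, 10000 genes averaging 2 direct electronic
    annotations, a 30/10/10/0/50% confirm/reject/remove/specialize/unchanged
    event mix, and half an experimental-background and half a novel
    experimental annotation per gene.
    """

    n_terms: int = 150
    max_parents: int = 3
    n_genes: int = 10_000
    annotations_per_gene: float = 2.0
    p_confirm: float = 0.3
    p_reject: float = 0.1
    p_remove: float = 0.1
    p_specialize: float = 0.0
    p_unchanged: float = 0.5
    p_descendant_confirm: float = 0.5
    experimental_background_per_gene: float = 0.5
    novel_experimental_per_gene: float = 0.5
    p_part_of: float = 0.2
    source_mix: tuple[tuple[str, float], ...] = tuple(
        (label, 1 / 6)
        for label in (
            "ec2go", "uniprot_subcell", "uniprotkb_kw",
            "ensembl_compara", "hamap2go", "interpro",
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_confirm, self.p_reject, self.p_remove,
                 self.p_specialize, self.p_unchanged)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("event probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"event probabilities must sum to 1, got {sum(probs)}")
        if self.n_terms < 1 or self.n_genes < 1 or self.max_parents < 1:
            raise ValueError("all sizes must be >= 1")
        if self.annotations_per_gene < 1:
            raise ValueError("annotations_per_gene must be >= 1")

    @property
    def event_probabilities(self) -> tuple[float, ...]:
        return (self.p_confirm, self.p_reject, self.p_remove,
                self.p_specialize, self.p_unchanged)


@dataclass
class GroundTruth:
    """What the simulator actually drew, and the values the pipeline should find."""

    tallies: dict[str, int] = field(default_factory=dict)
    expected_reliability: float = float("nan")
    realized_reliability: float = float("nan")
    expected_coverage: float = float("nan")
    events: dict[tuple[str, str], str] = field(default_factory=dict, repr=False)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "tallies": self.tallies,
            "expected_reliability": self.expected_reliability,
            "realized_reliability": self.realized_reliability,
            "expected_coverage": self.expected_coverage,
            "config": self.config,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


class SimulatedReleasePair(NamedTuple):
    ontology: OntologyGraph
    old: AnnotationCorpus
    new: AnnotationCorpus
    truth: GroundTruth


def generate_ontology(
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> OntologyGraph:
    """Random rooted DAG per namespace; acyclic by construction.

    Terms are created in order and each non-root term draws 1..max_parents
    parents among earlier terms of its namespace (first edge is_a, later ones
    part_of with probability ``p_part_of``), so every term reaches its root.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    g = OntologyGraph()
    counter = 0
    for ns in NAMESPACES:
        ns_terms: list[str] = []
        for i in range(config.n_terms):
            counter += 1
            term = f"GO:{counter:07d}"
            g.terms.add(term)
            g.name[term] = f"synthetic {ns.split('_')[-1]} term {i}"
            g.namespace[term] = ns
            if i == 0:
                g.parents[term] = set()
            else:
                k = int(rng.integers(1, config.max_parents + 1))
                k = min(k, len(ns_terms))
                chosen = rng.choice(len(ns_terms), size=k, replace=False)
                edges = set()
                for j, idx in enumerate(sorted(int(x) for x in chosen)):
                    rel = "is_a"
                    if j > 0 and rng.random() < config.p_part_of:
                        rel = "part_of"
                    edges.add((ns_terms[idx], rel))
                g.parents[term] = edges
            ns_terms.append(term)
    g.validate()
    return g


def _choice(rng: np.random.Generator, seq: list[str]) -> str:
    return seq[int(rng.integers(0, len(seq)))]


def generate_release_pair(
    config: SimulationConfig, graph: OntologyGraph | None = None
) -> SimulatedReleasePair:
    """Draw an (ontology, old release, new release, ground truth) quadruple."""
    rng = np.random.default_rng(config.seed)
    if graph is None:
        graph = generate_ontology(config, rng=rng)
    terms = sorted(t for t in graph.terms if t not in graph.obsolete)
    source_labels = [s for s, _ in config.source_mix]
    source_probs = np.asarray([p for _, p in config.source_mix], dtype=float)
    source_probs = source_probs / source_probs.sum()
    ref_by_source = {v: k for k, v in DEFAULT_SOURCE_MAP.items()}
    strict_desc: dict[str, list[str]] = {}

    def descendants_of(term: str) -> list[str]:
        if term not in strict_desc:
            strict_desc[term] = sorted(graph.descendants(term) - {term})
        return strict_desc[term]

    def iea(gene: str, term: str, source: str, date: str) -> AnnotationRecord:
        return AnnotationRecord(
            gene=gene, term=term, evidence="IEA",
            reference=ref_by_source[source], aspect="",
            taxon=9606, taxon_raw="taxon:9606", date=date,
            assigned_by="annotrack-sim",
        )

    def exp(gene: str, term: str, negated: bool, date: str) -> AnnotationRecord:
        return AnnotationRecord(
            gene=gene, term=term, qualifier="NOT" if negated else "",
            evidence="IDA", reference="PMID:0000001",
            taxon=9606, taxon_raw="taxon:9606", date=date,
            assigned_by="annotrack-sim",
        )

    old_records: list[AnnotationRecord] = []
    new_records: list[AnnotationRecord] = []
    tallies = {k: 0 for k in (
        "n_electronic", "n_confirm", "n_confirm_exact", "n_confirm_descendant",
        "n_reject", "n_remove", "n_specialize", "n_specialize_fallback",
        "n_unchanged", "n_background_experimental", "n_novel_experimental",
    )}
    events: dict[tuple[str, str], str] = {}
    electronic_closure: dict[str, set[str]] = {}
    old_exp_direct: dict[str, set[str]] = {}
    new_exp_positive: set[tuple[str, str]] = set()
    coverage_predicted = 0
    coverage_missed = 0

    genes = [f"G{i:06d}" for i in range(config.n_genes)]
    for gene in genes:
        # Direct electronic terms form an antichain (no chosen term implies
        # another), so each annotation's event is visible at its own term
        # without interference from a sibling annotation's closure. This is
        # what makes the drawn tallies an exact oracle for the engine's
        # labels at directly annotated terms.
        n_annot = 1 + int(rng.poisson(config.annotations_per_gene - 1.0))
        chosen: set[str] = set()
        chosen_closure: set[str] = set()
        attempts = 0
        while len(chosen) < n_annot and attempts < 20 * n_annot:
            attempts += 1
            t = _choice(rng, terms)
            if t in chosen_closure or graph.ancestors(t) & chosen:
                continue
            chosen.add(t)
            chosen_closure |= graph.ancestors(t)
        electronic_closure[gene] = chosen_closure

        # Experimental background present identically in both releases; its
        # closure must not imply any chosen term, so confirmations stay "new".
        n_bg = int(rng.poisson(config.experimental_background_per_gene))
        background: set[str] = set()
        attempts = 0
        while len(background) < n_bg and attempts < 20 * max(n_bg, 1):
            attempts += 1
            t = _choice(rng, terms)
            if t in background or graph.ancestors(t) & chosen:
                continue
            background.add(t)
        old_exp_direct[gene] = background
        background_closure: set[str] = set()
        for t in background:
            background_closure |= graph.ancestors(t)
        for t in sorted(background):
            old_records.append(exp(gene, t, False, "20080116"))
            new_records.append(exp(gene, t, False, "20110111"))
            new_exp_positive.add((gene, t))

        for t in sorted(chosen):
            source = source_labels[int(rng.choice(len(source_labels), p=source_probs))]
            old_records.append(iea(gene, t, source, "20080116"))
            tallies["n_electronic"] += 1
            event = _EVENTS[int(rng.choice(len(_EVENTS),
                                           p=config.event_probabilities))]
            if event == "confirm":
                tallies["n_confirm"] += 1
                target = t
                if rng.random() < config.p_descendant_confirm:
                    # a descendant whose closure meets no *other* chosen term
                    candidates = [
                        d for d in descendants_of(t)
                        if not (graph.ancestors(d) & chosen) - {t}
                        and (gene, d) not in new_exp_positive
                    ]
                    if candidates:
                        target = _choice(rng, candidates)
                if target != t:
                    tallies["n_confirm_descendant"] += 1
                else:
                    tallies["n_confirm_exact"] += 1
                new_records.append(iea(gene, t, source, "20110111"))
                if (gene, target) not in new_exp_positive:
                    new_records.append(exp(gene, target, False, "20110111"))
                    new_exp_positive.add((gene, target))
            elif event == "reject":
                tallies["n_reject"] += 1
                new_records.append(exp(gene, t, True, "20110111"))
            elif event == "remove":
                tallies["n_remove"] += 1
            elif event == "specialize":
                candidates = [
                    d for d in descendants_of(t)
                    if not (graph.ancestors(d) & chosen) - {t}
                ]
                if candidates:
                    tallies["n_specialize"] += 1
                    new_records.append(iea(gene, _choice(rng, candidates),
                                           source, "20110111"))
                else:
                    tallies["n_specialize_fallback"] += 1
                    new_records.append(iea(gene, t, source, "20110111"))
            else:
                tallies["n_unchanged"] += 1
                new_records.append(iea(gene, t, source, "20110111"))
            events[(gene, t)] = event

        tallies["n_background_experimental"] += len(background)
        # Novel experimental annotations (coverage ground truth): never below
        # a chosen term, so they cannot confirm an electronic annotation.
        n_novel = int(rng.poisson(config.novel_experimental_per_gene))
        drawn = 0
        attempts = 0
        while drawn < n_novel and attempts < 20 * max(n_novel, 1):
            attempts += 1
            t = _choice(rng, terms)
            if (
                (gene, t) in new_exp_positive
                or graph.ancestors(t) & chosen
                or t in background_closure
            ):
                continue
            drawn += 1
            new_records.append(exp(gene, t, False, "20110111"))
            new_exp_positive.add((gene, t))
            tallies["n_novel_experimental"] += 1
            if t in electronic_closure[gene]:
                coverage_predicted += 1
            else:
                coverage_missed += 1

    informative = tallies["n_confirm"] + tallies["n_reject"] + tallies["n_remove"]
    denom = config.p_confirm + config.p_reject + config.p_remove
    truth = GroundTruth(
        tallies=tallies,
        expected_reliability=(config.p_confirm / denom) if denom else float("nan"),
        realized_reliability=(
            tallies["n_confirm"] / informative if informative else float("nan")
        ),
        expected_coverage=(
            coverage_predicted / (coverage_predicted + coverage_missed)
            if coverage_predicted + coverage_missed
            else float("nan")
        ),
        events=events,
        config=dataclasses.asdict(config),
    )
    old = AnnotationCorpus(records=old_records, release_label=OLD_RELEASE_LABEL)
    new = AnnotationCorpus(records=new_records, release_label=NEW_RELEASE_LABEL)
    return SimulatedReleasePair(graph, old, new, truth)


def write_simulation(pair: SimulatedReleasePair, out_dir: str) -> dict[str, str]:
    """Emit ontology.obo, old.gaf, new.gaf and truth.json into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "ontology": os.path.join(out_dir, "ontology.obo"),
        "old": os.path.join(out_dir, "old.gaf"),
        "new": os.path.join(out_dir, "new.gaf"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_obo(pair.ontology, paths["ontology"])
    write_gaf(pair.old, paths["old"])
    write_gaf(pair.new, paths["new"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(pair.truth.to_json() + "\n")
    return paths
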