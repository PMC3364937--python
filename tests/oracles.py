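"""Independent brute-force oracles used by the test suite.

Everything here re-derives expected results from first principles — explicit
path enumeration over the DAG and literal application of the
confirm/reject/remove/uninformative and predicted/missed rules — without
touching the library's closure or classification code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from annotrack.ontology import OntologyGraph


# -- DAG oracles ---------------------------------------------------------------


def path_ancestors(graph: OntologyGraph, term: str) -> set[str]:
    """All terms reachable from ``term`` by enumerating every parent path.

    Mirrors the propagation rule (is_a always, part_of within a namespace)
    but walks every path explicitly, with no memoisation or closure algebra.
    """
    found: set[str] = set()

    def walk(t: str) -> None:
        found.add(t)
        for parent, rel in graph.parents.get(t, ()):
            if rel == "is_a" or (
                rel == "part_of"
                and graph.namespace.get(parent) == graph.namespace.get(t)
            ):
                walk(parent)

    walk(term)
    return found


def closure_of(graph: OntologyGraph, terms) -> set[str]:
    out: set[str] = set()
    for t in terms:
        out |= path_ancestors(graph, t)
    return out


# -- classification / coverage oracles ------------------------------------------


def oracle_classify(
    graph: OntologyGraph,
    old_eval_direct: dict[str, set[str]],
    new_eval_direct: dict[str, set[str]],
    old_ref_direct: dict[str, set[str]],
    new_ref_direct: dict[str, set[str]],
    old_ref_not: dict[str, set[str]],
    new_ref_not: dict[str, set[str]],
) -> dict[tuple[str, str], str]:
    """Literal rule application per old evaluated closure pair.

    Inputs are per-gene *direct* annotation term sets; all closures are
    rebuilt here by path enumeration.
    """
    out: dict[tuple[str, str], str] = {}
    for gene, direct in old_eval_direct.items():
        old_pairs = closure_of(graph, direct)
        new_nots = new_ref_not.get(gene, set()) - old_ref_not.get(gene, set())
        new_ref_pairs = closure_of(graph, new_ref_direct.get(gene, set())) - closure_of(
            graph, old_ref_direct.get(gene, set())
        )
        new_eval_pairs = closure_of(graph, new_eval_direct.get(gene, set()))
        for t in old_pairs:
            if t in new_nots:
                out[(gene, t)] = "rejected_explicit"
            elif t in new_ref_pairs:
                out[(gene, t)] = "confirmed"
            elif t not in new_eval_pairs:
                out[(gene, t)] = "removed"
            else:
                out[(gene, t)] = "uninformative"
    return out


def oracle_coverage(
    graph: OntologyGraph,
    old_eval_direct: dict[str, set[str]],
    old_ref_direct: dict[str, set[str]],
    new_ref_direct: dict[str, set[str]],
) -> dict[str, tuple[int, int]]:
    """(n_predicted, n_missed) per term by literal rule application."""
    pred: dict[str, int] = {}
    miss: dict[str, int] = {}
    genes = set(new_ref_direct)
    for gene in genes:
        new_pairs = closure_of(graph, new_ref_direct.get(gene, set()))
        old_known = closure_of(graph, old_ref_direct.get(gene, set()))
        electronic = closure_of(graph, old_eval_direct.get(gene, set()))
        for t in new_pairs - old_known:
            if t in electronic:
                pred[t] = pred.get(t, 0) + 1
            else:
                miss[t] = miss.get(t, 0) + 1
    return {
        t: (pred.get(t, 0), miss.get(t, 0)) for t in set(pred) | set(miss)
    }


# -- random instances -----------------------------------------------------------


def random_ontology(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Small single-namespace DAG, acyclic by sequential construction."""
    g = OntologyGraph()
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    for i, t in enumerate(terms):
        g.terms.add(t)
        g.name[t] = f"t{i}"
        g.namespace[t] = "biological_process"
        edges: set[tuple[str, str]] = set()
        if i > 0:
            # at most two parents keeps exhaustive path enumeration tractable
            k = int(rng.integers(1, min(i, 2) + 1))
            for idx in rng.choice(i, size=k, replace=False):
                rel = "is_a" if rng.random() < 0.7 else "part_of"
                edges.add((terms[int(idx)], rel))
        g.parents[t] = edges
    g.validate()
    return g


def random_instance(rng: np.random.Generator, n_terms: int = 15, n_genes: int = 30):
    """A random DAG plus random direct old/new annotation sets per gene."""
    graph = random_ontology(rng, int(rng.integers(3, n_terms + 1)))
    terms = sorted(graph.terms)
    genes = [f"g{i}" for i in range(int(rng.integers(1, n_genes + 1)))]

    def pick(max_n: int) -> set[str]:
        n = int(rng.integers(0, max_n + 1))
        return {terms[int(i)] for i in rng.choice(len(terms), size=n)} if n else set()

    old_eval = {g: pick(3) for g in genes}
    old_ref = {g: pick(2) for g in genes}
    old_not = {g: pick(1) for g in genes}
    new_eval = {}
    for g in genes:
        keep = {t for t in old_eval[g] if rng.random() < 0.6}
        new_eval[g] = keep | pick(2)
    new_ref = {g: old_ref[g] | pick(2) for g in genes}
    new_not = {g: old_not[g] | pick(1) for g in genes}
    return graph, genes, old_eval, old_ref, old_not, new_eval, new_ref, new_not


# -- statistics oracles ----------------------------------------------------------


def u_statistic(a, b) -> float:
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )


def exact_mwu_two_sided(a, b) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration of rank assignments.

    Valid for tie-free pooled samples, where the null distribution of U is
    symmetric about nm/2.
    """
    pooled = list(a) + list(b)
    n = len(a)
    center = len(a) * len(b) / 2.0
    dev = abs(u_statistic(a, b) - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        chosen = set(idx)
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        if abs(u_statistic(aa, bb) - center) >= dev - 1e-9:
            hits += 1
        total += 1
    return hits / total
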