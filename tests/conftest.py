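"""Shared fixtures: tiny hand-built ontologies and release pairs."""

from __future__ import annotations

import io

import pytest

from annotrack.annotations import AnnotationCorpus, parse_gaf
from annotrack.ontology import parse_ontology

CHAIN_OBO = """\
format-version: 1.2
ontology: go

[Term]
id: GO:0000001
name: bp root
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: B
namespace: biological_process
is_a: GO:0000002
"""

DIAMOND_OBO = """\
format-version: 1.2
ontology: go

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: B
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003
"""

# R <- A; A <- B; A <- C (B and C are siblings under A)
FOUR_TERM_OBO = """\
format-version: 1.2
ontology: go

[Term]
id: GO:0000001
name: R
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: B
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000004
name: C
namespace: biological_process
is_a: GO:0000002
"""

R, A, B, C = "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"


def gaf_text(rows, version: str = "2.0") -> str:
    """Rows of (gene, qualifier, term, evidence[, reference]) -> GAF text."""
    lines = [f"!gaf-version: {version}"]
    for row in rows:
        gene, qual, term, ev = row[:4]
        ref = row[4] if len(row) > 4 else "GO_REF:0000002"
        cols = ["UniProtKB", gene, gene, qual, term, ref, ev, "", "P", "", "",
                "protein", "taxon:9606", "20080101", "GOA", "", ""]
        lines.append("\t".join(cols if version == "2.0" else cols[:15]))
    return "\n".join(lines) + "\n"


def corpus(rows, label: str = "") -> AnnotationCorpus:
    return parse_gaf(io.StringIO(gaf_text(rows)), release_label=label)


@pytest.fixture
def chain_graph():
    return parse_ontology(io.StringIO(CHAIN_OBO))


@pytest.fixture
def diamond_graph():
    return parse_ontology(io.StringIO(DIAMOND_OBO))


@pytest.fixture
def four_term_graph():
    return parse_ontology(io.StringIO(FOUR_TERM_OBO))


@pytest.fixture
def worked_release_pair(four_term_graph):
    """The hand-enumerated 4-gene fixture.

    Old electronic: g1->B, g2->A, g3->B. Newer release: g1 keeps its
    electronic annotation and gains an experimental confirmation at B; g2's
    electronic annotation is replaced by an experimental NOT at A; g3
    disappears. Expected per-term reliability: A = 1/3 (one confirmed, one
    explicitly rejected, one removed), B = 1/2, R = 1/3.
    """
    old = corpus(
        [("g1", "", B, "IEA"), ("g2", "", A, "IEA"), ("g3", "", B, "IEA")],
        label="old",
    )
    new = corpus(
        [
            ("g1", "", B, "IEA"),
            ("g1", "", B, "IDA", "PMID:1"),
            ("g2", "NOT", A, "IDA", "PMID:2"),
        ],
        label="new",
    )
    return four_term_graph, old, new
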