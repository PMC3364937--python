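"""GAF annotation releases: parsing, writing, evidence and source semantics.

A GAF release maps gene products (e.g. UniProtKB accessions) to GO terms, each
mapping carrying a qualifier (``NOT`` marks an explicit negative assertion), an
evidence code, and a database reference. Evidence codes fall into three broad
categories:

* experimental — curator-read experiments: EXP, IMP, IGI, IPI, IEP, IDA
* curated — curator-assigned from non-experimental evidence: ISS, RCA, IC, NAS, TAS
* electronic — computationally assigned without curator oversight: IEA

Codes tracking curation status (ND), obsolete codes (NR) and codes with too
little data to assess (ISO, ISA, ISM, IGC, IBA, IBD, IKR, IRD) are excluded,
as are codes this module has never heard of.

For electronic annotations the *source* (the pipeline that produced them) is
recovered from the database-reference column through a mapping of GO_REF
identifiers; a default table covering the six major UniProt-GOA sources ships
with the module and can be overridden from a two-column TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

log = logging.getLogger(__name__)

EXPERIMENTAL_CODES = frozenset({"EXP", "IMP", "IGI", "IPI", "IEP", "IDA"})
CURATED_CODES = frozenset({"ISS", "RCA", "IC", "NAS", "TAS"})
ELECTRONIC_CODES = frozenset({"IEA"})
EXCLUDED_CODES = frozenset(
    {"ND", "NR", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD"}
)

CATEGORIES = ("experimental", "curated", "electronic", "excluded")

#: GO reference-registry ids of the six electronic-annotation sources.
DEFAULT_SOURCE_MAP: dict[str, str] = {
    "GO_REF:0000002": "interpro",
    "GO_REF:0000003": "ec2go",
    "GO_REF:0000004": "uniprotkb_kw",
    "GO_REF:0000019": "ensembl_compara",
    "GO_REF:0000020": "hamap2go",
    "GO_REF:0000023": "uniprot_subcell",
}

SOURCE_LABELS = (
    "ec2go",
    "uniprot_subcell",
    "uniprotkb_kw",
    "ensembl_compara",
    "hamap2go",
    "interpro",
    "other",
)


class GafParseError(Exception):
    """Malformed GAF content; message names the offending line number."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One GAF line: a (gene product, GO term) assertion with its provenance."""

    gene: str
    term: str
    qualifier: str = ""
    evidence: str = ""
    reference: str = ""
    db: str = "UniProtKB"
    symbol: str = ""
    with_from: str = ""
    aspect: str = ""
    object_name: str = ""
    synonym: str = ""
    object_type: str = "protein"
    taxon: int | None = None
    taxon_raw: str = ""
    date: str = ""
    assigned_by: str = ""
    extension: str = ""
    gene_product_form: str = ""

    @property
    def negated(self) -> bool:
        """True when the qualifier carries NOT (including compound qualifiers)."""
        return "NOT" in self.qualifier.split("|")


@dataclass
class AnnotationCorpus:
    """One annotation release: its records plus the release date label.

    Release identity is the *file's* release label; per-record date columns are
    retained but never used for interval logic.
    """

    records: list[AnnotationRecord] = field(default_factory=list)
    release_label: str = ""
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)


def classify_evidence(code: str) -> str:
    """Map an evidence code to its category; total and case-normalizing."""
    code = code.strip().upper()
    if code in EXPERIMENTAL_CODES:
        return "experimental"
    if code in CURATED_CODES:
        return "curated"
    if code in ELECTRONIC_CODES:
        return "electronic"
    if code not in EXCLUDED_CODES:
        log.debug("unknown evidence code %r treated as excluded", code)
    return "excluded"


def attribute_source(
    record: AnnotationRecord, mapping: dict[str, str] | None = None
) -> str:
    """Source label of an electronic annotation, from its reference column."""
    if record.evidence.upper() != "IEA":
        raise ValueError(
            f"source attribution applies to IEA records only, got {record.evidence!r}"
        )
    mapping = DEFAULT_SOURCE_MAP if mapping is None else mapping
    return mapping.get(record.reference.strip(), "other")


def load_source_map(source: str | TextIO) -> dict[str, str]:
    """Read a reference-id -> source-label mapping from a two-column TSV."""
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        out: dict[str, str] = {}
        for line in source:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"source map lines need 2 columns, got {line!r}")
            out[parts[0]] = parts[1]
        return out
    finally:
        if close:
            source.close()


# -- GAF I/O -------------------------------------------------------------------

_GAF_COLUMNS = {"gaf1": 15, "gaf2": 17}


def _parse_taxon(value: str, lineno: int) -> int | None:
    first = value.split("|")[0].strip()
    if first.lower().startswith("taxon:"):
        first = first[6:]
    if not first:
        return None
    try:
        return int(first)
    except ValueError:
        log.warning("line %d: unparsable taxon %r; record kept with taxon unset",
                    lineno, value)
        return None


def parse_gaf(
    source: str | TextIO,
    dialect: str | None = None,
    release_label: str = "",
    errors: str = "raise",
) -> AnnotationCorpus:
    """Parse a GAF 1.0/2.0 file into an :class:`AnnotationCorpus`.

    ``dialect`` (``"gaf1"``/``"gaf2"``) is taken from the ``!gaf-version``
    header when not given. A line with the wrong column count raises
    :class:`GafParseError` naming the line number, or with
    ``errors="collect"`` is skipped and recorded on ``corpus.errors``. An
    unparsable taxon column only logs a warning and leaves ``taxon`` unset.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        records: list[AnnotationRecord] = []
        problems: list[str] = []
        ncols = _GAF_COLUMNS[dialect] if dialect else None
        for lineno, line in enumerate(source, start=1):
            line = line.rstrip("\n")
            if line.startswith("!"):
                header = line[1:].strip().lower()
                if header.startswith("gaf-version:") and ncols is None:
                    ver = header.split(":", 1)[1].strip()
                    ncols = 15 if ver.startswith("1") else 17
                continue
            if not line.strip():
                continue
            if ncols is None:
                ncols = 17
            cols = line.split("\t")
            if len(cols) != ncols:
                message = (
                    f"line {lineno}: expected {ncols} tab-separated columns, "
                    f"got {len(cols)}"
                )
                if errors == "raise":
                    raise GafParseError(message)
                log.warning("%s (line skipped)", message)
                problems.append(message)
                continue
            cols = cols + [""] * (17 - len(cols))
            records.append(
                AnnotationRecord(
                    db=cols[0],
                    gene=cols[1],
                    symbol=cols[2],
                    qualifier=cols[3],
                    term=cols[4],
                    reference=cols[5],
                    evidence=cols[6],
                    with_from=cols[7],
                    aspect=cols[8],
                    object_name=cols[9],
                    synonym=cols[10],
                    object_type=cols[11],
                    taxon=_parse_taxon(cols[12], lineno),
                    taxon_raw=cols[12],
                    date=cols[13],
                    assigned_by=cols[14],
                    extension=cols[15],
                    gene_product_form=cols[16],
                )
            )
        return AnnotationCorpus(
            records=records, release_label=release_label, errors=problems
        )
    finally:
        if close:
            source.close()


def _record_row(r: AnnotationRecord, ncols: int) -> str:
    taxon = r.taxon_raw or (f"taxon:{r.taxon}" if r.taxon is not None else "")
    cols = [
        r.db, r.gene, r.symbol, r.qualifier, r.term, r.reference, r.evidence,
        r.with_from, r.aspect, r.object_name, r.synonym, r.object_type,
        taxon, r.date, r.assigned_by, r.extension, r.gene_product_form,
    ]
    for i, required in ((1, "gene"), (4, "term"), (6, "evidence")):
        if not cols[i]:
            raise ValueError(f"record missing required field {required}: {r}")
    return "\t".join(cols[:ncols])


def write_gaf(
    corpus: AnnotationCorpus, dest: str | TextIO, dialect: str = "gaf2"
) -> None:
    """Write a corpus as GAF; ``parse_gaf`` round-trips it record for record."""
    ncols = _GAF_COLUMNS[dialect]
    close = False
    if isinstance(dest, str):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        dest.write("!gaf-version: %s\n" % ("1.0" if dialect == "gaf1" else "2.0"))
        if corpus.release_label:
            dest.write(f"!release: {corpus.release_label}\n")
        for r in corpus.records:
            dest.write(_record_row(r, ncols) + "\n")
    finally:
        if close:
            dest.close()


# -- hygiene and stratification --------------------------------------------------


def drop_contradictory_pairs(
    corpus: AnnotationCorpus,
) -> tuple[AnnotationCorpus, list[tuple[str, str]]]:
    """Remove every (gene, term) annotated both with and without NOT.

    Such dual annotations arise when a function holds in one spatio-temporal
    context but not another; with no context information in the file they are
    uninterpretable, so all records of the pair are discarded. Returns the
    filtered corpus and the sorted list of dropped (gene, term) pairs.
    """
    polarity: dict[tuple[str, str], set[bool]] = {}
    for r in corpus.records:
        polarity.setdefault((r.gene, r.term), set()).add(r.negated)
    dropped = sorted(k for k, v in polarity.items() if len(v) > 1)
    bad = set(dropped)
    kept = [r for r in corpus.records if (r.gene, r.term) not in bad]
    return AnnotationCorpus(records=kept, release_label=corpus.release_label), dropped


@dataclass(frozen=True)
class Selector:
    """Stratum selector; unset fields impose no constraint."""

    categories: frozenset[str] | None = None
    sources: frozenset[str] | None = None
    taxa: frozenset[int] | None = None
    namespaces: frozenset[str] | None = None
    terms: frozenset[str] | None = None

    @staticmethod
    def of(
        categories: Iterable[str] | None = None,
        sources: Iterable[str] | None = None,
        taxa: Iterable[int] | None = None,
        namespaces: Iterable[str] | None = None,
        terms: Iterable[str] | None = None,
    ) -> "Selector":
        f = lambda x: frozenset(x) if x is not None else None
        return Selector(f(categories), f(sources), f(taxa), f(namespaces), f(terms))


def filter_corpus(
    corpus: AnnotationCorpus,
    selector: Selector,
    graph=None,
    source_map: dict[str, str] | None = None,
) -> AnnotationCorpus:
    """Restrict a corpus to records matching every set selector constraint.

    Namespace and term constraints need the ontology ``graph`` (terms are
    resolved through alt_id merges first; a term filter naming an unknown term
    raises)."""
    if selector.namespaces is not None or selector.terms is not None:
        if graph is None:
            raise ValueError("namespace/term selectors require the ontology graph")
    term_filter: frozenset[str] | None = None
    if selector.terms is not None:
        resolved = set()
        for t in selector.terms:
            canon = graph.resolve_or_none(t)
            if canon is None:
                raise KeyError(f"term filter references unknown term {t}")
            resolved.add(canon)
        term_filter = frozenset(resolved)

    def keep(r: AnnotationRecord) -> bool:
        if selector.categories is not None:
            if classify_evidence(r.evidence) not in selector.categories:
                return False
        if selector.sources is not None:
            if r.evidence.upper() != "IEA":
                return False
            if attribute_source(r, source_map) not in selector.sources:
                return False
        if selector.taxa is not None and r.taxon not in selector.taxa:
            return False
        if selector.namespaces is not None or term_filter is not None:
            canon = graph.resolve_or_none(r.term)
            if canon is None:
                return False
            if selector.namespaces is not None:
                if graph.namespace.get(canon) not in selector.namespaces:
                    return False
            if term_filter is not None and canon not in term_filter:
                return False
        return True

    return AnnotationCorpus(
        records=[r for r in corpus.records if keep(r)],
        release_label=corpus.release_label,
    )
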