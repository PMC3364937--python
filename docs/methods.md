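# Methods

## Model

`annotrack` treats a pair of GO annotation releases as a longitudinal
experiment. The *evaluated* stratum of the older release (by default the
electronic, IEA-coded annotations) is scored against a *reference* stratum of
the newer release (by default the experimental evidence codes EXP, IMP, IGI,
IPI, IEP, IDA). The unit of accounting is the closure pair: gene *g* paired
with term *t* whenever *g*'s direct annotations imply *t* under the true-path
rule. Working on closure pairs, rather than annotation lines, realizes the
three DAG rules in one stroke:

1. a new experimental annotation at a descendant of *t* confirms (*g*, *t*),
   because the descendant implies *t*;
2. a new, less specific experimental annotation confirms exactly the
   ancestral pairs it implies and leaves deeper pairs untouched;
3. replacing an electronic annotation by a more specific one keeps every
   implied pair in the newer closure, so specialization never counts as
   removal.

Each old evaluated pair receives exactly one label, tested in this order:

* `rejected_explicit` — the newer reference stratum gained a NOT assertion
  at exactly *t*. NOT qualifiers are exact-term assertions of absence and
  never propagate. Explicit rejection is tested first: when a curator NOT at
  *t* coincides with a new experimental descendant elsewhere in the DAG, the
  exact-term curator assertion wins. This precedence is deliberately
  isolated in one predicate (`quality.classify_pairs`).
* `confirmed` — *t* is in the gene's *new* reference closure, i.e. the newer
  release's reference closure minus the older release's reference closure.
  Subtracting the old reference closure means a pair already experimentally
  implied before the interval confirms nothing and is no coverage event.
* `removed` — *t* left the gene's evaluated closure in the newer release
  (implicit rejection).
* `uninformative` — still present, neither confirmed nor contradicted.

Per term, reliability is confirmed/(confirmed+rejected+removed) and coverage
is predicted/(predicted+missed) over new reference pairs. Ratios with zero
denominator are reported as missing (NaN in the TSV), never coerced to 0 or
1: a term whose annotations all persisted carries no evidence either way.

Dual NOT/positive annotations of the same (gene, term) within one release
are context-dependent assertions that the file format cannot disambiguate;
all records of such pairs are discarded before evaluation and the dropped
pairs are reported.

## Specificity

Specificity is information content, `IC(t) = −log₂ freq(t)`. Frequencies
count *genes* (a gene contributes at most one closure pair per term, so
duplicate records cannot distort IC) and are normalized per namespace by the
root's count, which equals the number of genes annotated in that namespace.
Hence `freq(root) = 1`, `IC(root) = 0`, and IC is monotone non-decreasing
along every propagating edge. The log base and denominator are conventions
of this package (the bits scale is the natural one for information content);
changing base only rescales all values. Unannotated terms are omitted from
the table rather than given infinite IC. IC reported for a release-pair
evaluation is computed on the *old* release's evaluated stratum.

Note one consequence of root normalization: adding a newly annotated gene
enlarges the denominator, so "more data never raises IC" holds in the form:
adding an annotation to an already-annotated gene never increases any IC.

## Ontology handling

Propagating relations are is_a and part_of — GO's classic true-path
relations; other relation types (regulates, etc.) are parsed but never
traversed. part_of edges that cross a namespace boundary do not propagate,
since the three ontologies are analyzed separately. Obsolete terms are
parsed and flagged, never silently dropped; merged identifiers resolve
through the alt_id table. Because the vocabulary itself changes between
releases, per-term outputs can be restricted to the terms present in both
ontology releases (`shared_terms`); both annotation releases are propagated
on a single analysis ontology (normally the newer one) so closure
memberships are always comparable.

## Thresholds

Per-term ratios on a handful of pairs are noisy, so a term is flagged
*reportable* only with at least `min_old_annotations` (default 10) evaluated
closure pairs in the old release and `min_new_experimental` (default 10)
reference closure pairs in the new release. All terms are retained in the
full output; the thresholds only gate the reportable view and the summary
statistics.

## Summaries

Distribution summaries report first/second/third quartiles (linear
interpolation between order statistics — boxplot conventions differ, so the
convention is fixed here), the mean, and outliers farther than 1.5 IQR from
the nearest quartile. Strata are compared with a two-tailed Mann-Whitney U
test, significance at 0.05; the null distribution is exact for tie-free
samples with min(n, m) ≤ 8 and a tie-corrected normal approximation
otherwise.

## Synthetic release pairs

The simulator exists to give the pipeline a recoverable ground truth, not to
mimic curator sociology. It generates one random rooted DAG per namespace
(terms created in order, each non-root term drawing 1–`max_parents` parents
among earlier terms, so acyclicity and root reachability hold by
construction), annotates each gene with direct IEA annotations plus an
experimental background present in both releases, then draws one event per
electronic annotation: confirm (0.3), reject (0.1), remove (0.1), specialize
(0.0) or unchanged (0.5) by default — the reference event mix — over 10 000
genes averaging two direct annotations each (truncated Poisson). Confirmations
land at a strict descendant half the time; novel experimental annotations
(0.5 per gene) are injected independently so coverage has its own ground
truth. A reject event replaces the electronic annotation with the exact-term
NOT — retaining the positive would create exactly the dual NOT/positive
pattern that hygiene filtering discards, erasing the event.

Three sampling constraints make the drawn event tallies an *exact* oracle for
the engine's labels at directly annotated terms: each gene's direct terms
form an antichain (no chosen term implies another), background terms never
imply a chosen term, and descendant targets/novel terms never touch another
chosen term's closure. Without them, one annotation's event would leak into
another's ancestor closure and the recovery check would only hold
approximately. What the simulator consequently does *not* emulate: correlated
annotation depth within genes, term-popularity skew, curator batch effects,
or per-organism differences — so passing recovery tests validates the
engine's semantics, not the field realism of any particular rate estimate.

Event-rate recovery is asserted at the event level: pooled reliability over
*direct* pairs, which are independent Bernoulli draws, is compared to
p_confirm/(p_confirm+p_reject+p_remove) within three binomial standard
errors. Closure-level pooling is reported too but over-weights shared
general terms (a gene's confirmed annotation confirms the root pair it
shares with a removed sibling annotation), which biases the closure-pooled
ratio upward by a few percent at the default settings; this is a property of
closure accounting itself, visible equally in real data.

A single NumPy generator seeded from `seed` drives structure and events;
identical seeds give byte-identical OBO/GAF output.

## Numerical and degenerate cases

* Empty strata produce empty tables with a warning, not errors.
* Unknown evidence codes are excluded (logged), so future codes cannot break
  parsing; unknown GO_REF ids map to source `other`.
* Unparsable taxon fields keep the record with taxon unset (warning).
* Acyclicity, dangling parent references, and root reachability are checked
  at parse time; violations raise with the offending cycle or identifiers.
* Test and acceptance problem sizes (≤15-term DAGs for brute-force path
  enumeration, 200 random instances, 10 000-gene simulations) were chosen so
  exhaustive oracles stay exact while the whole suite runs in seconds.

## Known limitations

* Reliability inherits the biases of its gold standard: positive
  experimental annotations vastly outnumber NOTs, inflating reliability,
  while counting every silent removal as negative deflates it.
* Results on real UniProt-GOA history require the historical release files;
  this package ships only the engine and its synthetic validation.
* Isoform-level qualifiers (GAF column 17) are not interpreted.
* Source attribution trusts the GO_REF registry ids in the reference column;
  pipelines that omit them fall into `other`.
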