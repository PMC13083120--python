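# Methods

This note records the models and conventions the package implements, the
defaults and why they were chosen, and what the synthetic evaluation does
and does not establish.

## Data model and standoff dialect

A document is a plain-text narrative plus standoff annotations referencing
it by character offset: text-bound mentions (`T`, entities and event
triggers), events (`E`), binary relations (`R`), attributes (`A`) and
verbatim note lines (`#`). Offsets are **0-based, half-open, counted in
Unicode code points** of the UTF-8 text — stated prominently because
standoff corpora are routinely mis-read by one-off converters.
Discontinuous spans are semicolon-separated fragment pairs; a mention's
surface is the fragment texts joined by a single space, and any
disagreement between stored surface and the text at the offsets is a hard
error, not a warning.

Scheme labels contain spaces ('Drug name') but the on-disk dialect forbids
them, so the writer maps `' ' → '_'` and the reader maps `'_' → ' '`. The
mapping is bijective for every label of the bundled scheme (none contains
an underscore); documents using underscore-bearing custom labels would need
a custom alias table.

The parser accepts attributes on any host so that invalid files can be
loaded and diagnosed; the *validator* enforces that attributes sit on
events. Validation reports a closed set of rule codes (unknown labels after
alias resolution, relation endpoint constraints, trigger/event type
agreement, at most one intent/actuality attribute per event) and never
throws on structurally sound input.

Intent/actuality is modelled as four mutually exclusive binary attributes.
A valued form (`Intent E1 <label>`) is also parsed and folded to the binary
form during normalisation, since both encodings occur in standoff practice.

## Matching and alignment

Two criteria: **strict** (identical fragment list, equal label) and
**relaxed** (equal label, ≥ 1 character overlap, any fragment vs any
fragment). The relaxed threshold is deliberately one character — a
proportional-overlap option was considered and left out of v1 to keep the
match definition binary and simple.

Given the admissible pairs, annotations are aligned one-to-one by solving
an assignment problem (`scipy.optimize.linear_sum_assignment`) with a
lexicographic objective: (1) maximum cardinality, (2) maximum total
character overlap, (3) a deterministic positional tie-break preferring
earlier (start-offset-sorted) items. Greedy first-come pairing was
rejected because it undercounts agreement on crossing overlaps; the test
suite verifies the aligner against a brute-force enumeration oracle on
instances of ≤ 12 annotations. A caveat for cross-tool comparisons: other
evaluation scripts may pair greedily, and pairing policy affects counts
precisely in the crossing-overlap cases.

## Layer scores

* **entities** — typed-span match over non-trigger mentions (triggers are
  stored in the entity collection, as the standoff dialect does, but score
  in the event layer);
* **events** — equal event type plus a span match between triggers.
  Role-labelled argument agreement is deliberately *not* part of the event
  layer; it is a separate diagnostic (`score_event_arguments`) restricted
  to matched events, so trigger and argument disagreement are not
  conflated;
* **relations** — equal type and both endpoints paired in the entity
  correspondence computed under the same criterion;
* **attributes** — equal name (and value, if valued) and host events paired
  in the event correspondence.

Correspondences are computed once per (document pair, criterion) and
reused, so layer dependence holds by construction.

Degenerate cases: a layer empty on both sides of a document scores
P = R = 1 (nothing to find, nothing found) but is excluded from macro
averaging; corpus micro scores pool raw counts, so the convention cannot
inflate them; a layer empty in the *entire* corpus is reported as
undefined (NaN/null), not 0. Swapping reference and response swaps P and R
and preserves F1; the corpus report prints the swapped run alongside.

Both **micro** (pooled counts) and **macro** (mean per-document F1)
averages are reported because "averaged F1" is genuinely ambiguous in the
literature; micro is the headline default, being the standard for span F1
and robust to short documents.

Interpretation bands: F1 > 0.80 high, 0.60–0.80 moderate, < 0.60 low, with
[0.50, 0.60] flagged "potentially acceptable" for the event-like layers
(events, attributes), which are known to score lower.

## Synthetic corpus generator

The generator emulates the observable structure of UK incident-report
corpora, which are access-restricted: each report has up to five free-text
subsections (summary, underlying factors, actions taken, actions planned,
outcome) and an overall harm level (low / moderate / high / unspecified)
used for stratification. Text is template-with-slots in the style of a
worked incident narrative, assembled with exact offset tracking — no
language-model generation — so annotations are schema-valid by construction
and corpora are byte-identical under a fixed seed.

Defaults are the study conditions of the development corpus the scheme was
built on: mean 1200/55 ≈ 21.8 entity and 350/55 ≈ 6.4 event annotations
per report (Poisson-distributed, floors of 3 and 1); per-type frequency
weights proportional to that corpus's published counts, with a floor weight
of 2 for types it recorded at zero (e.g. 'Dose duration', 'Monitoring') so
rare-type code paths are exercised — a documented divergence from the
empirical table; intent/actuality attributes on 20/350 of events and
'Negated' on 5/350. Per-report annotation type multisets are drawn from the
weights first and then woven into sentences, so empirical frequencies
converge to the configured weights exactly as the corpus grows. Harm-level
weights are not published; 0.45 / 0.25 / 0.05 / 0.25 was fixed once as a
realistic skew (most incidents reported with low or unspecified harm).

What the generator does **not** emulate: real narrative style (fragmented
syntax, misspellings, implicit events), report-length heterogeneity between
reporting systems, nested or discontinuous gold spans, and inter-section
discourse structure. Passing agreement tests on synthetic corpora therefore
validates the *metric machinery* (counts, alignment, cascades,
determinism), not annotation difficulty on real narratives.

`stratified_sample` reproduces stratified systematic sampling: partition by
harm level, one seeded shuffle per stratum, then every *k*-th report, so a
stratum of size *n* contributes ⌊n/k⌋ reports.

## Disagreement model and parameter recovery

Operators applied independently per annotation, mirroring the recurring
disagreement themes between trained annotators:

| operator | rate | theme |
| --- | --- | --- |
| span-boundary jitter (≥ 1 char overlap and the label always preserved) | `p_boundary` | span granularity |
| attribute omission | `p_attr_drop` | attribute assignment |
| relation retargeting to a schema-compatible entity | `p_rel_retarget` | relation scope |
| relabelling within confusability sets (dose ↔ strength, artefact ↔ knowledge, corrective ↔ preventive) | `p_relabel` | category confusion |
| deletion (entities and whole events; cascades, no dangling references) | `p_delete` | recall control |
| spurious-entity insertion over unannotated tokens | `p_insert` | precision control |

Insertions never overlap gold spans, so they are guaranteed false
positives; jitter never removes all overlap, so boundary-only noise yields
relaxed entity F1 of exactly 1.0 — a structural property the tests assert
on every seed. Jitter also never pulls a newline or tab into a span (the
serialized surface must stay single-line); the rare single-character span
that cannot move in any direction is left unchanged.

For deletion/insertion-only configurations `expected_scores` gives the
closed form: entity recall `1 − p_delete`, entity precision
`(1 − p_delete) / (1 − p_delete + p_insert)`, event recall `1 − p_delete`,
relation recall `(1 − p_delete)²` (both endpoints must survive), attribute
recall `(1 − p_delete)(1 − p_attr_drop)` (host survival composed with the
drop rate), all with precision 1 except entities. With span-editing
operators active no closed form is claimed and the function refuses. The
test suite and acceptance script recover these parameters by Monte Carlo at
≥ 2,000 gold annotations within ±0.02.

Relaxed-F1 ≥ strict-F1 holds as a theorem for entities and events (strict
admissible pairs are a subset of relaxed ones, denominators fixed). For
relations and attributes it is not a strict theorem — the relaxed entity
correspondence could in principle pair endpoints differently — but the
overlap-maximising secondary objective makes exact matches preferred, and
the property held without exception over every tested corpus (500 noisy
pairs per run, all layers).

## Numerical and design choices

* Word counts (corpus statistics) split on Unicode whitespace; hyphenated
  tokens are one word. Averages are printed both exact and rounded half-up,
  since published summary tables round. The "total words" column is the
  summed word count over annotations of a type — an interpretation recorded
  in the rendered output footer.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; CLI `perturb` derives one sub-seed per document (reduced
  mod 2³¹) so corpora of any size stay reproducible.
* Reports are timestamp-free; the run manifest (command, config hash,
  seeds, inputs, version, timestamp) is a sidecar file, so report artifacts
  are byte-identical across reruns.
* The canonical entity spellings follow the relation-table form ('Drug
  form', 'Drug dose', 'Drug frequency', 'Dose route', 'Dose duration',
  'Drug strength or amount'); other published variants ('Dosage form',
  'Frequency', 'Patient age', …) resolve through the alias table.
  'Gender' is one canonical type whose values (female/male/other) are
  report-level breakdowns, not separate types.
* An optional event-to-event 'Mismatch' link type exists behind
  `build_default_schema(enable_mismatch=True)`; it is off by default and
  outside the nine entity-relation types.
* The bundled demo document keeps the age-group mention unlinked: the
  registry's nine relation types carry no person–age relation, and the
  validator enforces the registry exactly.

## Known limitations

* Two annotators only; no chance-corrected coefficients (kappa) — span
  tasks are evaluated with P/R/F1 here, and generalising to > 2 annotators
  is out of scope for v1.
* No partial-credit (weighted) matching; scores are count-based.
* The synthetic narratives make no claim of clinical plausibility, and
  report-length fidelity between reporting systems is only qualitative.
* Scores computed by this package are comparable with other tools only if
  the pairing policy (optimal vs greedy) matches.
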