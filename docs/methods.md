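# Methods

## Model

`seqfca` audits one sub-hierarchy of a terminology at a time. The formal
context is K = (O, A, R) with O the concepts under the audited root, and
each object's sole attribute its **name sequence**: the preferred name,
tokenized and normalized. Intersecting two objects means computing the
longest common substring(s) of their sequences, token-wise; the multistage
procedure intersects all original pairs, then each newly added sequence
against the whole cumulated set, until a stage adds nothing. Every derived
sequence that is not an existing attribute is a candidate concept, named by
its own tokens.

Positioning relies on the sublist relation as a lexical proxy for
subsumption: Y supertype of X iff S_Y is a *proper* contiguous substring of
S_X (equality is handled by the existing-concept check). A candidate
without any supertype among the audited concepts is treated as
outside-the-hierarchy and dropped; so is a candidate whose sequence matches
any normalized preferred name or synonym anywhere in the full terminology
(classified as a same-branch synonym or an other-branch concept). Survivors
are reported with their most specific supertypes and most general subtypes.

## Assumptions and known limitations

* Detection is purely lexical. Subsumptions that share no tokens
  ("Carcinoma" IS-A "Neoplasm") are invisible; conversely a substring is
  not always a genuine supertype, which is why the qualification and
  existing-concept filters exist, and why validation is offered.
* No new vocabulary can be invented: a missing concept is only found if its
  words occur contiguously inside at least two existing names.
* Candidates are positioned against original concepts only; no order among
  candidates themselves is computed.
* Display names are the space-joined *normalized* tokens ("dendrite cell
  sarcoma", not "Dendritic Cell Sarcoma"); there is no inverse-normalization
  rule to recover inflected surface forms. For the same reason the
  literature search queries the normalized form only.

## Numerical and procedural choices

* **Tokenization** (unstated upstream, chosen here): lowercase; split on
  whitespace, hyphen and slash; strip surrounding punctuation; keep
  stopwords ("and" is part of "histiocytic and dendritic cell neoplasm").
* **Normalization**: two word-for-word table passes — inflectional
  normalization, then single-word synonym substitution, in that order.
  Tables are closed to idempotence at load; conflicting duplicate keys and
  substitution cycles are load-time errors. Length is never changed, so
  normalization commutes with the substring machinery.
* **LCS ties**: all distinct maximal-length common substrings are kept.
  Single-word candidates are kept at derivation and filtered by
  qualification, not by a length threshold.
* **Sublist boundary cases**: containment at the first or last position
  counts, and equality counts for the relation itself; supertype/subtype
  relations additionally require *proper* containment.
* **Subtype reduction** removes a collected subtype dominated by another
  through IS-A ancestry *or* sequence containment. Both orders are needed:
  hierarchy-only dominance occurs when a more specific concept's name is
  not a contiguous extension (e.g. an infix-modified name), containment-only
  dominance when the terminology lacks the intermediate IS-A edge.
* **Multistage bookkeeping**: later stages intersect only pairs touching
  the newest additions; this is output-equivalent to the naive all-pairs
  fixpoint (asserted against that oracle on random contexts) but cheaper.
  Provenance is merged across every pair that regenerates a candidate.
  `max_stages` defaults to 32; exhaustion flags the result non-closed via a
  warning rather than failing.
* **Phrase matching** (literature search) is case-insensitive with token
  boundaries, so "melanomas" does not match "melanoma"; a document is
  excluded when it contains any blocker phrase — a longer existing-concept
  or suggested-subtype name containing the query phrase. Phrases longer
  than the candidate but absent from the terminology cannot be blocked;
  that failure mode is reproduced deliberately.
* **IS-A path search** in the UMLS-like tables is breadth-first over
  child→parent edges pooled across sources, default depth bound 10,
  zero-length paths excluded.
* **Precision figures** are reported to two decimals, round-half-up,
  matching the convention of the published tables they mirror. The two
  evidence strata (terminology membership; UMLS semantic-type overlap) are
  computed independently and never pooled; candidates covered by neither
  are counted separately.

## Synthetic-data generator

The generator emulates the compositional-naming regime in which the method
is exact: names are modifier chains over head nouns, grown by prepending
one unused modifier to an existing name, so every suffix of a name is a
concept and IS-A coincides with sequence containment. Hiding then removes a
non-adjacent subset of internal concepts and rewires their children to
their parents, planting recoverable missing concepts with known positions.

Defaults — 3 heads, 6 modifiers, chains up to 3 modifiers, 40 concepts,
hide fraction 0.2, one global seed — produce desk-sized terminologies on
which the end-to-end pipeline runs in milliseconds; the recovery suites use
20 independent seeds. An *eligible* hidden concept (two surviving children
whose LCS is its name, plus a surviving qualification witness) is recovered
with its exact true position by construction, and with hiding disabled the
pipeline emits nothing; passing these suites therefore demonstrates
correctness of the machinery in the containment-faithful regime, **not**
performance on real terminologies, where names violate containment, carry
synonyms, and mix branches. The `noise` option plants containment-violating
concepts to probe that blind spot.

## Design choices that were genuinely open

* The FCA attribute is built from the preferred name only; synonyms are
  normalized and indexed solely for the existing-concept check. Letting
  synonyms participate in intersection would multiply attributes per object
  and is left as an extension.
* Qualification consults preferred-name sequences only (not synonyms of
  original concepts) when searching for supertypes.
* When the full terminology is not supplied, the existing-concept check
  degrades to matching within the audited sub-hierarchy.
* Multiple preferred names per concept id are not supported; one id, one
  attribute.
* The CLI `validate` subcommand re-runs detection from the same inputs
  rather than parsing the detection TSV back in; detection is
  byte-deterministic, so the two are equivalent.
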