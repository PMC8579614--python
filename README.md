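# seqfca

Sequence-based formal concept analysis for finding **potentially missing
concepts** in biomedical terminology hierarchies (NCI-Thesaurus- or
SNOMED-CT-style IS-A graphs), with automatic concept **naming**,
**positioning**, and extrinsic **validation**.

## The idea

Compound concept names in clinical terminologies are compositional:
*Follicular Dendritic Cell Sarcoma* and *Interdigitating Dendritic Cell
Sarcoma* both specialize a concept named by their shared words. `seqfca`
treats each audited concept as an FCA object whose single attribute is the
**sequence** of its normalized name tokens, S_X = [w_1, ..., w_n]. The
intersection of two objects is the **longest common substring(s)** of their
sequences — the longest contiguous token run occurring in both — so every
derived formal concept arrives with a ready-to-use name. Pairwise
intersection is repeated over the cumulated set until closure (multistage
FCA).

A derived sequence X is then positioned through the **sublist relation**
(S_Y a proper contiguous substring of S_X means Y is a supertype of X):

* X is *qualified* only if some existing concept's sequence is a proper
  substring of S_X; without a supertype X almost always names knowledge from
  another branch ("outside the given hierarchy") and is discarded;
* candidates whose sequence matches any existing preferred name or synonym
  are discarded;
* survivors are reported with their most specific supertypes and most
  general subtypes (dominated subtypes removed via IS-A ancestry *and*
  sequence containment).

Findings can be validated against UMLS-style tables (term lookup by CUI,
directed IS-A paths between mapped CUIs, semantic-type overlap) and a
title/abstract corpus with a more-specific-phrase exclusion rule.

## Worked example

The packaged 7-concept neoplasm slice (`seqfca fixtures` writes it as TSV):

```sh
seqfca fixtures --out fx
seqfca detect --concepts fx/fig1/concepts.tsv --hierarchy fx/fig1/hierarchy.tsv \
    --norm-table fx/fig1/norm_table.tsv --root C3262 --out run
```

prints

```
existing_concepts	7
newly_formalized	2
qualified	1
unqualified	1
existing_removed	0
potentially_missing	1
```

Two sequences are derived: `dendrite cell` (from *Histiocytic and Dendritic
Cell Neoplasm* × the sarcomas) has no supertype in the branch and is
rejected, while `dendrite cell sarcoma` survives. `run/missing_concepts.tsv`
contains the single record

```
display_name	sequence	supertypes	subtypes	provenance	stage
dendrite cell sarcoma	dendrite cell sarcoma	C9118	C9281;C9282	...	1
```

i.e. *Dendritic Cell Sarcoma*, to be inserted under *Sarcoma* (C9118) as the
parent of *Follicular* (C9281) and *Interdigitating Dendritic Cell Sarcoma*
(C9282) — the two more specific subtypes (C150704, C156408) are reduced
away. `seqfca validate` adds UMLS/corpus evidence, `seqfca evaluate` emits
per-stratum confusion counts with precision with/without the positioning
filter, and `seqfca simulate` generates synthetic terminologies with planted
(hidden) concepts and ground-truth positions.

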