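# Methods

## The resolution model

A phylogenetic definition anchors a clade name to specifier species on a
rooted tree. `cladedef` evaluates a definition on a tree in four stages.

**Specifier matching.** Specifiers are matched to tips by normalized
binomial: quotes stripped, underscores mapped to spaces, whitespace
collapsed; the genus token compares case-sensitively, the epithet
case-insensitively. An alias map (alternate tip label → accepted name) is
consulted next — the packaged map carries the one equivalence the corpus
itself states, *Othnielosaurus consors* = *Nanosaurus agilis*. A bare-genus
fallback (specifier *Pinacosaurus grangeri* matching a tip labeled
`Pinacosaurus`) exists because reference phylogenies often score
genus-level OTUs, but it is **off by default**: silent genus matching can
misresolve, and definitions use species-level specifiers deliberately. An
exact match always wins over the fallback; an ambiguous match is an error,
never a guess. An unmatched **internal** specifier makes the name
*unresolvable* (`MISSING_INTERNAL`) — the tree simply cannot witness the
definition. Unmatched **external** or qualifying specifiers are vacuously
satisfied with a logged warning; this mirrors standard practice, where a
name is resolved on a reference tree lacking some external specifier whose
position is known from other studies.

**Core clade selection.** Minimum-clade: the extent of the MRCA of the
internal specifiers. Maximum-clade: the clades containing all internals
form a nested chain from that MRCA to the root, and "excludes the
externals" is monotone along it (tip sets only grow rootward), so a
rootward walk finds the unique largest admissible clade. If even the MRCA
contains an external, no clade qualifies and the name is *inapplicable*
(`EXTERNAL_INSIDE_MINIMAL`) — reported as inapplicability, not as an empty
clade, matching how such cases are described for names like
*Aralosaurini* and *Shamosaurinae*.

**Exclusion semantics.** By default every listed external specifier (and
every qualifying-clause taxon, however the list is joined) must be absent
from the clade. The corpus's long-form prose is uniformly explicit here
("…but not X, Y, and Z", "provided that it does not include X, Y, or Z"),
and every published Composition is consistent with the exclude-all
reading. The governing code's distinction between `&` and `∨` among
external specifiers is cited but not restated in the source material, so
the parser records the connective faithfully while the resolver decides
semantics; the alternative at-least-one reading is exposed as
`exclusion_mode="any"` (along the same chain the predicate "lacks at least
one external" is also monotone) but is never the default.

**Qualifying clauses and contexts void, they do not re-select.** A
"provided that it does not include X" clause whose taxon lands inside the
selected clade makes the name inapplicable (`QUALIFIER_VIOLATED`) rather
than re-anchoring the definition to some smaller or larger clade. The
corpus depends on this: *Saurolophinae*'s definition is explicitly meant
to *become inapplicable* when *Hadrosaurus foulkii* falls within the
*Saurolophus* branch — re-selecting the largest sub-branch free of
*H. foulkii* would defeat the purpose of the clause. The same voiding
logic governs `∈`/`∉` context restrictions: the core clade is computed
from the internal/external specifiers alone and then tested against the
contexts. "Within" means subclade-or-equal of at least one (`∨`) or every
(`&`) referenced clade — equality is allowed so that a name like
*Clypeodonta* stays applicable when it coincides with *Ornithopoda*;
"outside" means subclade of none, regardless of connective, which is the
natural reading of "outside A or B". Context references are resolved
recursively against the corpus with per-tree memoization; a referenced
name that fails yields `CONTEXT_UNRESOLVED` (unresolvable, since the
constraint cannot be evaluated), and mutual references yield
`DEPENDENCY_CYCLE`. The packaged corpus's context graph is a DAG
(*Orodrominae* → *Thescelosauridae*, etc.), so cycles only arise in user
corpora.

Inapplicable (`EXTERNAL_INSIDE_MINIMAL`, `QUALIFIER_VIOLATED`,
`CONTEXT_VIOLATED`) means the topology violates the definition's
conditions; unresolvable (`MISSING_INTERNAL`, `CONTEXT_UNRESOLVED`,
`DEPENDENCY_CYCLE`) means the question could not be evaluated on this
input. The distinction is load-bearing for the exit-code contract and for
synonymy detection, which only considers resolved names.

**Synonymy.** On one tree, resolved names are grouped by extent; every
unordered pair within a group is a heterodefinitional synonym pair.
Pairs are annotated with years parsed best-effort from authorship strings
(last four-digit token; absent when none). Priority between synonyms is a
nomenclatural-code judgment and is deliberately not adjudicated. The
packaged corpus currently carries empty authorship strings — the
transcription keeps registration numbers, statuses, kinds, specifiers and
contexts, but author-year citation text was not carried over — so year
annotations there are absent by design; toy corpora with authorship text
exercise the extraction.

## The notation and parser

The abbreviated grammar (whitespace-insensitive between tokens):

```
definition := kind "∇" [context] "(" internals [" ~ " externals] [" | ~ " qualifiers] ")"
kind       := "max" | "min"
context    := ("∈" | "∉") clade_ref (("&" | "∨") clade_ref)*
internals  := taxon ("&" taxon)*
externals  := taxon (("&" | "∨") taxon)*     # connective uniform per list
qualifiers := taxon (("&" | "∨") taxon)*
```

Connectives must be uniform within one list; internal specifiers are
always conjunctive. Taxon names are `Genus epithet` pairs (a capitalized
token followed by a lowercase token); a single capitalized token is a
supraspecific clade-name reference, which is all a context may contain.
Context references stay symbolic at parse time — no corpus lookup — so
definitions parse in isolation. Any trailing material after a name up to
the next structural token (bracketed citation keys, parenthesized
author-year citations, loose words like "Owen in") is captured verbatim
into the name's `authority` and never participates in identity; markdown
emphasis markers are discarded. The ASCII alias words (`and`, `or`,
`not`, `provided-not`, `in`, `not-in`, `max-clade`, `min-clade`) are
reserved: they cannot appear as authority text except that `in`/`not-in`
are demoted to plain words outside context position (required for
authorities of the "Owen in …" form). Serialization emits a canonical
single-spaced Unicode form, omitting authorities unless asked; parse ∘
serialize is the identity on parsed structure, a property the test suite
checks over the whole corpus and over randomized definitions.

The parser is a small hand-written tokenizer plus recursive descent with
character positions in every syntax error; the grammar is tiny and
notation-specific, and owning it keeps the authority-capture rules exact.

## The corpus transcription

The 81 entries were transcribed from the published definition table, with
the long-form definition paragraphs as the authority wherever an
abbreviation could be misread; registration numbers come from the
per-name entries. The five new names (*Corythosauria*, *Euceratopsia*,
*Panoplosaurini*, *Saphornithischia*, *Struthiosaurini*) are flagged
`new`, the rest `converted`. On load, every entry's abbreviated string is
re-parsed and must reproduce the structured fields exactly — a
transcription-drift tripwire — and registration-number uniqueness plus all
structural invariants are enforced. A JSON Schema
(`data/corpus.schema.json`) documents the format for user corpora;
validation is performed by the loader's explicit checks.

## Scenario trees

Each packaged scenario is a minimal toy topology (6–16 tips) encoding a
placement hypothesis described verbally in the systematics literature,
with the expectation list stating which names must resolve (and to what
extent), or fail (and why). They are deliberately *not* tracings of
published figures — figure topologies are not reliably recoverable — so
each tree contains only the taxa needed to pin the behavior: the
alternative *Hadrosaurus* placements, the heterodontosaurid-within-
Pachycephalosauria arrangement (where the core four-taxon clade must
still resolve), the two ceratopsian arrangements that create or dissolve
the *Euceratopsia*/*Coronosauria* synonymy, separations of the
*Aralosaurini*/*Tsintaosaurini* internal-specifier pairs, *Hypsilophodon*
outside *Ornithopoda* (engaging the `∈` restrictions), and *Jeholosaurus*
inside *Thescelosauridae* (engaging the `∉` restriction). Where a needed
specifier is absent from the hypothesis as published, it is grafted at a
point consistent with the accompanying discussion; the exact attachment
within the stated clade is an arbitrary but documented choice, and the
expectations never depend on it.

## Random trees and the oracle experiment

`random_tree(n_tips, seed, polytomy_prob)` builds a rooted tree by
uniform recursive splitting: each block of tips is shuffled and cut into
two parts (three with probability `polytomy_prob` when the block allows),
recursively. It is deterministic in its arguments; node counts lie in
[n+1, 2n−1]. `random_definition` draws 1–3 internal, 0–3 external and 0–2
qualifying specifiers from the tip set, substituting an absent label with
probability 0.15 per pick to exercise the unresolvable and
vacuous-exclusion paths. The oracle experiment resolves each random
definition twice — by the rootward-walk resolver and by exhaustive clade
enumeration (`brute_force_resolve`, guarded to ≤64 tips) — and demands
identical status, reason code and extent. The shipped experiment uses
1,000 trees of 4–20 tips with polytomy probability 0.3, sizes at which
enumeration is exact and the whole run takes under a second; the
equivalence argument (chain structure plus monotone predicates) is
size-independent, so the small trees are not a limitation of the claim,
only of the certificate.

What these synthetic inputs do not emulate: real reference phylogenies'
taxon sampling, branch lengths (ignored by design), reticulation
(out of scope), or label noise beyond the normalization rules. Passing
tests therefore certify the resolution semantics, not the biological
correctness of any particular published topology.

## Numerical and design choices

- Trees are used exactly as rooted; no rerooting. Unary nodes are
  collapsed on read (they would duplicate extents); zero-length branches
  are retained; branch lengths never affect resolution.
- Resolution is fully deterministic: corpus order is preserved in batch
  output, set operations are over frozen label sets, and no randomness
  exists outside the explicitly seeded generators.
- The qualifying clause is checked before the context constraint, so a
  doubly failing name reports `QUALIFIER_VIOLATED`.
- Duplicate tip labels (after normalization) are rejected at read time;
  resolution never guesses among homonymous tips.
- CLI exit codes: 0 = every selected name resolved; 3 = ran correctly but
  some name was inapplicable/unresolvable; 1 = input or parse error. This
  lets pipelines distinguish a nomenclatural finding from a failure.

## Known limitations

- Apomorphy-based and specimen-anchored definitions are out of scope; the
  corpus uses none.
- Priority between heterodefinitional synonyms is annotated (years) but
  never ruled on.
- The ASCII alias words are reserved tokens, so an authority string
  containing a bare `and`/`or` would terminate authority capture early;
  no corpus entry does this.
- The packaged corpus omits authority citation text (empty `authorship`),
  so synonym-year annotation is only informative for user corpora that
  supply it.
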