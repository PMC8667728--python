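"""Semantics of clade definitions on a rooted tree.

Given a phylogeny and a corpus of definitions, each name either
*resolves* to a clade extent, is *inapplicable* (the topology violates
the definition's conditions), or is *unresolvable* (required specifiers
or referenced contexts are unavailable).  The pipeline per name:

1. match specifiers to tips — an unmatched internal specifier makes the
   name unresolvable (``MISSING_INTERNAL``); unmatched externals and
   qualifying taxa are vacuously satisfied with a warning, mirroring how
   reference phylogenies routinely omit some specifiers;
2. resolve the core clade — minimum-clade: the MRCA of the internals;
   maximum-clade: walk rootward from that MRCA while the candidate still
   excludes the externals (``EXTERNAL_INSIDE_MINIMAL`` when even the MRCA
   fails);
3. apply the qualifying clause — "provided that it does not include X"
   voids the name (``QUALIFIER_VIOLATED``) rather than re-anchoring it;
4. check the context constraint — ``∈`` requires the candidate to be a
   subclade (or equal) of at least one / every referenced clade depending
   on the connective; ``∉`` requires it to be a subclade of none.
   Referenced names are themselves resolved recursively with memoization;
   cycles yield ``DEPENDENCY_CYCLE``.

Exclusion semantics: by default every listed external specifier must be
absent from the clade, whichever connective joins the list — the corpus
prose ("does not include X, Y, or Z") is uniformly consistent with this
reading.  The alternative at-least-one reading is available as
``exclusion_mode="any"`` but is never the default.

:func:`brute_force_resolve` re-derives the same contract by exhaustive
clade enumeration and is the oracle the test suite holds the fast path
to.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy

from .definitions import (
    CladeDefinition,
    Connective,
    ContextConstraint,
    DefinitionKind,
    Polarity,
    TaxonName,
)
from .trees import (
    CladeExtent,
    Phylogeny,
    enumerate_clades,
    extent,
    match_specifier,
    mrca,
)

__all__ = [
    "ReasonCode",
    "ResolveOptions",
    "ResolutionResult",
    "SynonymyPair",
    "SynonymyReport",
    "UnknownNameError",
    "resolve_minimum",
    "resolve_maximum",
    "apply_qualifying",
    "check_context",
    "resolve_definition",
    "resolve_name",
    "resolve_all",
    "detect_synonyms",
    "brute_force_resolve",
    "results_to_records",
    "results_to_json",
    "results_to_tsv",
    "synonymy_to_json",
]


class ReasonCode(str, Enum):
    MISSING_INTERNAL = "MISSING_INTERNAL"
    EXTERNAL_INSIDE_MINIMAL = "EXTERNAL_INSIDE_MINIMAL"
    QUALIFIER_VIOLATED = "QUALIFIER_VIOLATED"
    CONTEXT_VIOLATED = "CONTEXT_VIOLATED"
    CONTEXT_UNRESOLVED = "CONTEXT_UNRESOLVED"
    DEPENDENCY_CYCLE = "DEPENDENCY_CYCLE"


# reasons that mean "conditions unmet on this topology" vs "cannot evaluate"
_INAPPLICABLE = {
    ReasonCode.EXTERNAL_INSIDE_MINIMAL,
    ReasonCode.QUALIFIER_VIOLATED,
    ReasonCode.CONTEXT_VIOLATED,
}


class UnknownNameError(KeyError):
    pass


@dataclass(frozen=True)
class ResolveOptions:
    """Per-run knobs for resolution."""

    exclusion_mode: str = "all"  # "all" | "any"
    aliases: Optional[Mapping[str, str]] = None
    genus_fallback: bool = False

    def __post_init__(self):
        if self.exclusion_mode not in ("all", "any"):
            raise ValueError(f"exclusion_mode must be 'all' or 'any', got {self.exclusion_mode!r}")


@dataclass
class ResolutionResult:
    clade_name: str
    status: str  # "resolved" | "inapplicable" | "unresolvable"
    extent: Optional[CladeExtent] = None
    reason_code: Optional[ReasonCode] = None
    reason: Optional[str] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        return self.status == "resolved"


def _failure(name: str, code: ReasonCode, message: str, warnings: list[str]) -> ResolutionResult:
    status = "inapplicable" if code in _INAPPLICABLE else "unresolvable"
    return ResolutionResult(
        clade_name=name,
        status=status,
        reason_code=code,
        reason=f"{code.value}: {message}",
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# core clade selection

def resolve_minimum(p: Phylogeny, internal_tips: Sequence[dendropy.Node]) -> CladeExtent:
    """Smallest clade containing every internal tip: the MRCA's extent."""
    labels = [next(iter(p.tips_under(t))) for t in internal_tips]
    return extent(p, mrca(p, labels))


def resolve_maximum(
    p: Phylogeny,
    internal_tips: Sequence[dendropy.Node],
    external_tips: Sequence[dendropy.Node],
    exclusion_mode: str = "all",
) -> Optional[CladeExtent]:
    """Largest clade containing the internals while excluding externals.

    Candidates containing all internals form a nested chain from the
    internals' MRCA up to the root, and the exclusion predicate is
    monotone along it, so a rootward walk finds the unique maximum.
    Returns ``None`` when even the MRCA fails the predicate
    (``EXTERNAL_INSIDE_MINIMAL``).  Under ``exclusion_mode="any"`` a
    candidate only needs to lack at least one external; with no matched
    externals either predicate is vacuously satisfied.
    """
    external_sets = [p.tips_under(t) for t in external_tips]

    def admissible(tips: frozenset[str]) -> bool:
        if not external_sets:
            return True
        if exclusion_mode == "all":
            return all(not (ext & tips) for ext in external_sets)
        return any(not (ext & tips) for ext in external_sets)

    labels = [next(iter(p.tips_under(t))) for t in internal_tips]
    node = mrca(p, labels)
    if not admissible(p.tips_under(node)):
        return None
    while True:
        parent = p.parent(node)
        if parent is None or not admissible(p.tips_under(parent)):
            return extent(p, node)
        node = parent


def apply_qualifying(
    p: Phylogeny,
    candidate: CladeExtent,
    excluded_tips: Sequence[dendropy.Node],
) -> bool:
    """True iff the candidate contains none of the qualifying taxa.

    The clause never shrinks or re-selects the clade — a violation voids
    the name on this topology.
    """
    return all(not (p.tips_under(t) & candidate.tips) for t in excluded_tips)


ContextEntry = Union[CladeExtent, "ResolutionResult", None]


def check_context(
    p: Phylogeny,
    candidate: CladeExtent,
    constraint: ContextConstraint,
    context_extents: Mapping[str, ContextEntry],
) -> Optional[ReasonCode]:
    """Evaluate a ``∈``/``∉`` constraint; ``None`` means satisfied.

    ``context_extents`` maps each referenced clade name to its resolved
    extent, or to a failed :class:`ResolutionResult` / ``None`` when it
    could not be resolved on this tree.  "Within" means subclade-or-equal
    of at least one (``∨``) or every (``&``) referenced clade; "outside"
    means subclade of none, regardless of connective.
    """
    extents: list[CladeExtent] = []
    for ref in constraint.contexts:
        if ref.binomial not in context_extents:
            raise KeyError(f"no context entry for {ref.binomial!r}")
        entry = context_extents[ref.binomial]
        if isinstance(entry, CladeExtent):
            extents.append(entry)
        elif isinstance(entry, ResolutionResult) and entry.resolved:
            extents.append(entry.extent)
        elif (
            isinstance(entry, ResolutionResult)
            and entry.reason_code is ReasonCode.DEPENDENCY_CYCLE
        ):
            return ReasonCode.DEPENDENCY_CYCLE
        else:
            return ReasonCode.CONTEXT_UNRESOLVED
    inside = [candidate.tips <= e.tips for e in extents]
    if constraint.polarity is Polarity.WITHIN:
        ok = all(inside) if constraint.connective is Connective.AND else any(inside)
    else:  # OUTSIDE: subclade of none of the listed contexts
        ok = not any(inside)
    return None if ok else ReasonCode.CONTEXT_VIOLATED


# ---------------------------------------------------------------------------
# specifier matching shared by both resolution routes

def _match_lists(p, d, options):
    """Returns (internal_tips, external_tips, qualifier_tips, warnings,
    missing_internal_or_None)."""
    warnings: list[str] = []
    internal_tips = []
    for s in d.internal:
        node = match_specifier(p, s, options.aliases, genus_fallback=options.genus_fallback)
        if node is None:
            return None, None, None, warnings, s
        internal_tips.append(node)
    external_tips, qualifier_tips = [], []
    for role, source, sink in (
        ("external", d.external, external_tips),
        ("qualifying", d.qualifying_excluded, qualifier_tips),
    ):
        for s in source:
            node = match_specifier(p, s, options.aliases, genus_fallback=options.genus_fallback)
            if node is None:
                warnings.append(
                    f"{role} specifier {s.binomial!r} not found on tree; "
                    "exclusion vacuously satisfied"
                )
            else:
                sink.append(node)
    return internal_tips, external_tips, qualifier_tips, warnings, None


# ---------------------------------------------------------------------------
# per-definition resolution (contexts precomputed)

def resolve_definition(
    p: Phylogeny,
    d: CladeDefinition,
    options: Optional[ResolveOptions] = None,
    context_extents: Optional[Mapping[str, ContextEntry]] = None,
) -> ResolutionResult:
    """Apply one definition to a tree, with context extents supplied.

    This is the core :func:`resolve_name` delegates to after resolving the
    definition's context references against the corpus.
    """
    options = options or ResolveOptions()
    name = d.clade_name or "<anonymous>"
    internal_tips, external_tips, qualifier_tips, warnings, missing = _match_lists(p, d, options)
    if missing is not None:
        return _failure(
            name,
            ReasonCode.MISSING_INTERNAL,
            f"internal specifier {missing.binomial!r} not found on tree",
            warnings,
        )
    if d.kind is DefinitionKind.MINIMUM:
        candidate = resolve_minimum(p, internal_tips)
    else:
        candidate = resolve_maximum(p, internal_tips, external_tips, options.exclusion_mode)
        if candidate is None:
            return _failure(
                name,
                ReasonCode.EXTERNAL_INSIDE_MINIMAL,
                "an external specifier falls inside the internals' minimal clade",
                warnings,
            )
    if not apply_qualifying(p, candidate, qualifier_tips):
        return _failure(
            name,
            ReasonCode.QUALIFIER_VIOLATED,
            "the clade includes a taxon its qualifying clause excludes",
            warnings,
        )
    if d.context is not None:
        code = check_context(p, candidate, d.context, context_extents or {})
        if code is not None:
            return _failure(name, code, "context constraint not satisfied", warnings)
    return ResolutionResult(clade_name=name, status="resolved", extent=candidate, warnings=warnings)


# ---------------------------------------------------------------------------
# corpus-aware resolution

def _corpus_index(corpus: Iterable[CladeDefinition]) -> dict[str, CladeDefinition]:
    return {d.clade_name: d for d in corpus}


def resolve_name(
    p: Phylogeny,
    corpus: Sequence[CladeDefinition],
    name: str,
    options: Optional[ResolveOptions] = None,
    *,
    _memo: Optional[dict[str, ResolutionResult]] = None,
    _stack: Optional[set[str]] = None,
) -> ResolutionResult:
    """Resolve one named definition, recursively resolving any contexts.

    Context references are looked up in the corpus and resolved with
    memoization shared across one call tree; mutually referencing
    definitions are reported as ``DEPENDENCY_CYCLE``.
    """
    index = _corpus_index(corpus)
    if name not in index:
        raise UnknownNameError(name)
    memo = {} if _memo is None else _memo
    stack = set() if _stack is None else _stack
    if name in memo:
        return memo[name]
    if name in stack:
        return _failure(
            name, ReasonCode.DEPENDENCY_CYCLE, "definition participates in a context cycle", []
        )
    d = index[name]
    context_extents: dict[str, ContextEntry] = {}
    if d.context is not None:
        stack.add(name)
        try:
            for ref in d.context.contexts:
                if ref.binomial not in index:
                    context_extents[ref.binomial] = None
                else:
                    context_extents[ref.binomial] = resolve_name(
                        p, corpus, ref.binomial, options, _memo=memo, _stack=stack
                    )
        finally:
            stack.discard(name)
    result = resolve_definition(p, d, options, context_extents)
    memo[name] = result
    return result


def resolve_all(
    p: Phylogeny,
    corpus: Sequence[CladeDefinition],
    options: Optional[ResolveOptions] = None,
    names: Optional[Sequence[str]] = None,
) -> dict[str, ResolutionResult]:
    """Resolve every (or each selected) corpus name on one tree.

    Results come back in corpus order; context resolution is memoized
    across the whole batch, and nothing here is order-dependent.
    """
    memo: dict[str, ResolutionResult] = {}
    wanted = None if names is None else set(names)
    out: dict[str, ResolutionResult] = {}
    for d in corpus:
        if wanted is not None and d.clade_name not in wanted:
            continue
        out[d.clade_name] = resolve_name(p, corpus, d.clade_name, options, _memo=memo)
    if wanted is not None:
        unknown = wanted - {d.clade_name for d in corpus}
        if unknown:
            raise UnknownNameError(sorted(unknown))
    return out


# ---------------------------------------------------------------------------
# synonymy

@dataclass(frozen=True)
class SynonymyPair:
    name_a: str
    name_b: str
    tips: frozenset[str]
    year_a: Optional[int]
    year_b: Optional[int]


@dataclass
class SynonymyReport:
    pairs: list[SynonymyPair]


_YEAR = re.compile(r"\b(\d{4})\b")


def _year_of(authorship: str) -> Optional[int]:
    matches = _YEAR.findall(authorship or "")
    return int(matches[-1]) if matches else None


def detect_synonyms(
    results: Mapping[str, ResolutionResult],
    corpus: Sequence[CladeDefinition],
) -> SynonymyReport:
    """Heterodefinitional synonyms on one tree: distinct resolved names
    whose extents are identical.

    Pairs are annotated with best-effort publication years parsed from the
    corpus authorship strings; priority between synonyms is a
    nomenclatural judgment and is deliberately not adjudicated here.
    """
    years = {d.clade_name: _year_of(d.authorship) for d in corpus}
    by_extent: dict[frozenset[str], list[str]] = {}
    for name, result in results.items():
        if result.resolved:
            by_extent.setdefault(result.extent.tips, []).append(name)
    pairs: list[SynonymyPair] = []
    for tips, names in by_extent.items():
        names = sorted(names)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                pairs.append(SynonymyPair(a, b, tips, years.get(a), years.get(b)))
    pairs.sort(key=lambda pr: (pr.name_a, pr.name_b))
    return SynonymyReport(pairs=pairs)


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_resolve(
    p: Phylogeny,
    d: CladeDefinition,
    options: Optional[ResolveOptions] = None,
    context_extents: Optional[Mapping[str, ContextEntry]] = None,
) -> ResolutionResult:
    """Resolve by exhaustive clade enumeration (trees of ≤64 tips).

    Every clade on the tree is enumerated; the minimum-kind answer is the
    smallest clade containing all internals, the maximum-kind answer the
    largest survivor of the internal/external filters.  The qualifying
    clause and context constraint are then checked on that unique
    candidate — they void rather than re-select, matching the corpus's
    applicability language.  Same result contract as
    :func:`resolve_definition`.
    """
    if p.n_tips > 64:
        raise ValueError(f"brute-force oracle limited to 64 tips (got {p.n_tips})")
    options = options or ResolveOptions()
    name = d.clade_name or "<anonymous>"
    internal_tips, external_tips, qualifier_tips, warnings, missing = _match_lists(p, d, options)
    if missing is not None:
        return _failure(
            name,
            ReasonCode.MISSING_INTERNAL,
            f"internal specifier {missing.binomial!r} not found on tree",
            warnings,
        )
    internal_labels = set().union(*[p.tips_under(t) for t in internal_tips])
    external_sets = [p.tips_under(t) for t in external_tips]
    clades = enumerate_clades(p)
    containing = [c for c in clades if internal_labels <= c.tips]
    if d.kind is DefinitionKind.MINIMUM:
        candidate = min(containing, key=len)
    else:
        if options.exclusion_mode == "all":
            ok = [c for c in containing if all(not (e & c.tips) for e in external_sets)]
        else:
            ok = [
                c
                for c in containing
                if not external_sets or any(not (e & c.tips) for e in external_sets)
            ]
        if not ok:
            return _failure(
                name,
                ReasonCode.EXTERNAL_INSIDE_MINIMAL,
                "an external specifier falls inside the internals' minimal clade",
                warnings,
            )
        candidate = max(ok, key=len)
    if any(p.tips_under(t) & candidate.tips for t in qualifier_tips):
        return _failure(
            name,
            ReasonCode.QUALIFIER_VIOLATED,
            "the clade includes a taxon its qualifying clause excludes",
            warnings,
        )
    if d.context is not None:
        ctx = context_extents or {}
        extents = []
        failure_code = None
        for ref in d.context.contexts:
            entry = ctx.get(ref.binomial)
            if isinstance(entry, CladeExtent):
                extents.append(entry)
            elif isinstance(entry, ResolutionResult) and entry.resolved:
                extents.append(entry.extent)
            elif (
                isinstance(entry, ResolutionResult)
                and entry.reason_code is ReasonCode.DEPENDENCY_CYCLE
            ):
                failure_code = ReasonCode.DEPENDENCY_CYCLE
                break
            else:
                failure_code = ReasonCode.CONTEXT_UNRESOLVED
                break
        if failure_code is None:
            inside = [candidate.tips <= e.tips for e in extents]
            if d.context.polarity is Polarity.WITHIN:
                ok_ctx = (
                    all(inside)
                    if d.context.connective is Connective.AND
                    else any(inside)
                )
            else:
                ok_ctx = not any(inside)
            if not ok_ctx:
                failure_code = ReasonCode.CONTEXT_VIOLATED
        if failure_code is not None:
            return _failure(name, failure_code, "context constraint not satisfied", warnings)
    return ResolutionResult(clade_name=name, status="resolved", extent=candidate, warnings=warnings)


# ---------------------------------------------------------------------------
# export

def results_to_records(
    results: Mapping[str, ResolutionResult],
    corpus: Optional[Sequence[CladeDefinition]] = None,
) -> list[dict]:
    kinds = {d.clade_name: d.kind.value for d in (corpus or [])}
    records = []
    for name, r in results.items():
        records.append(
            {
                "name": name,
                "kind": kinds.get(name, ""),
                "status": r.status,
                "reason": r.reason_code.value if r.reason_code else "",
                "n_tips": len(r.extent) if r.resolved else 0,
                "extent": r.extent.sorted_tips() if r.resolved else [],
                "warnings": list(r.warnings),
            }
        )
    return records


def results_to_json(results, corpus=None) -> str:
    return json.dumps(results_to_records(results, corpus), indent=2, ensure_ascii=False) + "\n"


_TSV_COLUMNS = ("name", "kind", "status", "reason", "n_tips", "extent")


def results_to_tsv(results, corpus=None) -> str:
    lines = ["\t".join(_TSV_COLUMNS)]
    for rec in results_to_records(results, corpus):
        lines.append(
            "\t".join(
                [
                    rec["name"],
                    rec["kind"],
                    rec["status"],
                    rec["reason"],
                    str(rec["n_tips"]),
                    ";".join(rec["extent"]),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def synonymy_to_json(report: SynonymyReport) -> str:
    records = [
        {
            "name_a": pr.name_a,
            "name_b": pr.name_b,
            "extent": sorted(pr.tips),
            "year_a": pr.year_a,
            "year_b": pr.year_b,
        }
        for pr in report.pairs
    ]
    return json.dumps(records, indent=2, ensure_ascii=False) + "\n"
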