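"""Rooted-tree substrate for definition resolution.

A :class:`Phylogeny` wraps a dendropy tree read from Newick, enforcing the
invariants resolution relies on: a single root, unique tip labels after
normalization, no unary internal nodes (collapsed on read), polytomies
allowed anywhere.  Trees are treated as rooted exactly as written — a
"largest clade" is only meaningful relative to a root, so no rerooting is
ever performed.  Branch lengths are carried through I/O but play no role.

Node handles exposed by this module are dendropy ``Node`` objects; clade
extents are frozen sets of normalized tip labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import dendropy

from .definitions import TaxonName, normalize_binomial, normalize_label

__all__ = [
    "Phylogeny",
    "CladeExtent",
    "NewickParseError",
    "DuplicateTipError",
    "MissingLabelError",
    "AmbiguousSpecifierError",
    "read_newick",
    "write_newick",
    "mrca",
    "extent",
    "enumerate_clades",
    "match_specifier",
]


class NewickParseError(ValueError):
    pass


class DuplicateTipError(ValueError):
    def __init__(self, offenders: list[str]):
        self.offenders = offenders
        super().__init__(f"duplicate tip labels after normalization: {offenders}")


class MissingLabelError(KeyError):
    def __init__(self, absentees: list[str]):
        self.absentees = absentees
        super().__init__(f"labels not present in tree: {absentees}")


class AmbiguousSpecifierError(ValueError):
    def __init__(self, specifier: str, candidates: list[str]):
        self.specifier = specifier
        self.candidates = candidates
        super().__init__(
            f"specifier {specifier!r} matches multiple tips: {sorted(candidates)}"
        )


@dataclass(frozen=True)
class CladeExtent:
    """A node handle plus exactly its descendant-tip label set."""

    node: dendropy.Node
    tips: frozenset[str]

    def __len__(self) -> int:
        return len(self.tips)

    def sorted_tips(self) -> list[str]:
        return sorted(self.tips)


class Phylogeny:
    """Rooted tree with uniquely labeled tips; the substrate for resolution."""

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = True
        dtree.suppress_unifurcations()
        self._tree = dtree
        self._tips: dict[str, dendropy.Node] = {}
        offenders = []
        for leaf in dtree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else (leaf.label or "")
            norm = normalize_binomial(label)
            if not norm:
                raise NewickParseError("unlabeled tip in tree")
            if norm in self._tips:
                offenders.append(norm)
            self._tips[norm] = leaf
        if offenders:
            raise DuplicateTipError(sorted(set(offenders)))
        # cache descendant-tip sets (postorder, each node once)
        self._extent: dict[int, frozenset[str]] = {}
        for node in dtree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else node.label
                self._extent[id(node)] = frozenset([normalize_binomial(label)])
            else:
                tips: set[str] = set()
                for child in node.child_nodes():
                    tips |= self._extent[id(child)]
                self._extent[id(node)] = frozenset(tips)

    # -- introspection ------------------------------------------------------
    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def tip(self, label: str) -> Optional[dendropy.Node]:
        return self._tips.get(normalize_binomial(label))

    def nodes(self) -> Iterable[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def parent(self, node: dendropy.Node) -> Optional[dendropy.Node]:
        return node.parent_node

    def tips_under(self, node: dendropy.Node) -> frozenset[str]:
        try:
            return self._extent[id(node)]
        except KeyError:
            raise ValueError("node does not belong to this phylogeny") from None

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Quoted labels, branch lengths, internal labels and square-bracket
    comments are accepted.  Labels are normalized (quotes stripped,
    underscores mapped to spaces, whitespace collapsed); tips whose
    normalized labels collide raise :class:`DuplicateTipError`.
    """
    if not text or not text.strip():
        raise NewickParseError("empty tree")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    if dtree.seed_node is None or not any(dtree.leaf_node_iter()):
        raise NewickParseError("empty tree")
    return Phylogeny(dtree)


def write_newick(p: Phylogeny) -> str:
    """Serialize back to Newick; labels containing spaces are quoted.

    ``read_newick(write_newick(p))`` reproduces the same rooted
    tip-partition structure (clade-extent multiset) as ``p``.
    """
    out = p.dendropy_tree.as_string(
        schema="newick",
        preserve_spaces=True,
        suppress_rooting=True,
        suppress_leaf_node_labels=False,
    )
    return out.strip() + "\n"


def mrca(p: Phylogeny, labels: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor: the deepest node whose extent covers
    ``labels``.  A single label returns the tip itself."""
    wanted = [normalize_binomial(l) for l in labels]
    if not wanted:
        raise ValueError("mrca requires at least one label")
    absent = [l for l in wanted if l not in p.tip_labels]
    if absent:
        raise MissingLabelError(sorted(absent))
    target = frozenset(wanted)
    node = p.tip(wanted[0])
    while not target <= p.tips_under(node):
        node = p.parent(node)
    return node


def extent(p: Phylogeny, node: dendropy.Node) -> CladeExtent:
    """The clade anchored at ``node``: its full descendant-tip set."""
    return CladeExtent(node=node, tips=p.tips_under(node))


def enumerate_clades(p: Phylogeny) -> list[CladeExtent]:
    """Every clade on the tree, one per node (tips included).

    The returned extents form a laminar family — any two are nested or
    disjoint — which makes this the exhaustive search space for the
    brute-force resolution oracle.
    """
    return [extent(p, node) for node in p.nodes()]


def match_specifier(
    p: Phylogeny,
    s: TaxonName,
    aliases: Optional[Mapping[str, str]] = None,
    *,
    genus_fallback: bool = False,
) -> Optional[dendropy.Node]:
    """Find the tip a specifier points at, or ``None``.

    Match order: exact normalized-binomial equality, then alias-map lookup
    (keys are alternate labels as they appear on trees, values the
    accepted name), then — only when ``genus_fallback`` is enabled — a
    unique tip labeled with the bare genus.  Reference trees often score
    genus-level OTUs, but silent genus matching can misresolve, so the
    fallback is off by default and ambiguity is an error, never a guess.
    """
    key = s.key
    node = p.tip(key)
    if node is not None:
        return node
    if aliases:
        norm_aliases = {
            normalize_binomial(k): normalize_binomial(v) for k, v in aliases.items()
        }
        candidates = [
            label for label in p.tip_labels if norm_aliases.get(label) == key
        ]
        if len(candidates) > 1:
            raise AmbiguousSpecifierError(s.binomial, candidates)
        if candidates:
            return p.tip(candidates[0])
    if genus_fallback:
        genus = key.split(" ")[0]
        candidates = [label for label in p.tip_labels if label == genus]
        if len(candidates) > 1:
            raise AmbiguousSpecifierError(s.binomial, candidates)
        if candidates:
            return p.tip(candidates[0])
    return None
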