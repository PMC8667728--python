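"""Definition semantics on trees: core selection, clauses, contexts, synonymy."""

import random

import pytest

import cladedef.resolver as resolver_mod
from cladedef.corpus import random_definition, random_tree
from cladedef.definitions import (
    CladeDefinition,
    Connective,
    ContextConstraint,
    DefinitionKind,
    Polarity,
    TaxonName,
    parse_definition,
)
from cladedef.resolver import (
    ReasonCode,
    ResolveOptions,
    UnknownNameError,
    apply_qualifying,
    brute_force_resolve,
    check_context,
    detect_synonyms,
    resolve_all,
    resolve_definition,
    resolve_maximum,
    resolve_minimum,
    resolve_name,
)
from cladedef.trees import CladeExtent, extent, match_specifier, read_newick


def _tips(p, *labels):
    return [p.tip(l) for l in labels]


def _def(text, name="X", **meta):
    return parse_definition(text, clade_name=name, **meta)


class TestCoreSelection:
    def test_minimum_cherry(self, five_tip_tree):
        ext = resolve_minimum(five_tip_tree, _tips(five_tip_tree, "D d", "E e"))
        assert ext.tips == {"D d", "E e"}

    def test_minimum_spanning(self, five_tip_tree):
        ext = resolve_minimum(five_tip_tree, _tips(five_tip_tree, "A a", "D d"))
        assert ext.tips == five_tip_tree.tip_labels

    def test_maximum_walks_rootward(self, five_tip_tree):
        ext = resolve_maximum(
            five_tip_tree, _tips(five_tip_tree, "D d"), _tips(five_tip_tree, "A a")
        )
        assert ext.tips == {"C c", "D d", "E e"}

    def test_maximum_sister_exclusion_leaves_tip(self, five_tip_tree):
        ext = resolve_maximum(
            five_tip_tree, _tips(five_tip_tree, "D d"), _tips(five_tip_tree, "E e")
        )
        assert ext.tips == {"D d"}

    def test_maximum_external_inside_minimal(self, five_tip_tree):
        out = resolve_maximum(
            five_tip_tree,
            _tips(five_tip_tree, "D d", "C c"),
            _tips(five_tip_tree, "E e"),
        )
        assert out is None

    def test_maximum_no_matched_externals_reaches_root(self, five_tip_tree):
        ext = resolve_maximum(five_tip_tree, _tips(five_tip_tree, "D d"), [])
        assert ext.tips == five_tip_tree.tip_labels

    def test_exclusion_mode_any(self, five_tip_tree):
        internals = _tips(five_tip_tree, "D d")
        externals = _tips(five_tip_tree, "A a", "C c")
        strict = resolve_maximum(five_tip_tree, internals, externals, "all")
        relaxed = resolve_maximum(five_tip_tree, internals, externals, "any")
        assert strict.tips == {"D d", "E e"}
        assert relaxed.tips == {"C c", "D d", "E e"}


class TestQualifyingClause:
    def test_violation_voids(self):
        # Hadrosaurus inside min(Saurolophus, Lambeosaurus): the clause bites
        p = read_newick("((Saurolophus_osborni,Hadrosaurus_foulkii),Lambeosaurus_lambei);")
        cand = extent(p, p.root)
        assert not apply_qualifying(p, cand, _tips(p, "Hadrosaurus foulkii"))

    def test_exclusion_satisfied(self):
        p = read_newick("(Hadrosaurus_foulkii,(Saurolophus_osborni,Lambeosaurus_lambei));")
        cand = extent(p, p.tip("Saurolophus osborni").parent_node)
        assert apply_qualifying(p, cand, _tips(p, "Hadrosaurus foulkii"))

    def test_empty_clause_always_ok(self, five_tip_tree):
        assert apply_qualifying(five_tip_tree, extent(five_tip_tree, five_tip_tree.root), [])


class TestContextCheck:
    def _constraint(self, polarity, *names, connective=Connective.NONE):
        return ContextConstraint(
            polarity,
            tuple(TaxonName(n, is_supraspecific=True) for n in names),
            connective,
        )

    def test_within_includes_equality(self, five_tip_tree):
        cand = extent(five_tip_tree, five_tip_tree.root)
        constraint = self._constraint(Polarity.WITHIN, "Ctx")
        assert check_context(five_tip_tree, cand, constraint, {"Ctx": cand}) is None

    def test_within_violated(self, five_tip_tree):
        cand = extent(five_tip_tree, five_tip_tree.root)
        small = extent(five_tip_tree, five_tip_tree.tip("D d").parent_node)
        constraint = self._constraint(Polarity.WITHIN, "Ctx")
        assert (
            check_context(five_tip_tree, cand, constraint, {"Ctx": small})
            is ReasonCode.CONTEXT_VIOLATED
        )

    def test_outside_violated_by_second_context(self):
        p = read_newick("((A,B),((C,D),(E,F)));")
        cand = extent(p, p.tip("C").parent_node)  # {C,D}
        big = extent(p, p.tip("C").parent_node.parent_node)  # {C,D,E,F}
        other = extent(p, p.tip("A").parent_node)  # {A,B}
        constraint = self._constraint(
            Polarity.OUTSIDE, "First", "Second", connective=Connective.OR
        )
        assert (
            check_context(p, cand, constraint, {"First": other, "Second": big})
            is ReasonCode.CONTEXT_VIOLATED
        )

    def test_within_and_requires_all(self, five_tip_tree):
        cde = extent(five_tip_tree, five_tip_tree.tip("D d").parent_node.parent_node)
        de = extent(five_tip_tree, five_tip_tree.tip("D d").parent_node)
        whole = extent(five_tip_tree, five_tip_tree.root)
        constraint = self._constraint(
            Polarity.WITHIN, "P", "Q", connective=Connective.AND
        )
        assert check_context(five_tip_tree, de, constraint, {"P": cde, "Q": whole}) is None
        assert (
            check_context(five_tip_tree, cde, constraint, {"P": de, "Q": whole})
            is ReasonCode.CONTEXT_VIOLATED
        )

    def test_unresolved_context(self, five_tip_tree):
        cand = extent(five_tip_tree, five_tip_tree.root)
        constraint = self._constraint(Polarity.WITHIN, "Ctx")
        assert (
            check_context(five_tip_tree, cand, constraint, {"Ctx": None})
            is ReasonCode.CONTEXT_UNRESOLVED
        )

    def test_missing_map_entry_is_an_error(self, five_tip_tree):
        cand = extent(five_tip_tree, five_tip_tree.root)
        constraint = self._constraint(Polarity.WITHIN, "Ctx")
        with pytest.raises(KeyError):
            check_context(five_tip_tree, cand, constraint, {})


class TestResolveName:
    def test_unknown_name(self, five_tip_tree):
        with pytest.raises(UnknownNameError):
            resolve_name(five_tip_tree, [_def("min ∇ (A a & B b)", "Known")], "Unknown")

    def test_missing_internal_is_unresolvable(self, five_tip_tree):
        corpus = [_def("min ∇ (A a & Z z)", "X")]
        r = resolve_name(five_tip_tree, corpus, "X")
        assert r.status == "unresolvable"
        assert r.reason_code is ReasonCode.MISSING_INTERNAL

    def test_unmatched_external_warns_and_resolves(self, five_tip_tree):
        corpus = [_def("max ∇ (D d ~ Z z)", "X")]
        r = resolve_name(five_tip_tree, corpus, "X")
        assert r.resolved and r.extent.tips == five_tip_tree.tip_labels
        assert any("vacuously" in w for w in r.warnings)

    def test_context_resolved_recursively(self):
        p = read_newick("((A,B),((C,D),E));")
        corpus = [
            _def("max ∇ (C ~ A)", "Outer"),  # {C,D,E}
            _def("min ∇ ∈ Outer (C & D)", "Inner"),
        ]
        r = resolve_name(p, corpus, "Inner")
        assert r.resolved and r.extent.tips == {"C", "D"}

    def test_context_failure_propagates_as_unresolved(self):
        p = read_newick("((A,B),((C,D),E));")
        corpus = [
            _def("max ∇ (C ~ Zz zz)", "Outer", validate=True),
            _def("min ∇ ∈ Missing (C & D)", "Inner"),
        ]
        r = resolve_name(p, corpus, "Inner")
        assert r.status == "unresolvable"
        assert r.reason_code is ReasonCode.CONTEXT_UNRESOLVED

    def test_mutual_contexts_cycle(self):
        p = read_newick("((A,B),(C,D));")
        corpus = [
            _def("min ∇ ∈ Beta (A & B)", "Alpha"),
            _def("min ∇ ∈ Alpha (C & D)", "Beta"),
        ]
        results = resolve_all(p, corpus)
        assert results["Alpha"].reason_code is ReasonCode.DEPENDENCY_CYCLE
        assert results["Beta"].reason_code is ReasonCode.DEPENDENCY_CYCLE


class TestResolveAll:
    def test_corpus_order_preserved(self, five_tip_tree):
        corpus = [_def("min ∇ (D d & E e)", "Second"), _def("min ∇ (A a & B b)", "First")]
        assert list(resolve_all(five_tip_tree, corpus)) == ["Second", "First"]

    def test_context_memoized_across_batch(self, monkeypatch):
        p = read_newick("((A,B),((C,D),E));")
        corpus = [
            _def("max ∇ (C ~ A)", "Shared"),
            _def("min ∇ ∈ Shared (C & D)", "UserOne"),
            _def("min ∇ ∈ Shared (D & E)", "UserTwo"),
        ]
        calls = []
        real = resolver_mod.resolve_definition

        def counting(p_, d, *args, **kwargs):
            calls.append(d.clade_name)
            return real(p_, d, *args, **kwargs)

        monkeypatch.setattr(resolver_mod, "resolve_definition", counting)
        resolve_all(p, corpus)
        assert calls.count("Shared") == 1

    def test_names_filter_and_unknown(self, five_tip_tree):
        corpus = [_def("min ∇ (A a & B b)", "Only")]
        assert list(resolve_all(five_tip_tree, corpus, names=["Only"])) == ["Only"]
        with pytest.raises(UnknownNameError):
            resolve_all(five_tip_tree, corpus, names=["Nope"])


class TestSynonymy:
    def test_three_names_one_extent_gives_three_pairs(self, five_tip_tree):
        corpus = [
            _def("min ∇ (D d & E e)", "Alpha", authorship="Brown, 1914"),
            _def("min ∇ (D d & E e)", "Beta", authorship="Marsh 1890"),
            _def("min ∇ (E e & D d)", "Gamma"),
        ]
        report = detect_synonyms(resolve_all(five_tip_tree, corpus), corpus)
        assert len(report.pairs) == 3
        pair = next(p for p in report.pairs if {p.name_a, p.name_b} == {"Alpha", "Beta"})
        assert (pair.year_a, pair.year_b) == (1914, 1890)
        gamma_pair = next(p for p in report.pairs if "Gamma" in (p.name_a, p.name_b))
        assert None in (gamma_pair.year_a, gamma_pair.year_b)

    def test_distinct_extents_empty_report(self, five_tip_tree):
        corpus = [_def("min ∇ (A a & B b)", "P"), _def("min ∇ (D d & E e)", "Q")]
        assert detect_synonyms(resolve_all(five_tip_tree, corpus), corpus).pairs == []

    def test_unresolved_names_never_pair(self, five_tip_tree):
        corpus = [
            _def("min ∇ (D d & E e)", "Good"),
            _def("min ∇ (Z z & Y y)", "Absent"),
        ]
        report = detect_synonyms(resolve_all(five_tip_tree, corpus), corpus)
        assert report.pairs == []


class TestAlgebraicProperties:
    @pytest.mark.parametrize("seed", range(30))
    def test_min_max_bounds(self, seed):
        """Minimality/maximality against the enumerated clade family."""
        rng = random.Random(seed)
        p = random_tree(rng.randint(4, 18), seed, polytomy_prob=0.3)
        labels = sorted(p.tip_labels)
        internals = rng.sample(labels, rng.randint(1, 3))
        externals = [l for l in rng.sample(labels, rng.randint(1, 3)) if l not in internals]
        from cladedef.trees import enumerate_clades

        min_ext = resolve_minimum(p, _tips(p, *internals)) if len(internals) >= 1 else None
        for clade in enumerate_clades(p):
            if set(internals) <= clade.tips:
                assert min_ext.tips <= clade.tips
        if externals:
            max_ext = resolve_maximum(p, _tips(p, *internals), _tips(p, *externals))
            for clade in enumerate_clades(p):
                if set(internals) <= clade.tips and not (set(externals) & clade.tips):
                    assert max_ext is not None and clade.tips <= max_ext.tips

    @pytest.mark.parametrize("seed", range(30))
    def test_adding_external_never_enlarges(self, seed):
        rng = random.Random(seed)
        p = random_tree(rng.randint(5, 18), seed, polytomy_prob=0.2)
        labels = sorted(p.tip_labels)
        internal = rng.sample(labels, 1)
        others = [l for l in labels if l not in internal]
        e1 = rng.sample(others, 1)
        e2 = e1 + rng.sample([l for l in others if l not in e1], 1)
        base = resolve_maximum(p, _tips(p, *internal), _tips(p, *e1))
        more = resolve_maximum(p, _tips(p, *internal), _tips(p, *e2))
        if base is not None and more is not None:
            assert more.tips <= base.tips

    @pytest.mark.parametrize("seed", range(30))
    def test_node_branch_triplet(self, seed):
        """On binary trees: min(X,Y) = max(X~Y) ⊎ max(Y~X) when all resolve."""
        rng = random.Random(seed)
        p = random_tree(rng.randint(4, 18), seed, polytomy_prob=0.0)
        x, y = rng.sample(sorted(p.tip_labels), 2)
        node = resolve_minimum(p, _tips(p, x, y))
        bx = resolve_maximum(p, _tips(p, x), _tips(p, y))
        by = resolve_maximum(p, _tips(p, y), _tips(p, x))
        assert bx is not None and by is not None
        assert not (bx.tips & by.tips)
        assert bx.tips | by.tips == node.tips


class TestBruteForceOracle:
    def test_guard(self):
        p = random_tree(70, 1)
        with pytest.raises(ValueError, match="64 tips"):
            brute_force_resolve(p, _def("min ∇ (T1 & T2)"))

    def test_example_agreement(self, five_tip_tree):
        d = _def("max ∇ (D d ~ A a)")
        fast = resolve_definition(five_tip_tree, d)
        slow = brute_force_resolve(five_tip_tree, d)
        assert fast.resolved and slow.resolved
        assert fast.extent.tips == slow.extent.tips == {"C c", "D d", "E e"}

    def test_missing_internal_agreement(self, five_tip_tree):
        d = _def("min ∇ (A a & Z z)")
        fast = resolve_definition(five_tip_tree, d)
        slow = brute_force_resolve(five_tip_tree, d)
        assert fast.reason_code is slow.reason_code is ReasonCode.MISSING_INTERNAL

    @pytest.mark.parametrize("chunk", range(4))
    def test_randomized_agreement(self, chunk):
        """Status, reason code and extent agree across 150 random cases/chunk,
        including randomized contexts and both exclusion modes."""
        from cladedef.trees import enumerate_clades

        rng = random.Random(1000 + chunk)
        for _ in range(150):
            p = random_tree(rng.randint(4, 20), rng.randrange(2**31), polytomy_prob=0.3)
            d = random_definition(rng, sorted(p.tip_labels))
            ctx = None
            if rng.random() < 0.35:
                clade = rng.choice(enumerate_clades(p))
                d = CladeDefinition(
                    clade_name=d.clade_name,
                    kind=d.kind,
                    internal=d.internal,
                    external=d.external,
                    external_connective=d.external_connective,
                    qualifying_excluded=d.qualifying_excluded,
                    qualifying_connective=d.qualifying_connective,
                    context=ContextConstraint(
                        rng.choice(list(Polarity)),
                        (TaxonName("Ctx", is_supraspecific=True),),
                        Connective.NONE,
                    ),
                )
                ctx = {"Ctx": clade}
            options = ResolveOptions(exclusion_mode=rng.choice(["all", "any"]))
            fast = resolve_definition(p, d, options, ctx)
            slow = brute_force_resolve(p, d, options, ctx)
            assert fast.status == slow.status
            assert fast.reason_code == slow.reason_code
            fast_tips = fast.extent.tips if fast.resolved else None
            slow_tips = slow.extent.tips if slow.resolved else None
            assert fast_tips == slow_tips
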