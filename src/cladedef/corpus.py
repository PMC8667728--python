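"""The packaged ornithischian clade-name corpus and test-surface generators.

Ships the 81 formally defined ornithischian clade names (76 conversions
of preexisting names plus five newly coined ones) as structured JSON,
cross-checked on load against a fresh parse of each entry's abbreviated
definition string.  Also provides the scenario-tree registry — small,
hand-built topologies encoding placement hypotheses that flip names
between resolved/inapplicable — and a seeded random-tree generator for
property tests and the brute-force oracle experiment.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .definitions import (
    CladeDefinition,
    Connective,
    ContextConstraint,
    DefinitionKind,
    Polarity,
    TaxonName,
    parse_definition,
    validate_definition,
)
from .trees import Phylogeny, read_newick

__all__ = [
    "Corpus",
    "CorpusError",
    "ScenarioTree",
    "load_corpus",
    "corpus_summary",
    "scenario_tree",
    "scenario_ids",
    "random_tree",
    "random_definition",
    "NEW_CLADE_NAMES",
]

# the five names coined rather than converted
NEW_CLADE_NAMES = frozenset(
    ["Corythosauria", "Euceratopsia", "Panoplosaurini", "Saphornithischia", "Struthiosaurini"]
)


class CorpusError(ValueError):
    pass


@dataclass
class Corpus:
    entries: list[CladeDefinition]
    alias_map: dict[str, str] = field(default_factory=dict)
    version: str = "1.0"

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def get(self, name: str) -> Optional[CladeDefinition]:
        for d in self.entries:
            if d.clade_name == name:
                return d
        return None

    @property
    def names(self) -> list[str]:
        return [d.clade_name for d in self.entries]


# ---------------------------------------------------------------------------
# loading / validation

_REQUIRED_ENTRY_KEYS = {
    "clade_name",
    "status",
    "registration_number",
    "kind",
    "abbreviated",
    "internal",
    "external",
    "external_connective",
    "qualifying_excluded",
    "qualifying_connective",
    "context",
}


def _entry_to_definition(raw: dict) -> CladeDefinition:
    missing = _REQUIRED_ENTRY_KEYS - raw.keys()
    if missing:
        raise CorpusError(f"entry {raw.get('clade_name', '?')!r}: missing keys {sorted(missing)}")
    context = None
    if raw["context"] is not None:
        c = raw["context"]
        context = ContextConstraint(
            polarity=Polarity(c["polarity"]),
            contexts=tuple(TaxonName(n, is_supraspecific=True) for n in c["contexts"]),
            connective=Connective(c["connective"]),
        )
    return CladeDefinition(
        clade_name=raw["clade_name"],
        kind=DefinitionKind(raw["kind"]),
        internal=tuple(TaxonName(n) for n in raw["internal"]),
        external=tuple(TaxonName(n) for n in raw["external"]),
        external_connective=Connective(raw["external_connective"]),
        qualifying_excluded=tuple(TaxonName(n) for n in raw["qualifying_excluded"]),
        qualifying_connective=Connective(raw["qualifying_connective"]),
        context=context,
        registration_number=int(raw["registration_number"]),
        authorship=raw.get("authorship", ""),
        status=raw["status"],
    )


def load_corpus(source: Union[str, Path] = "packaged") -> Corpus:
    """Load and validate a definition corpus.

    ``source`` is either the literal ``"packaged"`` (the shipped
    ornithischian corpus) or a path to a JSON file following
    ``data/corpus.schema.json``.  Each entry's abbreviated string is
    re-parsed and must reproduce the structured fields exactly; every
    entry must pass :func:`validate_definition`; registration numbers
    must be unique corpus-wide.
    """
    if isinstance(source, str) and source == "packaged":
        text = (resources.files("cladedef") / "data" / "corpus.json").read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CorpusError(f"corpus is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict) or "entries" not in raw or not isinstance(raw["entries"], list):
        raise CorpusError("corpus must be an object with an 'entries' array")

    entries: list[CladeDefinition] = []
    problems: list[str] = []
    for item in raw["entries"]:
        d = _entry_to_definition(item)
        violations = validate_definition(d)
        if violations:
            problems.extend(f"{d.clade_name}: {v}" for v in violations)
        # cross-check: the abbreviated string must parse to this structure
        reparsed = parse_definition(
            item["abbreviated"],
            validate=False,
            clade_name=d.clade_name,
            registration_number=d.registration_number,
            authorship=d.authorship,
            status=d.status,
        )
        if reparsed.strip_authorities() != d.strip_authorities():
            problems.append(
                f"{d.clade_name}: abbreviated string does not match structured fields"
            )
        entries.append(d)

    seen_reg: dict[int, str] = {}
    for d in entries:
        if d.registration_number in seen_reg:
            problems.append(
                f"duplicate registration number {d.registration_number} "
                f"({seen_reg[d.registration_number]} vs {d.clade_name})"
            )
        else:
            seen_reg[d.registration_number] = d.clade_name
    seen_names = set()
    for d in entries:
        if d.clade_name in seen_names:
            problems.append(f"duplicate clade name {d.clade_name}")
        seen_names.add(d.clade_name)
    if problems:
        raise CorpusError("; ".join(problems))
    return Corpus(
        entries=entries,
        alias_map=dict(raw.get("alias_map", {})),
        version=str(raw.get("version", "1.0")),
    )


def corpus_summary(c: Corpus) -> dict[str, int]:
    """Deterministic totals by status and definition kind."""
    return {
        "total": len(c.entries),
        "converted": sum(1 for d in c if d.status == "converted"),
        "new": sum(1 for d in c if d.status == "new"),
        "minimum": sum(1 for d in c if d.kind is DefinitionKind.MINIMUM),
        "maximum": sum(1 for d in c if d.kind is DefinitionKind.MAXIMUM),
    }


# ---------------------------------------------------------------------------
# scenario trees

@dataclass(frozen=True)
class ScenarioTree:
    """A packaged toy topology encoding one placement hypothesis.

    ``expected`` lists (clade_name, expected_status, expected_extent)
    triples; extent is a sorted tip-label list or None when only the
    status is asserted.  ``provenance`` describes, in this package's own
    words, the published placement the topology encodes — scenario trees
    are minimal encodings of verbally described hypotheses, never
    tracings of figures.
    """

    id: str
    description: str
    provenance: str
    newick: str
    expected: tuple[tuple[str, str, Optional[tuple[str, ...]]], ...]

    @property
    def tree(self) -> Phylogeny:
        return read_newick(self.newick)


def _s(*items):
    return tuple(sorted(items))


_SCENARIOS: dict[str, ScenarioTree] = {}


def _register(scenario: ScenarioTree) -> None:
    _SCENARIOS[scenario.id] = scenario


_register(
    ScenarioTree(
        id="primary_hadrosaurid",
        description="Hadrosaurus foulkii just outside the Saurolophus+Lambeosaurus node",
        provenance=(
            "The arrangement most recent hadrosaurid analyses recover: "
            "H. foulkii branches immediately rootward of the saurolophine/"
            "lambeosaurine split, so the Saurolophus branch excludes it."
        ),
        newick=(
            "(Iguanodon_bernissartensis,(Hadrosaurus_foulkii,"
            "((Saurolophus_osborni,Edmontosaurus_regalis),"
            "(Lambeosaurus_lambei,Parasaurolophus_walkeri))));"
        ),
        expected=(
            ("Saurolophinae", "resolved", _s("Saurolophus osborni", "Edmontosaurus regalis")),
            ("Hadrosaurinae", "resolved", _s("Hadrosaurus foulkii")),
            (
                "Euhadrosauria",
                "resolved",
                _s(
                    "Saurolophus osborni",
                    "Edmontosaurus regalis",
                    "Lambeosaurus lambei",
                    "Parasaurolophus walkeri",
                ),
            ),
            (
                "Hadrosauridae",
                "resolved",
                _s(
                    "Hadrosaurus foulkii",
                    "Saurolophus osborni",
                    "Edmontosaurus regalis",
                    "Lambeosaurus lambei",
                    "Parasaurolophus walkeri",
                ),
            ),
        ),
    )
)

_register(
    ScenarioTree(
        id="hadrosaurus_inside",
        description="Hadrosaurus foulkii nested inside the Saurolophus branch",
        provenance=(
            "The competing arrangement in which H. foulkii is recovered within "
            "the smallest clade containing S. osborni and L. lambei, on the "
            "Saurolophus side: the saurolophine name and Euhadrosauria are then "
            "set aside in favor of Hadrosaurinae."
        ),
        newick=(
            "(Iguanodon_bernissartensis,"
            "(((Lambeosaurus_lambei,Corythosaurus_casuarius),Parasaurolophus_walkeri),"
            "(Saurolophus_osborni,(Hadrosaurus_foulkii,Edmontosaurus_regalis))));"
        ),
        expected=(
            ("Saurolophinae", "inapplicable", None),
            ("Euhadrosauria", "inapplicable", None),
            (
                "Hadrosaurinae",
                "resolved",
                _s("Saurolophus osborni", "Hadrosaurus foulkii", "Edmontosaurus regalis"),
            ),
            (
                "Hadrosauridae",
                "resolved",
                _s(
                    "Lambeosaurus lambei",
                    "Corythosaurus casuarius",
                    "Parasaurolophus walkeri",
                    "Saurolophus osborni",
                    "Hadrosaurus foulkii",
                    "Edmontosaurus regalis",
                ),
            ),
        ),
    )
)

_register(
    ScenarioTree(
        id="heterodontosaurids_in_pachycephalosauria",
        description="heterodontosaurids as early-diverging pachycephalosaurs",
        provenance=(
            "A recent analysis recovered heterodontosaurids inside "
            "Pachycephalosauria, with Echinodon becklesii and Tianyulong "
            "confuciusi closer to pachycephalosaurids than to "
            "Heterodontosaurus; the four-taxon core heterodontosaurid clade "
            "nevertheless persists."
        ),
        newick=(
            "((Stegosaurus_stenops,Ankylosaurus_magniventris),"
            "((Iguanodon_bernissartensis,Hypsilophodon_foxii),"
            "((((Heterodontosaurus_tucki,Lycorhinus_angustidens),"
            "(Abrictosaurus_consors,Fruitadens_haagarorum)),"
            "((Echinodon_becklesii,Tianyulong_confuciusi),"
            "(Stegoceras_validum,Pachycephalosaurus_wyomingensis))),"
            "(Triceratops_horridus,Protoceratops_andrewsi))));"
        ),
        expected=(
            (
                "Heterodontosauridae",
                "resolved",
                _s(
                    "Abrictosaurus consors",
                    "Fruitadens haagarorum",
                    "Heterodontosaurus tucki",
                    "Lycorhinus angustidens",
                ),
            ),
        ),
    )
)

_register(
    ScenarioTree(
        id="leptoceratopsids_sister_to_ceratopsoidea",
        description="Leptoceratopsidae sister to Ceratopsoidea, Protoceratopsidae rootward",
        provenance=(
            "The alternative ceratopsian arrangement with leptoceratopsids as "
            "the sister group of Ceratopsoidea and protoceratopsids one node "
            "rootward; the three-specifier node and the Protoceratops+"
            "Triceratops node then pick out the same clade."
        ),
        newick=(
            "(Psittacosaurus_mongoliensis,"
            "((Protoceratops_andrewsi,Bagaceratops_rozhdestvenskyi),"
            "((Leptoceratops_gracilis,Montanoceratops_cerorhynchus),"
            "(Zuniceratops_christopheri,(Centrosaurus_apertus,Triceratops_horridus)))));"
        ),
        expected=(
            (
                "Euceratopsia",
                "resolved",
                _s(
                    "Protoceratops andrewsi",
                    "Bagaceratops rozhdestvenskyi",
                    "Leptoceratops gracilis",
                    "Montanoceratops cerorhynchus",
                    "Zuniceratops christopheri",
                    "Centrosaurus apertus",
                    "Triceratops horridus",
                ),
            ),
            (
                "Coronosauria",
                "resolved",
                _s(
                    "Protoceratops andrewsi",
                    "Bagaceratops rozhdestvenskyi",
                    "Leptoceratops gracilis",
                    "Montanoceratops cerorhynchus",
                    "Zuniceratops christopheri",
                    "Centrosaurus apertus",
                    "Triceratops horridus",
                ),
            ),
        ),
    )
)

_register(
    ScenarioTree(
        id="primary_ceratopsian",
        description="Protoceratopsidae sister to Ceratopsoidea (coronosaur node)",
        provenance=(
            "The majority arrangement: protoceratopsids and ceratopsoids are "
            "sisters (Coronosauria), with leptoceratopsids outside that node; "
            "the three-specifier node is then strictly larger than "
            "Coronosauria."
        ),
        newick=(
            "(Psittacosaurus_mongoliensis,"
            "((Leptoceratops_gracilis,Montanoceratops_cerorhynchus),"
            "((Protoceratops_andrewsi,Bagaceratops_rozhdestvenskyi),"
            "(Zuniceratops_christopheri,(Centrosaurus_apertus,Triceratops_horridus)))));"
        ),
        expected=(
            (
                "Euceratopsia",
                "resolved",
                _s(
                    "Protoceratops andrewsi",
                    "Bagaceratops rozhdestvenskyi",
                    "Leptoceratops gracilis",
                    "Montanoceratops cerorhynchus",
                    "Zuniceratops christopheri",
                    "Centrosaurus apertus",
                    "Triceratops horridus",
                ),
            ),
            (
                "Coronosauria",
                "resolved",
                _s(
                    "Protoceratops andrewsi",
                    "Bagaceratops rozhdestvenskyi",
                    "Zuniceratops christopheri",
                    "Centrosaurus apertus",
                    "Triceratops horridus",
                ),
            ),
        ),
    )
)

_register(
    ScenarioTree(
        id="primary_lambeosaurine",
        description="lambeosaurine tribes in their reference arrangement",
        provenance=(
            "The reference hadrosaurid arrangement: Aralosaurini, then "
            "Tsintaosaurini, diverge successively below the Parasaurolophini+"
            "Lambeosaurini node; both tribes resolve to their two named "
            "members."
        ),
        newick=(
            "(Hadrosaurus_foulkii,(Saurolophus_osborni,"
            "((Aralosaurus_tuberiferus,Canardia_garonnensis),"
            "((Pararhabdodon_isonensis,Tsintaosaurus_spinorhinus),"
            "(Parasaurolophus_walkeri,(Lambeosaurus_lambei,Corythosaurus_casuarius))))));"
        ),
        expected=(
            ("Aralosaurini", "resolved", _s("Aralosaurus tuberiferus", "Canardia garonnensis")),
            (
                "Tsintaosaurini",
                "resolved",
                _s("Pararhabdodon isonensis", "Tsintaosaurus spinorhinus"),
            ),
            (
                "Corythosauria",
                "resolved",
                _s(
                    "Parasaurolophus walkeri",
                    "Lambeosaurus lambei",
                    "Corythosaurus casuarius",
                ),
            ),
        ),
    )
)

_register(
    ScenarioTree(
        id="aralosaurus_separated",
        description="Aralosaurus closer to crown lambeosaurines than to Canardia",
        provenance=(
            "Topologies in which the two aralosaurin specifiers do not form an "
            "exclusive clade: their smallest containing clade sweeps in the "
            "external specifiers, so the tribe name is inapplicable."
        ),
        newick=(
            "(Hadrosaurus_foulkii,(Canardia_garonnensis,(Aralosaurus_tuberiferus,"
            "(Tsintaosaurus_spinorhinus,(Parasaurolophus_walkeri,Lambeosaurus_lambei)))));"
        ),
        expected=(("Aralosaurini", "inapplicable", None),),
    )
)

_register(
    ScenarioTree(
        id="tsintaosaurus_separated",
        description="Pararhabdodon and Tsintaosaurus on opposite sides of the lambeosaurine tree",
        provenance=(
            "The arrangement that splits the tsintaosaurin specifiers (as when "
            "most European lambeosaurines group apart from Tsintaosaurus): "
            "their MRCA contains the external specifiers and the tribe name is "
            "inapplicable."
        ),
        newick=(
            "(Saurolophus_osborni,(Tsintaosaurus_spinorhinus,(Aralosaurus_tuberiferus,"
            "(Pararhabdodon_isonensis,(Parasaurolophus_walkeri,Lambeosaurus_lambei)))));"
        ),
        expected=(("Tsintaosaurini", "inapplicable", None),),
    )
)

_register(
    ScenarioTree(
        id="hypsilophodon_outside_ornithopoda",
        description="Hypsilophodon (and Heterodontosaurus) outside Ornithopoda",
        provenance=(
            "Analyses placing H. foxii outside the cerapodan crown as an "
            "early neornithischian: the ∈-Ornithopoda restriction on "
            "Clypeodonta, Euornithopoda and Hypsilophodontia then bites, since "
            "their clades would have to span marginocephalians."
        ),
        newick=(
            "(Heterodontosaurus_tucki,(Hypsilophodon_foxii,"
            "((Pachycephalosaurus_wyomingensis,Triceratops_horridus),"
            "(Thescelosaurus_neglectus,(Tenontosaurus_tilletti,"
            "(Iguanodon_bernissartensis,Edmontosaurus_regalis))))));"
        ),
        expected=(
            (
                "Ornithopoda",
                "resolved",
                _s(
                    "Thescelosaurus neglectus",
                    "Tenontosaurus tilletti",
                    "Iguanodon bernissartensis",
                    "Edmontosaurus regalis",
                ),
            ),
            ("Clypeodonta", "inapplicable", None),
            ("Euornithopoda", "inapplicable", None),
            ("Hypsilophodontia", "inapplicable", None),
        ),
    )
)

_register(
    ScenarioTree(
        id="jeholosaurus_in_thescelosauridae",
        description="Jeholosaurus nested inside the thescelosaurid branch",
        provenance=(
            "The hypothesis placing Jeholosaurus within Thescelosauridae: the "
            "family name carries an ∉ restriction against exactly this, so "
            "Jeholosauridae is inapplicable while Thescelosauridae and "
            "Orodrominae still resolve."
        ),
        newick=(
            "((Pachycephalosaurus_wyomingensis,Triceratops_horridus),"
            "(((Jeholosaurus_shangyuanensis,Orodromeus_makelai),"
            "(Thescelosaurus_neglectus,Haya_griva)),"
            "(Hypsilophodon_foxii,(Rhabdodon_priscus,Iguanodon_bernissartensis))));"
        ),
        expected=(
            (
                "Thescelosauridae",
                "resolved",
                _s(
                    "Jeholosaurus shangyuanensis",
                    "Orodromeus makelai",
                    "Thescelosaurus neglectus",
                    "Haya griva",
                ),
            ),
            ("Jeholosauridae", "inapplicable", None),
            (
                "Orodrominae",
                "resolved",
                _s("Jeholosaurus shangyuanensis", "Orodromeus makelai"),
            ),
        ),
    )
)


def scenario_ids() -> list[str]:
    return sorted(_SCENARIOS)


def scenario_tree(scenario_id: str) -> ScenarioTree:
    """Look up a packaged scenario by id; unknown ids list what exists."""
    try:
        return _SCENARIOS[scenario_id]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; available: {', '.join(scenario_ids())}"
        ) from None


# ---------------------------------------------------------------------------
# random trees

def random_tree(n_tips: int, seed: int, polytomy_prob: float = 0.0) -> Phylogeny:
    """Seeded random rooted tree with tips ``T1..Tn``.

    Built by uniform recursive splitting: each internal node receives two
    child blocks, or three with probability ``polytomy_prob`` (when the
    block is large enough), and the tip set is partitioned uniformly at
    random among them.  Deterministic for a given
    ``(n_tips, seed, polytomy_prob)``.
    """
    if n_tips < 2:
        raise ValueError("random_tree requires n_tips >= 2")
    if not 0.0 <= polytomy_prob <= 1.0:
        raise ValueError("polytomy_prob must be within [0, 1]")
    rng = random.Random(seed)
    labels = [f"T{i}" for i in range(1, n_tips + 1)]

    def build(block: list[str]) -> str:
        if len(block) == 1:
            return block[0]
        k = 2
        if len(block) >= 3 and rng.random() < polytomy_prob:
            k = 3
        shuffled = block[:]
        rng.shuffle(shuffled)
        # pick k-1 cut points to split into k non-empty parts
        cuts = sorted(rng.sample(range(1, len(block)), k - 1))
        parts, prev = [], 0
        for cut in cuts + [len(block)]:
            parts.append(shuffled[prev:cut])
            prev = cut
        return "(" + ",".join(build(part) for part in parts) + ")"

    return read_newick(build(labels) + ";")


def random_definition(
    rng: random.Random,
    labels: list[str],
    *,
    missing_prob: float = 0.15,
) -> CladeDefinition:
    """Seeded random definition over a tree's tip labels.

    Draws a minimum- or maximum-kind definition with 1–3 internal, 0–3
    external and 0–2 qualifying specifiers, all distinct; with
    probability ``missing_prob`` per drawn specifier a label absent from
    the tree is substituted, exercising the unresolvable/warning paths.
    Companion to :func:`random_tree` for the oracle-equivalence
    experiment.
    """
    kind = rng.choice([DefinitionKind.MINIMUM, DefinitionKind.MAXIMUM])
    n_internal = rng.randint(2, 3) if kind is DefinitionKind.MINIMUM else rng.randint(1, 3)
    n_external = rng.randint(1, 3) if kind is DefinitionKind.MAXIMUM else rng.randint(0, 2)
    n_qualifying = rng.randint(0, 2)
    need = n_internal + n_external + n_qualifying
    pool = sorted(labels)
    absent = [f"Zz absent{i}" for i in range(1, need + 1)]
    picks = rng.sample(pool, min(need, len(pool)))
    while len(picks) < need:
        picks.append(absent.pop())
    picks = [
        absent.pop() if absent and rng.random() < missing_prob else label for label in picks
    ]
    # de-duplicate after substitution, padding from the absent reserve
    seen, uniq = set(), []
    for label in picks:
        if label in seen:
            label = absent.pop() if absent else f"Zz extra{len(uniq)}"
        seen.add(label)
        uniq.append(label)
    internal = uniq[:n_internal]
    external = uniq[n_internal : n_internal + n_external]
    qualifying = uniq[n_internal + n_external :]

    def conn(group):
        if len(group) <= 1:
            return Connective.NONE
        return rng.choice([Connective.AND, Connective.OR])

    return CladeDefinition(
        clade_name="RandomClade",
        kind=kind,
        internal=tuple(TaxonName(x) for x in internal),
        external=tuple(TaxonName(x) for x in external),
        external_connective=conn(external),
        qualifying_excluded=tuple(TaxonName(x) for x in qualifying),
        qualifying_connective=conn(qualifying),
    )
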