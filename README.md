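# cladedef

**Resolve rank-free phylogenetic clade definitions on rooted trees.**

Under phylogenetic nomenclature (the *PhyloCode* approach), a clade name is
not tied to a Linnaean rank but anchored to explicit *specifier* species on
a phylogeny. `cladedef` implements the two definition kinds this system
uses and works out, for any rooted tree you supply, which names apply,
what they cover, and why names that fail do so:

* **minimum-clade** ("node-based"): *the smallest clade containing A and B*
  — the most recent common ancestor of the internal specifiers and all its
  descendants;
* **maximum-clade** ("branch-based"/"stem-based"): *the largest clade
  containing A but not X* — the total clade of the branch just below the
  point where the external specifier attaches.

Definitions are written in a compact notation (`max` = the largest, `min` =
the smallest, `∇` = clade, `()` = containing, `&` = and, `∨` = or, `~` =
but not, `|` = on the condition that, `∈`/`∉` = within/outside another
named clade), e.g.

```
max ∇ (Ankylosaurus magniventris ~ Stegosaurus stenops)            # Ankylosauria
min ∇ ∈ Ornithopoda (Edmontosaurus regalis & Hypsilophodon foxii)  # Clypeodonta
max ∇ (Saurolophus osborni ~ Lambeosaurus lambei | ~ Hadrosaurus foulkii)
```

Every glyph has an ASCII alias (`max-clade`, `min-clade`, `and`, `or`,
`not`, `provided-not`, `in`, `not-in`) so definitions can be typed without
Unicode input.

On a given topology each name is **resolved** (with its exact extent, the
computable analogue of a published "Composition" list), **inapplicable**
(the topology violates a qualifying clause or an `∈`/`∉` context
restriction, or an external specifier falls inside the internals' minimal
clade), or **unresolvable** (an internal specifier is missing from the
tree). The package also detects **heterodefinitional synonyms** — distinct
definitions that pick out the same clade on a particular tree.

The package ships the complete formal nomenclature of ornithischian
("bird-hipped") dinosaur clades as its reference corpus: 81 registered
definitions — 76 conversions of preexisting names (*Ornithischia*,
*Ankylosauria*, *Hadrosauridae*, *Ceratopsia*, …) plus five newly coined
names — together with a registry of small scenario trees encoding the
competing placement hypotheses that flip those names between applicable
and inapplicable. It is aimed at systematists who want to check what a
proposed definition does across candidate topologies, and at anyone
building tooling around registered phylogenetic nomenclature.

## Worked example

The choice between *Saurolophinae* and *Hadrosaurinae* famously depends on
where *Hadrosaurus foulkii* attaches. Emit the packaged scenario in which
it nests inside the *Saurolophus* branch and resolve the three contested
names:

```bash
$ cladedef scenarios emit hadrosaurus_inside --out scenarios/
$ cladedef resolve --tree scenarios/hadrosaurus_inside.nwk \
    --names Saurolophinae,Hadrosaurinae,Euhadrosauria --format tsv
name	kind	status	reason	n_tips	extent
Euhadrosauria	minimum	inapplicable	QUALIFIER_VIOLATED	0
Hadrosaurinae	maximum	resolved		3	Edmontosaurus regalis;Hadrosaurus foulkii;Saurolophus osborni
Saurolophinae	maximum	inapplicable	QUALIFIER_VIOLATED	0
$ echo $?
3
```

Reading the report: *Saurolophinae* (`max ∇ (Saurolophus osborni ~
Lambeosaurus lambei | ~ Hadrosaurus foulkii)`) selects the *Saurolophus*
branch, but on this topology that branch contains *H. foulkii*, so its
qualifying clause voids the name — it is inapplicable, not merely smaller.
*Euhadrosauria* fails the same way. *Hadrosaurinae* (`max ∇ (Hadrosaurus
foulkii ~ Lambeosaurus lambei)`) was defined precisely to take over here:
it resolves to the three-taxon branch. Exit code 3 signals "ran fine, but
not every selected name resolved" (0 = all resolved, 1 = input error).

Other commands: `cladedef synonyms` reports equal-extent name pairs on a
tree, `cladedef validate-corpus` checks a corpus file against the shipped
JSON schema and prints totals, and `cladedef scenarios list` shows every
packaged topology. The same functionality is available as a library:

```python
import cladedef as cd

corpus = cd.load_corpus("packaged")          # 81 definitions
tree = cd.scenario_tree("hadrosaurus_inside").tree
results = cd.resolve_all(tree, corpus.entries,
                         cd.ResolveOptions(aliases=corpus.alias_map))
print(results["Hadrosaurinae"].extent.sorted_tips())
# ['Edmontosaurus regalis', 'Hadrosaurus foulkii', 'Saurolophus osborni']
```

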