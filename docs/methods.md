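# Methods

This note documents the data model, the tree-construction procedure, the
synthetic-data generator, and the numerical/design choices behind `eolkit`.

## The XML dialect and data model

The package speaks a pinned v1.0-style XML dialect. Every response is a
`<response>` document: search responses carry `<entry><id/><title/></entry>`
hits; taxon pages a single `<taxonConcept>` (id, scientific name, optional
0–100 richness score, provider `taxonConceptEntry` records, `dataObject`
media items, `commonName` vernaculars with BCP-47-ish language tags,
`reference` strings, `synonym` records, optional `iucnStatus`); provider
classification pages a single `<hierarchyEntry>` (ranked taxon, `ancestor`
list ordered most-inclusive → least-inclusive, `child` list in provider
order, synonyms). Documents are UTF-8; unknown elements are skipped with a
debug log rather than rejected, for forward compatibility. Media kinds are
classified from the trailing token of the dcmitype URI, case-insensitively;
unknown tokens become `Other` rather than errors.

The live EOL service has evolved past this dialect, so the transport layer
is pluggable and the package's own generators (`eolkit.fixtures`) emit
exactly the dialect the parsers read. Generator and parser are mutual
inverses over the whole reachable spec space, which the round-trip property
suites check directly; this is what makes an offline, fully reproducible
test bed possible.

### Name normalization

All name matching (exact search, table joins, tip matching) uses one rule:
trim, collapse internal whitespace, case-fold. Authority strings are never
stripped — silently removing authorship can fuse distinct names, so
unmatched rows are kept visible (`NA`) instead. Duplicate normalized names
on either side of a join raise an ambiguity error rather than guessing.

## Tabular extraction

Per-taxon tables have one row per input page, in input order, with
`taxon_name` and `eol_page_id` as the first two columns. Missing values are
typed-absent in memory (NaN/`pd.NA`) and render as the token `NA` in
CSV/TSV output, matching the R-culture conventions of this domain's
existing tooling. Language columns in counts mode use the raw tags
encountered; mapping tables would invent data. `provider_count` counts
pages, not entries (a provider listed twice on one page counts once),
because the quantity of interest is coverage. IUCN statuses are mapped to
the ten standard codes by parenthesised code first, then longest full-name
match; unrecognised text warns and records `NA`, never crashes. When a page
has no dedicated status element the extractor falls back to an
IUCN-attributed text object, since providers differ in where they attach
the assessment.

`relative_richness` divides each score by the mean over non-missing scores;
the new column therefore averages to exactly 1.0 (checked to 1e-12), and a
taxon's value reads as "times the group average". The richness score itself
is a server-side composite and is only ever parsed, never computed.

## Tree construction

`make_tree_data` turns a set of classification pages into a taxon × rank
matrix. Each page contributes the path `ancestors + taxon`; unranked levels
get position-based synthetic slots (`clade_depth_k`, 0-based depth) so they
survive into the matrix instead of being dropped — common for NCBI-style
lineages with unranked clades. The global rank order is a topological sort
of the pairwise orders implied by every page (stable Kahn's algorithm with
first-seen tie-breaking, so output order is deterministic); cyclically
conflicting page orders raise an error naming the cycle. Cells a page lacks
are explicit `None` — the matrix's purpose is to show where the data have
gaps before a tree is attempted.

`make_hierarchy_tree` requires an explicit missing-rank policy; there is no
default because the right choice (drop incomplete taxa vs. drop patchy
ranks) depends on the question. After the policy is applied the matrix must
be complete and non-empty. Construction is a prefix merge: paths are
inserted into a trie keyed by the *full* path prefix, so clades sharing
names through rank r share one node — and homonyms (the same genus name
under different kingdoms) remain distinct nodes, which matters whenever
plant and animal lineages are mixed. Rows whose retained-rank paths
coincide (two congeners after the species rank was dropped) merge into one
terminal with a warning; the tip label is the deepest retained cell.

Branch lengths are 1.0 per rank step. Monotypic (unary) chains are
collapsed: the surviving node's edge sums the collapsed steps, preserving
root-to-tip rank distance, and the collapsed clade names are retained on
the node, most-inclusive first, as edge-label candidates. If all paths
share a top prefix, the deepest shared node becomes the root and the names
above it are kept on the root (they have no edge); if the top ranks
disagree — as in any cross-kingdom set — a synthetic root labeled `root`
joins them. Siblings are sorted alphabetically, making every output
byte-deterministic and invariant to input order.

`make_edge_labels` maps, for each non-root node, its candidate chain to the
edge above it: `recent` keeps the least-inclusive name, `oldest` the
most-inclusive, `all` the ordered list. These semantics are this package's
pinned definition of edge-label deduplication. A tree whose labels do not
occur in the supplied matrix is rejected as inconsistent.

Newick output writes internal labels and (optionally) branch lengths,
quoting labels that contain characters outside `[A-Za-z0-9_.-]`;
`parse_newick` is built over dendropy and inverts the writer on its image.
The independent check of the whole construction is a brute-force pairwise
path-merge oracle (nested-dict trie, then canonicalization that collapses
chains and sorts siblings) that shares no code with the builder; the two
agree, label-for-label and length-for-length, on seeded random taxonomies
up to 8 ranks and 30 tips.

## The synthetic-data generator

`random_taxonomy(seed, n_tips, n_ranks, missing_prob)` grows a
classification by random attachment: each new terminal copies a random
existing path up to a uniformly chosen depth and continues with fresh
names, so shared ancestors and nontrivial topology arise naturally. Ranks
use the Linnaean series (kingdom … subspecies) up to 8 levels. Each
non-terminal rank of each taxon is independently missing with probability
`missing_prob`; the terminal rank is always present, since a terminal
without its own name is not a usable row. Names are globally unique by
construction, so generated taxonomies contain no homonyms (homonym handling
is exercised by the hand-built worked examples instead). Everything is
driven by one `random.Random(seed)` stream and is exactly reproducible.

`random_page_spec` / `random_hier_spec` sample valid page and
classification specs (scores in [0,100], unique object and entry ids,
non-ASCII text included) for the round-trip and conservation suites.

The packaged worked-example registry hand-encodes: the bear genus page
(id 14349) with classification entries from two providers (synonyms only on
the second — provider coverage genuinely differs); the polar bear with a
Vulnerable status; six "bear" taxa with NCBI-style kingdom→species
lineages, the two plants lacking an order-level ancestor so the tree-data
matrix exhibits real missing cells; and five invasive species with French
vernacular names and provider synonyms, including one species with none of
either. Page ids other than 14349 are arbitrary fixture identifiers.

**What the generator does not emulate:** real provider pages have
inconsistent rank vocabularies across providers, occasional duplicate
names, authority-qualified synonyms, and far richer media metadata; the
live service adds ranking heuristics to fuzzy search that are not
reproducible offline (the offline rule is: exact normalized matches first,
then case-insensitive substring matches, ties by ascending page id).
Passing tests therefore demonstrate correctness of parsing, tabulation and
tree construction on dialect-conformant input, not robustness to the full
messiness of live data.

## Problem sizes and tolerances

The property suites use 100 random taxonomies (2–30 tips, 2–8 ranks) for
oracle equivalence, 200 random specs/trees for round-trips, 40-page sets
for conservation checks, and 20 taxonomies at `missing_prob = 0.3` for the
policy checks; these sizes exercise every code path (shared prefixes,
collapsed chains, synthetic roots, empty sections, non-ASCII text) while
keeping the whole suite under a few seconds. The only floating-point
tolerance in the package's checks is 1e-12 on the mean of relative
richness; everything else is exact (integer counts, string equality,
canonical-form equality).

## Known limitations

* Only the pinned v1.0 XML dialect is supported; the current live API is
  deliberately out of scope.
* Exact matching is by normalized whole string; there is no fuzzy/phonetic
  reconciliation across providers.
* `drop_taxa` and `drop_ranks` are global policies; per-clade mixtures
  (drop species here, drop subspecies there) are not offered.
* Trees are rank-step dendrograms, not ultrametric or time-scaled.
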