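# eolkit

`eolkit` harvests Encyclopedia-of-Life-style XML taxon pages, extracts
tabular biodiversity data, and turns provider classification hierarchies
into taxonomic dendrograms.

It is written for researchers who want programmatic answers to questions
like *how much information is available about my group of interest?*, *what
are the vernacular names and taxonomic synonyms of these species?*, or *what
does the shared classification of an arbitrary set of taxa look like as a
tree?* — without copy-pasting from a website. Every step is scriptable, so a
batch workflow can be rerun at any time.

## What it does

* **Download** (v1.0 XML dialect): taxon pages by numeric page id, by
  searched name (exact or fuzzy matching), or provider classification pages
  ("hierarchy entries"). The HTTP transport is pluggable; a packaged
  **offline fixture registry** serves the same dialect with no network,
  which is how the entire test suite runs.
* **Extract** tables: the 0–100 content-richness score (parsed, never
  computed locally), media-object overviews, vernacular names per language,
  references, IUCN conservation status codes
  (NA/NE/DD/LC/NT/VU/EN/CR/EW/EX), provider coverage counts, taxonomic
  synonyms, parentage and offspring. Tables are pandas DataFrames; CSV/TSV
  writers render missing values as `NA`.
* **Standardize** richness by the group mean (`relative_richness`), so 1.0
  means "an average page for this group".
* **Build trees**: `make_tree_data` assembles a taxon × rank matrix (with
  explicit missing cells where a provider's classification has gaps);
  `make_hierarchy_tree` prefix-merges the root-to-tip paths into a rooted
  dendrogram with one unit of branch length per rank step, collapsing
  monotypic chains; `make_edge_labels` maps clade names onto edges;
  `write_newick`/`parse_newick` give deterministic Newick IO;
  `match_data_to_tree_tips` reorders any per-taxon table to tip order for
  plotting.

Because classification gaps are common, tree building requires an explicit
missing-rank policy: `drop_taxa` (keep only fully classified taxa),
`drop_ranks` (keep only ranks known for every taxon — e.g. a genus-level
tree), or `error`.

## Worked example

The packaged registry contains a bear-genus page (id 14349), six taxa that
share nothing but the word "bear" — polar bear, koala, water bear (a
tardigrade), bear grass, bear's breeches and the woolly bear moth — and
five invasive species with French vernacular names.

```python
import eolkit as ek
from eolkit import fixtures as fx

transport = ek.make_offline_transport(ek.build_worked_example_registry())

pages = ek.download_searched_taxa(["Ursus"], transport, exact=True)
print(ek.get_richness_scores(pages).to_string(index=False))
```

```
taxon_name  eol_page_id  richness_score
     Ursus        14349            87.5
```

The score says the genus page is content-rich (87.5 of 100). Downloading
the page by its id, `ek.download_eol_pages([14349], transport)`, returns
the identical parsed page. Following the NCBI classification entry gives
the parentage table:

```python
hset = ek.download_hierarchy(pages, "NCBI Taxonomy", transport)
print(ek.taxon_parents(next(iter(hset))).to_string(index=False))
```

```
   rank      name entry_id
kingdom  Animalia     None
 phylum  Chordata     None
  class  Mammalia     None
  order Carnivora     None
 family   Ursidae     None
```

Building the "bears" dendrogram:

```python
bears = ek.download_searched_taxa(list(fx.BEAR_LINEAGES), transport, exact=True)
hier = ek.download_hierarchy(bears, "NCBI Taxonomy", transport)
data = ek.make_tree_data(hier)
print(sorted(data.missing_cells()))
tree = ek.make_hierarchy_tree(data, "drop_ranks")
print(ek.write_newick(tree, branch_lengths=False))
```

```
[('Acanthus mollis', 'order'), ('Xerophyllum tenax', 'order')]
(('Echiniscus capillatus',('Phascolarctos cinereus','Ursus maritimus')Mammalia,'Pyrrharctia isabella')Animalia,('Acanthus mollis','Xerophyllum tenax')Tracheophyta)root;
```

The two plant lineages lack an order-level ancestor, so `drop_ranks`
discards the order rank and keeps all six tips; the root splits plants from
animals, and the two mammals (polar bear, koala) group inside Animalia.

The same pipelines are available from the shell:

```bash
$ eolkit search "Ursus maritimus" --exact --offline
query_name,matched_name,eol_page_id
Ursus maritimus,Ursus maritimus,328581
```

Subcommands: `search`, `download`, `extract
{richness|objects|names|refs|iucn|providers}`, `hierarchy
{synonyms|parents|children|match}`, `tree {data|build|labels|match-tips}`,
`fixtures {generate|registry}`. For live use, set an API key in
`EOL_API_KEY`; offline mode needs none.

## Scope

Live queries against the real eol.org service are out of scope (the public
API has moved on from the dialect implemented here); so are plotting,
authenticated accounts, media payload download, and computing the richness
score itself (a server-side composite that this package only parses).
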