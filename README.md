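# metadepot

Headless management of metagenomic project data: import and validate
four-file project archives, resolve taxonomic assignments through an
accession cache with first-common-ancestor summarization, answer combined
faceted queries over samples, sequences and assignments, aggregate
per-taxon count trees, and export any selection as a re-importable archive,
a FASTA subset, or a BIOM table.

It is aimed at labs that accumulate heterogeneous sequence-centric datasets
— shotgun contigs with per-sample read-recruitment counts as well as
metabarcoding OTU/ASV representatives with abundance tables — and want one
indexed, queryable repository for all of them, driven from Python or the
shell rather than a web GUI.

## Data model

The unit of exchange is a zip archive with four member roles:

| role | content |
| --- | --- |
| `samples` | tab-delimited metadata; `sample_name`, `collection_date`, `lat_lon` (the three standard BioSample attributes) plus any user columns |
| `composition` | sequence × sample numeric contributions (read counts or abundances), wide or long layout |
| `sequences` | FASTA with one nucleotide record per sequence |
| `assignments` | per-sequence taxonomic assignment lines: a method, either an explicit `taxonomy_id` or a CSV list of reference accessions, an optional `best_hit` flag, and any user columns |

A sequence originates from ≥1 samples (a contig may recruit reads from
several) and carries ≥0 assignments; sequences without assignments are
stored in a separate *unassigned* partition and are not searchable. Every
metadata column is registered in a dynamic field registry with an inferred
type (text / number / date / taxon / geo), which drives both filtering and
the facet widget choice (plain value list up to 1,000 distinct values,
autocompletion beyond).

## Taxon resolution

Assignments referencing accessions are resolved cache-first against an
accession→taxid table (sources ranked `USER > SILVA > NCBI`); misses go to a
pluggable batch resolver and the results — including failures — are cached.
For a row with accessions mapping to taxa t₁…tₖ in a rooted taxonomy, the
stored taxon is the first (lowest) common ancestor

    lca(t₁,…,tₖ) = argmax_{a ∈ ⋂ᵢ anc(tᵢ)} depth(a),

where `anc(t)` is the root path of `t`. Rows whose lookups all failed remain
pending; a retry pass re-queries exactly those and persists what it
recovers.

For taxonomy views (count tree, Krona rows) each sequence must map to one
taxon, so queries are normalized: a method is fixed when several are
present, and the best-hit restriction is switched on when sequences carry
multiple assignments. Under the normalized query the identity

    table total (sequence grouping) = Σ per-taxon exact counts = Σ Krona row counts

holds exactly; the test suite and the acceptance script verify it on
hundreds of randomized queries.

## Worked example

```python
from metadepot import Store, query as q
from metadepot.fixtures import FixtureSpec, make_archive, make_taxonomy
from metadepot.taxonomy import TableResolver

tax, parents = make_taxonomy(depth=6, branching=2, out_dir="demo")
archive, ledger = make_archive(
    FixtureSpec(seed=11, n_samples=6, n_sequences=40, n_methods=2), tax, parents)

db = Store("demo/depot")
db.attach_taxonomy(tax)
report = db.import_project(archive, "demo",
                           resolver=TableResolver(ledger["accession2taxid"]))
```

The import report prints `40` sequences, `28` assigned and `12` unassigned
— the partition that decides which sequences are searchable. Querying with
combined filters:

```python
page = q.run_query(db, q.Query(["demo"], [
    q.Categorical("host", ["bovine"]),
    q.NumericRange("length", 200, None),
    q.TaxonFilter([2]),           # one superkingdom, descendants included
]))
print(page.total_count)           # -> 6
```

`6` is the number of assigned sequences at least 200 bp long, assigned
within taxon 2's subtree, with at least one contributing sample whose host
is `bovine`. The taxonomy views agree with the table by construction:

```python
tree = q.taxon_count_tree(db, q.Query(["demo"]), method="blastn")
sum(n.count for n in tree.walk())  # -> 23, equal to the normalized
                                   #    table total and the Krona row sum
```

The scripts in `examples/` run these flows end to end (import/explore,
taxonomy views, exports) and print the conservation checks; the `metadepot`
command exposes the same operations from the shell (`metadepot --help`).

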