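# Methods

This note records the model behind metadepot, the semantics the query
engine guarantees, the numerical and design choices that were genuinely
open, and what the synthetic fixtures do and do not establish.

## Entities and storage

The central entity is the **sequence** (a shotgun contig, a singleton read,
or an OTU/ASV representative). Each sequence belongs to one project,
originates from ≥1 **samples** through numeric contributions (read
recruitment counts or relative abundances — both are accepted; values are
stored as floats and never rescaled), and carries ≥0 **assignments**
(method, accession list and/or explicit taxid, optional best-hit flag, user
fields). Sequences with zero assignments form the *unassigned* partition:
they are kept, exportable and retrievable, but excluded from exploration.
The two partitions are disjoint and exhaustive by construction — `assigned`
is a stored flag updated whenever assignments are appended.

Storage is a single sqlite database per store plus one indexed FASTA per
project (pyfaidx `.fai`), so residues never enter the database and any
record is served by a seek. Reference data shared by every project —
the taxonomy and the accession cache — live in the same file in their own
tables. All user metadata values are additionally written to typed
side tables (`sample_fields`, `assignment_fields`) carrying `vtext`,
`vnum` and `vdate` columns with one index per type; every filter the query
engine emits resolves through those indexes (or through indexed builtin
columns), not through full scans. Samples are global to the store, keyed by
`sample_name`, each carrying the set of projects it appears in; re-importing
a known sample with different metadata is a hard error rather than a silent
overwrite, because there is no principled way to pick a winner.

Imports are atomic: every referential and typing check runs before
anything is written, database writes happen in one transaction, and the
per-project FASTA is restored from a backup if the transaction fails.

## Field registry and type inference

Every metadata column is registered as `(name, entity, dtype)` with the set
of projects using it and, for text fields, a maintained distinct-value
count. Inference is deliberately simple: a column is `number` if every
non-empty value parses as a float, else `date` if every non-empty value is
ISO-8601 at year, month or day precision, else `text`. The three standard
sample attributes are fixed (`collection_date` date, `lat_lon` geo), the
sequence length is a number, and the assignment taxonomy is its own `taxon`
type. A new project whose column contradicts the registered type is
rejected (`ConflictingFieldType`): silently demoting to text would make
previously valid range queries start missing rows.

The facet widget for a text field switches from an enumerated value list to
autocompletion above 1,000 distinct values; number and date fields expose
observed min/max bounds, the taxonomy field a tree selector, the location
field a bounding box. The threshold is a constant of the exploration
contract, not a tunable.

## Taxon resolution

The accession cache maps canonical accessions (uppercased, version suffix
stripped, so `AB123456.1` and `AB123456.2` hit the same entry) to taxids
with a source tag. Precedence is `USER > SILVA > NCBI` and is
order-independent: an entry is replaced only by an equal- or higher-ranked
source, with one exception — a resolved entry always replaces an unresolved
marker, which is what lets the retry pass repair old failures regardless of
source rank.

Resolution of one assignment row: an explicit `taxonomy_id` wins (validated
against the taxonomy, `merged.dmp` remap applied); otherwise accessions are
looked up cache-first and the misses go to the resolver in one deduplicated
batch per import. One resolved accession yields its taxid; several yield
the first common ancestor of their taxa, computed as the deepest node on
the intersection of root paths. Accessions whose taxid is absent from the
loaded taxonomy are skipped with a warning rather than guessed at (offline
taxonomies lag the reference one); if nothing resolves, the assignment is
stored without a taxon and a retry pass (`retry_unresolved`) re-queries
exactly the unresolved cache entries later. Ordinary imports never re-query
a cached failure — only the retry pass does — so a flaky resolver cannot
make imports quadratic.

## Query semantics

A query is a conjunction of typed filters over selected projects, evaluated
at three grouping levels with fixed semantics:

* an assignment matches iff it passes all assignment-level filters (taxon
  membership by subtree expansion, method, best-hit, user fields);
* a sequence matches iff it is assigned, passes sequence-level filters, has
  ≥1 matching assignment (vacuously true without assignment filters), and
  has ≥1 contribution from a sample passing all sample-level filters — the
  existential reading, so a contig assembled from several samples surfaces
  if any of its sources is selected;
* a sample matches iff it passes sample-level filters and contributes to ≥1
  matching sequence.

Dates compare at day resolution: filter bounds snap partial dates to the
interval start (min side) or end (max side), and a record's partial date is
represented by its first covered day. Geographic boxes crossing the
antimeridian (`lon_min > lon_max`) split into two half-boxes; a box covering
the whole globe is treated as "no restriction drawn", so samples without
coordinates still match it — any smaller box excludes them. Sorting is
stable with the record identifier as the final tie-break, making pagination
reproducible.

### Count consistency

Taxonomy views need exactly one taxon per sequence. `effective_query_for_
taxonomy_views` normalizes a query exactly as an exploration GUI would:
if the selected projects use more than one assignment method and none is
filtered, the caller must pick one (a lone assignment per (sequence,
method) group is promoted to implicit best hit at import time, so the
best-hit restriction is always satisfiable); if any sequence carries
several assignments and the best-hit restriction is off, it is switched
on. Under the normalized query, each matching sequence has exactly one
designated assignment, and

    table total = Σ exact per-taxon counts = Σ Krona row counts.

A designated assignment whose taxon is still unresolved (pending retry)
would break this identity, so the count tree groups such sequences under a
synthetic "Unclassified" node (taxid 0) directly below the root; the
identity then holds unconditionally. Both exact and cumulative (self +
descendants) counts are exposed per node.

## Exports

The native export restricts the archive to matching sequences, matching
samples, the contributions linking the two, and the filter-surviving
assignments; resolved taxa are written back as explicit `taxonomy_id`
values next to the original accessions so re-import needs no resolver.
Sequence ids must be globally unique across the selected projects because
the archive format carries no project column; the fixture generator
prefixes ids per project, and a collision raises instead of silently
merging.

BIOM export projects each designated taxon onto the seven canonical ranks
(superkingdom/kingdom, phylum, class, order, family, genus, species; first
occurrence walking from the taxon toward the root wins) and additionally
stores `full_taxonomy`, the complete root-exclusive name path joined with
";", preserving ranks beyond the canonical seven (virus classification
routinely has them). Sequences without a resolved taxon are excluded from
BIOM — there is nothing to project — with the exclusion count reported;
they are still present in native exports. The JSON flavor is the default
(BIOM 1.0, sparse); HDF5 (BIOM 2.1, CSR + CSC) sits behind a flag. Both
writers are implemented here; the JSON dialect is cross-checked in the test
suite against the Bioconductor `biomformat` reader.

Materialized exports are written under random hex tokens with a JSON
registry for listing and atomic cleanup — the headless counterpart of
share-by-URL downloads.

## Synthetic fixtures

The generator emulates the *shape* of real imports: multi-line assignments,
CSV accession lists with version suffixes, an unassigned fraction (floor +
largest-remainder split, so 0.7 of 10 is exactly 7), a sample without
coordinates, month-precision dates, integer read counts or decimal
abundances, and congeneric multi-accession rows drawn from one subtree so
LCAs land at interior nodes. Taxonomies are complete b-ary trees with the
canonical ranks on levels 1–7 and "no rank" below. Everything derives from
one `random.Random(seed)`, and generated files (taxdump, archive zip,
mapping TSV) are byte-identical across runs; zip members carry a fixed
timestamp for that reason.

What the fixtures do **not** model: community ecology (no abundance
distributions), sequencing error, real accession formats, ragged or
polyphyletic taxonomies, or adversarial metadata. Passing tests therefore
demonstrate the correctness of the data management semantics — parsing,
resolution, querying, counting, exporting — not robustness to the full
messiness of public archives.

Ground-truth ledgers accompany every generated archive: per-row expected
taxa are computed inside the generator by an independent parent-walk (not
by the taxonomy module), so tests comparing stored taxa against the ledger
are genuine dual-route checks.

## Problem sizes and verification

The test suite exercises a 600-sequence, two-project, two-method store for
query-oracle equivalence (100 randomized filter conjunctions compared
against an exhaustive in-memory scan that shares no code with the SQL
engine), 50 randomized queries for the count-consistency identity, 20
selections for export round-trips, and a 9,841-node taxonomy with 10,000
random taxid sets for LCA-vs-brute-force agreement; the facet threshold is
checked at exactly 1,000 and 1,001 distinct values. The acceptance script
(`scripts/acceptance.py`) recomputes all of these from a command-line seed
and reports each measured value with its problem size.

## Known limitations

* One writer at a time per store (sqlite single-file locking); this mirrors
  the intended single-curator workflow.
* Cross-project export requires globally unique sequence ids.
* The live accession resolver (a web-service client) is out of scope by
  design; the interface is pluggable and the offline table resolver is the
  reference implementation.
* Similarity search and phylogenetic placement are not executed here: the
  FASTA export is the hand-off point, and their tabular results come back
  in through `append_assignments`.
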