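"""Taxon count trees, Krona text rows, and the count-consistency identity.

When several assignment methods (or several assignments per sequence) are
present, the taxonomy views need exactly one taxon per sequence. The query
normalizer injects a method choice and the best-hit restriction; after that
the table total, the count tree's summed exact counts and the Krona rows all
agree — the identity this example prints.
"""

import tempfile
from pathlib import Path

from metadepot import Store, query as q
from metadepot.fixtures import FixtureSpec, make_archive, make_taxonomy
from metadepot.taxonomy import TableResolver

work = Path(tempfile.mkdtemp(prefix="metadepot-example-"))
tax, parents = make_taxonomy(depth=6, branching=2, out_dir=work)
spec = FixtureSpec(seed=11, n_samples=6, n_sequences=40, n_methods=2)
archive, ledger = make_archive(spec, tax, parents)

db = Store(work / "depot")
db.attach_taxonomy(tax)
db.import_project(archive, "demo",
                  resolver=TableResolver(ledger["accession2taxid"]))

base = q.Query(["demo"])
normalized = q.effective_query_for_taxonomy_views(db, base, method="blastn")
print("normalization injected:",
      [type(f).__name__ for f in normalized.filters])

table_total = q.run_query(db, normalized).total_count
tree = q.taxon_count_tree(db, base, method="blastn")
tree_total = sum(node.count for node in tree.walk())
krona = q.krona_rows(tree)
print(f"table total={table_total}  tree exact-count sum={tree_total}  "
      f"krona sum={sum(c for c, _ in krona)}  (all must be equal)")

print("\ntop of the count tree (exact / cumulative sequences per taxon):")


def show(node, depth=0, budget=[8]):
    if budget[0] <= 0:
        return
    budget[0] -= 1
    print(f"  {'  ' * depth}{node.name} [{node.rank}] "
          f"{node.count}/{node.cumulative}")
    for child in node.children:
        show(child, depth + 1, budget)


show(tree)

print("\nfirst Krona text rows (count, then root-to-taxon name path):")
for count, path in krona[:4]:
    print("  " + "\t".join([str(count), *path]))

print("\nsample map points (lat, lon, sample, matching sequences):")
for lat, lon, name, n in q.geo_points(db, base)[:4]:
    print(f"  {lat:8.3f} {lon:9.3f}  {name}  {n}")
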