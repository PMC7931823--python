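"""Faceted query engine: oracle equivalence, facets, taxonomy views."""

from __future__ import annotations

import random

import pytest

from metadepot import errors
from metadepot import query as q
from metadepot.fixtures import FixtureSpec, make_archive
from _oracle import DEFAULT_REGISTRY, QueryOracle, random_query


@pytest.fixture(scope="module")
def oracle(dual_store):
    db = dual_store["db"]
    return QueryOracle(db.iter_samples(), db.iter_sequences(),
                       db.iter_assignments(), dual_store["parents"],
                       DEFAULT_REGISTRY)


def _engine_sets(db, query):
    seq = {(r["project"], r["sequence_id"]) for r in q.run_query(
        db, q.Query(query.projects, query.filters, "sequence",
                    limit=None)).rows}
    smp = {r["sample_name"] for r in q.run_query(
        db, q.Query(query.projects, query.filters, "sample",
                    limit=None)).rows}
    asg = {r["id"] for r in q.run_query(
        db, q.Query(query.projects, query.filters, "assignment",
                    limit=None)).rows}
    return seq, smp, asg


# ---------------------------------------------------------------------------
# basic semantics
# ---------------------------------------------------------------------------

def test_no_filter_totals_match_ledger(dual_store):
    db = dual_store["db"]
    ledgers = dual_store["ledgers"]
    page = q.run_query(db, q.Query(["p1", "p2"]))
    expected = sum(len(l["assigned_ids"]) for l in ledgers.values())
    assert page.total_count == expected
    one = q.run_query(db, q.Query(["p1"]))
    assert one.total_count == len(ledgers["p1"]["assigned_ids"])


def test_unknown_project_and_field_rejected(dual_store):
    db = dual_store["db"]
    with pytest.raises(errors.UnknownProject):
        q.run_query(db, q.Query(["nope"]))
    with pytest.raises(errors.UnknownField):
        q.run_query(db, q.Query(["p1"], [q.Categorical("nope", ["x"])]))
    with pytest.raises(errors.TypeMismatch):
        q.run_query(db, q.Query(["p1"], [q.Categorical("evalue", ["x"])]))


@pytest.mark.parametrize("make_filter", [
    lambda v: q.Categorical("host", [v["hosts"][0]]),
    lambda v: q.NumericRange("length", 300, 700),
    lambda v: q.NumericRange("evalue", None, 40.0),
    lambda v: q.DateRange("collection_date", "2017", "2019-06"),
    lambda v: q.TaxonFilter([v["taxids"][1]]),
    lambda v: q.GeoBox(-10, 50, 0, 90),
    lambda v: q.GeoBox(-60, 60, 100, -100),   # antimeridian wrap
    lambda v: q.MethodFilter([v["methods"][0]]),
    lambda v: q.BestHitOnly(True),
])
def test_each_filter_variant_matches_oracle(dual_store, oracle, make_filter):
    db = dual_store["db"]
    vocab = {"hosts": ["bovine", "human"], "methods": ["blastn", "blastx"],
             "taxids": [2, 5]}
    query = q.Query(["p1", "p2"], [make_filter(vocab)])
    assert _engine_sets(db, query) == oracle.run(query)


def test_random_conjunctions_match_oracle(dual_store, oracle):
    db = dual_store["db"]
    rng = random.Random(7)
    vocab = {"projects": ["p1", "p2"], "hosts": ["bovine", "human", "maize"],
             "methods": ["blastn", "blastx"],
             "taxids": sorted(dual_store["tax"].nodes),
             "years": list(range(2015, 2022)),
             "lat_range": (-40, 60), "lon_range": (-30, 130)}
    for _ in range(50):
        query = random_query(rng, vocab)
        assert _engine_sets(db, query) == oracle.run(query), query


def test_adding_a_filter_never_increases_totals(dual_store):
    db = dual_store["db"]
    rng = random.Random(8)
    vocab = {"projects": ["p1", "p2"], "hosts": ["bovine", "human"],
             "methods": ["blastn", "blastx"],
             "taxids": sorted(dual_store["tax"].nodes),
             "years": list(range(2015, 2022)),
             "lat_range": (-40, 60), "lon_range": (-30, 130)}
    for _ in range(20):
        base = random_query(rng, vocab)
        extra = random_query(rng, vocab)
        if not extra.filters:
            continue
        wider = q.Query(base.projects, base.filters, base.grouping)
        narrower = q.Query(base.projects,
                           base.filters + extra.filters[:1], base.grouping)
        assert q.run_query(db, narrower).total_count <= \
            q.run_query(db, wider).total_count


def test_grouping_coherence(dual_store):
    """Samples in a sample-grouped result contribute to sequences of the
    sequence-grouped result of the same query, and vice versa."""
    db = dual_store["db"]
    query = q.Query(["p1", "p2"], [q.NumericRange("length", 300, None)])
    seqs, samples, _ = _engine_sets(db, query)
    contribs = {}
    for s in db.iter_sequences():
        contribs[(s["project"], s["sequence_id"])] = set(s["contributions"])
    assert all(any(name in contribs[key] for key in seqs)
               for name in samples)
    assert all(contribs[key] & samples for key in seqs)


def test_pagination_is_stable_and_total_invariant(dual_store):
    db = dual_store["db"]
    base = q.Query(["p1", "p2"], sort="length")
    full = q.run_query(db, q.Query(["p1", "p2"], sort="length", limit=None))
    paged = []
    for offset in range(0, full.total_count, 17):
        page = q.run_query(db, q.Query(["p1", "p2"], sort="length",
                                       offset=offset, limit=17))
        assert page.total_count == full.total_count
        paged.extend(page.rows)
    assert paged == full.rows


# ---------------------------------------------------------------------------
# facets
# ---------------------------------------------------------------------------

def test_facet_widgets_by_dtype(dual_store):
    db = dual_store["db"]
    host = q.facet_spec(db, "host")
    assert host.widget == "enumerated_list"
    assert host.payload == sorted(set(host.payload))
    num = q.facet_spec(db, "evalue")
    assert num.widget == "numeric_range"
    lo, hi = num.payload
    assert 0 <= lo <= hi <= 100
    date = q.facet_spec(db, "collection_date")
    assert date.widget == "date_range"
    assert date.payload[0] <= date.payload[1]
    assert q.facet_spec(db, "taxonomy").widget == "taxonomy_tree"
    geo = q.facet_spec(db, "lat_lon")
    assert geo.widget == "geo_map"
    lat_min, lat_max, lon_min, lon_max = geo.payload
    assert -90 <= lat_min <= lat_max <= 90
    with pytest.raises(errors.UnknownField):
        q.facet_spec(db, "no_such_field")


def test_distinct_values_prefix_union_equals_full_set(dual_store):
    db = dual_store["db"]
    full = set(q.distinct_values(db, "host", "", None))
    assert full
    prefixes = {v[0] for v in full}
    union = set()
    for p in prefixes:
        union |= set(q.distinct_values(db, "host", p, None))
    assert union == full
    assert q.distinct_values(db, "host", "zz") == []
    # case-insensitive prefix
    sample = sorted(full)[0]
    assert sample in q.distinct_values(db, "host", sample[0].upper(), None)


# ---------------------------------------------------------------------------
# taxonomy-view normalization + count consistency
# ---------------------------------------------------------------------------

def test_effective_query_injects_method_and_besthit(dual_store):
    db = dual_store["db"]
    base = q.Query(["p1", "p2"])
    with pytest.raises(errors.AmbiguousMethod):
        q.effective_query_for_taxonomy_views(db, base)
    nq = q.effective_query_for_taxonomy_views(db, base, "blastn")
    kinds = {type(f) for f in nq.filters}
    assert q.MethodFilter in kinds and q.BestHitOnly in kinds
    # idempotent on an already-constrained query
    assert q.effective_query_for_taxonomy_views(db, nq, "blastn") is nq


def test_effective_query_single_method_unchanged(fresh_store, small_tax):
    from metadepot.taxonomy import TableResolver

    spec = FixtureSpec(seed=61, n_sequences=10, n_methods=1, id_prefix="m1")
    archive, ledger = make_archive(spec, small_tax["tax"],
                                   small_tax["parents"])
    db = fresh_store
    db.import_project(archive, "solo", {}, "create",
                      TableResolver(ledger["accession2taxid"]))
    base = q.Query(["solo"])
    nq = q.effective_query_for_taxonomy_views(db, base)
    assert not any(isinstance(f, q.MethodFilter) for f in nq.filters)


def test_count_consistency_table_vs_tree_vs_krona(dual_store):
    """The identity that makes the table and taxonomy views agree."""
    db = dual_store["db"]
    for method in ("blastn", "blastx"):
        query = q.Query(["p1", "p2"])
        nq = q.effective_query_for_taxonomy_views(db, query, method)
        table_total = q.run_query(db, nq).total_count
        tree = q.taxon_count_tree(db, query, method)
        assert sum(n.count for n in tree.walk()) == table_total
        assert tree.cumulative == table_total
        rows = q.krona_rows(tree)
        assert sum(c for c, _ in rows) == table_total
        assert len(rows) == sum(1 for n in tree.walk() if n.count > 0)


def test_tree_counts_match_ledger_best_hits(dual_store):
    """Exact per-taxon counts equal the ledger's designated best-hit taxa."""
    db = dual_store["db"]
    tree = q.taxon_count_tree(db, q.Query(["p1"]), "blastn")
    got = {n.taxid: n.count for n in tree.walk() if n.count > 0}
    expected: dict[int, int] = {}
    for seq, methods in dual_store["ledgers"]["p1"][
            "expected_best_taxid"].items():
        if "blastn" in methods:
            t = methods["blastn"]
            expected[t] = expected.get(t, 0) + 1
    assert got == expected


def test_cumulative_counts_are_subtree_sums(dual_store):
    db = dual_store["db"]
    tree = q.taxon_count_tree(db, q.Query(["p1", "p2"]), "blastn")
    for node in tree.walk():
        assert node.cumulative == sum(n.count for n in node.walk())


def test_krona_reaggregation_reproduces_cumulative(dual_store):
    db = dual_store["db"]
    tree = q.taxon_count_tree(db, q.Query(["p1", "p2"]), "blastx")
    rows = q.krona_rows(tree)
    # bottom-up re-aggregation: a node's cumulative count is the sum of row
    # counts whose path passes through the node's name path
    by_name_path = {}

    def collect(node, path):
        here = path + (node.name,) if node is not tree else ()
        by_name_path[here] = node
        for c in node.children:
            collect(c, here)

    collect(tree, ())
    for path, node in by_name_path.items():
        agg = sum(c for c, p in rows if p[:len(path)] == path)
        assert agg == node.cumulative, (path, node)


def test_empty_result_tree(dual_store):
    db = dual_store["db"]
    query = q.Query(["p1"], [q.NumericRange("length", 10_000, None)])
    assert q.taxon_count_tree(db, query, "blastn") is None
    assert q.krona_rows(None) == []


def test_unresolved_best_hits_grouped_under_unclassified(fresh_store,
                                                         bundle):
    from metadepot.taxonomy import NullResolver

    db = fresh_store
    db.import_project(bundle["archive"], "p1", {}, "create", NullResolver())
    query = q.Query(["p1"])
    for method in bundle["ledger"]["methods"]:
        tree = q.taxon_count_tree(db, query, method)
        if tree is None:
            continue
        nq = q.effective_query_for_taxonomy_views(db, query, method)
        assert sum(n.count for n in tree.walk()) == \
            q.run_query(db, nq).total_count
        assert any(n.taxid == q.UNCLASSIFIED_TAXID for n in tree.walk())


# ---------------------------------------------------------------------------
# geo points
# ---------------------------------------------------------------------------

def test_geo_points_match_brute_force(dual_store, oracle):
    db = dual_store["db"]
    query = q.Query(["p1", "p2"], [q.NumericRange("length", 250, None)])
    points = q.geo_points(db, query)
    seqs, samples, _ = oracle.run(query)
    with_coords = {s["sample_name"] for s in db.iter_samples()
                   if s["lat_lon"] is not None}
    assert {p[2] for p in points} == samples & with_coords
    assert len(points) <= q.run_query(
        db, q.Query(query.projects, query.filters, "sample")).total_count
    contribs = {}
    for s in db.iter_sequences():
        contribs[(s["project"], s["sequence_id"])] = set(s["contributions"])
    for lat, lon, name, count in points:
        expected = sum(1 for key in seqs if name in contribs[key])
        assert count == expected
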