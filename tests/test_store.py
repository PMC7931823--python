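"""Persistent store: import, partitioning, registry, retry, delete."""

from __future__ import annotations

import random

import pytest

from metadepot import errors
from metadepot.fixtures import FixtureSpec, make_archive
from metadepot.formats import AssignmentRow
from metadepot.store import Store, infer_dtype
from metadepot.taxonomy import NullResolver, TableResolver


def _counts(db: Store) -> dict:
    s = db.stats()
    return {k: s[k] for k in ("projects", "samples", "sequences_assigned",
                              "sequences_unassigned", "assignments",
                              "fields")}


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def test_import_partitions_sequences(loaded_store):
    """Sequences split into exactly the assigned/unassigned categories."""
    db, ledger, report = loaded_store
    assert report.sequences_assigned == len(ledger["assigned_ids"])
    assert report.sequences_unassigned == len(ledger["unassigned_ids"])
    assert report.sequences_total == ledger["n_sequences"]
    flags = {r[0] for r in db.conn.execute(
        "SELECT DISTINCT assigned FROM sequences")}
    assert flags <= {0, 1}
    assigned = {s["sequence_id"] for s in db.iter_sequences()
                if s["assigned"]}
    assert assigned == set(ledger["assigned_ids"])


def test_import_resolves_taxa_to_ledger_expectations(loaded_store):
    db, ledger, _ = loaded_store
    stored = {}
    for a in db.iter_assignments():
        stored.setdefault(a["sequence_id"], []).append(a)
    by_seq: dict[str, list] = {}
    for row in ledger["assignments"]:
        by_seq.setdefault(row["sequence_id"], []).append(row)
    for seq, expected_rows in by_seq.items():
        got = sorted(stored[seq], key=lambda a: a["ordinal"])
        assert [a["taxid"] for a in got] == \
            [r["expected_taxid"] for r in expected_rows]


def test_duplicate_project_rejected(loaded_store, bundle):
    db, _, _ = loaded_store
    with pytest.raises(errors.DuplicateProject):
        db.import_project(bundle["archive"], "p1")


def test_append_adds_exactly_new_sequences(fresh_store, small_tax):
    spec1 = FixtureSpec(seed=31, n_sequences=15, id_prefix="x1")
    spec2 = FixtureSpec(seed=32, n_sequences=5, n_samples=4, id_prefix="x2")
    a1, l1 = make_archive(spec1, small_tax["tax"], small_tax["parents"])
    a2, l2 = make_archive(spec2, small_tax["tax"], small_tax["parents"])
    db = fresh_store
    db.import_project(a1, "proj", {}, "create",
                      TableResolver(l1["accession2taxid"]))
    before = db.stats()
    db.import_project(a2, "proj", {}, "append",
                      TableResolver(l2["accession2taxid"]))
    after = db.stats()
    total = lambda s: s["sequences_assigned"] + s["sequences_unassigned"]
    assert total(after) - total(before) == 5


def test_append_duplicate_sequence_is_atomic(fresh_store, small_tax, bundle):
    db = fresh_store
    ledger = bundle["ledger"]
    db.import_project(bundle["archive"], "proj", {}, "create",
                      TableResolver(ledger["accession2taxid"]))
    before = _counts(db)
    dup, _ = make_archive(FixtureSpec(seed=11, n_sequences=3),
                          small_tax["tax"], small_tax["parents"])
    with pytest.raises(errors.DuplicateSequence):
        db.import_project(dup, "proj", {}, "append")
    assert _counts(db) == before


def test_conflicting_sample_metadata_rejected(fresh_store, small_tax):
    spec = FixtureSpec(seed=41, n_sequences=8, id_prefix="y1")
    archive, ledger = make_archive(spec, small_tax["tax"],
                                   small_tax["parents"])
    db = fresh_store
    db.import_project(archive, "one", {}, "create",
                      TableResolver(ledger["accession2taxid"]))
    spec2 = FixtureSpec(seed=41, n_sequences=8, id_prefix="y2")
    other, l2 = make_archive(spec2, small_tax["tax"], small_tax["parents"])
    # same sample names (same seed) but mutated metadata
    for rec in other.sample_table:
        rec.sample_name = rec.sample_name.replace("y2", "y1")
    other.composition.entries = {
        (seq, smp.replace("y2", "y1")): v
        for (seq, smp), v in other.composition.entries.items()}
    other.sample_table[0].extra["host"] = "something else entirely"
    with pytest.raises(errors.ConflictingSampleMetadata):
        db.import_project(other, "two", {}, "create",
                          TableResolver(l2["accession2taxid"]))


def test_shared_sample_gains_project(fresh_store, small_tax):
    spec = FixtureSpec(seed=41, n_sequences=8, id_prefix="y1")
    archive, ledger = make_archive(spec, small_tax["tax"],
                                   small_tax["parents"])
    db = fresh_store
    resolver = TableResolver(ledger["accession2taxid"])
    db.import_project(archive, "one", {}, "create", resolver)
    spec2 = FixtureSpec(seed=41, n_sequences=8, id_prefix="y2")
    other, l2 = make_archive(spec2, small_tax["tax"], small_tax["parents"])
    for rec in other.sample_table:  # identical metadata, shared names
        rec.sample_name = rec.sample_name.replace("y2", "y1")
    other.composition.entries = {
        (seq, smp.replace("y2", "y1")): v
        for (seq, smp), v in other.composition.entries.items()}
    db.import_project(other, "two", {}, "create",
                      TableResolver(l2["accession2taxid"]))
    sample = db.iter_samples()[0]
    assert sample["projects"] == {"one", "two"}


def test_missing_taxonomy_blocks_assigned_import(tmp_path, bundle):
    db = Store(tmp_path / "empty")
    with pytest.raises(errors.NoTaxonomy):
        db.import_project(bundle["archive"], "p")


# ---------------------------------------------------------------------------
# dtype inference + field registry
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("values,expected", [
    (["1", "2.5", ""], "number"),
    (["1e-30", "0.2"], "number"),
    (["2019-01-01", "2020-06"], "date"),
    (["2019-01-01", "abc"], "text"),
    (["1", "abc"], "text"),
    (["", "x"], "text"),
])
def test_infer_dtype(values, expected):
    assert infer_dtype(values) == expected


def test_field_registry_is_sound(loaded_store):
    """Every stored field has one descriptor; distinct counts match a
    brute-force scan of the raw dumps."""
    db, ledger, _ = loaded_store
    registry = {(d.name, d.entity): d for d in db.field_registry()}
    sample_fields = {k for s in db.iter_samples() for k in s["extra"]}
    for name in sample_fields:
        assert (name, "sample") in registry
    asg_fields = {k for a in db.iter_assignments() for k in a["extra"]}
    for name in asg_fields:
        assert (name, "assignment") in registry
    for (name, entity), desc in registry.items():
        if desc.dtype != "text":
            continue
        if entity == "sample":
            values = {s["extra"].get(name) for s in db.iter_samples()}
        elif name == "method":
            values = {a["method"] for a in db.iter_assignments()}
        else:
            values = {a["extra"].get(name) for a in db.iter_assignments()}
        values.discard(None)
        assert desc.distinct_count == len(values), (name, entity)


def test_conflicting_field_type_rejected(fresh_store, small_tax):
    db = fresh_store
    spec = FixtureSpec(seed=51, n_sequences=6, id_prefix="z1",
                       sample_fields=(("depth_m", "number", 0),))
    a1, l1 = make_archive(spec, small_tax["tax"], small_tax["parents"])
    db.import_project(a1, "one", {}, "create",
                      TableResolver(l1["accession2taxid"]))
    spec2 = FixtureSpec(seed=52, n_sequences=6, id_prefix="z2",
                        sample_fields=(("depth_m", "text", 3),))
    a2, l2 = make_archive(spec2, small_tax["tax"], small_tax["parents"])
    with pytest.raises(errors.ConflictingFieldType):
        db.import_project(a2, "two", {}, "create",
                          TableResolver(l2["accession2taxid"]))


# ---------------------------------------------------------------------------
# append_assignments
# ---------------------------------------------------------------------------

def test_append_assignments_migrates_partition(loaded_store):
    db, ledger, _ = loaded_store
    target = ledger["unassigned_ids"][0]
    before = db.stats()
    n = db.append_assignments("p1", [
        AssignmentRow(target, "pplacer", [], taxonomy_id=3, best_hit=True)])
    assert n == 1
    after = db.stats()
    assert after["sequences_unassigned"] == before["sequences_unassigned"] - 1
    assert after["sequences_assigned"] == before["sequences_assigned"] + 1
    assert after["sequences_assigned"] + after["sequences_unassigned"] == \
        before["sequences_assigned"] + before["sequences_unassigned"]


def test_append_assignments_empty_and_unknown(loaded_store):
    db, _, _ = loaded_store
    before = _counts(db)
    assert db.append_assignments("p1", []) == 0
    assert _counts(db) == before
    with pytest.raises(errors.UnknownSequence):
        db.append_assignments("p1", [AssignmentRow("ghost", "m", ["AB1"])])


def test_append_second_best_hit_conflicts(loaded_store):
    db, ledger, _ = loaded_store
    seq = ledger["assigned_ids"][0]
    method = db.iter_assignments()[0]["method"]
    row = next(a for a in db.iter_assignments()
               if a["sequence_id"] == seq and a["best_hit"])
    with pytest.raises(errors.BestHitConflict):
        db.append_assignments("p1", [
            AssignmentRow(seq, row["method"], [], taxonomy_id=2,
                          best_hit=True)])


# ---------------------------------------------------------------------------
# retry
# ---------------------------------------------------------------------------

def test_retry_unresolved_recovers_and_is_idempotent(fresh_store, small_tax,
                                                     bundle):
    db = fresh_store
    ledger = bundle["ledger"]
    # import with a resolver that knows nothing: all accession-based rows
    # stay unresolved, direct-taxid rows resolve normally
    report = db.import_project(bundle["archive"], "p1", {}, "create",
                               NullResolver())
    acc_rows = [r for r in ledger["assignments"] if r["accessions"]]
    assert report.unresolved == len(acc_rows)
    # a full-knowledge resolver recovers every pending assignment
    full = TableResolver(ledger["accession2taxid"])
    assert db.retry_unresolved(full) == len(acc_rows)
    assert db.retry_unresolved(full) == 0  # idempotent
    stored = {}
    for a in db.iter_assignments():
        stored.setdefault(a["sequence_id"], []).append(a)
    for row in ledger["assignments"]:
        got = [a for a in stored[row["sequence_id"]]
               if a["accessions"] == row["accessions"]
               and a["method"] == row["method"]]
        assert any(a["taxid"] == row["expected_taxid"] for a in got)


def test_retry_partial_knowledge_counts(fresh_store, small_tax, bundle):
    db = fresh_store
    ledger = bundle["ledger"]
    db.import_project(bundle["archive"], "p1", {}, "create", NullResolver())
    # resolver knowing only some accessions: rows recover iff at least one
    # of their accessions resolves
    known = dict(list(sorted(ledger["accession2taxid"].items()))[:10])
    partial = TableResolver(known)
    expected = sum(
        1 for r in ledger["assignments"]
        if r["accessions"] and any(a in known for a in r["accessions"]))
    assert db.retry_unresolved(partial) == expected


# ---------------------------------------------------------------------------
# delete + sequence access
# ---------------------------------------------------------------------------

def test_delete_only_project_empties_store(loaded_store):
    db, _, _ = loaded_store
    db.delete_project("p1")
    s = db.stats()
    assert s["projects"] == s["samples"] == 0
    assert s["sequences_assigned"] == s["sequences_unassigned"] == 0
    assert s["fields"] == 0


def test_delete_one_of_two_projects_keeps_shared_samples(fresh_store,
                                                         small_tax):
    db = fresh_store
    spec = FixtureSpec(seed=41, n_sequences=8, id_prefix="y1")
    archive, ledger = make_archive(spec, small_tax["tax"],
                                   small_tax["parents"])
    resolver = TableResolver(ledger["accession2taxid"])
    db.import_project(archive, "one", {}, "create", resolver)
    spec2 = FixtureSpec(seed=41, n_sequences=8, id_prefix="y2")
    other, l2 = make_archive(spec2, small_tax["tax"], small_tax["parents"])
    for rec in other.sample_table:
        rec.sample_name = rec.sample_name.replace("y2", "y1")
    other.composition.entries = {
        (seq, smp.replace("y2", "y1")): v
        for (seq, smp), v in other.composition.entries.items()}
    db.import_project(other, "two", {}, "create",
                      TableResolver(l2["accession2taxid"]))
    db.delete_project("two")
    samples = db.iter_samples()
    assert samples and all(s["projects"] == {"one"} for s in samples)


def test_reimport_after_delete_reproduces_counts(fresh_store, bundle):
    db = fresh_store
    resolver = TableResolver(bundle["ledger"]["accession2taxid"])
    db.import_project(bundle["archive"], "p1", {}, "create", resolver)
    before = _counts(db)
    db.delete_project("p1")
    db.import_project(bundle["archive"], "p1", {}, "create", resolver)
    assert _counts(db) == before


def test_get_sequence_matches_archive(loaded_store, bundle):
    db, ledger, _ = loaded_store
    rng = random.Random(9)
    records = bundle["archive"].sequences.records
    for rid in rng.sample(sorted(records), 20):
        assert db.get_sequence("p1", rid) == records[rid]
    with pytest.raises(errors.UnknownSequence):
        db.get_sequence("p1", "nope")
    with pytest.raises(errors.UnknownProject):
        db.get_sequence("nope", "nope")
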