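"""Shared fixtures: generated taxonomies, archives and populated stores."""

from __future__ import annotations

import pytest

from metadepot.fixtures import FixtureSpec, make_archive, make_taxonomy
from metadepot.store import Store
from metadepot.taxonomy import TableResolver


@pytest.fixture(scope="session")
def small_tax(tmp_path_factory):
    """127-node binary taxonomy with taxdump files on disk."""
    out = tmp_path_factory.mktemp("taxdump")
    tax, parents = make_taxonomy(6, 2, out)
    return {"tax": tax, "parents": parents, "dir": out}


@pytest.fixture(scope="session")
def bundle(small_tax):
    """One generated archive plus its ground-truth ledger."""
    spec = FixtureSpec(seed=11, n_samples=6, n_sequences=40, n_methods=2)
    archive, ledger = make_archive(spec, small_tax["tax"],
                                   small_tax["parents"])
    return {"spec": spec, "archive": archive, "ledger": ledger, **small_tax}


@pytest.fixture()
def fresh_store(tmp_path, small_tax):
    """Empty store with the session taxonomy loaded."""
    db = Store(tmp_path / "depot")
    db.attach_taxonomy(small_tax["tax"])
    yield db
    db.close()


@pytest.fixture()
def loaded_store(tmp_path, bundle):
    """Store holding the single-archive bundle as project 'p1'."""
    db = Store(tmp_path / "depot")
    db.attach_taxonomy(bundle["tax"])
    resolver = TableResolver(bundle["ledger"]["accession2taxid"])
    report = db.import_project(bundle["archive"], "p1", {}, "create", resolver)
    yield db, bundle["ledger"], report
    db.close()


@pytest.fixture(scope="session")
def dual_store(tmp_path_factory):
    """Two-project, two-method store (read-only in tests) with its ledgers.

    1093-node ternary taxonomy, 120 sequences per project, globally unique
    sequence ids via per-project prefixes.
    """
    out = tmp_path_factory.mktemp("dual")
    tax, parents = make_taxonomy(6, 3, out)
    db = Store(out / "depot")
    db.attach_taxonomy(tax)
    ledgers = {}
    for seed, prefix in ((21, "p1"), (22, "p2")):
        spec = FixtureSpec(seed=seed, n_samples=8, n_sequences=120,
                           n_methods=2, taxonomy_depth=6,
                           taxonomy_branching=3, id_prefix=prefix)
        archive, ledger = make_archive(spec, tax, parents)
        resolver = TableResolver(ledger["accession2taxid"])
        db.import_project(archive, prefix, {}, "create", resolver)
        ledgers[prefix] = ledger
    return {"db": db, "tax": tax, "parents": parents, "ledgers": ledgers,
            "dir": out}
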