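"""Persistent, indexed project store.

One store is a directory holding a single sqlite database plus one indexed
FASTA file per project (nucleotide residues are deliberately kept out of the
database, mirroring the usual practice of serving sequences from an indexed
flat file). The database carries:

* shared reference data: the taxonomy and the accession-to-taxon cache —
  these are common to every project in the store;
* per-project data: samples (shared across projects by ``sample_name``, each
  carrying the set of projects it appears in), sequences split into the
  *assigned* / *unassigned* partitions, assignments embedded per sequence,
  and the dynamic field registry describing every searchable field.

All searchable field values are additionally stored in typed side tables
(``sample_fields`` / ``assignment_fields``) with indexes per data type, so
that the query engine filters through indexes rather than full scans.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path

from pyfaidx import Fasta

from . import errors, formats
from .formats import (AssignmentRow, ProjectArchive, date_bounds,
                      parse_iso_date, read_archive)
from .taxonomy import (AccessionCache, AccessionResolver, Taxonomy,
                       TaxonomyNode, resolve_accessions,
                       resolve_assignment_taxon)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS projects (
    name TEXT PRIMARY KEY, attributes TEXT NOT NULL DEFAULT '{}',
    created TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS samples (
    sample_name TEXT PRIMARY KEY, collection_date TEXT, date_day TEXT,
    lat REAL, lon REAL, extra TEXT NOT NULL DEFAULT '{}');
CREATE TABLE IF NOT EXISTS sample_projects (
    sample_name TEXT NOT NULL, project TEXT NOT NULL,
    PRIMARY KEY (sample_name, project));
CREATE TABLE IF NOT EXISTS sample_fields (
    sample_name TEXT NOT NULL, field TEXT NOT NULL,
    vtext TEXT, vnum REAL, vdate TEXT);
CREATE INDEX IF NOT EXISTS idx_sf_text ON sample_fields (field, vtext);
CREATE INDEX IF NOT EXISTS idx_sf_num ON sample_fields (field, vnum);
CREATE INDEX IF NOT EXISTS idx_sf_date ON sample_fields (field, vdate);
CREATE INDEX IF NOT EXISTS idx_sf_name ON sample_fields (sample_name);
CREATE TABLE IF NOT EXISTS sequences (
    project TEXT NOT NULL, sequence_id TEXT NOT NULL,
    length INTEGER NOT NULL, assigned INTEGER NOT NULL,
    PRIMARY KEY (project, sequence_id));
CREATE INDEX IF NOT EXISTS idx_seq_assigned ON sequences (assigned);
CREATE INDEX IF NOT EXISTS idx_seq_length ON sequences (length);
CREATE TABLE IF NOT EXISTS contributions (
    project TEXT NOT NULL, sequence_id TEXT NOT NULL,
    sample_name TEXT NOT NULL, value REAL NOT NULL,
    PRIMARY KEY (project, sequence_id, sample_name));
CREATE INDEX IF NOT EXISTS idx_contrib_sample ON contributions (sample_name);
CREATE TABLE IF NOT EXISTS assignments (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    project TEXT NOT NULL, sequence_id TEXT NOT NULL,
    ordinal INTEGER NOT NULL, method TEXT,
    accessions TEXT NOT NULL DEFAULT '[]',
    taxid INTEGER, best_hit INTEGER);
CREATE INDEX IF NOT EXISTS idx_asg_seq ON assignments (project, sequence_id);
CREATE INDEX IF NOT EXISTS idx_asg_method ON assignments (method);
CREATE INDEX IF NOT EXISTS idx_asg_taxid ON assignments (taxid);
CREATE TABLE IF NOT EXISTS assignment_fields (
    assignment_id INTEGER NOT NULL, field TEXT NOT NULL,
    vtext TEXT, vnum REAL, vdate TEXT);
CREATE INDEX IF NOT EXISTS idx_af_text ON assignment_fields (field, vtext);
CREATE INDEX IF NOT EXISTS idx_af_num ON assignment_fields (field, vnum);
CREATE INDEX IF NOT EXISTS idx_af_date ON assignment_fields (field, vdate);
CREATE INDEX IF NOT EXISTS idx_af_id ON assignment_fields (assignment_id);
CREATE TABLE IF NOT EXISTS fields (
    name TEXT NOT NULL, entity TEXT NOT NULL, dtype TEXT NOT NULL,
    projects TEXT NOT NULL DEFAULT '[]',
    distinct_count INTEGER NOT NULL DEFAULT 0,
    PRIMARY KEY (name, entity));
CREATE TABLE IF NOT EXISTS acc_cache (
    accession TEXT PRIMARY KEY, taxid INTEGER, source TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS taxonomy_nodes (
    taxid INTEGER PRIMARY KEY, parent INTEGER NOT NULL,
    rank TEXT NOT NULL, name TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS taxonomy_merged (
    old INTEGER PRIMARY KEY, new INTEGER NOT NULL);
"""

#: built-in searchable fields registered on first import
_BUILTIN_FIELDS = (
    ("collection_date", "sample", "date"),
    ("lat_lon", "sample", "geo"),
    ("length", "sequence", "number"),
    ("method", "assignment", "text"),
    ("taxonomy", "assignment", "taxon"),
)


@dataclass
class FieldDescriptor:
    name: str
    entity: str          # sample | sequence | assignment
    dtype: str           # text | number | date | taxon | geo
    projects: set[str] = dc_field(default_factory=set)
    distinct_count: int = 0


@dataclass
class ImportReport:
    project: str
    samples: int = 0
    sequences_assigned: int = 0
    sequences_unassigned: int = 0
    assignments: int = 0
    new_fields: int = 0
    cache_hits: int = 0
    cache_misses: int = 0
    unresolved: int = 0
    warnings: list[str] = dc_field(default_factory=list)

    @property
    def sequences_total(self) -> int:
        return self.sequences_assigned + self.sequences_unassigned

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["sequences_total"] = self.sequences_total
        return d


def infer_dtype(values) -> str:
    """Infer a searchable dtype from raw string values.

    ``number`` if every non-empty value parses as a number, else ``date`` if
    every non-empty value is an ISO-8601 (possibly partial) date, else
    ``text``. At least one non-empty value is expected.
    """
    non_empty = [v for v in values if v is not None and str(v).strip()]
    if not non_empty:
        return "text"

    def is_number(v: str) -> bool:
        try:
            float(v)
        except ValueError:
            return False
        return True

    if all(is_number(v) for v in non_empty):
        return "number"

    def is_date(v: str) -> bool:
        try:
            parse_iso_date(v)
        except errors.MalformedDate:
            return False
        return True

    if all(is_date(v) for v in non_empty):
        return "date"
    return "text"


class _PersistentCache(AccessionCache):
    """Accession cache that writes through to the store's sqlite connection."""

    def __init__(self, conn: sqlite3.Connection):
        super().__init__()
        self._conn = conn
        for acc, taxid, source in conn.execute(
                "SELECT accession, taxid, source FROM acc_cache"):
            super().insert(acc, taxid, source, force=True)

    def insert(self, accession, taxid, source="NCBI", force=False) -> bool:
        stored = super().insert(accession, taxid, source, force)
        if stored:
            entry = self.get(accession)
            self._conn.execute(
                "INSERT OR REPLACE INTO acc_cache (accession, taxid, source) "
                "VALUES (?, ?, ?)", (entry.accession, entry.taxid, entry.source))
        return stored


class Store:
    """A metagenomic project store rooted at a directory."""

    def __init__(self, root: Path | str):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        (self.root / "fasta").mkdir(exist_ok=True)
        self.db_path = self.root / "store.sqlite"
        self.conn = sqlite3.connect(self.db_path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)
        self.conn.commit()
        self._cache: _PersistentCache | None = None
        self._taxonomy: Taxonomy | None = None

    def close(self) -> None:
        self.conn.close()

    # ------------------------------------------------------------------
    # shared reference data
    # ------------------------------------------------------------------

    @property
    def cache(self) -> AccessionCache:
        if self._cache is None:
            self._cache = _PersistentCache(self.conn)
        return self._cache

    def seed_cache(self, mapping_path: Path | str, source: str) -> int:
        count = self.cache.load_tsv(mapping_path, source)
        self.conn.commit()
        return count

    def load_taxonomy(self, nodes_path, names_path, merged_path=None) -> int:
        from .taxonomy import load_taxdump

        tax = load_taxdump(nodes_path, names_path, merged_path)
        self.attach_taxonomy(tax)
        return len(tax)

    def attach_taxonomy(self, tax: Taxonomy) -> None:
        self.conn.execute("DELETE FROM taxonomy_nodes")
        self.conn.execute("DELETE FROM taxonomy_merged")
        self.conn.executemany(
            "INSERT INTO taxonomy_nodes (taxid, parent, rank, name) "
            "VALUES (?, ?, ?, ?)",
            [(n.taxid, n.parent_taxid, n.rank, n.name)
             for n in tax.nodes.values()])
        self.conn.executemany(
            "INSERT INTO taxonomy_merged (old, new) VALUES (?, ?)",
            list(tax.merged.items()))
        self.conn.commit()
        self._taxonomy = tax

    @property
    def taxonomy(self) -> Taxonomy:
        if self._taxonomy is None:
            rows = self.conn.execute(
                "SELECT taxid, parent, rank, name FROM taxonomy_nodes").fetchall()
            if not rows:
                raise errors.NoTaxonomy(
                    "no taxonomy loaded; run `taxonomy load` first")
            nodes = {r[0]: TaxonomyNode(*r) for r in rows}
            root = next(t for t, n in nodes.items() if n.parent_taxid == t)
            merged = dict(self.conn.execute(
                "SELECT old, new FROM taxonomy_merged"))
            self._taxonomy = Taxonomy(nodes, root, merged)
        return self._taxonomy

    @property
    def has_taxonomy(self) -> bool:
        row = self.conn.execute(
            "SELECT COUNT(*) FROM taxonomy_nodes").fetchone()
        return row[0] > 0

    # ------------------------------------------------------------------
    # small accessors
    # ------------------------------------------------------------------

    def projects(self) -> list[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT name FROM projects ORDER BY name")]

    def has_project(self, name: str) -> bool:
        return self.conn.execute(
            "SELECT 1 FROM projects WHERE name = ?", (name,)).fetchone() is not None

    def fasta_path(self, project: str) -> Path:
        return self.root / "fasta" / f"{project}.fasta"

    def get_sequence(self, project: str, sequence_id: str) -> str:
        """Residues for one sequence via the per-project FASTA index."""
        path = self.fasta_path(project)
        if not path.exists():
            raise errors.UnknownProject(project)
        fa = Fasta(str(path))
        try:
            if sequence_id not in fa:
                raise errors.UnknownSequence(sequence_id)
            return str(fa[sequence_id][:]).upper()
        finally:
            fa.close()

    def field_registry(self) -> list[FieldDescriptor]:
        return [
            FieldDescriptor(name, entity, dtype, set(json.loads(projects)),
                            distinct_count)
            for name, entity, dtype, projects, distinct_count
            in self.conn.execute(
                "SELECT name, entity, dtype, projects, distinct_count "
                "FROM fields ORDER BY entity, name")
        ]

    def get_field(self, name: str, entity: str | None = None) -> FieldDescriptor:
        if entity is not None:
            rows = self.conn.execute(
                "SELECT name, entity, dtype, projects, distinct_count "
                "FROM fields WHERE name = ? AND entity = ?",
                (name, entity)).fetchall()
        else:
            rows = self.conn.execute(
                "SELECT name, entity, dtype, projects, distinct_count "
                "FROM fields WHERE name = ?", (name,)).fetchall()
        if not rows:
            raise errors.UnknownField(name)
        if len(rows) > 1:
            raise errors.UnknownField(
                f"{name!r} is ambiguous across entities "
                f"{sorted(r[1] for r in rows)}; specify the entity")
        name, entity, dtype, projects, distinct_count = rows[0]
        return FieldDescriptor(name, entity, dtype,
                               set(json.loads(projects)), distinct_count)

    def stats(self) -> dict:
        q = self.conn.execute
        return {
            "projects": q("SELECT COUNT(*) FROM projects").fetchone()[0],
            "samples": q("SELECT COUNT(*) FROM samples").fetchone()[0],
            "sequences_assigned": q(
                "SELECT COUNT(*) FROM sequences WHERE assigned = 1").fetchone()[0],
            "sequences_unassigned": q(
                "SELECT COUNT(*) FROM sequences WHERE assigned = 0").fetchone()[0],
            "assignments": q("SELECT COUNT(*) FROM assignments").fetchone()[0],
            "fields": q("SELECT COUNT(*) FROM fields").fetchone()[0],
            "cached_accessions": q(
                "SELECT COUNT(*) FROM acc_cache").fetchone()[0],
            "unresolved_accessions": q(
                "SELECT COUNT(*) FROM acc_cache WHERE taxid IS NULL").fetchone()[0],
            "taxonomy_nodes": q(
                "SELECT COUNT(*) FROM taxonomy_nodes").fetchone()[0],
        }

    # dump helpers used by the query oracle, exporters and tests ---------

    def iter_samples(self, projects: list[str] | None = None) -> list[dict]:
        rows = self.conn.execute(
            "SELECT sample_name, collection_date, lat, lon, extra "
            "FROM samples ORDER BY sample_name").fetchall()
        out = []
        for name, cdate, lat, lon, extra in rows:
            projs = {r[0] for r in self.conn.execute(
                "SELECT project FROM sample_projects WHERE sample_name = ?",
                (name,))}
            if projects is not None and not projs & set(projects):
                continue
            out.append({
                "sample_name": name, "collection_date": cdate,
                "lat_lon": (lat, lon) if lat is not None else None,
                "extra": json.loads(extra), "projects": projs,
            })
        return out

    def iter_sequences(self, projects: list[str] | None = None) -> list[dict]:
        if projects is None:
            projects = self.projects()
        marks = ",".join("?" * len(projects))
        rows = self.conn.execute(
            f"SELECT project, sequence_id, length, assigned FROM sequences "
            f"WHERE project IN ({marks}) ORDER BY project, sequence_id",
            projects).fetchall()
        out = []
        for project, seq, length, assigned in rows:
            contributions = dict(self.conn.execute(
                "SELECT sample_name, value FROM contributions "
                "WHERE project = ? AND sequence_id = ?", (project, seq)))
            out.append({"project": project, "sequence_id": seq,
                        "length": length, "assigned": bool(assigned),
                        "contributions": contributions})
        return out

    def iter_assignments(self, projects: list[str] | None = None) -> list[dict]:
        if projects is None:
            projects = self.projects()
        marks = ",".join("?" * len(projects))
        rows = self.conn.execute(
            f"SELECT id, project, sequence_id, ordinal, method, accessions, "
            f"taxid, best_hit FROM assignments WHERE project IN ({marks}) "
            f"ORDER BY project, sequence_id, ordinal", projects).fetchall()
        out = []
        for rid, project, seq, ordinal, method, accs, taxid, best in rows:
            extra = dict(self.conn.execute(
                "SELECT field, vtext FROM assignment_fields "
                "WHERE assignment_id = ?", (rid,)))
            out.append({"id": rid, "project": project, "sequence_id": seq,
                        "ordinal": ordinal, "method": method,
                        "accessions": json.loads(accs), "taxid": taxid,
                        "best_hit": None if best is None else bool(best),
                        "extra": extra})
        return out

    # ------------------------------------------------------------------
    # import
    # ------------------------------------------------------------------

    def import_project(self, archive: ProjectArchive | Path | str,
                       project_name: str,
                       attributes: dict | None = None,
                       mode: str = "create",
                       resolver: AccessionResolver | None = None
                       ) -> ImportReport:
        """Import an archive as a new project or append to an existing one.

        The operation is atomic: every check runs before anything is written,
        all database rows go into one transaction, and the per-project FASTA
        is restored on failure.
        """
        if mode not in ("create", "append"):
            raise ValueError(f"unknown import mode {mode!r}")
        if isinstance(archive, (str, Path)):
            parsed, vreport = read_archive(archive)
            if parsed is None or not vreport.ok:
                exc = errors.IOFailure(
                    "archive failed validation:\n" + vreport.summary())
                exc.report = vreport
                raise exc
            archive = parsed
            import_warnings = [f"{w.code}: {w.message}" for w in vreport.warnings]
        else:
            vreport = formats.validate_archive(archive)
            if not vreport.ok:
                exc = errors.IOFailure(
                    "archive failed validation:\n" + vreport.summary())
                exc.report = vreport
                raise exc
            import_warnings = [f"{w.code}: {w.message}" for w in vreport.warnings]

        exists = self.has_project(project_name)
        if mode == "create" and exists:
            raise errors.DuplicateProject(project_name)
        if mode == "append" and not exists:
            raise errors.UnknownProject(project_name)

        if archive.assignments and not self.has_taxonomy:
            raise errors.NoTaxonomy(
                "assignments present but no taxonomy is loaded")

        # -- pre-flight checks (nothing written yet) --------------------
        if exists:
            marks_seen = {r[0] for r in self.conn.execute(
                "SELECT sequence_id FROM sequences WHERE project = ?",
                (project_name,))}
            for rid in archive.sequences.records:
                if rid in marks_seen:
                    raise errors.DuplicateSequence(rid)

        for rec in archive.sample_table:
            row = self.conn.execute(
                "SELECT collection_date, lat, lon, extra FROM samples "
                "WHERE sample_name = ?", (rec.sample_name,)).fetchone()
            if row is not None:
                cdate, lat, lon, extra = row
                stored_ll = (lat, lon) if lat is not None else None
                if (cdate != rec.collection_date or stored_ll != rec.lat_lon
                        or json.loads(extra) != rec.extra):
                    raise errors.ConflictingSampleMetadata(rec.sample_name)

        new_fields = self._plan_fields(archive, project_name)

        # -- taxon resolution (mutates only the accession cache) --------
        report = ImportReport(project=project_name, warnings=import_warnings)
        resolved_taxids = self._resolve_rows(archive.assignments, resolver,
                                             report)

        # -- write ------------------------------------------------------
        fasta = self.fasta_path(project_name)
        fasta_backup = fasta.read_bytes() if fasta.exists() else None
        try:
            with self.conn:  # one transaction
                # registry first: typed side-table values need the dtypes
                self._register_fields(new_fields, project_name)
                self._write_project(archive, project_name, attributes or {},
                                    mode, resolved_taxids, report)
                self._append_fasta(archive.sequences, fasta)
                self._refresh_distinct_counts()
            report.new_fields = len(new_fields)
        except Exception:
            if fasta_backup is None:
                fasta.unlink(missing_ok=True)
            else:
                fasta.write_bytes(fasta_backup)
            fasta.with_suffix(fasta.suffix + ".fai").unlink(missing_ok=True)
            raise
        return report

    # -- import helpers --------------------------------------------------

    def _plan_fields(self, archive: ProjectArchive, project: str
                     ) -> dict[tuple[str, str], str]:
        """Infer dtypes for every field the archive brings and check them
        against the registry. Returns {(name, entity): dtype} for all fields
        present in this archive (existing or new)."""
        columns: dict[tuple[str, str], list[str]] = {}
        for rec in archive.sample_table:
            for k, v in rec.extra.items():
                if k == "collection_date":
                    continue
                columns.setdefault((k, "sample"), []).append(v)
        for row in archive.assignments:
            for k, v in row.extra.items():
                columns.setdefault((k, "assignment"), []).append(v)

        planned: dict[tuple[str, str], str] = {
            (name, entity): dtype for name, entity, dtype in _BUILTIN_FIELDS
        }
        for (name, entity), values in columns.items():
            planned[(name, entity)] = infer_dtype(values)

        for (name, entity), dtype in planned.items():
            row = self.conn.execute(
                "SELECT dtype FROM fields WHERE name = ? AND entity = ?",
                (name, entity)).fetchone()
            if row is not None and row[0] != dtype:
                raise errors.ConflictingFieldType(
                    f"{entity} field {name!r}: registry says {row[0]}, "
                    f"import infers {dtype}")
        return planned

    def _register_fields(self, planned: dict[tuple[str, str], str],
                         project: str) -> None:
        for (name, entity), dtype in planned.items():
            row = self.conn.execute(
                "SELECT projects FROM fields WHERE name = ? AND entity = ?",
                (name, entity)).fetchone()
            if row is None:
                self.conn.execute(
                    "INSERT INTO fields (name, entity, dtype, projects) "
                    "VALUES (?, ?, ?, ?)",
                    (name, entity, dtype, json.dumps([project])))
            else:
                projects = set(json.loads(row[0])) | {project}
                self.conn.execute(
                    "UPDATE fields SET projects = ? "
                    "WHERE name = ? AND entity = ?",
                    (json.dumps(sorted(projects)), name, entity))

    def _resolve_rows(self, rows: list[AssignmentRow],
                      resolver: AccessionResolver | None,
                      report: ImportReport) -> list[int | None]:
        """Taxon-resolve every assignment row, batching resolver calls.

        The deduplicated set of cache-missing accessions goes to the resolver
        in a single call; per-row resolution then works purely off the cache.
        """
        if not rows:
            return []
        tax = self.taxonomy
        cache = self.cache
        needed = {acc for row in rows if row.taxonomy_id is None
                  for acc in row.accessions}
        hits = sum(1 for acc in needed if acc in cache)
        report.cache_hits += hits
        report.cache_misses += len(needed) - hits
        if needed:
            resolve_accessions(needed, cache, resolver)

        out: list[int | None] = []
        for row in rows:
            taxid = resolve_assignment_taxon(row, cache, tax, resolver=None,
                                             warnings=report.warnings)
            if taxid is None:
                report.unresolved += 1
            out.append(taxid)
        return out

    def _write_project(self, archive: ProjectArchive, project: str,
                       attributes: dict, mode: str,
                       resolved_taxids: list[int | None],
                       report: ImportReport) -> None:
        if mode == "create":
            self.conn.execute(
                "INSERT INTO projects (name, attributes, created) "
                "VALUES (?, ?, ?)",
                (project, json.dumps(attributes),
                 datetime.now(timezone.utc).isoformat()))

        for rec in archive.sample_table:
            existing = self.conn.execute(
                "SELECT 1 FROM samples WHERE sample_name = ?",
                (rec.sample_name,)).fetchone()
            if existing is None:
                day = (date_bounds(rec.collection_date)[0].isoformat()
                       if rec.collection_date else None)
                lat, lon = rec.lat_lon if rec.lat_lon else (None, None)
                self.conn.execute(
                    "INSERT INTO samples (sample_name, collection_date, "
                    "date_day, lat, lon, extra) VALUES (?, ?, ?, ?, ?, ?)",
                    (rec.sample_name, rec.collection_date, day, lat, lon,
                     json.dumps(rec.extra)))
                self._write_sample_fields(rec)
                report.samples += 1
            self.conn.execute(
                "INSERT OR IGNORE INTO sample_projects (sample_name, project) "
                "VALUES (?, ?)", (rec.sample_name, project))

        assigned_ids = {r.sequence_id for r in archive.assignments}
        for rid, seq in archive.sequences.records.items():
            assigned = 1 if rid in assigned_ids else 0
            self.conn.execute(
                "INSERT INTO sequences (project, sequence_id, length, "
                "assigned) VALUES (?, ?, ?, ?)",
                (project, rid, len(seq), assigned))
            if assigned:
                report.sequences_assigned += 1
            else:
                report.sequences_unassigned += 1
        self.conn.executemany(
            "INSERT INTO contributions (project, sequence_id, sample_name, "
            "value) VALUES (?, ?, ?, ?)",
            [(project, seq, sample, value)
             for (seq, sample), value in archive.composition.entries.items()])

        self._insert_assignments(project, archive.assignments,
                                 resolved_taxids, report)

    def _write_sample_fields(self, rec: formats.SampleRecord) -> None:
        for k, v in rec.extra.items():
            if k == "collection_date":
                continue
            self._insert_field_value("sample_fields", "sample_name",
                                     rec.sample_name, k, "sample", v)

    def _insert_field_value(self, table: str, key_col: str, key, field: str,
                            entity: str, raw: str) -> None:
        dtype_row = self.conn.execute(
            "SELECT dtype FROM fields WHERE name = ? AND entity = ?",
            (field, entity)).fetchone()
        dtype = dtype_row[0] if dtype_row else "text"
        vnum = vdate = None
        if dtype == "number":
            try:
                vnum = float(raw)
            except ValueError:
                pass
        elif dtype == "date":
            try:
                vdate = date_bounds(parse_iso_date(raw))[0].isoformat()
            except errors.MalformedDate:
                pass
        self.conn.execute(
            f"INSERT INTO {table} ({key_col}, field, vtext, vnum, vdate) "
            f"VALUES (?, ?, ?, ?, ?)", (key, field, raw, vnum, vdate))

    def _insert_assignments(self, project: str, rows: list[AssignmentRow],
                            resolved_taxids: list[int | None],
                            report: ImportReport,
                            start_ordinals: dict[str, int] | None = None
                            ) -> list[int]:
        # implicit best hit: a lone assignment for its (sequence, method)
        # group is the group's best hit unless explicitly flagged otherwise
        group_sizes: dict[tuple[str, str | None], int] = {}
        for row in rows:
            key = (row.sequence_id, row.method)
            group_sizes[key] = group_sizes.get(key, 0) + 1

        ordinals: dict[str, int] = dict(start_ordinals or {})
        ids: list[int] = []
        for row, taxid in zip(rows, resolved_taxids):
            ordinal = ordinals.get(row.sequence_id, 0)
            ordinals[row.sequence_id] = ordinal + 1
            best = row.best_hit
            if best is None and group_sizes[(row.sequence_id, row.method)] == 1:
                best = True
            cur = self.conn.execute(
                "INSERT INTO assignments (project, sequence_id, ordinal, "
                "method, accessions, taxid, best_hit) "
                "VALUES (?, ?, ?, ?, ?, ?, ?)",
                (project, row.sequence_id, ordinal, row.method,
                 json.dumps(row.accessions), taxid,
                 None if best is None else int(best)))
            ids.append(cur.lastrowid)
            for k, v in row.extra.items():
                self._insert_field_value("assignment_fields", "assignment_id",
                                         cur.lastrowid, k, "assignment", v)
            report.assignments += 1
        return ids

    def _append_fasta(self, sequences: formats.SequenceSet,
                      fasta: Path) -> None:
        with open(fasta, "a", encoding="utf-8") as fh:
            formats.write_fasta(sequences, fh)
        fasta.with_suffix(fasta.suffix + ".fai").unlink(missing_ok=True)

    def _refresh_distinct_counts(self) -> None:
        """Recompute distinct_count for every text field (registry contract)."""
        for name, entity in self.conn.execute(
                "SELECT name, entity FROM fields WHERE dtype = 'text'").fetchall():
            if entity == "sample":
                n = self.conn.execute(
                    "SELECT COUNT(DISTINCT vtext) FROM sample_fields "
                    "WHERE field = ?", (name,)).fetchone()[0]
            elif entity == "assignment" and name == "method":
                n = self.conn.execute(
                    "SELECT COUNT(DISTINCT method) FROM assignments "
                    "WHERE method IS NOT NULL").fetchone()[0]
            else:
                n = self.conn.execute(
                    "SELECT COUNT(DISTINCT vtext) FROM assignment_fields "
                    "WHERE field = ?", (name,)).fetchone()[0]
            self.conn.execute(
                "UPDATE fields SET distinct_count = ? "
                "WHERE name = ? AND entity = ?", (n, name, entity))

    # ------------------------------------------------------------------
    # append assignments / retry / delete
    # ------------------------------------------------------------------

    def append_assignments(self, project: str, rows: list[AssignmentRow],
                           resolver: AccessionResolver | None = None) -> int:
        """Add classification results to existing sequences.

        Sequences gaining their first assignment migrate from the unassigned
        to the assigned partition; best-hit uniqueness per (sequence, method)
        is re-validated against rows already stored.
        """
        if not self.has_project(project):
            raise errors.UnknownProject(project)
        if not rows:
            return 0

        known = {r[0] for r in self.conn.execute(
            "SELECT sequence_id FROM sequences WHERE project = ?", (project,))}
        for row in rows:
            if row.sequence_id not in known:
                raise errors.UnknownSequence(row.sequence_id)

        existing_best = {
            (seq, method) for seq, method in self.conn.execute(
                "SELECT sequence_id, method FROM assignments "
                "WHERE project = ? AND best_hit = 1", (project,))}
        new_best: set[tuple[str, str | None]] = set()
        for row in rows:
            if row.best_hit:
                key = (row.sequence_id, row.method)
                if key in existing_best or key in new_best:
                    raise errors.BestHitConflict(f"{key[0]}/{key[1]}")
                new_best.add(key)

        new_fields = self._plan_fields(
            ProjectArchive([], formats.CompositionMatrix(),
                           formats.SequenceSet(), rows), project)
        report = ImportReport(project=project)
        resolved = self._resolve_rows(rows, resolver, report)

        start_ordinals = dict(self.conn.execute(
            "SELECT sequence_id, COUNT(*) FROM assignments "
            "WHERE project = ? GROUP BY sequence_id", (project,)))
        with self.conn:
            self._register_fields(new_fields, project)
            self._insert_assignments(project, rows, resolved, report,
                                     start_ordinals)
            newly_assigned = {row.sequence_id for row in rows}
            self.conn.executemany(
                "UPDATE sequences SET assigned = 1 "
                "WHERE project = ? AND sequence_id = ?",
                [(project, s) for s in newly_assigned])
            self._refresh_distinct_counts()
        return len(rows)

    def retry_unresolved(self, resolver: AccessionResolver) -> int:
        """Re-resolve assignments that still lack a taxon.

        Unresolved cache entries are re-queried (they expire here, unlike
        plain cache hits); assignments whose accessions now resolve get their
        taxon persisted. Returns the number of newly resolved assignments.
        Idempotent for an unchanged resolver.
        """
        tax = self.taxonomy
        cache = self.cache
        pending = self.conn.execute(
            "SELECT id, accessions FROM assignments "
            "WHERE taxid IS NULL AND accessions != '[]'").fetchall()
        if not pending:
            return 0

        wanted: set[str] = set()
        for _, accs in pending:
            for acc in json.loads(accs):
                entry = cache.get(acc)
                if entry is None or entry.taxid is None:
                    wanted.add(acc)
        if wanted:
            results = resolver.resolve(sorted(wanted))
            for acc in wanted:
                taxid = results.get(acc)
                if taxid is not None:
                    cache.insert(acc, taxid, "NCBI")
                # still-failing accessions simply stay unresolved

        count = 0
        with self.conn:
            for rid, accs in pending:
                row = AssignmentRow(sequence_id="", accessions=json.loads(accs))
                taxid = resolve_assignment_taxon(row, cache, tax)
                if taxid is not None:
                    self.conn.execute(
                        "UPDATE assignments SET taxid = ? WHERE id = ?",
                        (taxid, rid))
                    count += 1
        return count

    def delete_project(self, project: str) -> dict:
        """Remove a project and everything only it references."""
        if not self.has_project(project):
            raise errors.UnknownProject(project)
        removed = {"project": project}
        with self.conn:
            removed["assignments"] = self.conn.execute(
                "SELECT COUNT(*) FROM assignments WHERE project = ?",
                (project,)).fetchone()[0]
            self.conn.execute(
                "DELETE FROM assignment_fields WHERE assignment_id IN "
                "(SELECT id FROM assignments WHERE project = ?)", (project,))
            self.conn.execute(
                "DELETE FROM assignments WHERE project = ?", (project,))
            removed["sequences"] = self.conn.execute(
                "SELECT COUNT(*) FROM sequences WHERE project = ?",
                (project,)).fetchone()[0]
            self.conn.execute(
                "DELETE FROM sequences WHERE project = ?", (project,))
            self.conn.execute(
                "DELETE FROM contributions WHERE project = ?", (project,))
            self.conn.execute(
                "DELETE FROM sample_projects WHERE project = ?", (project,))
            orphan_samples = [r[0] for r in self.conn.execute(
                "SELECT sample_name FROM samples WHERE sample_name NOT IN "
                "(SELECT sample_name FROM sample_projects)")]
            removed["samples"] = len(orphan_samples)
            for s in orphan_samples:
                self.conn.execute(
                    "DELETE FROM sample_fields WHERE sample_name = ?", (s,))
                self.conn.execute(
                    "DELETE FROM samples WHERE sample_name = ?", (s,))
            # prune the project from field descriptors
            dropped_fields = 0
            for name, entity, projects in self.conn.execute(
                    "SELECT name, entity, projects FROM fields").fetchall():
                projs = set(json.loads(projects)) - {project}
                if projs:
                    self.conn.execute(
                        "UPDATE fields SET projects = ? "
                        "WHERE name = ? AND entity = ?",
                        (json.dumps(sorted(projs)), name, entity))
                else:
                    self.conn.execute(
                        "DELETE FROM fields WHERE name = ? AND entity = ?",
                        (name, entity))
                    dropped_fields += 1
            removed["fields_dropped"] = dropped_fields
            self.conn.execute("DELETE FROM projects WHERE name = ?", (project,))
            self._refresh_distinct_counts()
        fasta = self.fasta_path(project)
        fasta.unlink(missing_ok=True)
        fasta.with_suffix(fasta.suffix + ".fai").unlink(missing_ok=True)
        return removed
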