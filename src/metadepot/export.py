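"""Materialize query selections as re-importable archives, FASTA and BIOM.

The native export mirrors the import suite exactly: a selection leaves the
store as a four-file zip that can be fed back into any store. The BIOM export
targets the Biological Observation Matrix container (1.0 JSON by default,
2.1 HDF5 behind a flag) with per-observation taxonomy metadata. Because BIOM
enforces a fixed seven-rank taxonomy (kingdom through species), each
observation additionally carries a ``full_taxonomy`` string holding the
complete root-to-taxon name path, preserving ranks beyond the canonical
seven — e.g. the many intermediate ranks used in virus classification.
"""

from __future__ import annotations

import json
import uuid
import zipfile
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import errors, formats
from .formats import (AssignmentRow, CompositionMatrix, ProjectArchive,
                      SampleRecord, SequenceSet, format_lat_lon)
from .query import Query, designated_assignments, run_query
from .store import Store

#: ancestor ranks projected onto the canonical BIOM taxonomy slots, in order
BIOM_RANKS = ("superkingdom", "phylum", "class", "order", "family",
              "genus", "species")
_RANK_ALIASES = {"kingdom": "superkingdom", "domain": "superkingdom"}

FULL_TAXONOMY_SEP = ";"


def _no_limit(query: Query, grouping: str) -> Query:
    from dataclasses import replace
    return replace(query, grouping=grouping, offset=0, limit=None, sort=None)


def _selection(db: Store, query: Query):
    """Matching sequences, samples and assignments for an export."""
    seq_rows = run_query(db, _no_limit(query, "sequence")).rows
    if not seq_rows:
        raise errors.EmptySelection("query matches no sequence")
    sample_rows = run_query(db, _no_limit(query, "sample")).rows
    asg_rows = run_query(db, _no_limit(query, "assignment")).rows
    return seq_rows, sample_rows, asg_rows


def export_native(db: Store, query: Query) -> ProjectArchive:
    """Build a re-importable archive restricted to the selection.

    The archive holds the matching sequences, the matching samples, the
    contributions linking the two, and the filter-surviving assignments.
    Resolved taxa are written back as explicit ``taxonomy_id`` values next to
    the original accessions, so re-import needs no resolver. Sequence ids
    must be globally unique across the selected projects (the archive format
    has no project column).
    """
    seq_rows, sample_rows, asg_rows = _selection(db, query)

    ids_seen: dict[str, str] = {}
    for row in seq_rows:
        prev = ids_seen.get(row["sequence_id"])
        if prev is not None and prev != row["project"]:
            raise errors.DuplicateId(
                f"sequence id {row['sequence_id']!r} occurs in projects "
                f"{prev!r} and {row['project']!r}; cannot flatten into one "
                f"archive")
        ids_seen[row["sequence_id"]] = row["project"]

    records = {row["sequence_id"]: db.get_sequence(row["project"],
                                                   row["sequence_id"])
               for row in seq_rows}
    sequences = SequenceSet(records=records,
                            index={rid: (0, len(s))
                                   for rid, s in records.items()})

    sample_names = {row["sample_name"] for row in sample_rows}
    samples = [SampleRecord(row["sample_name"], row["collection_date"],
                            row["lat_lon"], dict(row["extra"]))
               for row in sample_rows]

    matrix = CompositionMatrix()
    keys = {(row["project"], row["sequence_id"]) for row in seq_rows}
    marks = ",".join("?" * len(query.projects))
    for project, seq, sample, value in db.conn.execute(
            f"SELECT project, sequence_id, sample_name, value "
            f"FROM contributions WHERE project IN ({marks})",
            list(query.projects)):
        if (project, seq) in keys and sample in sample_names:
            matrix.entries[(seq, sample)] = value

    details = {a["id"]: a for a in db.iter_assignments(list(query.projects))}
    assignments = []
    for row in asg_rows:
        a = details[row["id"]]
        assignments.append(AssignmentRow(
            sequence_id=a["sequence_id"],
            method=a["method"],
            accessions=list(a["accessions"]),
            taxonomy_id=a["taxid"],
            best_hit=a["best_hit"],
            extra=dict(a["extra"]),
        ))

    return ProjectArchive(sample_table=samples, composition=matrix,
                          sequences=sequences, assignments=assignments)


def export_native_zip(db: Store, query: Query, path: Path | str) -> Path:
    return formats.write_archive(export_native(db, query), path)


def export_fasta(db: Store, query: Query, path: Path | str) -> Path:
    """One FASTA record per matching sequence, residues as imported."""
    seq_rows = run_query(db, _no_limit(query, "sequence")).rows
    if not seq_rows:
        raise errors.EmptySelection("query matches no sequence")
    records = {}
    for row in seq_rows:
        rid = row["sequence_id"]
        if rid in records:
            raise errors.DuplicateId(rid)
        records[rid] = db.get_sequence(row["project"], rid)
    formats.write_fasta(records, path)
    return Path(path)


# ---------------------------------------------------------------------------
# BIOM
# ---------------------------------------------------------------------------

def _rank_projection(db: Store, taxid: int) -> tuple[list[str], str]:
    """(seven-rank taxonomy list, full name path) for one taxon."""
    tax = db.taxonomy
    slots = {r: "" for r in BIOM_RANKS}
    for anc in tax.ancestors(taxid):
        node = tax.node(anc)
        rank = _RANK_ALIASES.get(node.rank, node.rank)
        if rank in slots and not slots[rank]:
            slots[rank] = node.name
    full = FULL_TAXONOMY_SEP.join(tax.name_path(taxid, include_root=False))
    return [slots[r] for r in BIOM_RANKS], full


@dataclass
class BiomTable:
    """In-memory observation x sample table with taxonomy metadata."""

    observation_ids: list[str]
    sample_ids: list[str]
    data: dict[tuple[int, int], float]          # (obs idx, sample idx) -> value
    observation_metadata: list[dict]
    sample_metadata: list[dict]
    excluded_unresolved: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.observation_ids), len(self.sample_ids))

    def total(self) -> float:
        return sum(self.data.values())


def build_biom(db: Store, query: Query, method: str | None = None) -> BiomTable:
    """Assemble the BIOM table for a (normalized) selection.

    Observations are the matching sequences under best-hit normalization,
    columns the matching samples, and values the stored contributions.
    Sequences whose designated assignment has no resolved taxon are excluded
    (there is no taxonomy to project); the count of exclusions is kept on the
    table.
    """
    designated = designated_assignments(db, query, method)
    if not designated:
        raise errors.EmptySelection("query matches no sequence")
    resolved = [(p, s, t) for p, s, t in designated if t is not None]
    excluded = len(designated) - len(resolved)
    if not resolved:
        raise errors.EmptySelection(
            "no matching sequence has a resolved taxon")

    sample_rows = run_query(db, _no_limit(query, "sample")).rows
    sample_ids = [r["sample_name"] for r in sample_rows]
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    sample_metadata = []
    for r in sample_rows:
        md = {"collection_date": r["collection_date"] or "",
              "lat_lon": format_lat_lon(r["lat_lon"])}
        md.update(r["extra"])
        sample_metadata.append(md)

    observation_ids = []
    observation_metadata = []
    data: dict[tuple[int, int], float] = {}
    for i, (project, seq, taxid) in enumerate(resolved):
        observation_ids.append(seq)
        ranks, full = _rank_projection(db, taxid)
        observation_metadata.append(
            {"taxonomy": ranks, "full_taxonomy": full})
        for sample, value in db.conn.execute(
                "SELECT sample_name, value FROM contributions "
                "WHERE project = ? AND sequence_id = ?", (project, seq)):
            j = sample_pos.get(sample)
            if j is not None:
                data[(i, j)] = value

    if len(set(observation_ids)) != len(observation_ids):
        raise errors.DuplicateId(
            "sequence ids collide across the selected projects")
    return BiomTable(observation_ids, sample_ids, data,
                     observation_metadata, sample_metadata, excluded)


def write_biom_json(table: BiomTable, path: Path | str,
                    table_id: str = "metadepot export") -> Path:
    """BIOM 1.0 (sparse JSON) writer."""
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "metadepot",
        "date": datetime.now(timezone.utc).isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": list(table.shape),
        "rows": [{"id": rid, "metadata": md}
                 for rid, md in zip(table.observation_ids,
                                    table.observation_metadata)],
        "columns": [{"id": cid, "metadata": md}
                    for cid, md in zip(table.sample_ids,
                                       table.sample_metadata)],
        "data": [[i, j, v] for (i, j), v in sorted(table.data.items())],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return path


def write_biom_hdf5(table: BiomTable, path: Path | str,
                    table_id: str = "metadepot export") -> Path:
    """BIOM 2.1 (HDF5) writer: CSR under /observation, CSC under /sample."""
    import h5py
    import numpy as np

    n_obs, n_samp = table.shape
    entries = sorted(table.data.items())  # row-major

    def csr(items, nrows):
        indptr = [0]
        indices, values = [], []
        row = 0
        for (i, j), v in items:
            while row < i:
                indptr.append(len(indices))
                row += 1
            indices.append(j)
            values.append(v)
        while row < nrows:
            indptr.append(len(indices))
            row += 1
        return values, indices, indptr

    obs_vals, obs_idx, obs_ptr = csr(entries, n_obs)
    transposed = sorted((((j, i), v) for (i, j), v in table.data.items()))
    smp_vals, smp_idx, smp_ptr = csr(transposed, n_samp)

    str_dt = h5py.string_dtype(encoding="utf-8")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["id"] = table_id
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = "http://biom-format.org"
        f.attrs["format-version"] = [2, 1]
        f.attrs["generated-by"] = "metadepot"
        f.attrs["creation-date"] = datetime.now(timezone.utc).isoformat()
        f.attrs["shape"] = [n_obs, n_samp]
        f.attrs["nnz"] = len(entries)
        obs = f.create_group("observation")
        obs.create_dataset("ids", data=np.array(table.observation_ids,
                                                dtype=str_dt))
        m = obs.create_group("matrix")
        m.create_dataset("data", data=np.array(obs_vals, dtype="float64"))
        m.create_dataset("indices", data=np.array(obs_idx, dtype="int32"))
        m.create_dataset("indptr", data=np.array(obs_ptr, dtype="int32"))
        omd = obs.create_group("metadata")
        omd.create_dataset("taxonomy", data=np.array(
            [md["taxonomy"] for md in table.observation_metadata],
            dtype=str_dt))
        omd.create_dataset("full_taxonomy", data=np.array(
            [md["full_taxonomy"] for md in table.observation_metadata],
            dtype=str_dt))
        obs.create_group("group-metadata")
        smp = f.create_group("sample")
        smp.create_dataset("ids", data=np.array(table.sample_ids,
                                                dtype=str_dt))
        m = smp.create_group("matrix")
        m.create_dataset("data", data=np.array(smp_vals, dtype="float64"))
        m.create_dataset("indices", data=np.array(smp_idx, dtype="int32"))
        m.create_dataset("indptr", data=np.array(smp_ptr, dtype="int32"))
        smp.create_group("metadata")
        smp.create_group("group-metadata")
    return path


def export_biom(db: Store, query: Query, path: Path | str,
                method: str | None = None, flavor: str = "json") -> BiomTable:
    """Export the selection as a BIOM file; returns the assembled table."""
    table = build_biom(db, query, method)
    if flavor == "json":
        write_biom_json(table, path)
    elif flavor == "hdf5":
        write_biom_hdf5(table, path)
    else:
        raise ValueError(f"unknown BIOM flavor {flavor!r}")
    return table


# ---------------------------------------------------------------------------
# materialized exports
# ---------------------------------------------------------------------------

EXPORT_KINDS = ("native", "fasta", "biom")
_REGISTRY_NAME = "registry.json"


def _load_registry(export_dir: Path) -> dict[str, str]:
    reg = export_dir / _REGISTRY_NAME
    if reg.exists():
        return json.loads(reg.read_text(encoding="utf-8"))
    return {}


def _save_registry(export_dir: Path, registry: dict[str, str]) -> None:
    (export_dir / _REGISTRY_NAME).write_text(
        json.dumps(registry, indent=1), encoding="utf-8")


def materialize_export(db: Store, query: Query, kind: str,
                       export_dir: Path | str | None = None,
                       method: str | None = None,
                       flavor: str = "json") -> tuple[Path, str]:
    """Write an export under a collision-free token and register it.

    Exports are compressed into zip archives (the native kind already is
    one); the registry maps each token to its file for later retrieval and
    cleanup — the headless counterpart of a share-by-URL download.
    """
    if kind not in EXPORT_KINDS:
        raise ValueError(f"unknown export kind {kind!r}")
    export_dir = Path(export_dir) if export_dir else db.root / "exports"
    export_dir.mkdir(parents=True, exist_ok=True)
    token = uuid.uuid4().hex

    try:
        if kind == "native":
            out = export_dir / f"{token}.zip"
            export_native_zip(db, query, out)
        else:
            suffix = ".fasta" if kind == "fasta" else (
                ".biom" if flavor == "hdf5" else ".biom.json")
            inner = export_dir / f"{token}{suffix}"
            if kind == "fasta":
                export_fasta(db, query, inner)
            else:
                export_biom(db, query, inner, method=method, flavor=flavor)
            out = export_dir / f"{token}.zip"
            with zipfile.ZipFile(out, "w", zipfile.ZIP_DEFLATED) as zf:
                zf.write(inner, inner.name)
            inner.unlink()
    except OSError as exc:
        raise errors.IOFailure(str(exc)) from exc

    registry = _load_registry(export_dir)
    registry[token] = out.name
    _save_registry(export_dir, registry)
    return out, token


def list_exports(export_dir: Path | str) -> dict[str, Path]:
    export_dir = Path(export_dir)
    return {token: export_dir / name
            for token, name in _load_registry(export_dir).items()}


def cleanup_export(export_dir: Path | str, token: str) -> None:
    """Remove a materialized export and its registry entry together."""
    export_dir = Path(export_dir)
    registry = _load_registry(export_dir)
    if token not in registry:
        raise errors.IOFailure(f"unknown export token {token!r}")
    (export_dir / registry.pop(token)).unlink(missing_ok=True)
    _save_registry(export_dir, registry)
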