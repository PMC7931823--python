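"""Readers, writers and validators for the four-file project archive suite.

A project is exchanged as a zip archive with four member roles:

``samples``
    tab-delimited sample metadata with the three standard BioSample attributes
    (``sample_name``, ``collection_date``, ``lat_lon``) plus any user fields;
``composition``
    per-sequence, per-sample numeric contributions (read recruitment counts for
    shotgun contigs, abundances for metabarcoding OTUs);
``sequences``
    a FASTA file with one nucleotide record per sequence;
``assignments``
    tab-delimited taxonomic assignment rows, possibly several per sequence,
    each targeting either an explicit ``taxonomy_id`` or one or more reference
    accessions (CSV within the cell).

Members are matched by role through a ``manifest.json`` zip member, with a
fallback to file-name sniffing. All text is UTF-8, tab is the only separator
and no quoting is used: a tab inside a value is a malformed row.
"""

from __future__ import annotations

import csv
import io
import json
import re
import zipfile
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from . import errors

#: zip member roles that make up a complete archive
ARCHIVE_ROLES = ("samples", "composition", "sequences", "assignments")

_MANIFEST_NAME = "manifest.json"

_CANONICAL_SAMPLE_COLUMNS = ("sample_name", "collection_date", "lat_lon")

_ISO_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")

_NA_TOKENS = {"", "na", "n/a", "none", "null", "missing", "not collected"}

_BOOL_TOKENS = {
    "true": True, "false": False,
    "1": True, "0": False,
    "yes": True, "no": False,
}

_ACCESSION_VERSION_RE = re.compile(r"\.\d+$")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """One row of the sample metadata table.

    ``collection_date`` holds the validated ISO-8601 string (day, month or
    year precision); a malformed date is kept verbatim in ``extra`` instead.
    ``lat_lon`` is a decimal-degree ``(latitude, longitude)`` pair or ``None``.
    """

    sample_name: str
    collection_date: str | None = None
    lat_lon: tuple[float, float] | None = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class CompositionMatrix:
    """Sparse sequence x sample contribution matrix; absent cell means zero."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def sequence_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for seq, _ in self.entries:
            seen.setdefault(seq)
        return list(seen)

    @property
    def sample_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, sample in self.entries:
            seen.setdefault(sample)
        return list(seen)

    def row(self, sequence_id: str) -> dict[str, float]:
        return {s: v for (q, s), v in self.entries.items() if q == sequence_id}

    def row_sums(self) -> dict[str, float]:
        sums: dict[str, float] = {}
        for (seq, _), v in self.entries.items():
            sums[seq] = sums.get(seq, 0.0) + v
        return sums


@dataclass
class SequenceSet:
    """Nucleotide records plus a byte-offset index for random access.

    ``index`` maps each id to ``(byte offset of its header line, sequence
    length)`` within the source file, so any record can be served with a seek
    instead of a full scan. In-memory equality compares the records only.
    """

    records: dict[str, str] = field(default_factory=dict)
    index: dict[str, tuple[int, int]] = field(default_factory=dict)
    path: Path | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self.records == other.records

    def fetch(self, sequence_id: str) -> str:
        """Return residues for ``sequence_id`` via the byte-offset index."""
        if sequence_id not in self.index:
            raise errors.UnknownSequence(sequence_id)
        if self.path is None:
            return self.records[sequence_id]
        offset, _ = self.index[sequence_id]
        chunks: list[str] = []
        with open(self.path, "r", encoding="utf-8") as fh:
            fh.seek(offset)
            fh.readline()  # header line
            for line in fh:
                if line.startswith(">"):
                    break
                chunks.append(line.strip())
        return "".join(chunks)


@dataclass
class AssignmentRow:
    """One taxonomic assignment line for a sequence."""

    sequence_id: str
    method: str | None = None
    accessions: list[str] = field(default_factory=list)
    taxonomy_id: int | None = None
    best_hit: bool | None = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class ProjectArchive:
    """In-memory image of the four-file import/export unit."""

    sample_table: list[SampleRecord]
    composition: CompositionMatrix
    sequences: SequenceSet
    assignments: list[AssignmentRow]


@dataclass
class Finding:
    code: str
    member: str
    locator: str
    message: str


@dataclass
class ValidationReport:
    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, code: str, member: str, locator: str, message: str) -> None:
        self.errors.append(Finding(code, member, locator, message))

    def warn(self, code: str, member: str, locator: str, message: str) -> None:
        self.warnings.append(Finding(code, member, locator, message))

    def summary(self) -> str:
        lines = [f"{'OK' if self.ok else 'INVALID'}: "
                 f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        for f in self.errors:
            lines.append(f"  ERROR {f.code} [{f.member}:{f.locator}] {f.message}")
        for f in self.warnings:
            lines.append(f"  WARN  {f.code} [{f.member}:{f.locator}] {f.message}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# scalar parsers
# ---------------------------------------------------------------------------

def canonical_accession(raw: str) -> str:
    """Uppercase and strip a trailing version suffix (``AB123456.1`` ->
    ``AB123456``) so cache lookups are version-independent."""
    return _ACCESSION_VERSION_RE.sub("", raw.strip().upper())


def parse_lat_lon(text: str | None) -> tuple[float, float] | None:
    """Parse a collection-location cell into decimal degrees.

    Two dialects are accepted: the BioSample hemisphere form
    ``"38.98 N 77.11 W"`` (S/W mapping to negative sign) and plain decimal
    ``"lat lon"`` or ``"lat,lon"``. Empty or NA-like text yields ``None``.
    """
    if text is None:
        return None
    stripped = text.strip()
    if stripped.lower() in _NA_TOKENS:
        return None
    tokens = [t for t in re.split(r"[,\s]+", stripped) if t]
    try:
        if len(tokens) == 4:
            lat_hem, lon_hem = tokens[1].upper(), tokens[3].upper()
            if lat_hem not in "NS" or lon_hem not in "EW" or \
                    len(lat_hem) != 1 or len(lon_hem) != 1:
                raise ValueError
            lat = float(tokens[0]) * (-1.0 if lat_hem == "S" else 1.0)
            lon = float(tokens[2]) * (-1.0 if lon_hem == "W" else 1.0)
        elif len(tokens) == 2:
            lat, lon = float(tokens[0]), float(tokens[1])
        else:
            raise ValueError
    except ValueError:
        raise errors.MalformedCoordinate(text) from None
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise errors.MalformedCoordinate(text)
    return (lat, lon)


def format_lat_lon(point: tuple[float, float] | None) -> str:
    if point is None:
        return ""
    return f"{format_number(point[0])} {format_number(point[1])}"


def parse_iso_date(text: str) -> str:
    """Validate an ISO-8601 date at day, month or year precision.

    Returns the canonical string; raises :class:`~metadepot.errors.MalformedDate`
    on anything else (free-text dates are kept as plain text by the caller).
    """
    m = _ISO_DATE_RE.match(text.strip())
    if not m:
        raise errors.MalformedDate(text)
    year, month, day = m.group(1), m.group(2), m.group(3)
    try:
        date(int(year), int(month) if month else 1, int(day) if day else 1)
        if month and day:
            date(int(year), int(month), int(day))
    except ValueError:
        raise errors.MalformedDate(text) from None
    if month and not 1 <= int(month) <= 12:
        raise errors.MalformedDate(text)
    return m.group(0)


def date_bounds(iso: str) -> tuple[date, date]:
    """Day interval covered by a (possibly partial) ISO date string."""
    m = _ISO_DATE_RE.match(iso)
    if not m:
        raise errors.MalformedDate(iso)
    year = int(m.group(1))
    if m.group(3):
        d = date(year, int(m.group(2)), int(m.group(3)))
        return d, d
    if m.group(2):
        month = int(m.group(2))
        first = date(year, month, 1)
        last = (date(year + 1, 1, 1) if month == 12
                else date(year, month + 1, 1))
        return first, date.fromordinal(last.toordinal() - 1)
    return date(year, 1, 1), date(year, 12, 31)


def format_number(v: float) -> str:
    """Normalized numeric rendering: integral values print without decimals."""
    f = float(v)
    if f.is_integer():
        return str(int(f))
    return repr(f)


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _read_tsv(path: Path | str) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a strict TSV: header + (line number, cells) rows.

    Quoting is disabled on purpose: a tab inside a value changes the column
    count and is reported as a malformed row by the caller.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        rows = [(i + 1, row) for i, row in enumerate(reader)]
    rows = [(n, r) for n, r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise errors.MalformedRow("empty file")
    header_no, header = rows[0]
    return [h.strip() for h in header], rows[1:]


def _open_text_w(target):
    """Writable text handle from a path or an already-open file-like."""
    from contextlib import nullcontext

    if hasattr(target, "write"):
        return nullcontext(target)
    return open(target, "w", encoding="utf-8", newline="")


def _write_tsv(path, header: list[str], rows: Iterable[list[str]]) -> None:
    with _open_text_w(path) as fh:
        for cells in [header, *rows]:
            for c in cells:
                if "\t" in c or "\n" in c:
                    raise errors.MalformedRow(
                        f"value contains a separator character: {c!r}")
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

def read_sample_table(path: Path | str) -> list[SampleRecord]:
    """Parse the sample metadata TSV.

    The three standard columns map to typed fields; every other column is
    preserved verbatim in ``extra`` in file order. A non-ISO collection date
    is not an error: the raw text moves to ``extra["collection_date"]`` and
    the typed field stays empty (the archive validator warns about it).
    """
    header, rows = _read_tsv(path)
    lowered = [h.lower() for h in header]
    for required in _CANONICAL_SAMPLE_COLUMNS:
        if required not in lowered:
            raise errors.MissingColumn(required)
    col = {name: lowered.index(name) for name in _CANONICAL_SAMPLE_COLUMNS}
    extra_cols = [(i, header[i]) for i in range(len(header))
                  if i not in col.values()]

    records: list[SampleRecord] = []
    seen: set[str] = set()
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise errors.MalformedRow(
                f"line {lineno}: expected {len(header)} columns, got {len(cells)}")
        name = cells[col["sample_name"]].strip()
        if not name:
            raise errors.MalformedRow(f"line {lineno}: empty sample_name")
        if name in seen:
            raise errors.DuplicateSample(name)
        seen.add(name)

        extra = {h: cells[i].strip() for i, h in extra_cols if cells[i].strip()}

        raw_date = cells[col["collection_date"]].strip()
        collection_date: str | None = None
        if raw_date and raw_date.lower() not in _NA_TOKENS:
            try:
                collection_date = parse_iso_date(raw_date)
            except errors.MalformedDate:
                extra["collection_date"] = raw_date

        lat_lon = parse_lat_lon(cells[col["lat_lon"]])
        records.append(SampleRecord(name, collection_date, lat_lon, extra))
    return records


def write_sample_table(records: list[SampleRecord], path: Path | str) -> None:
    extra_cols: dict[str, None] = {}
    for r in records:
        for k in r.extra:
            if k != "collection_date":
                extra_cols.setdefault(k)
    header = list(_CANONICAL_SAMPLE_COLUMNS) + list(extra_cols)
    rows = []
    for r in records:
        date_cell = r.collection_date or r.extra.get("collection_date", "")
        rows.append([r.sample_name, date_cell, format_lat_lon(r.lat_lon)]
                    + [r.extra.get(k, "") for k in extra_cols])
    _write_tsv(path, header, rows)


# ---------------------------------------------------------------------------
# composition matrix
# ---------------------------------------------------------------------------

_LONG_SEQ_NAMES = {"sequence", "sequence_id", "seq", "qseqid"}
_LONG_SAMPLE_NAMES = {"sample", "sample_name"}


def read_composition(path: Path | str) -> CompositionMatrix:
    """Parse the contribution table.

    The wide layout (header = sample names, rows = sequence ids) is the
    default; a 3-column long layout ``sequence<TAB>sample<TAB>value`` is
    auto-detected from the header. Blank and zero cells are omitted from the
    sparse matrix; integers and decimals are both accepted.
    """
    header, rows = _read_tsv(path)
    if (len(header) == 3
            and header[0].lower() in _LONG_SEQ_NAMES
            and header[1].lower() in _LONG_SAMPLE_NAMES):
        return _read_composition_long(header, rows)
    return _read_composition_wide(header, rows)


def _parse_cell(raw: str, locator: str) -> float | None:
    cell = raw.strip()
    if not cell:
        return None
    try:
        value = float(cell)
    except ValueError:
        raise errors.NonNumericCell(f"{locator}: {cell!r}") from None
    if value != value:  # NaN
        raise errors.NonNumericCell(f"{locator}: {cell!r}")
    return value


def _read_composition_wide(header, rows) -> CompositionMatrix:
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise errors.MalformedRow("duplicate sample column in header")
    matrix = CompositionMatrix()
    seen: set[str] = set()
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise errors.MalformedRow(
                f"line {lineno}: expected {len(header)} columns, got {len(cells)}")
        seq = cells[0].strip()
        if seq in seen:
            raise errors.DuplicateSequenceRow(seq)
        seen.add(seq)
        for sample, raw in zip(samples, cells[1:]):
            value = _parse_cell(raw, f"line {lineno}, sample {sample}")
            if value is None or value == 0:
                continue
            if value < 0:
                raise errors.NegativeContribution(f"{seq}, {sample}: {value}")
            matrix.entries[(seq, sample)] = value
    return matrix


def _read_composition_long(header, rows) -> CompositionMatrix:
    matrix = CompositionMatrix()
    for lineno, cells in rows:
        if len(cells) != 3:
            raise errors.MalformedRow(
                f"line {lineno}: expected 3 columns, got {len(cells)}")
        seq, sample = cells[0].strip(), cells[1].strip()
        value = _parse_cell(cells[2], f"line {lineno}")
        if (seq, sample) in matrix.entries:
            raise errors.DuplicateSequenceRow(f"{seq}/{sample}")
        if value is None or value == 0:
            continue
        if value < 0:
            raise errors.NegativeContribution(f"{seq}, {sample}: {value}")
        matrix.entries[(seq, sample)] = value
    return matrix


def write_composition(matrix: CompositionMatrix, path: Path | str) -> None:
    """Write the matrix in the wide layout with normalized numbers."""
    samples = sorted(matrix.sample_names)
    header = ["sequence_id"] + samples
    rows = []
    for seq in matrix.sequence_ids:
        row = matrix.row(seq)
        rows.append([seq] + [format_number(row[s]) if s in row else ""
                             for s in samples])
    _write_tsv(path, header, rows)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Path | str) -> SequenceSet:
    """Parse a FASTA file and build the byte-offset random-access index.

    The record id is the header token before the first whitespace. Duplicate
    ids and empty sequences are rejected.
    """
    path = Path(path)
    offsets: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        for line in iter(fh.readline, ""):
            if line.startswith(">"):
                rid = line[1:].split()[0] if line[1:].split() else ""
                if rid in offsets:
                    raise errors.DuplicateId(rid)
                offsets[rid] = pos
            pos = fh.tell()

    records: dict[str, str] = {}
    index: dict[str, tuple[int, int]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise errors.EmptySequence(rec.id)
        records[rec.id] = seq
        index[rec.id] = (offsets[rec.id], len(seq))
    if len(records) < len(offsets):
        # headers present but without ids / unreachable via SeqIO
        for rid in offsets:
            if rid not in records:
                raise errors.EmptySequence(rid or "<empty header>")
    return SequenceSet(records=records, index=index, path=path)


def write_fasta(sequences: SequenceSet | Mapping[str, str],
                path, width: int = 60) -> None:
    records = sequences.records if isinstance(sequences, SequenceSet) else sequences
    with _open_text_w(path) as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# assignment table
# ---------------------------------------------------------------------------

_SEQ_COL_NAMES = {"sequence_id", "sequence"}
_KNOWN_ASSIGNMENT_COLS = {"method", "accessions", "accession",
                          "taxonomy_id", "best_hit"}


def read_assignment_table(path: Path | str) -> list[AssignmentRow]:
    """Parse assignment rows; several lines may target one sequence.

    The accession cell may hold a CSV list; entries are trimmed, uppercased
    and stripped of version suffixes. A row must carry an explicit
    ``taxonomy_id`` or at least one accession.
    """
    header, rows = _read_tsv(path)
    lowered = [h.lower() for h in header]
    seq_idx = next((i for i, h in enumerate(lowered) if h in _SEQ_COL_NAMES), None)
    if seq_idx is None:
        raise errors.MissingColumn("sequence_id")

    def find(name: str) -> int | None:
        return lowered.index(name) if name in lowered else None

    method_idx = find("method")
    acc_idx = find("accessions")
    if acc_idx is None:
        acc_idx = find("accession")
    taxid_idx = find("taxonomy_id")
    best_idx = find("best_hit")
    typed = {seq_idx, method_idx, acc_idx, taxid_idx, best_idx} - {None}
    extra_cols = [(i, header[i]) for i in range(len(header)) if i not in typed]

    out: list[AssignmentRow] = []
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise errors.MalformedRow(
                f"line {lineno}: expected {len(header)} columns, got {len(cells)}")

        def cell(idx: int | None) -> str:
            return cells[idx].strip() if idx is not None else ""

        accessions = [canonical_accession(a)
                      for a in cell(acc_idx).split(",") if a.strip()]
        raw_taxid = cell(taxid_idx)
        taxid: int | None = None
        if raw_taxid:
            try:
                taxid = int(raw_taxid)
            except ValueError:
                raise errors.MalformedRow(
                    f"line {lineno}: non-integer taxonomy_id {raw_taxid!r}") from None
        if taxid is None and not accessions:
            raise errors.NoTarget(f"line {lineno}")

        raw_best = cell(best_idx)
        best_hit: bool | None = None
        if raw_best:
            try:
                best_hit = _BOOL_TOKENS[raw_best.lower()]
            except KeyError:
                raise errors.MalformedBestHit(
                    f"line {lineno}: {raw_best!r}") from None

        out.append(AssignmentRow(
            sequence_id=cell(seq_idx),
            method=cell(method_idx) or None,
            accessions=accessions,
            taxonomy_id=taxid,
            best_hit=best_hit,
            extra={h: cells[i].strip() for i, h in extra_cols if cells[i].strip()},
        ))
    return out


def write_assignment_table(rows: list[AssignmentRow], path: Path | str) -> None:
    extra_cols: dict[str, None] = {}
    for r in rows:
        for k in r.extra:
            extra_cols.setdefault(k)
    header = ["sequence_id", "method", "accessions", "taxonomy_id", "best_hit"]
    header += list(extra_cols)
    body = []
    for r in rows:
        body.append([
            r.sequence_id,
            r.method or "",
            ",".join(r.accessions),
            "" if r.taxonomy_id is None else str(r.taxonomy_id),
            "" if r.best_hit is None else ("true" if r.best_hit else "false"),
        ] + [r.extra.get(k, "") for k in extra_cols])
    _write_tsv(path, header, body)


# ---------------------------------------------------------------------------
# archive-level validation and zip round-trip
# ---------------------------------------------------------------------------

def validate_archive(archive: ProjectArchive) -> ValidationReport:
    """Cross-file referential-integrity checks on a parsed archive.

    Findings never raise; everything lands in the report. The checks mirror
    what the import pipeline relies on: every composition cell refers to a
    known sequence and sample, every assignment refers to a known sequence,
    and at most one assignment per (sequence, method) carries the best-hit
    flag.
    """
    report = ValidationReport()
    sample_names = {s.sample_name for s in archive.sample_table}
    seq_ids = set(archive.sequences.records)

    comp_seqs: set[str] = set()
    comp_samples: set[str] = set()
    for (seq, sample) in archive.composition.entries:
        comp_seqs.add(seq)
        comp_samples.add(sample)
        if seq not in seq_ids:
            report.error("DanglingSequence", "composition", seq,
                         f"composition row for {seq!r} absent from FASTA")
        if sample not in sample_names:
            report.error("DanglingSample", "composition", sample,
                         f"composition references unknown sample {sample!r}")

    for i, row in enumerate(archive.assignments):
        if row.sequence_id not in seq_ids:
            report.error("DanglingSequence", "assignments",
                         f"row {i + 1}", f"assignment for unknown sequence "
                         f"{row.sequence_id!r}")

    best: dict[tuple[str, str | None], int] = {}
    per_method: dict[tuple[str, str | None], int] = {}
    for row in archive.assignments:
        key = (row.sequence_id, row.method)
        per_method[key] = per_method.get(key, 0) + 1
        if row.best_hit:
            best[key] = best.get(key, 0) + 1
    for key, n in best.items():
        if n > 1:
            report.error("BestHitConflict", "assignments", "/".join(
                str(k) for k in key),
                f"{n} best_hit=true rows for sequence {key[0]!r}, "
                f"method {key[1]!r}")
    for key, n in per_method.items():
        if n > 1 and best.get(key, 0) == 0:
            report.warn("MissingBestHit", "assignments", "/".join(
                str(k) for k in key),
                f"{n} assignments share method {key[1]!r} on {key[0]!r} "
                f"but none is flagged best_hit")

    for s in archive.sample_table:
        if s.sample_name not in comp_samples:
            report.warn("UnreferencedSample", "samples", s.sample_name,
                        "sample never referenced by the composition matrix")
        if "collection_date" in s.extra:
            report.warn("MalformedDate", "samples", s.sample_name,
                        f"non-ISO collection date kept as text: "
                        f"{s.extra['collection_date']!r}")
    for rid in seq_ids - comp_seqs:
        report.warn("NoContributions", "sequences", rid,
                    "FASTA record absent from composition; "
                    "imported with zero contributions")
    return report


def write_archive(archive: ProjectArchive, path: Path | str) -> Path:
    """Write the four members plus manifest into a zip.

    The archive must pass :func:`validate_archive`; the produced zip
    re-imports to an equal in-memory structure (field order and numeric
    formatting normalized).
    """
    report = validate_archive(archive)
    if not report.ok:
        raise errors.IOFailure(
            "refusing to write an invalid archive:\n" + report.summary())
    path = Path(path)
    members = {
        "samples": "samples.tsv",
        "composition": "composition.tsv",
        "sequences": "sequences.fasta",
        "assignments": "assignments.tsv",
    }
    buffers: dict[str, str] = {}

    def render(writer, payload) -> str:
        buf = io.StringIO()
        writer(payload, buf)
        return buf.getvalue()

    buffers["samples"] = render(write_sample_table, archive.sample_table)
    buffers["composition"] = render(write_composition, archive.composition)
    buffers["sequences"] = render(write_fasta, archive.sequences)
    buffers["assignments"] = render(write_assignment_table, archive.assignments)

    try:
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            write_zip_member(zf, _MANIFEST_NAME, json.dumps(members, indent=1))
            for role, name in members.items():
                write_zip_member(zf, name, buffers[role])
    except OSError as exc:
        raise errors.IOFailure(str(exc)) from exc
    return path


def write_zip_member(zf: zipfile.ZipFile, name: str, text: str) -> None:
    """Store a member with a fixed timestamp so archives are byte-reproducible."""
    info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, text)


def _sniff_role(name: str) -> str | None:
    base = Path(name).name.lower()
    if base.endswith((".fasta", ".fa", ".fna")):
        return "sequences"
    if "sample" in base:
        return "samples"
    if any(k in base for k in ("composition", "contrib", "abundance", "otu")):
        return "composition"
    if "assign" in base:
        return "assignments"
    return None


def _resolve_members(zf: zipfile.ZipFile) -> dict[str, str]:
    names = [n for n in zf.namelist() if not n.endswith("/")]
    if _MANIFEST_NAME in names:
        manifest = json.loads(zf.read(_MANIFEST_NAME).decode("utf-8"))
        return {role: manifest[role] for role in ARCHIVE_ROLES
                if role in manifest and manifest[role] in names}
    resolved: dict[str, str] = {}
    for n in names:
        role = _sniff_role(n)
        if role and role not in resolved:
            resolved[role] = n
    return resolved


def read_archive(path: Path | str,
                 workdir: Path | str | None = None
                 ) -> tuple[ProjectArchive | None, ValidationReport]:
    """Open a project zip, parse all members and validate.

    Parse failures become report errors (so a broken archive yields a report,
    not a traceback); the archive object is returned only when every member
    parsed. Members are extracted next to the zip (or into ``workdir``) so the
    FASTA random-access index points at a real file.
    """
    import tempfile

    path = Path(path)
    report = ValidationReport()
    try:
        zf = zipfile.ZipFile(path)
    except (OSError, zipfile.BadZipFile) as exc:
        report.error("IOFailure", "-", str(path), str(exc))
        return None, report

    with zf:
        members = _resolve_members(zf)
        for role in ARCHIVE_ROLES:
            if role not in members:
                report.error("MissingMember", role, "-",
                             f"archive member for role {role!r} is missing")
        if not report.ok:
            return None, report
        if workdir is None:
            workdir = Path(tempfile.mkdtemp(prefix="metadepot-archive-"))
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        extracted = {}
        for role in ARCHIVE_ROLES:
            target = workdir / f"{role}{Path(members[role]).suffix or '.tsv'}"
            target.write_bytes(zf.read(members[role]))
            extracted[role] = target

    parsed: dict[str, object] = {}
    parsers = {
        "samples": read_sample_table,
        "composition": read_composition,
        "sequences": read_fasta,
        "assignments": read_assignment_table,
    }
    for role, parser in parsers.items():
        try:
            parsed[role] = parser(extracted[role])
        except errors.MetadepotError as exc:
            report.error(exc.code, role, "-", str(exc))
    if not report.ok:
        return None, report

    archive = ProjectArchive(
        sample_table=parsed["samples"],
        composition=parsed["composition"],
        sequences=parsed["sequences"],
        assignments=parsed["assignments"],
    )
    cross = validate_archive(archive)
    report.errors.extend(cross.errors)
    report.warnings.extend(cross.warnings)
    return archive, report
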