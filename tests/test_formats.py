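"""File-suite readers, writers and the archive validator."""

from __future__ import annotations

import io
import zipfile

import pytest
from hypothesis import given, settings, strategies as st

from metadepot import errors, formats
from metadepot.fixtures import BROKEN_DEFECTS, FixtureSpec, make_broken_archive


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# lat/lon
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("38.98 N 77.11 W", (38.98, -77.11)),
    ("12.5 S 45.25 E", (-12.5, 45.25)),
    ("0 0", (0.0, 0.0)),
    ("-33.9, 18.4", (-33.9, 18.4)),
    ("90 N 180 W", (90.0, -180.0)),
    ("", None),
    ("NA", None),
    ("not collected", None),
])
def test_parse_lat_lon_dialects(text, expected):
    assert formats.parse_lat_lon(text) == expected


@pytest.mark.parametrize("text", [
    "91.0 N 10.0 E",      # latitude beyond the pole
    "10.0 N 181.0 E",
    "38.98 X 77.11 W",    # bad hemisphere letter
    "1 2 3",
    "abc",
])
def test_parse_lat_lon_rejects(text):
    with pytest.raises(errors.MalformedCoordinate):
        formats.parse_lat_lon(text)


def test_lat_lon_grid_round_trip():
    for lat in range(-90, 91, 15):
        for lon in range(-180, 181, 30):
            p = (float(lat), float(lon))
            assert formats.parse_lat_lon(formats.format_lat_lon(p)) == p


@given(lat=st.floats(-90, 90), lon=st.floats(-180, 180))
@settings(max_examples=100, deadline=None)
def test_lat_lon_float_round_trip(lat, lon):
    p = (lat, lon)
    assert formats.parse_lat_lon(formats.format_lat_lon(p)) == p


# ---------------------------------------------------------------------------
# dates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,lo,hi", [
    ("2020-06-15", "2020-06-15", "2020-06-15"),
    ("2020-06", "2020-06-01", "2020-06-30"),
    ("2020-02", "2020-02-01", "2020-02-29"),  # leap year
    ("2019", "2019-01-01", "2019-12-31"),
    ("2020-12", "2020-12-01", "2020-12-31"),
])
def test_date_bounds(text, lo, hi):
    a, b = formats.date_bounds(formats.parse_iso_date(text))
    assert (a.isoformat(), b.isoformat()) == (lo, hi)


@pytest.mark.parametrize("text", ["June 2020", "2020-13", "2020-02-30",
                                  "20-01-01", "2020/01/01"])
def test_bad_dates_rejected(text):
    with pytest.raises(errors.MalformedDate):
        formats.parse_iso_date(text)


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

SAMPLE_HEADER = "sample_name\tcollection_date\tlat_lon\thost\n"


def test_sample_table_parses_standard_and_extra(tmp_path):
    path = write(tmp_path, "s.tsv", SAMPLE_HEADER
                 + "s1\t2020-01-02\t10.5 N 20.25 E\tcow\n"
                 + "s2\t\t\t\n")
    records = formats.read_sample_table(path)
    assert [r.sample_name for r in records] == ["s1", "s2"]
    assert records[0].collection_date == "2020-01-02"
    assert records[0].lat_lon == (10.5, 20.25)
    assert records[0].extra == {"host": "cow"}
    assert records[1].collection_date is None
    assert records[1].lat_lon is None


@pytest.mark.parametrize("missing", ["sample_name", "collection_date",
                                     "lat_lon"])
def test_sample_table_requires_standard_columns(tmp_path, missing):
    cols = [c for c in ("sample_name", "collection_date", "lat_lon", "host")
            if c != missing]
    path = write(tmp_path, "s.tsv",
                 "\t".join(cols) + "\n" + "\t".join(["x"] * len(cols)) + "\n")
    with pytest.raises(errors.MissingColumn) as exc:
        formats.read_sample_table(path)
    assert missing in str(exc.value)


def test_sample_table_duplicate_and_malformed(tmp_path):
    dup = write(tmp_path, "dup.tsv", SAMPLE_HEADER
                + "s1\t\t\ta\n" + "s1\t\t\tb\n")
    with pytest.raises(errors.DuplicateSample):
        formats.read_sample_table(dup)
    bad = write(tmp_path, "bad.tsv", SAMPLE_HEADER + "s1\t\t\n")
    with pytest.raises(errors.MalformedRow):
        formats.read_sample_table(bad)


def test_sample_table_non_iso_date_kept_as_text(tmp_path):
    path = write(tmp_path, "s.tsv", SAMPLE_HEADER
                 + "s1\tspring 2019\t\t\n")
    rec = formats.read_sample_table(path)[0]
    assert rec.collection_date is None
    assert rec.extra["collection_date"] == "spring 2019"


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_composition_wide_sparse(tmp_path):
    path = write(tmp_path, "c.tsv",
                 "sequence_id\tsA\tsB\n"
                 "q1\t3\t0\n" "q2\t1.5\t2\n" "q3\t\t4\n")
    m = formats.read_composition(path)
    assert len(m.entries) == 4  # zero and blank cells omitted
    assert m.entries[("q2", "sA")] == 1.5
    assert m.row_sums() == {"q1": 3.0, "q2": 3.5, "q3": 4.0}


def test_composition_long_dialect(tmp_path):
    path = write(tmp_path, "c.tsv",
                 "sequence\tsample\tvalue\n" "q1\tsA\t3\n" "q1\tsB\t2\n")
    m = formats.read_composition(path)
    assert m.entries == {("q1", "sA"): 3.0, ("q1", "sB"): 2.0}


@pytest.mark.parametrize("body,err", [
    ("q1\t-4\t1\n", errors.NegativeContribution),
    ("q1\t1\t1\nq1\t2\t2\n", errors.DuplicateSequenceRow),
    ("q1\tx\t1\n", errors.NonNumericCell),
])
def test_composition_rejects(tmp_path, body, err):
    path = write(tmp_path, "c.tsv", "sequence_id\tsA\tsB\n" + body)
    with pytest.raises(err):
        formats.read_composition(path)


def test_composition_round_trip_preserves_row_sums(tmp_path, bundle):
    m = bundle["archive"].composition
    out = tmp_path / "c.tsv"
    formats.write_composition(m, out)
    again = formats.read_composition(out)
    # row sums recomputed independently of the writer
    expected = {}
    for (seq, _), v in m.entries.items():
        expected[seq] = expected.get(seq, 0.0) + v
    assert again.row_sums() == pytest.approx(expected)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_fasta_parse_and_lengths(tmp_path):
    path = write(tmp_path, "f.fasta", ">s1 desc\nACGT\n>s2\nACGTA\nCGT\n")
    s = formats.read_fasta(path)
    assert s.records["s1"] == "ACGT"
    assert s.index["s1"][1] == 4
    assert s.records["s2"] == "ACGTACGT"


def test_fasta_duplicate_and_empty(tmp_path):
    dup = write(tmp_path, "d.fasta", ">s1\nAC\n>s1\nGT\n")
    with pytest.raises(errors.DuplicateId):
        formats.read_fasta(dup)
    empty = write(tmp_path, "e.fasta", ">s1\n>s2\nAC\n")
    with pytest.raises(errors.EmptySequence):
        formats.read_fasta(empty)


def test_fasta_index_fetch_matches_full_parse(tmp_path, bundle):
    """Random access through the byte-offset index equals a full scan."""
    records = dict(list(bundle["archive"].sequences.records.items())[:100])
    path = tmp_path / "r.fasta"
    formats.write_fasta(records, path)
    s = formats.read_fasta(path)
    for rid, seq in records.items():
        assert s.fetch(rid) == seq  # seek-based
        assert s.records[rid] == seq  # full-parse


# ---------------------------------------------------------------------------
# assignments
# ---------------------------------------------------------------------------

ASG_HEADER = "sequence_id\tmethod\taccessions\ttaxonomy_id\tbest_hit\tevalue\n"


def test_assignment_csv_split_and_version_strip(tmp_path):
    path = write(tmp_path, "a.tsv", ASG_HEADER
                 + "q1\tblastn\tAB123456.1, kx987654\t\ttrue\t1e-5\n")
    rows = formats.read_assignment_table(path)
    assert rows[0].accessions == ["AB123456", "KX987654"]
    assert rows[0].best_hit is True
    assert rows[0].extra == {"evalue": "1e-5"}


def test_assignment_multiple_lines_per_sequence(tmp_path):
    path = write(tmp_path, "a.tsv", ASG_HEADER
                 + "q1\tblastn\tAB1\t\t\t\n" + "q1\tblastx\tAB2\t\t\t\n")
    rows = formats.read_assignment_table(path)
    assert [r.sequence_id for r in rows] == ["q1", "q1"]
    assert [r.method for r in rows] == ["blastn", "blastx"]


def test_assignment_explicit_taxid_without_accessions(tmp_path):
    path = write(tmp_path, "a.tsv", ASG_HEADER + "q1\t\t\t42\t\t\n")
    assert formats.read_assignment_table(path)[0].taxonomy_id == 42


@pytest.mark.parametrize("line,err", [
    ("q1\tblastn\t\t\t\t\n", errors.NoTarget),
    ("q1\tblastn\tAB1\t\tmaybe\t\n", errors.MalformedBestHit),
    ("q1\tblastn\tAB1\tabc\t\t\n", errors.MalformedRow),
])
def test_assignment_rejects(tmp_path, line, err):
    path = write(tmp_path, "a.tsv", ASG_HEADER + line)
    with pytest.raises(err):
        formats.read_assignment_table(path)


@pytest.mark.parametrize("token,value", [
    ("true", True), ("FALSE", False), ("1", True), ("0", False),
    ("Yes", True), ("no", False),
])
def test_best_hit_boolean_dialects(tmp_path, token, value):
    path = write(tmp_path, "a.tsv", ASG_HEADER + f"q1\t\tAB1\t\t{token}\t\n")
    assert formats.read_assignment_table(path)[0].best_hit is value


# ---------------------------------------------------------------------------
# archive validation + round-trip
# ---------------------------------------------------------------------------

_EXPECTED_DEFECT_CODE = {
    "missing_member": "MissingMember",
    "dangling_sequence": "DanglingSequence",
    "dangling_sample": "DanglingSample",
    "best_hit_conflict": "BestHitConflict",
    "bad_latlon": "MalformedCoordinate",
    "negative_count": "NegativeContribution",
}


@pytest.mark.parametrize("defect", BROKEN_DEFECTS)
def test_broken_archive_reports_injected_defect(tmp_path, small_tax, defect):
    path = make_broken_archive(FixtureSpec(seed=5, n_sequences=12), defect,
                               tmp_path / f"{defect}.zip", small_tax["tax"])
    archive, report = formats.read_archive(path, tmp_path / defect)
    assert not report.ok
    codes = {f.code for f in report.errors}
    assert _EXPECTED_DEFECT_CODE[defect] in codes
    if defect == "missing_member":
        assert len(report.errors) == 1


def test_valid_archive_round_trips(tmp_path, bundle):
    out = tmp_path / "a.zip"
    formats.write_archive(bundle["archive"], out)
    again, report = formats.read_archive(out, tmp_path / "x")
    assert report.ok
    assert again.sample_table == bundle["archive"].sample_table
    assert again.composition == bundle["archive"].composition
    assert again.sequences == bundle["archive"].sequences
    assert again.assignments == bundle["archive"].assignments


def test_unicode_metadata_survives_round_trip(tmp_path):
    archive = formats.ProjectArchive(
        sample_table=[formats.SampleRecord(
            "sø1", "2020-01-01", (1.0, 2.0), {"host": "Ñandú grebe"})],
        composition=formats.CompositionMatrix({("q1", "sø1"): 2.0}),
        sequences=formats.SequenceSet(records={"q1": "ACGT"},
                                      index={"q1": (0, 4)}),
        assignments=[formats.AssignmentRow("q1", "blastn", ["AB1"])],
    )
    out = tmp_path / "u.zip"
    formats.write_archive(archive, out)
    again, report = formats.read_archive(out, tmp_path / "x")
    assert report.ok
    assert again.sample_table[0].sample_name == "sø1"
    assert again.sample_table[0].extra["host"] == "Ñandú grebe"


def test_writer_refuses_invalid_archive(tmp_path):
    archive = formats.ProjectArchive(
        sample_table=[], composition=formats.CompositionMatrix(),
        sequences=formats.SequenceSet(),
        assignments=[formats.AssignmentRow("ghost", "m", ["AB1"])])
    with pytest.raises(errors.IOFailure):
        formats.write_archive(archive, tmp_path / "bad.zip")
    assert not (tmp_path / "bad.zip").exists()


def test_archive_role_sniffing_without_manifest(tmp_path, bundle):
    """Member resolution falls back to file-name sniffing."""
    src = tmp_path / "a.zip"
    formats.write_archive(bundle["archive"], src)
    dst = tmp_path / "nomanifest.zip"
    with zipfile.ZipFile(src) as zin, \
            zipfile.ZipFile(dst, "w") as zout:
        for name in zin.namelist():
            if name != "manifest.json":
                zout.writestr(name, zin.read(name))
    again, report = formats.read_archive(dst, tmp_path / "y")
    assert report.ok
    assert again.composition == bundle["archive"].composition


def test_missing_member_detected(tmp_path, bundle):
    src = tmp_path / "a.zip"
    formats.write_archive(bundle["archive"], src)
    dst = tmp_path / "truncated.zip"
    with zipfile.ZipFile(src) as zin, zipfile.ZipFile(dst, "w") as zout:
        for name in zin.namelist():
            if name not in ("manifest.json", "samples.tsv"):
                zout.writestr(name, zin.read(name))
    archive, report = formats.read_archive(dst, tmp_path / "z")
    assert archive is None
    assert [f.code for f in report.errors] == ["MissingMember"]
    assert report.errors[0].member == "samples"
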