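"""Deterministic synthetic-data generator with known ground truth.

Everything the test surface needs — taxonomies in taxdump dialect, accession
mapping tables, valid project archives, and archives with one injected
defect — is generated from a :class:`FixtureSpec` and a seed. Alongside each
archive comes a ground-truth *ledger*: the true taxon behind every accession,
the expected resolved taxon of every assignment row (first common ancestors
computed here by an independent parent-walk, not by the taxonomy module),
the best-hit choice per method, and the contribution totals. Tests read
expectations from the ledger or from closed-form counts, never from the code
under test.

The generator emulates the shape of real imports (multi-line assignments,
CSV accession lists with version suffixes, partial dates, a sample without
coordinates, an unassigned fraction) but not community ecology: abundances
are uniform draws, not an ecological model, and sequences are uniform
random nucleotides.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

from . import formats
from .formats import (AssignmentRow, CompositionMatrix, ProjectArchive,
                      SampleRecord, SequenceSet)
from .taxonomy import Taxonomy, TaxonomyNode

CANONICAL_RANKS = ("superkingdom", "phylum", "class", "order", "family",
                   "genus", "species")

_METHOD_POOL = ("blastn", "blastx", "diamond", "vsearch")
_HOST_POOL = ("bovine", "human", "tomato", "maize", "bat", "tick")
_HABITAT_POOL = ("soil", "freshwater", "marine", "gut", "phyllosphere")

BROKEN_DEFECTS = ("missing_member", "dangling_sequence", "dangling_sample",
                  "best_hit_conflict", "bad_latlon", "negative_count")


@dataclass
class FixtureSpec:
    """Knobs of the generator; defaults emulate a small shotgun project."""

    seed: int = 0
    n_samples: int = 6
    n_sequences: int = 40
    fraction_assigned: float = 0.7
    n_methods: int = 2
    taxonomy_depth: int = 7        # levels below the root
    taxonomy_branching: int = 2
    #: accession-count distribution for accession-based assignment rows
    accession_multiplicity: Mapping[int, float] = dc_field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    #: fraction of assignment rows carrying an explicit taxonomy_id instead
    direct_taxid_fraction: float = 0.25
    seq_length: tuple[int, int] = (120, 800)
    #: "int" = shotgun read-recruitment counts; "decimal" = OTU abundances
    contribution_kind: str = "int"
    lat_range: tuple[float, float] = (-35.0, 55.0)
    lon_range: tuple[float, float] = (-20.0, 120.0)
    date_range: tuple[int, int] = (2015, 2021)
    #: (name, dtype, n_distinct) — n_distinct 0 means free values
    sample_fields: tuple = (("host", "text", 4), ("habitat", "text", 3))
    assignment_fields: tuple = (("evalue", "number", 0),
                                ("identity", "number", 0))
    id_prefix: str = "p1"


def largest_remainder_split(total: int, fraction: float) -> tuple[int, int]:
    """Split ``total`` into (assigned, unassigned) by floor + largest
    remainder, so e.g. 0.7 of 10 is exactly 7 (ties favour assigned)."""
    quota_a = fraction * total
    quota_u = (1 - fraction) * total
    assigned, unassigned = int(quota_a), int(quota_u)
    if assigned + unassigned < total:  # one leftover unit
        if quota_a - assigned >= quota_u - unassigned:
            assigned += 1
        else:
            unassigned += 1
    return assigned, total - assigned


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def make_taxonomy(depth: int, branching: int,
                  out_dir: Path | str | None = None
                  ) -> tuple[Taxonomy, dict[int, int]]:
    """Complete ``branching``-ary taxonomy of ``depth`` levels below the root.

    Node count is sum(b^d for d in 0..depth); taxids are assigned in
    breadth-first order starting at 1. Levels 1..7 carry the canonical ranks
    in order, deeper levels "no rank" (strain-like). When ``out_dir`` is
    given, ``nodes.dmp`` and ``names.dmp`` are written there in taxdump
    dialect. Returns the taxonomy plus the raw parent map the ledger uses
    for independent ancestor walks.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    parents: dict[int, int] = {1: 1}
    ranks: dict[int, str] = {1: "no rank"}
    level_nodes = [1]
    next_id = 2
    for level in range(1, depth + 1):
        rank = (CANONICAL_RANKS[level - 1] if level <= len(CANONICAL_RANKS)
                else "no rank")
        new_level = []
        for parent in level_nodes:
            for _ in range(branching):
                parents[next_id] = parent
                ranks[next_id] = rank
                new_level.append(next_id)
                next_id += 1
        level_nodes = new_level

    nodes = {t: TaxonomyNode(t, parents[t], ranks[t], f"taxon_{t}")
             for t in parents}
    tax = Taxonomy(nodes, root_taxid=1)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "nodes.dmp", "w", encoding="utf-8") as fh:
            for t in sorted(parents):
                fh.write(f"{t}\t|\t{parents[t]}\t|\t{ranks[t]}\t|\n")
        with open(out_dir / "names.dmp", "w", encoding="utf-8") as fh:
            for t in sorted(parents):
                fh.write(f"{t}\t|\ttaxon_{t}\t|\t\t|\tscientific name\t|\n")
    return tax, parents


def path_to_root(parents: Mapping[int, int], taxid: int) -> list[int]:
    """Independent parent-walk used for ledger LCAs and oracle checks."""
    path = [taxid]
    while parents[path[-1]] != path[-1]:
        path.append(parents[path[-1]])
    return path


def brute_force_lca(parents: Mapping[int, int], taxids: list[int]) -> int:
    """LCA as the deepest element of the intersected root paths."""
    paths = [list(reversed(path_to_root(parents, t))) for t in taxids]
    answer = paths[0][0]
    for level in zip(*paths):
        if len(set(level)) != 1:
            break
        answer = level[0]
    return answer


# ---------------------------------------------------------------------------
# archive
# ---------------------------------------------------------------------------

def _pick_multiplicity(rng: random.Random, dist: Mapping[int, float]) -> int:
    r = rng.random()
    acc = 0.0
    for k in sorted(dist):
        acc += dist[k]
        if r <= acc:
            return k
    return max(dist)


def _field_values(rng: random.Random, name: str, dtype: str, n_distinct: int,
                  n_rows: int) -> list[str]:
    if dtype == "number":
        return [formats.format_number(round(rng.uniform(0, 100), 3))
                for _ in range(n_rows)]
    if dtype == "date":
        return [f"{rng.randint(2000, 2021)}-{rng.randint(1, 12):02d}"
                for _ in range(n_rows)]
    if n_distinct and n_distinct > 0:
        if name == "host":
            pool = [_HOST_POOL[i % len(_HOST_POOL)] + (
                "" if i < len(_HOST_POOL) else f"_{i}")
                for i in range(n_distinct)]
        elif name == "habitat":
            pool = [_HABITAT_POOL[i % len(_HABITAT_POOL)] + (
                "" if i < len(_HABITAT_POOL) else f"_{i}")
                for i in range(n_distinct)]
        else:
            pool = [f"{name}_{i + 1:05d}" for i in range(n_distinct)]
        # guarantee the target distinct count when rows allow it
        values = [pool[i % len(pool)] for i in range(n_rows)]
        rng.shuffle(values)
        return values
    return [f"{name}_{rng.randint(1, 10_000):05d}" for _ in range(n_rows)]


def make_archive(spec: FixtureSpec, tax: Taxonomy,
                 parents: Mapping[int, int] | None = None
                 ) -> tuple[ProjectArchive, dict]:
    """Generate a valid archive plus its ground-truth ledger.

    Guaranteed features (when sizes permit): at least one sequence with
    several assignment lines, one multi-accession row, one unassigned
    sequence, and one sample without coordinates. The ledger's expected taxa
    come from an independent parent-walk over the raw parent map.
    """
    rng = random.Random(spec.seed)
    if parents is None:
        parents = {t: n.parent_taxid for t, n in tax.nodes.items()}
    non_leaves = {parents[t] for t in parents if parents[t] != t}
    leaves = [t for t in sorted(parents) if t not in non_leaves]
    all_taxids = sorted(parents)
    prefix = spec.id_prefix

    # -- samples ---------------------------------------------------------
    samples: list[SampleRecord] = []
    sample_field_values = {
        name: _field_values(rng, name, dtype, n_distinct, spec.n_samples)
        for name, dtype, n_distinct in spec.sample_fields}
    for i in range(spec.n_samples):
        name = f"{prefix}_S{i + 1:03d}"
        if i == spec.n_samples - 1 and spec.n_samples > 1:
            lat_lon = None  # one sample always lacks coordinates
        else:
            lat_lon = (round(rng.uniform(*spec.lat_range), 4),
                       round(rng.uniform(*spec.lon_range), 4))
        year = rng.randint(*spec.date_range)
        if i == 0 and spec.n_samples > 1:
            cdate = f"{year}-{rng.randint(1, 12):02d}"  # month precision
        else:
            cdate = (f"{year}-{rng.randint(1, 12):02d}-"
                     f"{rng.randint(1, 28):02d}")
        extra = {name_: values[i]
                 for name_, values in sample_field_values.items()}
        samples.append(SampleRecord(name, cdate, lat_lon, extra))

    # -- sequences + partition ------------------------------------------
    n_assigned, n_unassigned = largest_remainder_split(
        spec.n_sequences, spec.fraction_assigned)
    seq_ids = [f"{prefix}_seq{i + 1:05d}" for i in range(spec.n_sequences)]
    assigned_ids = seq_ids[:n_assigned]
    unassigned_ids = seq_ids[n_assigned:]
    records = {
        rid: "".join(rng.choice("ACGT")
                     for _ in range(rng.randint(*spec.seq_length)))
        for rid in seq_ids}
    sequences = SequenceSet(records=records,
                            index={r: (0, len(s)) for r, s in records.items()})

    # -- composition -----------------------------------------------------
    matrix = CompositionMatrix()
    contribution_total = 0.0
    for rid in seq_ids:
        k = min(rng.randint(1, 3), spec.n_samples)
        for sample in rng.sample(samples, k):
            if spec.contribution_kind == "int":
                value = float(rng.randint(1, 500))
            else:
                value = round(rng.uniform(0.001, 1.0), 4)
            matrix.entries[(rid, sample.sample_name)] = value
            contribution_total += value

    # -- assignments -----------------------------------------------------
    methods = list(_METHOD_POOL[:spec.n_methods])
    accession2taxid: dict[str, int] = {}
    acc_counter = 0

    def new_accession(taxid: int) -> str:
        nonlocal acc_counter
        acc_counter += 1
        acc = f"AC{acc_counter:06d}"
        accession2taxid[acc] = taxid
        return acc

    rows: list[AssignmentRow] = []
    ledger_rows: list[dict] = []
    expected_best: dict[str, dict[str, int | None]] = {}

    # text fields with a distinct-value target cycle through a pool of that
    # size, so the target is met exactly once enough rows exist
    text_cyclers: dict[str, list] = {
        name: [[f"{name}_{i + 1:05d}" for i in range(n_distinct)], 0]
        for name, dtype, n_distinct in spec.assignment_fields
        if dtype == "text" and n_distinct}

    def make_row(rid: str, method: str, best: bool | None,
                 force_multi_acc: bool = False) -> None:
        direct = (not force_multi_acc
                  and rng.random() < spec.direct_taxid_fraction)
        extra = {}
        for name, dtype, n_distinct in spec.assignment_fields:
            if name in text_cyclers:
                pool, pos = text_cyclers[name]
                extra[name] = pool[pos % len(pool)]
                text_cyclers[name][1] = pos + 1
            else:
                extra[name] = _field_values(rng, name, dtype, n_distinct, 1)[0]
        if direct:
            taxid = rng.choice(all_taxids)
            row = AssignmentRow(rid, method, [], taxid, best, extra)
            expected = taxid
            acc_taxids: list[int] = []
        else:
            mult = (max(2, _pick_multiplicity(rng, spec.accession_multiplicity))
                    if force_multi_acc
                    else _pick_multiplicity(rng, spec.accession_multiplicity))
            if mult > 1:
                # congeneric hits: leaves below one random internal node
                anchor = rng.choice([t for t in all_taxids
                                     if t not in leaves] or all_taxids)
                below = [t for t in leaves
                         if anchor in path_to_root(parents, t)]
                chosen = [rng.choice(below or leaves) for _ in range(mult)]
            else:
                chosen = [rng.choice(leaves)]
            accs = [new_accession(t) for t in chosen]
            # exercise version-suffix stripping on the raw cell
            raw_accs = [a + ".1" if rng.random() < 0.3 else a for a in accs]
            row = AssignmentRow(rid, method, [
                formats.canonical_accession(a) for a in raw_accs],
                None, best, extra)
            acc_taxids = chosen
            expected = (chosen[0] if len(chosen) == 1
                        else brute_force_lca(parents, chosen))
        rows.append(row)
        ledger_rows.append({
            "sequence_id": rid, "method": method,
            "accessions": list(row.accessions),
            "taxonomy_id": row.taxonomy_id, "best_hit": best,
            "accession_taxids": acc_taxids, "expected_taxid": expected,
        })
        if best or best is None:
            expected_best.setdefault(rid, {})[method] = expected

    forced_multi_line = assigned_ids[0] if assigned_ids else None
    forced_multi_acc = assigned_ids[1 % len(assigned_ids)] if assigned_ids \
        else None
    for rid in assigned_ids:
        seq_methods = [m for m in methods if rng.random() < 0.8] or \
            [rng.choice(methods)]
        if rid == forced_multi_line and len(seq_methods) >= 1:
            n_rows_first = 2
        else:
            n_rows_first = None
        for mi, method in enumerate(seq_methods):
            n_rows = (n_rows_first if mi == 0 and n_rows_first
                      else (2 if rng.random() < 0.25 else 1))
            best_at = rng.randrange(n_rows)
            for j in range(n_rows):
                if n_rows == 1:
                    best = True if rng.random() < 0.5 else None
                else:
                    best = (j == best_at)
                make_row(rid, method, best,
                         force_multi_acc=(rid == forced_multi_acc
                                          and mi == 0 and j == 0))

    archive = ProjectArchive(sample_table=samples, composition=matrix,
                             sequences=sequences, assignments=rows)
    ledger = {
        "prefix": prefix,
        "samples": [s.sample_name for s in samples],
        "sample_without_coords": (samples[-1].sample_name
                                  if spec.n_samples > 1 else None),
        "n_sequences": spec.n_sequences,
        "assigned_ids": assigned_ids,
        "unassigned_ids": unassigned_ids,
        "methods": methods,
        "accession2taxid": accession2taxid,
        "assignments": ledger_rows,
        "expected_best_taxid": expected_best,
        "contribution_total": contribution_total,
    }
    return archive, ledger


def write_mapping(accession2taxid: Mapping[str, int],
                  path: Path | str) -> int:
    """Write the ledger's accession table as an accession2taxid-style TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\ttaxid\n")
        for acc in sorted(accession2taxid):
            fh.write(f"{acc}\t{accession2taxid[acc]}\n")
    return len(accession2taxid)


# ---------------------------------------------------------------------------
# broken archives
# ---------------------------------------------------------------------------

def make_broken_archive(spec: FixtureSpec, defect: str,
                        out_path: Path | str,
                        tax: Taxonomy | None = None) -> Path:
    """Write an archive zip with exactly one injected defect.

    The starting point is a valid generated archive; the defect is injected
    into the in-memory structures (or, for ``missing_member``, by dropping a
    zip member), and the members are rendered directly so the normal writer's
    validity check cannot interfere.
    """
    import io
    import zipfile

    if defect not in BROKEN_DEFECTS:
        raise ValueError(f"unknown defect {defect!r}; "
                         f"choose from {BROKEN_DEFECTS}")
    if tax is None:
        tax, _ = make_taxonomy(spec.taxonomy_depth, spec.taxonomy_branching)
    archive, _ = make_archive(spec, tax)

    if defect == "dangling_sequence":
        sample = archive.sample_table[0].sample_name
        archive.composition.entries[("ghost_seq", sample)] = 7.0
    elif defect == "dangling_sample":
        seq = next(iter(archive.sequences.records))
        archive.composition.entries[(seq, "ghost_sample")] = 7.0
    elif defect == "best_hit_conflict":
        target = None
        groups: dict[tuple[str, str | None], list] = {}
        for row in archive.assignments:
            groups.setdefault((row.sequence_id, row.method), []).append(row)
        for rows in groups.values():
            if len(rows) > 1:
                target = rows
                break
        if target is None:  # make a sibling if none exists
            first = archive.assignments[0]
            sibling = AssignmentRow(first.sequence_id, first.method,
                                    list(first.accessions),
                                    first.taxonomy_id, True,
                                    dict(first.extra))
            archive.assignments.append(sibling)
            target = [first, sibling]
        for row in target:
            row.best_hit = True
    elif defect == "bad_latlon":
        archive.sample_table[0].lat_lon = (91.0, 10.0)
    elif defect == "negative_count":
        key = next(iter(archive.composition.entries))
        archive.composition.entries[key] = -4.0

    def render(writer, payload) -> str:
        buf = io.StringIO()
        writer(payload, buf)
        return buf.getvalue()

    members = {
        "samples": ("samples.tsv",
                    render(formats.write_sample_table, archive.sample_table)),
        "composition": ("composition.tsv",
                        render(formats.write_composition, archive.composition)),
        "sequences": ("sequences.fasta",
                      render(formats.write_fasta, archive.sequences)),
        "assignments": ("assignments.tsv",
                        render(formats.write_assignment_table,
                               archive.assignments)),
    }
    if defect == "missing_member":
        members.pop("assignments")

    out_path = Path(out_path)
    manifest = {role: name for role, (name, _) in members.items()}
    import json
    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        formats.write_zip_member(zf, "manifest.json",
                                 json.dumps(manifest, indent=1))
        for role, (name, text) in members.items():
            formats.write_zip_member(zf, name, text)
    return out_path


def load_spec(path: Path | str) -> FixtureSpec:
    """Read a FixtureSpec from a YAML key-value file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f for f in FixtureSpec.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown fixture-spec keys: {sorted(unknown)}")
    for key in ("seq_length", "lat_range", "lon_range", "date_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    for key in ("sample_fields", "assignment_fields"):
        if key in raw:
            raw[key] = tuple(tuple(item) for item in raw[key])
    if "accession_multiplicity" in raw:
        raw["accession_multiplicity"] = {
            int(k): float(v) for k, v in raw["accession_multiplicity"].items()}
    return FixtureSpec(**raw)
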