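"""Faceted query engine with sequence/sample/assignment grouping.

Match semantics
---------------
A query is a conjunction of typed filters over one or more projects:

* an **assignment** matches iff it satisfies every assignment-level filter
  (taxon membership via subtree expansion, method, best-hit flag, and any
  user assignment field);
* a **sequence** matches iff it satisfies the sequence-level filters, has at
  least one matching assignment (vacuously true when no assignment-level
  filter is present), and receives a contribution from at least one sample
  satisfying every sample-level filter ("any contributing sample" — a contig
  assembled from several samples surfaces if any of its sources is selected);
* a **sample** matches iff it satisfies the sample-level filters and
  contributes to at least one matching sequence.

Only sequences in the *assigned* partition are searchable; unassigned
sequences exist solely for sequence retrieval and export.

The taxonomy views (count tree, Krona rows) require a single taxon per
sequence. :func:`effective_query_for_taxonomy_views` normalizes a query the
same way the exploration GUI of a data portal would: when the selected
projects involve several assignment methods one must be chosen, and when any
sequence carries multiple assignments the best-hit restriction is switched
on — this is exactly what makes the table total and the tree totals agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Union

from . import errors
from .formats import date_bounds, parse_iso_date
from .store import Store

# ---------------------------------------------------------------------------
# filter variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Categorical:
    """Keep records whose text field takes one of the accepted values."""
    field: str
    values: frozenset[str]

    def __init__(self, field: str, values: Iterable[str]):
        object.__setattr__(self, "field", field)
        object.__setattr__(self, "values", frozenset(values))


@dataclass(frozen=True)
class NumericRange:
    field: str
    min: float | None = None
    max: float | None = None


@dataclass(frozen=True)
class DateRange:
    """Day-resolution date window; partial ISO bounds snap to the interval
    start on the min side and the interval end on the max side."""
    field: str
    min: str | None = None
    max: str | None = None


@dataclass(frozen=True)
class TaxonFilter:
    """Membership in the union of the given taxa's subtrees (inclusive)."""
    taxids: frozenset[int]

    def __init__(self, taxids: Iterable[int]):
        object.__setattr__(self, "taxids", frozenset(taxids))


@dataclass(frozen=True)
class GeoBox:
    """Latitude/longitude box; ``lon_min > lon_max`` wraps the antimeridian."""
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float


@dataclass(frozen=True)
class MethodFilter:
    methods: frozenset[str]

    def __init__(self, methods: Iterable[str]):
        object.__setattr__(self, "methods", frozenset(methods))


@dataclass(frozen=True)
class BestHitOnly:
    enabled: bool = True


Filter = Union[Categorical, NumericRange, DateRange, TaxonFilter, GeoBox,
               MethodFilter, BestHitOnly]

GROUPINGS = ("sequence", "sample", "assignment")


@dataclass(frozen=True)
class Query:
    projects: tuple[str, ...]
    filters: tuple[Filter, ...] = ()
    grouping: str = "sequence"
    sort: str | None = None
    descending: bool = False
    offset: int = 0
    limit: int | None = None

    def __init__(self, projects, filters=(), grouping="sequence", sort=None,
                 descending=False, offset=0, limit=None):
        if grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {grouping!r}")
        object.__setattr__(self, "projects", tuple(projects))
        object.__setattr__(self, "filters", tuple(filters))
        object.__setattr__(self, "grouping", grouping)
        object.__setattr__(self, "sort", sort)
        object.__setattr__(self, "descending", descending)
        object.__setattr__(self, "offset", offset)
        object.__setattr__(self, "limit", limit)


@dataclass
class ResultPage:
    rows: list[dict]
    total_count: int
    grouping: str


@dataclass
class FacetSpec:
    field: str
    widget: str  # enumerated_list | autocomplete | numeric_range |
    #              date_range | taxonomy_tree | geo_map
    payload: object = None


#: distinct-value threshold separating the plain enumerated list widget from
#: the autocompleting one for text fields
FACET_LIST_THRESHOLD = 1000

_BUILTIN_ENTITY = {
    "collection_date": ("sample", "date"),
    "lat_lon": ("sample", "geo"),
    "length": ("sequence", "number"),
    "method": ("assignment", "text"),
    "taxonomy": ("assignment", "taxon"),
}


# ---------------------------------------------------------------------------
# predicate compilation
# ---------------------------------------------------------------------------

class _Pred:
    """A compiled SQL predicate fragment plus its bound parameters."""

    def __init__(self, sql: str, params: list):
        self.sql = sql
        self.params = params


def _field_info(db: Store, name: str) -> tuple[str, str]:
    """(entity, dtype) for a filterable field, registry-backed."""
    if name in _BUILTIN_ENTITY:
        return _BUILTIN_ENTITY[name]
    desc = db.get_field(name)
    return desc.entity, desc.dtype


def _date_lo(iso: str) -> str:
    return date_bounds(parse_iso_date(iso))[0].isoformat()


def _date_hi(iso: str) -> str:
    return date_bounds(parse_iso_date(iso))[1].isoformat()


def _compile_filters(db: Store, filters: Iterable[Filter]
                     ) -> dict[str, list[_Pred]]:
    """Partition filters by entity level and compile each to SQL.

    Sample predicates reference alias ``m`` (samples), sequence predicates
    alias ``s`` (sequences) and assignment predicates alias ``a``
    (assignments); user-field conditions go through EXISTS subqueries on the
    typed side tables so they run off the per-dtype indexes.
    """
    out: dict[str, list[_Pred]] = {"sample": [], "sequence": [],
                                   "assignment": []}
    for f in filters:
        if isinstance(f, GeoBox):
            if (f.lat_min <= -90 and f.lat_max >= 90
                    and f.lon_min <= -180 and f.lon_max >= 180):
                continue  # whole globe selected = no restriction drawn,
                #           so samples without coordinates still match
            sql = "m.lat IS NOT NULL AND m.lat >= ? AND m.lat <= ? AND "
            params: list = [f.lat_min, f.lat_max]
            if f.lon_min <= f.lon_max:
                sql += "m.lon >= ? AND m.lon <= ?"
                params += [f.lon_min, f.lon_max]
            else:  # antimeridian crossing: split into two boxes
                sql += "(m.lon >= ? OR m.lon <= ?)"
                params += [f.lon_min, f.lon_max]
            out["sample"].append(_Pred(sql, params))
        elif isinstance(f, MethodFilter):
            marks = ",".join("?" * len(f.methods))
            out["assignment"].append(
                _Pred(f"a.method IN ({marks})", sorted(f.methods)))
        elif isinstance(f, BestHitOnly):
            if f.enabled:
                out["assignment"].append(_Pred("a.best_hit = 1", []))
        elif isinstance(f, TaxonFilter):
            tax = db.taxonomy
            expanded: set[int] = set()
            for t in f.taxids:
                expanded |= tax.subtree(t)
            marks = ",".join("?" * len(expanded))
            out["assignment"].append(
                _Pred(f"a.taxid IN ({marks})", sorted(expanded)))
        elif isinstance(f, (Categorical, NumericRange, DateRange)):
            entity, dtype = _field_info(db, f.field)
            _check_type(f, dtype)
            out[entity].append(_compile_field_filter(f, entity, dtype))
        else:
            raise TypeError(f"unknown filter {f!r}")
    return out


def _check_type(f: Filter, dtype: str) -> None:
    ok = (isinstance(f, Categorical) and dtype == "text") \
        or (isinstance(f, NumericRange) and dtype == "number") \
        or (isinstance(f, DateRange) and dtype == "date")
    if not ok:
        raise errors.TypeMismatch(
            f"filter {type(f).__name__} does not apply to a {dtype} field "
            f"({f.field!r})")


def _compile_field_filter(f: Filter, entity: str, dtype: str) -> _Pred:
    # direct-column fields first
    if entity == "sequence":
        if f.field != "length":
            raise errors.UnknownField(f.field)
        sql, params = _range_sql("s.length", f.min, f.max)
        return _Pred(sql, params)
    if entity == "sample" and f.field == "collection_date":
        lo = _date_lo(f.min) if f.min else None
        hi = _date_hi(f.max) if f.max else None
        sql, params = _range_sql("m.date_day", lo, hi)
        return _Pred(f"m.date_day IS NOT NULL AND {sql}", params)
    if entity == "assignment" and f.field == "method":
        marks = ",".join("?" * len(f.values))
        return _Pred(f"a.method IN ({marks})", sorted(f.values))

    # user fields live in the typed side tables
    table, key = (("sample_fields", "sf.sample_name = m.sample_name")
                  if entity == "sample"
                  else ("assignment_fields", "sf.assignment_id = a.id"))
    if isinstance(f, Categorical):
        marks = ",".join("?" * len(f.values))
        cond, params = f"sf.vtext IN ({marks})", sorted(f.values)
    elif isinstance(f, NumericRange):
        cond, params = _range_sql("sf.vnum", f.min, f.max)
        cond = f"sf.vnum IS NOT NULL AND {cond}"
    else:
        lo = _date_lo(f.min) if f.min else None
        hi = _date_hi(f.max) if f.max else None
        cond, params = _range_sql("sf.vdate", lo, hi)
        cond = f"sf.vdate IS NOT NULL AND {cond}"
    sql = (f"EXISTS (SELECT 1 FROM {table} sf WHERE {key} "
           f"AND sf.field = ? AND {cond})")
    return _Pred(sql, [f.field] + params)


def _range_sql(column: str, lo, hi) -> tuple[str, list]:
    parts, params = [], []
    if lo is not None:
        parts.append(f"{column} >= ?")
        params.append(lo)
    if hi is not None:
        parts.append(f"{column} <= ?")
        params.append(hi)
    if not parts:
        return "1 = 1", []
    return " AND ".join(parts), params


def _and(preds: list[_Pred]) -> tuple[str, list]:
    if not preds:
        return "1 = 1", []
    sql = " AND ".join(f"({p.sql})" for p in preds)
    params = [x for p in preds for x in p.params]
    return sql, params


# ---------------------------------------------------------------------------
# core evaluation
# ---------------------------------------------------------------------------

def _check_projects(db: Store, query: Query) -> None:
    if not query.projects:
        raise errors.UnknownProject("query selects no project")
    for p in query.projects:
        if not db.has_project(p):
            raise errors.UnknownProject(p)


def _materialize_matching_sequences(db: Store, query: Query
                                    ) -> dict[str, list[_Pred]]:
    """Fill temp table ``_match_seq`` with the matching (project, sequence)
    pairs of the query; returns the compiled predicate partition for reuse."""
    _check_projects(db, query)
    preds = _compile_filters(db, query.filters)
    pmarks = ",".join("?" * len(query.projects))
    seq_sql, seq_params = _and(preds["sequence"])
    asg_sql, asg_params = _and(preds["assignment"])
    smp_sql, smp_params = _and(preds["sample"])

    sql = (f"SELECT s.project AS project, s.sequence_id AS sequence_id, "
           f"s.length AS length FROM sequences s "
           f"WHERE s.project IN ({pmarks}) AND s.assigned = 1 "
           f"AND ({seq_sql})")
    params = list(query.projects) + seq_params
    if preds["assignment"]:
        sql += (" AND EXISTS (SELECT 1 FROM assignments a "
                "WHERE a.project = s.project "
                "AND a.sequence_id = s.sequence_id AND (" + asg_sql + "))")
        params += asg_params
    sql += (" AND EXISTS (SELECT 1 FROM contributions c "
            "JOIN samples m ON m.sample_name = c.sample_name "
            "WHERE c.project = s.project AND c.sequence_id = s.sequence_id "
            "AND (" + smp_sql + "))")
    params += smp_params

    db.conn.execute("DROP TABLE IF EXISTS temp._match_seq")
    db.conn.execute(f"CREATE TEMP TABLE _match_seq AS {sql}", params)
    return preds


def run_query(db: Store, query: Query) -> ResultPage:
    """Evaluate a query and return one page of rows at the grouping level.

    ``total_count`` is computed over the full result set and is independent
    of pagination. Rows are stably sorted: the requested sort key first, then
    the record identifier as the final tie-break so pagination is
    reproducible.
    """
    preds = _materialize_matching_sequences(db, query)
    conn = db.conn

    if query.grouping == "sequence":
        total = conn.execute(
            "SELECT COUNT(*) FROM _match_seq").fetchone()[0]
        order = _order_clause(query, {"sequence_id": "sequence_id",
                                      "length": "length",
                                      "project": "project"},
                              default="project, sequence_id",
                              tiebreak="project, sequence_id")
        rows = conn.execute(
            f"SELECT project, sequence_id, length FROM _match_seq "
            f"ORDER BY {order} {_page_clause(query)}").fetchall()
        page = [{"project": p, "sequence_id": q, "length": n}
                for p, q, n in rows]
        return ResultPage(page, total, "sequence")

    if query.grouping == "sample":
        smp_sql, smp_params = _and(preds["sample"])
        base = (f"FROM samples m WHERE ({smp_sql}) AND EXISTS ("
                "SELECT 1 FROM contributions c JOIN _match_seq ms "
                "ON ms.project = c.project "
                "AND ms.sequence_id = c.sequence_id "
                "WHERE c.sample_name = m.sample_name)")
        total = conn.execute(
            f"SELECT COUNT(*) {base}", smp_params).fetchone()[0]
        order = _order_clause(query, {"sample_name": "m.sample_name",
                                      "collection_date": "m.date_day"},
                              default="m.sample_name",
                              tiebreak="m.sample_name")
        rows = conn.execute(
            f"SELECT m.sample_name, m.collection_date, m.lat, m.lon, m.extra "
            f"{base} ORDER BY {order} {_page_clause(query)}",
            smp_params).fetchall()
        import json as _json
        page = [{"sample_name": n, "collection_date": d,
                 "lat_lon": (lat, lon) if lat is not None else None,
                 "extra": _json.loads(extra)}
                for n, d, lat, lon, extra in rows]
        return ResultPage(page, total, "sample")

    # grouping == "assignment": matching assignments of matching sequences
    asg_sql, asg_params = _and(preds["assignment"])
    base = (f"FROM assignments a JOIN _match_seq ms "
            f"ON ms.project = a.project AND ms.sequence_id = a.sequence_id "
            f"WHERE ({asg_sql})")
    total = conn.execute(f"SELECT COUNT(*) {base}", asg_params).fetchone()[0]
    order = _order_clause(query, {"sequence_id": "a.sequence_id",
                                  "method": "a.method",
                                  "taxonomy": "a.taxid"},
                          default="a.project, a.sequence_id, a.ordinal",
                          tiebreak="a.project, a.sequence_id, a.ordinal")
    rows = conn.execute(
        f"SELECT a.id, a.project, a.sequence_id, a.ordinal, a.method, "
        f"a.taxid, a.best_hit {base} ORDER BY {order} {_page_clause(query)}",
        asg_params).fetchall()
    page = [{"id": i, "project": p, "sequence_id": q, "ordinal": o,
             "method": m, "taxid": t,
             "best_hit": None if b is None else bool(b)}
            for i, p, q, o, m, t, b in rows]
    return ResultPage(page, total, "assignment")


def _order_clause(query: Query, known: dict[str, str], default: str,
                  tiebreak: str) -> str:
    if query.sort is None:
        return default
    col = known.get(query.sort)
    if col is None:
        raise errors.UnknownField(
            f"cannot sort {query.grouping} rows by {query.sort!r}")
    direction = "DESC" if query.descending else "ASC"
    return f"{col} {direction}, {tiebreak}"


def _page_clause(query: Query) -> str:
    if query.limit is None:
        return f"LIMIT -1 OFFSET {int(query.offset)}"
    return f"LIMIT {int(query.limit)} OFFSET {int(query.offset)}"


# ---------------------------------------------------------------------------
# facets
# ---------------------------------------------------------------------------

def facet_spec(db: Store, field: str, entity: str | None = None) -> FacetSpec:
    """Widget choice for a registered field.

    Text fields with at most :data:`FACET_LIST_THRESHOLD` distinct values get
    the enumerated plain list (values included, sorted); beyond the threshold
    the widget switches to autocompletion and values are served on demand by
    :func:`distinct_values`. Number/date fields expose their observed bounds,
    the taxonomy field a tree selector rooted at the taxonomy root, and the
    location field a map with the bounding box of observed points.
    """
    desc = db.get_field(field, entity)
    if desc.dtype == "text":
        if desc.distinct_count <= FACET_LIST_THRESHOLD:
            return FacetSpec(field, "enumerated_list",
                             distinct_values(db, field, "", None,
                                             entity=desc.entity))
        return FacetSpec(field, "autocomplete", None)
    if desc.dtype == "number":
        lo, hi = _observed_bounds(db, desc, "vnum")
        return FacetSpec(field, "numeric_range", (lo, hi))
    if desc.dtype == "date":
        if field == "collection_date":
            lo, hi = db.conn.execute(
                "SELECT MIN(date_day), MAX(date_day) FROM samples").fetchone()
        else:
            lo, hi = _observed_bounds(db, desc, "vdate")
        return FacetSpec(field, "date_range", (lo, hi))
    if desc.dtype == "taxon":
        return FacetSpec(field, "taxonomy_tree", db.taxonomy.root_taxid)
    if desc.dtype == "geo":
        row = db.conn.execute(
            "SELECT MIN(lat), MAX(lat), MIN(lon), MAX(lon) FROM samples "
            "WHERE lat IS NOT NULL").fetchone()
        return FacetSpec(field, "geo_map", row)
    raise errors.UnknownField(field)


def _observed_bounds(db: Store, desc, column: str):
    if desc.entity == "sequence":
        return db.conn.execute(
            "SELECT MIN(length), MAX(length) FROM sequences").fetchone()
    table = "sample_fields" if desc.entity == "sample" else "assignment_fields"
    return db.conn.execute(
        f"SELECT MIN({column}), MAX({column}) FROM {table} WHERE field = ?",
        (desc.name,)).fetchone()


def distinct_values(db: Store, field: str, prefix: str = "",
                    limit: int | None = 20,
                    entity: str | None = None) -> list[str]:
    """Sorted distinct values of a text field matching a case-insensitive
    prefix (the autocompletion back end)."""
    desc = db.get_field(field, entity)
    if desc.dtype != "text":
        raise errors.TypeMismatch(f"{field!r} is not a text field")
    if desc.entity == "assignment" and field == "method":
        sql, params = ("SELECT DISTINCT method AS v FROM assignments "
                       "WHERE method IS NOT NULL"), []
    elif desc.entity == "sample":
        sql, params = ("SELECT DISTINCT vtext AS v FROM sample_fields "
                       "WHERE field = ?"), [field]
    else:
        sql, params = ("SELECT DISTINCT vtext AS v FROM assignment_fields "
                       "WHERE field = ?"), [field]
    if prefix:
        escaped = (prefix.replace("\\", "\\\\").replace("%", r"\%")
                   .replace("_", r"\_"))
        sql += r" AND v LIKE ? ESCAPE '\'"
        params.append(escaped + "%")
    sql += " ORDER BY v"
    if limit is not None:
        sql += f" LIMIT {int(limit)}"
    return [r[0] for r in db.conn.execute(sql, params)]


# ---------------------------------------------------------------------------
# taxonomy views
# ---------------------------------------------------------------------------

def effective_query_for_taxonomy_views(db: Store, query: Query,
                                       method: str | None = None) -> Query:
    """Normalize a query so each matching sequence maps to exactly one taxon.

    If the selected projects involve more than one assignment method and the
    query has no method filter, a filter fixing the caller-chosen ``method``
    is injected (:class:`~metadepot.errors.AmbiguousMethod` if none given).
    If any sequence in the selected projects carries multiple assignments and
    the best-hit restriction is absent, it is switched on. Already-constrained
    queries come back unchanged, so the operation is idempotent.
    """
    _check_projects(db, query)
    pmarks = ",".join("?" * len(query.projects))
    filters = list(query.filters)

    has_method = any(isinstance(f, MethodFilter) for f in filters) or any(
        isinstance(f, Categorical) and f.field == "method" for f in filters)
    if not has_method:
        methods = [r[0] for r in db.conn.execute(
            f"SELECT DISTINCT method FROM assignments "
            f"WHERE project IN ({pmarks}) AND method IS NOT NULL",
            list(query.projects))]
        if len(methods) > 1:
            if method is None:
                raise errors.AmbiguousMethod(
                    f"{len(methods)} assignment methods in selection "
                    f"({sorted(methods)}); choose one")
            filters.append(MethodFilter({method}))

    has_best = any(isinstance(f, BestHitOnly) and f.enabled for f in filters)
    if not has_best:
        multi = db.conn.execute(
            f"SELECT 1 FROM assignments WHERE project IN ({pmarks}) "
            f"GROUP BY project, sequence_id HAVING COUNT(*) > 1 LIMIT 1",
            list(query.projects)).fetchone()
        if multi is not None:
            filters.append(BestHitOnly(True))

    if len(filters) == len(query.filters):
        return query
    return replace(query, filters=tuple(filters))


@dataclass
class TaxonCount:
    """One node of the per-taxon sequence-count tree.

    ``count`` is the number of matching sequences whose designated (best-hit)
    assignment resolves exactly to this taxon; ``cumulative`` additionally
    includes all descendants.
    """
    taxid: int
    name: str
    rank: str
    count: int = 0
    cumulative: int = 0
    children: list["TaxonCount"] = dc_field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


#: taxid of the synthetic node grouping sequences whose designated assignment
#: has no resolved taxon yet (pending resolver retry)
UNCLASSIFIED_TAXID = 0


def designated_assignments(db: Store, query: Query,
                           method: str | None = None
                           ) -> list[tuple[str, str, int | None]]:
    """Normalize the query and map each matching sequence to its single
    designated assignment's taxon.

    Returns ``(project, sequence_id, taxid-or-None)`` triples, one per
    matching sequence; the designated assignment is the first (by import
    ordinal) assignment surviving the normalized query's assignment-level
    filters — under best-hit normalization that is the method's best hit.
    """
    nq = effective_query_for_taxonomy_views(db, query, method)
    preds = _materialize_matching_sequences(db, nq)
    asg_sql, asg_params = _and(preds["assignment"])
    rows = db.conn.execute(
        f"SELECT a.project, a.sequence_id, a.taxid FROM assignments a "
        f"JOIN _match_seq ms ON ms.project = a.project "
        f"AND ms.sequence_id = a.sequence_id WHERE ({asg_sql}) "
        f"ORDER BY a.project, a.sequence_id, a.ordinal",
        asg_params).fetchall()
    out: list[tuple[str, str, int | None]] = []
    seen: set[tuple[str, str]] = set()
    for project, seq, taxid in rows:
        if (project, seq) in seen:
            continue
        seen.add((project, seq))
        out.append((project, seq, taxid))
    return out


def taxon_count_tree(db: Store, query: Query,
                     method: str | None = None) -> TaxonCount | None:
    """Per-taxon sequence counts under the normalized query.

    Each matching sequence contributes exactly once, at the taxon of its
    designated assignment; the tree contains every counted taxon plus all its
    ancestors up to the root, each carrying the exact and cumulative counts.
    The sum of exact counts over the whole tree equals the table view's
    ``total_count`` at sequence grouping for the same normalized query — the
    count-consistency rule the exploration views rely on. Sequences whose
    designated assignment is still unresolved are grouped under a synthetic
    "Unclassified" node directly below the root. Returns ``None`` for an
    empty result.
    """
    counts: dict[int, int] = {}
    for _, _, taxid in designated_assignments(db, query, method):
        node_id = UNCLASSIFIED_TAXID if taxid is None else taxid
        counts[node_id] = counts.get(node_id, 0) + 1
    if not counts:
        return None

    tax = db.taxonomy
    nodes: dict[int, TaxonCount] = {}

    def ensure(taxid: int) -> TaxonCount:
        if taxid in nodes:
            return nodes[taxid]
        if taxid == UNCLASSIFIED_TAXID:
            node = TaxonCount(taxid, "Unclassified", "no rank")
            nodes[taxid] = node
            ensure(tax.root_taxid).children.append(node)
            return node
        info = tax.node(taxid)
        node = TaxonCount(taxid, info.name, info.rank)
        nodes[taxid] = node
        if taxid != tax.root_taxid:
            ensure(info.parent_taxid).children.append(node)
        return node

    for taxid, n in counts.items():
        ensure(taxid).count = n
    root = ensure(tax.root_taxid)

    def accumulate(node: TaxonCount) -> int:
        node.children.sort(key=lambda c: c.taxid)
        node.cumulative = node.count + sum(
            accumulate(c) for c in node.children)
        return node.cumulative

    accumulate(root)
    return root


def krona_rows(tree: TaxonCount | None) -> list[tuple[int, tuple[str, ...]]]:
    """Flatten a count tree into Krona text-import rows.

    One row per node with a positive exact count: the count followed by the
    root-to-node name path (the root itself is excluded from paths, except
    for counts sitting directly on the root). Row counts sum to the table
    total; re-aggregating rows bottom-up reproduces the cumulative counts.
    """
    if tree is None:
        return []
    out: list[tuple[int, tuple[str, ...]]] = []

    def visit(node: TaxonCount, path: tuple[str, ...]) -> None:
        here = path if node is tree else path + (node.name,)
        if node.count > 0:
            out.append((node.count, here if here else (node.name,)))
        for child in node.children:
            visit(child, here)

    visit(tree, ())
    return out


def krona_text(tree: TaxonCount | None) -> str:
    """Krona's tab-separated text import dialect."""
    return "\n".join(
        "\t".join([str(count), *path]) for count, path in krona_rows(tree))


def geo_points(db: Store, query: Query
               ) -> list[tuple[float, float, str, int]]:
    """Collection-location points for the matching samples.

    One ``(lat, lon, sample_name, matching-sequence count)`` tuple per
    matching sample that has coordinates; samples lacking a location are
    omitted from the map but still count in the table view.
    """
    preds = _materialize_matching_sequences(db, query)
    smp_sql, smp_params = _and(preds["sample"])
    rows = db.conn.execute(
        f"SELECT m.lat, m.lon, m.sample_name, "
        f"COUNT(DISTINCT c.project || '/' || c.sequence_id) "
        f"FROM samples m "
        f"JOIN contributions c ON c.sample_name = m.sample_name "
        f"JOIN _match_seq ms ON ms.project = c.project "
        f"AND ms.sequence_id = c.sequence_id "
        f"WHERE m.lat IS NOT NULL AND ({smp_sql}) "
        f"GROUP BY m.sample_name ORDER BY m.sample_name",
        smp_params).fetchall()
    return [(lat, lon, name, n) for lat, lon, name, n in rows]
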