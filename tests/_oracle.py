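"""Independent in-memory query oracle and random-query generator.

The oracle re-implements the documented match semantics as a plain Python
scan over raw record dumps, sharing no code with the SQL query engine: field
typing comes from a caller-supplied registry map, taxon subtree membership
from a raw parent map walked by hand, and date snapping is recomputed with
the standard library. It is deliberately slow and simple.
"""

from __future__ import annotations

import calendar
import random
from datetime import date

from metadepot import query as q


def snap_date(text: str, side: str) -> date:
    """Partial ISO date -> first (side='lo') or last (side='hi') covered day."""
    parts = text.split("-")
    year = int(parts[0])
    if len(parts) == 1:
        return date(year, 1, 1) if side == "lo" else date(year, 12, 31)
    month = int(parts[1])
    if len(parts) == 2:
        last = calendar.monthrange(year, month)[1]
        return date(year, month, 1) if side == "lo" else date(year, month, last)
    return date(year, month, int(parts[2]))


def taxon_path(parents: dict[int, int], taxid: int) -> list[int]:
    path = [taxid]
    while parents[path[-1]] != path[-1]:
        path.append(parents[path[-1]])
    return path


class QueryOracle:
    """Exhaustive-scan evaluation of a query over raw store dumps."""

    def __init__(self, samples, sequences, assignments, parents,
                 registry):
        self.samples = {s["sample_name"]: s for s in samples}
        self.sequences = sequences
        self.assignments = assignments
        self.parents = parents
        self.registry = registry  # field -> (entity, dtype)

    # -- per-record predicates ------------------------------------------

    def _sample_ok(self, s, f) -> bool:
        if isinstance(f, q.GeoBox):
            if (f.lat_min <= -90 and f.lat_max >= 90
                    and f.lon_min <= -180 and f.lon_max >= 180):
                return True
            if s["lat_lon"] is None:
                return False
            lat, lon = s["lat_lon"]
            if not (f.lat_min <= lat <= f.lat_max):
                return False
            if f.lon_min <= f.lon_max:
                return f.lon_min <= lon <= f.lon_max
            return lon >= f.lon_min or lon <= f.lon_max
        if isinstance(f, q.DateRange) and f.field == "collection_date":
            if s["collection_date"] is None:
                return False
            day = snap_date(s["collection_date"], "lo")
            if f.min is not None and day < snap_date(f.min, "lo"):
                return False
            if f.max is not None and day > snap_date(f.max, "hi"):
                return False
            return True
        raw = s["extra"].get(f.field)
        if isinstance(f, q.Categorical):
            return raw in f.values
        if raw is None:
            return False
        if isinstance(f, q.NumericRange):
            v = float(raw)
            return ((f.min is None or v >= f.min)
                    and (f.max is None or v <= f.max))
        if isinstance(f, q.DateRange):
            day = snap_date(raw, "lo")
            return ((f.min is None or day >= snap_date(f.min, "lo"))
                    and (f.max is None or day <= snap_date(f.max, "hi")))
        raise AssertionError(f)

    def _assignment_ok(self, a, f) -> bool:
        if isinstance(f, q.MethodFilter):
            return a["method"] in f.methods
        if isinstance(f, q.BestHitOnly):
            return (not f.enabled) or a["best_hit"] is True
        if isinstance(f, q.TaxonFilter):
            if a["taxid"] is None:
                return False
            return any(t in f.taxids
                       for t in taxon_path(self.parents, a["taxid"]))
        raw = a["extra"].get(f.field)
        if isinstance(f, q.Categorical):
            if f.field == "method":
                return a["method"] in f.values
            return raw in f.values
        if raw is None:
            return False
        if isinstance(f, q.NumericRange):
            v = float(raw)
            return ((f.min is None or v >= f.min)
                    and (f.max is None or v <= f.max))
        if isinstance(f, q.DateRange):
            day = snap_date(raw, "lo")
            return ((f.min is None or day >= snap_date(f.min, "lo"))
                    and (f.max is None or day <= snap_date(f.max, "hi")))
        raise AssertionError(f)

    def _sequence_ok(self, s, f) -> bool:
        assert isinstance(f, q.NumericRange) and f.field == "length"
        return ((f.min is None or s["length"] >= f.min)
                and (f.max is None or s["length"] <= f.max))

    # -- evaluation ------------------------------------------------------

    def _split(self, filters):
        smp, seq, asg = [], [], []
        for f in filters:
            if isinstance(f, q.GeoBox):
                smp.append(f)
            elif isinstance(f, (q.MethodFilter, q.BestHitOnly, q.TaxonFilter)):
                asg.append(f)
            else:
                entity = self.registry[f.field][0]
                {"sample": smp, "sequence": seq,
                 "assignment": asg}[entity].append(f)
        return smp, seq, asg

    def run(self, query: q.Query):
        """Matching (project, sequence_id) set, sample-name set and
        assignment-id set for the query."""
        projects = set(query.projects)
        smp_f, seq_f, asg_f = self._split(query.filters)

        ok_samples = {name for name, s in self.samples.items()
                      if all(self._sample_ok(s, f) for f in smp_f)}
        ok_assignments = [a for a in self.assignments
                          if a["project"] in projects
                          and all(self._assignment_ok(a, f) for f in asg_f)]
        ok_asg_by_seq: dict[tuple[str, str], list] = {}
        for a in ok_assignments:
            ok_asg_by_seq.setdefault(
                (a["project"], a["sequence_id"]), []).append(a)

        match_seq = set()
        for s in self.sequences:
            if s["project"] not in projects or not s["assigned"]:
                continue
            if not all(self._sequence_ok(s, f) for f in seq_f):
                continue
            key = (s["project"], s["sequence_id"])
            if asg_f and key not in ok_asg_by_seq:
                continue
            if not any(name in ok_samples for name in s["contributions"]):
                continue
            match_seq.add(key)

        contributing: dict[str, set] = {}
        for s in self.sequences:
            key = (s["project"], s["sequence_id"])
            if key in match_seq:
                for name in s["contributions"]:
                    contributing.setdefault(name, set()).add(key)
        match_samples = {name for name in ok_samples if name in contributing}
        match_asg = {a["id"] for a in ok_assignments
                     if (a["project"], a["sequence_id"]) in match_seq}
        return match_seq, match_samples, match_asg


# ---------------------------------------------------------------------------
# random queries
# ---------------------------------------------------------------------------

def random_query(rng: random.Random, vocab: dict) -> q.Query:
    """Draw a random conjunction spanning all filter variants."""
    makers = [
        lambda: q.Categorical("host", rng.sample(
            vocab["hosts"], rng.randint(1, min(2, len(vocab["hosts"]))))),
        lambda: q.NumericRange("length",
                               rng.choice([None, rng.randint(100, 400)]),
                               rng.choice([None, rng.randint(400, 900)])),
        lambda: q.NumericRange("evalue",
                               rng.choice([None, round(rng.uniform(0, 50), 2)]),
                               rng.choice([None, round(rng.uniform(50, 100), 2)])),
        lambda: q.DateRange("collection_date",
                            rng.choice([None, str(rng.choice(vocab["years"]))]),
                            rng.choice([None, str(rng.choice(vocab["years"]))
                                        + rng.choice(["", "-06"])])),
        lambda: q.TaxonFilter(rng.sample(vocab["taxids"], rng.randint(1, 2))),
        lambda: _random_box(rng, vocab),
        lambda: q.MethodFilter([rng.choice(vocab["methods"])]),
        lambda: q.BestHitOnly(True),
    ]
    filters = []
    for maker in rng.sample(makers, rng.randint(0, 3)):
        f = maker()
        if isinstance(f, q.DateRange) and f.min and f.max \
                and f.min > f.max:
            f = q.DateRange("collection_date", f.max[:4], f.min)
        filters.append(f)
    projects = rng.sample(vocab["projects"],
                          rng.randint(1, len(vocab["projects"])))
    return q.Query(projects=projects, filters=filters,
                   grouping=rng.choice(["sequence", "sample", "assignment"]))


def _random_box(rng: random.Random, vocab: dict) -> q.GeoBox:
    kind = rng.random()
    if kind < 0.15:
        return q.GeoBox(-90, 90, -180, 180)  # whole globe
    if kind < 0.3:  # antimeridian wrap
        return q.GeoBox(-60, 60, rng.uniform(60, 150), rng.uniform(-150, -60))
    lat = sorted(rng.uniform(*vocab["lat_range"]) for _ in range(2))
    lon = sorted(rng.uniform(*vocab["lon_range"]) for _ in range(2))
    return q.GeoBox(lat[0], lat[1], lon[0], lon[1])


DEFAULT_REGISTRY = {
    "host": ("sample", "text"),
    "habitat": ("sample", "text"),
    "collection_date": ("sample", "date"),
    "lat_lon": ("sample", "geo"),
    "length": ("sequence", "number"),
    "method": ("assignment", "text"),
    "taxonomy": ("assignment", "taxon"),
    "evalue": ("assignment", "number"),
    "identity": ("assignment", "number"),
}
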