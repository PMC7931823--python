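"""Rooted taxonomy store, accession-to-taxon cache, and first-common-ancestor
resolution.

The taxonomy is loaded from the NCBI taxdump dialect (``nodes.dmp`` /
``names.dmp``, pipe-and-tab delimited). Assignments reference taxa either
directly by taxid or through one or more sequence-database accessions; in the
multi-accession case the sequence is summarized by the first (i.e. lowest)
common ancestor of the accessions' taxa.

Accession-to-taxid pairs live in a cache keyed by the canonical versionless
accession. Cache entries carry a source tag with fixed precedence
``USER > SILVA > NCBI``: a curated SILVA mapping overrides a plain NCBI one no
matter the loading order, and user-supplied overrides beat both. Lookups that
fail at resolution time are cached as unresolved so they are not re-queried on
every import; a dedicated retry pass re-queries exactly those.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol

from . import errors
from .formats import AssignmentRow, canonical_accession

#: marker for an accession or assignment whose taxon could not be determined
UNRESOLVED = None

CACHE_SOURCES = ("NCBI", "SILVA", "USER")
_SOURCE_RANK = {"NCBI": 1, "SILVA": 2, "USER": 3}


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str


class Taxonomy:
    """Rooted, rank-labelled taxonomy with ancestor/LCA/subtree queries."""

    def __init__(self, nodes: Mapping[int, TaxonomyNode], root_taxid: int,
                 merged: Mapping[int, int] | None = None):
        self.nodes: dict[int, TaxonomyNode] = dict(nodes)
        self.root_taxid = root_taxid
        self.merged: dict[int, int] = dict(merged or {})
        self._children: dict[int, list[int]] | None = None
        self._validate()

    # -- construction helpers -------------------------------------------

    def _validate(self) -> None:
        if self.root_taxid not in self.nodes:
            raise errors.OrphanNode(self.root_taxid)
        for node in self.nodes.values():
            if node.taxid == self.root_taxid:
                continue
            if node.parent_taxid not in self.nodes:
                raise errors.OrphanNode(node.taxid)
        # every chain must reach the root within |nodes| steps
        limit = len(self.nodes)
        for taxid in self.nodes:
            cur, steps = taxid, 0
            while cur != self.root_taxid:
                cur = self.nodes[cur].parent_taxid
                steps += 1
                if steps > limit:
                    raise errors.CycleDetected(taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes or taxid in self.merged

    def __len__(self) -> int:
        return len(self.nodes)

    def canonical(self, taxid: int) -> int:
        """Remap a merged/obsolete taxid to its current one when known."""
        return self.merged.get(taxid, taxid)

    def node(self, taxid: int) -> TaxonomyNode:
        taxid = self.canonical(taxid)
        try:
            return self.nodes[taxid]
        except KeyError:
            raise errors.UnknownTaxon(taxid) from None

    # -- queries ---------------------------------------------------------

    def ancestors(self, taxid: int) -> list[int]:
        """Ancestor chain from the taxon itself up to (and including) the root."""
        taxid = self.canonical(taxid)
        if taxid not in self.nodes:
            raise errors.UnknownTaxon(taxid)
        path = [taxid]
        while path[-1] != self.root_taxid:
            path.append(self.nodes[path[-1]].parent_taxid)
        return path

    def depth(self, taxid: int) -> int:
        return len(self.ancestors(taxid)) - 1

    def lca(self, taxids: Iterable[int]) -> int:
        """First common ancestor: the deepest node on every input's root path."""
        taxids = list(taxids)
        if not taxids:
            raise errors.EmptyInput("lca of empty set")
        paths = [list(reversed(self.ancestors(t))) for t in taxids]
        answer = self.root_taxid
        for level in zip(*paths):
            if len(set(level)) != 1:
                break
            answer = level[0]
        return answer

    def children(self, taxid: int) -> list[int]:
        if self._children is None:
            self._children = {t: [] for t in self.nodes}
            for node in self.nodes.values():
                if node.taxid != self.root_taxid:
                    self._children[node.parent_taxid].append(node.taxid)
        taxid = self.canonical(taxid)
        if taxid not in self.nodes:
            raise errors.UnknownTaxon(taxid)
        return self._children[taxid]

    def subtree(self, taxid: int) -> set[int]:
        """All descendants of ``taxid``, the node itself included."""
        taxid = self.canonical(taxid)
        if taxid not in self.nodes:
            raise errors.UnknownTaxon(taxid)
        out: set[int] = set()
        stack = [taxid]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(self.children(cur))
        return out

    def name_path(self, taxid: int, include_root: bool = False) -> list[str]:
        """Scientific names from the root down to ``taxid``."""
        chain = list(reversed(self.ancestors(taxid)))
        if not include_root:
            chain = chain[1:]
        return [self.nodes[t].name for t in chain]


def _taxdump_rows(path: Path | str) -> Iterable[list[str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[:-2]
            yield [c.strip() for c in line.split("\t|\t")]


def load_taxdump(nodes_path: Path | str, names_path: Path | str,
                 merged_path: Path | str | None = None) -> Taxonomy:
    """Load a taxonomy from NCBI taxdump-dialect files.

    Only names of class ``scientific name`` are retained. The root is the node
    that is its own parent. An optional ``merged.dmp`` installs a remap table
    for obsolete taxids.
    """
    raw: dict[int, tuple[int, str]] = {}
    root: int | None = None
    for cells in _taxdump_rows(nodes_path):
        taxid, parent = int(cells[0]), int(cells[1])
        rank = cells[2] if len(cells) > 2 else "no rank"
        raw[taxid] = (parent, rank)
        if taxid == parent:
            root = taxid
    if root is None:
        raise errors.OrphanNode("no self-parented root node found")

    names: dict[int, str] = {}
    for cells in _taxdump_rows(names_path):
        if len(cells) >= 4 and cells[3] == "scientific name":
            names[int(cells[0])] = cells[1]
        elif len(cells) == 2:  # tolerant two-column dialect
            names.setdefault(int(cells[0]), cells[1])

    merged: dict[int, int] = {}
    if merged_path is not None:
        for cells in _taxdump_rows(merged_path):
            merged[int(cells[0])] = int(cells[1])

    nodes = {
        taxid: TaxonomyNode(taxid, parent, rank,
                            names.get(taxid, f"taxid {taxid}"))
        for taxid, (parent, rank) in raw.items()
    }
    return Taxonomy(nodes, root, merged)


# ---------------------------------------------------------------------------
# accession cache + resolver
# ---------------------------------------------------------------------------

@dataclass
class AccessionCacheEntry:
    accession: str
    taxid: int | None  # None == UNRESOLVED
    source: str


class AccessionCache:
    """Accession -> taxid map with source precedence and unresolved markers."""

    def __init__(self) -> None:
        self._entries: dict[str, AccessionCacheEntry] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, accession: str) -> bool:
        return canonical_accession(accession) in self._entries

    def get(self, accession: str) -> AccessionCacheEntry | None:
        return self._entries.get(canonical_accession(accession))

    def entries(self) -> list[AccessionCacheEntry]:
        return list(self._entries.values())

    def unresolved_accessions(self) -> list[str]:
        return [e.accession for e in self._entries.values() if e.taxid is None]

    def insert(self, accession: str, taxid: int | None,
               source: str = "NCBI", force: bool = False) -> bool:
        """Insert honouring source precedence; returns True if stored.

        A higher-ranked source replaces a lower-ranked entry; equal rank
        replaces (so reloading a mapping updates it). A resolved entry also
        replaces an unresolved one regardless of rank, which is what the retry
        pass relies on.
        """
        if source not in _SOURCE_RANK:
            raise errors.MalformedMapping(f"unknown cache source {source!r}")
        acc = canonical_accession(accession)
        if not acc:
            raise errors.MalformedMapping("empty accession")
        old = self._entries.get(acc)
        if old is not None and not force:
            if old.taxid is not None or taxid is None:
                if _SOURCE_RANK[source] < _SOURCE_RANK[old.source]:
                    return False
        self._entries[acc] = AccessionCacheEntry(acc, taxid, source)
        return True

    def load_tsv(self, path: Path | str, source: str) -> int:
        """Seed from an accession2taxid-style TSV (accession, taxid, ...).

        A header row whose second column is not numeric is skipped. Returns
        the number of rows read (whether or not precedence kept them).
        """
        count = 0
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
            for lineno, cells in enumerate(reader, start=1):
                if not cells or not any(c.strip() for c in cells):
                    continue
                if len(cells) < 2:
                    raise errors.MalformedMapping(f"line {lineno}")
                acc, raw_taxid = cells[0].strip(), cells[1].strip()
                if lineno == 1 and not raw_taxid.lstrip("-").isdigit():
                    continue  # header
                try:
                    taxid = int(raw_taxid)
                except ValueError:
                    raise errors.MalformedMapping(
                        f"line {lineno}: {raw_taxid!r}") from None
                self.insert(acc, taxid, source)
                count += 1
        return count


def seed_cache(cache: AccessionCache, mapping_path: Path | str,
               source: str) -> int:
    """Functional alias for :meth:`AccessionCache.load_tsv`."""
    return cache.load_tsv(mapping_path, source)


class AccessionResolver(Protocol):
    """Pure batch lookup: accession -> taxid, or ``None`` where it failed.

    The production system would back this with the Entrez web service; tests
    and offline deployments use :class:`TableResolver`.
    """

    def resolve(self, accessions: Iterable[str]) -> dict[str, int | None]:
        ...


class TableResolver:
    """Resolver backed by an in-memory table or an accession2taxid TSV."""

    def __init__(self, mapping: Mapping[str, int] | None = None):
        self._map = {canonical_accession(a): t
                     for a, t in (mapping or {}).items()}

    @classmethod
    def from_tsv(cls, path: Path | str) -> "TableResolver":
        cache = AccessionCache()
        cache.load_tsv(path, "NCBI")
        return cls({e.accession: e.taxid for e in cache.entries()
                    if e.taxid is not None})

    def resolve(self, accessions: Iterable[str]) -> dict[str, int | None]:
        return {a: self._map.get(canonical_accession(a)) for a in accessions}


class NullResolver:
    """Resolver that knows nothing; every lookup fails."""

    def resolve(self, accessions: Iterable[str]) -> dict[str, int | None]:
        return {a: None for a in accessions}


def resolve_accessions(accessions: Iterable[str], cache: AccessionCache,
                       resolver: AccessionResolver | None,
                       source: str = "NCBI") -> dict[str, int | None]:
    """Cache-first batch lookup; misses go to the resolver once, results are
    cached (failures as unresolved markers). Already-cached unresolved entries
    are *not* re-queried here — that is the retry pass's job."""
    wanted = {canonical_accession(a) for a in accessions}
    out: dict[str, int | None] = {}
    misses: list[str] = []
    for acc in sorted(wanted):
        entry = cache.get(acc)
        if entry is not None:
            out[acc] = entry.taxid
        else:
            misses.append(acc)
    if misses:
        results = resolver.resolve(misses) if resolver is not None else {}
        for acc in misses:
            taxid = results.get(acc)
            cache.insert(acc, taxid, source)
            out[acc] = taxid
    return out


def resolve_assignment_taxon(row: AssignmentRow, cache: AccessionCache,
                             tax: Taxonomy,
                             resolver: AccessionResolver | None = None,
                             warnings: list[str] | None = None) -> int | None:
    """Determine the taxon for one assignment row.

    An explicit ``taxonomy_id`` wins (validated against the taxonomy,
    merged-id remap applied). Otherwise each accession is looked up
    cache-first; a single resolved accession yields its taxid, several yield
    the first common ancestor of their taxa. Accessions whose taxid is not in
    the loaded taxonomy are skipped with a warning; if nothing resolves the
    assignment stays unresolved (``None``).
    """
    if row.taxonomy_id is not None:
        taxid = tax.canonical(row.taxonomy_id)
        if taxid not in tax.nodes:
            raise errors.UnknownTaxon(row.taxonomy_id)
        return taxid

    resolved = resolve_accessions(row.accessions, cache, resolver)
    taxids: list[int] = []
    for acc in (canonical_accession(a) for a in row.accessions):
        taxid = resolved.get(acc)
        if taxid is None:
            continue
        taxid = tax.canonical(taxid)
        if taxid not in tax.nodes:
            if warnings is not None:
                warnings.append(
                    f"accession {acc}: taxid {resolved[acc]} absent from the "
                    f"loaded taxonomy; skipped")
            continue
        taxids.append(taxid)
    if not taxids:
        return UNRESOLVED
    if len(taxids) == 1:
        return taxids[0]
    return tax.lca(taxids)


def retry_unresolved(db, resolver: AccessionResolver) -> int:
    """Re-query unresolved accessions and persist recovered assignment taxa.

    Thin functional wrapper over :meth:`metadepot.store.Store.retry_unresolved`
    so the operation is reachable from this module as well.
    """
    return db.retry_unresolved(resolver)
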