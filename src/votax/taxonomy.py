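"""Offline taxonomy store: taxdump loading, lineages, generic-name tests.

The store consumes the NCBI taxdump dialect (fields separated by
``\\t|\\t``, records terminated by ``\\t|``) for nodes and names, plus a
plain two-column accession-to-taxid map.  Everything is resolved locally;
no network or SQL server is involved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

#: Canonical 8-slot rank ladder, root-first.
STANDARD_RANKS: tuple[str, ...] = (
    "domain", "kingdom", "phylum", "class", "order", "family", "genus", "species",
)

#: Rank labels that fill a standardized slot.  NCBI historically labels the
#: top split "superkingdom"; both spellings land in the domain slot.
_RANK_TO_SLOT: dict[str, int] = {rank: i for i, rank in enumerate(STANDARD_RANKS)}
_RANK_TO_SLOT["superkingdom"] = 0

#: Sentinel for an accession that cannot be resolved to a taxon.
UNRESOLVED = None

#: Default generic / partial annotation keywords (user-extensible).
DEFAULT_GENERIC_KEYWORDS: tuple[str, ...] = (
    "uncultured",
    "unidentified",
    "unclassified",
    "environmental sample",
    "metagenome",
)


class TaxonomyError(Exception):
    """Base class for taxonomy store failures."""


class TaxdumpFormatError(TaxonomyError):
    """A taxdump table is malformed or internally inconsistent."""


class UnknownTaxidError(TaxonomyError, KeyError):
    """A taxid was queried that the store does not contain."""


@dataclass(slots=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str
    synonyms: list[str] = field(default_factory=list)


@dataclass(frozen=True, slots=True)
class LineageNode:
    rank: str
    name: str
    taxid: int


@dataclass(frozen=True, slots=True)
class Lineage:
    """Root-to-leaf lineage plus its fixed 8-slot standardized view.

    ``standardized[i]`` is the name filling slot ``STANDARD_RANKS[i]`` or
    ``None`` (blank); ``standardized_taxids`` mirrors it with taxids.
    """

    nodes: tuple[LineageNode, ...]
    standardized: tuple[Optional[str], ...]
    standardized_taxids: tuple[Optional[int], ...]

    @property
    def terminal_name(self) -> str:
        return self.nodes[-1].name


@dataclass(frozen=True)
class GenericNameList:
    """Case-insensitive substring keywords marking uninformative names."""

    keywords: tuple[str, ...] = DEFAULT_GENERIC_KEYWORDS

    def __post_init__(self):
        object.__setattr__(
            self, "_lowered", tuple(k.lower() for k in self.keywords)
        )

    def matches(self, name: str) -> bool:
        lowered = name.lower()
        return any(k in lowered for k in self._lowered)


def is_generic(name: str, generics: GenericNameList) -> bool:
    """True iff any keyword occurs case-insensitively as a substring."""
    return generics.matches(name)


def _iter_taxdump_rows(source) -> Iterable[tuple[int, list[str]]]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from _iter_taxdump_rows(fh)
        return
    for lineno, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.endswith("\t|"):
            line = line[: -len("\t|")]
        yield lineno, line.split("\t|\t")


class TaxonomyStore:
    """Queryable local taxonomy with memoized lineage resolution."""

    def __init__(self, nodes: dict[int, TaxonNode], merged: Optional[dict[int, int]] = None):
        self._nodes = nodes
        self._merged = dict(merged or {})
        self._lineage_cache: dict[int, Lineage] = {}
        roots = [n.taxid for n in nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxdumpFormatError(
                f"expected exactly one self-parented root node, found {len(roots)}"
            )
        self.root_taxid = roots[0]
        for node in nodes.values():
            if node.parent_taxid not in nodes:
                raise TaxdumpFormatError(
                    f"taxid {node.taxid} references missing parent {node.parent_taxid}"
                )
            if not node.scientific_name:
                raise TaxdumpFormatError(f"taxid {node.taxid} has no scientific name")

    def __contains__(self, taxid: int) -> bool:
        return self.canonical_taxid(taxid) in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def taxids(self):
        return self._nodes.keys()

    def canonical_taxid(self, taxid: int) -> int:
        """Follow the merged-taxid table (identity if not merged)."""
        return self._merged.get(taxid, taxid)

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[self.canonical_taxid(taxid)]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def lineage_of(self, taxid: int) -> Lineage:
        """Root-first lineage of ``taxid``, including unranked nodes."""
        taxid = self.canonical_taxid(taxid)
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        chain: list[TaxonNode] = []
        current = self.node(taxid)
        for _ in range(len(self._nodes) + 1):
            chain.append(current)
            if current.taxid == self.root_taxid:
                break
            current = self.node(current.parent_taxid)
        else:
            raise TaxdumpFormatError(f"cycle detected in parent chain of taxid {taxid}")
        chain.reverse()
        names: list[Optional[str]] = [None] * len(STANDARD_RANKS)
        taxids: list[Optional[int]] = [None] * len(STANDARD_RANKS)
        for n in chain:
            slot = _RANK_TO_SLOT.get(n.rank)
            if slot is not None:
                names[slot] = n.scientific_name
                taxids[slot] = n.taxid
        lineage = Lineage(
            nodes=tuple(LineageNode(n.rank, n.scientific_name, n.taxid) for n in chain),
            standardized=tuple(names),
            standardized_taxids=tuple(taxids),
        )
        self._lineage_cache[taxid] = lineage
        return lineage


def terminal_rank(lineage: Lineage) -> Optional[str]:
    """The most specific filled standardized rank, or None if all blank."""
    for i in range(len(STANDARD_RANKS) - 1, -1, -1):
        if lineage.standardized[i] is not None:
            return STANDARD_RANKS[i]
    return None


def load_taxdump(nodes_source, names_source, merged_source=None) -> TaxonomyStore:
    """Build a :class:`TaxonomyStore` from taxdump-dialect tables.

    Parameters
    ----------
    nodes_source, names_source
        Paths or line iterables in NCBI taxdump dialect.  Nodes rows carry
        (taxid, parent taxid, rank, ...); names rows carry (taxid, name,
        unique name, name class, ...).  At least one "scientific name" row
        is required per taxid; rows whose class contains "synonym" are
        attached as synonyms.
    merged_source
        Optional merged.dmp-style table of (old taxid, new taxid) pairs.
    """
    nodes: dict[int, TaxonNode] = {}
    for lineno, fields in _iter_taxdump_rows(nodes_source):
        if len(fields) < 3:
            raise TaxdumpFormatError(
                f"nodes table line {lineno}: expected at least taxid|parent|rank"
            )
        taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        nodes[taxid] = TaxonNode(taxid, parent, rank, "")
    for lineno, fields in _iter_taxdump_rows(names_source):
        if len(fields) < 4:
            raise TaxdumpFormatError(
                f"names table line {lineno}: expected taxid|name|unique name|class"
            )
        taxid, name, name_class = int(fields[0]), fields[1], fields[3]
        node = nodes.get(taxid)
        if node is None:
            raise TaxdumpFormatError(
                f"names table line {lineno}: taxid {taxid} absent from nodes table"
            )
        if name_class == "scientific name":
            node.scientific_name = name
        elif "synonym" in name_class:
            node.synonyms.append(name)
    for node in nodes.values():
        if not node.scientific_name:
            raise TaxdumpFormatError(f"taxid {node.taxid} has no scientific name entry")
    merged: dict[int, int] = {}
    if merged_source is not None:
        for lineno, fields in _iter_taxdump_rows(merged_source):
            if len(fields) < 2:
                raise TaxdumpFormatError(
                    f"merged table line {lineno}: expected old|new taxid pair"
                )
            merged[int(fields[0])] = int(fields[1])
    return TaxonomyStore(nodes, merged)


def load_accession_map(source: Union[str, Path, io.TextIOBase, Iterable[str]]) -> dict[str, int]:
    """Load a 2-column (accession, taxid) TSV; '#' comment lines ignored."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return load_accession_map(fh)
    mapping: dict[str, int] = {}
    for lineno, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise TaxdumpFormatError(
                f"accession map line {lineno}: expected accession<TAB>taxid"
            )
        mapping[fields[0]] = int(fields[1])
    return mapping


def resolve_accession(accession: str, mapping: dict[str, int]):
    """Map an accession to a taxid; version-suffixed accessions fall back
    to the unversioned key.  Returns :data:`UNRESOLVED` when unmapped."""
    taxid = mapping.get(accession)
    if taxid is not None:
        return taxid
    if "." in accession:
        taxid = mapping.get(accession.rsplit(".", 1)[0])
        if taxid is not None:
            return taxid
    return UNRESOLVED
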