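"""Tabular alignment (BLAST outfmt-6 style) parsing and hit hygiene.

Dialect: the standard 12 tabular columns extended with the query length
as column 13 (qlen is indispensable for query coverage).  Trailing extra
columns are tolerated and ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from .taxonomy import UNRESOLVED, TaxonomyStore, resolve_accession

COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen"
).split()


class BlastFormatError(ValueError):
    """Raised when the tabular input violates the expected dialect."""


@dataclass(slots=True)
class BlastHit:
    """One alignment record linking a query to a subject taxon."""

    query_id: str
    subject_accession: str
    percent_identity: float
    alignment_length: int
    qstart: int
    qend: int
    qlen: int
    bitscore: float
    evalue: float
    mismatches: int = 0
    gapopen: int = 0
    sstart: int = 0
    send: int = 0
    taxid: Optional[int] = UNRESOLVED

    def __post_init__(self):
        if not (1 <= min(self.qstart, self.qend) and max(self.qstart, self.qend) <= self.qlen):
            raise ValueError(
                f"query coordinates ({self.qstart},{self.qend}) outside 1..{self.qlen}"
            )
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity {self.percent_identity} outside [0,100]")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")


def coverage(hit: BlastHit) -> float:
    """Fraction of the query spanned by the alignment, in [0, 1].

    Measured on the query (aligned query span over query length), so
    subject-side gaps do not inflate it; orientation-independent.
    """
    lo, hi = sorted((hit.qstart, hit.qend))
    return (hi - lo + 1) / hit.qlen


def parse_tabular(source: Union[str, Path, Iterable[str]]) -> list[BlastHit]:
    """Parse a 13-column tabular stream into :class:`BlastHit` records.

    '#' comment lines are skipped; malformed rows raise
    :class:`BlastFormatError` naming the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return parse_tabular(fh)
    hits: list[BlastHit] = []
    for lineno, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 13:
            raise BlastFormatError(
                f"line {lineno}: expected at least 13 tab-separated columns "
                f"({', '.join(COLUMNS)}); the standard 12-column format must be "
                f"extended with qlen as column 13"
            )
        try:
            hit = BlastHit(
                query_id=fields[0],
                subject_accession=fields[1],
                percent_identity=float(fields[2]),
                alignment_length=int(fields[3]),
                mismatches=int(fields[4]),
                gapopen=int(fields[5]),
                qstart=int(fields[6]),
                qend=int(fields[7]),
                sstart=int(fields[8]),
                send=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                qlen=int(fields[12]),
            )
        except ValueError as exc:
            raise BlastFormatError(f"line {lineno}: {exc}") from None
        hits.append(hit)
    return hits


def write_tabular(hits: Iterable[BlastHit], sink) -> None:
    """Write hits back out in the 13-column dialect (parse round-trips)."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_tabular(hits, fh)
        return
    for h in hits:
        sink.write(
            "\t".join(
                str(v)
                for v in (
                    h.query_id, h.subject_accession, h.percent_identity,
                    h.alignment_length, h.mismatches, h.gapopen,
                    h.qstart, h.qend, h.sstart, h.send,
                    h.evalue, h.bitscore, h.qlen,
                )
            )
            + "\n"
        )


def dedupe_best_hsp(hits: list[BlastHit]) -> list[BlastHit]:
    """Keep at most one HSP per (query, subject): highest bitscore, ties
    broken by higher identity then first-seen.  Survivor order preserved."""
    best: dict[tuple[str, str], tuple[int, BlastHit]] = {}
    for pos, hit in enumerate(hits):
        key = (hit.query_id, hit.subject_accession)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = (pos, hit)
            continue
        _, current = incumbent
        if (hit.bitscore, hit.percent_identity) > (current.bitscore, current.percent_identity):
            best[key] = (incumbent[0], hit)  # keep first-seen position
    return [hit for _, hit in sorted(best.values(), key=lambda item: item[0])]


def cap_hits(hits: list[BlastHit], max_hits: int) -> list[BlastHit]:
    """Keep the ``max_hits`` highest-bitscore hits, preserving input order
    among survivors (ties favor earlier rows)."""
    if len(hits) <= max_hits:
        return list(hits)
    ranked = sorted(range(len(hits)), key=lambda i: (-hits[i].bitscore, i))
    keep = sorted(ranked[:max_hits])
    return [hits[i] for i in keep]


def resolve_hit_taxa(
    hits: Iterable[BlastHit], mapping: dict[str, int], store: TaxonomyStore
) -> None:
    """Attach taxids in place; accessions unmapped or absent from the
    store are left :data:`UNRESOLVED` (dropped later, never a crash)."""
    for hit in hits:
        taxid = resolve_accession(hit.subject_accession, mapping)
        if taxid is UNRESOLVED or taxid not in store:
            hit.taxid = UNRESOLVED
        else:
            hit.taxid = store.canonical_taxid(taxid)
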