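"""Writers for the three result files (QIIME-style taxonomy convention).

All files are UTF-8 TSV with one '#' header line and are byte-stable
across runs: no timestamps or environment data appear in data rows.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

from .classify import Classification
from .taxonomy import STANDARD_RANKS

UNCLASSIFIED_TOKEN = "Unclassified"

STANDARD_HEADER = "#query_id\ttaxonomy\tconfidence\tnote"
FULL_HEADER = "#query_id\ttaxonomy\tconfidence\tnote"
VOTE_LOG_HEADER = (
    "#query_id\trecord\trank\teligible\twinner\twinner_votes\t"
    "winner_fraction\tgeneric_ignored\taccepted"
)


def _open_sink(sink, func, classifications):
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            func(classifications, fh)
        return True
    return False


def standardized_lineage_string(classification: Classification) -> str:
    """Semicolon-joined filled slots root-first, up to the accepted rank.

    Blank slots *between* filled slots are kept as empty components so a
    downstream parser can still assign rank positions; slots below the
    accepted rank are omitted entirely.
    """
    if not classification.is_classified:
        return UNCLASSIFIED_TOKEN
    last = STANDARD_RANKS.index(classification.accepted_rank)
    parts = [name or "" for name in classification.standardized[: last + 1]]
    return ";".join(parts)


def full_lineage_string(classification: Classification, root_taxid: Optional[int] = None) -> str:
    """Semicolon-joined names of every lineage node, unranked included.

    The root node itself is omitted when ``root_taxid`` is given (the
    conventional lineage string starts below the root).
    """
    if not classification.is_classified:
        return UNCLASSIFIED_TOKEN
    nodes = classification.full_lineage.nodes
    if root_taxid is not None:
        nodes = tuple(n for n in nodes if n.taxid != root_taxid)
    return ";".join(n.name for n in nodes)


def write_standard_taxonomy(classifications: Iterable[Classification], sink) -> None:
    """Write query_id, standardized lineage string, confidence, note."""
    if _open_sink(sink, write_standard_taxonomy, classifications):
        return
    sink.write(STANDARD_HEADER + "\n")
    for c in classifications:
        sink.write(
            f"{c.query_id}\t{standardized_lineage_string(c)}\t"
            f"{c.confidence:.4f}\t{c.message}\n"
        )


def write_full_taxonomy(
    classifications: Iterable[Classification], sink, root_taxid: Optional[int] = None
) -> None:
    """As :func:`write_standard_taxonomy` but with the complete lineage,
    including unranked intermediate nodes."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_full_taxonomy(classifications, fh, root_taxid)
        return
    sink.write(FULL_HEADER + "\n")
    for c in classifications:
        sink.write(
            f"{c.query_id}\t{full_lineage_string(c, root_taxid)}\t"
            f"{c.confidence:.4f}\t{c.message}\n"
        )


def write_vote_log(classifications: Iterable[Classification], sink) -> None:
    """Voting audit: one row per rank attempted plus a terminal status row.

    Rank rows carry the votes cast, the winner's tally and fraction, and
    the generic/partial exclusions at that rank; unclassified queries are
    flagged on their status row.
    """
    if _open_sink(sink, write_vote_log, classifications):
        return
    sink.write(VOTE_LOG_HEADER + "\n")
    for c in classifications:
        for vote in c.vote_log:
            accepted = "yes" if (c.is_classified and vote.rank == c.accepted_rank) else "no"
            winner = vote.winner if vote.winner is not None else "-"
            winner_votes = vote.votes.get(vote.winner, 0) if vote.winner else 0
            fraction = f"{vote.winner_fraction:.4f}" if vote.winner_fraction is not None else "-"
            sink.write(
                f"{c.query_id}\trank\t{vote.rank}\t{vote.eligible}\t{winner}\t"
                f"{winner_votes}\t{fraction}\t{vote.generic_ignored}\t{accepted}\n"
            )
        rank = c.accepted_rank or "-"
        sink.write(
            f"{c.query_id}\tstatus\t{rank}\t{c.n_passing_hits}\t{c.status}\t"
            f"0\t{c.confidence:.4f}\t0\t{'yes' if c.is_classified else 'no'}\n"
        )


def read_taxonomy_table(source) -> dict[str, tuple[list[str], float, str]]:
    """Parse a taxonomy TSV back into query_id -> (components, confidence,
    note).  Inverse of the two taxonomy writers (round-trip tested)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_taxonomy_table(fh)
    out: dict[str, tuple[list[str], float, str]] = {}
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        qid, lineage, confidence, note = line.split("\t")
        out[qid] = (lineage.split(";"), float(confidence), note)
    return out
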