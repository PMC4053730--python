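"""Bottom-up consensus-vote classification of alignment hits.

Pipeline per query: quality-filter hits on coverage / baseline identity /
taxon resolution, reject generic-dominated hit sets, then vote rank by
rank from species up to domain.  A rank is accepted when a unique winning
name's vote fraction strictly surpasses the rank's majority threshold;
all higher ranks are then called from the winner's lineage and lower
slots stay blank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .blast import BlastHit, cap_hits, coverage, dedupe_best_hsp
from .taxonomy import (
    STANDARD_RANKS,
    UNRESOLVED,
    GenericNameList,
    Lineage,
    TaxonomyStore,
    is_generic,
)

# Voting order: most specific rank first.
VOTING_ORDER: tuple[str, ...] = tuple(reversed(STANDARD_RANKS))

#: Ranks governed by the low (fine-rank) majority threshold.
LOW_MAJORITY_RANKS = frozenset({"species", "genus", "family"})

# Outcome statuses.
CLASSIFIED = "classified"
UNCLASSIFIED_NO_HITS = "unclassified_no_hits"
UNCLASSIFIED_LOW_COVERAGE = "unclassified_low_coverage"
UNCLASSIFIED_TOO_GENERIC = "unclassified_too_generic"
UNCLASSIFIED_NO_CONSENSUS = "unclassified_no_consensus"

_STATUS_MESSAGES = {
    UNCLASSIFIED_NO_HITS: "no hits returned for this query",
    UNCLASSIFIED_LOW_COVERAGE: "too few hits passed the coverage/identity filters",
    UNCLASSIFIED_TOO_GENERIC: "generic or partial annotations dominate the hit set",
    UNCLASSIFIED_NO_CONSENSUS: "no rank reached a voting majority",
}

#: Identity presets (species, genus, other) per amplicon.
PRESET_IDENTITIES: dict[str, tuple[float, float, float]] = {
    "its": (95.2, 83.05, 80.0),
    "18s": (99.0, 96.0, 80.0),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """All thresholds the voting algorithm uses.

    Identity thresholds are percent values; coverage and majorities are
    fractions in (0, 1].  ``preset`` records which identity bundle is in
    force ("its", "18s", or "custom").
    """

    min_coverage: float = 0.70
    identity_species: float = 95.2
    identity_genus: float = 83.05
    identity_other: float = 80.0
    majority_low: float = 0.60
    majority_high: float = 0.90
    generic_fraction_max: float = 0.70
    generics: GenericNameList = field(default_factory=GenericNameList)
    max_hits: int = 100
    min_passing_hits: int = 1
    preset: str = "custom"

    def __post_init__(self):
        for name in ("min_coverage", "majority_low", "majority_high", "generic_fraction_max"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name}={value} outside (0, 1]")
        for name in ("identity_species", "identity_genus", "identity_other"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name}={value} outside [0, 100]")
        if self.max_hits < 1 or self.min_passing_hits < 1:
            raise ValueError("max_hits and min_passing_hits must be >= 1")
        if self.preset in PRESET_IDENTITIES:
            expected = PRESET_IDENTITIES[self.preset]
            actual = (self.identity_species, self.identity_genus, self.identity_other)
            if actual != expected:
                raise ValueError(
                    f"preset {self.preset!r} fixes identities {expected}, got {actual}"
                )
        elif self.preset != "custom":
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "ClassifierConfig":
        """Build a config from a named identity preset ("its" or "18s")."""
        if preset not in PRESET_IDENTITIES:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESET_IDENTITIES)}")
        species, genus, other = PRESET_IDENTITIES[preset]
        return cls(
            identity_species=species,
            identity_genus=genus,
            identity_other=other,
            preset=preset,
            **overrides,
        )

    @classmethod
    def from_json(cls, source, **overrides) -> "ClassifierConfig":
        """Load a config from a JSON file/dict keyed by field names;
        keyword overrides win over file values."""
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as fh:
                data = json.load(fh)
        else:
            data = dict(source)
        data.update({k: v for k, v in overrides.items() if v is not None})
        preset = data.get("preset", "custom")
        if "generics" in data and not isinstance(data["generics"], GenericNameList):
            data["generics"] = GenericNameList(tuple(data["generics"]))
        if preset in PRESET_IDENTITIES:
            species, genus, other = PRESET_IDENTITIES[preset]
            data.setdefault("identity_species", species)
            data.setdefault("identity_genus", genus)
            data.setdefault("identity_other", other)
        return cls(**data)

    def identity_threshold(self, rank: str) -> float:
        if rank == "species":
            return self.identity_species
        if rank == "genus":
            return self.identity_genus
        return self.identity_other

    def majority_threshold(self, rank: str) -> float:
        return self.majority_low if rank in LOW_MAJORITY_RANKS else self.majority_high


@dataclass(frozen=True, slots=True)
class RankVote:
    """Audit record of one voting round at one rank."""

    rank: str
    eligible: int
    votes: dict[str, int]
    generic_ignored: int
    identity_excluded: int
    winner: Optional[str]
    winner_fraction: Optional[float]


@dataclass(slots=True)
class Classification:
    query_id: str
    status: str
    accepted_rank: Optional[str] = None
    standardized: tuple = tuple([None] * len(STANDARD_RANKS))
    full_lineage: Optional[Lineage] = None
    vote_log: list[RankVote] = field(default_factory=list)
    message: str = ""
    n_passing_hits: int = 0

    @property
    def is_classified(self) -> bool:
        return self.status == CLASSIFIED

    @property
    def confidence(self) -> float:
        """Winner fraction at the accepted rank; 0 for unclassified."""
        if not self.is_classified:
            return 0.0
        for vote in self.vote_log:
            if vote.rank == self.accepted_rank:
                return vote.winner_fraction
        return 0.0


def filter_hits(
    hits: list[BlastHit], cfg: ClassifierConfig
) -> tuple[list[BlastHit], list[tuple[BlastHit, str]]]:
    """Partition hits into quality-passing and (hit, reason) rejects.

    A hit passes with a resolved taxid, coverage >= min_coverage and
    identity >= the baseline (identity_other) threshold.
    """
    passing: list[BlastHit] = []
    rejected: list[tuple[BlastHit, str]] = []
    for hit in hits:
        if hit.taxid is UNRESOLVED:
            rejected.append((hit, "unresolved_taxon"))
        elif coverage(hit) < cfg.min_coverage:
            rejected.append((hit, "low_coverage"))
        elif hit.percent_identity < cfg.identity_other:
            rejected.append((hit, "low_identity"))
        else:
            passing.append(hit)
    return passing, rejected


def eligible_at_rank(
    passing: list[BlastHit], rank: str, cfg: ClassifierConfig, store: TaxonomyStore
) -> tuple[list[tuple[BlastHit, str]], int]:
    """Voters at ``rank`` and the count of hits ignored as generic/partial.

    A hit votes iff its identity meets the rank's threshold, its
    standardized lineage names this rank, and that name is not generic.
    Generic or partial annotations are uninformative at ranks where they
    carry no real name, so they are skipped there and counted in
    ``generic_ignored``; they vote again at ranks where their lineage is
    informative (a kingdom-only record votes at kingdom).
    """
    slot = STANDARD_RANKS.index(rank)
    threshold = cfg.identity_threshold(rank)
    voters: list[tuple[BlastHit, str]] = []
    generic_ignored = 0
    for hit in passing:
        if hit.percent_identity < threshold:
            continue
        name = store.lineage_of(hit.taxid).standardized[slot]
        if name is None or is_generic(name, cfg.generics):
            generic_ignored += 1
        else:
            voters.append((hit, name))
    return voters, generic_ignored


def tally(voters: list[tuple[BlastHit, str]], rank: str, *, generic_ignored: int = 0,
          identity_excluded: int = 0) -> RankVote:
    """Count one vote per voter; the winner needs a strictly unique
    maximum (ties yield no winner)."""
    votes: dict[str, int] = {}
    for _, name in voters:
        votes[name] = votes.get(name, 0) + 1
    winner: Optional[str] = None
    winner_fraction: Optional[float] = None
    if votes:
        top = max(votes.values())
        leaders = [name for name, count in votes.items() if count == top]
        if len(leaders) == 1:
            winner = leaders[0]
            winner_fraction = top / len(voters)
    return RankVote(
        rank=rank,
        eligible=len(voters),
        votes=votes,
        generic_ignored=generic_ignored,
        identity_excluded=identity_excluded,
        winner=winner,
        winner_fraction=winner_fraction,
    )


def _winning_lineage(
    voters: list[tuple[BlastHit, str]], winner: str, rank: str, store: TaxonomyStore
) -> Lineage:
    # Representative = winner-voting hit with highest bitscore (first-seen on ties).
    slot = STANDARD_RANKS.index(rank)
    best = max(
        (hit for hit, name in voters if name == winner),
        key=lambda h: h.bitscore,
    )
    winner_taxid = store.lineage_of(best.taxid).standardized_taxids[slot]
    return store.lineage_of(winner_taxid)


def classify_query(
    hits: list[BlastHit],
    cfg: ClassifierConfig,
    store: TaxonomyStore,
    query_id: Optional[str] = None,
) -> Classification:
    """Classify one query from its (deduplicated, capped) hit list.

    All failure modes are statuses on the returned record, never
    exceptions.
    """
    if query_id is None:
        query_id = hits[0].query_id if hits else "<unknown>"
    if not hits:
        return Classification(
            query_id=query_id,
            status=UNCLASSIFIED_NO_HITS,
            message=_STATUS_MESSAGES[UNCLASSIFIED_NO_HITS],
        )
    passing, _rejected = filter_hits(hits, cfg)
    if len(passing) < cfg.min_passing_hits:
        return Classification(
            query_id=query_id,
            status=UNCLASSIFIED_LOW_COVERAGE,
            message=_STATUS_MESSAGES[UNCLASSIFIED_LOW_COVERAGE],
            n_passing_hits=len(passing),
        )
    generic_count = 0
    for hit in passing:
        lineage = store.lineage_of(hit.taxid)
        if is_generic(lineage.terminal_name, cfg.generics) or all(
            name is None for name in lineage.standardized
        ):
            generic_count += 1
    if generic_count / len(passing) > cfg.generic_fraction_max:
        return Classification(
            query_id=query_id,
            status=UNCLASSIFIED_TOO_GENERIC,
            message=_STATUS_MESSAGES[UNCLASSIFIED_TOO_GENERIC],
            n_passing_hits=len(passing),
        )
    vote_log: list[RankVote] = []
    for rank in VOTING_ORDER:
        voters, generic_ignored = eligible_at_rank(passing, rank, cfg, store)
        vote = tally(
            voters,
            rank,
            generic_ignored=generic_ignored,
            identity_excluded=len(passing) - len(voters) - generic_ignored,
        )
        vote_log.append(vote)
        if vote.winner is not None and vote.winner_fraction > cfg.majority_threshold(rank):
            full = _winning_lineage(voters, vote.winner, rank, store)
            slot = STANDARD_RANKS.index(rank)
            standardized = tuple(
                name if i <= slot else None
                for i, name in enumerate(full.standardized)
            )
            return Classification(
                query_id=query_id,
                status=CLASSIFIED,
                accepted_rank=rank,
                standardized=standardized,
                full_lineage=full,
                vote_log=vote_log,
                n_passing_hits=len(passing),
            )
    return Classification(
        query_id=query_id,
        status=UNCLASSIFIED_NO_CONSENSUS,
        message=_STATUS_MESSAGES[UNCLASSIFIED_NO_CONSENSUS],
        vote_log=vote_log,
        n_passing_hits=len(passing),
    )


def classify_batch(
    hits: list[BlastHit],
    cfg: ClassifierConfig,
    store: TaxonomyStore,
    query_ids: Optional[list[str]] = None,
) -> list[Classification]:
    """Classify every query in a multi-query hit table.

    Hits are grouped per query, HSP-deduplicated and capped at
    ``cfg.max_hits``, then classified.  Output order follows
    ``query_ids`` when given (queries with no rows come back as
    no-hit records), else first appearance in the table.
    """
    grouped: dict[str, list[BlastHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    if query_ids is None:
        order = list(grouped)
    else:
        order = list(query_ids)
        order.extend(q for q in grouped if q not in set(query_ids))
    results = []
    for qid in order:
        qhits = cap_hits(dedupe_best_hsp(grouped.get(qid, [])), cfg.max_hits)
        results.append(classify_query(qhits, cfg, store, query_id=qid))
    return results
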