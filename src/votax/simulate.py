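"""Offline fixtures: toy taxonomies, error-bearing reads, emulated hit tables.

Everything the classification pipeline consumes can be generated here
deterministically from a seed — miniature taxdump tables with the
database pathologies seen in real searches (generic leaves, partial
high-rank-only records, rank gaps), pyrosequencing-style reads (per-base
substitutions then 3'-end exponential truncation), and alignment hit
tables derived from true edit distances that stand in for a live search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._align import semiglobal_distance
from .blast import BlastHit

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {ord(b): i for i, b in enumerate("ACGT")}


@dataclass(frozen=True, slots=True)
class Organism:
    name: str
    taxid: int
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"organism {self.name!r} has an empty reference sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(
                f"organism {self.name!r}: reference must be uppercase ACGT"
            )


@dataclass(frozen=True)
class CommunitySpec:
    """Description of an in-silico community and its read-error model."""

    organisms: tuple[Organism, ...]
    reads_per_organism: int = 32
    error_rate: float = 0.01
    trunc_mean: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 1)")
        if self.trunc_mean < 0:
            raise ValueError("trunc_mean must be >= 0")
        if self.reads_per_organism < 1:
            raise ValueError("reads_per_organism must be >= 1")
        if not self.organisms:
            raise ValueError("community needs at least one organism")

    @classmethod
    def from_json(cls, source, **overrides) -> "CommunitySpec":
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as fh:
                data = json.load(fh)
        else:
            data = dict(source)
        data.update({k: v for k, v in overrides.items() if v is not None})
        data["organisms"] = tuple(
            Organism(o["name"], int(o["taxid"]), o["sequence"].upper())
            if not isinstance(o, Organism) else o
            for o in data["organisms"]
        )
        return cls(**data)


@dataclass(frozen=True, slots=True)
class TruthRow:
    read_id: str
    organism: str
    taxid: int
    n_substitutions: int
    n_truncated: int


def simulate_reads(spec: CommunitySpec) -> tuple[list[tuple[str, str]], list[TruthRow]]:
    """Generate reads and their ground-truth table.

    Per read: copy the reference, substitute each base independently with
    probability ``error_rate`` (replacement uniform over the other three
    bases), then truncate the 3' end by round-to-nearest of an
    exponential draw with mean ``trunc_mean`` (capped at length - 1).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[tuple[str, str]] = []
    truth: list[TruthRow] = []
    for org in spec.organisms:
        template = np.array([_BASE_INDEX[b] for b in org.sequence.encode()], dtype=np.int8)
        safe_name = org.name.replace(" ", "_")
        for j in range(spec.reads_per_organism):
            bases = template.copy()
            mask = rng.random(bases.size) < spec.error_rate
            n_sub = int(mask.sum())
            if n_sub:
                offsets = rng.integers(1, 4, size=n_sub, dtype=np.int8)
                bases[mask] = (bases[mask] + offsets) % 4
            if spec.trunc_mean > 0:
                n_trunc = min(int(round(rng.exponential(spec.trunc_mean))), bases.size - 1)
            else:
                n_trunc = 0
            if n_trunc:
                bases = bases[: bases.size - n_trunc]
            read_id = f"{safe_name}_{j + 1:04d}"
            reads.append((read_id, _BASES[bases].tobytes().decode()))
            truth.append(TruthRow(read_id, org.name, org.taxid, n_sub, n_trunc))
    return reads, truth


def write_truth_table(truth: Sequence[TruthRow], sink) -> None:
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_truth_table(truth, fh)
        return
    sink.write("#read_id\torganism\ttaxid\tn_substitutions\tn_truncated\n")
    for row in truth:
        sink.write(
            f"{row.read_id}\t{row.organism}\t{row.taxid}\t"
            f"{row.n_substitutions}\t{row.n_truncated}\n"
        )


def read_truth_table(source) -> list[TruthRow]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_truth_table(fh)
    rows = []
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        read_id, organism, taxid, n_sub, n_trunc = line.split("\t")
        rows.append(TruthRow(read_id, organism, int(taxid), int(n_sub), int(n_trunc)))
    return rows


# ---------------------------------------------------------------------------
# Toy taxonomies


@dataclass(frozen=True)
class ToyTaxonomy:
    """Taxdump-dialect tables plus the generator's ground truth."""

    nodes_dmp: str
    names_dmp: str
    organisms: tuple[tuple[str, int], ...]  # (species name, species taxid)
    lineages: dict[int, tuple[tuple[str, str], ...]]  # taxid -> ((rank, name), ...)
    generic_leaf_taxids: tuple[int, ...] = ()
    kingdom_only_taxids: tuple[int, ...] = ()
    rank_gap_species_taxid: Optional[int] = None

    def write(self, directory) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes_path = directory / "nodes.dmp"
        names_path = directory / "names.dmp"
        nodes_path.write_text(self.nodes_dmp, encoding="utf-8")
        names_path.write_text(self.names_dmp, encoding="utf-8")
        return nodes_path, names_path


def make_toy_taxonomy(
    n_organisms: int,
    rank_gap: bool = False,
    generic_leaves: int = 0,
    kingdom_only_leaves: int = 0,
) -> ToyTaxonomy:
    """Build a connected 8-rank toy taxonomy in taxdump dialect.

    Each organism sits on a full domain..species path under a shared
    Eukaryota/Fungi head.  Optional pathological decoys mirror real
    database defects: a genus attached directly to a phylum (rank gap,
    with one species beneath it), species-rank leaves with generic
    "uncultured" names, and unranked leaves hanging directly off the
    kingdom (partial, kingdom-only records).
    """
    if n_organisms < 1:
        raise ValueError("n_organisms must be >= 1")
    nodes: list[tuple[int, int, str]] = [
        (1, 1, "no rank"),
        (2, 1, "superkingdom"),
        (3, 2, "kingdom"),
    ]
    names: list[tuple[int, str, str]] = [
        (1, "root", "scientific name"),
        (2, "Eukaryota", "scientific name"),
        (3, "Fungi", "scientific name"),
        (3, "Mycota", "synonym"),
    ]
    lineages: dict[int, tuple[tuple[str, str], ...]] = {
        1: (("no rank", "root"),),
        2: (("no rank", "root"), ("superkingdom", "Eukaryota")),
        3: (("no rank", "root"), ("superkingdom", "Eukaryota"), ("kingdom", "Fungi")),
    }
    organisms: list[tuple[str, int]] = []
    next_taxid = 4
    rank_chain = ("phylum", "class", "order", "family", "genus")
    first_phylum_taxid: Optional[int] = None
    for i in range(1, n_organisms + 1):
        parent = 3
        chain = list(lineages[3])
        for rank in rank_chain:
            name = f"{rank.capitalize()}{i}"
            nodes.append((next_taxid, parent, rank))
            names.append((next_taxid, name, "scientific name"))
            chain.append((rank, name))
            lineages[next_taxid] = tuple(chain)
            if rank == "phylum" and first_phylum_taxid is None:
                first_phylum_taxid = next_taxid
            parent = next_taxid
            next_taxid += 1
        species_name = f"Genus{i} species{i}"
        nodes.append((next_taxid, parent, "species"))
        names.append((next_taxid, species_name, "scientific name"))
        lineages[next_taxid] = tuple(chain) + (("species", species_name),)
        organisms.append((species_name, next_taxid))
        next_taxid += 1

    rank_gap_species_taxid: Optional[int] = None
    if rank_gap:
        gap_genus = next_taxid
        nodes.append((gap_genus, first_phylum_taxid, "genus"))
        names.append((gap_genus, "Gapgenus", "scientific name"))
        lineages[gap_genus] = lineages[first_phylum_taxid] + (("genus", "Gapgenus"),)
        next_taxid += 1
        rank_gap_species_taxid = next_taxid
        nodes.append((rank_gap_species_taxid, gap_genus, "species"))
        names.append((rank_gap_species_taxid, "Gapgenus gapspecies", "scientific name"))
        lineages[rank_gap_species_taxid] = lineages[gap_genus] + (
            ("species", "Gapgenus gapspecies"),
        )
        next_taxid += 1

    generic_taxids: list[int] = []
    if generic_leaves:
        env = next_taxid
        nodes.append((env, first_phylum_taxid, "no rank"))
        names.append((env, "environmental samples", "scientific name"))
        lineages[env] = lineages[first_phylum_taxid] + (("no rank", "environmental samples"),)
        next_taxid += 1
        for k in range(1, generic_leaves + 1):
            name = f"uncultured soil basidiomycete clone {k}"
            nodes.append((next_taxid, env, "species"))
            names.append((next_taxid, name, "scientific name"))
            lineages[next_taxid] = lineages[env] + (("species", name),)
            generic_taxids.append(next_taxid)
            next_taxid += 1

    kingdom_only_taxids: list[int] = []
    for k in range(1, kingdom_only_leaves + 1):
        name = f"eukaryote isolate K{k}"
        nodes.append((next_taxid, 3, "no rank"))
        names.append((next_taxid, name, "scientific name"))
        lineages[next_taxid] = lineages[3] + (("no rank", name),)
        kingdom_only_taxids.append(next_taxid)
        next_taxid += 1

    nodes_dmp = "".join(
        f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n" for taxid, parent, rank in nodes
    )
    names_dmp = "".join(
        f"{taxid}\t|\t{name}\t|\t\t|\t{name_class}\t|\n"
        for taxid, name, name_class in names
    )
    return ToyTaxonomy(
        nodes_dmp=nodes_dmp,
        names_dmp=names_dmp,
        organisms=tuple(organisms),
        lineages=lineages,
        generic_leaf_taxids=tuple(generic_taxids),
        kingdom_only_taxids=tuple(kingdom_only_taxids),
        rank_gap_species_taxid=rank_gap_species_taxid,
    )


def random_reference(length: int, rng: np.random.Generator) -> str:
    """Uniform-random ACGT reference of the requested length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


# ---------------------------------------------------------------------------
# Hit-table emulation


@dataclass(frozen=True, slots=True)
class NoiseOptions:
    """Controlled pathologies injected into emulated hit tables."""

    short_hit_fraction: float = 0.0
    short_hit_span: float = 0.5
    generic_hit_fraction: float = 0.0
    generic_accessions: tuple[str, ...] = ()


def emulate_hits(
    reads: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    top_k: int = 5,
    noise: Optional[NoiseOptions] = None,
    seed: int = 0,
) -> list[BlastHit]:
    """Emulate a nucleotide search: edit-distance-derived hit table.

    For each read the ``top_k`` references by semi-global edit distance
    become hits; percent identity is 100*(read length - distance)/read
    length, with full-span query coordinates.  Noise options replace a
    fraction of hits with short-coverage spans and append high-identity
    hits against generic accessions.  Deterministic given ``seed``.
    """
    noise = noise or NoiseOptions()
    rng = np.random.default_rng(seed)
    hits: list[BlastHit] = []
    for read_id, read_seq in reads:
        qlen = len(read_seq)
        distances = [
            (semiglobal_distance(read_seq, ref_seq), idx)
            for idx, (_, ref_seq) in enumerate(references)
        ]
        distances.sort()
        for dist, idx in distances[:top_k]:
            accession = references[idx][0]
            identity = round(max(0.0, 100.0 * (qlen - dist) / qlen), 2)
            qend = qlen
            if noise.short_hit_fraction and rng.random() < noise.short_hit_fraction:
                qend = max(1, int(qlen * noise.short_hit_span))
            hits.append(
                BlastHit(
                    query_id=read_id,
                    subject_accession=accession,
                    percent_identity=identity,
                    alignment_length=qend,
                    qstart=1,
                    qend=qend,
                    qlen=qlen,
                    sstart=1,
                    send=qend,
                    mismatches=dist,
                    evalue=0.0,
                    bitscore=round(2.0 * (qlen - dist), 1),
                )
            )
        if (
            noise.generic_hit_fraction
            and noise.generic_accessions
            and rng.random() < noise.generic_hit_fraction
        ):
            accession = noise.generic_accessions[
                int(rng.integers(0, len(noise.generic_accessions)))
            ]
            hits.append(
                BlastHit(
                    query_id=read_id,
                    subject_accession=accession,
                    percent_identity=99.0,
                    alignment_length=qlen,
                    qstart=1,
                    qend=qlen,
                    qlen=qlen,
                    sstart=1,
                    send=qlen,
                    mismatches=0,
                    evalue=0.0,
                    bitscore=round(1.98 * qlen, 1),
                )
            )
    return hits
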