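"""IUPAC-degeneracy-aware edit-distance profiling of a primer vs clades.

The primer aligns end-to-end against any window of each target (free
target ends); degenerate primer symbols match every base in their IUPAC
set at zero cost.  Per-clade distance histograms are normalized within
the clade, giving the relative proportion of taxa at each distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from ._align import (
    IUPAC_MASKS,
    hamming_window_distance,
    reverse_complement,
    semiglobal_distance,
)


def iupac_compatible(primer_symbol: str, target_base: str) -> bool:
    """True iff ``target_base`` belongs to the primer symbol's base set."""
    try:
        p = IUPAC_MASKS[primer_symbol.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC symbol {primer_symbol!r}") from None
    if target_base.upper() not in "ACGT":
        raise ValueError(f"target base must be one of A/C/G/T, got {target_base!r}")
    return bool(p & IUPAC_MASKS[target_base.upper()])


def best_edit_distance(
    primer: str, target: str, hamming: bool = False, revcomp: bool = False
) -> int:
    """Minimum distance of the primer over all placements on the target.

    Default mode is semi-global edit distance (indels cost 1); with
    ``hamming=True`` only gapless windows are scored (mismatches only).
    ``revcomp=True`` also scans the reverse complement and keeps the
    smaller distance.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    if not target:
        raise ValueError("target must be non-empty")
    score = hamming_window_distance if hamming else semiglobal_distance
    best = score(primer, target)
    if revcomp:
        best = min(best, score(primer, reverse_complement(target)))
    return best


@dataclass(frozen=True)
class PrimerProfile:
    primer: str
    per_sequence: dict[str, int]
    per_clade: dict[str, dict[int, float]]
    clade_counts: dict[str, int]


def profile_clades(
    primer: str,
    clades: Mapping[str, Sequence[tuple[str, str]]],
    hamming: bool = False,
    revcomp: bool = False,
) -> PrimerProfile:
    """Best distances per sequence and normalized histograms per clade.

    ``clades`` maps clade label -> [(sequence id, sequence), ...]; every
    clade must be non-empty.  Each clade's histogram sums to 1.
    """
    per_sequence: dict[str, int] = {}
    per_clade: dict[str, dict[int, float]] = {}
    clade_counts: dict[str, int] = {}
    for clade, members in clades.items():
        if not members:
            raise ValueError(f"clade {clade!r} has no sequences")
        counts: dict[int, int] = {}
        for seq_id, seq in members:
            d = best_edit_distance(primer, seq, hamming=hamming, revcomp=revcomp)
            per_sequence[seq_id] = d
            counts[d] = counts.get(d, 0) + 1
        total = len(members)
        per_clade[clade] = {d: c / total for d, c in sorted(counts.items())}
        clade_counts[clade] = total
    return PrimerProfile(
        primer=primer,
        per_sequence=per_sequence,
        per_clade=per_clade,
        clade_counts=clade_counts,
    )


def load_clade_map(source) -> dict[str, list[str]]:
    """Read a 2-column (sequence id, clade) TSV into clade -> id list."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return load_clade_map(fh)
    clades: dict[str, list[str]] = {}
    for lineno, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"clade map line {lineno}: expected id<TAB>clade")
        clades.setdefault(fields[1], []).append(fields[0])
    return clades


def write_profile(profile: PrimerProfile, sink) -> None:
    """Long-format TSV: clade, distance, proportion, taxa count."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_profile(profile, fh)
        return
    sink.write("#clade\tdistance\tproportion\tn_taxa\n")
    for clade in sorted(profile.per_clade):
        total = profile.clade_counts[clade]
        for distance, proportion in profile.per_clade[clade].items():
            sink.write(f"{clade}\t{distance}\t{proportion:.6f}\t{total}\n")
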