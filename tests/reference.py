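"""Independent brute-force references used as oracles by the test suite.

Everything here re-derives the rules from scratch with plain loops and
dicts, deliberately avoiding the package's own lineage/vote machinery.
"""

RANKS8 = ["domain", "kingdom", "phylum", "class", "order", "family", "genus", "species"]

# Hand-enumerated IUPAC sets (written out independently of the package).
IUPAC_TABLE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def ref_chain(store, taxid):
    """Raw parent-chain walk, root-first, via node records only."""
    chain = []
    node = store.node(taxid)
    while True:
        chain.append(node)
        if node.parent_taxid == node.taxid:
            break
        node = store.node(node.parent_taxid)
    chain.reverse()
    return chain


def ref_standardized(store, taxid):
    """taxid -> {rank: name or None} over the 8 canonical ranks."""
    slots = {r: None for r in RANKS8}
    for node in ref_chain(store, taxid):
        rank = "domain" if node.rank in ("superkingdom", "domain") else node.rank
        if rank in slots:
            slots[rank] = node.scientific_name
    return slots


def ref_is_generic(name, keywords):
    return any(k.lower() in name.lower() for k in keywords)


def ref_coverage(hit):
    lo, hi = sorted((hit.qstart, hit.qend))
    return (hi - lo + 1) / hit.qlen


def ref_classify(hits, cfg, store):
    """Full re-derivation of the classification outcome.

    Returns (status, accepted_rank, standardized 8-tuple).
    """
    keywords = cfg.generics.keywords
    if not hits:
        return ("unclassified_no_hits", None, tuple([None] * 8))
    passing = [
        h for h in hits
        if h.taxid is not None
        and ref_coverage(h) >= cfg.min_coverage
        and h.percent_identity >= cfg.identity_other
    ]
    if len(passing) < cfg.min_passing_hits:
        return ("unclassified_low_coverage", None, tuple([None] * 8))
    n_generic = 0
    for h in passing:
        terminal = ref_chain(store, h.taxid)[-1].scientific_name
        std = ref_standardized(store, h.taxid)
        if ref_is_generic(terminal, keywords) or all(v is None for v in std.values()):
            n_generic += 1
    if n_generic / len(passing) > cfg.generic_fraction_max:
        return ("unclassified_too_generic", None, tuple([None] * 8))
    for rank in reversed(RANKS8):
        if rank == "species":
            identity_cut = cfg.identity_species
        elif rank == "genus":
            identity_cut = cfg.identity_genus
        else:
            identity_cut = cfg.identity_other
        majority = cfg.majority_low if rank in ("species", "genus", "family") else cfg.majority_high
        ballots = []
        for h in passing:
            if h.percent_identity < identity_cut:
                continue
            name = ref_standardized(store, h.taxid)[rank]
            if name is None or ref_is_generic(name, keywords):
                continue
            ballots.append((name, h))
        if not ballots:
            continue
        counts = {}
        for name, _ in ballots:
            counts[name] = counts.get(name, 0) + 1
        top = max(counts.values())
        leaders = [n for n, c in counts.items() if c == top]
        if len(leaders) != 1:
            continue
        winner = leaders[0]
        if top / len(ballots) <= majority:
            continue
        rep = max((h for n, h in ballots if n == winner), key=lambda h: h.bitscore)
        std = ref_standardized(store, rep.taxid)
        idx = RANKS8.index(rank)
        out = tuple(std[r] if i <= idx else None for i, r in enumerate(RANKS8))
        return ("classified", rank, out)
    return ("unclassified_no_consensus", None, tuple([None] * 8))


def ref_best_edit_distance(primer, target):
    """Window-enumeration x full-DP oracle for semi-global edit distance.

    For every window start i, run a global DP of the primer against
    target[i:] and take the minimum over all window ends (including the
    empty window).
    """
    m = len(primer)
    best = m  # empty window: delete the whole primer
    psets = [IUPAC_TABLE[c.upper()] for c in primer]
    for i in range(len(target)):
        suffix = target[i:]
        n = len(suffix)
        prev = list(range(n + 1))  # D[0][k] = k (window chars consumed by insertions)
        for p in range(1, m + 1):
            cur = [p] + [0] * n
            for k in range(1, n + 1):
                sub = 0 if suffix[k - 1].upper() in psets[p - 1] else 1
                cur[k] = min(prev[k - 1] + sub, prev[k] + 1, cur[k - 1] + 1)
            prev = cur
        best = min(best, min(prev))
    return best
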