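import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reference import ref_classify
from votax.blast import BlastHit
from votax.classify import (
    CLASSIFIED,
    UNCLASSIFIED_LOW_COVERAGE,
    UNCLASSIFIED_NO_CONSENSUS,
    UNCLASSIFIED_NO_HITS,
    UNCLASSIFIED_TOO_GENERIC,
    ClassifierConfig,
    classify_batch,
    classify_query,
    eligible_at_rank,
    filter_hits,
    tally,
)
from votax.taxonomy import UNRESOLVED, GenericNameList


def hit(taxid, identity=100.0, cov=1.0, query="q1", subject=None, bitscore=None, qlen=200):
    span = max(1, round(cov * qlen))
    return BlastHit(
        query_id=query,
        subject_accession=subject or f"acc{taxid}",
        percent_identity=identity,
        alignment_length=span,
        qstart=1,
        qend=span,
        qlen=qlen,
        bitscore=bitscore if bitscore is not None else 2.0 * span * identity / 100,
        evalue=0.0,
        taxid=taxid,
    )


class TestClassifierConfig:
    def test_paper_defaults(self):
        cfg = ClassifierConfig()
        assert cfg.min_coverage == 0.70
        assert cfg.majority_low == 0.60
        assert cfg.majority_high == 0.90
        assert cfg.generic_fraction_max == 0.70
        assert cfg.max_hits == 100

    def test_its_preset(self):
        cfg = ClassifierConfig.from_preset("its")
        assert (cfg.identity_species, cfg.identity_genus, cfg.identity_other) == (95.2, 83.05, 80.0)

    def test_18s_preset(self):
        cfg = ClassifierConfig.from_preset("18s")
        assert (cfg.identity_species, cfg.identity_genus, cfg.identity_other) == (99.0, 96.0, 80.0)

    def test_preset_identity_mismatch_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            ClassifierConfig(identity_species=90.0, preset="its")

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            ClassifierConfig(min_coverage=0.0)
        with pytest.raises(ValueError):
            ClassifierConfig(majority_low=1.5)

    def test_from_json_with_overrides(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"preset": "18s", "min_coverage": 0.5}')
        cfg = ClassifierConfig.from_json(path, majority_low=0.65)
        assert cfg.identity_species == 99.0
        assert cfg.min_coverage == 0.5
        assert cfg.majority_low == 0.65

    def test_majority_rank_assignment(self):
        cfg = ClassifierConfig()
        assert cfg.majority_threshold("species") == cfg.majority_low
        assert cfg.majority_threshold("family") == cfg.majority_low
        assert cfg.majority_threshold("order") == cfg.majority_high
        assert cfg.majority_threshold("domain") == cfg.majority_high


class TestFilterHits:
    def test_low_coverage_rejected(self, its_cfg, toy):
        taxid = toy.organisms[0][1]
        passing, rejected = filter_hits([hit(taxid, cov=0.65)], its_cfg)
        assert passing == []
        assert rejected[0][1] == "low_coverage"

    def test_perfect_hit_passes(self, its_cfg, toy):
        passing, rejected = filter_hits([hit(toy.organisms[0][1])], its_cfg)
        assert len(passing) == 1 and not rejected

    def test_unresolved_rejected(self, its_cfg):
        passing, rejected = filter_hits([hit(UNRESOLVED)], its_cfg)
        assert rejected[0][1] == "unresolved_taxon"

    def test_low_identity_rejected(self, its_cfg, toy):
        _, rejected = filter_hits([hit(toy.organisms[0][1], identity=75.0)], its_cfg)
        assert rejected[0][1] == "low_identity"

    def test_matches_brute_force_partition(self, its_cfg, toy):
        rng = random.Random(3)
        taxids = [t for _, t in toy.organisms] + [UNRESOLVED]
        hits = [
            hit(rng.choice(taxids), identity=rng.uniform(60, 100), cov=rng.uniform(0.3, 1.0))
            for _ in range(100)
        ]
        passing, rejected = filter_hits(hits, its_cfg)
        for h in hits:
            lo, hi = sorted((h.qstart, h.qend))
            expected_pass = (
                h.taxid is not UNRESOLVED
                and (hi - lo + 1) / h.qlen >= its_cfg.min_coverage
                and h.percent_identity >= its_cfg.identity_other
            )
            assert (h in passing) == expected_pass
        assert len(passing) + len(rejected) == len(hits)


class TestEligibleAtRank:
    def test_kingdom_only_hit(self, its_cfg, store, toy):
        h = hit(toy.kingdom_only_taxids[0])
        voters, ignored = eligible_at_rank([h], "species", its_cfg, store)
        assert voters == [] and ignored == 1
        voters, ignored = eligible_at_rank([h], "kingdom", its_cfg, store)
        assert ignored == 0
        assert voters == [(h, "Fungi")]

    def test_identity_gates_species_but_not_genus(self, its_cfg, store, toy):
        h = hit(toy.organisms[0][1], identity=94.0)
        voters, ignored = eligible_at_rank([h], "species", its_cfg, store)
        assert voters == [] and ignored == 0  # identity-excluded, not generic
        voters, _ = eligible_at_rank([h], "genus", its_cfg, store)
        assert voters == [(h, "Genus1")]

    def test_empty_input(self, its_cfg, store):
        assert eligible_at_rank([], "species", its_cfg, store) == ([], 0)

    def test_generic_name_ignored_at_its_rank_but_votes_above(self, its_cfg, store, toy):
        h = hit(toy.generic_leaf_taxids[0])
        voters, ignored = eligible_at_rank([h], "species", its_cfg, store)
        assert voters == [] and ignored == 1
        voters, ignored = eligible_at_rank([h], "phylum", its_cfg, store)
        assert ignored == 0 and voters[0][1] == "Phylum1"


class TestTally:
    def test_majority_winner(self):
        voters = [(hit(1), "A")] * 7 + [(hit(1), "B")] * 3
        vote = tally(voters, "species")
        assert vote.winner == "A"
        assert vote.winner_fraction == pytest.approx(0.7)
        assert vote.eligible == 10

    def test_tie_has_no_winner(self):
        voters = [(hit(1), "A")] * 5 + [(hit(1), "B")] * 5
        vote = tally(voters, "genus")
        assert vote.winner is None and vote.winner_fraction is None

    def test_empty(self):
        vote = tally([], "species")
        assert vote.eligible == 0 and vote.winner is None

    @given(st.lists(st.sampled_from("ABCDE"), max_size=50))
    def test_matches_brute_force_max_count(self, names):
        voters = [(hit(1), n) for n in names]
        vote = tally(voters, "order")
        counts = {n: names.count(n) for n in set(names)}
        if counts:
            top = max(counts.values())
            leaders = sorted(n for n, c in counts.items() if c == top)
            if len(leaders) == 1:
                assert vote.winner == leaders[0]
                assert vote.winner_fraction == pytest.approx(top / len(names))
            else:
                assert vote.winner is None
        else:
            assert vote.winner is None
        assert vote.votes == counts


class TestClassifyQuery:
    def test_no_hits(self, its_cfg, store):
        result = classify_query([], its_cfg, store, query_id="qx")
        assert result.status == UNCLASSIFIED_NO_HITS
        assert result.message

    def test_unanimous_species(self, its_cfg, store, toy):
        taxid = toy.organisms[0][1]
        hits = [hit(taxid, subject=f"a{i}") for i in range(10)]
        result = classify_query(hits, its_cfg, store)
        assert result.status == CLASSIFIED
        assert result.accepted_rank == "species"
        assert result.confidence == 1.0
        assert all(name is not None for name in result.standardized)

    def test_species_tie_escalates_to_genus(self, its_cfg, store):
        # two species of one genus: add a sibling species under Genus1
        from votax.simulate import make_toy_taxonomy

        t = make_toy_taxonomy(1)
        extra_nodes = t.nodes_dmp + "100\t|\t8\t|\tspecies\t|\n"
        extra_names = t.names_dmp + "100\t|\tGenus1 speciesB\t|\t\t|\tscientific name\t|\n"
        import io

        from votax.taxonomy import load_taxdump

        s2 = load_taxdump(io.StringIO(extra_nodes), io.StringIO(extra_names))
        hits = [hit(9, subject=f"a{i}") for i in range(5)] + [
            hit(100, subject=f"b{i}") for i in range(5)
        ]
        result = classify_query(hits, ClassifierConfig.from_preset("its"), s2)
        assert result.status == CLASSIFIED
        assert result.accepted_rank == "genus"
        assert result.standardized[6] == "Genus1"
        assert result.standardized[7] is None

    def test_generic_dominated_then_excluded(self, its_cfg, store, toy):
        # 8 hits to one generic leaf + 2 hits to a real class-level node
        generic_taxid = toy.generic_leaf_taxids[0]
        class1_taxid = 5  # Class1 of organism 1
        assert store.node(class1_taxid).rank == "class"
        generic_hits = [hit(generic_taxid, subject=f"g{i}") for i in range(8)]
        real_hits = [hit(class1_taxid, subject=f"r{i}") for i in range(2)]
        result = classify_query(generic_hits + real_hits, its_cfg, store)
        assert result.status == UNCLASSIFIED_TOO_GENERIC
        # with the generic hits removed from input, classifies at class
        result2 = classify_query(real_hits, its_cfg, store)
        assert result2.status == CLASSIFIED
        assert result2.accepted_rank == "class"

    def test_all_low_coverage_unclassified(self, its_cfg, store, toy):
        hits = [hit(toy.organisms[0][1], cov=0.5, subject=f"a{i}") for i in range(5)]
        result = classify_query(hits, its_cfg, store)
        assert result.status == UNCLASSIFIED_LOW_COVERAGE

    def test_split_across_kingdom_no_consensus(self, its_cfg, store, toy):
        # three different phyla split the vote 1/1/1 all the way up except
        # kingdom/domain where unanimity holds
        hits = [hit(t, subject=f"a{i}") for i, (_, t) in enumerate(toy.organisms)]
        result = classify_query(hits, its_cfg, store)
        assert result.status == CLASSIFIED
        assert result.accepted_rank == "kingdom"
        assert result.standardized[:2] == ("Eukaryota", "Fungi")
        assert result.standardized[2:] == tuple([None] * 6)

    def test_vote_log_covers_all_attempted_ranks(self, its_cfg, store, toy):
        hits = [hit(t, subject=f"a{i}") for i, (_, t) in enumerate(toy.organisms)]
        result = classify_query(hits, its_cfg, store)
        attempted = [v.rank for v in result.vote_log]
        assert attempted == ["species", "genus", "family", "order", "class", "phylum", "kingdom"]

    def test_winner_fraction_strictly_surpasses_threshold(self, store, toy):
        # 3-of-5 at species = 0.60 does NOT surpass the 0.60 majority
        a, b = toy.organisms[0][1], toy.organisms[1][1]
        hits = [hit(a, subject=f"a{i}") for i in range(3)] + [
            hit(b, subject=f"b{i}") for i in range(2)
        ]
        cfg = ClassifierConfig.from_preset("its")
        result = classify_query(hits, cfg, store)
        assert result.accepted_rank != "species"
        for vote in result.vote_log:
            if vote.rank == "species":
                assert vote.winner_fraction == pytest.approx(0.6)

    def test_vote_conservation_invariant(self, its_cfg, store, toy):
        rng = random.Random(5)
        taxids = [t for _, t in toy.organisms] + list(toy.generic_leaf_taxids) + list(
            toy.kingdom_only_taxids
        )
        for _ in range(20):
            hits = [
                hit(rng.choice(taxids), identity=rng.uniform(80, 100), subject=f"a{i}")
                for i in range(rng.randint(1, 15))
            ]
            result = classify_query(hits, its_cfg, store)
            for vote in result.vote_log:
                assert (
                    sum(vote.votes.values()) + vote.generic_ignored + vote.identity_excluded
                    == result.n_passing_hits
                )
                assert vote.eligible == sum(vote.votes.values())

    def test_monotone_acceptance_under_lower_thresholds(self, store, toy):
        from votax.taxonomy import STANDARD_RANKS

        rng = random.Random(17)
        taxids = [t for _, t in toy.organisms] + [toy.rank_gap_species_taxid]
        base = ClassifierConfig.from_preset("its")
        low = ClassifierConfig.from_preset("its", majority_low=0.01, majority_high=0.01)
        for _ in range(50):
            hits = [
                hit(rng.choice(taxids), identity=rng.uniform(85, 100), subject=f"a{i}")
                for i in range(rng.randint(1, 8))
            ]
            r1 = classify_query(hits, base, store)
            r2 = classify_query(hits, low, store)
            if r1.status == CLASSIFIED:
                assert r2.status == CLASSIFIED
                # lowered thresholds may accept at the same or a *lower* rank
                assert STANDARD_RANKS.index(r2.accepted_rank) >= STANDARD_RANKS.index(
                    r1.accepted_rank
                )

    def test_determinism(self, its_cfg, store, toy):
        hits = [hit(t, subject=f"a{i}") for i, (_, t) in enumerate(toy.organisms)]
        r1 = classify_query(hits, its_cfg, store)
        r2 = classify_query(hits, its_cfg, store)
        assert r1 == r2


def _oracle_templates(oracle_toy):
    species1 = oracle_toy.organisms[0][1]
    species2 = oracle_toy.organisms[1][1]
    return [
        dict(taxid=species1, identity=100.0, cov=1.0),
        dict(taxid=species1, identity=96.0, cov=1.0),
        dict(taxid=species2, identity=100.0, cov=1.0),
        dict(taxid=species1, identity=90.0, cov=1.0),
        dict(taxid=species1, identity=100.0, cov=0.5),
        dict(taxid=oracle_toy.rank_gap_species_taxid, identity=100.0, cov=1.0),
        dict(taxid=oracle_toy.generic_leaf_taxids[0], identity=100.0, cov=1.0),
        dict(taxid=oracle_toy.kingdom_only_taxids[0], identity=100.0, cov=1.0),
    ]


class TestOracleEquivalence:
    def test_randomized_tables_match_reference(self, its_cfg, oracle_store, oracle_toy):
        rng = random.Random(23)
        templates = _oracle_templates(oracle_toy)
        for _ in range(300):
            k = rng.randint(0, 8)
            hits = [
                hit(subject=f"acc{i}", bitscore=500.0 - i, **rng.choice(templates))
                for i in range(k)
            ]
            result = classify_query(hits, its_cfg, oracle_store, query_id="q1")
            status, rank, std = ref_classify(hits, its_cfg, oracle_store)
            assert (result.status, result.accepted_rank, result.standardized) == (
                status, rank, std,
            )

    def test_exhaustive_small_tables_match_reference(self, its_cfg, oracle_store, oracle_toy):
        templates = _oracle_templates(oracle_toy)
        n_cases = 0
        for k in range(0, 5):
            for combo in itertools.combinations_with_replacement(range(len(templates)), k):
                hits = [
                    hit(subject=f"acc{i}", bitscore=500.0 - i, **templates[t])
                    for i, t in enumerate(combo)
                ]
                result = classify_query(hits, its_cfg, oracle_store, query_id="q1")
                assert (result.status, result.accepted_rank, result.standardized) == ref_classify(
                    hits, its_cfg, oracle_store
                )
                n_cases += 1
        assert n_cases > 400


class TestClassifyBatch:
    def test_missing_query_reported_no_hits(self, its_cfg, store, toy):
        hits = [hit(toy.organisms[0][1], query="q1"), hit(toy.organisms[1][1], query="q3")]
        results = classify_batch(hits, its_cfg, store, query_ids=["q1", "q2", "q3"])
        assert [r.query_id for r in results] == ["q1", "q2", "q3"]
        assert results[1].status == UNCLASSIFIED_NO_HITS
        assert results[1].message

    def test_shuffle_invariance(self, its_cfg, store, toy):
        rng = random.Random(9)
        hits = []
        for q in ("q1", "q2", "q3"):
            for i, (_, t) in enumerate(toy.organisms):
                hits.append(hit(t, query=q, subject=f"acc{i}", bitscore=400.0 + i))
        shuffled = hits[:]
        rng.shuffle(shuffled)
        by_query_1 = {r.query_id: r for r in classify_batch(hits, its_cfg, store)}
        by_query_2 = {r.query_id: r for r in classify_batch(shuffled, its_cfg, store)}
        assert by_query_1 == by_query_2

    def test_batch_equals_per_query(self, its_cfg, store, toy):
        from votax.blast import cap_hits, dedupe_best_hsp

        rng = random.Random(13)
        hits = []
        for q in ("q1", "q2"):
            for i in range(12):
                hits.append(
                    hit(rng.choice([t for _, t in toy.organisms]), query=q,
                        subject=f"acc{rng.randint(1, 6)}", bitscore=float(rng.randint(100, 500)))
                )
        results = classify_batch(hits, its_cfg, store)
        for r in results:
            qhits = [h for h in hits if h.query_id == r.query_id]
            expected = classify_query(
                cap_hits(dedupe_best_hsp(qhits), its_cfg.max_hits), its_cfg, store,
                query_id=r.query_id,
            )
            assert r == expected
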