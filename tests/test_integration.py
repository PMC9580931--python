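"""Integration semantics, checked against an independent all-pairs oracle."""

import random

import pytest

from itgdb.curation import curate
from itgdb.fixtures import FixtureSpec, build_sources
from itgdb.integration import (
    build_itgdb,
    contains,
    integrate_sequence_based,
    integrate_taxonomy_based,
)
from itgdb.model import Lineage, ReferenceDB, SequenceRecord

from conftest import make_db, make_lineage, random_dna


# ------------------------------------------------------------------ oracle

def oracle_sequence_integration(basis_entries, candidate_entries):
    """Naive all-pairs substring scan implementing the replace/skip/add rule."""
    working = list(basis_entries)  # (id, seq, ranks)
    decisions = []
    for cid, cseq, cranks in candidate_entries:
        victims = [wid for wid, wseq, _ in working if wseq in cseq]
        if victims:
            vs = set(victims)
            working = [w for w in working if w[0] not in vs]
            working.append((cid, cseq, cranks))
            decisions.append((cid, "replaced", tuple(victims)))
        else:
            holders = [wid for wid, wseq, _ in working if cseq in wseq]
            if holders:
                decisions.append((cid, "skipped", tuple(holders)))
            else:
                working.append((cid, cseq, cranks))
                decisions.append((cid, "added", ()))
    return working, decisions


def containment_rich_db(rng, n, min_len=30, max_len=120, prefix="x"):
    """Random database where substrings/superstrings/equalities are common."""
    entries = []
    seqs = []
    for i in range(n):
        roll = rng.random()
        if seqs and roll < 0.25:  # superstring of an earlier sequence
            base = rng.choice(seqs)
            seq = random_dna(rng, rng.randint(0, 15)) + base + random_dna(rng, rng.randint(0, 15))
        elif seqs and roll < 0.45:  # substring of an earlier sequence
            base = rng.choice(seqs)
            if len(base) > 8:
                a = rng.randint(0, len(base) // 3)
                b = rng.randint(2 * len(base) // 3, len(base))
                seq = base[a:b]
            else:
                seq = base
        elif seqs and roll < 0.55:  # exact copy
            seq = rng.choice(seqs)
        else:
            seq = random_dna(rng, rng.randint(min_len, max_len))
        seqs.append(seq)
        entries.append((f"{prefix}{i:04d}", seq, f"Genus{i % 7}_species{i % 7}"))
    return entries


def run_both(basis_entries, candidate_entries, k=12):
    basis = make_db(basis_entries)
    candidate = make_db(candidate_entries)
    merged, log = integrate_sequence_based(basis, candidate, k=k)
    oracle_entries, oracle_decisions = oracle_sequence_integration(
        [(r.id, r.seq, l.ranks) for r, l in basis],
        [(r.id, r.seq, l.ranks) for r, l in candidate],
    )
    return merged, log, oracle_entries, oracle_decisions


# -------------------------------------------------------------- containment

class TestContains:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGTACGT", "GTAC", True),
            ("ACGTT", "ACGAT", False),  # one nucleotide difference: no containment
            ("ACGT", "ACGT", True),     # equality counts
            ("ACGT", "ACGTA", False),
            ("ACGTN", "GTN", True),     # degenerate codes compared literally
            ("ACGTA", "GTN", False),
        ],
    )
    def test_literal_substring_semantics(self, a, b, expected):
        assert contains(a, b) is expected


# ----------------------------------------------------------- sequence mode

class TestSequenceIntegration:
    def test_candidate_containing_basis_replaces_it(self):
        merged, log, *_ = run_both(
            [("s1", "CGTA", "Genus1_species1")], [("c1", "ACGTAT", "Genus2_species2")]
        )
        assert merged.ids() == ["c1"]
        assert log.n_replaced == 1
        # the replacement carries the candidate's own lineage
        assert merged.get("c1")[1].species == "Genus2_species2"

    def test_candidate_inside_basis_is_skipped(self):
        merged, log, *_ = run_both(
            [("s1", "ACGTAT", "Genus1_species1")], [("c1", "CGTA", "Genus2_species2")]
        )
        assert merged.ids() == ["s1"]
        assert log.n_skipped == 1
        assert log.decisions[0] == ("c1", "skipped", ("s1",))

    def test_unrelated_candidate_is_added(self):
        merged, log, *_ = run_both(
            [("s1", "AAAAAAA", "Genus1_species1")], [("c1", "CCCCCCC", "Genus2_species2")]
        )
        assert set(merged.ids()) == {"s1", "c1"}
        assert log.n_added == 1

    def test_one_candidate_replaces_several_contained_basis_entries(self):
        merged, log, *_ = run_both(
            [("s1", "AAACCC", "g1_s1"), ("s2", "CCCGGG", "g2_s2"), ("s3", "TTTTTTTT", "g3_s3")],
            [("c1", "AAACCCGGG", "g4_s4")],
        )
        assert set(merged.ids()) == {"s3", "c1"}
        assert log.decisions[0] == ("c1", "replaced", ("s1", "s2"))

    def test_log_accounts_for_every_candidate(self, rng):
        basis = containment_rich_db(rng, 50, prefix="b")
        candidate = containment_rich_db(rng, 50, prefix="c")
        _, log, _, _ = run_both(basis, candidate)
        assert log.n_added + log.n_replaced + log.n_skipped == log.n_candidate == 50
        assert [cid for cid, _, _ in log.decisions] == [cid for cid, _, _ in candidate]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_oracle(self, seed):
        rng = random.Random(seed)
        basis = containment_rich_db(rng, 60, prefix="b")
        candidate = containment_rich_db(rng, 60, prefix="c")
        merged, log, oracle_entries, oracle_decisions = run_both(basis, candidate)
        assert merged.entry_set() == frozenset(oracle_entries)
        assert log.decisions == oracle_decisions

    @pytest.mark.parametrize("k", [4, 12, 64])
    def test_index_anchor_size_does_not_change_semantics(self, k):
        rng = random.Random(99)
        basis = containment_rich_db(rng, 40, min_len=5, max_len=80, prefix="b")
        candidate = containment_rich_db(rng, 40, min_len=5, max_len=80, prefix="c")
        merged, log, oracle_entries, oracle_decisions = run_both(basis, candidate, k=k)
        assert merged.entry_set() == frozenset(oracle_entries)
        assert log.decisions == oracle_decisions

    def test_every_output_is_superstring_of_some_input(self, rng):
        basis = containment_rich_db(rng, 30, prefix="b")
        candidate = containment_rich_db(rng, 30, prefix="c")
        merged, *_ = run_both(basis, candidate)
        inputs = [seq for _, seq, _ in basis + candidate]
        for rec, _ in merged:
            assert any(s in rec.seq for s in inputs)

    def test_id_collision_is_an_error(self):
        basis = make_db([("x", "AAAA", "g_s")])
        candidate = make_db([("x", "CCCC", "g_s")])
        with pytest.raises(ValueError, match="collides"):
            integrate_sequence_based(basis, candidate)


# ----------------------------------------------------------- taxonomy mode

class TestTaxonomyIntegration:
    def test_new_taxonomy_is_added(self):
        basis = make_db([("b1", "AAAA", "Foo_one")])
        candidate = make_db([("c1", "CCCC", "Foo_bar")])
        merged, log = integrate_taxonomy_based(basis, candidate)
        assert set(merged.ids()) == {"b1", "c1"}
        assert log.decisions == [("c1", "added", ())]

    def test_identical_lineage_and_sequence_skipped(self):
        basis = make_db([("b1", "AAAA", "Foo_bar")])
        candidate = make_db([("c1", "AAAA", "Foo_bar")])
        merged, log = integrate_taxonomy_based(basis, candidate)
        assert merged.ids() == ["b1"]
        assert log.decisions == [("c1", "skipped", ("b1",))]

    def test_one_nucleotide_difference_is_added(self):
        basis = make_db([("b1", "AAAA", "Foo_bar")])
        candidate = make_db([("c1", "AAAT", "Foo_bar")])
        merged, log = integrate_taxonomy_based(basis, candidate)
        assert set(merged.ids()) == {"b1", "c1"}
        assert log.n_added == 1

    def test_basis_never_shrinks(self, rng):
        dbs, _ = build_sources(FixtureSpec(seed=5))
        basis, _ = curate(dbs["rdp"])
        candidate, _ = curate(dbs["silva"])
        merged, _ = integrate_taxonomy_based(basis, candidate.with_prefixed_ids("c"))
        for rec, lin in basis:
            assert rec.id in merged

    def test_species_set_is_union_of_inputs(self, rng):
        dbs, _ = build_sources(FixtureSpec(seed=5))
        basis, _ = curate(dbs["rdp"])
        candidate, _ = curate(dbs["silva"])
        merged, _ = integrate_taxonomy_based(basis, candidate.with_prefixed_ids("c"))
        assert merged.species_set() == basis.species_set() | candidate.species_set()

    def test_within_lineage_sequences_pairwise_distinct(self, rng):
        dbs, _ = build_sources(FixtureSpec(seed=6, shared_all=4, seqs_per_species=2))
        basis, _ = curate(dbs["rdp"])
        candidate, _ = curate(dbs["silva"])
        merged, _ = integrate_taxonomy_based(basis, candidate.with_prefixed_ids("c"))
        for lineage, ids in merged.lineage_index().items():
            seqs = [merged.get(i)[0].seq for i in ids]
            assert len(seqs) == len(set(seqs))

    def test_uncurated_input_rejected(self):
        basis = make_db([("b1", "AAAA", "metagenome")])
        candidate = make_db([("c1", "CCCC", "Foo_bar")])
        with pytest.raises(ValueError, match="curate"):
            integrate_taxonomy_based(basis, candidate)


# ------------------------------------------------------------------ folding

class TestBuildItgdb:
    def test_three_disjoint_single_entry_sources(self):
        sources = [
            make_db([("a", "AAAA", "Genus1_species1")]),
            make_db([("a", "CCCC", "Genus2_species2")]),
            make_db([("a", "GGGG", "Genus3_species3")]),
        ]
        merged, logs = build_itgdb(sources, mode="taxonomy")
        assert len(merged) == 3
        assert len(logs) == 2
        assert merged.species_set() == {"Genus1_species1", "Genus2_species2", "Genus3_species3"}

    @pytest.mark.parametrize("mode", ["sequence", "taxonomy"])
    def test_folding_a_db_with_itself_is_identity_up_to_prefixes(self, mode, rng):
        dbs, _ = build_sources(FixtureSpec(seed=8, n_containment=0))
        db, _ = curate(dbs["silva"])
        merged, _ = build_itgdb([db, db, db], mode=mode)
        assert {(r.seq, l.ranks) for r, l in merged} == {(r.seq, l.ranks) for r, l in db}

    def test_two_round_fold_matches_stepwise_oracle(self):
        # 12-entry trio engineered with containments and shared taxonomies.
        rdp = make_db([
            ("r1", "AAACCCGGG", "Genus1_species1"),
            ("r2", "TTTGGGCCC", "Genus2_species2"),
            ("r3", "ACACACAC", "Genus3_species3"),
            ("r4", "GTGTGTGT", "Genus4_species4"),
        ])
        silva = make_db([
            ("s1", "TTAAACCCGGGTT", "Genus5_species5"),   # engulfs r1 -> replaced
            ("s2", "ACGTACGTACGT", "Genus6_species6"),    # new -> added
            ("s3", "ACAC", "Genus7_species7"),            # inside r3 -> skipped
            ("s4", "GTGTGTGT", "Genus4_species4"),        # equals r4 -> replaced
        ])
        gg = make_db([
            ("g1", "TTAAACCCGGGTT", "Genus5_species5"),   # equals s1 -> replaced
            ("g2", "CCCCCCCCCC", "Genus8_species8"),      # new -> added
            ("g3", "CGTACG", "Genus9_species9"),          # inside s2 -> skipped
            ("g4", "TTTGGGCCCAA", "Genus2_species2"),     # engulfs r2 -> replaced
        ])
        merged, logs = build_itgdb([rdp, silva, gg], mode="sequence",
                                   names=["rdp", "silva", "gg"])
        assert {(r.seq, l.species) for r, l in merged} == {
            ("ACACACAC", "Genus3_species3"),
            ("ACGTACGTACGT", "Genus6_species6"),
            ("TTAAACCCGGGTT", "Genus5_species5"),
            ("GTGTGTGT", "Genus4_species4"),
            ("CCCCCCCCCC", "Genus8_species8"),
            ("TTTGGGCCCAA", "Genus2_species2"),
        }
        assert [d[1] for d in logs[0].decisions] == ["replaced", "added", "skipped", "replaced"]
        assert [d[1] for d in logs[1].decisions] == ["replaced", "added", "skipped", "replaced"]
        # round two: g1 replaces the silva-round survivor of the s1 chain
        assert logs[1].decisions[0][2] == ("silva|s1",)

    def test_fewer_than_two_sources_rejected(self):
        with pytest.raises(ValueError, match="two"):
            build_itgdb([make_db([("a", "AAAA", "g_s")])], mode="sequence")

    def test_determinism(self, rng):
        dbs, _ = build_sources(FixtureSpec(seed=9))
        args = [dbs["rdp"], dbs["silva"], dbs["greengenes"]]
        m1, l1 = build_itgdb(args, mode="sequence")
        m2, l2 = build_itgdb(args, mode="sequence")
        assert m1 == m2
        assert [log.decisions for log in l1] == [log.decisions for log in l2]
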