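"""Grafting, substitution pools, greedy dehumanization, variants."""

import numpy as np
import pytest

import epigraft as eg
from conftest import minimal_destroying_mutations, naive_scan
from epigraft.alignment import PairwiseAlignment, _column_map
from epigraft.humanness import AMINO_ACIDS


def _stretch(start, end, donor, partners=("A", "B")):
    return eg.EpitopeStretch(
        start=start, end=end, supporting_partners=frozenset(partners),
        donor_residues=donor[start - 1 : end],
    )


def _manual_alignment(aligned_donor: str, aligned_scaffold: str) -> PairwiseAlignment:
    return PairwiseAlignment(
        aligned_donor=aligned_donor,
        aligned_scaffold=aligned_scaffold,
        column_map=_column_map(aligned_donor, aligned_scaffold),
        score=0.0,
    )


class TestTransplant:
    def test_identity_alignment_substitutes_stretch_residues(self):
        donor, scaffold = "AAACDEAAAA", "AAAAAAAAAA"
        aln = eg.align_donor_scaffold(donor, scaffold)
        grafted, plan = eg.transplant_stretches(
            scaffold, donor, [_stretch(4, 6, donor)], aln
        )
        assert grafted == "AAACDEAAAA"
        assert plan.substitutions == [(4, "A", "C"), (5, "A", "D"), (6, "A", "E")]
        assert plan.transplanted == {4: "C", 5: "D", 6: "E"}

    def test_empty_stretch_list_is_identity(self):
        donor, scaffold = "ACDEFGHIK", "MNPQRSTVW"
        aln = eg.align_donor_scaffold(donor, scaffold)
        grafted, plan = eg.transplant_stretches(scaffold, donor, [], aln)
        assert grafted == scaffold
        assert not plan.transplanted and not plan.substitutions

    def test_scaffold_gap_inside_stretch_inserts_donor_residue(self):
        # donor position 5 sits over a scaffold gap
        donor = "AAACDEAAA"
        scaffold = "AAACEAAA"
        aln = _manual_alignment("AAACDEAAA", "AAAC-EAAA")
        grafted, plan = eg.transplant_stretches(
            scaffold, donor, [_stretch(4, 6, donor)], aln
        )
        assert grafted == "AAACDEAAA"
        assert len(grafted) == len(scaffold) + 1
        assert plan.insertions == [(5, "D")]

    def test_donor_gap_inside_stretch_deletes_scaffold_residue(self):
        donor = "AAACEAAA"
        scaffold = "AAACWEAAA"
        aln = _manual_alignment("AAAC-EAAA", "AAACWEAAA")
        grafted, plan = eg.transplant_stretches(
            scaffold, donor, [_stretch(4, 5, donor)], aln
        )
        assert grafted == "AAACEAAA"
        assert plan.deletions == [(5, "W")]

    def test_stretch_outside_donor_rejected(self):
        donor, scaffold = "ACDEF", "ACDEF"
        aln = eg.align_donor_scaffold(donor, scaffold)
        bad = eg.EpitopeStretch(start=4, end=9, supporting_partners=frozenset({"A"}))
        with pytest.raises(ValueError, match="outside donor range"):
            eg.transplant_stretches(scaffold, donor, [bad], aln)

    @pytest.mark.parametrize("seed", range(6))
    def test_graft_integrity_on_random_fixtures(self, seed):
        """Outside stretches the graft is the scaffold; inside, the donor."""
        rng = np.random.default_rng(seed)
        letters = list(AMINO_ACIDS)
        donor = "".join(rng.choice(letters, size=40))
        # related scaffold: mutate 30%, occasionally delete
        chars = [
            str(rng.choice([c for c in letters if c != ch]))
            if rng.random() < 0.3 else ch
            for ch in donor
        ]
        scaffold = "".join(c for c in chars if rng.random() > 0.05)
        s1 = int(rng.integers(3, 12))
        s2 = int(rng.integers(20, 32))
        stretches = [_stretch(s1, s1 + 4, donor), _stretch(s2, s2 + 3, donor)]
        aln = eg.align_donor_scaffold(donor, scaffold)
        grafted, plan = eg.transplant_stretches(scaffold, donor, stretches, aln)
        # stretch columns carry exactly the donor residues
        inside = "".join(grafted[p - 1] for p in sorted(plan.transplanted))
        expected = "".join(donor[s.start - 1 : s.end] for s in stretches)
        assert inside == expected
        # non-transplanted positions, in order, equal the scaffold minus the
        # residues consumed by the stretches
        outside = "".join(
            ch for i, ch in enumerate(grafted, 1) if i not in plan.transplanted
        )
        consumed = {s for p, s in plan.graft_to_scaffold.items()
                    if p in plan.transplanted and s is not None}
        consumed |= {s for s, _ in plan.deletions}
        remaining = "".join(
            ch for i, ch in enumerate(scaffold, 1) if i not in consumed
        )
        assert outside == remaining


class TestSubstitutionPool:
    def test_counting_examples(self):
        msa = {"scaffold": "A", "v1": "A", "v2": "A", "v3": "S"}
        pool = eg.build_substitution_pool(msa, "scaffold", "A", [1], min_count=1)
        assert pool.pools[1] == {"S": 1.0}

        conserved = {"scaffold": "A", "v1": "A", "v2": "A"}
        pool = eg.build_substitution_pool(conserved, "scaffold", "A", [1], 1)
        assert pool.pools[1] == {}

        mixed = {"scaffold": "S", "v1": "A", "v2": "A", "v3": "S", "v4": "T"}
        pool = eg.build_substitution_pool(mixed, "scaffold", "S", [1], min_count=2)
        assert pool.pools[1] == {"A": 2.0}

    def test_gaps_and_x_excluded(self):
        msa = {"scaffold": "A", "v1": "-", "v2": "X", "v3": "T"}
        pool = eg.build_substitution_pool(msa, "scaffold", "A", [1], 1)
        assert pool.pools[1] == {"T": 1.0}

    def test_position_without_column_is_an_error(self):
        msa = {"scaffold": "AC", "v1": "AT"}
        with pytest.raises(ValueError, match="no alignment column"):
            eg.build_substitution_pool(msa, "scaffold", "ACD", [3], 1)

    def test_inserted_positions_inherit_nearest_column_and_are_flagged(self):
        msa = {"scaffold": "AC", "v1": "TC"}
        g2s = {1: 1, 2: None, 3: 2}  # position 2 is a grafting insertion
        pool = eg.build_substitution_pool(msa, "scaffold", "ADC", [1, 2, 3], 1, g2s)
        assert pool.inherited == {2}
        assert pool.pools[2] == {"A": 1.0, "T": 1.0}  # column of position 1, D excluded

    def test_current_residue_never_in_own_pool(self):
        msa, seq = {"scaffold": "A", "v1": "A", "v2": "S"}, "A"
        pool = eg.build_substitution_pool(msa, "scaffold", seq, [1], 1)
        assert "A" not in pool.pools[1]


class TestDehumanize:
    def test_zero_matches_is_a_fixed_point(self):
        proteome = eg.generate_proteome(5, (40, 40), alphabet="DE", seed=1)
        idx = eg.build_kmer_index(proteome, 9)
        seq = "KRKRKRKRKRKRKR"
        cand = eg.dehumanize(seq, idx, set(), eg.SubstitutionPool.unrestricted(seq))
        assert cand.status == "clean"
        assert cand.sequence == seq and not cand.mutations

    def test_single_window_single_mutable_position(self, planted_case):
        query, proteome, truth = planted_case(seed=1, plant_at=[11])
        idx = eg.build_kmer_index(proteome, 9)
        immutable = set(range(1, len(query) + 1)) - {13}
        pool = eg.SubstitutionPool(pools={13: {"S": 1.0}})
        if query[12] == "S":  # ensure the replacement actually differs
            pool = eg.SubstitutionPool(pools={13: {"T": 1.0}})
        cand = eg.dehumanize(query, idx, immutable, pool)
        assert cand.status == "clean"
        assert len(cand.mutations) == 1 and cand.mutations[0].position == 13
        assert not naive_scan(cand.sequence, proteome)

    def test_overlapping_windows_destroyed_by_one_shared_mutation(self, planted_case):
        # a planted 10-mer produces two overlapping 9-mer matches
        query, proteome, _ = planted_case(seed=5, plant_at=[11, 12])
        idx = eg.build_kmer_index(proteome, 9)
        pool = eg.SubstitutionPool.unrestricted(query)
        cand = eg.dehumanize(query, idx, set(), pool)
        assert cand.status == "clean"
        assert len(cand.mutations) == 1
        p = cand.mutations[0].position
        assert 12 <= p <= 19  # covered by both windows
        assert minimal_destroying_mutations(query, idx, set()) == 1

    def test_window_inside_immutable_region_is_infeasible(self, planted_case):
        query, proteome, truth = planted_case(seed=2, plant_at=[11])
        idx = eg.build_kmer_index(proteome, 9)
        immutable = set(range(11, 20))  # the whole matched window
        cand = eg.dehumanize(query, idx, immutable,
                             eg.SubstitutionPool.unrestricted(query))
        assert cand.status == "infeasible"
        assert 11 in cand.offending_windows
        assert all(m.position not in immutable for m in cand.mutations)

    def test_budget_exhaustion_status(self, planted_case):
        query, proteome, _ = planted_case(seed=4, plant_at=[5, 20, 31])
        idx = eg.build_kmer_index(proteome, 9)
        cand = eg.dehumanize(query, idx, set(),
                             eg.SubstitutionPool.unrestricted(query),
                             max_mutations=0)
        assert cand.status == "budget_exhausted"
        assert not cand.mutations

    def test_mutation_count_bounded_by_initial_matches(self, planted_case):
        query, proteome, _ = planted_case(seed=6, plant_at=[3, 14, 25])
        idx = eg.build_kmer_index(proteome, 9)
        initial = len(eg.scan_sequence(query, idx).matches)
        cand = eg.dehumanize(query, idx, set(),
                             eg.SubstitutionPool.unrestricted(query))
        assert cand.status == "clean"
        assert len(cand.mutations) <= initial
        # per-step provenance: every mutation destroyed at least one window
        assert all(m.windows_destroyed for m in cand.mutations)

    def test_no_new_proteome_windows_created(self, planted_case):
        """Soundness: the clean sequence has no match by independent rescan."""
        for seed in (11, 12, 13):
            query, proteome, _ = planted_case(seed=seed, plant_at=[8, 22])
            idx = eg.build_kmer_index(proteome, 9)
            cand = eg.dehumanize(query, idx, set(),
                                 eg.SubstitutionPool.unrestricted(query))
            if cand.status == "clean":
                assert naive_scan(cand.sequence, proteome) == []


class TestVariantsAndEvaluation:
    def test_named_variant_applied_at_matching_position(self):
        seq = "A" * 20 + "K" + "A" * 10
        out = eg.apply_variants(seq, [eg.io.parse_mutation("K21Q")])
        assert out[20] == "Q"
        assert out[:20] == seq[:20] and out[21:] == seq[21:]
        assert len(out) == len(seq)

    def test_empty_variant_list_is_identity(self):
        assert eg.apply_variants("ACDEF", []) == "ACDEF"

    def test_from_residue_mismatch_guards_numbering(self):
        seq = "A" * 20 + "R" + "A" * 10
        with pytest.raises(ValueError, match="from-residue mismatch"):
            eg.apply_variants(seq, [eg.io.parse_mutation("K21Q")])

    def test_variants_with_inverses_restore_the_sequence(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        muts = [eg.Mutation(3, "D", "W"), eg.Mutation(10, "L", "A")]
        forward = eg.apply_variants(seq, muts)
        back = eg.apply_variants(forward, [m.inverse() for m in muts])
        assert back == seq

    def test_evaluate_design_flags_broken_epitope(self, planted_case):
        query, proteome, _ = planted_case(seed=3, plant_at=[11])
        idx = eg.build_kmer_index(proteome, 9)
        plan = eg.GraftPlan(stretches=[], transplanted={15: query[14]})
        cand = eg.dehumanize(query, idx, {15},
                             eg.SubstitutionPool.unrestricted(query))
        report = eg.evaluate_design(cand, idx, plan)
        assert report["epitope_intact"]
        # misconfigured immutable set: the epitope position was free to mutate
        broken = eg.dehumanize(query, idx, set(),
                               eg.SubstitutionPool.unrestricted(query))
        wrong_plan = eg.GraftPlan(stretches=[], transplanted={
            broken.mutations[0].position: broken.mutations[0].from_aa
        }) if broken.mutations else None
        if wrong_plan:
            report2 = eg.evaluate_design(broken, idx, wrong_plan)
            assert not report2["epitope_intact"]
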