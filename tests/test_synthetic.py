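"""Fixture generators: determinism and ground-truth consistency."""

import numpy as np
import pytest

import epigraft as eg
from conftest import naive_scan


class TestProteome:
    def test_shapes_and_determinism(self):
        recs = eg.generate_proteome(10, (50, 50), seed=1)
        assert len(recs) == 10
        assert all(len(r.sequence) == 50 for r in recs)
        again = eg.generate_proteome(10, (50, 50), seed=1)
        assert [(r.id, r.sequence) for r in recs] == [
            (r.id, r.sequence) for r in again
        ]
        other = eg.generate_proteome(10, (50, 50), seed=2)
        assert [r.sequence for r in recs] != [r.sequence for r in other]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            eg.generate_proteome(0, (10, 10))
        with pytest.raises(ValueError):
            eg.generate_proteome(1, (5, 2))
        with pytest.raises(ValueError, match="alphabet"):
            eg.generate_proteome(1, (10, 10), alphabet="")


class TestPlanting:
    def test_single_plant_found_by_brute_scan(self):
        rng = np.random.default_rng(7)
        query = "".join(rng.choice(list("ACDEFGHIKL"), size=30))
        proteome = eg.generate_proteome(5, (40, 40), seed=7)
        planted, truth = eg.plant_shared_windows(
            query, proteome, [(11, proteome[2].id, 5)]
        )
        assert truth == [(11, query[10:19])]
        assert naive_scan(query, planted) == [(11, query[10:19])]

    def test_empty_spec_leaves_proteome_unchanged(self):
        proteome = eg.generate_proteome(3, (30, 30), seed=1)
        out, truth = eg.plant_shared_windows("A" * 20, proteome, [])
        assert truth == []
        assert [r.sequence for r in out] == [r.sequence for r in proteome]

    def test_same_window_into_two_proteins_gives_one_match_two_sources(self):
        rng = np.random.default_rng(9)
        query = "".join(rng.choice(list("MNPQRSTVWY"), size=25))
        proteome = eg.generate_proteome(4, (40, 40), alphabet="ACDE", seed=3)
        planted, _ = eg.plant_shared_windows(
            query, proteome,
            [(5, proteome[0].id, 10), (5, proteome[1].id, 20)],
        )
        idx = eg.build_kmer_index(planted, 9)
        report = eg.scan_sequence(query, idx)
        assert len(report.matches) == 1
        assert len(report.matches[0].sources) == 2
        assert report.distinct_proteins_hit == 2

    def test_contradictory_plants_rejected(self):
        proteome = eg.generate_proteome(2, (40, 40), seed=1)
        query = "ACDEFGHIKLMNPQRSTVWY"
        with pytest.raises(ValueError, match="contradictory"):
            eg.plant_shared_windows(
                query, proteome,
                [(1, proteome[0].id, 5), (10, proteome[0].id, 5)],
            )

    def test_out_of_range_plants_rejected(self):
        proteome = eg.generate_proteome(2, (40, 40), seed=1)
        with pytest.raises(ValueError, match="does not fit"):
            eg.plant_shared_windows("ACDEFGHIKL", proteome, [(5, proteome[0].id, 5)])


class TestToyComplex:
    def test_far_partner_no_contacts(self):
        model, partition, expected = eg.generate_toy_complex(10, 6, 20.0, (5, 8))
        assert expected == set()
        profile = eg.per_residue_bsa(model, partition, partner_id="P")
        assert all(v["P"] == 0.0 for v in profile.bsa.values())

    def test_close_partner_contacts_exactly_the_span(self):
        model, partition, expected = eg.generate_toy_complex(12, 8, 3.3, (5, 8))
        assert expected == {5, 6, 7, 8}
        profile = eg.per_residue_bsa(model, partition, partner_id="P")
        assert eg.contact_residues(profile, "P", 1.0) == {5, 6, 7, 8}

    def test_multi_span_contacts(self):
        model, partition, expected = eg.generate_toy_complex(
            20, 12, 3.3, [(5, 8), (12, 14)]
        )
        assert expected == {5, 6, 7, 8, 12, 13, 14}
        profile = eg.per_residue_bsa(model, partition, partner_id="P")
        assert eg.contact_residues(profile, "P", 1.0) == expected

    def test_geometry_deterministic_across_seeds_without_jitter(self):
        m1, _, _ = eg.generate_toy_complex(10, 8, 3.3, (5, 8), seed=1)
        m2, _, _ = eg.generate_toy_complex(10, 8, 3.3, (5, 8), seed=2)
        c1 = [a.coords for ch in m1.chains.values() for r in ch for a in r.atoms]
        c2 = [a.coords for ch in m2.chains.values() for r in ch for a in r.atoms]
        assert c1 == c2

    def test_impossible_geometry_rejected(self):
        # an interior length-1 span at close distance cannot avoid
        # contacting the span's neighbours
        with pytest.raises(ValueError, match="geometrically impossible"):
            eg.generate_toy_complex(10, 6, 3.3, (5, 5))

    def test_partner_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            eg.generate_toy_complex(10, 2, 3.3, (3, 8))


class TestSpeciesMsa:
    def test_zero_rate_gives_identical_rows_and_empty_pools(self):
        base = "ACDEFGHIKL"
        msa, truth = eg.generate_species_msa(base, 5, 0.0, seed=1, base_id="scaffold")
        assert all(row == base for row in msa.values())
        pool = eg.build_substitution_pool(msa, "scaffold", base,
                                          range(1, len(base) + 1), 1)
        assert all(not p for p in pool.pools.values())

    def test_truth_counts_match_recount(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        msa, truth = eg.generate_species_msa(base, 6, 0.3, seed=4)
        for col, counts in enumerate(truth):
            recount = {}
            for row in msa.values():
                aa = row[col]
                recount[aa] = recount.get(aa, 0) + 1
            assert recount == counts

    def test_full_rate_substitutes_every_variant_column(self):
        base = "AAAAAAAAAA"
        msa, truth = eg.generate_species_msa(base, 3, 1.0, seed=2, base_id="b")
        for rid, row in msa.items():
            if rid != "b":
                assert all(ch != "A" for ch in row)

    def test_seeded_determinism(self):
        a, _ = eg.generate_species_msa("ACDEFGHIKL", 4, 0.2, seed=9)
        b, _ = eg.generate_species_msa("ACDEFGHIKL", 4, 0.2, seed=9)
        assert a == b

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            eg.generate_species_msa("ACDE", 3, 1.5)


class TestFullFixture:
    def test_regeneration_is_identical(self, seed7):
        again = eg.full_fixture(7)
        assert again.donor == seed7.donor
        assert again.scaffold == seed7.scaffold
        assert again.grafted == seed7.grafted
        assert [(r.id, r.sequence) for r in again.proteome] == [
            (r.id, r.sequence) for r in seed7.proteome
        ]
        assert again.msa == seed7.msa

    def test_distinct_seeds_differ(self, seed7):
        other = eg.full_fixture(8)
        assert other.donor != seed7.donor

    def test_planted_truth_recovered_by_scan(self, seed7):
        idx = eg.build_kmer_index(seed7.proteome, seed7.k)
        report = eg.scan_sequence(seed7.grafted, idx)
        found = [(m.query_start, m.window) for m in report.matches]
        assert found == sorted(seed7.planted_windows)

    def test_contact_truth_recovered_by_footprint(self, seed7):
        for pid, (model, partition, expected) in seed7.complexes.items():
            profile = eg.per_residue_bsa(model, partition, partner_id=pid)
            assert eg.contact_residues(profile, pid, 1.0) == expected

    def test_msa_truth_matches_alignment(self, seed7):
        for col, counts in enumerate(seed7.msa_truth):
            recount = {}
            for row in seed7.msa.values():
                aa = row[col]
                recount[aa] = recount.get(aa, 0) + 1
            assert recount == counts

    def test_written_files_round_trip(self, seed7, tmp_path):
        paths = seed7.write(tmp_path)
        donor = eg.io.read_fasta(paths["donor"])[0][1]
        assert donor == seed7.donor
        proteome = eg.io.read_proteome(paths["proteome"])
        assert [(r.id, r.sequence) for r in proteome] == [
            (r.id, r.sequence) for r in seed7.proteome
        ]
        model = eg.load_structure(paths["complex_P1"].read_text(), "pdb")
        assert model.chain_sequence("T") == seed7.donor
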