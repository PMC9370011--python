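"""Contact free energies, grid enumeration and primary-contact selection."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import scmfold as sf
from scmfold.scan import _rank_key


class TestFreeEnergy:
    @pytest.mark.parametrize(
        "h_a, h_b, n_ij, expected_1dp",
        [
            (4.61, 7.36, 92, -8.9),   # AMAIY + ILTII
            (6.17, 5.34, 73, -8.2),   # VQLWV + VVVPY
            (6.04, 5.34, 83, -7.8),   # MFCQL + VVVPY
            (0.0, 0.0, 65, 17.2),     # purely entropic cost
        ],
    )
    def test_worked_examples(self, default_config, h_a, h_b, n_ij, expected_1dp):
        dg = sf.contact_free_energy(h_a, h_b, n_ij, default_config)
        assert round(dg, 1) == pytest.approx(expected_1dp)

    def test_sidechain_constant_emerges_from_width(self):
        # the 10.9 kT constant is 1.09 kT/residue over 2 x 5 residues, not a
        # hard-coded number; other widths scale it
        assert sf.ScanConfig(width=5).sidechain_cost_kt == pytest.approx(10.9)
        assert sf.ScanConfig(width=7).sidechain_cost_kt == pytest.approx(15.26)

    def test_decomposition_is_exact(self, default_config):
        hyd, loop, side = sf.contact_energy_components(4.61, 7.36, 92, default_config)
        assert hyd + loop + side == sf.contact_free_energy(4.61, 7.36, 92,
                                                           default_config)
        assert hyd == pytest.approx(-(4.61 + 7.36) / 0.45)
        assert loop == pytest.approx(1.5 * math.log(92))
        assert side == pytest.approx(10.9)

    def test_invalid_separation(self, default_config):
        with pytest.raises(ValueError, match="n_ij"):
            sf.contact_free_energy(1.0, 1.0, 0, default_config)

    @given(
        h_a=st.floats(-5, 12), h_b=st.floats(-5, 12),
        delta=st.floats(0.01, 5), n_ij=st.integers(65, 100),
    )
    def test_monotonicity(self, default_config, h_a, h_b, delta, n_ij):
        """More hydrophobic segments stabilise; longer loops destabilise."""
        dg = sf.contact_free_energy(h_a, h_b, n_ij, default_config)
        assert sf.contact_free_energy(h_a + delta, h_b, n_ij, default_config) < dg
        if n_ij < 100:
            assert sf.contact_free_energy(h_a, h_b, n_ij + 1, default_config) > dg


class TestEnumeration:
    def test_grid_matches_brute_force_oracle(self, fp_scale, default_config):
        for seed in range(5):
            rec = sf.generate_sequence(sf.GeneratorSpec(length=180, seed=seed))
            grid = sf.enumerate_candidates(rec, fp_scale, default_config)
            oracle = sf.oracle_scan(rec, fp_scale, default_config)
            assert len(grid) == len(oracle)
            for cand, (ca, cb, dg) in zip(grid, oracle):
                assert (cand.window_a.center, cand.window_b.center) == (ca, cb)
                assert cand.dG_total == pytest.approx(dg, abs=1e-9)

    def test_separation_bounds_inclusive(self, fp_scale):
        config = sf.ScanConfig(min_separation=65, max_separation=66)
        rec = sf.generate_sequence(sf.GeneratorSpec(length=75, seed=0))
        seps = {c.n_ij for c in sf.enumerate_candidates(rec, fp_scale, config)}
        assert seps == {65, 66}

    def test_too_short_sequence_warns_and_returns_empty(self, fp_scale,
                                                        default_config):
        rec = sf.generate_sequence(sf.GeneratorSpec(length=60, seed=1))
        with pytest.warns(UserWarning, match="no admissible"):
            assert sf.enumerate_candidates(rec, fp_scale, default_config) == []

    def test_p53_grid_contains_dominant_pair(self, p53, fp_scale, default_config):
        grid = sf.enumerate_candidates(p53, fp_scale, default_config)
        match = [c for c in grid
                 if (c.window_a.center, c.window_b.center) == (161, 253)]
        assert len(match) == 1
        assert match[0].n_ij == 92


class TestSelection:
    def test_empty_grid_rejected(self, default_config):
        with pytest.raises(ValueError, match="empty"):
            sf.select_primary_contacts([], default_config)

    def test_p53_ranking(self, p53_contacts):
        """The dominant contact is the native AMAIY-ILTII pair; the next two
        are the known non-native competitors."""
        top = p53_contacts.contacts[0]
        assert top.label == "C1"
        assert (top.window_a.span, top.window_b.span) == ("159-163", "251-255")
        assert round(top.stability_kt, 1) == 8.9
        second = p53_contacts.contacts[1]
        assert (second.window_a.sequence, second.window_b.sequence) == (
            "VQLWV", "VVVPY")
        assert round(second.stability_kt, 1) == 8.2
        third = p53_contacts.contacts[2]
        assert (third.window_a.sequence, third.window_b.sequence) == (
            "MFCQL", "VVVPY")
        assert round(third.stability_kt, 1) == 7.8

    def test_selected_within_cutoff(self, p53_contacts, default_config):
        best = p53_contacts.contacts[0].stability_kt
        for c in p53_contacts:
            assert c.stability_kt >= best - default_config.cutoff_kt

    def test_shared_segments_stay_distinct(self, p53_contacts):
        # VVVPY partners both VQLWV and MFCQL; sharing one segment must not
        # suppress either contact
        b_seqs = [c.window_b.sequence for c in p53_contacts]
        assert b_seqs.count("VVVPY") >= 2

    def test_suppression_soundness(self, p53, fp_scale, default_config):
        """Every reported contact is the best-ranked member of its overlap
        neighborhood in the full grid."""
        grid = sf.enumerate_candidates(p53, fp_scale, default_config)
        by_centers = {(c.window_a.center, c.window_b.center): c for c in grid}
        selected = sf.select_primary_contacts(grid, default_config)
        for c in selected:
            for da in range(-4, 5):
                for db in range(-4, 5):
                    other = by_centers.get((c.window_a.center + da,
                                            c.window_b.center + db))
                    if other is None or other is c:
                        continue
                    assert _rank_key(other) > _rank_key(c) or (da, db) == (0, 0)

    def test_planted_pair_collapses_to_single_contact(self, fp_scale,
                                                      default_config):
        spec = sf.GeneratorSpec(
            length=200, composition={"G": 0.5, "S": 0.5}, seed=7,
            plants=(("IIIII", 50), ("WWWWW", 120)),
        )
        rec = sf.generate_sequence(spec)
        contacts = sf.scan_protein(rec, fp_scale, default_config)
        assert len(contacts) == 1
        top = contacts.contacts[0]
        assert (top.window_a.center, top.window_b.center) == (52, 122)
        assert top.n_ij == 70

    def test_exact_ties_break_deterministically(self, fp_scale):
        # three identical plants give two energy-identical contacts
        # (42-112 and 112-182, both n_ij = 70): the N-terminal-most pair
        # must rank first, identically on every run
        spec = sf.GeneratorSpec(
            length=250, composition={"G": 1.0}, seed=0,
            plants=(("IIIII", 40), ("IIIII", 110), ("IIIII", 180)),
        )
        rec = sf.generate_sequence(spec)
        contacts = sf.scan_protein(rec, fp_scale, sf.ScanConfig(cutoff_kt=1.0))
        pairs = [(c.window_a.center, c.window_b.center) for c in contacts]
        assert pairs[:2] == [(42, 112), (112, 182)]
        again = sf.scan_protein(rec, fp_scale, sf.ScanConfig(cutoff_kt=1.0))
        assert pairs == [(c.window_a.center, c.window_b.center) for c in again]
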