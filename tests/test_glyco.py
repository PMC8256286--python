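"""Glycopeptide masses, ladders, fragments and EIC extraction."""

import numpy as np
import pytest

from cmannose import (
    HEX,
    PROTON,
    Chromatogram,
    GlycoSpecies,
    Peptide,
    Scan,
    SpectrumRun,
    enumerate_glycoforms,
    extract_eic,
    fragment_ions,
    glyco_mass,
    peptide_neutral_mass,
    quantify_glycoforms,
    simulate_ms1_run,
)

from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_by_ions, oracle_peptide_mass, random_peptide

aa_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


@given(left=aa_text, right=aa_text)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_mass_is_additive_over_concatenation(left, right):
    """mass(AB) = mass(A) + mass(B) − water, for any split point."""
    whole = peptide_neutral_mass(Peptide(left + right))
    parts = peptide_neutral_mass(Peptide(left)) + peptide_neutral_mass(Peptide(right))
    assert whole == pytest.approx(parts - 18.010565, abs=1e-8)


class TestNeutralMass:
    def test_glycine_matches_residue_table_oracle(self):
        assert peptide_neutral_mass(Peptide("G", fixed_mods={})) == pytest.approx(
            75.03203, abs=1e-5
        )

    def test_random_peptides_match_oracle(self, rng):
        for _ in range(200):
            seq = random_peptide(rng)
            assert peptide_neutral_mass(Peptide(seq)) == pytest.approx(
                oracle_peptide_mass(seq), abs=5e-4
            )

    def test_empty_fixed_mods_equal_default_on_cys_free_peptide(self):
        assert peptide_neutral_mass(Peptide("AGSTW", fixed_mods={})) == (
            peptide_neutral_mass(Peptide("AGSTW"))
        )

    def test_carbamidomethyl_applied_per_cysteine(self):
        delta = peptide_neutral_mass(Peptide("ACC")) - peptide_neutral_mass(
            Peptide("ACC", fixed_mods={})
        )
        assert delta == pytest.approx(2 * 57.02146, abs=1e-6)

    def test_peptide_bond_additivity(self):
        lhs = (
            peptide_neutral_mass(Peptide("AG"))
            - peptide_neutral_mass(Peptide("A"))
            - peptide_neutral_mass(Peptide("G"))
            + 18.010565
        )
        assert abs(lhs) < 1e-6

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'J'"):
            peptide_neutral_mass(Peptide("AJG"))


class TestGlycoMass:
    p = Peptide("WSDWSSWSPCT", n_consensus_trp=3, has_ofucose_site=True)

    def test_one_mannose_adds_162_05(self):
        delta = glyco_mass(self.p, 1) - glyco_mass(self.p, 0)
        assert round(delta, 2) == 162.05

    def test_zero_glycans_is_bare_peptide(self):
        assert glyco_mass(self.p, 0) == peptide_neutral_mass(self.p)

    def test_fucglc_minus_fuc_is_exactly_one_hexose(self):
        d = glyco_mass(self.p, 0, "FucGlc") - glyco_mass(self.p, 0, "Fuc")
        assert d == pytest.approx(HEX, abs=1e-12)

    def test_too_many_hexoses_rejected(self):
        with pytest.raises(ValueError, match="n_hex"):
            glyco_mass(self.p, 4)

    def test_fucose_without_site_rejected(self):
        bare = Peptide("WSDWSSWSPC", n_consensus_trp=3)
        with pytest.raises(ValueError, match="O-fucose"):
            glyco_mass(bare, 0, "Fuc")


class TestGlycoformLadder:
    def test_three_sites_with_fucose_gives_12_species(self):
        p = Peptide("WSDWSSWSPCT", n_consensus_trp=3, has_ofucose_site=True)
        species = enumerate_glycoforms(p)
        assert len(species) == 12
        labels = [s.label for s in species]
        assert labels[:3] == ["Hex0", "Hex0+Fuc", "Hex0+FucGlc"]
        assert labels[-1] == "Hex3+FucGlc"

    def test_no_sites_no_fucose_gives_bare_peptide_only(self):
        assert len(enumerate_glycoforms(Peptide("ACDEF"))) == 1

    def test_three_sites_no_fucose_gives_4_species(self):
        p = Peptide("WSDWSSWSPC", n_consensus_trp=3)
        labels = [s.label for s in enumerate_glycoforms(p)]
        assert labels == ["Hex0", "Hex1", "Hex2", "Hex3"]

    def test_mz_strictly_decreasing_in_charge(self):
        p = Peptide("WSDWSSWSPC", n_consensus_trp=3)
        mzs = [GlycoSpecies(p, 2, charge=z).mz for z in (1, 2, 3, 4)]
        assert all(b < a for a, b in zip(mzs, mzs[1:]))


class TestFragmentIons:
    def test_ag_y1_matches_oracle(self):
        ions = dict(fragment_ions(Peptide("AG")))
        assert ions["y1"] == pytest.approx(76.03931, abs=1e-5)
        assert ions == pytest.approx(oracle_by_ions("AG"), abs=1e-4)

    def test_by_complementarity_on_random_peptides(self, rng):
        """b_i + y_(n-i) equals neutral mass + 2 protons for every i."""
        for _ in range(100):
            seq = random_peptide(rng, min_len=3)
            p = Peptide(seq)
            ions = dict(fragment_ions(p))
            m = peptide_neutral_mass(p)
            for i in range(1, len(seq)):
                assert ions[f"b{i}"] + ions[f"y{len(seq) - i}"] == pytest.approx(
                    m + 2 * PROTON, abs=1e-9
                )

    def test_hexose_on_first_residue_shifts_prefix_ions_only(self):
        p = Peptide("WAGST", n_consensus_trp=1)
        bare = dict(fragment_ions(p))
        modded = dict(fragment_ions(p, site_mods={1: "Hex"}))
        for i in range(1, 5):
            assert modded[f"b{i}+Hex"] == pytest.approx(bare[f"b{i}"] + 162.05282, abs=1e-9)
        for j in range(1, 5):
            assert modded[f"y{j}"] == pytest.approx(bare[f"y{j}"], abs=1e-12)
        # full-length y would carry the hexose too: the b/y complement of the
        # modified ladder sums to the glycosylated neutral mass + 2 protons
        assert modded["b1+Hex"] + modded["y4"] == pytest.approx(
            peptide_neutral_mass(p) + 162.05282 + 2 * PROTON, abs=1e-9
        )

    def test_max_index_out_of_range(self):
        with pytest.raises(ValueError):
            fragment_ions(Peptide("AG"), max_index=2)

    def test_site_mod_position_out_of_range(self):
        with pytest.raises(ValueError, match="position"):
            fragment_ions(Peptide("AG"), site_mods={3: "Hex"})


def _gaussian_run(mzs, amps, apices, width=0.2, cadence=0.05, span=(8.0, 16.0)):
    times = np.arange(*span, cadence)
    scans = []
    for t in times:
        intens = [a * np.exp(-((t - ap) ** 2) / (2 * width**2)) for a, ap in zip(amps, apices)]
        scans.append(Scan(float(t), np.array(mzs), np.array(intens)))
    return SpectrumRun(tuple(scans))


class TestEic:
    def test_single_species_apex_recovered_within_one_scan(self):
        run = _gaussian_run([800.4], [1e6], [12.0])
        eic = extract_eic(run, 800.4, 0.3)
        assert len(eic.rt) == len(run)
        assert abs(eic.apex_rt - 12.0) <= 0.05

    def test_no_nearby_peaks_gives_all_zero_trace(self):
        run = _gaussian_run([800.4], [1e6], [12.0])
        eic = extract_eic(run, 900.0, 0.3)
        assert np.all(eic.intensity == 0)

    def test_no_crosstalk_between_species_10_da_apart(self):
        run = _gaussian_run([800.0, 810.0], [1e6, 5e5], [11.0, 13.0])
        only_first = _gaussian_run([800.0], [1e6], [11.0])
        a = extract_eic(run, 800.0, 0.3).area()
        b = extract_eic(only_first, 800.0, 0.3).area()
        assert a == pytest.approx(b, rel=0.01)

    def test_empty_run_gives_empty_chromatogram(self):
        eic = extract_eic(SpectrumRun(()), 500.0, 0.3)
        assert len(eic.rt) == 0
        assert eic.apex_intensity == 0.0

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            extract_eic(SpectrumRun(()), 500.0, 0.0)

    def test_eic_never_exceeds_total_ion_current(self, rng):
        run, _ = simulate_ms1_run(
            enumerate_glycoforms(Peptide("WSDWSSWSPC", n_consensus_trp=3)),
            [1.0, 0.6, 0.3, 0.1],
            [10.0, 11.0, 12.0, 13.0],
            seed=7,
        )
        tic = run.total_ion_current()
        for target in (500.0, 800.0, 1100.0):
            assert np.all(extract_eic(run, target, 0.3).intensity <= tic + 1e-9)


class TestQuantifyGlycoforms:
    species = enumerate_glycoforms(Peptide("WSDWSSWSPC", n_consensus_trp=3))

    def test_single_detectable_species_reports_one(self):
        run, _ = simulate_ms1_run(self.species[:1], [1.0], [10.0], seed=1)
        prof = quantify_glycoforms(run, self.species[:1])
        assert prof.relative == {"Hex0": 1.0}
        assert prof.max_label == "Hex0"

    def test_planted_ratios_recovered_within_5pct(self):
        run, _ = simulate_ms1_run(
            self.species[:3], [1.0, 0.5, 0.1], [10.0, 11.5, 13.0], snr=100, seed=3
        )
        prof = quantify_glycoforms(run, self.species[:3])
        assert prof.relative["Hex0"] == 1.0
        assert prof.relative["Hex1"] == pytest.approx(0.5, rel=0.05)
        assert prof.relative["Hex2"] == pytest.approx(0.1, rel=0.05)

    def test_absent_species_reports_zero(self):
        run, _ = simulate_ms1_run(
            self.species[:2], [1.0, 0.5], [10.0, 11.5], snr=1e9, seed=4, n_noise_peaks=0
        )
        prof = quantify_glycoforms(run, self.species)
        assert prof.relative["Hex3"] == 0.0

    def test_all_zero_traces_warn(self):
        run = _gaussian_run([500.0], [0.0], [10.0])
        with pytest.warns(UserWarning, match="zero"):
            prof = quantify_glycoforms(run, self.species[:2])
        assert prof.all_zero
        assert set(prof.relative.values()) == {0.0}

    def test_species_must_share_a_peptide(self):
        other = enumerate_glycoforms(Peptide("AGSTK"))
        run = _gaussian_run([500.0], [1.0], [10.0])
        with pytest.raises(ValueError, match="same peptide"):
            quantify_glycoforms(run, [self.species[0], other[0]])

    def test_area_mode_and_smoothing_run(self):
        run, _ = simulate_ms1_run(self.species[:2], [1.0, 0.5], [10.0, 11.5], seed=5)
        prof = quantify_glycoforms(run, self.species[:2], use_area=True, smooth=True)
        assert prof.relative["Hex1"] == pytest.approx(0.5, rel=0.06)
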