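"""Peak picking, adduct assignment and quantification against generator truth."""

from dataclasses import replace

import numpy as np
import pytest

from lipidex import (
    LipidSpecies,
    MassSpectrum,
    ProteinSpecies,
    assign_adducts,
    average_charge,
    pick_peaks,
    quantify_bound_fractions,
    simulate_spectrum,
)
from lipidex.species import PROTON_MASS, mz_of
from lipidex.spectra import DETECTION_THRESHOLD, Peak, PeakList, fraction_bound


def _gaussian(mz, centre, fwhm, amp=1.0):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-0.5 * ((mz - centre) / sigma) ** 2)


def _peaklist(entries):
    return PeakList(tuple(Peak(mz, inten, inten) for mz, inten in entries))


PROTEIN = ProteinSpecies("P", 33_000.0, (10, 13))
POPE = LipidSpecies("POPE", "PE", formula="C39H76NO8P")


class TestPickPeaks:
    def test_single_noiseless_gaussian(self):
        mz = np.arange(2990.0, 3010.0, 0.1)
        s = MassSpectrum(mz, _gaussian(mz, 3000.0, 2.0))
        peaks = pick_peaks(s)
        assert len(peaks) == 1
        assert abs(peaks.peaks[0].mz - 3000.0) <= 0.1

    def test_two_separated_gaussians(self):
        mz = np.arange(2990.0, 3030.0, 0.1)
        y = _gaussian(mz, 3000.0, 2.0) + _gaussian(mz, 3020.0, 2.0, amp=0.5)
        peaks = pick_peaks(MassSpectrum(mz, y), min_spacing=5.0)
        assert len(peaks) == 2

    def test_flat_spectrum_yields_empty_list(self):
        mz = np.arange(1000.0, 1010.0, 0.1)
        assert len(pick_peaks(MassSpectrum(mz, np.ones_like(mz)))) == 0

    def test_close_peaks_suppressed_keeping_taller(self):
        mz = np.arange(2990.0, 3010.0, 0.1)
        y = _gaussian(mz, 3000.0, 1.0) + _gaussian(mz, 3000.8, 1.0, amp=0.4)
        peaks = pick_peaks(MassSpectrum(mz, y), min_spacing=2.0)
        assert len(peaks) == 1

    def test_psh_fixture_has_full_adduct_ladder_per_charge(self, psh_fixture):
        s = simulate_spectrum(psh_fixture.spec)
        peaks = pick_peaks(s)
        result = assign_adducts(
            peaks,
            psh_fixture.spec.protein,
            [lip for lip, _ in psh_fixture.spec.lipids],
        )
        z_main = [a for a in result.assignments if a.charge == 11]
        # apo + 3 single-class adducts (and composites) at the principal charge
        assert len(z_main) >= 4
        assert {a.total_adducts for a in z_main} >= {0, 1, 2, 3}


class TestAssignAdducts:
    def test_apo_peak_assigned_zero_adducts(self):
        peak_mz = mz_of(33_000.0, 11)
        result = assign_adducts(_peaklist([(peak_mz, 1.0)]), PROTEIN, [POPE])
        (a,) = result.assignments
        assert a.charge == 11
        assert a.adduct_counts == {}
        assert a.mass_error == pytest.approx(0.0, abs=1e-6)

    def test_single_pope_adduct(self):
        peak_mz = mz_of(33_000.0 + POPE.mass, 11)
        result = assign_adducts(_peaklist([(peak_mz, 1.0)]), PROTEIN, [POPE])
        (a,) = result.assignments
        assert a.adduct_counts == {"POPE": 1}

    def test_far_off_peak_reported_unassigned(self):
        result = assign_adducts(_peaklist([(mz_of(33_400.0, 11), 1.0)]), PROTEIN, [POPE])
        assert not result.assignments
        assert len(result.unassigned) == 1

    def test_cdl_vs_two_pe_collision_flagged_and_tiebroken(self):
        # construct the near-collision explicitly: a double-PE mass within
        # tolerance of a CDL-like species (2 x 718.0 = 1436.0 vs 1436.5)
        pe = LipidSpecies("PE", "PE", average_mass=718.0)
        cdl = LipidSpecies("CDL", "CDL", average_mass=1436.5)
        peak_mz = mz_of(33_000.0 + 1436.2, 11)
        result = assign_adducts(
            _peaklist([(peak_mz, 1.0)]), PROTEIN, [pe, cdl], max_adducts=2
        )
        (a,) = result.assignments
        assert a.ambiguous
        assert a.adduct_counts == {"CDL": 1}  # fewer total adducts wins
        assert any(alt == {"PE": 2} for alt in a.alternatives)

    def test_candidate_order_invariance_without_ties(self, psh_fixture):
        s = simulate_spectrum(replace(psh_fixture.spec, noise_sd=0.0))
        peaks = pick_peaks(s)
        cands = [lip for lip, _ in psh_fixture.spec.lipids]
        fwd = assign_adducts(peaks, psh_fixture.spec.protein, cands)
        rev = assign_adducts(peaks, psh_fixture.spec.protein, cands[::-1])
        for a, b in zip(fwd.assignments, rev.assignments):
            assert a.adduct_counts == b.adduct_counts
            assert a.charge == b.charge


class TestQuantify:
    def test_only_apo(self):
        result = assign_adducts(_peaklist([(mz_of(33_000.0, 11), 1.0)]), PROTEIN, [POPE])
        fr = quantify_bound_fractions(result.assignments)
        assert fr["any"] == {0: 1.0}

    def test_equal_apo_and_single_adduct(self):
        peaks = _peaklist(
            [(mz_of(33_000.0, 11), 1.0), (mz_of(33_000.0 + POPE.mass, 11), 1.0)]
        )
        fr = quantify_bound_fractions(assign_adducts(peaks, PROTEIN, [POPE]).assignments)
        assert fr["POPE"][0] == pytest.approx(0.5)
        assert fr["POPE"][1] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, murj_fixture):
        s = simulate_spectrum(murj_fixture.spec)
        result = assign_adducts(
            pick_peaks(s), murj_fixture.spec.protein,
            [lip for lip, _ in murj_fixture.spec.lipids],
        )
        fr = quantify_bound_fractions(result.assignments)
        for counts in fr.values():
            assert sum(counts.values()) == pytest.approx(1.0, abs=1e-6)

    def test_all_adduct_states_detectable_at_baseline(self, psh_fixture):
        s = simulate_spectrum(psh_fixture.spec)  # baseline detergent
        result = assign_adducts(
            pick_peaks(s), psh_fixture.spec.protein,
            [lip for lip, _ in psh_fixture.spec.lipids],
        )
        fr = quantify_bound_fractions(result.assignments)["any"]
        for count in range(4):
            assert fr.get(count, 0.0) >= DETECTION_THRESHOLD

    def test_high_detergent_removes_all_bound_lipids(self, psh_fixture):
        s = simulate_spectrum(psh_fixture.spec, detergent_conc=0.5)
        result = assign_adducts(
            pick_peaks(s), psh_fixture.spec.protein,
            [lip for lip, _ in psh_fixture.spec.lipids],
        )
        fr = quantify_bound_fractions(result.assignments)["any"]
        assert fraction_bound(fr, 1) < DETECTION_THRESHOLD

    def test_invariant_to_uniform_rescaling(self, psh_fixture):
        s = simulate_spectrum(psh_fixture.spec)
        cands = [lip for lip, _ in psh_fixture.spec.lipids]
        fr1 = quantify_bound_fractions(
            assign_adducts(pick_peaks(s), psh_fixture.spec.protein, cands).assignments
        )
        fr2 = quantify_bound_fractions(
            assign_adducts(
                pick_peaks(s.scaled(37.0)), psh_fixture.spec.protein, cands
            ).assignments
        )
        for key in fr1:
            for c in fr1[key]:
                assert fr1[key][c] == pytest.approx(fr2[key].get(c, 0.0), abs=1e-9)

    @pytest.mark.parametrize("fixture_name", ["psh_titration", "murj_lipid2"])
    def test_round_trip_recovers_count_distribution(self, fixture_name, request):
        fx = request.getfixturevalue(
            {"psh_titration": "psh_fixture", "murj_lipid2": "murj_fixture"}[fixture_name]
        )
        spec = replace(fx.spec, noise_sd=0.0)
        s = simulate_spectrum(spec)
        result = assign_adducts(
            pick_peaks(s), spec.protein, [lip for lip, _ in spec.lipids]
        )
        obs = quantify_bound_fractions(result.assignments)["any"]
        true_any = np.array([1.0])
        for dist in spec.count_distributions().values():
            true_any = np.convolve(true_any, dist)
        tv = 0.5 * sum(
            abs(obs.get(c, 0.0) - true_any[c]) for c in range(len(true_any))
        )
        assert tv < 0.05


class TestAverageCharge:
    def test_single_charge_state(self):
        result = assign_adducts(_peaklist([(mz_of(33_000.0, 12), 1.0)]),
                                ProteinSpecies("P", 33_000.0, (12, 12)), [POPE])
        assert average_charge(result.assignments) == 12.0

    def test_symmetric_weights(self):
        protein = ProteinSpecies("P", 33_000.0, (13, 15))
        peaks = _peaklist(sorted(
            [(mz_of(33_000.0, 15), 0.2), (mz_of(33_000.0, 14), 0.6),
             (mz_of(33_000.0, 13), 0.2)]
        ))
        result = assign_adducts(peaks, protein, [POPE])
        assert average_charge(result.assignments) == pytest.approx(14.0)

    def test_detergent_shifts_envelope_to_higher_charge(self, murj_fixture):
        from lipidex.synthetic import blend_envelopes

        spec = murj_fixture.spec
        cands = [lip for lip, _ in spec.lipids]
        base = simulate_spectrum(spec)
        shifted = simulate_spectrum(
            spec,
            charge_envelope=blend_envelopes(
                spec.charge_envelope, murj_fixture.charge_envelope_high, 1.0
            ),
        )
        z_base = average_charge(
            assign_adducts(pick_peaks(base), spec.protein, cands).assignments
        )
        z_shifted = average_charge(
            assign_adducts(pick_peaks(shifted), spec.protein, cands).assignments
        )
        assert z_shifted > z_base
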