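"""Forward-simulator correctness: EX2 closed form, observation model,
ligand coupling, envelopes, titrations, proteolysis decay."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxstab import (
    DEFAULT_LABELING_TIMES,
    LigandCoupling,
    ProteinEntry,
    ProteolysisModel,
    SyntheticSystem,
    ValidationError,
    compute_intrinsic_rates,
    ligand_occupancy,
    simulate_isotope_envelope,
    simulate_peptide_uptake,
    simulate_proteolysis_timecourse,
    simulate_residue_exchange,
    simulate_titration,
)
from hdxstab.simulate import calibrate_plimstex_system, mix_envelopes


class TestIntrinsicRates:
    def test_override_with_nterm_rule(self):
        assert compute_intrinsic_rates("ASA", override=1.0).tolist() == [0.0, 1.0, 1.0]

    def test_proline_rule(self):
        assert compute_intrinsic_rates("APA", override=1.0).tolist() == [0.0, 0.0, 1.0]

    def test_base_catalyzed_pd_dependence(self):
        """In the base-catalysed regime near neutral pD, one pD unit is a
        10-fold rate change (rate tracks [OD-])."""
        r84 = compute_intrinsic_rates("AAA", pD=8.4)[2]
        r74 = compute_intrinsic_rates("AAA", pD=7.4)[2]
        assert r84 / r74 == pytest.approx(10.0, rel=0.05)

    def test_rates_increase_with_temperature(self):
        cold = compute_intrinsic_rates("AAKA", temperature=278.0)
        warm = compute_intrinsic_rates("AAKA", temperature=310.0)
        assert np.all(warm[1:] > cold[1:])

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValidationError):
            compute_intrinsic_rates("AXZ")


class TestResidueExchange:
    def test_closed_form_value(self):
        """k=0.1/s, P=10, f_D=0.9, t=100 s gives D = 0.9 (1 - e^-1)."""
        seq = "AAAA"
        system = SyntheticSystem(
            protein=ProteinEntry(name="t", sequence=seq),
            log_protection=np.full(4, math.log(10.0)),
            intrinsic_rates=compute_intrinsic_rates(seq, override=0.1),
            seed=0,
        )
        curves = simulate_residue_exchange(system, [100.0]).expectation()
        assert curves[0, 1] == pytest.approx(0.9 * (1 - math.exp(-1)), rel=1e-12)

    def test_infinite_protection_never_exchanges(self, toy_sequence):
        system = SyntheticSystem(
            protein=ProteinEntry(name="t", sequence=toy_sequence),
            log_protection=np.full(len(toy_sequence), 700.0),  # P ~ e^700
            intrinsic_rates=compute_intrinsic_rates(toy_sequence, override=1.0),
            seed=0,
        )
        curves = simulate_residue_exchange(system, DEFAULT_LABELING_TIMES).expectation()
        assert np.allclose(curves, 0.0)

    def test_saturation_at_label_fraction(self, toy_system):
        curves = simulate_residue_exchange(toy_system, [1e12]).expectation()
        exchanging = toy_system.intrinsic_rates > 0
        assert curves[0, exchanging] == pytest.approx(0.9, abs=1e-9)
        assert np.all(curves[0, ~exchanging] == 0.0)

    @settings(max_examples=25, derandomize=True)
    @given(theta=st.floats(0.0, 1.0))
    def test_monotone_in_time_and_occupancy(self, theta):
        seq = "MKTAYIAKQRQISPVKSHFSRQLEERLGLIEVQA"
        rng = np.random.default_rng(42)
        system = SyntheticSystem(
            protein=ProteinEntry(name="toy", sequence=seq),
            log_protection=rng.uniform(0.0, 5.0, len(seq)),
            intrinsic_rates=compute_intrinsic_rates(seq, override=0.05),
            seed=7,
        )
        coupling = LigandCoupling(
            midpoint=1.0, delta_log_protection=np.full(len(seq), 2.0)
        )
        curves = simulate_residue_exchange(
            system, DEFAULT_LABELING_TIMES, theta, coupling
        ).expectation()
        assert np.all(np.diff(curves, axis=0) >= -1e-15)  # non-decreasing in t
        free = simulate_residue_exchange(system, DEFAULT_LABELING_TIMES).expectation()
        assert np.all(curves <= free + 1e-15)  # protection only reduces uptake

    def test_fast_mode_converges_to_slow_mixture_as_coupling_vanishes(self, toy_system):
        """The two limits agree only as the bound-state protection increment
        goes to zero; the gap must shrink with delta ln P."""
        times = DEFAULT_LABELING_TIMES
        n = len(toy_system.protein.sequence)
        gaps = []
        for delta in (2.0, 0.5, 0.1, 0.01):
            fast = simulate_residue_exchange(
                toy_system, times, 0.5,
                LigandCoupling(1.0, np.full(n, delta), mode="fast_exchange"),
            ).expectation()
            slow = simulate_residue_exchange(
                toy_system, times, 0.5,
                LigandCoupling(1.0, np.full(n, delta), mode="slow_two_population"),
            ).expectation()
            gaps.append(float(np.max(np.abs(fast - slow))))
        assert gaps[0] > gaps[-1]
        assert all(a >= b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-4


class TestPeptideObservation:
    def test_hand_computed_uptake(self):
        """10-residue proline-free peptide, all D_i = 0.5, retention 0.85:
        observed uptake = 8 * 0.5 * 0.85 * 1.00628 Da."""
        seq = "NWVFGGGTKL"
        # choose protection so D(t) = 0.5 exactly at t: k t = ln(9/4) with f_D=0.9
        t = math.log(9.0 / 4.0)
        system = SyntheticSystem(
            protein=ProteinEntry(name="t", sequence=seq),
            log_protection=np.zeros(len(seq)),
            intrinsic_rates=compute_intrinsic_rates(seq, override=1.0),
            back_exchange_retention=0.85,
            deuteron_mass=1.00628,
            noise_sd=0.0,
            seed=0,
        )
        table = simulate_peptide_uptake(system, [(1, 10)], times=[t], noise_sd=0.0)
        rec = table.records[0]
        assert rec.mt - rec.m0 == pytest.approx(8 * 0.5 * 0.85 * 1.00628, rel=1e-9)

    def test_time_zero_is_undeuterated(self, toy_system):
        table = simulate_peptide_uptake(toy_system, [(2, 12)], times=[0.0], noise_sd=0.0)
        assert table.records[0].mt == table.records[0].m0

    def test_same_seed_reproduces_bitwise(self, toy_system):
        t1 = simulate_peptide_uptake(toy_system, [(2, 12)], replicates=2)
        t2 = simulate_peptide_uptake(toy_system, [(2, 12)], replicates=2)
        assert [r.mt for r in t1.records] == [r.mt for r in t2.records]

    def test_too_short_peptide_rejected(self, toy_system):
        with pytest.raises(ValidationError):
            simulate_peptide_uptake(toy_system, [(2, 3)])


class TestEnvelopes:
    def test_all_zero_probabilities_single_peak(self):
        env = simulate_isotope_envelope(5, [0.0] * 5, 400.0, 2)
        peaks = [(mz, i) for mz, i in env if i > 0]
        assert peaks == [(400.0, 1.0)]

    def test_mixture_centroid_is_weighted_mean(self):
        from hdxstab import centroid_mass

        a = simulate_isotope_envelope(10, [0.1] * 10, 500.0, 1)
        b = simulate_isotope_envelope(10, [0.6] * 10, 500.0, 1)
        mixed = mix_envelopes([a, b], [0.5, 0.5])
        expected = 0.5 * centroid_mass(a, 1) + 0.5 * centroid_mass(b, 1)
        assert centroid_mass(mixed, 1) == pytest.approx(expected, rel=1e-12)

    def test_bad_charge_rejected(self):
        with pytest.raises(ValidationError):
            simulate_isotope_envelope(3, [0.5] * 3, 500.0, 0)


class TestTitration:
    def _conditions(self):
        return calibrate_plimstex_system("NWVFGGGTKL", 5.0, -2.0, 1.5, l_max=25.0)

    def test_zero_ligand_is_baseline(self):
        system, coupling, interval = self._conditions()
        series = simulate_titration(
            system, coupling, interval, [0.0, 1.0, 5.0, 25.0],
            replicates=1, noise_sd=0.0,
        )
        assert series.mean_uptakes[0] == pytest.approx(5.0, rel=1e-9)

    def test_midpoint_is_halfway(self):
        system, coupling, interval = self._conditions()
        series = simulate_titration(
            system, coupling, interval, [0.0, 1.5], replicates=1, noise_sd=0.0
        )
        base, mid = series.mean_uptakes
        delta_asym = -2.0 / (25.0 / 26.5)
        assert mid - base == pytest.approx(delta_asym / 2.0, rel=1e-9)

    def test_saturation_plateau(self):
        system, coupling, interval = self._conditions()
        series = simulate_titration(
            system, coupling, interval, [1.5e4], replicates=1, noise_sd=0.0
        )
        delta_asym = -2.0 / (25.0 / 26.5)
        plateau = 5.0 + delta_asym
        assert series.mean_uptakes[0] == pytest.approx(plateau, rel=1e-3)

    def test_empty_concentrations_rejected(self):
        system, coupling, interval = self._conditions()
        from hdxstab import UsageError

        with pytest.raises(UsageError):
            simulate_titration(system, coupling, interval, [])

    def test_depletion_occupancy_below_hyperbolic(self):
        n = 10
        hyp = LigandCoupling(1.0, np.zeros(n), occupancy_model="hyperbolic")
        dep = LigandCoupling(
            1.0, np.zeros(n), occupancy_model="quadratic_depletion", protein_total=0.25
        )
        L = 0.5
        assert ligand_occupancy(L, dep) < ligand_occupancy(L, hyp)
        # and the two converge as protein -> 0
        dilute = LigandCoupling(
            1.0, np.zeros(n), occupancy_model="quadratic_depletion", protein_total=1e-9
        )
        assert ligand_occupancy(L, dilute) == pytest.approx(
            ligand_occupancy(L, hyp), rel=1e-6
        )


class TestProteolysisSimulation:
    def test_zero_rate_stays_intact(self):
        model = ProteolysisModel(rate=0.0, rate_bound=0.0, noise_sd=0.0)
        tc = simulate_proteolysis_timecourse(model)
        assert all(f == 1.0 for f in tc.fractions)

    def test_half_life_arithmetic(self):
        model = ProteolysisModel(
            rate=math.log(2.0), rate_bound=0.0, noise_sd=0.0, timepoints=(0.0, 1.0)
        )
        tc = simulate_proteolysis_timecourse(model)
        assert tc.fractions[1] == pytest.approx(0.5, rel=1e-12)

    def test_seeded_noise_reproducible(self):
        model = ProteolysisModel(rate=0.3, rate_bound=0.05, noise_sd=0.05)
        a = simulate_proteolysis_timecourse(model, seed=11)
        b = simulate_proteolysis_timecourse(model, seed=11)
        assert a.fractions == b.fractions
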