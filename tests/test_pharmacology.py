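"""Closed-form and oracle tests for the synapse and receptor-competition layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from neuroqsp.pharmacology import (
    DrugProfile,
    SynapseParams,
    functional_concentration,
    neurotransmitter_trace,
    occupancy_to_concentration,
    receptor_activation,
    receptor_occupancy,
    simulate_pet_displacement,
    steady_state_level,
)

LN2 = math.log(2.0)


def make_synapse(rate=5.0, quantum=100.0, half_life=100.0, baseline=0.0):
    return SynapseParams("dopamine", rate, quantum, half_life, baseline)


class TestSteadyState:
    def test_no_release_gives_baseline(self):
        assert steady_state_level(make_synapse(rate=0.0)) == 0.0
        assert steady_state_level(make_synapse(rate=0.0, baseline=3.0)) == 3.0

    def test_linear_in_half_life(self):
        lo = steady_state_level(make_synapse(half_life=80.0))
        hi = steady_state_level(make_synapse(half_life=160.0))
        assert hi == pytest.approx(2.0 * lo)

    def test_comt_half_life_ratio(self):
        """160 ms vs 100 ms clearance at equal release -> 1.6x basal tone."""
        mm = steady_state_level(make_synapse(half_life=160.0))
        vv = steady_state_level(make_synapse(half_life=100.0))
        assert mm / vv == pytest.approx(1.6)

    def test_invalid_half_life(self):
        with pytest.raises(ValueError):
            make_synapse(half_life=0.0)


class TestTrace:
    def test_single_release_half_life(self):
        syn = make_synapse(rate=0.0, quantum=80.0, half_life=100.0)
        dt = 0.001
        trace = neurotransmitter_trace(syn, [0.2], duration=1.0, dt=dt)
        i_release = int(round(0.2 / dt))
        i_half = i_release + int(round(0.1 / dt))
        assert trace[i_release] == pytest.approx(80.0)
        assert trace[i_half] == pytest.approx(40.0, rel=1e-9)

    def test_empty_firing_monotone_decay(self):
        syn = make_synapse(rate=0.0, half_life=50.0)
        trace = neurotransmitter_trace(syn, [], duration=0.5, dt=0.001, initial=10.0)
        assert np.all(np.diff(trace) < 0)
        assert trace[-1] < 0.01

    def test_periodic_firing_matches_closed_form(self):
        """Long-run mean of the pulsatile trace equals the steady-state closed form."""
        syn = make_synapse(rate=5.0, quantum=30.0, half_life=100.0)
        duration = 40.0  # 400 half-lives
        times = np.arange(0.0, duration, 0.2)
        trace = neurotransmitter_trace(syn, times, duration=duration, dt=0.002)
        burn = len(trace) // 10
        assert np.mean(trace[burn:]) == pytest.approx(steady_state_level(syn), rel=0.02)

    def test_under_resolved_dt_rejected(self):
        syn = make_synapse(half_life=10.0)
        with pytest.raises(ValueError, match="under-resolves"):
            neurotransmitter_trace(syn, [], duration=1.0, dt=0.005)


class TestOccupancy:
    def test_half_maximal_at_ki(self):
        occ = receptor_occupancy(ligand_conc=50.0, drug_conc=0.0, ki_ligand=50.0, ki_drug=1.0)
        assert occ.occ_ligand == pytest.approx(0.5)
        occ = receptor_occupancy(ligand_conc=0.0, drug_conc=2.0, ki_ligand=50.0, ki_drug=2.0)
        assert occ.occ_drug == pytest.approx(0.5)

    def test_equal_thirds(self):
        occ = receptor_occupancy(10.0, 5.0, 10.0, 5.0)
        for f in (occ.occ_ligand, occ.occ_drug, occ.occ_free):
            assert f == pytest.approx(1.0 / 3.0)

    @given(
        st.floats(0.0, 1e4),
        st.floats(0.0, 1e4),
        st.floats(1e-3, 1e4),
        st.floats(1e-3, 1e4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_fractions_sum_to_one_and_bounded(self, l, d, kl, kd):
        occ = receptor_occupancy(l, d, kl, kd)
        assert occ.occ_ligand + occ.occ_drug + occ.occ_free == pytest.approx(1.0, abs=1e-9)
        for f in (occ.occ_ligand, occ.occ_drug, occ.occ_free):
            assert 0.0 <= f <= 1.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            receptor_occupancy(-1.0, 0.0, 1.0, 1.0)

    def test_equilibrium_matches_kinetic_ode_oracle(self):
        """Equilibrium closed form = fixed point of the two-ligand rate system."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            l, d = rng.uniform(1.0, 500.0, 2)
            kl, kd = rng.uniform(5.0, 500.0, 2)
            kon_l, kon_d = rng.uniform(0.001, 0.01, 2)  # 1/(nM s)
            koff_l, koff_d = kon_l * kl, kon_d * kd

            def rhs(_t, y):
                bl, bd = y
                free = 1.0 - bl - bd
                return [kon_l * l * free - koff_l * bl, kon_d * d * free - koff_d * bd]

            sol = solve_ivp(rhs, (0.0, 5e4), [0.0, 0.0], rtol=1e-11, atol=1e-13)
            occ = receptor_occupancy(l, d, kl, kd)
            assert sol.y[0, -1] == pytest.approx(occ.occ_ligand, abs=1e-6)
            assert sol.y[1, -1] == pytest.approx(occ.occ_drug, abs=1e-6)


class TestActivation:
    def test_neutral_antagonist_silences(self):
        occ = receptor_occupancy(0.0, 1e9, 1.0, 1.0)
        assert receptor_activation(occ, efficacy_drug=0.0) == pytest.approx(0.0, abs=1e-6)

    def test_partial_agonist_level(self):
        occ = receptor_occupancy(0.0, 1e12, 1.0, 1.0)
        assert receptor_activation(occ, 0.3) == pytest.approx(0.3, rel=1e-6)

    def test_mixed_occupancy_with_expression_scale(self):
        from neuroqsp.pharmacology import OccupancySolution

        occ = OccupancySolution(occ_ligand=0.4, occ_drug=0.2, occ_free=0.4)
        assert receptor_activation(occ, 0.5, 1.3) == pytest.approx(0.65)


class TestPetDisplacement:
    def test_identical_conditions_zero_change(self):
        syn = make_synapse()
        assert simulate_pet_displacement(1.0, syn, ligand_ki=100.0) == pytest.approx(0.0)

    def test_longer_half_life_displaces_tracer(self):
        """Raising basal tone (e.g. COMT MM vs VV) lowers tracer binding."""
        ref = make_synapse(half_life=100.0)
        test = make_synapse(half_life=160.0)
        change = simulate_pet_displacement(
            1.0, test, ligand_ki=100.0, reference_synapse=ref
        )
        assert change < 0.0

    def test_drug_at_ki_halves_binding(self):
        syn = make_synapse(rate=0.0)  # no ligand competition
        change = simulate_pet_displacement(
            1.0, syn, ligand_ki=100.0, drug_conc=5.0, drug_ki=5.0
        )
        assert change == pytest.approx(-0.5)

    def test_antitone_in_drug_concentration(self):
        syn = make_synapse()
        changes = [
            simulate_pet_displacement(1.0, syn, 100.0, drug_conc=c, drug_ki=10.0)
            for c in (0.0, 5.0, 20.0, 100.0)
        ]
        assert all(a > b for a, b in zip(changes, changes[1:]))


def make_drug(anchors, ki_d2=2.0, dose=10.0):
    return DrugProfile(
        name="testdrug",
        standard_dose=dose,
        affinities={"D2": ki_d2},
        occupancy_anchors=anchors,
    )


class TestFunctionalConcentration:
    def test_anchor_reproduction(self):
        syn = make_synapse()
        drug = make_drug([(2.0, 0.5), (10.0, 0.8), (20.0, 0.9)])
        ligand = steady_state_level(syn)
        for dose, occ_target in drug.occupancy_anchors:
            conc = functional_concentration(drug, dose, syn, ligand_ki=160.0)
            occ = receptor_occupancy(ligand, conc, 160.0, drug.ki("D2"))
            assert occ.occ_drug == pytest.approx(occ_target, abs=1e-6)

    def test_strictly_increasing_in_dose(self):
        syn = make_synapse()
        drug = make_drug([(2.0, 0.5), (10.0, 0.8), (20.0, 0.9)])
        doses = [0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 20.0, 35.0]
        concs = [functional_concentration(drug, d, syn, 160.0) for d in doses]
        assert all(a < b for a, b in zip(concs, concs[1:]))

    def test_single_anchor_no_competition_returns_ki(self):
        syn = make_synapse(rate=0.0)  # zero basal ligand
        drug = make_drug([(10.0, 0.5)])
        conc = functional_concentration(drug, 10.0, syn, 160.0)
        assert conc == pytest.approx(drug.ki("D2"))

    def test_infeasible_anchor_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            occupancy_to_concentration(1.0, 2.0, 0.0, 160.0)
        with pytest.raises(ValueError):
            make_drug([(2.0, 0.5), (10.0, 0.4)])  # occupancy decreasing


class TestDrugProfileInvariants:
    def test_invalid_ki(self):
        with pytest.raises(ValueError):
            DrugProfile("x", 10.0, {"D2": -1.0})

    def test_invalid_efficacy(self):
        with pytest.raises(ValueError):
            DrugProfile("x", 10.0, {"D2": 1.0}, {"D2": 1.5})

    def test_anchor_dose_ordering(self):
        with pytest.raises(ValueError):
            DrugProfile("x", 10.0, {"D2": 1.0}, occupancy_anchors=[(5.0, 0.5), (5.0, 0.6)])

    def test_packaged_profiles_valid(self, drug_profiles):
        assert set(drug_profiles) == {
            "aripiprazole", "clozapine", "haloperidol", "olanzapine",
            "paliperidone", "quetiapine", "risperidone",
        }
        standard = {"aripiprazole": 20, "clozapine": 200, "olanzapine": 15,
                    "risperidone": 4, "haloperidol": 10, "quetiapine": 400,
                    "paliperidone": 9}
        for name, dose in standard.items():
            assert drug_profiles[name].standard_dose == dose
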