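"""Strand-displacement expansion: templates, rates, censuses, leak injection."""

import numpy as np
import pytest

import dsdctrl as d
from dsdctrl.crn import Reaction
from dsdctrl.dsd import (
    RateScheme,
    UnsupportedReactionError,
    census,
    expand_annihilation,
    expand_catalysis,
    expand_crn,
    expand_degradation,
    inject_dsd_leak,
)


@pytest.fixture()
def cat_scheme():
    return RateScheme(complementarity={"ki": 5e-2}, clamp_auxiliaries=True)


class TestCatalysisTemplate:
    def test_cascade_structure(self, cat_scheme):
        rxn = Reaction({"R": 1}, {"R": 1, "V": 1}, 5e-2, "catalysis", "ki")
        net = expand_catalysis(rxn, cat_scheme)
        # 5 reversible displacement pairs + 1 irreversible cleanup
        assert len(net.crn.reactions) == 11
        c = census(net)
        assert c.double_stranded_supplied == 2  # one Join + one Fork
        assert c.single_stranded_supplied == 3  # recycled strand not counted

    def test_join_capture_rate_is_degree_times_kt(self, cat_scheme):
        rxn = Reaction({"R": 1}, {"R": 1, "V": 1}, 5e-2, "catalysis", "ki")
        net = expand_catalysis(rxn, cat_scheme)
        first = net.crn.reactions[0]
        assert set(first.reactants) == {"R", "JoinVR"}
        assert first.rate_constant == pytest.approx(5e-2 * 1e-4)  # c*kt = 5e-6

    def test_release_rate_matches_unimolecular_approximation(self, cat_scheme):
        """With auxiliaries clamped at Cmax the cascade's product release rate
        constant approaches ki = Cmax*c*kt within 10%."""
        rxn = Reaction({"R": 1}, {"R": 1, "V": 1}, 5e-2, "catalysis", "ki")
        net = expand_catalysis(rxn, cat_scheme)
        net.crn.get_species("R").initial_concentration = 10.0
        traj = d.simulate(net.crn, t_end=200.0, n_points=201, clamp=net.clamped_names())
        t = traj.times
        i0, i1 = 50, 150
        slope = (traj["V"][i1] - traj["V"][i0]) / (t[i1] - t[i0])
        r_free = float(np.mean(traj["R"][i0 : i1 + 1]))
        k_eff = slope / r_free
        ki = cat_scheme.Cmax * 5e-2 * cat_scheme.kt
        assert abs(k_eff - ki) / ki < 0.10

    def test_wrong_shape_rejected(self, cat_scheme):
        with pytest.raises(UnsupportedReactionError):
            expand_catalysis(Reaction({"R": 1}, {}, 1.0, "degradation", "a"), cat_scheme)


class TestDegradationTemplate:
    def test_single_capture(self):
        scheme = RateScheme(complementarity={"a": 2.5e-3})
        net = expand_degradation(Reaction({"Y": 1}, {}, 2.5e-3, "degradation", "a"), scheme)
        assert len(net.crn.reactions) == 1
        assert census(net).double_stranded_supplied == 1
        rxn = net.crn.reactions[0]
        assert rxn.rate_constant == pytest.approx(2.5e-3 * 1e-4)
        # products are inert
        roles = {s.name: s.role for s in net.crn.species}
        assert all(roles[n] == "waste" for n in rxn.products)

    def test_kleak_adds_reverse_reaction(self):
        scheme = RateScheme(complementarity={"a": 2.5e-3}, kleak=1e-9)
        net = expand_degradation(Reaction({"Y": 1}, {}, 2.5e-3, "degradation", "a"), scheme)
        assert len(net.crn.reactions) == 2
        back = net.crn.reactions[1]
        assert back.tag == "leak" and back.rate_constant == 1e-9
        assert set(back.products) == {"JoinY", "Y"}


class TestAnnihilationTemplate:
    def test_cooperative_structure_and_rate(self):
        scheme = RateScheme(complementarity={"eta": 0.25})
        rxn = Reaction({"V": 1, "Vp": 1}, {}, 2.5e-5, "annihilation", "eta")
        net = expand_annihilation(rxn, scheme)
        assert len(net.crn.reactions) == 6
        assert census(net).double_stranded_supplied == 1
        fwd = net.crn.reactions[0]
        assert fwd.rate_constant == pytest.approx(0.25 * 1e-4)  # 2.5e-5

    def test_symmetric_inputs_decay_identically(self):
        scheme = RateScheme(complementarity={"eta": 0.25}, clamp_auxiliaries=True)
        rxn = Reaction({"V": 1, "Vp": 1}, {}, 2.5e-5, "annihilation", "eta")
        net = expand_annihilation(rxn, scheme)
        for name in ("V", "Vp"):
            net.crn.get_species(name).initial_concentration = 8.0
        traj = d.simulate(net.crn, t_end=500.0, n_points=50, clamp=net.clamped_names())
        np.testing.assert_allclose(traj["V"], traj["Vp"], atol=1e-9)
        assert traj["V"][-1] < 8.0


class TestWholeCircuitExpansion:
    def test_integral_census_reproduces_printed_counts(self, integral_scheme):
        p = d.IntegralCircuitParams(include_output_annihilation=False)
        net = expand_crn(d.build_integral_circuit(p), integral_scheme)
        c = census(net)
        assert c.double_stranded_supplied == 15
        assert c.single_stranded_supplied == 20

    def test_state_feedback_census_reproduces_printed_counts(self, statefb_scheme):
        p = d.StateFeedbackParams(include_x_annihilation=False)
        net = expand_crn(d.build_state_feedback_circuit(p), statefb_scheme)
        c = census(net)
        assert c.double_stranded_supplied == 15
        assert c.single_stranded_supplied == 20

    def test_double_strand_count_identity(self, integral_circuit, integral_scheme):
        """#double-stranded = 2*catalysis + degradation + annihilation."""
        net = expand_crn(integral_circuit, integral_scheme)
        from collections import Counter

        tags = Counter(r.tag for r in integral_circuit.crn.reactions)
        expect = 2 * tags["catalysis"] + tags["degradation"] + tags["annihilation"]
        assert census(net).double_stranded_supplied == expect

    def test_empty_crn_gives_zero_counts(self, integral_scheme):
        from dsdctrl.dualrail import DualRailCRN
        from dsdctrl.crn import CRN

        empty = DualRailCRN(crn=CRN(), pairs=[])
        c = census(expand_crn(empty, integral_scheme))
        assert (
            c.double_stranded_supplied
            == c.single_stranded_supplied
            == c.waste_species
            == c.intermediate_species
            == 0
        )

    def test_provenance_maps_every_reaction_once(self, integral_circuit, integral_scheme):
        net = expand_crn(integral_circuit, integral_scheme)
        assert set(net.provenance) == set(range(len(net.crn.reactions)))
        assert set(net.provenance.values()) == set(range(len(integral_circuit.crn.reactions)))

    def test_supplied_species_initialised_at_cmax(self, integral_circuit, integral_scheme):
        net = expand_crn(integral_circuit, integral_scheme)
        for name in net.supplied:
            assert net.crn.get_species(name).initial_concentration == integral_scheme.Cmax


class TestEffectiveRates:
    def test_integral_scheme_products(self, integral_circuit, integral_scheme):
        net = expand_crn(integral_circuit, integral_scheme)
        rates = d.effective_rates(net, integral_circuit)
        assert rates["b"] == pytest.approx(1e-3)
        assert rates["a"] == pytest.approx(2.5e-3)
        assert rates["ki"] == pytest.approx(5e-2)
        assert rates["eta"] == pytest.approx(2.5e-5)  # binding-limited, bimolecular

    def test_state_feedback_scheme_implies_unit_gains(self, statefb_circuit, statefb_scheme):
        net = expand_crn(statefb_circuit, statefb_scheme)
        rates = d.effective_rates(net, statefb_circuit)
        assert rates["q"] == rates["qk1"] == rates["qk2"] == pytest.approx(8e-3)

    def test_full_complementarity_gives_cmax_kt(self):
        scheme = RateScheme(complementarity={"x": 1.0})
        net = expand_degradation(Reaction({"A": 1}, {}, 1.0, "degradation", "x"), scheme)
        from dsdctrl.dualrail import DualRailCRN
        from dsdctrl.crn import CRN, Species

        host = DualRailCRN(
            crn=CRN(
                species=[Species("A")],
                reactions=[Reaction({"A": 1}, {}, 1.0, "degradation", "x")],
            ),
            pairs=[],
        )
        rates = d.effective_rates(net, host)
        assert rates["x"] == pytest.approx(scheme.Cmax * scheme.kt)


class TestLeakInjection:
    def test_zero_rates_leave_network_unchanged(self, integral_circuit):
        out = d.inject_leak(integral_circuit, "Y", 0.0, 0.0)
        assert len(out.crn.reactions) == len(integral_circuit.crn.reactions)
        assert {s.name for s in out.crn.species} == {
            s.name for s in integral_circuit.crn.species
        }

    def test_sources_added_on_both_rails(self, integral_circuit):
        out = d.inject_leak(integral_circuit, "Y", 1e-3, 1e-3, 5.0, 5.0)
        names = {s.name for s in out.crn.species}
        assert {"Z+", "Z-"} <= names
        leaks = [r for r in out.crn.reactions if r.tag == "leak"]
        assert len(leaks) == 2
        assert {next(iter(r.reactants)) for r in leaks} == {"Z+", "Z-"}

    def test_unknown_pair_rejected(self, integral_circuit):
        with pytest.raises(KeyError):
            d.inject_leak(integral_circuit, "Q", 1e-3, 1e-3)

    def test_dsd_level_leak_reverses_captures(self, integral_circuit, integral_scheme):
        net = expand_crn(integral_circuit, integral_scheme)
        leaky = inject_dsd_leak(net, 1e-9)
        extra = len(leaky.crn.reactions) - len(net.crn.reactions)
        n_deg = sum(1 for r in integral_circuit.crn.reactions if r.tag == "degradation")
        assert extra == n_deg
        assert inject_dsd_leak(net, 0.0) is net


class TestLimitBehaviour:
    def test_output_gap_shrinks_in_large_excess_limit(self, integral_params):
        """Scaling Cmax x10 with degrees /10 (fixed effective rates) moves the
        compiled network's output toward the abstract circuit's."""
        circuit = d.build_integral_circuit(
            d.IntegralCircuitParams(include_output_annihilation=False), reference=10.0
        )
        traj = d.simulate(circuit.crn, t_end=4000.0, n_points=101)
        ybar = d.signal(traj, circuit.pair("Y"))
        gaps = []
        for scale in (1.0, 10.0):
            comp = {k: v / scale for k, v in
                    {"a": 2.5e-3, "b": 1e-3, "ki": 5e-2, "eta": 0.25}.items()}
            scheme = RateScheme(Cmax=1e4 * scale, complementarity=comp)
            net = expand_crn(circuit, scheme)
            dtraj = d.simulate(net.crn, t_end=4000.0, n_points=101)
            gaps.append(float(np.max(np.abs((dtraj["Y"] - dtraj["Yp"]) - ybar))))
        assert gaps[1] < gaps[0]

    def test_dsd_response_is_slower_than_abstract(self, integral_scheme):
        """Time to reach 90% of the commanded step is longer for the compiled
        network than for the abstract circuit."""
        circuit = d.build_integral_circuit(
            d.IntegralCircuitParams(include_output_annihilation=False), reference=10.0
        )
        traj = d.simulate(circuit.crn, t_end=2000.0, n_points=201)
        ybar = d.signal(traj, circuit.pair("Y"))
        net = expand_crn(circuit, integral_scheme)
        dtraj = d.simulate(net.crn, t_end=2000.0, n_points=201)
        ydsd = dtraj["Y"] - dtraj["Yp"]

        def t90(t, y):
            hits = np.nonzero(y >= 9.0)[0]
            return t[hits[0]] if hits.size else np.inf

        assert t90(dtraj.times, ydsd) >= t90(traj.times, ybar)
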