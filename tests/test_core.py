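"""Reaction-network core: validation, derivative assembly, conservation."""

import numpy as np
import pytest

from spinesim.core import (Compartment, Network, NetworkValidationError,
                           Reaction, Species, assemble_network,
                           molecules_to_uM)


def toy_ab(k=2.0, a0=1.0, b0=0.0):
    return Network(
        [Compartment("cytosol", 1.0)],
        [Species("A", "cytosol", a0), Species("B", "cytosol", b0)],
        [Reaction(id="ab", stoichiometry={"A": -1, "B": +1},
                  rate_law="mass_action", parameters={"k": k})],
    )


def naive_derivative(net, state, t=0.0, drives=None):
    """Independent loop-over-reactions rate summation (test oracle)."""
    conc = {}
    for i, s in enumerate(net.dynamic_species):
        conc[s.name] = state[i]
    for s in net.clamped_species:
        conc[s.name] = s.initial_concentration
    for s in net.driven_species:
        conc[s.name] = (drives or {}).get(s.name, 0.0)
    dydt = np.zeros(net.n)
    for r in net.reactions:
        if r.rate_law == "mass_action":
            rate = r.parameters["k"]
            for name, st in r.stoichiometry.items():
                if st < 0:
                    rate *= conc[name] ** (-st)
        elif r.rate_law == "michaelis_menten":
            S = conc[r.parameters["substrate"]]
            rate = r.parameters["Vmax"] * S / (r.parameters["Km"] + S)
        elif r.rate_law == "hill":
            S = conc[r.parameters["substrate"]]
            n, K = r.parameters["n"], r.parameters["K"]
            rate = r.parameters["Vmax"] * S ** n / (K ** n + S ** n)
        else:
            import sympy as sp
            local = {k: v for k, v in r.parameters.items()
                     if isinstance(v, (int, float))}
            rate = float(sp.sympify(r.formula, locals={**conc, **local}))
        for m in r.modifiers:
            S = conc[m["species"]]
            n, K = m.get("n", 1), m["K"]
            rate *= S ** n / (K ** n + S ** n)
        vhome = net.compartments[r.compartment].volume
        for name, st in r.stoichiometry.items():
            if name in net.index:
                i = net.index[name]
                vdest = net.compartments[net.dynamic_species[i].compartment].volume
                dydt[i] += st * rate * vhome / vdest
    return dydt


class TestValidation:
    def test_undeclared_species_named_in_error(self):
        with pytest.raises(NetworkValidationError, match="'X'"):
            Network([Compartment("cytosol", 1.0)],
                    [Species("A", "cytosol", 1.0)],
                    [Reaction(id="bad", stoichiometry={"A": -1, "X": 1},
                              rate_law="mass_action", parameters={"k": 1.0})])

    def test_unknown_rate_law(self):
        with pytest.raises(NetworkValidationError, match="rate law"):
            Network([Compartment("cytosol", 1.0)],
                    [Species("A", "cytosol", 1.0)],
                    [Reaction(id="bad", stoichiometry={"A": -1},
                              rate_law="frobnicate", parameters={})])

    def test_missing_parameter(self):
        with pytest.raises(NetworkValidationError, match="'k'"):
            Network([Compartment("cytosol", 1.0)],
                    [Species("A", "cytosol", 1.0)],
                    [Reaction(id="bad", stoichiometry={"A": -1},
                              rate_law="mass_action", parameters={})])

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(NetworkValidationError, match="volume"):
            Compartment("cytosol", -1.0)

    def test_duplicate_species_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate"):
            Network([Compartment("cytosol", 1.0)],
                    [Species("A", "cytosol", 1.0), Species("A", "cytosol", 0.0)],
                    [])

    def test_assemble_from_document(self):
        doc = {
            "compartments": {"cytosol": 1.0},
            "species": [{"name": "A", "compartment": "cytosol",
                         "initial_concentration": 2.0}],
            "reactions": [{"id": "d", "stoichiometry": {"A": -1},
                           "rate_law": "mass_action", "parameters": {"k": 3.0}}],
        }
        net = assemble_network(doc)
        assert net.derivative(np.array([2.0]))[0] == pytest.approx(-6.0)


class TestDerivative:
    def test_mass_action_single_reaction(self):
        net = toy_ab(k=2.0, a0=1.0)
        d = net.derivative(np.array([1.0, 0.0]))
        assert d == pytest.approx([-2.0, 2.0])

    def test_reversible_equilibrium_zero_derivative(self):
        # Glu + R <-> GluR at detailed-balance concentrations
        net = Network(
            [Compartment("cytosol", 1.0)],
            [Species("Glu", "cytosol", 1.0), Species("R", "cytosol", 1.0),
             Species("GluR", "cytosol", 0.5)],
            [Reaction(id="f", stoichiometry={"Glu": -1, "R": -1, "GluR": 1},
                      rate_law="mass_action", parameters={"k": 1.0}),
             Reaction(id="b", stoichiometry={"GluR": -1, "Glu": 1, "R": 1},
                      rate_law="mass_action", parameters={"k": 2.0})],
        )
        # Kd = 2: [Glu][R]/[GluR] = 1*1/0.5 = 2 -> equilibrium
        assert net.derivative(np.array([1.0, 1.0, 0.5])) == pytest.approx([0.0] * 3)

    def test_empty_network_zero_derivative(self):
        net = Network([Compartment("cytosol", 1.0)],
                      [Species("A", "cytosol", 1.0)], [])
        assert net.derivative(np.array([1.0])) == pytest.approx([0.0])

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            toy_ab().derivative(np.array([1.0]))

    def test_negative_state_raises(self):
        with pytest.raises(ValueError, match="negative"):
            toy_ab().derivative(np.array([-1.0, 0.0]))

    def test_cross_compartment_flux_volume_scaled(self):
        # amount leaving a small box equals amount entering a big one
        net = Network(
            [Compartment("PSD", 0.002), Compartment("cytosol", 0.02)],
            [Species("Xa", "PSD", 1.0), Species("Xb", "cytosol", 0.0)],
            [Reaction(id="ex", stoichiometry={"Xa": -1, "Xb": 1},
                      rate_law="mass_action", parameters={"k": 5.0},
                      compartment="PSD")],
        )
        d = net.derivative(np.array([1.0, 0.0]))
        # concentration rates scale inversely with volume; amounts balance
        assert d[0] * 0.002 + d[1] * 0.02 == pytest.approx(0.0, abs=1e-15)
        assert d[0] == pytest.approx(-5.0)
        assert d[1] == pytest.approx(5.0 * 0.002 / 0.02)

    def test_full_model_matches_naive_oracle(self, model):
        """Compiled RHS equals an independent per-reaction rate summation on
        random nonnegative states (the core correctness property)."""
        net = model.network
        gen = np.random.default_rng(42)
        base = model.baseline
        for _ in range(100):
            y = base * gen.uniform(0.2, 3.0, size=net.n)
            drives = {"Glu_mglur": gen.uniform(0, 100),
                      "Glu_psd": gen.uniform(0, 1000)}
            got = net.derivative(y, 0.0, drives)
            want = naive_derivative(net, y, 0.0, drives)
            scale = np.maximum(np.abs(want), 1e-6)
            assert np.max(np.abs(got - want) / scale) < 1e-9


class TestConservedMoieties:
    def test_binding_network_conserves_receptor(self):
        net = Network(
            [Compartment("cytosol", 1.0)],
            [Species("Glu", "cytosol", 1.0, driven=True),
             Species("R", "cytosol", 1.0), Species("GluR", "cytosol", 0.0)],
            [Reaction(id="f", stoichiometry={"R": -1, "GluR": 1},
                      rate_law="tabulated_custom", parameters={"kon": 1.0},
                      formula="kon*Glu*R"),
             Reaction(id="b", stoichiometry={"GluR": -1, "R": 1},
                      rate_law="mass_action", parameters={"k": 2.0})],
        )
        laws = net.conserved_moieties()
        assert len(laws) == 1
        assert laws[0] == {"R": 1.0, "GluR": 1.0} or laws[0] == {"R": -1.0, "GluR": -1.0}

    def test_source_reaction_breaks_conservation(self):
        net = Network(
            [Compartment("cytosol", 1.0)],
            [Species("A", "cytosol", 0.0)],
            [Reaction(id="src", stoichiometry={"A": +1},
                      rate_law="mass_action", parameters={"k": 1.0})],
        )
        assert all("A" not in law for law in net.conserved_moieties())

    def test_full_model_receptor_and_galpha_laws_exist(self, model):
        """The assembled model symbolically conserves total mGluR and total
        G-alpha (and the nullspace agrees with a numeric rank check)."""
        net = model.network
        laws = net.conserved_moieties()
        S = net.stoichiometric_matrix()
        assert len(laws) == S.shape[0] - np.linalg.matrix_rank(S)

        def is_conserved(names):
            # the candidate combination must lie in the left null space
            c = np.zeros(net.n)
            for name in names:
                c[net.index[name]] = 1.0
            return np.allclose(c @ S, 0.0, atol=1e-12)

        receptor = [s.name for s in net.dynamic_species
                    if s.name.startswith("mGluR_")]
        assert is_conserved(receptor)
        galpha = ["Gq_GDP", "GaGTP", "GaGDP", "PLCa",
                  "mGluR_RG", "mGluR_RaG", "mGluR_LRG", "mGluR_LRaG"]
        assert is_conserved(galpha)
        # and a deliberately wrong combination is not conserved
        assert not is_conserved(["GaGTP", "PLCa"])

    def test_laws_hold_along_trajectory(self, model):
        """Every symbolic conservation law drifts < 1e-6 (relative) over a
        stimulated trajectory."""
        net = model.network
        from spinesim.simulate import integrate_network
        drives = {"Glu_mglur": lambda t: 50.0 * np.exp(-t), "Glu_psd": lambda t: 0.0}
        t, y = integrate_network(net, model.baseline, (0.0, 10.0),
                                 drive_fns=drives,
                                 t_eval=np.linspace(0, 10, 21))
        for law in net.conserved_moieties():
            totals = np.array([net.moiety_total(law, y[:, j])
                               for j in range(y.shape[1])])
            ref = max(abs(totals[0]), 1e-12)
            assert np.max(np.abs(totals - totals[0])) / ref < 1e-6


def test_molecule_count_conversion():
    # 3000 molecules in the cleft volume (0.0015 µm³) is a mM-scale pulse
    c = molecules_to_uM(3000, 0.0015)
    assert c == pytest.approx(3321.1, rel=1e-3)
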