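"""Group-I metabotropic glutamate receptor cascade.

Receptor activation follows a cubic ternary-complex scheme over three binary
axes — glutamate bound (L), active conformation (a), G-protein coupled (G) —
giving eight receptor states.  Naming: R, Ra, RG, RaG, LR, LRa, LRG, LRaG.
Thermodynamic closure: glutamate binds every inactive state with dissociation
constant ``Kd_glu``; the active conformation is favored by agonist
(equilibrium Ka1 liganded vs Ka0 constitutive), so active states bind
glutamate with Kd_glu*Ka0/Ka1.  G-protein (heterotrimeric Gq-GDP) couples to
every receptor state with one affinity, and only *active* coupled states
(RaG, LRaG) catalyze GDP->GTP exchange, releasing GalphaGTP and Gbetagamma.

The G cycle closes through phospholipase C: GalphaGTP binds PLC in a
Ca2+-dependent manner to form active PLC* which (i) hydrolyzes PIP2 into IP3
and DAG and (ii) acts as a GTPase-activating protein, returning GalphaGDP.
Because the PLC pool is finite, GalphaGTP degradation saturates at high
drive; this is what separates the downstream (GalphaGTP) concentration-
response midpoint from the receptor-occupancy midpoint, an order of
magnitude apart in the calibration data.  Cytosolic IP3 is degraded by a
calcium-dependent 3-kinase (to IP4) and a 5-phosphatase (to IP2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .core import Network, Reaction, Species, Compartment, DEFAULT_COMPARTMENTS
from .simulate import integrate_network

RECEPTOR_STATES = ["mGluR_R", "mGluR_Ra", "mGluR_RG", "mGluR_RaG",
                   "mGluR_LR", "mGluR_LRa", "mGluR_LRG", "mGluR_LRaG"]
LIGANDED = [s for s in RECEPTOR_STATES if "_L" in s]
ACTIVE = [s for s in RECEPTOR_STATES if "a" in s.split("_")[1]]
COUPLED = [s for s in RECEPTOR_STATES if s.endswith("G")]


def mglur_species(p: Dict[str, float]) -> List[Species]:
    """Cascade species (all cytosolic); receptor starts unliganded/inactive,
    G-protein as holo Gq-GDP.  The baseline pinning step replaces these
    initials with the cascade's basal fixed point."""
    sp = [Species(name, "cytosol", 0.0) for name in RECEPTOR_STATES]
    sp[0].initial_concentration = p["R_total"]
    sp += [
        Species("Gq_GDP", "cytosol", p["G_total"]),
        Species("GaGTP", "cytosol", 0.0),
        Species("GaGDP", "cytosol", 0.0),
        Species("Gbg", "cytosol", 0.0),
        Species("PLC", "cytosol", p["PLC_total"]),
        Species("PLCa", "cytosol", 0.0),
        Species("PIP2", "cytosol", p["PIP2_total"]),
        Species("IP3", "cytosol", 0.1),
        Species("DAG", "cytosol", 0.0),
        Species("IP2", "cytosol", 0.0),
        Species("IP4", "cytosol", 0.0),
    ]
    return sp


def mglur_reactions(p: Dict[str, float],
                    glu_species: str = "Glu_mglur") -> List[Reaction]:
    """The full cascade as a declarative reaction block."""
    rxns: List[Reaction] = []
    kon = p["kon_glu"]
    koff_i = kon * p["Kd_glu"]
    koff_a = kon * p["Kd_glu"] * p["Ka0"] / p["Ka1"]

    def bind(unbound, bound, koff):
        rxns.append(Reaction(
            id=f"bind_{unbound}", stoichiometry={unbound: -1, bound: +1},
            rate_law="tabulated_custom", parameters={"kon": kon},
            formula=f"kon*{glu_species}*{unbound}"))
        rxns.append(Reaction(
            id=f"unbind_{bound}", stoichiometry={bound: -1, unbound: +1},
            rate_law="mass_action", parameters={"k": koff}))

    bind("mGluR_R", "mGluR_LR", koff_i)
    bind("mGluR_RG", "mGluR_LRG", koff_i)
    bind("mGluR_Ra", "mGluR_LRa", koff_a)
    bind("mGluR_RaG", "mGluR_LRaG", koff_a)

    # conformational activation; liganded receptors activate more readily
    kf0, kb0 = p["k_act"] * p["Ka0"], p["k_act"]
    kf1, kb1 = p["k_act"] * p["Ka1"], p["k_act"]
    for inact, act, kf, kb in (
            ("mGluR_R", "mGluR_Ra", kf0, kb0),
            ("mGluR_RG", "mGluR_RaG", kf0, kb0),
            ("mGluR_LR", "mGluR_LRa", kf1, kb1),
            ("mGluR_LRG", "mGluR_LRaG", kf1, kb1)):
        rxns.append(Reaction(id=f"act_{inact}", stoichiometry={inact: -1, act: +1},
                             rate_law="mass_action", parameters={"k": kf}))
        rxns.append(Reaction(id=f"deact_{act}", stoichiometry={act: -1, inact: +1},
                             rate_law="mass_action", parameters={"k": kb}))

    # G-protein coupling, one affinity for all receptor states
    for free, coupled in (("mGluR_R", "mGluR_RG"), ("mGluR_Ra", "mGluR_RaG"),
                          ("mGluR_LR", "mGluR_LRG"), ("mGluR_LRa", "mGluR_LRaG")):
        rxns.append(Reaction(
            id=f"gbind_{free}", stoichiometry={free: -1, "Gq_GDP": -1, coupled: +1},
            rate_law="mass_action", parameters={"k": p["kon_G"]}))
        rxns.append(Reaction(
            id=f"gunbind_{coupled}", stoichiometry={coupled: -1, free: +1, "Gq_GDP": +1},
            rate_law="mass_action", parameters={"k": p["kon_G"] * p["Kd_G"]}))

    # nucleotide exchange: active ternary complexes release GaGTP + Gbg
    for coupled, free in (("mGluR_RaG", "mGluR_Ra"), ("mGluR_LRaG", "mGluR_LRa")):
        rxns.append(Reaction(
            id=f"exchange_{coupled}",
            stoichiometry={coupled: -1, free: +1, "GaGTP": +1, "Gbg": +1},
            rate_law="mass_action", parameters={"k": p["k_cat"]}))

    rxns.append(Reaction(id="ga_hydrolysis", stoichiometry={"GaGTP": -1, "GaGDP": +1},
                         rate_law="mass_action", parameters={"k": p["k_hyd"]}))
    rxns.append(Reaction(id="g_reassociation",
                         stoichiometry={"GaGDP": -1, "Gbg": -1, "Gq_GDP": +1},
                         rate_law="mass_action", parameters={"k": p["k_reassoc"]}))

    # Ca-dependent PLC activation (GaGTP binding) and GAP-accelerated
    # hydrolysis within the complex
    rxns.append(Reaction(
        id="plc_activation", stoichiometry={"PLC": -1, "GaGTP": -1, "PLCa": +1},
        rate_law="mass_action", parameters={"k": p["kon_plc"]},
        modifiers=[{"species": "Ca_cyt", "kind": "hill",
                    "K": p["K_plc_ca"], "n": 1}]))
    rxns.append(Reaction(
        id="plc_deactivation", stoichiometry={"PLCa": -1, "PLC": +1, "GaGTP": +1},
        rate_law="mass_action", parameters={"k": p["koff_plc"]}))
    rxns.append(Reaction(
        id="plc_gap", stoichiometry={"PLCa": -1, "PLC": +1, "GaGDP": +1},
        rate_law="mass_action", parameters={"k": p["k_gap"]}))

    # PIP2 hydrolysis by PLC* and slow membrane replenishment
    rxns.append(Reaction(
        id="pip2_hydrolysis", stoichiometry={"PIP2": -1, "IP3": +1, "DAG": +1},
        rate_law="tabulated_custom", parameters={"k_pip2": p["k_pip2"]},
        formula="k_pip2*PLCa*PIP2"))
    rxns.append(Reaction(
        id="pip2_replenish", stoichiometry={"PIP2": +1},
        rate_law="tabulated_custom",
        parameters={"k_rep": p["k_pip2_rep"], "pip2_tot": p["PIP2_total"]},
        formula="k_rep*(pip2_tot - PIP2)"))

    # constitutive (receptor-independent) IP3 production: sets the basal
    # turnover rate independently of the cascade gain
    if p.get("ip3_source", 0.0) > 0:
        rxns.append(Reaction(
            id="ip3_source", stoichiometry={"IP3": +1},
            rate_law="tabulated_custom", parameters={"s0": p["ip3_source"]},
            formula="s0"))

    # IP3 degradation: Ca-dependent 3-kinase and 5-phosphatase
    rxns.append(Reaction(
        id="ip3_3kinase", stoichiometry={"IP3": -1, "IP4": +1},
        rate_law="michaelis_menten",
        parameters={"Vmax": p["V_3k"], "Km": p["Km_3k"], "substrate": "IP3"},
        modifiers=[{"species": "Ca_cyt", "kind": "hill",
                    "K": p["K_3k_ca"], "n": p["n_3k_ca"]}]))
    rxns.append(Reaction(
        id="ip3_5phosphatase", stoichiometry={"IP3": -1, "IP2": +1},
        rate_law="michaelis_menten",
        parameters={"Vmax": p["V_5p"], "Km": p["Km_5p"], "substrate": "IP3"}))

    for prod, k in (("DAG", "k_dag_clear"), ("IP2", "k_ip2_clear"),
                    ("IP4", "k_ip4_clear")):
        rxns.append(Reaction(id=f"{prod.lower()}_clear", stoichiometry={prod: -1},
                             rate_law="mass_action", parameters={"k": p[k]}))
    return rxns


# ---------------------------------------------------------------------------
# standalone cascade (clamped calcium): calibration-curve operations


def standalone_cascade_network(p: Dict[str, float],
                               ca_clamp: float = 0.06) -> Network:
    """Cascade-only network with cytosolic Ca clamped at its basal value and
    glutamate as a driven input — the configuration used for the
    radioligand-style concentration-response calibrations."""
    comps = [Compartment(n, v) for n, v in DEFAULT_COMPARTMENTS.items()]
    species = mglur_species(p)
    species.append(Species("Ca_cyt", "cytosol", ca_clamp, clamped=True))
    species.append(Species("Glu_mglur", "cleft", 0.0, driven=True))
    return Network(comps, species, mglur_reactions(p))


@dataclass
class DoseResponse:
    """Concentration-response pairs with an attached Hill fit."""
    dose: np.ndarray
    response: np.ndarray
    fit: "object" = None  # analysis.HillFit

    @property
    def ec50(self) -> float:
        return self.fit.ec50


def _cascade_steady_state(net: Network, glu: float, duration: float,
                          y0: Optional[np.ndarray] = None,
                          rtol: float = 1e-8, atol: float = 1e-12) -> np.ndarray:
    drive = {"Glu_mglur": (lambda t, L=glu: L)}
    if y0 is None:
        y0 = net.initial_state()
    t, y = integrate_network(net, y0, (0.0, duration),
                             drive_fns=drive, t_eval=np.array([duration]),
                             rtol=rtol, atol=atol)
    return y[:, -1]


def _cascade_basal(net: Network, t_relax: float = 4000.0) -> np.ndarray:
    """Zero-glutamate fixed point of a standalone cascade network."""
    return _cascade_steady_state(net, 0.0, t_relax, rtol=1e-10, atol=1e-14)


def galphagtp_dose_response(p: Dict[str, float],
                            glu_grid: Optional[Sequence[float]] = None,
                            duration: float = 140 * 60.0) -> DoseResponse:
    """Maximum-equilibrium GalphaGTP vs glutamate, basal-normalized.

    A long stimulation (default 140 simulated minutes) at each concentration;
    the response is the equilibrium [GaGTP] divided by the time-matched basal
    (zero-glutamate) value, then Hill-fitted for the EC50.
    """
    from .analysis import fit_hill
    if glu_grid is None:
        glu_grid = np.geomspace(0.01, 1000.0, 13)
    glu_grid = np.sort(np.asarray(glu_grid, dtype=float))
    net = standalone_cascade_network(p)
    i_ga = net.index["GaGTP"]
    y0 = _cascade_basal(net)
    basal = y0[i_ga]
    resp = np.array([
        _cascade_steady_state(net, L, duration, y0)[i_ga] / basal
        for L in glu_grid
    ])
    fit = fit_hill(glu_grid, resp)
    return DoseResponse(glu_grid, resp, fit)


def glutamate_binding_curve(p: Dict[str, float],
                            glu_grid: Optional[Sequence[float]] = None,
                            pulse_duration: float = 10.0) -> DoseResponse:
    """Fraction of glutamate-bound receptor after a long square pulse."""
    from .analysis import fit_hill
    if glu_grid is None:
        glu_grid = np.geomspace(0.003, 300.0, 13)
    glu_grid = np.sort(np.asarray(glu_grid, dtype=float))
    net = standalone_cascade_network(p)
    idx = [net.index[s] for s in LIGANDED]
    y0 = _cascade_basal(net)
    resp = np.array([
        _cascade_steady_state(net, L, pulse_duration, y0)[idx].sum() / p["R_total"]
        for L in glu_grid
    ])
    fit = fit_hill(glu_grid, resp)
    return DoseResponse(glu_grid, resp, fit)


def ip3_balance(plc_star: float, pip2: float, ip3: float, ca: float,
                p: Dict[str, float]) -> float:
    """Net dIP3/dt (µM/s) from production by PLC* on PIP2 and degradation by
    the Ca-dependent 3-kinase plus the 5-phosphatase."""
    if min(plc_star, pip2, ip3, ca) < 0:
        raise ValueError("concentrations must be nonnegative")
    production = p["k_pip2"] * plc_star * pip2 + p.get("ip3_source", 0.0)
    ca_fac = ca ** p["n_3k_ca"] / (p["K_3k_ca"] ** p["n_3k_ca"] + ca ** p["n_3k_ca"])
    v3 = p["V_3k"] * ca_fac * ip3 / (p["Km_3k"] + ip3)
    v5 = p["V_5p"] * ip3 / (p["Km_5p"] + ip3)
    return production - v3 - v5
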