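"""Calcium homeostasis: plasma-membrane extrusion, buffering, and
PSD <-> cytosol diffusion of Ca and IP3.

Cytosolic calcium is extruded by the Na+/Ca2+ exchanger (NCX, low affinity,
first-order Hill) and the plasma-membrane Ca2+-ATPase (PMCA, high affinity,
n=2), balanced at rest by a leak down the cleft -> cytosol gradient.  The
synaptic-cleft calcium pool is treated as a clamped 2 mM reservoir.  Free
calcium binds calmodulin, calcineurin and PKC in both cytosol and PSD —
pure buffering, no downstream enzymatic action.  Ca and IP3 exchange between
PSD and cytosol by first-order, amount-conserving diffusion.

The plasma and ER leak rates are not free parameters: they are solved at
model assembly so the stated resting point (60 nM cytosolic Ca, 100 nM IP3,
2 mM cleft, 0.5 mM ER) is an exact fixed point of the assembled system
("baseline pinning").
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .core import Reaction, Species

#: (name, total µM, kon /(µM·s), koff /s) per buffer; Kd = koff/kon
BUFFERS = [
    ("CaM", 10.0, 50.0, 100.0),   # calmodulin (lumped sites), Kd 2 µM
    ("CaN", 1.0, 30.0, 9.0),      # calcineurin, Kd 0.3 µM
    ("PKC", 2.0, 20.0, 100.0),    # protein kinase C, Kd 5 µM
]
BUFFER_COMPARTMENTS = ["cytosol", "PSD"]


def pmca_ncx_flux(ca: float, p: Dict[str, float]) -> Tuple[float, float]:
    """PMCA and NCX extrusion fluxes (µM/s, cytosol-referenced)."""
    pmca = p["pmca_vmax"] * ca ** 2 / (p["pmca_K"] ** 2 + ca ** 2)
    ncx = p["ncx_vmax"] * ca / (p["ncx_K"] + ca)
    return pmca, ncx


def plasma_membrane_fluxes(ca_cyt: float, ca_cleft: float,
                           p: Dict[str, float]) -> float:
    """Net plasma-membrane calcium flux (µM/s into the cytosol):
    leak in minus PMCA and NCX out; zero at the pinned resting pair."""
    if ca_cyt < 0 or ca_cleft < 0:
        raise ValueError("calcium concentrations must be nonnegative")
    pmca, ncx = pmca_ncx_flux(ca_cyt, p)
    leak = p["pm_leak"] * (ca_cleft - ca_cyt)
    return leak - pmca - ncx


def buffer_equilibrium(ca: float, total: float, kon: float, koff: float) -> float:
    """Equilibrium bound-buffer concentration: total * Ca/(Ca + Kd)."""
    kd = koff / kon
    return total * ca / (ca + kd)


def calcium_species(p: Dict[str, float], ca0: float = 0.06,
                    ip30: float = 0.1) -> List[Species]:
    """Ca pools, PSD IP3, and buffer species initialized at basal equilibrium."""
    sp = [
        Species("Ca_cyt", "cytosol", ca0),
        Species("Ca_PSD", "PSD", ca0),
        Species("Ca_ER", "ER", p["ca_er_rest"]),
        Species("Ca_cleft", "cleft", p["ca_cleft_rest"], clamped=True),
        Species("IP3_psd", "PSD", ip30),
    ]
    for comp in BUFFER_COMPARTMENTS:
        for name, total, kon, koff in BUFFERS:
            bound = buffer_equilibrium(ca0, total, kon, koff)
            sp.append(Species(f"{name}_{comp}", comp, total - bound))
            sp.append(Species(f"Ca{name}_{comp}", comp, bound))
    return sp


def calcium_reactions(p: Dict[str, float]) -> List[Reaction]:
    rxns = [
        Reaction(id="pmca", stoichiometry={"Ca_cyt": -1}, rate_law="hill",
                 parameters={"Vmax": p["pmca_vmax"], "K": p["pmca_K"], "n": 2,
                             "substrate": "Ca_cyt"}),
        Reaction(id="ncx", stoichiometry={"Ca_cyt": -1}, rate_law="hill",
                 parameters={"Vmax": p["ncx_vmax"], "K": p["ncx_K"], "n": 1,
                             "substrate": "Ca_cyt"}),
        Reaction(id="pm_leak", stoichiometry={"Ca_cyt": +1},
                 rate_law="tabulated_custom",
                 parameters={"k_pm": p["pm_leak"]},
                 formula="k_pm*(Ca_cleft - Ca_cyt)"),
    ]
    # buffering: Ca + B <-> CaB in cytosol and PSD
    for comp in BUFFER_COMPARTMENTS:
        ca_name = "Ca_cyt" if comp == "cytosol" else "Ca_PSD"
        for name, total, kon, koff in BUFFERS:
            rxns.append(Reaction(
                id=f"buf_on_{name}_{comp}",
                stoichiometry={ca_name: -1, f"{name}_{comp}": -1,
                               f"Ca{name}_{comp}": +1},
                rate_law="mass_action", parameters={"k": kon},
                compartment=comp))
            rxns.append(Reaction(
                id=f"buf_off_{name}_{comp}",
                stoichiometry={f"Ca{name}_{comp}": -1, ca_name: +1,
                               f"{name}_{comp}": +1},
                rate_law="mass_action", parameters={"k": koff},
                compartment=comp))
    # PSD <-> cytosol first-order exchange (amount-conserving by core's
    # volume bookkeeping; rates referenced to the PSD)
    rxns.append(Reaction(
        id="ca_psd_exchange", stoichiometry={"Ca_PSD": -1, "Ca_cyt": +1},
        rate_law="tabulated_custom", parameters={"k_ex": p["k_ex_ca"]},
        formula="k_ex*(Ca_PSD - Ca_cyt)", compartment="PSD"))
    rxns.append(Reaction(
        id="ip3_psd_exchange", stoichiometry={"IP3_psd": -1, "IP3": +1},
        rate_law="tabulated_custom", parameters={"k_ex": p["k_ex_ip3"]},
        formula="k_ex*(IP3_psd - IP3)", compartment="PSD"))
    return rxns


def intercompartment_exchange(conc_a: float, conc_b: float, k_ex: float,
                              vol_a: float, vol_b: float
                              ) -> Tuple[float, float]:
    """Paired concentration derivatives (µM/s) for first-order exchange
    referenced to compartment a; conserves total amount exactly."""
    if k_ex < 0:
        raise ValueError("exchange rate must be nonnegative")
    amount_flux = k_ex * (conc_a - conc_b) * vol_a  # µM·µm³/s out of a
    return -amount_flux / vol_a, amount_flux / vol_b
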