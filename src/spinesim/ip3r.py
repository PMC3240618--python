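"""IP3 receptor gating and ER calcium fluxes.

The channel follows the De Young-Keizer formulation: each of four identical,
independent subunits carries an IP3 site, an activating Ca site and an
inhibitory Ca site, giving eight states S_ijk (i = IP3, j = activating Ca,
k = inhibitory Ca).  A subunit is open-competent in S110; the tetramer
conducts when at least three subunits (config-exposed: 3-of-4 or 4-of-4) are
open-competent.  The resulting equilibrium open probability is bell-shaped in
cytosolic Ca with a maximum in the 0.2-0.5 µM range.

Binding constants are the canonical De Young-Keizer set (µM, per second):
rates a1..a5 with dissociation constants d1..d5; the inhibitory-site affinity
depends on IP3 occupancy (d2 vs d4) and the IP3-site affinity on inhibitory
occupancy (d1 vs d3), with the thermodynamic cycle closed (d1*d2 = d3*d4).

ER membrane fluxes (all referenced to cytosolic µM/s):
    J_IP3R  = Pmax * P_open * ([Ca]_ER - [Ca]_cyt)
    J_SERCA = Vmax * [Ca]^2 / (K^2 + [Ca]^2)       (cytosol -> ER)
    J_leak  = k_leak * ([Ca]_ER - [Ca]_cyt)
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Tuple

import numpy as np

from .core import Reaction, Species

#: canonical subunit binding parameters; a* in /(µM·s), d* in µM
DYK_PARAMS = {
    "a1": 400.0, "d1": 0.13,
    "a2": 0.2,   "d2": 1.049,
    "a3": 400.0, "d3": 0.9434,
    "a4": 0.2,   "d4": 0.1445,
    "a5": 20.0,  "d5": 0.08234,
}

STATE_NAMES = [f"IP3R_x{i}{j}{k}" for i, j, k in product((0, 1), repeat=3)]


def subunit_equilibrium(ca: float, ip3: float, p: Dict[str, float] = DYK_PARAMS
                        ) -> Dict[str, float]:
    """Detailed-balance equilibrium occupancy of the eight subunit states."""
    w = {}
    for i, j, k in product((0, 1), repeat=3):
        weight = 1.0
        if i:
            weight *= ip3 / p["d1"]
        if j:
            weight *= ca / p["d5"]
        if k:
            # inhibitory affinity depends on IP3 occupancy; cycle closure
            # makes the path choice immaterial
            weight *= ca / (p["d2"] if i else p["d4"])
        w[(i, j, k)] = weight
    Z = sum(w.values())
    return {f"IP3R_x{i}{j}{k}": w[(i, j, k)] / Z for i, j, k in w}


def subunit_steady_state(ca: float, ip3: float,
                         p: Dict[str, float] = DYK_PARAMS) -> Dict[str, float]:
    """Exact kinetic steady state of the 8-state subunit at clamped ligands.

    The canonical constants close the binding cycle only to ~3 digits
    (d1*d2 vs d3*d4), so the true stationary distribution differs from the
    detailed-balance weights by a small circulating flux; baseline pinning
    uses this exact version.
    """
    idx = {name: i for i, name in enumerate(STATE_NAMES)}
    Q = np.zeros((8, 8))
    for src, dst, kon, koff, ligand in _edges(p):
        kf = kon * (ip3 if ligand == "IP3" else ca)
        i, j = idx[src], idx[dst]
        Q[j, i] += kf
        Q[i, i] -= kf
        Q[i, j] += koff
        Q[j, j] -= koff
    A = np.vstack([Q, np.ones(8)])
    b = np.zeros(9)
    b[-1] = 1.0
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    return {name: float(x[idx[name]]) for name in STATE_NAMES}


def channel_open_probability(x110: np.ndarray, subunits_required: int = 3
                             ) -> np.ndarray:
    """Tetramer open probability from the open-competent subunit fraction."""
    c = np.asarray(x110, dtype=float)
    if subunits_required == 4:
        return c ** 4
    if subunits_required == 3:
        return 4.0 * c ** 3 * (1.0 - c) + c ** 4
    raise ValueError("subunits_required must be 3 or 4")


def ip3r_open_probability(ca: float, ip3: float,
                          params: Dict[str, float] = DYK_PARAMS,
                          subunits_required: int = 3) -> float:
    """Equilibrium open probability at clamped Ca and IP3 (both µM, >= 0)."""
    if ca < 0 or ip3 < 0:
        raise ValueError("Ca and IP3 must be nonnegative")
    occ = subunit_equilibrium(ca, ip3, params)
    return float(channel_open_probability(occ["IP3R_x110"], subunits_required))


def _edges(p: Dict[str, float]) -> List[Tuple[str, str, float, float, str]]:
    """Subunit transitions: (from, to, k_on (/µM/s), k_off (/s), ligand)."""
    edges = []
    for i, j, k in product((0, 1), repeat=3):
        if i == 0:  # IP3 binding; affinity depends on inhibitory site
            a, d = (p["a3"], p["d3"]) if k else (p["a1"], p["d1"])
            edges.append((f"IP3R_x0{j}{k}", f"IP3R_x1{j}{k}", a, a * d, "IP3"))
        if j == 0:  # activating Ca
            edges.append((f"IP3R_x{i}0{k}", f"IP3R_x{i}1{k}",
                          p["a5"], p["a5"] * p["d5"], "Ca_cyt"))
        if k == 0:  # inhibitory Ca; affinity depends on IP3 site
            a, d = (p["a2"], p["d2"]) if i else (p["a4"], p["d4"])
            edges.append((f"IP3R_x{i}{j}0", f"IP3R_x{i}{j}1", a, a * d, "Ca_cyt"))
    return edges


def ip3r_species(ca0: float = 0.06, ip30: float = 0.1,
                 params: Dict[str, float] = DYK_PARAMS) -> List[Species]:
    """Subunit-state species (occupancy fractions), initialized at the exact
    kinetic steady state for basal Ca/IP3 so the model starts on its fixed
    point."""
    occ = subunit_steady_state(ca0, ip30, params)
    return [Species(name, "ER", occ[name]) for name in STATE_NAMES]


def ip3r_reactions(model_params: Dict[str, float]) -> List[Reaction]:
    """Subunit gating plus the three ER-membrane calcium fluxes.

    Gating transitions change only subunit occupancies: the ligand (IP3 or
    cytosolic Ca) enters the rate but is not consumed, because the subunit
    pool represents channel state, not a stoichiometric sink (the bound
    ligand amounts are negligible against the cytosolic pools).
    """
    p = {**DYK_PARAMS, **{k: v for k, v in model_params.items() if k in DYK_PARAMS}}
    rxns = []
    for src, dst, kon, koff, ligand in _edges(p):
        rxns.append(Reaction(
            id=f"ip3r_{src[-3:]}_to_{dst[-3:]}",
            stoichiometry={src: -1, dst: +1},
            rate_law="tabulated_custom",
            parameters={"kon": kon},
            formula=f"kon*{ligand}*{src}",
            compartment="ER",
        ))
        rxns.append(Reaction(
            id=f"ip3r_{dst[-3:]}_to_{src[-3:]}",
            stoichiometry={dst: -1, src: +1},
            rate_law="mass_action",
            parameters={"k": koff},
            compartment="ER",
        ))

    popen = "(4*IP3R_x110**3*(1-IP3R_x110) + IP3R_x110**4)"
    if int(model_params.get("ip3r_subunits_required", 3)) == 4:
        popen = "IP3R_x110**4"
    rxns.append(Reaction(
        id="ip3r_flux",
        stoichiometry={"Ca_ER": -1, "Ca_cyt": +1},
        rate_law="tabulated_custom",
        parameters={"perm": model_params["ip3r_permeability"]},
        formula=f"perm*{popen}*(Ca_ER - Ca_cyt)",
        compartment="cytosol",
    ))
    rxns.append(Reaction(
        id="serca",
        stoichiometry={"Ca_cyt": -1, "Ca_ER": +1},
        rate_law="hill",
        parameters={"Vmax": model_params["serca_vmax"],
                    "K": model_params["serca_K"], "n": 2,
                    "substrate": "Ca_cyt"},
        compartment="cytosol",
    ))
    rxns.append(Reaction(
        id="er_leak",
        stoichiometry={"Ca_ER": -1, "Ca_cyt": +1},
        rate_law="tabulated_custom",
        parameters={"k_leak": model_params["er_leak"]},
        formula="k_leak*(Ca_ER - Ca_cyt)",
        compartment="cytosol",
    ))
    return rxns


@dataclass(frozen=True)
class ERFluxes:
    J_IP3R: float
    J_SERCA: float
    J_leak: float


def er_calcium_fluxes(ca_cyt: float, ca_er: float, ip3: float,
                      model_params: Dict[str, float],
                      x110: float = None) -> ERFluxes:
    """The three ER fluxes in cytosol-referenced µM/s at the given state.

    If ``x110`` is omitted the equilibrium subunit occupancy at (ca, ip3) is
    used; pass the kinetic value to evaluate along a trajectory.
    """
    if ca_cyt < 0 or ca_er < 0:
        raise ValueError("calcium concentrations must be nonnegative")
    if x110 is None:
        x110 = subunit_equilibrium(ca_cyt, ip3)["IP3R_x110"]
    po = float(channel_open_probability(
        x110, int(model_params.get("ip3r_subunits_required", 3))))
    grad = ca_er - ca_cyt
    j_ip3r = model_params["ip3r_permeability"] * po * grad
    j_serca = (model_params["serca_vmax"] * ca_cyt ** 2
               / (model_params["serca_K"] ** 2 + ca_cyt ** 2))
    j_leak = model_params["er_leak"] * grad
    return ERFluxes(j_ip3r, j_serca, j_leak)
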