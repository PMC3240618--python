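"""Ionotropic glutamate receptors: Markov kinetic schemes for AMPA and NMDA.

State occupancies are fractions of each receptor population (80 AMPARs and
20 NMDARs clustered in the PSD at 20 nm from the release site) and obey the
master equation of the scheme; glutamate-dependent transitions read the cleft
concentration at the PSD as a driven input.

AMPA: sequential double-binding scheme with one open and two desensitized
states (fast, low-affinity, strongly desensitizing — millimolar cleft
transients gate it).  NMDA: double binding, one desensitized state, slower
opening/closing (Lester/Jahr-type constants).  AMPARs are taken as
GluA2-containing and carry no calcium by default; the NMDA open fraction
drives a fixed-driving-force calcium influx into the PSD:

    J_Ca = c_nmda * n_nmda * [open fraction]   (µM/s into the PSD)

No membrane voltage or Mg2+ block is modeled — the source model is purely
biochemical; the coefficient c_nmda lumps single-channel flux and driving
force and is pinned by the full-model single-release calcium-peak anchor.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .core import Reaction, Species

AMPA_STATES = ["AMPA_C0", "AMPA_C1", "AMPA_C2", "AMPA_O", "AMPA_D1", "AMPA_D2"]
NMDA_STATES = ["NMDA_C0", "NMDA_C1", "NMDA_C2", "NMDA_O", "NMDA_D"]

#: transition rates; glutamate-dependent entries are /(µM·s), others /s
AMPA_RATES = {
    "kon1": 4.59, "koff1": 4260.0,   # C0 <-> C1 (2x binding statistical factor applied)
    "kon2": 4.59, "koff2": 4260.0,   # C1 <-> C2
    "beta": 4000.0, "alpha": 1000.0,  # C2 <-> O
    "kd1": 300.0, "kr1": 2.0,        # C1 <-> D1
    "kd2": 700.0, "kr2": 10.0,       # C2 <-> D2
}

NMDA_RATES = {
    "kon1": 5.0, "koff1": 82.0,
    "kon2": 5.0, "koff2": 82.0,
    "beta": 46.5, "alpha": 91.6,     # C2 <-> O
    "kd": 8.4, "kr": 1.8,            # C2 <-> D
}


def _edge_list(kind: str, rates: Dict[str, float]
               ) -> List[Tuple[str, str, float, bool]]:
    """(src, dst, rate, glu_dependent) transitions of one scheme."""
    if kind == "AMPA":
        r = rates
        return [
            ("AMPA_C0", "AMPA_C1", 2 * r["kon1"], True),
            ("AMPA_C1", "AMPA_C0", r["koff1"], False),
            ("AMPA_C1", "AMPA_C2", r["kon2"], True),
            ("AMPA_C2", "AMPA_C1", 2 * r["koff2"], False),
            ("AMPA_C2", "AMPA_O", r["beta"], False),
            ("AMPA_O", "AMPA_C2", r["alpha"], False),
            ("AMPA_C1", "AMPA_D1", r["kd1"], False),
            ("AMPA_D1", "AMPA_C1", r["kr1"], False),
            ("AMPA_C2", "AMPA_D2", r["kd2"], False),
            ("AMPA_D2", "AMPA_C2", r["kr2"], False),
        ]
    if kind == "NMDA":
        r = rates
        return [
            ("NMDA_C0", "NMDA_C1", 2 * r["kon1"], True),
            ("NMDA_C1", "NMDA_C0", r["koff1"], False),
            ("NMDA_C1", "NMDA_C2", r["kon2"], True),
            ("NMDA_C2", "NMDA_C1", 2 * r["koff2"], False),
            ("NMDA_C2", "NMDA_O", r["beta"], False),
            ("NMDA_O", "NMDA_C2", r["alpha"], False),
            ("NMDA_C2", "NMDA_D", r["kd"], False),
            ("NMDA_D", "NMDA_C2", r["kr"], False),
        ]
    raise ValueError(f"unknown receptor kind {kind!r}")


def iglur_species() -> List[Species]:
    """All scheme states, fully unbound/closed at rest."""
    sp = []
    for name in AMPA_STATES + NMDA_STATES:
        init = 1.0 if name.endswith("C0") else 0.0
        sp.append(Species(name, "PSD", init))
    return sp


def iglur_reactions(model_params: Dict[str, float],
                    glu_species: str = "Glu_psd") -> List[Reaction]:
    """Master-equation transitions plus the NMDA calcium source."""
    rxns = []
    for kind, rates in (("AMPA", AMPA_RATES), ("NMDA", NMDA_RATES)):
        for src, dst, rate, glu_dep in _edge_list(kind, rates):
            if glu_dep:
                rxns.append(Reaction(
                    id=f"{src}_to_{dst}",
                    stoichiometry={src: -1, dst: +1},
                    rate_law="tabulated_custom",
                    parameters={"kon": rate},
                    formula=f"kon*{glu_species}*{src}",
                    compartment="PSD",
                ))
            else:
                rxns.append(Reaction(
                    id=f"{src}_to_{dst}",
                    stoichiometry={src: -1, dst: +1},
                    rate_law="mass_action",
                    parameters={"k": rate},
                    compartment="PSD",
                ))
    rxns.append(Reaction(
        id="nmda_ca_influx",
        stoichiometry={"Ca_PSD": +1},
        rate_law="tabulated_custom",
        parameters={"c_nmda": model_params["nmda_ca_coefficient"],
                    "n_nmda": model_params.get("n_nmda", 20)},
        formula="c_nmda*n_nmda*NMDA_O",
        compartment="PSD",
    ))
    return rxns


def rate_matrix(kind: str, glu_uM: float) -> Tuple[List[str], np.ndarray]:
    """Generator matrix Q of one scheme at clamped glutamate.

    Returns (state order, Q) with d(occupancy)/dt = Q @ occupancy; columns
    sum to zero.  Used for stationary-distribution and matrix-exponential
    oracles.
    """
    states = AMPA_STATES if kind == "AMPA" else NMDA_STATES
    rates = AMPA_RATES if kind == "AMPA" else NMDA_RATES
    idx = {s: i for i, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))
    for src, dst, rate, glu_dep in _edge_list(kind, rates):
        k = rate * glu_uM if glu_dep else rate
        Q[idx[dst], idx[src]] += k
        Q[idx[src], idx[src]] -= k
    return states, Q


def nmda_calcium_flux(open_fraction: float, n_receptors: float,
                      coefficient: float) -> float:
    """Calcium influx into the PSD (µM/s): linear in open fraction and count."""
    if not 0.0 <= open_fraction <= 1.0:
        raise ValueError("open fraction must lie in [0, 1]")
    return coefficient * n_receptors * open_fraction
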