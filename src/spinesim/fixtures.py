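"""Synthetic validation fixtures with closed-form answers.

Each fixture pairs a toy input (a miniature reaction network or an analytic
curve) with its exact solution computed analytically — never by the engine
under test — so the ODE core, the exchange bookkeeping and the curve fitters
can be validated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

from .core import Compartment, Network, Reaction, Species

FIXTURE_KINDS = ("exp_decay_network", "binding_isotherm", "hill_curve",
                 "two_box_exchange")


@dataclass
class Fixture:
    kind: str
    payload: Dict = field(default_factory=dict)
    expected: Callable = None  # analytic answer


def make_fixture(kind: str, **kw) -> Fixture:
    if kind == "exp_decay_network":
        k = kw.get("k", 1.0)
        a0 = kw.get("A0", 1.0)
        net = Network(
            [Compartment("cytosol", 1.0)],
            [Species("A", "cytosol", a0)],
            [Reaction(id="decay", stoichiometry={"A": -1},
                      rate_law="mass_action", parameters={"k": k})],
        )
        return Fixture(kind, {"network": net, "k": k, "A0": a0},
                       expected=lambda t: a0 * np.exp(-k * np.asarray(t)))

    if kind == "binding_isotherm":
        kd = kw.get("Kd", 1.0)
        kon = kw.get("kon", 10.0)
        net = Network(
            [Compartment("cytosol", 1.0)],
            [Species("R", "cytosol", 1.0), Species("LR", "cytosol", 0.0),
             Species("L", "cytosol", 0.0, driven=True)],
            [Reaction(id="bind", stoichiometry={"R": -1, "LR": +1},
                      rate_law="tabulated_custom", parameters={"kon": kon},
                      formula="kon*L*R"),
             Reaction(id="unbind", stoichiometry={"LR": -1, "R": +1},
                      rate_law="mass_action", parameters={"k": kon * kd})],
        )
        return Fixture(kind, {"network": net, "Kd": kd},
                       expected=lambda c: np.asarray(c) / (np.asarray(c) + kd))

    if kind == "hill_curve":
        ec50 = kw.get("ec50", 2.0)
        n = kw.get("n", 1.0)
        top = kw.get("top", 1.0)
        bottom = kw.get("bottom", 0.0)
        dose = kw.get("dose", np.geomspace(ec50 / 100, ec50 * 100, 17))

        def curve(d):
            d = np.asarray(d, dtype=float)
            return bottom + (top - bottom) * d ** n / (ec50 ** n + d ** n)

        return Fixture(kind, {"dose": dose, "response": curve(dose),
                              "ec50": ec50, "n": n, "top": top,
                              "bottom": bottom}, expected=curve)

    if kind == "two_box_exchange":
        k_ex = kw.get("k_ex", 5.0)
        va, vb = kw.get("va", 0.002), kw.get("vb", 0.02)
        ca0, cb0 = kw.get("ca0", 1.0), kw.get("cb0", 0.0)
        net = Network(
            [Compartment("PSD", va), Compartment("cytosol", vb)],
            [Species("Xa", "PSD", ca0), Species("Xb", "cytosol", cb0)],
            [Reaction(id="exchange", stoichiometry={"Xa": -1, "Xb": +1},
                      rate_law="tabulated_custom", parameters={"k_ex": k_ex},
                      formula="k_ex*(Xa - Xb)", compartment="PSD")],
        )
        c_inf = (va * ca0 + vb * cb0) / (va + vb)
        lam = k_ex * (1.0 + va / vb)

        def solution(t):
            t = np.asarray(t, dtype=float)
            return (c_inf + (ca0 - c_inf) * np.exp(-lam * t),
                    c_inf + (cb0 - c_inf) * np.exp(-lam * t) * (-va / vb)
                    * (ca0 - c_inf) / max(cb0 - c_inf, 1e-300)
                    if cb0 != c_inf else
                    c_inf - (va / vb) * (ca0 - c_inf) * np.exp(-lam * t))

        # simpler closed form: both boxes relax to c_inf with rate lam,
        # amplitudes set by amount conservation
        def solution(t):  # noqa: F811
            t = np.asarray(t, dtype=float)
            e = np.exp(-lam * t)
            return (c_inf + (ca0 - c_inf) * e, c_inf + (cb0 - c_inf) * e)

        return Fixture(kind, {"network": net, "rate": lam, "c_inf": c_inf},
                       expected=solution)

    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
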