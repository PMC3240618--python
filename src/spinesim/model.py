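"""Assembly of the full four-compartment spine model.

Combines the reaction blocks of the mGluRI cascade, IP3R/ER fluxes, calcium
homeostasis and the ionotropic receptor schemes into one Network, with cleft
glutamate at the mGluRI and PSD locations as driven inputs.

Baseline pinning
----------------
Three derived parameters are solved at assembly so that the published resting
state — cytosolic Ca 60 nM, IP3 100 nM, cleft Ca 2 mM, ER Ca 0.5 mM — is an
exact fixed point of the assembled ODE system rather than a fitted outcome:

* 5-phosphatase rate ``k_5p``: balances basal PLC* production of IP3,
* ER leak: balances SERCA against basal IP3R flux at the resting pair,
* plasma-membrane leak: balances PMCA + NCX at resting cytosolic Ca.

All other initial concentrations (cascade intermediates, buffer loading,
IP3R subunit occupancies) are set to their basal equilibrium values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional

import numpy as np
import yaml

from . import calcium, iglur, ip3r, mglur
from .cleft import DiffusionParams, TransporterParams
from .core import Compartment, Network, Species
from .simulate import integrate_network


def load_default_params() -> Dict:
    """Parameter table shipped with the package (deep copy, safe to edit)."""
    with resources.files("spinesim.data").joinpath("params.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class SpineModel:
    """Assembled model: parameter table, compiled network, pinned baseline."""

    params: Dict
    network: Network
    baseline: np.ndarray
    basal_ca: float = 0.06
    basal_ip3: float = 0.1

    def diffusion_params(self) -> DiffusionParams:
        return DiffusionParams(**self.params["diffusion"])

    def transporter_params(self) -> TransporterParams:
        return TransporterParams(**self.params["transporters"])

    def species_index(self, name: str) -> int:
        return self.network.index[name]

    def baseline_value(self, name: str) -> float:
        return float(self.baseline[self.network.index[name]])


def _cascade_basal_state(mp: Dict, ca0: float, t_relax: float = 4000.0
                         ) -> Dict[str, float]:
    """Basal (zero-glutamate) fixed point of the standalone cascade with
    cytosolic Ca clamped; returns name -> concentration."""
    net = mglur.standalone_cascade_network(mp, ca_clamp=ca0)
    t, y = integrate_network(net, net.initial_state(), (0.0, t_relax),
                             drive_fns={"Glu_mglur": lambda t: 0.0},
                             t_eval=np.array([t_relax]), rtol=1e-10, atol=1e-14)
    return {s.name: float(y[net.index[s.name], -1]) for s in net.dynamic_species}


def pin_baseline(params: Dict) -> Dict:
    """Solve the derived constants that make the resting state exact.

    Returns a new parameter table with ``k_5p``, ``er_leak`` and ``pm_leak``
    replaced by their pinned values, plus the cascade basal state under key
    ``_basal_cascade`` (consumed by :func:`build_model`).
    """
    params = copy.deepcopy(params)
    mp = params["mglur"]
    cp = params["calcium"]
    ipp = params["ip3r"]
    ca0, ip30 = 0.06, 0.1
    er0 = cp["ca_er_rest"]
    cleft0 = cp["ca_cleft_rest"]

    basal = _cascade_basal_state(mp, ca0)
    production = (mp["k_pip2"] * basal["PLCa"] * basal["PIP2"]
                  + mp.get("ip3_source", 0.0))
    ca_fac = ca0 ** mp["n_3k_ca"] / (mp["K_3k_ca"] ** mp["n_3k_ca"]
                                     + ca0 ** mp["n_3k_ca"])
    v3 = mp["V_3k"] * ca_fac * ip30 / (mp["Km_3k"] + ip30)
    v5_needed = production - v3
    if v5_needed <= 0:
        raise ValueError(
            "cannot pin basal IP3: 3-kinase flux alone exceeds basal production"
        )
    mp["V_5p"] = float(v5_needed * (mp["Km_5p"] + ip30) / ip30)

    dyk = {**ip3r.DYK_PARAMS,
           **{k: v for k, v in ipp.items() if k in ip3r.DYK_PARAMS}}
    x110 = ip3r.subunit_steady_state(ca0, ip30, dyk)["IP3R_x110"]
    po = float(ip3r.channel_open_probability(
        x110, int(ipp["ip3r_subunits_required"])))
    j_ip3r = ipp["ip3r_permeability"] * po * (er0 - ca0)
    j_serca = ipp["serca_vmax"] * ca0 ** 2 / (ipp["serca_K"] ** 2 + ca0 ** 2)
    er_leak = (j_serca - j_ip3r) / (er0 - ca0)
    if er_leak <= 0:
        raise ValueError("cannot pin ER leak: basal IP3R flux exceeds SERCA uptake")
    ipp["er_leak"] = float(er_leak)

    pmca, ncx = calcium.pmca_ncx_flux(ca0, cp)
    cp["pm_leak"] = float((pmca + ncx) / (cleft0 - ca0))

    params["_basal_cascade"] = basal
    return params


def build_model(params: Optional[Dict] = None) -> SpineModel:
    """Assemble, pin and compile the default spine model."""
    if params is None:
        params = load_default_params()
    params = pin_baseline(params)
    mp, cp, ipp, igp = (params["mglur"], params["calcium"],
                        params["ip3r"], params["iglur"])
    basal = params.pop("_basal_cascade")
    ca0, ip30 = 0.06, 0.1

    comps = [Compartment(n, v) for n, v in params["compartments"].items()]
    species = mglur.mglur_species(mp)
    for s in species:
        if s.name in basal:
            s.initial_concentration = max(basal[s.name], 0.0)
    species += calcium.calcium_species(cp, ca0, ip30)
    dyk = {**ip3r.DYK_PARAMS,
           **{k: v for k, v in ipp.items() if k in ip3r.DYK_PARAMS}}
    species += ip3r.ip3r_species(ca0, ip30, dyk)
    species += iglur.iglur_species()
    species += [Species("Glu_mglur", "cleft", 0.0, driven=True),
                Species("Glu_psd", "cleft", 0.0, driven=True)]
    # second messengers start exactly at the pinned baseline; DAG is fed by
    # PIP2 hydrolysis only (the constitutive IP3 source bypasses it)
    plc_production = mp["k_pip2"] * basal["PLCa"] * basal["PIP2"]
    ca_fac = ca0 ** mp["n_3k_ca"] / (mp["K_3k_ca"] ** mp["n_3k_ca"]
                                     + ca0 ** mp["n_3k_ca"])
    v3 = mp["V_3k"] * ca_fac * ip30 / (mp["Km_3k"] + ip30)
    v5_b = mp["V_5p"] * ip30 / (mp["Km_5p"] + ip30)
    pinned_initials = {
        "IP3": ip30,
        "DAG": plc_production / mp["k_dag_clear"],
        "IP2": v5_b / mp["k_ip2_clear"],
        "IP4": v3 / mp["k_ip4_clear"],
    }
    for s in species:
        if s.name in pinned_initials:
            s.initial_concentration = pinned_initials[s.name]

    ip3r_params = {**ipp}
    reactions = (mglur.mglur_reactions(mp)
                 + calcium.calcium_reactions(cp)
                 + ip3r.ip3r_reactions(ip3r_params)
                 + iglur.iglur_reactions(igp))
    net = Network(comps, species, reactions)
    net.compile()
    return SpineModel(params=params, network=net, baseline=net.initial_state())


_default_model_cache: Dict[int, SpineModel] = {}


def default_model() -> SpineModel:
    """Shared default model instance (assembly and compilation are cached)."""
    if 0 not in _default_model_cache:
        _default_model_cache[0] = build_model()
    return _default_model_cache[0]
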