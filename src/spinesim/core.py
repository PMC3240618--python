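"""Compartmentalized reaction-network core.

All biology modules (mGluRI cascade, IP3R/ER, iGluR, calcium homeostasis)
contribute declarative species/reaction blocks that are assembled here into a
single :class:`Network` whose right-hand side is compiled (via sympy) into a
fast numpy function with an analytic Jacobian for stiff integration.

Unit conventions (one canon for the whole package):
    concentrations  µM
    time            s
    volumes         µm³
Molecule counts are converted through Avogadro's number and the compartment
volume at ingestion.  Every reaction has a *home* compartment: its rate law is
evaluated there in µM/s, converted to an amount flux (µM·µm³/s) by the home
volume, and re-scaled by the destination volume for species living elsewhere,
so cross-compartment fluxes are mass-conserving by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import sympy as sp

AVOGADRO = 6.02214076e23

# litres per µm³ : 1 µm³ = 1e-15 L.  count -> µM conversion:
#   c[µM] = n / (N_A * V[µm³] * 1e-15) * 1e6
def molecules_to_uM(n: float, volume_um3: float) -> float:
    """Convert a molecule count in a compartment of given volume to µM."""
    return n / (AVOGADRO * volume_um3 * 1e-15) / 1e-6


class NetworkValidationError(ValueError):
    """Raised when a model document references undeclared entities or
    carries an unknown rate-law kind / missing parameter."""


@dataclass(frozen=True)
class Compartment:
    name: str
    volume: float  # µm³

    def __post_init__(self):
        if not self.volume > 0:
            raise NetworkValidationError(
                f"compartment {self.name!r} must have positive volume, got {self.volume}"
            )


@dataclass
class Species:
    """A chemical species resident in one compartment.

    ``clamped`` species hold a constant concentration (reservoirs such as
    cleft calcium); ``driven`` species take their concentration from an
    external time function (cleft glutamate sampled at a receptor location).
    Neither contributes a state-vector entry.
    """

    name: str
    compartment: str
    initial_concentration: float = 0.0  # µM
    clamped: bool = False
    driven: bool = False

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise NetworkValidationError(
                f"species {self.name!r}: negative initial concentration"
            )


RATE_LAWS = ("mass_action", "michaelis_menten", "hill", "tabulated_custom")


@dataclass
class Reaction:
    """One reaction: signed stoichiometry plus a rate law.

    rate_law kinds
        mass_action        rate = k * Π [reactant]^|stoich|
        michaelis_menten   rate = Vmax*[S]/(Km+[S])           (S = parameters['substrate'])
        hill               rate = Vmax*[S]^n/(K^n+[S]^n)
        tabulated_custom   rate = sympy expression in `formula` over species
                           names and parameters

    ``modifiers`` multiply the rate by saturating factors, e.g. the calcium
    dependence of PLC activation: {"species": "Ca_cyt", "kind": "hill",
    "K": 0.2, "n": 1}.  The rate is in µM/s referenced to ``compartment``.
    """

    id: str
    stoichiometry: Dict[str, float]
    rate_law: str
    parameters: Dict[str, object] = field(default_factory=dict)
    compartment: str = "cytosol"
    modifiers: List[dict] = field(default_factory=list)
    formula: Optional[str] = None


class Network:
    """Assembled reaction network with a compiled ODE right-hand side."""

    def __init__(
        self,
        compartments: Sequence[Compartment],
        species: Sequence[Species],
        reactions: Sequence[Reaction],
    ):
        self.compartments = {c.name: c for c in compartments}
        self.species = list(species)
        self.reactions = list(reactions)
        self._validate()

        self.dynamic_species = [s for s in self.species if not (s.clamped or s.driven)]
        self.driven_species = [s for s in self.species if s.driven]
        self.clamped_species = [s for s in self.species if s.clamped]
        self.index = {s.name: i for i, s in enumerate(self.dynamic_species)}
        self.driven_index = {s.name: i for i, s in enumerate(self.driven_species)}
        self.n = len(self.dynamic_species)
        self._volumes = np.array(
            [self.compartments[s.compartment].volume for s in self.dynamic_species]
        )
        self._compiled = None

    # -- validation ---------------------------------------------------------
    def _validate(self):
        names = [s.name for s in self.species]
        seen = {}
        for s in self.species:
            key = (s.name,)
            if s.name in seen:
                raise NetworkValidationError(f"duplicate species name {s.name!r}")
            seen[s.name] = s
            if s.compartment not in self.compartments:
                raise NetworkValidationError(
                    f"species {s.name!r} placed in undeclared compartment {s.compartment!r}"
                )
        declared = set(names)
        for r in self.reactions:
            if r.rate_law not in RATE_LAWS:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: unknown rate law {r.rate_law!r}"
                )
            if r.compartment not in self.compartments:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: undeclared compartment {r.compartment!r}"
                )
            for name in r.stoichiometry:
                if name not in declared:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references undeclared species {name!r}"
                    )
            for m in r.modifiers:
                if m["species"] not in declared:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} modifier references undeclared species "
                        f"{m['species']!r}"
                    )
            if r.rate_law == "mass_action" and "k" not in r.parameters:
                raise NetworkValidationError(f"reaction {r.id!r}: missing parameter 'k'")
            if r.rate_law in ("michaelis_menten", "hill"):
                need = {"michaelis_menten": ("Vmax", "Km", "substrate"),
                        "hill": ("Vmax", "K", "n", "substrate")}[r.rate_law]
                for p in need:
                    if p not in r.parameters:
                        raise NetworkValidationError(
                            f"reaction {r.id!r}: missing parameter {p!r}"
                        )
                if r.parameters["substrate"] not in declared:
                    raise NetworkValidationError(
                        f"reaction {r.id!r}: substrate {r.parameters['substrate']!r} "
                        "is undeclared"
                    )
            if r.rate_law == "tabulated_custom" and not r.formula:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: tabulated_custom requires a formula"
                )

    # -- symbolic assembly --------------------------------------------------
    def _symbols(self):
        t = sp.Symbol("t", real=True)
        ysym = {s.name: sp.Symbol(f"y{i}", real=True)
                for i, s in enumerate(self.dynamic_species)}
        gsym = {s.name: sp.Symbol(f"g{i}", real=True)
                for i, s in enumerate(self.driven_species)}
        csub = {s.name: sp.Float(s.initial_concentration) for s in self.clamped_species}
        concs = {}
        concs.update(ysym)
        concs.update(gsym)
        concs.update(csub)
        return t, ysym, gsym, concs

    def rate_expression(self, r: Reaction, concs: Mapping[str, sp.Expr]) -> sp.Expr:
        """Symbolic rate (µM/s, home compartment) of one reaction."""
        if r.rate_law == "mass_action":
            expr = sp.Float(r.parameters["k"])
            for name, st in r.stoichiometry.items():
                if st < 0:
                    expr *= concs[name] ** int(round(-st))
        elif r.rate_law == "michaelis_menten":
            S = concs[r.parameters["substrate"]]
            expr = sp.Float(r.parameters["Vmax"]) * S / (sp.Float(r.parameters["Km"]) + S)
        elif r.rate_law == "hill":
            S = concs[r.parameters["substrate"]]
            n = sp.Float(r.parameters["n"])
            K = sp.Float(r.parameters["K"])
            expr = sp.Float(r.parameters["Vmax"]) * S ** n / (K ** n + S ** n)
        else:  # tabulated_custom
            local = dict(concs)
            for k, v in r.parameters.items():
                if isinstance(v, (int, float)):
                    local[k] = sp.Float(v)
            expr = sp.sympify(r.formula, locals=local)
        for m in r.modifiers:
            S = concs[m["species"]]
            kind = m.get("kind", "hill")
            if kind == "hill":
                n = sp.Float(m.get("n", 1))
                K = sp.Float(m["K"])
                expr *= S ** n / (K ** n + S ** n)
            elif kind == "linear":
                expr *= S / sp.Float(m["K"])
            else:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: unknown modifier kind {kind!r}"
                )
        return expr

    def _build_rhs_exprs(self):
        t, ysym, gsym, concs = self._symbols()
        dydt = [sp.Integer(0)] * self.n
        for r in self.reactions:
            rate = self.rate_expression(r, concs)
            vhome = self.compartments[r.compartment].volume
            for name, st in r.stoichiometry.items():
                i = self.index.get(name)
                if i is None:
                    continue  # clamped/driven: no state entry
                vdest = self._volumes[i]
                dydt[i] = dydt[i] + st * rate * (vhome / vdest)
        return t, ysym, gsym, dydt

    def compile(self):
        """Lambdify the RHS and its Jacobian.  Cached."""
        if self._compiled is not None:
            return self._compiled
        t, ysym, gsym, dydt = self._build_rhs_exprs()
        yargs = [ysym[s.name] for s in self.dynamic_species]
        gargs = [gsym[s.name] for s in self.driven_species]
        args = [t] + yargs + gargs
        f = sp.lambdify(args, dydt, modules="numpy", cse=True)
        jac_mat = sp.Matrix(dydt).jacobian(sp.Matrix(yargs))
        jf = sp.lambdify(args, jac_mat, modules="numpy", cse=True)
        nf = len(gargs)

        def rhs(tt, y, g=()):
            return np.asarray(f(tt, *y, *g), dtype=float)

        def jac(tt, y, g=()):
            return np.asarray(jf(tt, *y, *g), dtype=float)

        self._compiled = (rhs, jac, nf)
        return self._compiled

    # -- public operations --------------------------------------------------
    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.dynamic_species])

    def derivative(self, state: np.ndarray, t: float = 0.0,
                   drives: Optional[Mapping[str, float]] = None) -> np.ndarray:
        """d(state)/dt in µM/s.  Raises on dimension mismatch or negative state."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n,):
            raise ValueError(
                f"state dimension {state.shape} does not match network ({self.n},)"
            )
        if np.any(state < 0):
            bad = self.dynamic_species[int(np.argmin(state))].name
            raise ValueError(
                f"negative concentration in state (species {bad!r}): integrator "
                "contract violated"
            )
        g = self._drive_vector(drives)
        rhs, _, _ = self.compile()
        return rhs(t, state, g)

    def _drive_vector(self, drives: Optional[Mapping[str, float]]) -> np.ndarray:
        g = np.zeros(len(self.driven_species))
        if drives:
            for name, val in drives.items():
                g[self.driven_index[name]] = val
        return g

    def stoichiometric_matrix(self) -> np.ndarray:
        """Amount-based stoichiometric matrix (dynamic species × reactions)."""
        S = np.zeros((self.n, len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for name, st in r.stoichiometry.items():
                i = self.index.get(name)
                if i is not None:
                    S[i, j] = st
        return S

    def conserved_moieties(self) -> List[Dict[str, float]]:
        """Linear combinations of species *amounts* with zero net derivative.

        Returns coefficient maps over dynamic-species names; a law Σ c_i n_i
        (n_i the amount, i.e. concentration × compartment volume) is constant
        along any trajectory.  Computed as the rational left null space of the
        stoichiometric matrix, so the guarantee is symbolic, not numeric.
        """
        S = sp.Matrix(self.stoichiometric_matrix().astype(int))
        laws = []
        for v in S.T.nullspace():
            coeffs = sp.nsimplify(v.T, rational=True)
            denlcm = sp.lcm([sp.fraction(c)[1] for c in coeffs] or [1])
            vec = [sp.simplify(c * denlcm) for c in coeffs]
            law = {
                self.dynamic_species[i].name: float(vec[i])
                for i in range(self.n)
                if vec[i] != 0
            }
            if law:
                laws.append(law)
        return laws

    def moiety_total(self, law: Mapping[str, float], state: np.ndarray) -> float:
        """Evaluate a conservation law on a state vector (amount units µM·µm³)."""
        return float(
            sum(c * state[self.index[name]] * self._volumes[self.index[name]]
                for name, c in law.items())
        )


def assemble_network(document: Mapping) -> Network:
    """Build a :class:`Network` from a declarative model document.

    The document carries keys ``compartments`` (name → volume µm³),
    ``species`` (list of species mappings) and ``reactions`` (list of
    reaction mappings), mirroring the shipped YAML parameter table.
    """
    try:
        comps = [Compartment(name, float(v)) for name, v in document["compartments"].items()]
    except KeyError as e:
        raise NetworkValidationError(f"model document missing key: {e}") from e
    species = []
    for s in document.get("species", []):
        species.append(
            Species(
                name=s["name"],
                compartment=s["compartment"],
                initial_concentration=float(s.get("initial_concentration", 0.0)),
                clamped=bool(s.get("clamped", False)),
                driven=bool(s.get("driven", False)),
            )
        )
    reactions = []
    for r in document.get("reactions", []):
        reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                rate_law=r["rate_law"],
                parameters=dict(r.get("parameters", {})),
                compartment=r.get("compartment", "cytosol"),
                modifiers=list(r.get("modifiers", [])),
                formula=r.get("formula"),
            )
        )
    return Network(comps, species, reactions)


DEFAULT_COMPARTMENTS = {
    "cleft": 0.0015,
    "PSD": 0.002,
    "cytosol": 0.02,
    "ER": 0.002,
}
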