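"""Shared stiff-ODE integration over a compiled Network."""

from __future__ import annotations

from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .core import Network


class SolverError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:.6g} s)")
        self.last_time = last_time


def integrate_network(net: Network, y0: np.ndarray,
                      t_span: Tuple[float, float],
                      drive_fns: Optional[Mapping[str, Callable[[float], float]]] = None,
                      t_eval: Optional[np.ndarray] = None,
                      rtol: float = 1e-8, atol: float = 1e-12,
                      max_step: float = np.inf) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate a network with BDF; returns (t, y[species, time]).

    Driven species read ``drive_fns[name](t)``.  Concentrations may undershoot
    zero by no more than the solver tolerance; they are clipped to zero in the
    returned trajectory (reporting contract), while the raw state is used
    internally for continuation.
    """
    rhs, jac, _ = net.compile()
    order = [net.driven_index[name] for name in (drive_fns or {})]
    fns = list((drive_fns or {}).values())
    nd = len(net.driven_species)

    def g_of(t):
        g = np.zeros(nd)
        for i, fn in zip(order, fns):
            g[i] = fn(t)
        return g

    def f(t, y):
        return rhs(t, y, g_of(t))

    def J(t, y):
        return jac(t, y, g_of(t))

    sol = solve_ivp(f, t_span, y0, method="BDF", jac=J, t_eval=t_eval,
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise SolverError(f"solver failed: {sol.message}",
                          float(sol.t[-1]) if len(sol.t) else t_span[0])
    return sol.t, np.clip(sol.y, 0.0, None)
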