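"""Stimulation protocols, equilibration, and trajectory simulation.

Protocols are ordered lists of vesicular release events (3000 molecules
each).  Named patterns:

* ``single``   one release at t = 0
* ``burst4``   one burst: 4 pulses at 100 Hz
* ``tbs5``     theta-burst: 5 bursts of 4 pulses at 100 Hz, 200 ms between
               burst onsets
* ``tbs9``     9 such bursts
* ``tetanus``  f Hz for 1 s (default 100 Hz)
* ``train``    n pulses at f Hz

Simulations start from the pinned baseline, read cleft glutamate at the
mGluRI location (100 or 1000 nm) and at the PSD (20 nm) from the diffusion
field, and integrate the stiff ODE system with BDF, restarting at each
release time so the kernel onsets never fall inside a solver step.  The
receptor subset under study is selected by zeroing the glutamate input of
the excluded pathway; the baseline is shared across subsets.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cleft import GlutamateField, ReleaseEvent
from .model import SpineModel
from .simulate import integrate_network

RECEPTOR_SUBSETS = ("all", "mglur", "iglur")


@dataclass(frozen=True)
class StimulusProtocol:
    name: str
    events: tuple  # of ReleaseEvent

    @property
    def span(self) -> float:
        return self.events[-1].time if self.events else 0.0


def make_protocol(name: str, frequency: float = 100.0, n_pulses: int = 1,
                  n_bursts: int = 5, burst_interval: float = 0.2,
                  molecules: float = 3000.0) -> StimulusProtocol:
    """Build a named stimulation pattern as an explicit event-time list."""
    if name == "single":
        times = [0.0]
    elif name == "burst4":
        times = [i / 100.0 for i in range(4)]
    elif name in ("tbs5", "tbs9", "tbs"):
        nb = {"tbs5": 5, "tbs9": 9}.get(name, n_bursts)
        times = [b * burst_interval + i / 100.0 for b in range(nb) for i in range(4)]
    elif name == "tetanus":
        if not frequency > 0:
            raise ValueError("tetanus frequency must be positive")
        n = int(round(frequency))
        times = [i / frequency for i in range(n)]
    elif name == "train":
        if not frequency > 0:
            raise ValueError("train frequency must be positive")
        times = [i / frequency for i in range(n_pulses)]
    elif name == "none":
        times = []
    else:
        raise ValueError(f"unknown protocol {name!r}")
    return StimulusProtocol(name, tuple(ReleaseEvent(t, molecules) for t in times))


@dataclass
class SimulationConfig:
    """Run configuration: receptor geometry, transporters, solver knobs."""

    mglur_location_nm: float = 100.0
    iglur_location_nm: float = 20.0
    transporters: bool = True
    receptors: str = "all"  # all | mglur | iglur
    duration: Optional[float] = None      # default: protocol span + post_stimulus
    post_stimulus: float = 20.0           # s simulated past the last release
    rtol: float = 1e-8
    atol: float = 1e-12
    dt_out: float = 1e-3                  # output grid, s

    def __post_init__(self):
        if self.receptors not in RECEPTOR_SUBSETS:
            raise ValueError(f"receptors must be one of {RECEPTOR_SUBSETS}")
        if not self.mglur_location_nm > 0:
            raise ValueError("mGluRI location must be positive")


@dataclass
class SimulationResult:
    """Uniform-grid trajectory plus metadata."""

    time: np.ndarray
    series: Dict[str, np.ndarray]
    config: SimulationConfig
    protocol: StimulusProtocol
    baseline: Dict[str, float]
    solver_stats: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.series[key]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time})
        for k, v in self.series.items():
            df[k] = v
        return df


#: state/readout names exported on the output grid
_EXPORTS = {
    "ca_cyt_uM": "Ca_cyt",
    "ca_psd_uM": "Ca_PSD",
    "ca_er_uM": "Ca_ER",
    "ip3_uM": "IP3",
    "gagtp_uM": "GaGTP",
    "plca_uM": "PLCa",
    "ampa_open": "AMPA_O",
    "nmda_open": "NMDA_O",
}


def equilibrate(model: SpineModel, t_relax: float = 200.0,
                tol: float = 1e-6) -> np.ndarray:
    """Verify/refine the pinned baseline: relax without stimulus and check
    the residual max |dy/dt| (µM/s) against ``tol``."""
    net = model.network
    drives = {"Glu_mglur": lambda t: 0.0, "Glu_psd": lambda t: 0.0}
    t, y = integrate_network(net, model.baseline, (0.0, t_relax),
                             drive_fns=drives, t_eval=np.array([t_relax]),
                             rtol=1e-10, atol=1e-14)
    state = y[:, -1]
    resid = np.abs(net.derivative(state, 0.0)).max()
    if resid > tol:
        raise RuntimeError(
            f"equilibration failed: residual {resid:.3e} µM/s exceeds {tol:.1e}"
        )
    return state


def run_square_pulse(model: SpineModel, glu_uM: float, pulse: float = 1.0,
                     config: Optional[SimulationConfig] = None
                     ) -> SimulationResult:
    """Bath application: clamp glutamate at the mGluRI location to ``glu_uM``
    for ``pulse`` seconds, then back to ambient.  Used for the
    concentration-response characterization of the metabotropic pathway."""
    config = config or SimulationConfig(receptors="mglur")
    net = model.network
    ambient = model.diffusion_params().ambient
    duration = config.duration or (pulse + config.post_stimulus)

    def step(t):
        return glu_uM if t < pulse else ambient

    zero = lambda t: ambient
    drives = {"Glu_mglur": step if config.receptors in ("all", "mglur") else zero,
              "Glu_psd": zero}
    grid = np.round(np.arange(0.0, duration + 0.5 * config.dt_out,
                              config.dt_out), 9)
    y = model.baseline.copy()
    t_all, y_all = [np.array([0.0])], [y[:, None]]
    for a, b in ((0.0, pulse), (pulse, duration)):
        t_eval = grid[(grid > a) & (grid <= b)]
        tt, yy = integrate_network(net, y, (a, b), drive_fns=drives,
                                   t_eval=t_eval, rtol=config.rtol,
                                   atol=config.atol)
        y = yy[:, -1]
        t_all.append(tt)
        y_all.append(yy)
    t = np.concatenate(t_all)
    Y = np.concatenate(y_all, axis=1)
    series = {col: Y[net.index[name]] for col, name in _EXPORTS.items()}
    series["glu_mglur_uM"] = np.array([drives["Glu_mglur"](tt) for tt in t])
    series["glu_psd_uM"] = np.zeros_like(t) + ambient
    baseline = {col: float(model.baseline[net.index[name]])
                for col, name in _EXPORTS.items()}
    return SimulationResult(time=t, series=series, config=config,
                            protocol=StimulusProtocol("square_pulse", ()),
                            baseline=baseline)


def run(model: SpineModel, protocol: StimulusProtocol,
        config: Optional[SimulationConfig] = None) -> SimulationResult:
    """Simulate a protocol from the baseline and sample on a uniform grid."""
    config = config or SimulationConfig()
    net = model.network
    transporters = model.transporter_params() if config.transporters else None
    fieldobj = GlutamateField(list(protocol.events), model.diffusion_params(),
                              transporters)
    ambient = model.diffusion_params().ambient

    def glu_at(r_nm):
        def fn(t):
            return fieldobj.scalar(r_nm, t)
        return fn

    zero = lambda t: ambient
    drives = {
        "Glu_mglur": glu_at(config.mglur_location_nm)
        if config.receptors in ("all", "mglur") else zero,
        "Glu_psd": glu_at(config.iglur_location_nm)
        if config.receptors in ("all", "iglur") else zero,
    }

    duration = config.duration
    if duration is None:
        duration = protocol.span + config.post_stimulus
    if protocol.events and duration <= protocol.span:
        raise ValueError("duration must exceed the protocol span")

    # segment boundaries at release onsets (kernel kinks)
    bounds = sorted({0.0, duration} | {e.time for e in protocol.events
                                       if 0.0 < e.time < duration})
    grid = np.round(np.arange(0.0, duration + 0.5 * config.dt_out,
                              config.dt_out), 9)
    y = model.baseline.copy()
    t_all, y_all = [np.array([0.0])], [y[:, None]]
    wall = _time.perf_counter()
    for a, b in zip(bounds[:-1], bounds[1:]):
        t_eval = grid[(grid > a) & (grid <= b)]
        tt, yy = integrate_network(net, y, (a, b), drive_fns=drives,
                                   t_eval=t_eval if len(t_eval) else None,
                                   rtol=config.rtol, atol=config.atol)
        y = yy[:, -1]
        if len(t_eval):
            t_all.append(tt)
            y_all.append(yy)
    wall = _time.perf_counter() - wall

    t = np.concatenate(t_all)
    Y = np.concatenate(y_all, axis=1)
    series = {col: Y[net.index[name]] for col, name in _EXPORTS.items()}
    series["glu_mglur_uM"] = np.array([drives["Glu_mglur"](tt) for tt in t])
    series["glu_psd_uM"] = np.array([drives["Glu_psd"](tt) for tt in t])
    baseline = {col: float(model.baseline[net.index[name]])
                for col, name in _EXPORTS.items()}
    return SimulationResult(
        time=t, series=series, config=config, protocol=protocol,
        baseline=baseline,
        solver_stats={"wall_time_s": wall, "n_segments": len(bounds) - 1,
                      "n_points": len(t)},
    )
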