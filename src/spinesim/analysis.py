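"""Quantification of simulated transients.

AUC is the left-endpoint Riemann sum of the above-baseline signal on the
uniform 1 ms output grid; figure-style normalizations divide by a named
reference AUC.  Concentration-response curves are fitted with a four-
parameter logistic on log-dose; transient decays with a mono-exponential
from the post-stimulus peak to the end of the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit


class FitQualityError(RuntimeError):
    """Input does not determine the requested fit."""


@dataclass
class AUCResult:
    """Above-baseline area (µM·s) with optional fold normalization."""

    value: float
    baseline: float
    reference: Optional[float] = None

    @property
    def normalized(self) -> Optional[float]:
        return None if self.reference is None else self.value / self.reference


def auc_riemann(t: np.ndarray, y: np.ndarray, baseline: float,
                reference: Optional[float] = None,
                rtol_grid: float = 1e-6) -> AUCResult:
    """Left-endpoint Riemann sum of (y - baseline) over a uniform grid."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > rtol_grid * dt[0]:
        raise ValueError("non-uniform grid: resample before integrating")
    value = float(np.sum((y[:-1] - baseline) * dt[0]))
    return AUCResult(value=value, baseline=baseline, reference=reference)


@dataclass
class HillFit:
    ec50: float
    hill: float
    top: float
    bottom: float
    residual: float

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ec50 / np.maximum(d, 1e-300)) ** self.hill)


def fit_hill(dose: Sequence[float], response: Sequence[float]) -> HillFit:
    """Least-squares 4-parameter logistic on log-dose.

    Requires at least four points spanning the transition (the response range
    must not be degenerate); raises :class:`FitQualityError` otherwise.
    """
    d = np.asarray(dose, dtype=float)
    r = np.asarray(response, dtype=float)
    if len(d) < 4:
        raise FitQualityError("need >= 4 dose points for a 4-parameter fit")
    if np.ptp(r) <= 0:
        raise FitQualityError("flat response: transition not spanned")
    order = np.argsort(d)
    d, r = d[order], r[order]
    pos = d > 0
    bottom0, top0 = float(r[0]), float(r[-1])
    half = bottom0 + 0.5 * (top0 - bottom0)
    ec50_0 = float(np.interp(half, r[pos], d[pos])) if top0 > bottom0 else np.median(d[pos])

    def model(x, log_ec50, hill, top, bottom):
        return bottom + (top - bottom) / (1.0 + (np.exp(log_ec50) / x) ** hill)

    try:
        popt, _ = curve_fit(
            model, d[pos], r[pos],
            p0=[np.log(max(ec50_0, d[pos].min())), 1.0, top0, bottom0],
            maxfev=20000)
    except RuntimeError as e:  # pragma: no cover
        raise FitQualityError(f"logistic fit failed: {e}") from e
    log_ec50, hill, top, bottom = popt
    resid = float(np.sqrt(np.mean((model(d[pos], *popt) - r[pos]) ** 2)))
    fit = HillFit(ec50=float(np.exp(log_ec50)), hill=float(hill),
                  top=float(top), bottom=float(bottom), residual=resid)
    if not fit.ec50 > 0:  # pragma: no cover
        raise FitQualityError("nonpositive EC50")
    return fit


@dataclass
class DecayFit:
    tau: float
    amplitude: float
    baseline: float
    t_start: float
    residual: float


def fit_mono_exponential_decay(t: np.ndarray, y: np.ndarray,
                               from_time: Optional[float] = None,
                               baseline: Optional[float] = None) -> DecayFit:
    """Fit baseline + A*exp(-(t-t_peak)/tau) from the (post-``from_time``)
    global maximum to the end of the record."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = slice(None) if from_time is None else t >= from_time
    ts, ys = t[sel], y[sel]
    if len(ts) < 4:
        raise FitQualityError("decay window too short")
    ipk = int(np.argmax(ys))
    ts, ys = ts[ipk:], ys[ipk:]
    if len(ts) < 4 or ys[-1] >= ys[0]:
        raise FitQualityError("segment after peak is not decaying")
    t0 = ts[0]

    def decay(tt, tau):
        # |tau| guards the optimizer's sign excursions
        return np.exp(-np.minimum((tt - t0) / max(abs(tau), 1e-9), 700.0))

    if baseline is None:
        def model(tt, tau, A, b):
            return b + A * decay(tt, tau)
        p0 = [max((ts[-1] - t0) / 3.0, 1e-3), ys[0] - ys[-1], ys[-1]]
    else:
        def model(tt, tau, A):
            return baseline + A * decay(tt, tau)
        p0 = [max((ts[-1] - t0) / 3.0, 1e-3), ys[0] - baseline]
    try:
        popt, _ = curve_fit(model, ts, ys, p0=p0, maxfev=20000)
    except RuntimeError as e:  # pragma: no cover
        raise FitQualityError(f"decay fit failed: {e}") from e
    tau = float(abs(popt[0]))
    A = float(popt[1])
    b = float(baseline if baseline is not None else popt[2])
    resid = float(np.sqrt(np.mean((model(ts, *popt) - ys) ** 2)))
    if tau <= 0:  # pragma: no cover
        raise FitQualityError("nonpositive time constant")
    return DecayFit(tau=tau, amplitude=A, baseline=b, t_start=t0, residual=resid)


def transient_duration(t: np.ndarray, y: np.ndarray, baseline: float,
                       fraction: float = 0.01) -> float:
    """Duration of a transient: time from onset until the signal last falls
    below ``fraction`` of its peak amplitude above baseline."""
    y = np.asarray(y, dtype=float) - baseline
    peak = y.max()
    if peak <= 0:
        return 0.0
    above = np.nonzero(y > fraction * peak)[0]
    return float(t[above[-1]] - t[above[0]])


def contribution_decomposition(model, protocol, config=None) -> Dict:
    """AUC table for the receptor subsets {mGluRI-only, AMPA/NMDA-only, all}
    sharing one baseline and protocol, with additivity indices
    AUC(all) / (AUC(mGluRI) + AUC(iGluR)) for calcium and IP3."""
    from .protocols import SimulationConfig, run
    from dataclasses import replace
    config = config or SimulationConfig()
    out = {"ca": {}, "ip3": {}}
    for subset in ("mglur", "iglur", "all"):
        res = run(model, protocol, replace(config, receptors=subset))
        for key, col in (("ca", "ca_cyt_uM"), ("ip3", "ip3_uM")):
            out[key][subset] = auc_riemann(res.time, res[col],
                                           res.baseline[col]).value
    for key in ("ca", "ip3"):
        denom = out[key]["mglur"] + out[key]["iglur"]
        out[key]["additivity_index"] = out[key]["all"] / denom if denom > 0 else np.nan
    return out
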