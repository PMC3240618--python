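#!/usr/bin/env python
"""Staged calibration of the spine-model rate constants against its anchors.

The kinetic scheme families are fixed; this script tunes the handful of
constants that the anchor measurements pin down, in dependency order:

  A  Kd_glu               -> receptor binding EC50 0.56 µM (10-s pulses).
                             With equal cube affinities the ensemble binds
                             hyperbolically with midpoint
                             Kd_glu*(1+Ka0)/(1+Ka1), so this converges in
                             one secant step.
  B  k_cat                -> GalphaGTP concentration-response EC50 5.6 µM.
                             The equilibrium GaGTP curve is a Moebius
                             transform of occupancy — an exact hyperbola
                             with midpoint Kocc*(1-p0)/(1-pm); k_cat sets
                             pm (saturating exchange over GAP capacity).
  C  ip3r_permeability    -> 200 nM cytosolic Ca peak (5 releases at 50 Hz,
                             mGluRI only, 100 nm), and
     ip3_source           -> 800 ms mono-exponential decay.  Baseline
                             pinning ties the 5-phosphatase Vmax to total
                             basal production, so the constitutive IP3
                             source sets basal IP3 turnover — which the Ca
                             transient tracks (the pumps are not
                             rate-limiting) — independently of the cascade
                             gain k_pip2.  Iterated; the two interact.
  D  nmda_ca_coefficient  -> full-model single-release Ca peak 516 nM
                             (bisection: the response is steeply convex
                             near the CICR threshold).

The glutamate-field constants (h*alpha and transporter k_bind) follow from
the 40/32 µM peak anchors: h*alpha in closed form, k_bind by bisection on
the uptake PDE (stage G below, optional).

Run from the repository root:

    python scripts/calibrate_model.py [--rounds 1] [--skip A,B]

and copy the printed parameter block into src/spinesim/data/params.yaml.
"""

import argparse
import copy
import sys

import numpy as np

from spinesim.analysis import fit_mono_exponential_decay, transient_duration
from spinesim.cleft import (DiffusionParams, GlutamateField, ReleaseEvent,
                            TransporterParams)
from spinesim.mglur import galphagtp_dose_response, glutamate_binding_curve
from spinesim.model import build_model, load_default_params
from spinesim.protocols import SimulationConfig, make_protocol, run


def secant(fun, x0, target, rel_step=0.1, iters=6, tol=0.01, clip=(0.45, 2.2)):
    x1 = x0 * (1 + rel_step)
    f0, f1 = fun(x0), fun(x1)
    print(f"    x={x0:.5g} f={f0:.5g}; x={x1:.5g} f={f1:.5g} (target {target})")
    for _ in range(iters):
        if abs(f1 / target - 1) < tol:
            break
        if f1 == f0:
            break
        x2 = x1 + (target - f1) * (x1 - x0) / (f1 - f0)
        x2 = max(min(x2, x1 * clip[1]), x1 * clip[0])
        x0, f0 = x1, f1
        x1, f1 = x2, fun(x2)
        print(f"    -> x={x1:.5g} f={f1:.5g}")
    return x1, f1


def transient(params):
    model = build_model(copy.deepcopy(params))
    res = run(model, make_protocol("train", frequency=50.0, n_pulses=5),
              SimulationConfig(receptors="mglur", mglur_location_nm=100.0,
                               post_stimulus=15.0))
    t, ca = res.time, res["ca_cyt_uM"]
    fit = fit_mono_exponential_decay(t, ca, from_time=float(t[ca.argmax()]),
                                     baseline=0.06)
    return (float(ca.max()), fit.tau, float(res["ip3_uM"].max()),
            transient_duration(t, ca, 0.06))


def single_all(params):
    model = build_model(copy.deepcopy(params))
    res = run(model, make_protocol("single"),
              SimulationConfig(receptors="all", post_stimulus=10.0))
    return float(res["ca_cyt_uM"].max()), float(res["ip3_uM"].max())


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--rounds", type=int, default=1)
    ap.add_argument("--skip", default="", help="comma list of stages to skip")
    args = ap.parse_args()
    skip = set(args.skip.split(",")) if args.skip else set()
    params = load_default_params()

    if "G" not in skip:
        print("[G] transporter k_bind -> 32 µM peak at 1000 nm")
        t = np.arange(0.0, 1.0, 2e-5)
        dp = DiffusionParams(**params["diffusion"])
        lo, hi = 0.05, 20.0
        for _ in range(40):
            mid = (lo * hi) ** 0.5
            tp = TransporterParams(**{**params["transporters"], "k_bind": mid})
            pk = GlutamateField([ReleaseEvent(0.0)], dp, tp).concentration(
                1000.0, t).max()
            if pk > 32.0:
                lo = mid
            else:
                hi = mid
        params["transporters"]["k_bind"] = mid
        print(f"  k_bind = {mid:.5g} (peak {pk:.2f} µM)")

    for rnd in range(args.rounds):
        print(f"== round {rnd + 1} ==")
        if "A" not in skip:
            print("  [A] binding EC50 -> 0.56 µM via Kd_glu")
            def fa(x):
                params["mglur"]["Kd_glu"] = x
                return glutamate_binding_curve(params["mglur"]).ec50
            params["mglur"]["Kd_glu"], got = secant(
                fa, params["mglur"]["Kd_glu"], 0.56, rel_step=0.3)
            print(f"  Kd_glu = {params['mglur']['Kd_glu']:.5g} (EC50 {got:.4g})")

        if "B" not in skip:
            print("  [B] GaGTP EC50 -> 5.6 µM via k_cat")
            def fb(x):
                params["mglur"]["k_cat"] = x
                return galphagtp_dose_response(params["mglur"]).ec50
            params["mglur"]["k_cat"], got = secant(
                fb, params["mglur"]["k_cat"], 5.6, rel_step=0.08)
            print(f"  k_cat = {params['mglur']['k_cat']:.5g} (EC50 {got:.4g})")

        if "C" not in skip:
            print("  [C] Ca peak 200 nM / tau 800 ms via perm + ip3_source")
            for _ in range(3):
                def fc(x):
                    params["ip3r"]["ip3r_permeability"] = x
                    return transient(params)[0]
                params["ip3r"]["ip3r_permeability"], _ = secant(
                    fc, params["ip3r"]["ip3r_permeability"], 0.2,
                    rel_step=0.07, clip=(0.6, 1.6))
                def ft(x):
                    params["mglur"]["ip3_source"] = x
                    return 1.0 / transient(params)[1]  # tau falls as source rises
                params["mglur"]["ip3_source"], _ = secant(
                    ft, params["mglur"]["ip3_source"], 1.0 / 0.8,
                    rel_step=0.25, tol=0.025)
                pk, tau, ip3pk, dur = transient(params)
                print(f"    perm={params['ip3r']['ip3r_permeability']:.4g} "
                      f"ip3_source={params['mglur']['ip3_source']:.4g}: "
                      f"peak={pk * 1e3:.1f} nM tau={tau:.3f} s "
                      f"duration={dur:.2f} s IP3={ip3pk * 1e3:.0f} nM")

        if "D" not in skip:
            print("  [D] full-model single-release Ca peak -> 516 nM (bisect)")
            lo, hi = 1000.0, 20000.0
            for _ in range(16):
                mid = 0.5 * (lo + hi)
                params["iglur"]["nmda_ca_coefficient"] = mid
                ca1, ip31 = single_all(params)
                if abs(ca1 * 1e3 - 516) < 2:
                    break
                if ca1 * 1e3 < 516:
                    lo = mid
                else:
                    hi = mid
            print(f"  c_nmda = {mid:.1f} (Ca {ca1 * 1e3:.0f} nM, "
                  f"IP3 {ip31 * 1e3:.0f} nM)")

    print("\n== final calibrated values ==")
    for sect, key in [("transporters", "k_bind"), ("mglur", "Kd_glu"),
                      ("mglur", "k_cat"), ("mglur", "k_pip2"),
                      ("ip3r", "ip3r_permeability"),
                      ("iglur", "nmda_ca_coefficient")]:
        print(f"  {sect}.{key}: {params[sect][key]:.6g}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
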