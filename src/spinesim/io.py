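"""Configuration loading/validation, result serialization, run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("spinesim")


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


#: section -> key -> predicate description; every listed key must be present
#: and satisfy the predicate
_POSITIVE = ("must be > 0", lambda v: isinstance(v, (int, float)) and v > 0)
_NONNEG = ("must be >= 0", lambda v: isinstance(v, (int, float)) and v >= 0)
_SCHEMA = {
    "compartments": {name: _POSITIVE for name in ("cleft", "PSD", "cytosol", "ER")},
    "diffusion": {"D": _POSITIVE, "height": _POSITIVE,
                  "alpha": ("must lie in (0, 1]",
                            lambda v: isinstance(v, (int, float)) and 0 < v <= 1),
                  "sigma0": _POSITIVE, "ambient": _NONNEG},
    "transporters": {"density": _NONNEG, "exclusion_radius": _NONNEG,
                     "k_bind": _NONNEG, "k_unbind": _NONNEG,
                     "k_translocate": _NONNEG},
    "mglur": {k: _POSITIVE for k in
              ("R_total", "G_total", "PLC_total", "PIP2_total", "kon_glu",
               "Kd_glu", "Ka0", "Ka1", "k_act", "kon_G", "Kd_G", "k_cat",
               "k_hyd", "k_reassoc", "kon_plc", "koff_plc", "k_gap",
               "K_plc_ca", "k_pip2", "k_pip2_rep", "V_3k", "Km_3k",
               "K_3k_ca", "n_3k_ca", "ip3_source", "V_5p", "Km_5p", "k_dag_clear", "k_ip2_clear",
               "k_ip4_clear")},
    "ip3r": {"ip3r_permeability": _POSITIVE,
             "ip3r_subunits_required": ("must be 3 or 4", lambda v: v in (3, 4)),
             "serca_vmax": _POSITIVE, "serca_K": _POSITIVE},
    "calcium": {k: _POSITIVE for k in
                ("ca_cleft_rest", "ca_er_rest", "pmca_vmax", "pmca_K",
                 "ncx_vmax", "ncx_K", "pm_leak", "k_ex_ca", "k_ex_ip3")},
    "iglur": {"n_ampa": _NONNEG, "n_nmda": _NONNEG,
              "nmda_ca_coefficient": _NONNEG},
    "geometry": {"mglur_location_nm": _POSITIVE, "iglur_location_nm": _POSITIVE},
}


def validate_params(params: Dict) -> Dict:
    """Validate a parameter table against the schema; returns it unchanged."""
    if not isinstance(params, dict):
        raise ConfigError("parameter document must be a mapping")
    for section, keys in _SCHEMA.items():
        if section not in params:
            raise ConfigError(f"missing section {section!r}")
        for key, (desc, pred) in keys.items():
            if key not in params[section]:
                raise ConfigError(f"missing key {section}.{key}")
            if not pred(params[section][key]):
                raise ConfigError(
                    f"invalid value for {section}.{key}: "
                    f"{params[section][key]!r} ({desc})")
    return params


def load_config(path) -> Dict:
    """Load and validate a model parameter YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        params = yaml.safe_load(fh)
    validate_params(params)
    logger.info("loaded config %s (hash %s)", path, params_hash(params))
    return params


def save_config(params: Dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def params_hash(params: Dict) -> str:
    """Stable short hash of a parameter table."""
    blob = json.dumps(params, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically: the full config
    snapshot, parameter hash, package version and solver statistics."""

    params: Dict
    protocol_name: str
    config: Dict
    solver_stats: Dict
    version: str = ""
    parameter_hash: str = ""

    def __post_init__(self):
        from . import __version__
        if not self.version:
            self.version = __version__
        if not self.parameter_hash:
            self.parameter_hash = params_hash(self.params)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=float)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def manifest_for(result, model) -> RunManifest:
    from dataclasses import asdict as dc_asdict
    params = {k: v for k, v in model.params.items() if not k.startswith("_")}
    return RunManifest(params=params,
                       protocol_name=result.protocol.name,
                       config=dc_asdict(result.config),
                       solver_stats=dict(result.solver_stats))


def write_result(result, model, out_csv, out_manifest: Optional[str] = None
                 ) -> None:
    """CSV trace (RFC-4180, header row) plus a JSON manifest sidecar."""
    df = result.to_frame()
    df.to_csv(out_csv, index=False)
    if out_manifest is None:
        out_manifest = str(Path(out_csv).with_suffix(".manifest.json"))
    Path(out_manifest).write_text(manifest_for(result, model).to_json())
    logger.info("wrote %s (%d rows) and %s", out_csv, len(df), out_manifest)
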