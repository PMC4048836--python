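"""Configuration files, typed TSV tables, and reproducible run manifests.

Analysis outputs are TSV with a ``#``-prefixed metadata header (keys, units,
column names); numeric columns round-trip at full double precision.  Every
simulation output is accompanied by a JSON manifest recording the full
parameter set, seeds, package version, wall-clock bounds and content digests
of the files written, so a run can be reproduced bit-for-bit (KMC event
sequences) or to solver tolerance (adaptive ODE).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .lattice import KmcParams, er_params, invitro_params
from .mean_field import MeanFieldParams

__all__ = [
    "load_config",
    "write_table",
    "read_table",
    "RunManifest",
    "file_digest",
]

_MF_KEYS = {"k_in", "k_out", "k_p", "k_f", "k_A", "k_L", "c", "i_max"}
_KMC_KEYS = {"k_D", "k_H", "k_R", "k_E", "k_K", "k_A", "k_L", "k_f", "k_in",
             "k_out", "efflux_exponent"}
_META_KEYS = {"model", "preset", "seed", "t_max", "n_samples", "geometry",
              "rho", "N_m", "boundary_mode"}


def load_config(path) -> dict:
    """Load and validate a flat key-value (YAML) configuration file.

    Returns a dict with a ``params`` entry holding a validated
    :class:`MeanFieldParams` or :class:`KmcParams` (per the ``model`` key)
    plus the run-control keys.  Unknown keys are rejected with their path;
    presets ``invitro``/``er`` expand to the corresponding rate conventions.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key-value mapping")
    model = raw.get("model")
    if model not in ("mean_field", "kmc"):
        raise ConfigError("config key 'model' must be 'mean_field' or 'kmc'")
    allowed = (_MF_KEYS if model == "mean_field" else _KMC_KEYS) | _META_KEYS
    for key in raw:
        if key not in allowed:
            raise ConfigError(f"unknown config key: {key!r}")
    rate_keys = _MF_KEYS if model == "mean_field" else _KMC_KEYS
    kwargs = {k: raw[k] for k in rate_keys if k in raw}
    try:
        if model == "mean_field":
            params = MeanFieldParams(**kwargs)
        else:
            preset = raw.get("preset")
            if preset == "invitro":
                base = invitro_params(
                    k_f=raw.get("k_f", 0.0), k_L=raw.get("k_L", 0.0)
                )
                params = base
            elif preset == "er":
                params = er_params(k_in=raw.get("k_in", 1.0),
                                   k_out=raw.get("k_out", 0.0))
            elif preset is None:
                params = KmcParams(**kwargs)
            else:
                raise ConfigError(f"unknown preset {preset!r}")
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    out = {k: raw[k] for k in _META_KEYS if k in raw}
    out["params"] = params
    return out


def write_table(path, df: pd.DataFrame, metadata: Optional[Dict] = None) -> None:
    """Write a TSV with '#'-prefixed metadata header, full float precision."""
    path = Path(path)
    lines = []
    meta = dict(metadata or {})
    meta.setdefault("aggrophase_version", __version__)
    for k, v in meta.items():
        lines.append(f"# {k}: {json.dumps(v) if not isinstance(v, str) else v}")
    header = "\n".join(lines)
    body = df.to_csv(sep="\t", index=False, float_format="%.17g")
    path.write_text((header + "\n" if header else "") + body)


def read_table(path) -> tuple:
    """Read a TSV written by :func:`write_table`; returns (DataFrame, meta)."""
    path = Path(path)
    meta = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" not in stripped:
                    raise ConfigError(f"malformed metadata line: {line!r}")
                k, v = stripped.split(":", 1)
                v = v.strip()
                try:
                    meta[k.strip()] = json.loads(v)
                except (json.JSONDecodeError, ValueError):
                    meta[k.strip()] = v
            else:
                rows.append(line)
    if not rows:
        raise ConfigError("table has no header row")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), sep="\t",
                     float_precision="round_trip")
    return df, meta


def file_digest(path) -> str:
    """SHA-256 hex digest of a file's content."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record accompanying every simulation output."""

    parameters: dict
    seed: Optional[int]
    version: str = __version__
    started: float = field(default_factory=time.time)
    finished: Optional[float] = None
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> digest

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def close(self) -> None:
        self.finished = time.time()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=_json_default) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
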