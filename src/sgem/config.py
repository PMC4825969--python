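"""YAML/JSON config files for simulation protocols and model parameters.

Layout::

    protocol:
      t_end: 240.0
      dt: 0.01
      n_paths: 2000
      seed: 1
    model:
      alpha: 1.0e-6
      beta: 6

Both blocks are optional; missing keys fall back to the package defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import InvalidInputError
from .grid import SimulationProtocol
from .stochastic import SGEMParams

__all__ = ["load_config"]


def load_config(path: str | Path) -> tuple[SimulationProtocol, SGEMParams]:
    """Parse a config file into a (protocol, model-params) pair."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    proto_kw = dict(raw.get("protocol", {}))
    model_kw = dict(raw.get("model", {}))
    unknown = set(raw) - {"protocol", "model"}
    if unknown:
        raise InvalidInputError(f"{path}: unknown config blocks {sorted(unknown)}")
    try:
        protocol = SimulationProtocol(**proto_kw)
        params = SGEMParams(**model_kw)
    except TypeError as exc:
        raise InvalidInputError(f"{path}: bad config key ({exc})") from None
    return protocol, params
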