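"""Pipeline configuration.

Every numeric threshold of the pipeline (glucose bands, CGM timing, beat
window arithmetic, voting windows, ...) lives in ``defaults.yaml`` next to
this module and is loaded into one nested dictionary.  Code never hard-codes
these constants; it asks the config.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Any, Mapping

import yaml


def load_config(path: str | None = None, overrides: Mapping[str, Any] | None = None) -> dict:
    """Load the pipeline configuration.

    Parameters
    ----------
    path:
        Optional YAML file; when omitted the packaged ``defaults.yaml`` is used.
    overrides:
        Nested mapping merged on top of the loaded file.
    """
    if path is None:
        text = resources.files("ecglow").joinpath("defaults.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _merge(base: dict, upd: Mapping[str, Any]) -> dict:
    out = copy.deepcopy(base)
    for key, value in upd.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


DEFAULTS: dict = load_config()
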