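"""Access to the packaged default simulation presets (YAML)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

__all__ = ["load_presets"]


@lru_cache(maxsize=1)
def load_presets() -> dict:
    """Return the packaged preset tree (parsed once, cached)."""
    text = resources.files("kirquant").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)
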