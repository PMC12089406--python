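"""Element property tables (covalent and van der Waals radii, Å).

The tables ship as YAML data files so they can be audited and swapped
without touching code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=None)
def _load(name: str) -> dict[str, float]:
    text = resources.files("nacsel.data").joinpath(name).read_text()
    raw = yaml.safe_load(text)
    return {str(k).upper(): float(v) for k, v in raw.items()}


def covalent_radius(element: str) -> float:
    """Single-bond covalent radius in Å. Unknown elements fall back to 1.5 Å."""
    return _load("covalent_radii.yaml").get(element.upper(), 1.5)


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å. Unknown elements fall back to 1.7 Å."""
    return _load("vdw_radii.yaml").get(element.upper(), 1.7)


def is_valid_element(symbol: str) -> bool:
    """True for symbols present in the shipped covalent-radius table."""
    return symbol.upper() in _load("covalent_radii.yaml")
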