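"""Monoisotopic element masses and charged-species conventions.

The mass table ships as a small JSON data file so that the set of supported
elements (C, H, D, N, O, P -- all that lipid MRM work needs) is declarative.
Charged-species arithmetic uses the proton mass and neglects the electron
mass (< 0.0006 Da, far below unit-resolution reporting).
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["MONOISOTOPIC_MASS", "PROTON_MASS", "DEUTERIUM_SHIFT"]


def _load_masses() -> dict[str, float]:
    path = resources.files("lipidmrm").joinpath("data/element_masses.json")
    with path.open() as fh:
        return json.load(fh)


#: Monoisotopic atomic masses (Da), keyed by element symbol. ``D`` is deuterium.
MONOISOTOPIC_MASS: dict[str, float] = _load_masses()

#: Mass of a proton (Da); electron mass neglected.
PROTON_MASS: float = 1.00728

#: Mass increment of one H -> D substitution (Da).
DEUTERIUM_SHIFT: float = MONOISOTOPIC_MASS["D"] - MONOISOTOPIC_MASS["H"]
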