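"""Named-atom distance/angle measurements over a structure.

Atoms are addressed by a compact spec string:

    ``chain/resid/name``   e.g. ``A/170/OG1``
    ``resname/name``       e.g. ``DK2/OH7`` (first matching residue)

Distances report in Å, angles in degrees; report rounding (0.1 Å, 1°)
happens at the rendering layer, full precision is retained in JSON.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .nac import oh_geometry
from .structure import ConformerEnsemble

__all__ = ["find_atom", "measure_distance", "measure_angle"]


def find_atom(ensemble: ConformerEnsemble, spec: str) -> int:
    """Resolve an atom spec to a topology index; lists near-matches on miss."""
    parts = spec.split("/")
    if len(parts) == 3:
        chain, resid_s, name = parts
        try:
            resid = int(resid_s)
        except ValueError as exc:
            raise InputError(f"bad residue id in atom spec {spec!r}") from exc
        hits = [
            i for i, a in enumerate(ensemble.topology)
            if a.chain == chain and a.residue_id == resid and a.name == name
        ]
        near = [
            f"{a.chain}/{a.residue_id}/{a.name}"
            for a in ensemble.topology
            if a.chain == chain and a.residue_id == resid
        ]
    elif len(parts) == 2:
        resname, name = parts
        hits = [
            i for i, a in enumerate(ensemble.topology)
            if a.residue_name == resname and a.name == name
        ]
        near = [
            f"{a.residue_name}/{a.name}"
            for a in ensemble.topology
            if a.residue_name == resname
        ]
    else:
        raise InputError(f"atom spec {spec!r}: use chain/resid/name or resname/name")
    if not hits:
        raise InputError(
            f"no atom matches {spec!r}; atoms in that residue: {sorted(set(near))[:20]}"
        )
    return hits[0]


def measure_distance(ensemble: ConformerEnsemble, spec_a: str, spec_b: str,
                     frame: int = 0) -> float:
    xyz = ensemble.coords(frame)
    ia, ib = find_atom(ensemble, spec_a), find_atom(ensemble, spec_b)
    return float(np.linalg.norm(xyz[ia] - xyz[ib]))


def measure_angle(ensemble: ConformerEnsemble, spec_a: str, spec_b: str,
                  spec_c: str, frame: int = 0) -> float:
    """Angle a-b-c in degrees (vertex at b)."""
    xyz = ensemble.coords(frame)
    ia = find_atom(ensemble, spec_a)
    ib = find_atom(ensemble, spec_b)
    ic = find_atom(ensemble, spec_c)
    _, theta = oh_geometry(xyz[ia], xyz[ib], xyz[ic])
    return theta
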