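"""Synthetic active sites, substrates and planted-truth conformer ensembles.

Everything here is geometric fixture generation, not molecular mechanics:
a truncated octahedral Fe(IV)=O "theozyme" site (two methylimidazole N
donors for the His pair, two acetate O donors for Asp/succinate, one water),
idealized 2,5-diketopiperazine (DKP) substrates carrying the labelled
candidate C-H sites of the bicyclomycin pathway intermediates, and conformer
ensembles in which each frame rigidly re-poses the substrate either into a
near-attack pose at a chosen target site (with margin inside the criterion)
or into a pose where every site is safely inactive.  The per-frame truth is
recorded in a ledger, so tally recovery can be asserted exactly rather than
statistically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .chem import classify_carbon_sites, infer_bonds, load_site_labels, place_hydrogens
from .errors import GeometryError, ValidationError
from .nac import NACCriteria
from .structure import Atom, ConformerEnsemble

__all__ = [
    "TheozymeSpec",
    "PlantLedger",
    "build_theozyme",
    "build_dkp",
    "combine",
    "sample_nac_ensemble",
]


# ---------------------------------------------------------------- geometry --

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle(b,c,d) and torsion(a,b,c,d)."""
    theta, phi = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise GeometryError("collinear reference atoms in internal-coordinate build")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(phi),
         bond * np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _align_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp -= np.dot(perp, u) * u
        return _rotation_about(perp, np.pi)
    return _rotation_about(axis / s, float(np.arctan2(s, c)))


def _mkatoms(records: list[tuple], start_serial: int = 0) -> list[Atom]:
    atoms = []
    for k, (name, element, resname, resid, chain, kind, pos) in enumerate(records):
        atoms.append(
            Atom(
                serial=start_serial + k, name=name, element=element,
                residue_name=resname, residue_id=resid, chain=chain,
                record_kind=kind, position=tuple(float(x) for x in pos),
            )
        )
    return atoms


# --------------------------------------------------------------- theozyme --

@dataclasses.dataclass
class TheozymeSpec:
    """Parameters of the truncated octahedral Fe(IV)=O site.

    The 1.62 Å default ferryl bond is a conventional Fe(IV)=O length, kept
    configurable; first-shell donor distances are idealized coordination
    values.
    """

    fe_oxo_length: float = 1.62
    fe_n_length: float = 2.10  # imidazole N donors
    fe_o_carboxylate: float = 2.00  # acetate O donors
    fe_o_water: float = 2.20


def _methylimidazole(attach_axis: np.ndarray, fe_n: float) -> list[tuple[str, str, np.ndarray]]:
    """Planar 5-ring + exocyclic methyl; coordinating N3 along attach_axis."""
    axis = attach_axis / np.linalg.norm(attach_axis)
    perp = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(perp, axis)) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp = perp - np.dot(perp, axis) * axis
    perp /= np.linalg.norm(perp)
    ring_r = 1.17  # pentagon circumradius -> ~1.37 Å edges
    center = axis * (fe_n + ring_r)
    names = ["N3", "C4", "C5", "N1", "C2"]
    elements = ["N", "C", "C", "N", "C"]
    out = []
    pent = []
    for k in range(5):
        ang = np.pi + 2 * np.pi * k / 5  # vertex 0 points back toward Fe
        pos = center + ring_r * (np.cos(ang) * axis + np.sin(ang) * perp)
        pent.append(pos)
        out.append((names[k], elements[k], pos))
    n1 = pent[3]
    methyl_dir = n1 - center
    out.append(("CM", "C", n1 + 1.47 * methyl_dir / np.linalg.norm(methyl_dir)))
    return out


def _acetate(attach_axis: np.ndarray, fe_o: float) -> list[tuple[str, str, np.ndarray]]:
    axis = attach_axis / np.linalg.norm(attach_axis)
    perp = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(perp, axis)) > 0.9:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp - np.dot(perp, axis) * axis
    perp /= np.linalg.norm(perp)
    o1 = axis * fe_o
    c = o1 + 1.27 * axis
    cos120, sin120 = np.cos(np.radians(60)), np.sin(np.radians(60))
    o2 = c + 1.25 * (cos120 * axis + sin120 * perp)
    c2 = c + 1.50 * (cos120 * axis - sin120 * perp)
    return [("O1", "O", o1), ("C", "C", c), ("O2", "O", o2), ("C2", "C", c2)]


def build_theozyme(spec: TheozymeSpec | None = None) -> ConformerEnsemble:
    """One-frame ensemble of the idealized Fe(IV)=O active-site model.

    Fe sits at the origin with the oxo oxygen on +z at ``fe_oxo_length``;
    the five remaining octahedral positions carry two methylimidazole N
    donors (±x), two acetate O donors (±y) and one water (-z).
    """
    spec = spec or TheozymeSpec()
    records: list[tuple] = []
    records.append(("FE", "FE", "FE", 1, "A", "hetero", np.zeros(3)))
    records.append(("O1", "O", "OXO", 2, "A", "hetero",
                    np.array([0.0, 0.0, spec.fe_oxo_length])))
    records.append(("O", "O", "HOH", 3, "A", "water",
                    np.array([0.0, 0.0, -spec.fe_o_water])))
    resid = 4
    for sign in (1.0, -1.0):
        for name, el, pos in _methylimidazole(np.array([sign, 0.0, 0.0]), spec.fe_n_length):
            records.append((name, el, "MIM", resid, "A", "hetero", pos))
        resid += 1
    for sign in (1.0, -1.0):
        for name, el, pos in _acetate(np.array([0.0, sign, 0.0]), spec.fe_o_carboxylate):
            records.append((name, el, "ACT", resid, "A", "hetero", pos))
        resid += 1
    atoms = _mkatoms(records)
    coords = np.array([a.position for a in atoms])
    return ConformerEnsemble(atoms, [coords])


# -------------------------------------------------------------- substrates --

def _dkp_heavy_atoms(substrate_id: int) -> list[tuple[str, str, np.ndarray]]:
    """Heavy-atom skeleton: DKP ring + leucine-like and isoleucine-like side
    chains, with the hydroxyl decorations that distinguish substrates 2/3."""
    s = 1.45  # hexagon edge ~= ring bond length
    ring_names = ["N1", "CO1", "CA1", "N2", "CO2", "CA2"]
    ring_elements = ["N", "C", "C", "N", "C", "C"]
    pos = {}
    for k, name in enumerate(ring_names):
        ang = 2 * np.pi * k / 6
        z = 0.25 if name == "CA1" else (-0.25 if name == "CA2" else 0.0)  # sp3 pucker
        pos[name] = np.array([s * np.cos(ang), s * np.sin(ang), z])
    # carbonyl oxygens, radially outward in the amide plane
    for co in ("CO1", "CO2"):
        out_dir = pos[co] / np.linalg.norm(pos[co][:2].tolist() + [0.0])
        out_dir = np.array([out_dir[0], out_dir[1], 0.0])
        pos["O" + co[-1]] = pos[co] + 1.23 * out_dir

    tet = 109.47122
    # leucine-like chain on CA1 (primes): CB1 - CG1 < (CD1, CD2)
    pos["CB1"] = _nerf(pos["N1"], pos["CO1"], pos["CA1"], 1.53, tet, -120.0)
    pos["CG1"] = _nerf(pos["CO1"], pos["CA1"], pos["CB1"], 1.53, tet, 180.0)
    pos["CD1"] = _nerf(pos["CA1"], pos["CB1"], pos["CG1"], 1.53, tet, 60.0)
    pos["CD2"] = _nerf(pos["CA1"], pos["CB1"], pos["CG1"], 1.53, tet, 180.0)
    # isoleucine-like chain on CA2: CB2 < (CG2 - CD3, CG3)
    pos["CB2"] = _nerf(pos["N2"], pos["CO2"], pos["CA2"], 1.53, tet, 120.0)
    pos["CG2"] = _nerf(pos["CO2"], pos["CA2"], pos["CB2"], 1.53, tet, 60.0)
    pos["CG3"] = _nerf(pos["CO2"], pos["CA2"], pos["CB2"], 1.53, tet, 180.0)
    pos["CD3"] = _nerf(pos["CA2"], pos["CB2"], pos["CG2"], 1.53, tet, 180.0)
    if substrate_id in (2, 3):  # 7-OH on the C-7 carbon
        pos["OH7"] = _nerf(pos["CB2"], pos["CG2"], pos["CD3"], 1.43, tet, 180.0)
    if substrate_id == 3:  # 2'-OH: the tertiary prime carbon is pre-hydroxylated
        pos["OG1"] = _nerf(pos["CA1"], pos["CB1"], pos["CG1"], 1.43, tet, 300.0)
    order = [n for n in (
        "N1", "CO1", "O1", "CA1", "N2", "CO2", "O2", "CA2",
        "CB1", "CG1", "CD1", "CD2", "CB2", "CG2", "CG3", "CD3", "OH7", "OG1",
    ) if n in pos]
    element = {n: ("N" if n.startswith("N") else "O" if n.startswith("O") else "C")
               for n in order}
    return [(n, element[n], pos[n]) for n in order]


def build_dkp(substrate_id: int):
    """Idealized DKP substrate 1, 2 or 3 with labelled candidate sites.

    Returns ``(ensemble, site_map, bond_graph)``.  Explicit hydrogens are
    added on every labelled site carbon with ideal sp3 geometry, so
    downstream tallies use them verbatim.  Site labels follow the shipped
    default config (C-7, C-2', C-5a, C-6 on substrate 1; C-2', C-3', C-5 on
    2; C-3', C-5, C-6 on 3).
    """
    if substrate_id not in (1, 2, 3):
        raise ValidationError(f"unknown substrate id: {substrate_id!r}")
    resname = f"DK{substrate_id}"
    heavy = _dkp_heavy_atoms(substrate_id)
    records = [(n, el, resname, 1, "S", "hetero", p) for n, el, p in heavy]
    ens0 = ConformerEnsemble(_mkatoms(records), [np.array([p for _, _, p in heavy])])
    graph0 = infer_bonds(ens0)
    labels = load_site_labels()[resname]
    sites0 = classify_carbon_sites(
        graph0, ens0, range(ens0.n_atoms), substrate_id=str(substrate_id),
        label_assignments=labels, labeled_only=True,
    )
    # add ideal hydrogens on the labelled site carbons
    h_records = []
    frame0 = ens0.coords(0)
    for site in sites0.sites:
        carbon_name = ens0.topology[site.carbon_index].name
        for ih, hpos in enumerate(place_hydrogens(site, graph0, frame0), 1):
            h_records.append(
                (f"H{carbon_name[1:]}{ih}", "H", resname, 1, "S", "hetero", hpos)
            )
    all_records = records + h_records
    coords = np.array([r[-1] for r in all_records])
    ens = ConformerEnsemble(_mkatoms(all_records), [coords])
    graph = infer_bonds(ens)
    site_map = classify_carbon_sites(
        graph, ens, range(ens.n_atoms), substrate_id=str(substrate_id),
        label_assignments=labels, labeled_only=True,
    )
    return ens, site_map, graph


def combine(theozyme: ConformerEnsemble, substrate: ConformerEnsemble):
    """Concatenate theozyme + substrate topologies into one single-frame
    ensemble; returns (ensemble, substrate_index_offset)."""
    offset = theozyme.n_atoms
    records = [
        (a.name, a.element, a.residue_name, a.residue_id, a.chain, a.record_kind, a.position)
        for a in theozyme.topology + substrate.topology
    ]
    coords = np.vstack([theozyme.coords(0), substrate.coords(0)])
    return ConformerEnsemble(_mkatoms(records), [coords]), offset


# ------------------------------------------------------------ NAC planting --

@dataclasses.dataclass
class PlantLedger:
    """Exact per-frame ground truth of a generated ensemble."""

    target_site: str
    plan: list[bool]
    seed: int

    @property
    def planted_count(self) -> int:
        return sum(self.plan)

    def to_json(self) -> str:
        return json.dumps(
            {"target_site": self.target_site, "seed": self.seed,
             "planted_count": self.planted_count, "plan": self.plan},
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def sample_nac_ensemble(
    target_site: str,
    f_active: float,
    n: int,
    seed: int,
    substrate_id: int = 1,
    spec: TheozymeSpec | None = None,
    criteria: NACCriteria | None = None,
):
    """Generate an n-frame ensemble with an exactly known active-frame plan.

    Each frame re-poses the rigid substrate relative to the fixed theozyme.
    With probability ``f_active`` the pose is constructed so the target
    site's hydrogen meets the near-attack criterion with margin (O···H drawn
    uniform on [2.0, 2.7] Å, angle uniform on [160°, 180°]) while every
    other site's hydrogens stay >= 3.5 Å from the oxo oxygen; otherwise all
    sites sit > 3.2 Å away.  The planting is geometric, so the returned
    :class:`PlantLedger` is exact, not statistical.

    Returns ``(ensemble, site_map, graph, oxo_index, ledger)`` where indices
    refer to the combined topology.
    """
    if not 0.0 <= f_active <= 1.0:
        raise ValidationError(f"f_active out of [0, 1]: {f_active}")
    if n < 1:
        raise ValidationError(f"need n >= 1 frames, got {n}")
    rng = np.random.default_rng(seed)
    theo = build_theozyme(spec)
    sub, site_map0, graph0 = build_dkp(substrate_id)
    if target_site not in site_map0.labels:
        raise ValidationError(
            f"target site {target_site!r} not among {site_map0.labels}"
        )
    base, offset = combine(theo, sub)
    # bond perception restricted to the substrate: in the unposed base frame
    # the substrate still sits at its build origin near the theozyme
    graph = infer_bonds(base, range(offset, base.n_atoms))
    sites = classify_carbon_sites(
        graph, base, range(offset, base.n_atoms), substrate_id=str(substrate_id),
        label_assignments=load_site_labels()[f"DK{substrate_id}"], labeled_only=True,
    )
    oxo_pos = np.array([0.0, 0.0, (spec or TheozymeSpec()).fe_oxo_length])
    oxo_index = 1  # by construction of build_theozyme
    sub_idx = list(range(offset, base.n_atoms))
    sub_coords0 = base.coords(0)[sub_idx]

    target = sites.site(target_site)
    t_c = base.coords(0)[target.carbon_index]
    t_h = base.coords(0)[target.hydrogen_indices[0]]
    other_h = [
        i for s in sites.sites if s.label != target_site for i in s.hydrogen_indices
    ]
    other_h_local = [sub_idx.index(i) for i in other_h]
    c_local = sub_idx.index(target.carbon_index)
    h_local = sub_idx.index(target.hydrogen_indices[0])

    plan = [bool(rng.random() < f_active) for _ in range(n)]
    frames = []
    theo_coords = base.coords(0)[: offset]
    extent = float(np.max(np.linalg.norm(sub_coords0 - sub_coords0.mean(axis=0), axis=1)))
    for iframe in range(n):
        if plan[iframe]:
            placed = _active_pose(
                sub_coords0, c_local, h_local, other_h_local, oxo_pos, rng
            )
        else:
            placed = _inactive_pose(sub_coords0, oxo_pos, extent, rng)
        frames.append(np.vstack([theo_coords, placed]))
    ens = ConformerEnsemble(base.topology, frames)
    ledger = PlantLedger(target_site=target_site, plan=plan, seed=seed)
    return ens, sites, graph, oxo_index, ledger


def _active_pose(sub_coords, c_local, h_local, other_h_local, oxo_pos, rng):
    """Rigid pose with the chosen C-H satisfying the criterion with margin
    and all other-site hydrogens >= 3.5 Å from the oxo."""
    c0, h0 = sub_coords[c_local], sub_coords[h_local]
    ch_len = float(np.linalg.norm(h0 - c0))
    d = rng.uniform(2.0, 2.7)
    theta = rng.uniform(160.0, 180.0)
    z = np.array([0.0, 0.0, 1.0])
    h_target = oxo_pos + d * z
    for _attempt in range(64):
        phi_c = rng.uniform(0.0, 2 * np.pi)
        # C placed so that angle O-H-C = theta (H->O is -z)
        pol = np.radians(180.0 - theta)
        dir_hc = np.array(
            [np.sin(pol) * np.cos(phi_c), np.sin(pol) * np.sin(phi_c), np.cos(pol)]
        )
        c_target = h_target + ch_len * dir_hc
        u = (h0 - c0) / ch_len
        v = (h_target - c_target) / ch_len
        R0 = _align_rotation(u, v)
        for psi in rng.permutation(np.linspace(0.0, 2 * np.pi, 24, endpoint=False)):
            R = _rotation_about(v, float(psi)) @ R0
            placed = (sub_coords - c0) @ R.T + c_target
            d_other = np.linalg.norm(placed[other_h_local] - oxo_pos, axis=1)
            if (not other_h_local) or d_other.min() >= 3.5:
                return placed
    raise GeometryError(
        "could not construct an active pose: off-target hydrogens clash with "
        "the oxo for every sampled orientation"
    )


def _inactive_pose(sub_coords, oxo_pos, extent, rng):
    """Rigid pose with every substrate atom guaranteed > 3.2 Å from the oxo."""
    # random orientation from three Euler-like spins
    R = (
        _rotation_about(np.array([0.0, 0.0, 1.0]), rng.uniform(0, 2 * np.pi))
        @ _rotation_about(np.array([0.0, 1.0, 0.0]), rng.uniform(0, np.pi))
        @ _rotation_about(np.array([1.0, 0.0, 0.0]), rng.uniform(0, 2 * np.pi))
    )
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    centroid_target = oxo_pos + (3.2 + extent + rng.uniform(0.8, 3.0)) * direction
    centered = sub_coords - sub_coords.mean(axis=0)
    return centered @ R.T + centroid_target
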