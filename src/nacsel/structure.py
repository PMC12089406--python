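"""Coordinate-ensemble I/O and rigid-body geometry.

Structures are read through gemmi (PDB and mmCIF, including multi-MODEL
files) into a :class:`ConformerEnsemble`: one shared atom topology plus a
stack of coordinate frames, which is how MD-snapshot ensembles exported as
multi-model PDB arrive.  Superposition is a plain Kabsch least-squares fit;
whole-structure comparisons pair Cα atoms by global sequence alignment
because the enzymes compared here share only ~35-42% sequence identity and
residue numbering does not correspond.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .elements import covalent_radius
from .errors import GeometryError, InputError, TopologyError, ValidationError

__all__ = [
    "Atom",
    "ConformerEnsemble",
    "AtomSelector",
    "SuperpositionResult",
    "read_structure",
    "write_pdb",
    "select_atoms",
    "identify_oxo",
    "superpose",
    "superpose_calpha",
]


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom of the shared topology; position is its model-0 location (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    record_kind: str  # polymer | hetero | water
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValidationError(f"non-finite coordinates for atom {self.name}")


class ConformerEnsemble:
    """An ordered set of coordinate frames over one atom topology."""

    def __init__(self, topology: Sequence[Atom], frames: Sequence[np.ndarray]):
        if len(frames) < 1:
            raise ValidationError("ensemble needs at least one frame")
        self.topology: list[Atom] = list(topology)
        self.frames: list[np.ndarray] = []
        for k, f in enumerate(frames):
            arr = np.asarray(f, dtype=float)
            if arr.shape != (len(self.topology), 3):
                raise TopologyError(
                    f"frame {k + 1} has {arr.shape[0]} coordinate triples, "
                    f"topology has {len(self.topology)} atoms"
                )
            self.frames.append(arr)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def coords(self, frame: int = 0) -> np.ndarray:
        return self.frames[frame]

    def subset(self, indices: Sequence[int]) -> "ConformerEnsemble":
        idx = list(indices)
        topo = [self.topology[i] for i in idx]
        return ConformerEnsemble(topo, [f[idx] for f in self.frames])


@dataclasses.dataclass
class AtomSelector:
    """Conjunctive atom filter; at least one criterion must be set."""

    element: str | None = None
    residue_name: str | None = None
    chain: str | None = None
    name: str | None = None
    record_kind: str | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (self.element, self.residue_name, self.chain, self.name, self.record_kind)
        ):
            raise ValidationError("AtomSelector requires at least one filter")

    def matches(self, atom: Atom) -> bool:
        return (
            (self.element is None or atom.element.upper() == self.element.upper())
            and (self.residue_name is None or atom.residue_name == self.residue_name)
            and (self.chain is None or atom.chain == self.chain)
            and (self.name is None or atom.name == self.name)
            and (self.record_kind is None or atom.record_kind == self.record_kind)
        )


def _record_kind(residue: gemmi.Residue) -> str:
    if residue.is_water():
        return "water"
    if residue.het_flag == "H":
        return "hetero"
    return "polymer"


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to altloc 'A' then lexical."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in residue:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc != "A", a.altloc))
        kept.append(group[0])
    return kept


def read_structure(path: str | Path, format_hint: str = "auto") -> ConformerEnsemble:
    """Read a (possibly multi-MODEL) PDB or mmCIF file as an ensemble.

    Alternate locations are collapsed to the highest-occupancy conformer
    (ties resolved to altloc 'A').  HETATM records are retained.  All models
    must share one atom topology; the frame order follows the file.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        if format_hint == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format_hint == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif format_hint == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValidationError(f"unknown format hint: {format_hint!r}")
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise InputError(f"{path} contains no models")

    topology: list[Atom] = []
    frames: list[np.ndarray] = []
    signature: list[tuple] | None = None
    for imodel, model in enumerate(st):
        sig, xyz = [], []
        for chain in model:
            for residue in chain:
                kind = _record_kind(residue)
                for a in _resolve_altlocs(residue):
                    sig.append((chain.name, residue.seqid.num, residue.name, a.name))
                    xyz.append((a.pos.x, a.pos.y, a.pos.z))
                    if imodel == 0:
                        topology.append(
                            Atom(
                                serial=len(topology),
                                name=a.name,
                                element=a.element.name.upper(),
                                residue_name=residue.name,
                                residue_id=residue.seqid.num,
                                chain=chain.name,
                                record_kind=kind,
                                position=(a.pos.x, a.pos.y, a.pos.z),
                            )
                        )
        if signature is None:
            signature = sig
        elif sig != signature:
            raise TopologyError(
                f"model {imodel + 1} of {path} has a different atom topology "
                f"({len(sig)} atoms vs {len(signature)})"
            )
        frames.append(np.array(xyz, dtype=float))
    return ConformerEnsemble(topology, frames)


def write_pdb(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-MODEL PDB file (3-decimal precision)."""
    lines: list[str] = []
    multi = ensemble.n_frames > 1
    for imodel, frame in enumerate(ensemble.frames):
        if multi:
            lines.append(f"MODEL     {imodel + 1:4d}")
        for i, atom in enumerate(ensemble.topology):
            record = "ATOM  " if atom.record_kind == "polymer" else "HETATM"
            x, y, z = frame[i]
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"{record}{(i % 99999) + 1:5d} {name:<4.4s} {atom.residue_name:<3.3s}"
                f" {atom.chain:1.1s}{atom.residue_id:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2.2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select_atoms(ensemble: ConformerEnsemble, sel: AtomSelector) -> list[int]:
    """Indices (topology order) of atoms matching every set filter."""
    return [i for i, a in enumerate(ensemble.topology) if sel.matches(a)]


def identify_oxo(
    ensemble: ConformerEnsemble,
    fe_index: int,
    d_range: tuple[float, float] = (1.5, 1.9),
) -> int:
    """Locate the ferryl (Fe=O) oxygen relative to a given iron atom.

    The oxo oxygen is the unique oxygen whose model-0 distance to Fe falls in
    ``d_range`` and that is not covalently bonded to any carbon (which rules
    out carboxylate, α-ketoglutarate and succinate oxygens).  Resting-state
    crystal structures carry no ferryl oxygen; callers analysing those must
    supply an explicit proxy index instead of calling this.
    """
    fe = ensemble.topology[fe_index]
    if fe.element != "FE":
        raise ValidationError(f"atom {fe_index} is {fe.element}, not FE")
    xyz = ensemble.coords(0)
    d_fe = np.linalg.norm(xyz - xyz[fe_index], axis=1)
    candidates = []
    carbon_idx = [i for i, a in enumerate(ensemble.topology) if a.element == "C"]
    for i, atom in enumerate(ensemble.topology):
        if atom.element != "O" or not (d_range[0] <= d_fe[i] <= d_range[1]):
            continue
        cutoff = covalent_radius("C") + covalent_radius("O") + 0.45
        bonded_to_c = any(
            np.linalg.norm(xyz[i] - xyz[j]) <= cutoff for j in carbon_idx
        )
        if not bonded_to_c:
            candidates.append(i)
    if not candidates:
        raise GeometryError(
            "no oxo found: no free oxygen within "
            f"{d_range} Å of Fe; supply an explicit proxy oxygen index"
        )
    if len(candidates) > 1:
        raise GeometryError(f"ambiguous oxo: candidates at indices {candidates}")
    return candidates[0]


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector; maps B onto A as R @ b + t
    rmsd: float  # Å over the paired atoms
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rmsd_A": self.rmsd,
            "n_pairs": self.n_pairs,
            "matrix": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }


def superpose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    pairing: Iterable[tuple[int, int]],
) -> SuperpositionResult:
    """Least-squares rigid-body superposition (Kabsch) of B onto A.

    ``pairing`` lists (index_in_A, index_in_B) atom pairs; at least three
    non-collinear pairs are required.  The returned rotation is proper
    (det = +1, never a reflection).
    """
    pairs = list(pairing)
    if len(pairs) < 3:
        raise GeometryError(f"superposition needs >=3 pairs, got {len(pairs)}")
    P = np.asarray(coords_a, dtype=float)[[i for i, _ in pairs]]
    Q = np.asarray(coords_b, dtype=float)[[j for _, j in pairs]]
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinear point sets leave a rotational degree of freedom unresolved
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) pairing; superposition underdetermined")
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    rmsd = float(np.sqrt(np.mean(np.sum((Q0 @ R.T - P0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=len(pairs))


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}


def _calpha_records(ensemble: ConformerEnsemble) -> list[tuple[int, str]]:
    out = []
    for i, a in enumerate(ensemble.topology):
        if a.record_kind == "polymer" and a.name == "CA" and a.residue_name in _THREE_TO_ONE:
            out.append((i, _THREE_TO_ONE[a.residue_name]))
    return out


def superpose_calpha(
    ens_a: ConformerEnsemble,
    ens_b: ConformerEnsemble,
    frame_a: int = 0,
    frame_b: int = 0,
) -> SuperpositionResult:
    """Whole-structure Cα superposition with sequence-alignment pairing.

    Residues are matched by a global pairwise alignment with identity
    scoring, not by residue number — the structures compared here are
    homologues with unrelated numbering.  No outlier rejection is applied.
    """
    from Bio import Align

    ca_a, ca_b = _calpha_records(ens_a), _calpha_records(ens_b)
    if len(ca_a) < 3 or len(ca_b) < 3:
        raise GeometryError("need at least 3 Cα atoms in each structure")
    seq_a = "".join(c for _, c in ca_a)
    seq_b = "".join(c for _, c in ca_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    pairing = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            pairing.append((ca_a[a0 + off][0], ca_b[b0 + off][0]))
    if len(pairing) < 3:
        raise GeometryError("sequence alignment produced fewer than 3 Cα pairs")
    return superpose(ens_a.coords(frame_a), ens_b.coords(frame_b), pairing)
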