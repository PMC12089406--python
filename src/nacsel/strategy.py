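"""Site-selectivity strategy classification.

An αKG-dependent dioxygenase can pick its C-H site three ways: let the
substrate's intrinsically most reactive bond win (substrate/innate control),
wall off the reactive bond and force a less reactive one onto the ferryl
oxygen (steric control), or anchor a substrate functional group — here an
ortho hydroxyl — by hydrogen bonding so that a neighbouring C-H is presented
(directing-group control).  Given the inherent-reactivity ranking from a
theozyme barrier table, the observed (or NAC-predicted) site, and
hydrogen-bond evidence around the reacting carbon, the classification is a
total three-way partition:

    observed == inherent                      -> substrate_control
    observed != inherent, directing H-bond    -> directing_group_control
    observed != inherent, no directing H-bond -> steric_control

A grid-based buried-cavity volume descriptor supports the steric argument:
a tight pocket (small volume) is what enforces steric control.
"""

from __future__ import annotations

import dataclasses
import io
import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .chem import CARBONYL_CO_MAX, BondGraph, SubstrateSiteMap
from .elements import vdw_radius
from .errors import GeometryError, InputError, ValidationError
from .structure import ConformerEnsemble

__all__ = [
    "BarrierTable",
    "HBondEvidence",
    "StrategyCall",
    "load_barriers",
    "shipped_barrier_table",
    "inherent_site",
    "detect_directing_contact",
    "classify_strategy",
    "pocket_volume",
]


@dataclasses.dataclass
class BarrierTable:
    """Per-site hydrogen-abstraction free-energy barriers (kcal/mol)."""

    substrate_id: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("barrier table is empty")
        for site, dg in self.entries.items():
            if not (np.isfinite(dg) and dg > 0):
                raise ValidationError(f"barrier for {site} not finite/positive: {dg}")


def load_barriers(source: str | Path | io.TextIOBase, substrate_id: str = "") -> BarrierTable:
    """Parse a two-column TSV (site <TAB> kcal/mol; '#' comments allowed)."""
    if isinstance(source, (str, Path)):
        name = str(source)
        try:
            text = Path(source).read_text()
        except OSError as exc:
            raise InputError(f"cannot read barrier table {source}: {exc}") from exc
    else:
        name, text = "<stream>", source.read()
    entries: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{name}:{lineno}: expected 'site<TAB>barrier', got {line!r}")
        site, raw = parts[0].strip(), parts[1].strip()
        try:
            dg = float(raw)
        except ValueError as exc:
            raise InputError(f"{name}:{lineno}: non-numeric barrier {raw!r}") from exc
        if site in entries:
            raise ValidationError(f"{name}:{lineno}: duplicate site label {site!r}")
        entries[site] = dg
    return BarrierTable(substrate_id=substrate_id or name, entries=entries)


def shipped_barrier_table(substrate_id: int) -> BarrierTable:
    """Default barrier table for substrate 1, 2 or 3 (text-quoted values)."""
    if substrate_id not in (1, 2, 3):
        raise ValidationError(f"no shipped barrier table for substrate {substrate_id}")
    text = resources.files("nacsel.data").joinpath(
        f"barriers_substrate{substrate_id}.tsv"
    ).read_text()
    return load_barriers(io.StringIO(text), substrate_id=str(substrate_id))


def inherent_site(table: BarrierTable) -> dict:
    """The inherently most reactive site: minimal abstraction barrier.

    Exact ties return every tied label with ``tie=True``; downstream
    classification refuses unresolved ties.
    """
    best = min(table.entries.values())
    labels = sorted(s for s, dg in table.entries.items() if dg == best)
    return {
        "site_label": labels[0] if len(labels) == 1 else labels,
        "barrier": best,
        "tie": len(labels) > 1,
    }


@dataclasses.dataclass
class HBondEvidence:
    """Heavy-atom hydrogen-bond evidence for a directing hydroxyl."""

    present: bool
    donor_acceptor_pairs: list[dict] = dataclasses.field(default_factory=list)
    directing_hydroxyl_site_distance_bonds: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _substrate_hydroxyl_oxygens(
    graph: BondGraph, ensemble: ConformerEnsemble
) -> list[int]:
    """Oxygens in the graph bonded to exactly one heavy atom, a carbon, by a
    single (non-carbonyl-length) bond — i.e. hydroxyl/alcohol oxygens."""
    out = []
    for n in graph.nodes:
        if ensemble.topology[n].element != "O":
            continue
        heavy = [m for m in graph[n] if ensemble.topology[m].element != "H"]
        if len(heavy) != 1 or ensemble.topology[heavy[0]].element != "C":
            continue
        if graph[n][heavy[0]]["length"] >= CARBONYL_CO_MAX:
            out.append(n)
    return out


def detect_directing_contact(
    frame: np.ndarray,
    graph: BondGraph,
    ensemble: ConformerEnsemble,
    sites: SubstrateSiteMap,
    reacting_site: str,
    enzyme_polar_atoms: Sequence[int],
    cutoff: float = 3.5,
    max_bond_separation: int = 2,
) -> HBondEvidence:
    """Look for a substrate hydroxyl adjacent to the reacting carbon that
    hydrogen-bonds (heavy-atom distance <= ``cutoff``) to an enzyme O/N.

    Detection is heavy-atom only — crystal models deposit no polar
    hydrogens — and the hydroxyl must sit within ``max_bond_separation``
    covalent bonds of the reacting carbon to count as *directing* that site.
    """
    site = sites.site(reacting_site)  # KeyError if absent
    hydroxyls = _substrate_hydroxyl_oxygens(graph, ensemble)
    pairs: list[dict] = []
    best_sep: int | None = None
    for o_idx in hydroxyls:
        try:
            sep = nx.shortest_path_length(graph, site.carbon_index, o_idx)
        except nx.NetworkXNoPath:
            continue
        if sep > max_bond_separation:
            continue
        for p_idx in enzyme_polar_atoms:
            el = ensemble.topology[p_idx].element
            if el not in ("O", "N"):
                continue
            d = float(np.linalg.norm(frame[o_idx] - frame[p_idx]))
            if d <= cutoff:
                pairs.append(
                    {"substrate_oxygen": int(o_idx), "partner_atom": int(p_idx),
                     "distance_A": d}
                )
                best_sep = sep if best_sep is None else min(best_sep, sep)
    return HBondEvidence(
        present=bool(pairs),
        donor_acceptor_pairs=pairs,
        directing_hydroxyl_site_distance_bonds=best_sep,
    )


@dataclasses.dataclass
class StrategyCall:
    strategy: str  # substrate_control | steric_control | directing_group_control
    inherent_site: str
    observed_site: str
    evidence: HBondEvidence | None
    narrative: str

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "inherent_site": self.inherent_site,
            "observed_site": self.observed_site,
            "evidence": self.evidence.to_dict() if self.evidence else None,
            "narrative": self.narrative,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def classify_strategy(
    inherent: str | dict,
    observed: str,
    evidence: HBondEvidence | None = None,
) -> StrategyCall:
    """Classify the enzyme's site-selectivity strategy (total 3-way partition).

    ``inherent`` may be a bare site label or the dict from
    :func:`inherent_site`; an unresolved barrier tie is refused.
    """
    if isinstance(inherent, dict):
        if inherent.get("tie"):
            raise ValidationError(
                "inherent-reactivity tie between "
                f"{inherent['site_label']}; classification refused — resolve the "
                "tie (finer barriers or explicit choice) and retry"
            )
        inherent_label = inherent["site_label"]
    else:
        inherent_label = inherent
    if not inherent_label or not observed:
        raise ValidationError("both inherent and observed site labels are required")
    has_evidence = bool(evidence is not None and evidence.present)
    if observed == inherent_label:
        strategy = "substrate_control"
        why = (
            f"observed site {observed} coincides with the inherently most reactive "
            f"site {inherent_label}: selectivity follows the substrate's innate C-H "
            "reactivity."
        )
    elif has_evidence:
        strategy = "directing_group_control"
        n = len(evidence.donor_acceptor_pairs)
        why = (
            f"observed site {observed} differs from the inherent site "
            f"{inherent_label}, and {n} hydrogen-bond contact(s) anchor a hydroxyl "
            f"{evidence.directing_hydroxyl_site_distance_bonds} bond(s) from the "
            "reacting carbon: a directing group re-orients the substrate."
        )
    else:
        strategy = "steric_control"
        why = (
            f"observed site {observed} differs from the inherent site "
            f"{inherent_label} with no directing hydrogen bond detected: the pocket "
            "shape overrides innate reactivity."
        )
    return StrategyCall(
        strategy=strategy,
        inherent_site=inherent_label,
        observed_site=observed,
        evidence=evidence,
        narrative=why,
    )


_LATTICE_26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=float,
)
_LATTICE_26 /= np.linalg.norm(_LATTICE_26, axis=1, keepdims=True)


def pocket_volume(
    coords: np.ndarray,
    elements: Sequence[str],
    center: np.ndarray,
    shell_radius: float = 8.0,
    grid_spacing: float = 0.5,
    probe: float = 1.4,
    buriedness_k: int = 16,
) -> float:
    """Grid-based buried-cavity volume (Å³) around ``center``.

    Grid points within ``shell_radius`` of the center count toward the pocket
    if they (a) clear every atom's vdW + probe sphere and (b) are buried:
    scanning the 26 cubic-lattice directions, at least ``buriedness_k`` rays
    hit an atom within ``shell_radius``.  This is a POCASA-style
    approximation — useful for rank comparisons between pockets, not for
    reproducing any particular server's absolute numbers.
    """
    if not (shell_radius > probe > 0):
        raise ValidationError("require shell_radius > probe > 0")
    if grid_spacing > 1.0:
        raise ValidationError("grid_spacing must be <= 1.0 Å")
    coords = np.asarray(coords, dtype=float)
    center = np.asarray(center, dtype=float)
    d_center = np.linalg.norm(coords - center, axis=1)
    near = d_center <= 2.0 * shell_radius
    if not near.any():
        raise GeometryError("no cavity context: no atoms within 2x shell_radius of center")
    coords = coords[near]
    radii = np.array([vdw_radius(e) for e, keep in zip(elements, near) if keep])

    # candidate grid: points inside the shell sphere
    n = int(np.ceil(shell_radius / grid_spacing))
    axis = np.arange(-n, n + 1) * grid_spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + center
    pts = pts[np.linalg.norm(pts - center, axis=1) <= shell_radius]

    # exclude points inside any (vdW + probe) sphere
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    max_r = radii.max() + probe
    free = np.ones(len(pts), dtype=bool)
    neighbor_lists = tree.query_ball_point(pts, max_r)
    for ip, nbrs in enumerate(neighbor_lists):
        if nbrs:
            d = np.linalg.norm(coords[nbrs] - pts[ip], axis=1)
            if (d <= radii[nbrs] + probe).any():
                free[ip] = False
    cand = pts[free]
    if len(cand) == 0:
        return 0.0

    # buriedness: ray-march each of 26 lattice directions through an
    # occupancy grid (atoms dilated by their vdW radius)
    occ_n = int(np.ceil((shell_radius + max_r) / grid_spacing)) + 2
    occ_shape = (2 * occ_n + 1,) * 3
    occ = np.zeros(occ_shape, dtype=bool)
    origin = center - occ_n * grid_spacing
    for a_xyz, a_r in zip(coords, radii):
        lo = np.floor((a_xyz - a_r - origin) / grid_spacing).astype(int)
        hi = np.ceil((a_xyz + a_r - origin) / grid_spacing).astype(int)
        lo = np.clip(lo, 0, occ_shape[0] - 1)
        hi = np.clip(hi, 0, occ_shape[0] - 1)
        xs = np.arange(lo[0], hi[0] + 1)
        ys = np.arange(lo[1], hi[1] + 1)
        zs = np.arange(lo[2], hi[2] + 1)
        bx, by, bz = np.meshgrid(xs, ys, zs, indexing="ij")
        vox = origin + np.stack([bx, by, bz], axis=-1) * grid_spacing
        inside = np.linalg.norm(vox - a_xyz, axis=-1) <= a_r
        occ[bx[inside], by[inside], bz[inside]] = True

    n_steps = int(np.floor(shell_radius / grid_spacing))
    buried_count = np.zeros(len(cand), dtype=int)
    for direction in _LATTICE_26:
        hit = np.zeros(len(cand), dtype=bool)
        for step in range(1, n_steps + 1):
            probe_pts = cand + direction * (step * grid_spacing)
            ijk = np.round((probe_pts - origin) / grid_spacing).astype(int)
            ok = np.all((ijk >= 0) & (ijk < occ_shape[0]), axis=1)
            sampled = np.zeros(len(cand), dtype=bool)
            sampled[ok] = occ[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]]
            hit |= sampled
        buried_count += hit
    n_buried = int((buried_count >= buriedness_k).sum())
    return float(n_buried) * grid_spacing**3
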