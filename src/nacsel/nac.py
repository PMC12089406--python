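"""Near-attack-conformation (NAC) counting over conformer ensembles.

A conformation is "active" for a C-H site when the ferryl oxygen sits within
abstraction range of one of the site's hydrogens: d(O···H) <= 2.8 Å with the
O-H-C angle (vertex at H) within 170 ± 15°, both bounds inclusive and the
angle capped at the geometric maximum of 180°.  Counting such frames across
an MD-snapshot ensemble, per candidate site, predicts which C-H position the
enzyme scaffold presents for hydroxylation.

The module exposes both a functional surface (:func:`tally_ensemble`,
:func:`predict_sites`) and a model/results pair (:class:`NACModel` ->
:class:`NACResults`) that adds binomial uncertainty on the per-site active
fractions and a summary table.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import BondGraph, SubstrateSiteMap, site_hydrogen_positions
from .errors import GeometryError, ValidationError
from .structure import ConformerEnsemble

__all__ = [
    "NACCriteria",
    "GeometryRecord",
    "NACSummary",
    "oh_geometry",
    "is_active",
    "tally_ensemble",
    "predict_sites",
    "NACModel",
    "NACResults",
]


@dataclasses.dataclass(frozen=True)
class NACCriteria:
    """Geometric definition of an active (near-attack) conformation."""

    d_max: float = 2.8  # Å, O···H upper bound
    theta_center: float = 170.0  # degrees
    theta_tol: float = 15.0  # degrees

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValidationError(f"d_max must be positive, got {self.d_max}")
        if not 0 < self.theta_center <= 180:
            raise ValidationError(f"theta_center out of (0, 180]: {self.theta_center}")
        if self.theta_tol < 0:
            raise ValidationError(f"theta_tol must be >= 0: {self.theta_tol}")

    @property
    def theta_window(self) -> tuple[float, float]:
        """Inclusive angle window, capped at 180° (the nominal upper edge
        170 + 15 = 185° is geometrically unreachable)."""
        return (self.theta_center - self.theta_tol,
                min(self.theta_center + self.theta_tol, 180.0))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class GeometryRecord:
    frame: int
    site_label: str
    hydrogen_ordinal: int
    d_OH: float
    theta_OHC: float
    active: bool


@dataclasses.dataclass
class NACSummary:
    n_frames: int
    per_site: dict  # site_label -> {"n_active": int, "mean_d_active": float | None}
    criteria: NACCriteria
    records: list[GeometryRecord] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": label,
                "n_active": v["n_active"],
                "n_frames": self.n_frames,
                "fraction": v["n_active"] / self.n_frames,
                "mean_d_active": v["mean_d_active"],
            }
            for label, v in self.per_site.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "criteria": self.criteria.to_dict(),
                "n_frames": self.n_frames,
                "per_site": self.per_site,
            },
            indent=2,
            sort_keys=True,
        )


def oh_geometry(O: np.ndarray, H: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """d(O-H) in Å and the O-H-C angle in degrees (vertex at the hydrogen)."""
    O, H, C = (np.asarray(p, dtype=float) for p in (O, H, C))
    ho = O - H
    hc = C - H
    d_oh = float(np.linalg.norm(ho))
    d_hc = float(np.linalg.norm(hc))
    if d_oh < 1e-9 or d_hc < 1e-9:
        raise GeometryError("coincident points in O-H-C geometry")
    cosang = np.clip(np.dot(ho, hc) / (d_oh * d_hc), -1.0, 1.0)
    return d_oh, float(np.degrees(np.arccos(cosang)))


def is_active(d_OH: float, theta_OHC: float, crit: NACCriteria = NACCriteria()) -> bool:
    """Inclusive-bounds test of the near-attack criterion."""
    lo, hi = crit.theta_window
    return d_OH <= crit.d_max and lo <= theta_OHC <= hi


def tally_ensemble(
    ensemble: ConformerEnsemble,
    sites: SubstrateSiteMap,
    oxo_index: int,
    crit: NACCriteria = NACCriteria(),
    graph: BondGraph | None = None,
    methyl_rotamers: int = 1,
    keep_records: bool = False,
) -> NACSummary:
    """Count, per site, the frames in which any site hydrogen is active.

    A frame is active for a site iff at least one of that site's hydrogens
    satisfies the criterion (a methyl reacts through whichever hydrogen is
    presented).  Explicit model hydrogens are used verbatim; otherwise ideal
    sp3 positions are placed per frame.  ``mean_d_active`` averages, over the
    active frames, the shortest qualifying O···H distance.
    """
    if ensemble.n_frames < 1:
        raise ValidationError("empty ensemble")
    if ensemble.topology[oxo_index].element != "O":
        raise ValidationError(
            f"oxo_index {oxo_index} is element "
            f"{ensemble.topology[oxo_index].element}, expected O"
        )
    if graph is None:
        needs_placement = any(not s.hydrogen_indices for s in sites.sites)
        if needs_placement:
            raise ValidationError(
                "sites lack explicit hydrogens; pass the bond graph for placement"
            )
    per_site = {
        s.label: {"n_active": 0, "_d_sum": 0.0, "mean_d_active": None} for s in sites.sites
    }
    records: list[GeometryRecord] = []
    for iframe, frame in enumerate(ensemble.frames):
        o_pos = frame[oxo_index]
        for site in sites.sites:
            c_pos = frame[site.carbon_index]
            h_positions = site_hydrogen_positions(site, graph, frame, methyl_rotamers)
            best_d = None
            for ih, h_pos in enumerate(h_positions):
                d, theta = oh_geometry(o_pos, h_pos, c_pos)
                act = is_active(d, theta, crit)
                if keep_records:
                    records.append(
                        GeometryRecord(iframe, site.label, ih, d, theta, act)
                    )
                if act and (best_d is None or d < best_d):
                    best_d = d
            if best_d is not None:
                per_site[site.label]["n_active"] += 1
                per_site[site.label]["_d_sum"] += best_d
    for v in per_site.values():
        if v["n_active"]:
            v["mean_d_active"] = v.pop("_d_sum") / v["n_active"]
        else:
            v.pop("_d_sum")
            v["mean_d_active"] = None
    return NACSummary(
        n_frames=ensemble.n_frames,
        per_site=per_site,
        criteria=crit,
        records=records if keep_records else None,
    )


def predict_sites(summary: NACSummary) -> list[dict]:
    """Rank predicted hydroxylation sites by active-conformation count.

    Sites with zero active frames are omitted.  Ties in count break by
    ascending mean active O···H distance (closer approach wins), then by
    lexical site label.
    """
    entries = [
        {
            "site_label": label,
            "n_active": v["n_active"],
            "fraction": v["n_active"] / summary.n_frames,
            "mean_d_active": v["mean_d_active"],
        }
        for label, v in summary.per_site.items()
        if v["n_active"] > 0
    ]
    entries.sort(
        key=lambda e: (-e["n_active"], e["mean_d_active"] or math.inf, e["site_label"])
    )
    return entries


class NACModel:
    """Near-attack-conformation model over one ensemble.

    Parameters
    ----------
    ensemble : ConformerEnsemble
        Coordinate frames of the enzyme-Fe(IV)=O-substrate complex.
    sites : SubstrateSiteMap
        Labeled candidate C-H sites on the substrate.
    oxo_index : int
        Topology index of the ferryl oxygen (or an explicit proxy).
    criteria : NACCriteria, optional
        Geometric activity definition; defaults to d <= 2.8 Å, 170 ± 15°.
    """

    def __init__(
        self,
        ensemble: ConformerEnsemble,
        sites: SubstrateSiteMap,
        oxo_index: int,
        criteria: NACCriteria = NACCriteria(),
        graph: BondGraph | None = None,
        methyl_rotamers: int = 1,
    ):
        self.ensemble = ensemble
        self.sites = sites
        self.oxo_index = oxo_index
        self.criteria = criteria
        self.graph = graph
        self.methyl_rotamers = methyl_rotamers

    @classmethod
    def from_files(
        cls,
        structure_path: str,
        substrate_residue: str,
        fe_element: str = "FE",
        criteria: NACCriteria = NACCriteria(),
        label_config: dict | None = None,
        oxo_index: int | None = None,
    ) -> "NACModel":
        """Build a model straight from a multi-model coordinate file."""
        from .chem import classify_carbon_sites, infer_bonds, load_site_labels
        from .structure import AtomSelector, identify_oxo, read_structure, select_atoms

        ens = read_structure(structure_path)
        if oxo_index is None:
            fe_idx = select_atoms(ens, AtomSelector(element=fe_element))
            if len(fe_idx) != 1:
                raise ValidationError(f"expected exactly one Fe atom, found {len(fe_idx)}")
            oxo_index = identify_oxo(ens, fe_idx[0])
        sub_idx = select_atoms(ens, AtomSelector(residue_name=substrate_residue))
        if not sub_idx:
            raise ValidationError(f"no atoms with residue name {substrate_residue!r}")
        graph = infer_bonds(ens, sub_idx)
        labels = (label_config or load_site_labels()).get(substrate_residue, {})
        sites = classify_carbon_sites(
            graph, ens, sub_idx, substrate_id=substrate_residue,
            label_assignments=labels, labeled_only=bool(labels),
        )
        return cls(ens, sites, oxo_index, criteria, graph=graph)

    def fit(self, keep_records: bool = False) -> "NACResults":
        summary = tally_ensemble(
            self.ensemble,
            self.sites,
            self.oxo_index,
            self.criteria,
            graph=self.graph,
            methyl_rotamers=self.methyl_rotamers,
            keep_records=keep_records,
        )
        return NACResults(self, summary)


class NACResults:
    """Per-site active-conformation counts with binomial uncertainty."""

    def __init__(self, model: NACModel, summary: NACSummary):
        self.model = model
        self.nac_summary = summary
        self.n_frames = summary.n_frames

    def counts(self) -> dict[str, int]:
        return {k: v["n_active"] for k, v in self.nac_summary.per_site.items()}

    def fractions(self) -> dict[str, float]:
        return {k: v["n_active"] / self.n_frames for k, v in self.nac_summary.per_site.items()}

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Wilson score interval on each site's active fraction."""
        out = {}
        for label, v in self.nac_summary.per_site.items():
            lo, hi = _wilson_interval(v["n_active"], self.n_frames, alpha)
            out[label] = (lo, hi)
        return out

    def predicted_sites(self) -> list[dict]:
        return predict_sites(self.nac_summary)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        df = self.nac_summary.to_frame()
        ci = self.conf_int(alpha)
        df["ci_low"] = [ci[s][0] for s in df["site"]]
        df["ci_high"] = [ci[s][1] for s in df["site"]]
        return df.sort_values(
            ["n_active", "site"], ascending=[False, True]
        ).reset_index(drop=True)

    def plot_counts(self, ax=None):
        """Bar chart of active-conformation counts per site."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        df = self.summary()
        ax.bar(df["site"], df["n_active"], color="#4878a8")
        ax.set_ylabel(f"active conformations / {self.n_frames}")
        ax.set_xlabel("site")
        return ax


def _wilson_interval(k: int, n: int, alpha: float) -> tuple[float, float]:
    z = stats.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)
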