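"""Near-attack-conformation geometry, criterion and ensemble tally."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nacsel as ns
from nacsel.errors import GeometryError, ValidationError

from conftest import rigid_transform


class TestOHGeometry:
    def test_collinear_points(self):
        d, theta = ns.oh_geometry((0, 0, 3.0), (0, 0, 1.0), (0, 0, 0))
        assert d == pytest.approx(2.0)
        assert theta == pytest.approx(180.0)

    def test_right_angle(self):
        d, theta = ns.oh_geometry((1, 0, 1), (0, 0, 1), (0, 0, 0))
        assert theta == pytest.approx(90.0)

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            O, H, C = rng.uniform(-5, 5, size=(3, 3))
            d, theta = ns.oh_geometry(O, H, C)
            # independent recomputation from the three side lengths
            a = np.linalg.norm(O - H)
            b = np.linalg.norm(C - H)
            c = np.linalg.norm(O - C)
            cos_t = (a * a + b * b - c * c) / (2 * a * b)
            assert d == pytest.approx(a, abs=1e-9)
            assert theta == pytest.approx(math.degrees(math.acos(np.clip(cos_t, -1, 1))),
                                          abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            ns.oh_geometry((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestIsActive:
    @pytest.mark.parametrize(
        "d,theta,expected",
        [
            (2.8, 170.0, True),   # distance boundary inclusive
            (2.81, 170.0, False),
            (2.0, 155.0, True),   # lower angle edge inclusive
            (2.0, 154.9, False),
            (2.0, 180.0, True),   # window capped at the geometric max
        ],
    )
    def test_boundary_truth_table(self, d, theta, expected):
        assert ns.is_active(d, theta) is expected

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValidationError):
            ns.NACCriteria(d_max=-1)
        with pytest.raises(ValidationError):
            ns.NACCriteria(theta_center=200)
        with pytest.raises(ValidationError):
            ns.NACCriteria(theta_tol=-2)

    @settings(derandomize=True, max_examples=200)
    @given(
        d=st.floats(0.1, 5.0),
        theta=st.floats(0.0, 180.0),
        dd=st.floats(0.0, 1.0),
        dt=st.floats(0.0, 20.0),
    )
    def test_widening_criteria_never_deactivates(self, d, theta, dd, dt):
        tight = ns.NACCriteria()
        loose = ns.NACCriteria(d_max=tight.d_max + dd, theta_tol=tight.theta_tol + dt)
        if ns.is_active(d, theta, tight):
            assert ns.is_active(d, theta, loose)


def _brute_force_tally(ensemble, sites, oxo_index, crit):
    """Independent double-loop recount, straight from the criterion text."""
    counts = {s.label: 0 for s in sites.sites}
    for frame in ensemble.frames:
        for s in sites.sites:
            hit = False
            for hi in s.hydrogen_indices:
                a = float(np.linalg.norm(frame[oxo_index] - frame[hi]))
                b = float(np.linalg.norm(frame[s.carbon_index] - frame[hi]))
                c = float(np.linalg.norm(frame[oxo_index] - frame[s.carbon_index]))
                theta = math.degrees(
                    math.acos(max(-1.0, min(1.0, (a * a + b * b - c * c) / (2 * a * b))))
                )
                if a <= crit.d_max and (
                    crit.theta_center - crit.theta_tol
                    <= theta
                    <= min(crit.theta_center + crit.theta_tol, 180.0)
                ):
                    hit = True
            if hit:
                counts[s.label] += 1
    return counts


class TestTally:
    def test_matches_brute_force_on_mini_ensembles(self):
        rng = np.random.default_rng(23)
        crit = ns.NACCriteria()
        for trial in range(12):
            sid = int(rng.integers(1, 4))
            ens, sites, g, oxo, _ = ns.sample_nac_ensemble(
                target_site={1: "C-7", 2: "C-5", 3: "C-6"}[sid],
                f_active=float(rng.uniform(0, 1)),
                n=int(rng.integers(5, 50)),
                seed=int(rng.integers(0, 2**31)),
                substrate_id=sid,
            )
            got = {k: v["n_active"] for k, v in
                   ns.tally_ensemble(ens, sites, oxo, crit, graph=g).per_site.items()}
            assert got == _brute_force_tally(ens, sites, oxo, crit)

    def test_all_frames_active_counts_all(self):
        ens, sites, g, oxo, ledger = ns.sample_nac_ensemble("C-7", 1.0, 30, seed=2)
        s = ns.tally_ensemble(ens, sites, oxo, graph=g)
        assert s.per_site["C-7"]["n_active"] == 30 == ledger.planted_count

    def test_counts_invariant_under_rigid_motion(self):
        ens, sites, g, oxo, _ = ns.sample_nac_ensemble("C-2'", 0.3, 40, seed=9)
        base = {k: v["n_active"] for k, v in
                ns.tally_ensemble(ens, sites, oxo, graph=g).per_site.items()}
        rng = np.random.default_rng(1)
        R, t = rigid_transform(rng)
        moved = ns.ConformerEnsemble(ens.topology, [f @ R.T + t for f in ens.frames])
        got = {k: v["n_active"] for k, v in
               ns.tally_ensemble(moved, sites, oxo, graph=g).per_site.items()}
        assert got == base

    def test_counts_monotone_in_criteria(self):
        ens, sites, g, oxo, _ = ns.sample_nac_ensemble("C-6", 0.4, 60, seed=14,
                                                       substrate_id=3)
        base = ns.tally_ensemble(ens, sites, oxo, ns.NACCriteria(), graph=g)
        for crit in (ns.NACCriteria(d_max=3.4), ns.NACCriteria(theta_tol=25.0),
                     ns.NACCriteria(d_max=3.4, theta_tol=25.0)):
            wider = ns.tally_ensemble(ens, sites, oxo, crit, graph=g)
            for label in base.per_site:
                assert wider.per_site[label]["n_active"] >= base.per_site[label]["n_active"]

    def test_non_oxygen_oxo_index_rejected(self):
        ens, sites, g, oxo, _ = ns.sample_nac_ensemble("C-7", 0.0, 3, seed=1)
        with pytest.raises(ValidationError):
            ns.tally_ensemble(ens, sites, 0, graph=g)  # index 0 is the Fe

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            ns.ConformerEnsemble([], [])


class TestPredictSites:
    def _summary(self, per_site, n):
        return ns.NACSummary(n_frames=n, per_site=per_site, criteria=ns.NACCriteria())

    def test_descending_count_order(self):
        s = self._summary(
            {"C-6": {"n_active": 49, "mean_d_active": 2.5},
             "C-7": {"n_active": 3, "mean_d_active": 2.4},
             "C-2'": {"n_active": 0, "mean_d_active": None}},
            5000,
        )
        assert [e["site_label"] for e in ns.predict_sites(s)] == ["C-6", "C-7"]

    def test_tie_breaks_by_closer_mean_distance(self):
        s = self._summary(
            {"A": {"n_active": 5, "mean_d_active": 2.1},
             "B": {"n_active": 5, "mean_d_active": 2.4}},
            100,
        )
        assert [e["site_label"] for e in ns.predict_sites(s)] == ["A", "B"]
        # and the reverse ordering when distances swap
        s2 = self._summary(
            {"A": {"n_active": 5, "mean_d_active": 2.4},
             "B": {"n_active": 5, "mean_d_active": 2.1}},
            100,
        )
        assert [e["site_label"] for e in ns.predict_sites(s2)] == ["B", "A"]

    def test_all_zero_counts_gives_empty_ranking(self):
        s = self._summary({"A": {"n_active": 0, "mean_d_active": None}}, 10)
        assert ns.predict_sites(s) == []


class TestModelResults:
    def test_summary_table_and_intervals(self):
        ens, sites, g, oxo, ledger = ns.sample_nac_ensemble("C-7", 0.1, 200, seed=6)
        res = ns.NACModel(ens, sites, oxo, graph=g).fit()
        df = res.summary()
        assert set(df.columns) >= {"site", "n_active", "fraction", "ci_low", "ci_high"}
        row = df[df.site == "C-7"].iloc[0]
        assert row.n_active == ledger.planted_count
        assert row.ci_low <= row.fraction <= row.ci_high
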