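"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

import nacsel as ns


def rigid_transform(rng):
    """A random proper rigid-body transform (R, t)."""
    from nacsel.synthetic import _rotation_about

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = _rotation_about(axis, rng.uniform(0, 2 * np.pi))
    t = rng.uniform(-20, 20, size=3)
    return R, t


def fibonacci_sphere(n, radius):
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@pytest.fixture(scope="session")
def theozyme():
    return ns.build_theozyme()


@pytest.fixture(scope="session")
def dkp1():
    return ns.build_dkp(1)


@pytest.fixture(scope="session")
def dkp3():
    return ns.build_dkp(3)


@pytest.fixture(scope="session")
def cage():
    """Spherical carbon cage enclosing an empty cavity of radius 3.0 Å at the
    default probe (atom centers at 3.0 + r_vdw(C) + probe = 6.1 Å)."""
    coords = fibonacci_sphere(400, 6.1)
    return coords, ["C"] * 400


def make_ensemble(records, frames):
    """Build an ensemble from (name, element, resname, resid, chain, kind, xyz)."""
    from nacsel.synthetic import _mkatoms

    return ns.ConformerEnsemble(_mkatoms(records), [np.asarray(f, float) for f in frames])


@pytest.fixture()
def minimal_pdb(tmp_path):
    """Single-MODEL PDB with 4 atoms: FE, O, C, H."""
    text = (
        "HETATM    1 FE   FE  A   1       0.000   0.000   0.000  1.00  0.00          FE\n"
        "HETATM    2  O1  OXO A   2       0.000   0.000   1.620  1.00  0.00           O\n"
        "HETATM    3  C1  LIG A   3       2.500   0.000   0.000  1.00  0.00           C\n"
        "HETATM    4  H1  LIG A   3       3.100   0.800   0.000  1.00  0.00           H\n"
        "END\n"
    )
    p = tmp_path / "minimal.pdb"
    p.write_text(text)
    return p
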