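import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pocketdyn.structure_io import Ensemble, Frame

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_frame(coords, label="toy", **overrides):
    """Protein-like Frame from bare coordinates (CA/ALA/chain A)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    fields = dict(
        names=np.full(n, "CA"),
        elements=np.full(n, "C"),
        residue_names=np.full(n, "ALA"),
        residue_numbers=np.arange(1, n + 1),
        chains=np.full(n, "A"),
    )
    fields.update(overrides)
    return Frame(coords, label=label, **fields)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_frame(rng):
    return make_frame(rng.normal(0.0, 5.0, (25, 3)))


@pytest.fixture
def static_ensemble(random_frame):
    """Ten identical copies of one frame."""
    coords = np.repeat(random_frame.coords[None], 10, axis=0)
    return Ensemble(random_frame, dt=10.0, coords=coords.copy())


# Minimal hand-written PDB fixtures (fixed-column format)

SINGLE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1      11.000  12.000  13.000  1.00  0.00"
    "           C\n"
    "END\n"
)

PROTEIN_WITH_WATERS_PDB = "".join(
    [
        f"ATOM  {i+1:5d}  CA  ALA A{i+1:4d}    {8.0+i:8.3f}{4.0:8.3f}{2.0:8.3f}"
        f"  1.00  0.00           C\n"
        for i in range(10)
    ]
    + [
        f"HETATM{11+i:5d}  O   HOH A{100+i:4d}    {20.0+i:8.3f}{20.0:8.3f}"
        f"{20.0:8.3f}  1.00  0.00           O\n"
        for i in range(3)
    ]
    + ["END\n"]
)

ALTLOC_PDB = (
    "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.30  0.00"
    "           C\n"
    "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.70  0.00"
    "           C\n"
    "ATOM      3  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00"
    "           C\n"
    "END\n"
)


@pytest.fixture
def single_atom_pdb(tmp_path):
    p = tmp_path / "single.pdb"
    p.write_text(SINGLE_ATOM_PDB)
    return p


@pytest.fixture
def waters_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(PROTEIN_WITH_WATERS_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
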