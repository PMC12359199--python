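import numpy as np
import pytest

from plddtkit.structures import Atom, Residue, StructureModel


def ca_only_model(xs, names=None, chain="A"):
    """Chain of CA-only residues at the given x positions (y = z = 0)."""
    names = names or ["ALA"] * len(xs)
    residues = tuple(
        Residue(i + 1, nm, (Atom("CA", "C", np.array([float(x), 0.0, 0.0])),))
        for i, (x, nm) in enumerate(zip(xs, names))
    )
    return StructureModel(chain, residues)


def random_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t


@pytest.fixture
def collinear_pair():
    """The hand-scored fixture: reference CA at 0/4/8, model CA at 0/4/9."""
    return ca_only_model([0, 4, 8]), ca_only_model([0, 4, 9])


def format_pdb_atom(serial, name, resname, chain, resseq, x, y, z,
                    occ=1.0, b=0.0, element=" C", altloc=" "):
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {pad_name}{altloc}{resname:>3s} {chain}{resseq:>4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


def write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
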