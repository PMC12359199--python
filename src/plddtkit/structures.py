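"""Read, renumber and annotate single-chain protein structures.

The package works on monomeric protein chains whose residues are numbered by
their 1-based position in the chain's FASTA sequence (experimental structures
frequently use author numbering with gaps and offsets, so renumbering is a
first-class operation).  Per-residue confidence scores are written into the
PDB B-factor column, the convention used by structure-prediction databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Common non-standard residues mapped to their parent standard residue.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "HYP": "PRO", "KCX": "LYS", "MLY": "LYS",
    "PCA": "GLU", "CME": "CYS",
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self):
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))


@dataclass(frozen=True)
class Residue:
    residue_index: int  # 1-based position in the FASTA sequence
    residue_name: str   # 3-letter code
    atoms: tuple[Atom, ...]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.residue_name]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.residue_index}")

    @property
    def ca(self) -> Atom:
        return self.atom("CA")


@dataclass(frozen=True)
class StructureModel:
    """A single protein chain: ordered residues with heavy-atom coordinates.

    Residue indices strictly increase (gaps allowed for unresolved residues),
    every residue carries exactly one CA atom, and ``sequence`` is the
    1-letter string the indices refer to (may be empty if unknown).
    """

    chain_id: str
    residues: tuple[Residue, ...]
    sequence: str = ""

    def __post_init__(self):
        idx = [r.residue_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue_index values must strictly increase")
        for r in self.residues:
            if sum(1 for a in r.atoms if a.name == "CA") != 1:
                raise ValueError(f"residue {r.residue_index} must have exactly one CA")
        if self.sequence:
            for r in self.residues:
                if r.residue_index > len(self.sequence):
                    raise ValueError("residue_index beyond sequence length")
                expect = self.sequence[r.residue_index - 1]
                if r.one_letter != expect:
                    raise ValueError(
                        f"residue {r.residue_index} is {r.one_letter}, "
                        f"sequence says {expect}"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_indices(self) -> list[int]:
        return [r.residue_index for r in self.residues]

    def ca_coords(self) -> np.ndarray:
        """CA coordinates as an (L, 3) array in residue order."""
        return np.array([r.ca.xyz for r in self.residues], dtype=float)

    def residue(self, residue_index: int) -> Residue:
        for r in self.residues:
            if r.residue_index == residue_index:
                return r
        raise KeyError(f"residue {residue_index} not in model")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Apply the rigid motion x -> R x + t to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = []
        for r in self.residues:
            atoms = tuple(Atom(a.name, a.element, R @ a.xyz + t) for a in r.atoms)
            new.append(Residue(r.residue_index, r.residue_name, atoms))
        return StructureModel(self.chain_id, tuple(new), self.sequence)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def read_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Parse one chain of a PDB (or mmCIF) file into a :class:`StructureModel`.

    Hydrogens and waters are discarded; of altloc duplicates the
    highest-occupancy copy is kept (ties by altloc letter).  Residues lacking
    a CA atom are dropped with a log line, as are non-standard residues with
    no standard parent.  Author residue numbers are kept as ``residue_index``
    (renumber with :func:`renumber_to_sequence` if they are not FASTA
    positions yet).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    st.remove_waters()
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if not names:
            raise ValueError(f"{path}: no chains")
        chain = names[0]
    if chain not in names:
        raise ValueError(f"{path}: chain {chain!r} not found (have {names})")

    residues: list[Residue] = []
    for res in model[chain]:
        name = res.name
        if name not in THREE_TO_ONE:
            parent = NONSTANDARD_PARENT.get(name)
            if parent is None:
                logger.info("dropping non-standard residue %s %s", name, res.seqid.num)
                continue
            name = parent
        by_name: dict[str, list[gemmi.Atom]] = {}
        for a in res:
            if a.element.name == "H":
                continue
            by_name.setdefault(a.name, []).append(a)
        atoms = tuple(
            Atom(n, _pick_altloc(alist).element.name,
                 np.array([_pick_altloc(alist).pos.x,
                           _pick_altloc(alist).pos.y,
                           _pick_altloc(alist).pos.z]))
            for n, alist in by_name.items()
        )
        if not any(a.name == "CA" for a in atoms):
            logger.info("dropping residue %s %s: no CA atom", name, res.seqid.num)
            continue
        residues.append(Residue(res.seqid.num, name, atoms))
    if not residues:
        raise ValueError(f"{path}: chain {chain!r} has no usable residues")
    return StructureModel(chain, tuple(residues))


def read_fasta(path: str | Path) -> str:
    """Return the first sequence in a FASTA file as a 1-letter string."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq)


def renumber_to_sequence(model: StructureModel, sequence: str) -> StructureModel:
    """Renumber residues to their 1-based position in ``sequence``.

    The model's residue letters, read in order, must embed as a subsequence
    of ``sequence``.  A constant-offset embedding consistent with the
    original author numbering is preferred (it preserves gap structure);
    otherwise the unique leftmost subsequence embedding is used.
    """
    letters = [r.one_letter for r in model.residues]
    author = [r.residue_index for r in model.residues]
    L = len(sequence)

    def offset_embedding() -> list[int] | None:
        for off in range(1 - min(author), L - max(author) + 1):
            pos = [a + off for a in author]
            if all(1 <= p <= L and sequence[p - 1] == c for p, c in zip(pos, letters)):
                return pos
        return None

    def leftmost_embedding() -> list[int] | None:
        pos, j = [], 0
        for c in letters:
            k = sequence.find(c, j)
            if k < 0:
                return None
            pos.append(k + 1)
            j = k + 1
        return pos

    new_idx = offset_embedding() or leftmost_embedding()
    if new_idx is None:
        raise ValueError("model residues do not embed in the given sequence")
    residues = tuple(
        Residue(i, r.residue_name, r.atoms)
        for i, r in zip(new_idx, model.residues)
    )
    return StructureModel(model.chain_id, residues, sequence)


def write_annotated_structure(model: StructureModel, scores, path: str | Path) -> None:
    """Write ``model`` as a PDB file with per-residue scores in the B-factor column.

    ``scores`` maps residue_index -> value in [0, 100] (an
    :class:`~plddtkit.lddt.LDDTProfile` works directly); every atom of a
    residue carries its residue's score, rounded to 2 decimals.
    """
    per_residue = getattr(scores, "per_residue", scores)
    missing = [r.residue_index for r in model.residues if r.residue_index not in per_residue]
    if missing:
        raise ValueError(f"no score for residues {missing}")
    for i, v in per_residue.items():
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"score {v} for residue {i} outside [0, 100]")

    st = gemmi.Structure()
    st.name = "plddtkit"
    gm = gemmi.Model("1")
    ch = gemmi.Chain(model.chain_id or "A")
    for r in model.residues:
        gr = gemmi.Residue()
        gr.name = r.residue_name
        gr.seqid = gemmi.SeqId(r.residue_index, " ")
        b = round(float(per_residue[r.residue_index]), 2)
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.xyz)
            ga.occ = 1.0
            ga.b_iso = b
            gr.add_atom(ga)
        ch.add_residue(gr)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def read_bfactor_scores(path: str | Path, chain: str | None = None) -> dict[int, float]:
    """Read per-residue scores back from the B-factor column (CA atom)."""
    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    ch = st[0][chain] if chain else st[0][0]
    out: dict[int, float] = {}
    for res in ch:
        for a in res:
            if a.name == "CA":
                out[res.seqid.num] = a.b_iso
    return out
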