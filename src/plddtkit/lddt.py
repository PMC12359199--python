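"""Local Distance Difference Test (LDDT) scoring.

LDDT is a superposition-free measure of how well a predicted structure
preserves the local inter-atomic distances of a reference structure.  For a
residue of interest, all partner atoms within an inclusion radius (15 A by
default) of it *in the reference* are collected; each reference/model
distance pair is checked against a ladder of tolerance thresholds
(0.5, 1, 2, 4 A), and the residue score is the fraction of (pair, threshold)
combinations preserved, scaled to 0-100.

Two modes are provided:

* ``calpha`` — partners are CA atoms only; one score per residue.
* ``all_atom`` — every heavy atom of the residue of interest is scored
  against heavy atoms of other residues, and the residue score is the mean
  over its atoms.  This all-atom variant is strictly more demanding in
  practice: it sees side-chain errors the CA-only score cannot.

Distances are always measured in the reference to build the inclusion set,
so the score is asymmetric in (reference, model) — that is intentional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import StructureModel

CATEGORIES = (">90", "70–90", "50–70", "<50")


@dataclass(frozen=True)
class LDDTConfig:
    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    mode: str = "calpha"  # "calpha" | "all_atom"
    min_sequence_separation: int = 0  # |i-j| must exceed this

    def __post_init__(self):
        if self.inclusion_radius <= 0:
            raise ValueError("inclusion_radius must be positive")
        t = self.thresholds
        if any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be positive and strictly increasing")
        if self.mode not in ("calpha", "all_atom"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class LDDTProfile:
    """Per-residue scores on the 0-100 scale plus their mean.

    Residues whose inclusion set is empty are simply absent from
    ``per_residue`` and excluded from ``model_level``.
    """

    per_residue: dict[int, float]
    model_level: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for i, v in self.per_residue.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"score {v} at residue {i} outside [0, 100]")
        if self.model_level is None:
            m = float(np.mean(list(self.per_residue.values()))) if self.per_residue else float("nan")
            object.__setattr__(self, "model_level", m)

    def __len__(self) -> int:
        return len(self.per_residue)


def _atom_table(model: StructureModel, mode: str):
    """Flatten a structure to parallel arrays (residue_index, atom_name, xyz)."""
    res_idx, names, coords = [], [], []
    for r in model.residues:
        for a in r.atoms:
            if mode == "calpha" and a.name != "CA":
                continue
            res_idx.append(r.residue_index)
            names.append(a.name)
            coords.append(a.xyz)
    return np.array(res_idx), names, np.array(coords, dtype=float)


def _shared_atoms(reference: StructureModel, model: StructureModel, mode: str):
    """Atoms present (same residue_index + atom name) in both structures."""
    ri_r, nm_r, xy_r = _atom_table(reference, mode)
    key_m = {}
    for r in model.residues:
        for a in r.atoms:
            key_m[(r.residue_index, a.name)] = a.xyz
    keep, xy_m = [], []
    for k, (ri, nm) in enumerate(zip(ri_r, nm_r)):
        key = (int(ri), nm)
        if key in key_m:
            keep.append(k)
            xy_m.append(key_m[key])
    if not keep:
        raise ValueError("reference and model share no residues/atoms")
    keep = np.array(keep)
    return ri_r[keep], [nm_r[k] for k in keep], xy_r[keep], np.array(xy_m, dtype=float)


def inclusion_pairs(
    reference: StructureModel, residue_index: int, config: LDDTConfig = LDDTConfig()
) -> set[tuple[tuple[int, str], tuple[int, str]]]:
    """Atom pairs scored for one residue, as ((res_i, atom), (res_j, atom)).

    Partners are atoms of *other* residues within ``inclusion_radius`` of the
    residue's atoms in the reference structure, subject to the sequence
    separation rule |i - j| > min_sequence_separation.
    """
    reference.residue(residue_index)  # raises if absent
    ri, names, xyz = _atom_table(reference, config.mode)
    own = np.flatnonzero(ri == residue_index)
    pairs = set()
    for a in own:
        d = np.linalg.norm(xyz - xyz[a], axis=1)
        ok = (np.abs(ri - residue_index) > config.min_sequence_separation) & (
            d <= config.inclusion_radius
        )
        for b in np.flatnonzero(ok):
            pairs.add(((residue_index, names[a]), (int(ri[b]), names[b])))
    return pairs


def _per_atom_scores(ri, xy_ref, xy_mod, config, neighbor_lists):
    """Fraction of preserved (pair, threshold) combos per atom; nan if no pairs."""
    thr = np.asarray(config.thresholds)
    n = len(ri)
    scores = np.full(n, np.nan)
    for a in range(n):
        nb = neighbor_lists[a]
        nb = nb[(np.abs(ri[nb] - ri[a]) > config.min_sequence_separation)]
        if nb.size == 0:
            continue
        d_ref = np.linalg.norm(xy_ref[nb] - xy_ref[a], axis=1)
        d_mod = np.linalg.norm(xy_mod[nb] - xy_mod[a], axis=1)
        diff = np.abs(d_ref - d_mod)
        hits = (diff[:, None] <= thr[None, :]).sum()
        scores[a] = 100.0 * hits / (nb.size * thr.size)
    return scores


def _neighbors_brute(xy_ref, radius):
    d = np.linalg.norm(xy_ref[:, None, :] - xy_ref[None, :, :], axis=2)
    return [np.flatnonzero((d[a] <= radius) & (np.arange(len(xy_ref)) != a))
            for a in range(len(xy_ref))]


def _neighbors_kdtree(xy_ref, radius):
    tree = cKDTree(xy_ref)
    out = []
    for a, nb in enumerate(tree.query_ball_point(xy_ref, r=radius)):
        nb = np.array([b for b in nb if b != a], dtype=int)
        out.append(nb)
    return out


def compute_lddt(
    reference: StructureModel,
    model: StructureModel,
    config: LDDTConfig = LDDTConfig(),
    method: str = "kdtree",
) -> LDDTProfile:
    """Score ``model`` against ``reference``; returns per-residue LDDT (0-100).

    Scoring is restricted to residues (and, in all-atom mode, atoms) present
    in both structures; pairs whose partner atom is missing from the model
    are dropped from numerator and denominator alike.  ``method`` selects the
    neighbor search ("kdtree" or "brute"); both give identical scores.
    """
    ri, names, xy_ref, xy_mod = _shared_atoms(reference, model, config.mode)
    find = {"kdtree": _neighbors_kdtree, "brute": _neighbors_brute}[method]
    neighbor_lists = find(xy_ref, config.inclusion_radius)
    atom_scores = _per_atom_scores(ri, xy_ref, xy_mod, config, neighbor_lists)

    per_residue: dict[int, float] = {}
    for r in np.unique(ri):
        s = atom_scores[ri == r]
        s = s[~np.isnan(s)]
        if s.size:
            per_residue[int(r)] = float(s.mean())
    if not per_residue:
        return LDDTProfile({}, float("nan"))
    return LDDTProfile(per_residue)


def residue_error(pred: LDDTProfile, true: LDDTProfile, residue_index: int) -> float:
    """|predicted - true| LDDT for one residue (both must define it)."""
    if residue_index not in pred.per_residue or residue_index not in true.per_residue:
        raise KeyError(f"residue {residue_index} undefined in a profile")
    return abs(pred.per_residue[residue_index] - true.per_residue[residue_index])


def model_error(pred: LDDTProfile, true: LDDTProfile) -> float:
    """Mean absolute LDDT error over residues defined in both profiles."""
    shared = sorted(set(pred.per_residue) & set(true.per_residue))
    if not shared:
        raise ValueError("profiles share no residues")
    return float(np.mean([residue_error(pred, true, i) for i in shared]))


def lddt_category(score: float) -> str:
    """Bin an LDDT value into the four standard confidence categories."""
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score {score} outside [0, 100]")
    if score > 90:
        return CATEGORIES[0]
    if score > 70:
        return CATEGORIES[1]
    if score > 50:
        return CATEGORIES[2]
    return CATEGORIES[3]
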