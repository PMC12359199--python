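"""Ensemble superposition and per-residue fluctuation (RMSF).

When a structure predictor is run several times with dropout enabled, the
spread of the resulting models carries information: residues the network is
unsure about land in different places each run.  RMSF quantifies that spread
per residue after removing the global rigid motion between members, and it
anticorrelates with local model quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import StructureModel


@dataclass(frozen=True)
class Ensemble:
    """>= 2 structure models sharing residue indexing (typically 5 dropout runs)."""

    members: tuple[StructureModel, ...]
    reference_member: int = 0

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if not (0 <= self.reference_member < len(self.members)):
            raise ValueError("reference_member out of range")
        if len(self.common_residues()) < 3:
            raise ValueError("members share fewer than 3 residues")

    def common_residues(self) -> list[int]:
        common = set(self.members[0].residue_indices)
        for m in self.members[1:]:
            common &= set(m.residue_indices)
        return sorted(common)


@dataclass(frozen=True)
class RMSFProfile:
    per_residue: dict[int, float]

    def __post_init__(self):
        if any(v < 0 for v in self.per_residue.values()):
            raise ValueError("RMSF values must be non-negative")

    def __len__(self) -> int:
        return len(self.per_residue)


def _shared_ca(mobile: StructureModel, target: StructureModel):
    shared = sorted(set(mobile.residue_indices) & set(target.residue_indices))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared CA atoms")
    P = np.array([mobile.residue(i).ca.xyz for i in shared])
    Q = np.array([target.residue(i).ca.xyz for i in shared])
    return shared, P, Q


def superpose(mobile: StructureModel, target: StructureModel):
    """Least-squares (Kabsch) superposition of mobile CA onto target CA.

    Returns ``(transformed_mobile, rmsd)`` where the rigid motion minimizing
    the CA RMSD over shared residues has been applied to every atom of
    ``mobile``.  Collinear CA sets are rejected (rotation underdetermined).
    """
    shared, P, Q = _shared_ca(mobile, target)
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    # collinearity check: second singular value of the centered cloud ~ 0
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) CA set: superposition underdetermined")
    rot, _ = Rotation.align_vectors(Qc, Pc)
    R = rot.as_matrix()
    t = Q.mean(0) - R @ P.mean(0)
    moved = mobile.transformed(R, t)
    Pm = np.array([moved.residue(i).ca.xyz for i in shared])
    rmsd = float(np.sqrt(np.mean(np.sum((Pm - Q) ** 2, axis=1))))
    return moved, rmsd


def compute_rmsf(ensemble: Ensemble) -> RMSFProfile:
    """Per-residue CA fluctuation about the member-mean position, in Angstrom.

    All members are superposed onto the reference member in a single pass;
    RMSF_i = sqrt(mean_m ||x_i^m - xbar_i||^2) over residues present in every
    member.
    """
    anchor = ensemble.members[ensemble.reference_member]
    aligned = []
    for k, m in enumerate(ensemble.members):
        aligned.append(m if k == ensemble.reference_member else superpose(m, anchor)[0])
    common = ensemble.common_residues()
    X = np.array([[m.residue(i).ca.xyz for i in common] for m in aligned])  # (M, L, 3)
    mean = X.mean(axis=0, keepdims=True)
    rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    return RMSFProfile({i: float(v) for i, v in zip(common, rmsf)})
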