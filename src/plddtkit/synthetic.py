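"""Synthetic structures, decoys, ensembles and feature tensors with known truth.

Everything downstream — the LDDT scorer, the RMSF pipeline and the
confidence head — is exercised on data generated here, so ground truth is
always available by construction:

* :func:`make_backbone` draws an idealized CA-trace protein from a
  parametric alpha-helix (rise 1.5 A/residue, radius 2.3 A, 100 deg/residue)
  broken into rigid segments by random hinge rotations, with CB side-chain
  stubs so all-atom scoring has something to chew on.
* :func:`make_decoy` perturbs chosen residue segments with i.i.d. Gaussian
  coordinate noise; the true LDDT of the decoy follows from the scorer.
* :func:`make_ensemble` emulates dropout replicates: per-residue jitter
  proportional to the injected error, so fluctuation anticorrelates with
  quality.
* :func:`make_feature_bundle` fills the four feature tensors with noise
  plus a quality signal at a controllable signal-to-noise ratio
  (``feature_snr``); at snr = 0 every channel, including RMSF, is made
  signal-free so negative controls are exact.

Training graphs are assembled with the *reference* backbone coordinates, so
quality information reaches the head only through the feature channels —
the property the negative control relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .features import (
    ESM_ATTN_DIM, ESM_EMBED_DIM, PAIR_DIM, SINGLE_DIM,
    AblationFlags, FeatureBundle, ProteinGraph, assemble_graph, save_bundle,
)
from .lddt import LDDTConfig, LDDTProfile, compute_lddt
from .rmsf import Ensemble, compute_rmsf
from .structures import ONE_TO_THREE, Atom, Residue, StructureModel

HELIX_RISE = 1.5     # A per residue
HELIX_RADIUS = 2.3   # A
HELIX_TWIST = np.deg2rad(100.0)
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: decoy segment noise levels (A) and their sampling probabilities; chosen to
#: populate all four LDDT confidence categories in a mixed dataset.
SEGMENT_SIGMAS = (0.0, 0.5, 1.5, 3.0, 6.0)
SEGMENT_PROBS = (0.30, 0.25, 0.20, 0.15, 0.10)


@dataclass(frozen=True)
class SyntheticSpec:
    length: int = 60
    error_segments: tuple[tuple[int, int, float], ...] = ()
    ensemble_size: int = 5
    ensemble_jitter_scale: float = 2.0   # A of jitter for a hypothetical LDDT-0 residue
    sidechain_noise_factor: float = 1.5  # side-chain sigma multiplier vs backbone
    feature_snr: float = 4.0             # variance ratio signal/noise in feature channels
    seed: int = 0

    def __post_init__(self):
        for start, end, sigma in self.error_segments:
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"segment ({start}, {end}) outside [1, {self.length}]")
            if sigma < 0:
                raise ValueError("segment sigma must be >= 0")
        if self.feature_snr < 0:
            raise ValueError("feature_snr must be >= 0")
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be >= 2")


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def make_backbone(L: int, seed: int = 0) -> StructureModel:
    """An idealized helical-segment protein of length ``L`` (deterministic per seed).

    CA atoms follow the parametric helix; at random segment boundaries
    (every 8-20 residues) the remaining chain is rigidly rotated about the
    boundary CA, producing a compact multi-segment fold while preserving
    consecutive CA-CA distances (~3.8 A).  Non-glycine residues get a CB
    stub at 1.5 A from the CA.
    """
    if L < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    t = np.arange(L)
    ca = np.stack(
        [HELIX_RADIUS * np.cos(HELIX_TWIST * t),
         HELIX_RADIUS * np.sin(HELIX_TWIST * t),
         HELIX_RISE * t], axis=1
    )
    b = 0
    while True:
        b += int(rng.integers(8, 21))
        if b >= L - 1:
            break
        R = _rotation_about(rng.normal(size=3), rng.uniform(-np.pi / 3, np.pi / 3))
        ca[b + 1:] = (ca[b + 1:] - ca[b]) @ R.T + ca[b]

    seq = "".join(rng.choice(list(AA20)) for _ in range(L))
    residues = []
    for i in range(L):
        atoms = [Atom("CA", "C", ca[i])]
        if seq[i] != "G":
            if L == 2:
                ref = ca[1 - i]
            elif i == 0:
                ref = ca[1]
            elif i == L - 1:
                ref = ca[L - 2]
            else:
                ref = 0.5 * (ca[i - 1] + ca[i + 1])
            v = ca[i] - ref
            n = np.linalg.norm(v)
            v = v / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
            atoms.append(Atom("CB", "C", ca[i] + 1.5 * v))
        residues.append(Residue(i + 1, ONE_TO_THREE[seq[i]], tuple(atoms)))
    return StructureModel("A", tuple(residues), seq)


def _per_residue_sigma(spec: SyntheticSpec) -> np.ndarray:
    sigma = np.zeros(spec.length)
    for start, end, s in spec.error_segments:
        sigma[start - 1:end] = s
    return sigma


def make_decoy(
    reference: StructureModel,
    spec: SyntheticSpec,
    lddt_config: LDDTConfig = LDDTConfig(),
) -> tuple[StructureModel, LDDTProfile]:
    """Perturbed copy of ``reference`` plus its true LDDT against the reference.

    Every atom of a residue inside an error segment receives i.i.d. Gaussian
    coordinate noise; backbone atoms (N/CA/C/O) get the segment's sigma and
    side-chain atoms get ``sidechain_noise_factor`` times it, reflecting
    that side chains are modeled less accurately than the backbone — this is
    what makes the all-atom score's extra stringency emerge.  Residues
    outside segments are untouched; larger sigma gives stochastically lower
    local LDDT.
    """
    if len(reference) != spec.length:
        raise ValueError("spec.length does not match the reference")
    rng = np.random.default_rng(spec.seed)
    sigma = _per_residue_sigma(spec)
    backbone = {"N", "CA", "C", "O"}
    residues = []
    for r, s in zip(reference.residues, sigma):
        atoms = tuple(
            Atom(a.name, a.element,
                 a.xyz + rng.normal(
                     0.0, s * (1.0 if a.name in backbone
                               else spec.sidechain_noise_factor), size=3)
                 if s > 0 else a.xyz)
            for a in r.atoms
        )
        residues.append(Residue(r.residue_index, r.residue_name, atoms))
    decoy = StructureModel(reference.chain_id, tuple(residues), reference.sequence)
    return decoy, compute_lddt(reference, decoy, lddt_config)


def make_ensemble(
    reference: StructureModel,
    true_lddt: LDDTProfile | dict[int, float],
    spec: SyntheticSpec,
    signal_free: bool = False,
) -> Ensemble:
    """Dropout-replicate stand-in: jittered copies with error-linked amplitude.

    Residue i is jittered with sigma = ensemble_jitter_scale * (100 -
    LDDT_i)/100, so poorly modeled residues fluctuate more.  With
    ``signal_free`` (used when feature_snr is 0) a constant, quality-blind
    sigma is applied instead.
    """
    per_residue = getattr(true_lddt, "per_residue", true_lddt)
    rng = np.random.default_rng(spec.seed + 101)
    defined = list(per_residue.values())
    fallback = float(np.mean(defined)) if defined else 100.0
    members = []
    for _ in range(spec.ensemble_size):
        residues = []
        for r in reference.residues:
            lddt = per_residue.get(r.residue_index, fallback)
            if signal_free:
                s = spec.ensemble_jitter_scale * 0.25
            else:
                s = spec.ensemble_jitter_scale * (100.0 - lddt) / 100.0
            atoms = tuple(
                Atom(a.name, a.element, a.xyz + (rng.normal(0.0, s, size=3) if s > 0 else 0.0))
                for a in r.atoms
            )
            residues.append(Residue(r.residue_index, r.residue_name, atoms))
        members.append(StructureModel(reference.chain_id, tuple(residues), reference.sequence))
    return Ensemble(tuple(members))


#: reference within-protein spread of true LDDT on the 0-1 scale; fixes the
#: absolute amplitude that makes a channel's variance ratio equal feature_snr
#: for a typical mixed-quality protein.
SIGNAL_REF_SD = 0.25


def _signal_amplitude(snr: float) -> float:
    return np.sqrt(snr) / SIGNAL_REF_SD


def make_feature_bundle(
    true_lddt: np.ndarray,
    L: int,
    spec: SyntheticSpec,
    reference: StructureModel | None = None,
    ablation: AblationFlags = AblationFlags(),
) -> FeatureBundle:
    """Feature tensors carrying a noisy per-residue quality signal.

    The quality signal is the absolute true LDDT on the 0-1 scale, embedded
    against unit noise at an amplitude that makes the variance ratio equal
    ``feature_snr`` for a typical mixed-quality protein: column 0 of the
    single representation and of the language-model embedding each get
    independent noisy copies; ``pair[i, j, 0]`` gets the endpoint-mean
    signal; the attention tensor is pure noise; all remaining entries are
    i.i.d. N(0,1).  Because the signal is absolute (not per-protein
    standardized), features carry cross-protein calibration, as real
    representations do.
    The RMSF channel comes from a generated ensemble (quality-linked jitter,
    or quality-blind when feature_snr is 0).  ``reference`` is needed for
    the RMSF channel; omit it to fall back to a noisy direct fluctuation
    proxy.
    """
    true_lddt = np.asarray(true_lddt, dtype=float)
    if true_lddt.shape != (L,):
        raise ValueError("true_lddt length does not match L")
    rng = np.random.default_rng(spec.seed + 202)
    amp = _signal_amplitude(spec.feature_snr)
    u = true_lddt / 100.0

    single = rng.normal(size=(L, SINGLE_DIM))
    single[:, 0] = amp * u + rng.normal(size=L)
    esm_embed = rng.normal(size=(L, ESM_EMBED_DIM))
    esm_embed[:, 0] = amp * u + rng.normal(size=L)
    pair = rng.normal(size=(L, L, PAIR_DIM))
    pair[:, :, 0] = amp * 0.5 * (u[:, None] + u[None, :]) + rng.normal(size=(L, L))
    esm_attn = rng.normal(size=(L, L, ESM_ATTN_DIM))

    signal_free = spec.feature_snr == 0
    if reference is not None:
        profile = {i + 1: v for i, v in enumerate(true_lddt)}
        ens = make_ensemble(reference, profile, spec, signal_free=signal_free)
        rp = compute_rmsf(ens).per_residue
        rmsf = np.array([rp.get(i + 1, 0.0) for i in range(L)])[:, None]
    else:
        base = np.zeros(L) if signal_free else (100.0 - true_lddt) / 100.0
        rmsf = (spec.ensemble_jitter_scale * base + 0.05 * np.abs(rng.normal(size=L)))[:, None]
    return FeatureBundle(single, pair, esm_embed, esm_attn, rmsf, ablation)


@dataclass(frozen=True)
class SyntheticProtein:
    """One generated fixture: reference, decoy with truth, ensemble, features."""

    name: str
    spec: SyntheticSpec
    reference: StructureModel
    decoy: StructureModel
    true_lddt: LDDTProfile
    ensemble: Ensemble
    bundle: FeatureBundle

    def graph(self) -> ProteinGraph:
        """Training graph: bundle features on the reference CA geometry."""
        return assemble_graph(
            self.bundle, self.reference.ca_coords(), self.reference.residue_indices
        )

    def true_vector(self) -> np.ndarray:
        vals = [self.true_lddt.per_residue.get(i, np.nan)
                for i in self.reference.residue_indices]
        return np.asarray(vals, dtype=float)


def _random_segments(L: int, rng: np.random.Generator):
    segs, start = [], 1
    while start <= L:
        end = min(L, start + int(rng.integers(8, 21)) - 1)
        sigma = float(rng.choice(SEGMENT_SIGMAS, p=SEGMENT_PROBS))
        segs.append((start, end, sigma))
        start = end + 1
    return tuple(segs)


def make_protein(spec: SyntheticSpec, name: str = "synth") -> SyntheticProtein:
    """Generate one complete fixture from a fully specified spec."""
    reference = make_backbone(spec.length, seed=spec.seed)
    decoy, profile = make_decoy(reference, spec)
    truth = np.array([
        profile.per_residue.get(i, np.nan) for i in range(1, spec.length + 1)
    ])
    fallback = np.nanmean(truth) if np.isfinite(truth).any() else 100.0
    truth = np.where(np.isfinite(truth), truth, fallback)
    ensemble = make_ensemble(reference, profile, spec,
                             signal_free=spec.feature_snr == 0)
    bundle = make_feature_bundle(truth, spec.length, spec, reference=reference)
    return SyntheticProtein(name, spec, reference, decoy, profile, ensemble, bundle)


def make_dataset(
    n_proteins: int,
    length_range: tuple[int, int] = (40, 80),
    template: SyntheticSpec = SyntheticSpec(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[SyntheticProtein]:
    """Generate ``n_proteins`` independent fixtures with randomized lengths
    and error segments (lengths honor a 40-residue floor by default).

    With ``out_dir`` set, writes reference/decoy/ensemble PDBs, the feature
    bundle and a JSON manifest per protein, in a layout the command-line
    ``train`` / ``evaluate`` subcommands consume.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    children = np.random.SeedSequence(seed).spawn(n_proteins)
    records = []
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        sub = int(rng.integers(0, 2**31 - 1))
        L = int(rng.integers(lo, hi + 1))
        spec = replace(
            template, length=L, seed=sub,
            error_segments=_random_segments(L, rng),
        )
        records.append(make_protein(spec, name=f"synth{k:03d}"))

    if out_dir is not None:
        from .structures import write_annotated_structure
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for rec in records:
            d = out / rec.name
            d.mkdir(exist_ok=True)
            ones = {i: 100.0 for i in rec.reference.residue_indices}
            write_annotated_structure(rec.reference, ones, d / "reference.pdb")
            write_annotated_structure(rec.decoy, ones, d / "decoy.pdb")
            for m, member in enumerate(rec.ensemble.members):
                write_annotated_structure(member, ones, d / f"ensemble_{m}.pdb")
            save_bundle(rec.bundle, d / "bundle.npz")
            manifest.append({
                "name": rec.name, "length": rec.spec.length, "seed": rec.spec.seed,
                "error_segments": [list(s) for s in rec.spec.error_segments],
                "feature_snr": rec.spec.feature_snr,
                "ensemble_jitter_scale": rec.spec.ensemble_jitter_scale,
                "true_lddt": {str(i): round(v, 4)
                              for i, v in sorted(rec.true_lddt.per_residue.items())},
            })
        (out / "manifest.json").write_text(json.dumps(
            {"seed": seed, "n_proteins": n_proteins, "proteins": manifest}, indent=2))
    return records


def training_pairs(records) -> list[tuple[ProteinGraph, LDDTProfile]]:
    """(graph, true profile) pairs ready for head training."""
    return [(rec.graph(), rec.true_lddt) for rec in records]
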