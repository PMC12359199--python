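"""Feature tensors and protein-graph assembly for the confidence head.

The head consumes four opaque tensors produced upstream by a structure
predictor and a protein language model — the per-residue "single"
representation (L x 384), the pairwise representation (L x L x 128),
layer-averaged language-model embeddings (L x 33) and layer/head-averaged
attention maps (L x L x 33) — plus per-residue RMSF.  Here they are bundled,
serialized, and rearranged into a graph: nodes are residues, edges connect
residue pairs whose CA atoms lie within 16 A.

Ablation flags reproduce the feature-analysis variants: drop RMSF, drop the
language-model channels, drop learned edge attributes (graph connectivity is
kept — message passing still needs edges), or keep only the single
representation ("no extra features").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

SINGLE_DIM = 384
PAIR_DIM = 128
ESM_EMBED_DIM = 33
ESM_ATTN_DIM = 33
EDGE_CUTOFF = 16.0


@dataclass(frozen=True)
class AblationFlags:
    use_rmsf: bool = True
    use_esm: bool = True
    use_edges: bool = True
    use_extra: bool = True


@dataclass(frozen=True)
class FeatureBundle:
    single: np.ndarray      # (L, 384)
    pair: np.ndarray        # (L, L, 128)
    esm_embed: np.ndarray   # (L, 33)
    esm_attn: np.ndarray    # (L, L, 33)
    rmsf: np.ndarray        # (L, 1)
    ablation: AblationFlags = AblationFlags()

    def __post_init__(self):
        L = self.single.shape[0]
        shapes = {
            "single": (L, SINGLE_DIM),
            "pair": (L, L, PAIR_DIM),
            "esm_embed": (L, ESM_EMBED_DIM),
            "esm_attn": (L, L, ESM_ATTN_DIM),
            "rmsf": (L, 1),
        }
        for name, want in shapes.items():
            arr = getattr(self, name)
            if arr.shape != want:
                raise ValueError(f"{name} has shape {arr.shape}, expected {want}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def L(self) -> int:
        return self.single.shape[0]

    @property
    def node_dim(self) -> int:
        f = self.ablation
        if not f.use_extra:
            return SINGLE_DIM
        return SINGLE_DIM + ESM_EMBED_DIM * f.use_esm + 1 * f.use_rmsf

    @property
    def edge_dim(self) -> int:
        f = self.ablation
        if not f.use_edges:
            return 0
        if not f.use_extra:
            return PAIR_DIM
        return PAIR_DIM + ESM_ATTN_DIM * f.use_esm


@dataclass(frozen=True)
class ProteinGraph:
    coords: np.ndarray          # (L, 3) CA coordinates, Angstrom
    node_input: np.ndarray      # (L, D_node) raw concatenated features
    edges: np.ndarray           # (E, 2) directed pairs (i, j), 0-based node ids
    edge_input: np.ndarray      # (E, D_edge); D_edge may be 0
    residue_indices: tuple[int, ...]

    @property
    def L(self) -> int:
        return self.coords.shape[0]

    @property
    def E(self) -> int:
        return self.edges.shape[0]


def build_edges(coords: np.ndarray, cutoff: float = EDGE_CUTOFF) -> np.ndarray:
    """Directed edge list: all ordered pairs i != j with ||x_i - x_j|| <= cutoff."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 residues to build edges")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    mask = (d <= cutoff) & ~np.eye(coords.shape[0], dtype=bool)
    i, j = np.nonzero(mask)
    return np.stack([i, j], axis=1)


def assemble_graph(
    bundle: FeatureBundle, coords: np.ndarray, residue_indices, cutoff: float = EDGE_CUTOFF
) -> ProteinGraph:
    """Concatenate bundle tensors into node/edge inputs on the 16 A CA graph.

    Pure rearrangement — no numeric transformation; the learned transition
    layers live inside the prediction head.  Edge i->j carries
    ``pair[i, j, :]`` (plus ``esm_attn[i, j, :]`` when language-model
    features are on); with ``use_edges`` off the edge list is kept for
    connectivity but ``edge_input`` is empty.
    """
    coords = np.asarray(coords, dtype=float)
    L = bundle.L
    if coords.shape != (L, 3) or len(residue_indices) != L:
        raise ValueError("bundle, coords and residue_indices disagree on L")
    f = bundle.ablation
    node_parts = [bundle.single]
    if f.use_extra:
        if f.use_esm:
            node_parts.append(bundle.esm_embed)
        if f.use_rmsf:
            node_parts.append(bundle.rmsf)
    node_input = np.concatenate(node_parts, axis=1)

    edges = build_edges(coords, cutoff)
    if f.use_edges:
        edge_parts = [bundle.pair[edges[:, 0], edges[:, 1], :]]
        if f.use_extra and f.use_esm:
            edge_parts.append(bundle.esm_attn[edges[:, 0], edges[:, 1], :])
        edge_input = np.concatenate(edge_parts, axis=1)
    else:
        edge_input = np.zeros((edges.shape[0], 0))
    return ProteinGraph(coords, node_input, edges, edge_input, tuple(residue_indices))


def save_bundle(bundle: FeatureBundle, path: str | Path) -> None:
    """Serialize to ``.npz`` with named arrays and a JSON-encoded ablation field.

    Layout (documented so real predictor/language-model tensors can be
    exported into it): arrays ``single`` (L,384), ``pair`` (L,L,128),
    ``esm_embed`` (L,33), ``esm_attn`` (L,L,33), ``rmsf`` (L,1), plus
    scalar ``L`` and a JSON string ``ablation``.
    """
    np.savez_compressed(
        path,
        single=bundle.single,
        pair=bundle.pair,
        esm_embed=bundle.esm_embed,
        esm_attn=bundle.esm_attn,
        rmsf=bundle.rmsf,
        L=np.array(bundle.L),
        ablation=np.array(json.dumps(vars(bundle.ablation))),
    )


def load_bundle(path: str | Path) -> FeatureBundle:
    with np.load(path) as z:
        flags = AblationFlags(**json.loads(str(z["ablation"])))
        return FeatureBundle(
            single=z["single"], pair=z["pair"], esm_embed=z["esm_embed"],
            esm_attn=z["esm_attn"], rmsf=z["rmsf"], ablation=flags,
        )
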