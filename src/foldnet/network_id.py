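"""Intrinsic-network identification by spatial overlap with templates.

Rows of the sparse coefficient matrix are per-atom spatial maps;
binarized maps are compared to template vertex sets by the overlap rate
``R(S, T) = |S & T| / |T|`` and each template is assigned the atom with
maximal R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .sparse_coding import SparseCodes
from .synthetic_cortex import SurfaceMesh

__all__ = [
    "SpatialMap",
    "NetworkMatch",
    "extract_spatial_maps",
    "binarize_map",
    "overlap_rate",
    "match_networks",
    "map_volume_to_surface",
]


@dataclass
class SpatialMap:
    atom_index: int
    values: np.ndarray  # per retained vertex
    vertex_ids: np.ndarray


@dataclass
class NetworkMatch:
    template_id: int
    atom_index: int
    S: set
    T: set
    R: float
    no_overlap: bool = False  # warning flag when every atom scored R == 0


def extract_spatial_maps(codes: SparseCodes, vertex_ids: np.ndarray) -> list:
    """One spatial map per atom: row k of alpha aligned to vertex ids."""
    vertex_ids = np.asarray(vertex_ids)
    if codes.alpha.shape[1] != vertex_ids.shape[0]:
        raise ValueError("vertex id count must match code columns")
    return [SpatialMap(atom_index=k, values=codes.alpha[k].copy(), vertex_ids=vertex_ids)
            for k in range(codes.m)]


def binarize_map(smap: SpatialMap, rule: str = "nonzero", tau: float = 2.0) -> set:
    """Turn a spatial map into a vertex set.

    ``nonzero``: vertices with a nonzero coefficient.  ``z``: vertices
    whose z-score (over the map's nonzero support) exceeds ``tau``.
    """
    values = smap.values
    ids = smap.vertex_ids
    if rule == "nonzero":
        sel = values != 0
    elif rule == "z":
        support = values != 0
        if not support.any():
            return set()
        mu = values[support].mean()
        sd = values[support].std()
        if sd == 0:
            return set()
        sel = np.zeros_like(support)
        sel[support] = (values[support] - mu) / sd > tau
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    return set(int(v) for v in ids[sel])


def overlap_rate(S: set, T: set) -> float:
    """``|S & T| / |T|`` — fraction of the template covered by S."""
    if not T:
        raise ValueError("template set is empty")
    return len(set(S) & set(T)) / len(T)


def match_networks(maps: list, templates: list, rule: str = "nonzero",
                   tau: float = 2.0) -> list:
    """Per template, the atom with maximal overlap rate (ties: lower atom index)."""
    if not templates:
        raise ValueError("need at least one template")
    sets = [(smap.atom_index, binarize_map(smap, rule=rule, tau=tau)) for smap in maps]
    matches = []
    for tid, T in enumerate(templates):
        T = set(T)
        best_atom, best_S, best_R = None, set(), -1.0
        for atom_index, S in sets:
            r = overlap_rate(S, T)
            # ties broken by the lower atom index regardless of map order
            if r > best_R or (r == best_R and best_atom is not None
                              and atom_index < best_atom):
                best_atom, best_S, best_R = atom_index, S, r
        matches.append(NetworkMatch(
            template_id=tid, atom_index=best_atom, S=best_S, T=T,
            R=best_R, no_overlap=(best_R == 0.0),
        ))
    return matches


def map_volume_to_surface(voxel_centers: np.ndarray, mesh: SurfaceMesh) -> set:
    """Assign each voxel center to the Euclidean-nearest mesh vertex.

    Returns the union of assigned vertex indices.  Distance ties go to
    the lower vertex index.
    """
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    voxel_centers = np.atleast_2d(np.asarray(voxel_centers, dtype=float))
    if voxel_centers.size == 0:
        return set()
    tree = cKDTree(mesh.vertex_coords)
    dist, idx = tree.query(voxel_centers)
    out = set()
    for p, d, i in zip(voxel_centers, dist, idx):
        # enforce the low-index tie rule, which KDTree does not guarantee
        cand = tree.query_ball_point(p, d + 1e-9)
        out.add(min(cand) if cand else int(i))
    return out
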