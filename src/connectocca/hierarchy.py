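"""Group-level dendrogram and the deduplicated multiscale module catalog.

A single hierarchical tree is built from the group FC and SC matrices: each
node's profile is its FC row concatenated with its SC row (each modality
standardized over all its entries; SC is log(1+x)-transformed first so
heavy-tailed streamline counts do not dominate), agglomerated by average
linkage on correlation distance. Cutting the tree at every level of a scale
grid and deduplicating the resulting node sets yields the "unique module"
catalog whose members define the multiscale connectivity features.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist

__all__ = ["ScaleGrid", "Dendrogram", "Module", "ModuleCatalog",
           "build_dendrogram", "cut", "enumerate_unique_modules", "restrict_catalog"]


@dataclass(frozen=True)
class ScaleGrid:
    """Arithmetic grid of tree-cut levels (numbers of modules M)."""

    m_min: int
    m_max: int
    m_step: int

    def __post_init__(self):
        if self.m_min < 2:
            raise ValueError("m_min must be >= 2")
        if self.m_max < self.m_min:
            raise ValueError("m_max must be >= m_min")
        if self.m_step < 1:
            raise ValueError("m_step must be >= 1")
        if (self.m_max - self.m_min) % self.m_step != 0:
            raise ValueError("(m_max - m_min) must be divisible by m_step")

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(range(self.m_min, self.m_max + 1, self.m_step))

    @property
    def n_levels(self) -> int:
        return (self.m_max - self.m_min) // self.m_step + 1

    def capped(self, v: int) -> "ScaleGrid":
        """Largest sub-grid (same m_min and step) whose m_max does not exceed ``v``."""
        if self.m_max <= v:
            return self
        if self.m_min > v:
            raise ValueError(f"grid m_min={self.m_min} exceeds node count {v}")
        m_max = self.m_min + self.m_step * ((v - self.m_min) // self.m_step)
        return ScaleGrid(self.m_min, m_max, self.m_step)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over V leaves (scipy linkage encoding)."""

    linkage_: np.ndarray  # (V-1, 4) scipy linkage matrix
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def merge_list(self) -> list[tuple[int, int, float]]:
        """Ordered merges as (cluster_a, cluster_b, height); clusters 0..V-1
        are leaves, cluster V+k is the result of merge k."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_]


@dataclass
class Module:
    module_id: str
    nodes: tuple[int, ...]
    scales: list[int] = field(default_factory=list)


@dataclass
class ModuleCatalog:
    """Deduplicated non-singleton modules cut from one dendrogram at a grid
    of levels, ordered by first appearance (coarsest level first), then by
    smallest node index."""

    modules: list[Module]
    grid: ScaleGrid

    def __len__(self) -> int:
        return len(self.modules)

    def node_sets(self) -> list[tuple[int, ...]]:
        return [m.nodes for m in self.modules]


def _check_square_symmetric(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return mat


def _global_z(mat: np.ndarray) -> np.ndarray:
    sd = mat.std()
    return (mat - mat.mean()) / (sd if sd > 0 else 1.0)


def build_dendrogram(
    group_fc: np.ndarray,
    group_sc: np.ndarray,
    *,
    method: str = "average",
    metric: str = "correlation",
    log_sc: bool = True,
    node_ids: Sequence[str] | None = None,
) -> Dendrogram:
    """Cluster nodes by their concatenated FC+SC connectivity profiles.

    Each modality is standardized across all of its entries before
    concatenation so FC (bounded in [-1,1]) and SC (counts) contribute on the
    same scale; ``log_sc`` applies log(1+x) to SC first. Distance/linkage
    default to correlation distance with average linkage but are overridable
    (e.g. ``metric='euclidean'``, ``method='ward'``).
    """
    fc = _check_square_symmetric(group_fc, "group_fc")
    sc = _check_square_symmetric(group_sc, "group_sc")
    if fc.shape != sc.shape:
        raise ValueError("group_fc and group_sc must share the node order")
    v = fc.shape[0]
    if v < 3:
        raise ValueError("need at least 3 nodes to build a dendrogram")
    if node_ids is None:
        node_ids = tuple(f"node_{i:04d}" for i in range(v))
    elif len(node_ids) != v:
        raise ValueError("node_ids length mismatch")
    sc_t = np.log1p(sc) if log_sc else sc
    profiles = np.hstack([_global_z(fc), _global_z(sc_t)])
    Z = linkage(pdist(profiles, metric=metric), method=method)
    return Dendrogram(linkage_=Z, leaf_ids=tuple(node_ids))


def cut(dendrogram: Dendrogram, m: int) -> list[tuple[int, ...]]:
    """Partition of the leaves into exactly ``m`` modules.

    Cuts are nested by construction (undoing the last merges), so the cut at
    ``m2 > m1`` refines the cut at ``m1``. Modules are returned ordered by
    their smallest node index.
    """
    v = dendrogram.n_leaves
    if not 1 <= m <= v:
        raise ValueError(f"m must lie in [1, {v}], got {m}")
    labels = cut_tree(dendrogram.linkage_, n_clusters=m).ravel()
    groups: dict[int, list[int]] = {}
    for node, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(node)
    return sorted((tuple(g) for g in groups.values()), key=lambda g: g[0])


def enumerate_unique_modules(dendrogram: Dendrogram, grid: ScaleGrid) -> ModuleCatalog:
    """Union of all grid-level cuts, deduplicated by exact node-set equality,
    with singleton modules discarded."""
    v = dendrogram.n_leaves
    if grid.m_max > v:
        raise ValueError(f"grid m_max={grid.m_max} exceeds leaf count {v}")
    seen: dict[tuple[int, ...], Module] = {}
    order: list[tuple[int, ...]] = []
    for m in grid.levels:
        for nodes in cut(dendrogram, m):
            if len(nodes) < 2:
                continue
            if nodes not in seen:
                seen[nodes] = Module(module_id="", nodes=nodes)
                order.append(nodes)
            if m not in seen[nodes].scales:
                seen[nodes].scales.append(m)
    modules = []
    for k, nodes in enumerate(order):
        mod = seen[nodes]
        mod.module_id = f"mod_{k:04d}"
        modules.append(mod)
    return ModuleCatalog(modules=modules, grid=grid)


def restrict_catalog(catalog: ModuleCatalog, keep_nodes: Sequence[int]) -> ModuleCatalog:
    """Restrict a catalog to a surviving node subset (frozen-tree lesions).

    Node indices are re-expressed in the reduced ordering; modules shrinking
    below two nodes are dropped and coinciding restrictions are merged (their
    scale lists united, first appearance kept).
    """
    keep = sorted(int(i) for i in keep_nodes)
    new_index = {old: new for new, old in enumerate(keep)}
    keep_set = set(keep)
    seen: dict[tuple[int, ...], Module] = {}
    order: list[tuple[int, ...]] = []
    for mod in catalog.modules:
        nodes = tuple(new_index[i] for i in mod.nodes if i in keep_set)
        if len(nodes) < 2:
            continue
        if nodes not in seen:
            seen[nodes] = Module(module_id="", nodes=nodes, scales=list(mod.scales))
            order.append(nodes)
        else:
            for s in mod.scales:
                if s not in seen[nodes].scales:
                    seen[nodes].scales.append(s)
    modules = []
    for k, nodes in enumerate(order):
        mod = seen[nodes]
        mod.module_id = f"mod_{k:04d}"
        mod.scales = sorted(mod.scales)
        modules.append(mod)
    return ModuleCatalog(modules=modules, grid=catalog.grid)
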