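"""Projection of the CCA solution back to feature space and its summaries.

The first canonical direction in component space is pulled back through the
PCA rotation, W = W_PCA . W_CCA, giving one absolute weight per connectivity
feature. The weight vector is z-scored across features and thresholded
(|map| at Z > 2 by default); surviving weights are aggregated per module, and
module node sets are intersected with resting-state-network labels to give
per-network overlap percentages. A per-scale modality balance table (with a
label-permutation test) summarizes whether either modality dominates at any
scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assoc import AssociationModel
from .features import FeatureMeta
from .hierarchy import ModuleCatalog

__all__ = ["BrainMap", "project_weights", "threshold_map",
           "overlap_with_networks", "weight_balance"]


@dataclass
class BrainMap:
    """Thresholded feature-space weight map of the first canonical mode."""

    w: np.ndarray                  # absolute projected weights, one per feature
    z: np.ndarray                  # z-scores of w across features
    surviving: np.ndarray          # indices of features with z > threshold
    z_thresh: float
    meta: list[FeatureMeta]
    per_module_weight: dict[str, float] = field(default_factory=dict)
    per_network_overlap: dict[str, float] = field(default_factory=dict)


def project_weights(model: AssociationModel) -> np.ndarray:
    """w = |W_PCA . a1|: absolute feature-space weights of the first mode."""
    if model.w_pca is None or model.A is None:
        raise ValueError("model is not fitted")
    return np.abs(model.w_pca @ model.A[:, 0])


def threshold_map(
    w: np.ndarray,
    meta: Sequence[FeatureMeta],
    z_thresh: float = 2.0,
) -> BrainMap:
    """z-score the weight vector across features and keep z > ``z_thresh``.

    A constant weight vector has all z = 0 and therefore an empty surviving
    set (not an error). Surviving weights are summed per module.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("w must be a vector of at least 2 feature weights")
    if len(meta) != w.size:
        raise ValueError("meta length mismatch with w")
    sd = w.std()
    z = (w - w.mean()) / sd if sd > 0 else np.zeros_like(w)
    surviving = np.flatnonzero(z > z_thresh)
    per_module: dict[str, float] = {}
    for j in surviving:
        mid = meta[j].module_id
        per_module[mid] = per_module.get(mid, 0.0) + float(w[j])
    return BrainMap(w=w, z=z, surviving=surviving, z_thresh=float(z_thresh),
                    meta=list(meta), per_module_weight=per_module)


def overlap_with_networks(
    brain_map: BrainMap,
    catalog: ModuleCatalog,
    network_of_node: Sequence[str],
) -> dict[str, float]:
    """Percentage of all nodes that belong to a surviving module and carry
    each network label (the map's functional characterization)."""
    network_of_node = np.asarray(network_of_node, dtype=object)
    v = network_of_node.size
    nodes_by_module = {m.module_id: m.nodes for m in catalog.modules}
    covered = np.zeros(v, dtype=bool)
    for mid in brain_map.per_module_weight:
        if mid not in nodes_by_module:
            raise ValueError(f"surviving module {mid!r} not in catalog")
        covered[list(nodes_by_module[mid])] = True
    networks = [l for l in dict.fromkeys(network_of_node)]
    out = {}
    for net in networks:
        hit = covered & (network_of_node == net)
        out[str(net)] = 100.0 * float(hit.sum()) / v
    brain_map.per_network_overlap = out
    return out


def weight_balance(
    w: np.ndarray,
    meta: Sequence[FeatureMeta],
    n_perm: int = 500,
    seed: int = 0,
) -> list[dict]:
    """Per-scale share of the weight mass carried by each modality.

    For every scale M in the catalog grid, features present at that scale are
    split by modality and the share of their total w mass computed; a
    two-sided permutation test (shuffling modality labels within the scale)
    asks whether the functional/structural imbalance exceeds chance.
    """
    w = np.asarray(w, dtype=float)
    if len(meta) != w.size:
        raise ValueError("meta length mismatch with w")
    rng = np.random.default_rng(seed)
    scales = sorted({s for m in meta for s in m.scales})
    rows = []
    for scale in scales:
        idx = np.array([j for j, m in enumerate(meta) if scale in m.scales])
        ws = w[idx]
        is_fc = np.array([meta[j].modality == "functional" for j in idx])
        total = float(ws.sum())
        if total <= 0:
            fc_share = 0.5
        else:
            fc_share = float(ws[is_fc].sum()) / total
        stat = abs(fc_share - 0.5)
        if total > 0 and 0 < is_fc.sum() < idx.size:
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(is_fc)
                exceed += abs(float(ws[perm].sum()) / total - 0.5) >= stat
            p = (1.0 + exceed) / (1.0 + n_perm)
        else:
            p = 1.0
        rows.append({
            "scale": int(scale),
            "functional_share": fc_share,
            "structural_share": 1.0 - fc_share,
            "n_functional": int(is_fc.sum()),
            "n_structural": int(idx.size - is_fc.sum()),
            "p_value": p,
        })
    return rows
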