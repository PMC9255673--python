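"""Virtual deletions: remove all nodes of a macroregion or resting-state
network, rerun the whole pipeline on the reduced matrices and quantify each
region's contribution by the performance ratio

    rho_i = R^2(region i absent) / R^2(all present),

with R the transferred test-set canonical correlation. rho close to 1 marks
a region whose connectivity is irrelevant (or compensated for) in predicting
behavior; rho < 1 marks a constructive region. By default the tree is
rebuilt and the model order reselected after every deletion ("full rerun");
a frozen-tree variant restricts the intact module catalog to the surviving
nodes instead. Subjects, split membership and seeds are identical across
runs so rho isolates the deletion effect.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hierarchy import restrict_catalog
from .pipeline import PipelineConfig, PipelineResult, SplitSpec, run_pipeline, split_cohort
from .synth import Cohort, UNASSIGNED

__all__ = ["LesionEntry", "LesionReport", "delete_region", "lesion_scan",
           "network_labels_from_overlap"]

log = logging.getLogger("connectocca")


@dataclass
class LesionEntry:
    region_label: str
    n_nodes_removed: int
    r2_absent: float
    r2_all: float
    rho: float


@dataclass
class LesionReport:
    entries: list[LesionEntry]
    label_kind: str           # "macroregion" | "network"
    domain_config: str        # e.g. "C+M+S", "cognition"
    r2_all: float

    def rho_by_label(self) -> dict[str, float]:
        return {e.region_label: e.rho for e in self.entries}


def _labels_of(cohort: Cohort, label_kind: str) -> tuple[np.ndarray, tuple[str, ...]]:
    if label_kind == "macroregion":
        return cohort.macroregion_of_node, cohort.macroregion_names
    if label_kind == "network":
        return cohort.network_of_node, cohort.network_names
    raise ValueError("label_kind must be 'macroregion' or 'network'")


def delete_region(cohort: Cohort, label: str, label_kind: str = "macroregion") -> Cohort:
    """Cohort with every node carrying ``label`` removed from all matrices.

    The label must exist in the cohort's label universe; a label with zero
    nodes returns the cohort unchanged. Behavior and subjects are untouched.
    """
    labels, universe = _labels_of(cohort, label_kind)
    if label not in universe and label != UNASSIGNED:
        raise ValueError(f"unknown {label_kind} label {label!r}")
    keep = np.flatnonzero(labels != label)
    if keep.size == cohort.n_nodes:
        return cohort
    if keep.size < 3:
        raise ValueError(f"deleting {label!r} would leave fewer than 3 nodes")
    return Cohort(
        subject_ids=cohort.subject_ids,
        fc=cohort.fc[:, keep[:, None], keep[None, :]],
        sc=cohort.sc[:, keep[:, None], keep[None, :]],
        node_ids=tuple(cohort.node_ids[i] for i in keep),
        macroregion_of_node=cohort.macroregion_of_node[keep],
        network_of_node=cohort.network_of_node[keep],
        behavior=cohort.behavior,
        macroregion_names=cohort.macroregion_names,
        network_names=cohort.network_names,
        planted_latent=cohort.planted_latent,
    )


def lesion_scan(
    cohort: Cohort,
    label_kind: str = "macroregion",
    config: PipelineConfig | None = None,
    split: SplitSpec | None = None,
    labels: Sequence[str] | None = None,
) -> LesionReport:
    """Full-rerun deletion scan over every label of one kind.

    One intact-pipeline run fixes R^2(all present); each label is then
    deleted and the entire pipeline (tree, catalog, features, model order,
    test R) recomputed on the reduced cohort with the same subject split and
    seeds. With ``config.frozen_tree`` the intact catalog is restricted to
    the surviving nodes instead of rebuilding the tree.
    """
    config = config or PipelineConfig()
    node_labels, universe = _labels_of(cohort, label_kind)
    if labels is None:
        labels = [l for l in universe if l != UNASSIGNED]
    if split is None:
        split = split_cohort(cohort.subject_ids, config.split_fractions, config.split_seed)
    base = run_pipeline(cohort, config, split=split)
    r_all = base.report["r_test"]
    r2_all = r_all**2
    if r2_all == 0:
        raise ValueError("intact pipeline has zero test association; rho undefined")
    entries = []
    for label in labels:
        n_removed = int(np.sum(node_labels == label))
        try:
            reduced = delete_region(cohort, label, label_kind)
            cat = None
            if config.frozen_tree:
                keep = np.flatnonzero(node_labels != label)
                cat = restrict_catalog(base.catalog, keep)
            res = run_pipeline(reduced, config, split=split, catalog=cat)
        except Exception as exc:
            raise RuntimeError(f"lesion pipeline failed for label {label!r}: {exc}") from exc
        r2 = res.report["r_test"] ** 2
        entries.append(LesionEntry(
            region_label=str(label),
            n_nodes_removed=n_removed,
            r2_absent=float(r2),
            r2_all=float(r2_all),
            rho=float(r2 / r2_all),
        ))
        log.info("lesion %s=%s: removed %d nodes, rho=%.3f", label_kind, label,
                 n_removed, entries[-1].rho)
    domain = "+".join(sorted(config.domain_subset)) if config.domain_subset else "C+M+S"
    return LesionReport(entries=entries, label_kind=label_kind,
                        domain_config=domain, r2_all=float(r2_all))


def network_labels_from_overlap(
    overlap_fractions: np.ndarray,
    network_names: Sequence[str],
    threshold: float = 0.5,
) -> np.ndarray:
    """Label each node with the network it overlaps at >= ``threshold``.

    ``overlap_fractions`` is nodes x networks with row sums <= 1. At the
    default threshold of 0.5 at most one network can qualify; lower
    thresholds may produce ties, which raise.
    """
    F = np.asarray(overlap_fractions, dtype=float)
    if F.ndim != 2 or F.shape[1] != len(network_names):
        raise ValueError("overlap_fractions must be nodes x networks")
    if F.min() < 0 or F.max() > 1 or (F.sum(axis=1) > 1 + 1e-9).any():
        raise ValueError("overlap fractions must lie in [0,1] with row sums <= 1")
    out = np.empty(F.shape[0], dtype=object)
    for i, row in enumerate(F):
        qualify = np.flatnonzero(row >= threshold)
        if qualify.size > 1:
            raise ValueError(f"node {i}: overlap tie at threshold {threshold}")
        out[i] = network_names[qualify[0]] if qualify.size else UNASSIGNED
    return out
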