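"""End-to-end orchestration: cohort splitting, the full fit pipeline, and
the report structure shared by the CLI, the lesion scan and the examples.

Pipeline order: impute scores -> split subjects -> group (training-mean)
FC/SC matrices -> dendrogram -> unique-module catalog -> feature matrix ->
modality filter -> z-score / PCA / CCA model-order selection -> test
evaluation -> permutation p-value -> weight-map summaries. All randomness is
drawn from named seeds in the config, so a rerun with an identical config is
byte-identical.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import assoc, features, hierarchy, maps
from .synth import Cohort

__all__ = ["SplitSpec", "PipelineConfig", "PipelineResult", "split_cohort", "run_pipeline"]

log = logging.getLogger("connectocca")

MODALITY_MODES = ("structural", "functional", "multimodal")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test subject id lists."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int = 0

    def __post_init__(self):
        groups = (set(self.train_ids), set(self.val_ids), set(self.test_ids))
        if sum(len(g) for g in groups) != len(groups[0] | groups[1] | groups[2]):
            raise ValueError("split groups must be disjoint")

    def indices(self, subject_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pos = {sid: i for i, sid in enumerate(subject_ids)}
        return tuple(
            np.array([pos[s] for s in ids], dtype=int)
            for ids in (self.train_ids, self.val_ids, self.test_ids)
        )


def split_cohort(
    subject_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
) -> SplitSpec:
    """Random disjoint train/validation/test assignment with exact counts
    round(N * fraction); any rounding remainder goes to the training set."""
    if len(fractions) != 3 or any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three non-negative numbers summing to 1")
    ids = list(subject_ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 subjects to split")
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("every split group must receive at least one subject")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    return SplitSpec(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train : n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val :]),
        seed=seed,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the cohort itself."""

    grid: hierarchy.ScaleGrid = field(default_factory=lambda: hierarchy.ScaleGrid(10, 100, 10))
    split_fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    split_seed: int = 0
    perm_seed: int = 0
    modality_mode: str = "multimodal"
    d_grid: tuple[int, ...] = tuple(range(2, 151, 2))
    k_impute: int = 5
    n_perm: int = 2000
    z_thresh: float = 2.0
    domain_subset: tuple[str, ...] | None = None
    score_exclusions: tuple[str, ...] = ()
    frozen_tree: bool = False
    linkage_method: str = "average"
    linkage_metric: str = "correlation"
    auto_cap_grid: bool = True
    perm_mode: str = "transfer"

    def __post_init__(self):
        if self.modality_mode not in MODALITY_MODES:
            raise ValueError(f"modality_mode must be one of {MODALITY_MODES}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.k_impute < 1:
            raise ValueError("k_impute must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.perm_mode not in ("transfer", "refit"):
            raise ValueError("perm_mode must be 'transfer' or 'refit'")


@dataclass
class PipelineResult:
    report: dict
    model: assoc.AssociationModel
    catalog: hierarchy.ModuleCatalog
    dendrogram: hierarchy.Dendrogram | None
    feature_matrix: features.FeatureMatrix
    brain_map: maps.BrainMap
    split: SplitSpec


def _select_scores(cohort: Cohort, config: PipelineConfig):
    """Apply score exclusions and the behavioral-domain subset."""
    table = cohort.behavior
    cols = [
        j
        for j in range(table.n_scores)
        if table.score_names[j] not in set(config.score_exclusions)
        and (config.domain_subset is None or table.domain_of_score[j] in set(config.domain_subset))
    ]
    if not cols:
        raise ValueError("score selection left no behavioral column")
    return table.select(cols)


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    split: SplitSpec | None = None,
    catalog: hierarchy.ModuleCatalog | None = None,
) -> PipelineResult:
    """Run the full association pipeline on one cohort.

    ``split`` may be supplied to reuse an existing cohort partition (the
    lesion scan does this so every deletion run shares subjects and seeds);
    ``catalog`` short-circuits tree building (frozen-tree lesion variant).
    """
    config = config or PipelineConfig()
    # 1. behavioral table: exclusions/domain subset, then imputation
    table = _select_scores(cohort, config)
    if np.isnan(table.Y).any():
        table = assoc.impute_knn(table, k=config.k_impute)
    # 2. split
    if split is None:
        split = split_cohort(cohort.subject_ids, config.split_fractions, config.split_seed)
    idx_tr, idx_va, idx_te = split.indices(cohort.subject_ids)
    # 3. hierarchy from training-mean group matrices
    dendro = None
    if catalog is None:
        grid = config.grid.capped(cohort.n_nodes) if config.auto_cap_grid else config.grid
        group_fc = cohort.fc[idx_tr].mean(axis=0)
        group_sc = cohort.sc[idx_tr].astype(float).mean(axis=0)
        dendro = hierarchy.build_dendrogram(
            group_fc, group_sc,
            method=config.linkage_method, metric=config.linkage_metric,
            node_ids=cohort.node_ids,
        )
        catalog = hierarchy.enumerate_unique_modules(dendro, grid)
    # 4. features, modality filter
    fm = features.build_feature_matrix(cohort, catalog)
    fm_mode = fm.select_modality(config.modality_mode)
    n_func = int(sum(m.modality == "functional" for m in fm.meta))
    n_struct = fm.n_features - n_func
    # 5. model-order selection on train/validation
    X = fm_mode.X
    Y = table.Y
    model = assoc.select_model_order(
        (X[idx_tr], Y[idx_tr]),
        (X[idx_va], Y[idx_va]),
        config.d_grid,
        feature_meta=fm_mode.meta,
        score_names=table.score_names,
    )
    # 6. transferred test evaluation + permutation inference
    r_test = assoc.evaluate_test((X[idx_te], Y[idx_te]), model)
    p = assoc.permutation_pvalue(
        (X[idx_te], Y[idx_te]), model,
        n_perm=config.n_perm, seed=config.perm_seed, mode=config.perm_mode,
        train=(X[idx_tr], Y[idx_tr]) if config.perm_mode == "refit" else None,
    )
    # 7. weight map and summaries
    w = maps.project_weights(model)
    bmap = maps.threshold_map(w, model.feature_meta, z_thresh=config.z_thresh)
    overlap = maps.overlap_with_networks(bmap, catalog, cohort.network_of_node)
    best = int(np.argmax(model.r_val_curve))
    domain_by_name = dict(zip(table.score_names, table.domain_of_score))
    report = {
        "n_subjects": cohort.n_subjects,
        "n_nodes": cohort.n_nodes,
        "modality_mode": config.modality_mode,
        "scale_grid": {"m_min": catalog.grid.m_min, "m_max": catalog.grid.m_max,
                       "m_step": catalog.grid.m_step, "n_levels": catalog.grid.n_levels},
        "split": {"n_train": len(split.train_ids), "n_val": len(split.val_ids),
                  "n_test": len(split.test_ids), "seed": split.seed},
        "n_unique_modules": len(catalog),
        "n_features": fm.n_features,
        "n_features_functional": n_func,
        "n_features_structural": n_struct,
        "n_features_used": fm_mode.n_features,
        "n_features_dropped": model.x_scaler.n_dropped,
        "model_order": model.D,
        "explained_variance": model.explained_variance,
        "r_train": float(model.r_train_curve[best]),
        "r_val": float(model.r_val_curve[best]),
        "r_test": float(r_test),
        "p_value": float(p),
        "n_perm": config.n_perm,
        "behavior_weights": [
            {"score": name, "domain": domain_by_name[name], "weight": float(wq)}
            for name, wq in zip(model.score_names, model.behavior_weights)
        ],
        "map": {
            "z_thresh": config.z_thresh,
            "n_surviving_features": int(bmap.surviving.size),
            "n_surviving_modules": len(bmap.per_module_weight),
            "per_network_overlap_pct": overlap,
        },
    }
    log.info(
        "pipeline done: mode=%s D=%d Ve=%.3f T=%.3f p=%.4g",
        config.modality_mode, model.D, model.explained_variance, r_test, p,
    )
    return PipelineResult(
        report=report, model=model, catalog=catalog, dendrogram=dendro,
        feature_matrix=fm, brain_map=bmap, split=split,
    )
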