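"""Plain-text serialization of cohorts, catalogs and reports.

Cohorts are written as one delimited-text matrix per subject per modality
(``<subject>_fc.tsv`` / ``<subject>_sc.tsv``, node order given by
``nodes.tsv``), a ``behavior.csv`` score table (empty cell = missing) with a
``scores.tsv`` sidecar carrying each score's behavioral domain, and an
optional ``spec.json``. Catalogs, dendrograms, feature matrices and fit /
lesion / map reports are written as JSON or TSV.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix, FeatureMeta
from .hierarchy import Dendrogram, Module, ModuleCatalog, ScaleGrid
from .lesion import LesionReport
from .maps import BrainMap
from .synth import BehaviorTable, Cohort, SynthSpec

__all__ = [
    "write_cohort", "read_cohort", "write_catalog", "read_catalog",
    "write_dendrogram", "write_features", "write_json", "write_lesion_report",
    "write_map_report", "write_node_map",
]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir, spec: SynthSpec | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(cohort.subject_ids):
        np.savetxt(out / f"{sid}_fc.tsv", cohort.fc[i], fmt="%.8g", delimiter="\t")
        np.savetxt(out / f"{sid}_sc.tsv", cohort.sc[i], fmt="%d", delimiter="\t")
    pd.DataFrame({
        "node_id": list(cohort.node_ids),
        "macroregion": list(cohort.macroregion_of_node),
        "network": list(cohort.network_of_node),
    }).to_csv(out / "nodes.tsv", sep="\t", index=False)
    beh = pd.DataFrame(cohort.behavior.Y, columns=list(cohort.behavior.score_names))
    beh.insert(0, "subject_id", list(cohort.subject_ids))
    beh.to_csv(out / "behavior.csv", index=False)
    pd.DataFrame({
        "score_name": list(cohort.behavior.score_names),
        "domain": list(cohort.behavior.domain_of_score),
    }).to_csv(out / "scores.tsv", sep="\t", index=False)
    meta = {
        "macroregion_names": list(cohort.macroregion_names),
        "network_names": list(cohort.network_names),
    }
    if spec is not None:
        meta["synth_spec"] = dataclasses.asdict(spec)
    write_json(meta, out / "spec.json")


def read_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    nodes = pd.read_csv(src / "nodes.tsv", sep="\t")
    beh = pd.read_csv(src / "behavior.csv")
    subject_ids = tuple(beh["subject_id"].astype(str))
    score_names = tuple(c for c in beh.columns if c != "subject_id")
    scores_path = src / "scores.tsv"
    if scores_path.exists():
        sc_tab = pd.read_csv(scores_path, sep="\t")
        domain_map = dict(zip(sc_tab["score_name"].astype(str), sc_tab["domain"].astype(str)))
        domains = tuple(domain_map.get(s, "unknown") for s in score_names)
    else:
        domains = tuple("unknown" for _ in score_names)
    behavior = BehaviorTable(beh[list(score_names)].to_numpy(dtype=float),
                             score_names, domains)
    v = len(nodes)
    fc = np.empty((len(subject_ids), v, v))
    sc = np.empty((len(subject_ids), v, v), dtype=np.int64)
    for i, sid in enumerate(subject_ids):
        fc[i] = np.loadtxt(src / f"{sid}_fc.tsv", delimiter="\t")
        sc[i] = np.loadtxt(src / f"{sid}_sc.tsv", delimiter="\t", dtype=np.int64)
    macro_names: tuple[str, ...] = ()
    net_names: tuple[str, ...] = ()
    meta_path = src / "spec.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        macro_names = tuple(meta.get("macroregion_names", ()))
        net_names = tuple(meta.get("network_names", ()))
    return Cohort(
        subject_ids=subject_ids,
        fc=fc,
        sc=sc,
        node_ids=tuple(nodes["node_id"].astype(str)),
        macroregion_of_node=nodes["macroregion"].astype(str).to_numpy(dtype=object),
        network_of_node=nodes["network"].astype(str).to_numpy(dtype=object),
        behavior=behavior,
        macroregion_names=macro_names,
        network_names=net_names,
    )


# ---------------------------------------------------------------------------
# Hierarchy artifacts
# ---------------------------------------------------------------------------

def write_dendrogram(dendrogram: Dendrogram, path) -> None:
    rows = [f"cluster_a\tcluster_b\theight"]
    rows += [f"{a}\t{b}\t{h:.10g}" for a, b, h in dendrogram.merge_list]
    Path(path).write_text("\n".join(rows) + "\n")


def write_catalog(catalog: ModuleCatalog, path) -> None:
    write_json({
        "grid": {"m_min": catalog.grid.m_min, "m_max": catalog.grid.m_max,
                 "m_step": catalog.grid.m_step},
        "modules": [
            {"id": m.module_id, "nodes": list(m.nodes), "scales": sorted(m.scales)}
            for m in catalog.modules
        ],
    }, path)


def read_catalog(path) -> ModuleCatalog:
    obj = json.loads(Path(path).read_text())
    grid = ScaleGrid(**obj["grid"])
    modules = [
        Module(module_id=m["id"], nodes=tuple(m["nodes"]), scales=list(m["scales"]))
        for m in obj["modules"]
    ]
    return ModuleCatalog(modules=modules, grid=grid)


# ---------------------------------------------------------------------------
# Features, reports, maps
# ---------------------------------------------------------------------------

def write_features(fm: FeatureMatrix, tsv_path, meta_path) -> None:
    cols = [f"{m.module_id}:{m.feature_class}" for m in fm.meta]
    df = pd.DataFrame(fm.X, columns=cols)
    df.insert(0, "subject_id", list(fm.subject_ids))
    df.to_csv(tsv_path, sep="\t", index=False)
    write_json([
        {"module_id": m.module_id, "feature_class": m.feature_class,
         "modality": m.modality, "scales": list(m.scales)}
        for m in fm.meta
    ], meta_path)


def write_lesion_report(report: LesionReport, path) -> None:
    write_json({
        "label_kind": report.label_kind,
        "domain_config": report.domain_config,
        "r2_all": report.r2_all,
        "entries": [dataclasses.asdict(e) for e in report.entries],
    }, path)


def write_map_report(bmap: BrainMap, balance: list[dict], path) -> None:
    write_json({
        "z_thresh": bmap.z_thresh,
        "w": [float(x) for x in bmap.w],
        "z": [float(x) for x in bmap.z],
        "surviving": [int(j) for j in bmap.surviving],
        "per_module_weight": bmap.per_module_weight,
        "per_network_overlap_pct": bmap.per_network_overlap,
        "modality_balance_by_scale": balance,
    }, path)


def write_node_map(bmap: BrainMap, catalog: ModuleCatalog, node_ids, path) -> None:
    """Per-node aggregated surviving weight, for external rendering."""
    nodes_by_module = {m.module_id: m.nodes for m in catalog.modules}
    w_node = np.zeros(len(node_ids))
    for mid, wt in bmap.per_module_weight.items():
        w_node[list(nodes_by_module[mid])] += wt
    pd.DataFrame({"node_id": list(node_ids), "weight": w_node}).to_csv(
        path, sep="\t", index=False
    )
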