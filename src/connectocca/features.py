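"""Per-module connectivity features and the multiscale feature matrix.

For every unique module four feature classes are computed per subject:

- FIC: mean absolute FC weight over within-module links,
- FEC: mean absolute FC weight over links leaving the module,
- SIC / SEC: the same link sets averaged on raw SC weights (no absolute
  value; streamline counts are non-negative).

The diagonal is always excluded; a module spanning all nodes has no external
links and is rejected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hierarchy import ModuleCatalog
from .synth import Cohort

__all__ = ["FEATURE_CLASSES", "FeatureMeta", "FeatureMatrix",
           "fc_from_timeseries", "module_features", "build_feature_matrix"]

FEATURE_CLASSES = ("FIC", "FEC", "SIC", "SEC")
_MODALITY = {"FIC": "functional", "FEC": "functional",
             "SIC": "structural", "SEC": "structural"}


@dataclass(frozen=True)
class FeatureMeta:
    module_id: str
    feature_class: str
    scales: tuple[int, ...]

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def modality(self) -> str:
        return _MODALITY[self.feature_class]


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with per-column metadata."""

    X: np.ndarray
    meta: list[FeatureMeta]
    subject_ids: tuple[str, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.subject_ids), len(self.meta)):
            raise ValueError("X shape inconsistent with subject/meta counts")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix must not contain missing cells")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def modality_columns(self, mode: str) -> np.ndarray:
        """Column indices for a modality mode (structural|functional|multimodal)."""
        if mode == "multimodal":
            return np.arange(self.n_features)
        if mode not in ("structural", "functional"):
            raise ValueError(f"unknown modality mode {mode!r}")
        return np.array([j for j, m in enumerate(self.meta) if m.modality == mode],
                        dtype=int)

    def select_modality(self, mode: str) -> "FeatureMatrix":
        cols = self.modality_columns(mode)
        return FeatureMatrix(self.X[:, cols], [self.meta[j] for j in cols],
                             self.subject_ids)


def fc_from_timeseries(ts: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix of node time series (T x V)."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x V matrix")
    t, v = ts.shape
    if t < 3:
        raise ValueError("need at least 3 timepoints")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series at node index {int(bad[0])}")
    A = np.corrcoef(ts, rowvar=False)
    A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    return A


def module_features(fc: np.ndarray, sc: np.ndarray, module: Sequence[int]) -> dict[str, float]:
    """FIC/FEC/SIC/SEC of one module on one subject's FC and SC matrices."""
    fc = np.asarray(fc, dtype=float)
    sc = np.asarray(sc, dtype=float)
    v = fc.shape[0]
    if fc.shape != (v, v) or sc.shape != (v, v):
        raise ValueError("fc and sc must be square matrices over the same nodes")
    idx = np.unique(np.asarray(list(module), dtype=int))
    if idx.size < 2:
        raise ValueError("module must contain at least 2 nodes")
    if idx.min() < 0 or idx.max() >= v:
        raise ValueError("module node index out of range")
    if idx.size == v:
        raise ValueError("module equals the full node set: external links undefined")
    s = idx.size
    inside = np.zeros(v, dtype=bool)
    inside[idx] = True
    out = {}
    for name_in, name_ex, mat, absolute in (
        ("FIC", "FEC", fc, True),
        ("SIC", "SEC", sc, False),
    ):
        A = np.abs(mat) if absolute else mat
        sub = A[np.ix_(idx, idx)]
        within = (sub.sum() - np.trace(sub)) / (s * (s - 1))
        cross = A[np.ix_(idx, ~inside)].sum() / (s * (v - s))
        out[name_in] = float(within)
        out[name_ex] = float(cross)
    return out


def build_feature_matrix(cohort: Cohort, catalog: ModuleCatalog) -> FeatureMatrix:
    """Assemble the N x F multiscale feature matrix for a whole cohort.

    Columns are ordered (module, class) following catalog order with classes
    FIC, FEC, SIC, SEC; any module equal to the full node set is skipped with
    a warning.
    """
    if len(catalog) == 0:
        raise ValueError("empty module catalog")
    n, v = cohort.n_subjects, cohort.n_nodes
    modules = []
    for mod in catalog.modules:
        if len(mod.nodes) >= v:
            warnings.warn(
                f"module {mod.module_id} spans all nodes; skipped", stacklevel=2
            )
            continue
        modules.append(mod)
    if not modules:
        raise ValueError("no usable module (all span the full node set)")
    k = len(modules)
    P = np.zeros((v, k))
    sizes = np.empty(k)
    for j, mod in enumerate(modules):
        P[list(mod.nodes), j] = 1.0
        sizes[j] = len(mod.nodes)
    within_pairs = sizes * (sizes - 1)
    cross_pairs = sizes * (v - sizes)

    zero = np.zeros(k)
    X = np.empty((n, 4 * k))
    for s in range(n):
        # |fc| has unit diagonal (mass `sizes` inside u'Au); sc has zero diagonal
        for base, A, diag_mass in ((0, np.abs(cohort.fc[s]), sizes),
                                   (1, cohort.sc[s].astype(float), zero)):
            AP = A @ P
            quad = (AP * P).sum(axis=0)   # u'Au, diagonal included
            tot = P.T @ A.sum(axis=1)     # u'A1
            X[s, 2 * base::4] = (quad - diag_mass) / within_pairs
            X[s, 2 * base + 1::4] = (tot - quad) / cross_pairs
    meta = []
    for mod in modules:
        for cls in FEATURE_CLASSES:
            meta.append(FeatureMeta(module_id=mod.module_id, feature_class=cls,
                                    scales=tuple(sorted(mod.scales))))
    return FeatureMatrix(X=X, meta=meta, subject_ids=cohort.subject_ids)
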