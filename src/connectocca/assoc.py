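"""Statistical core: k-NN imputation, z-scoring, PCA+CCA association,
train/validation model-order selection, test evaluation and permutation
inference.

The association statistic is the first-mode canonical correlation

    R = corr(U1, V1),   U = PC . A,   V = Y . B,

with ``PC`` the training-learned principal components of the z-scored
feature matrix and ``A``, ``B`` the canonical mixing matrices. Model order
``D`` (the number of retained components) is chosen by maximizing the
validation-set R computed with the *training* mixes; the test-set R and its
permutation p-value are then reported for that single D. The sign of a
canonical pair is arbitrary, so R is taken as a magnitude (flipped to be
non-negative) and B's first column is oriented to have a positive leading
coefficient.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

from .synth import BehaviorTable

__all__ = [
    "ColumnScaler",
    "CCAResult",
    "AssociationModel",
    "impute_knn",
    "cca_first_mode",
    "select_model_order",
    "evaluate_test",
    "permutation_pvalue",
]

_RANK_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_knn(Y, k: int = 5):
    """Fill missing cells with the column mean over the k nearest rows.

    Distances are root-mean-square differences over the z-scored columns
    observed in both rows (rows sharing no observed column are excluded as
    neighbors); ties are broken by row order. Observed cells are untouched.
    Accepts a :class:`BehaviorTable` or a plain array and returns the same
    type, completed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table = isinstance(Y, BehaviorTable)
    A = np.array(Y.Y if table else Y, dtype=float)
    if A.ndim != 2:
        raise ValueError("Y must be 2-D")
    n, q = A.shape
    obs = ~np.isnan(A)
    if not obs.any(axis=0).all():
        j = int(np.flatnonzero(~obs.any(axis=0))[0])
        raise ValueError(f"column {j} is fully missing and cannot be imputed")
    if not obs.any(axis=1).all():
        i = int(np.flatnonzero(~obs.any(axis=1))[0])
        raise ValueError(f"row {i} has no observed cell")
    mu = np.nanmean(A, axis=0)
    sd = np.nanstd(A, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (A - mu) / sd
    out = A.copy()
    for i in np.flatnonzero(~obs.all(axis=1)):
        diff = Z[i] - Z  # NaN wherever either row is missing
        joint = ~np.isnan(diff)
        n_joint = joint.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.sqrt(np.nansum(diff**2, axis=1) / np.maximum(n_joint, 1))
        d[i] = np.inf
        d[n_joint == 0] = np.inf
        for j in np.flatnonzero(~obs[i]):
            cand = d.copy()
            cand[~obs[:, j]] = np.inf
            order = np.argsort(cand, kind="stable")
            order = order[np.isfinite(cand[order])]
            if order.size == 0:
                raise ValueError(f"no usable neighbor for cell ({i}, {j})")
            chosen = order[:k]
            out[i, j] = mu[j] + sd[j] * float(np.mean(Z[chosen, j]))
    if table:
        return BehaviorTable(out, Y.score_names, Y.domain_of_score)
    return out


# ---------------------------------------------------------------------------
# z-scoring learned on the training set
# ---------------------------------------------------------------------------

@dataclass
class ColumnScaler:
    """Per-column z-scoring with parameters learned on the training set;
    zero-variance columns are dropped (recorded in ``kept``)."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # bool mask over the original columns

    @classmethod
    def fit(cls, X: np.ndarray) -> "ColumnScaler":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        kept = sd > 0
        return cls(mean=mean, sd=sd, kept=kept)

    @property
    def n_dropped(self) -> int:
        return int((~self.kept).sum())

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError("column count mismatch with fitted scaler")
        return (X[:, self.kept] - self.mean[self.kept]) / self.sd[self.kept]


# ---------------------------------------------------------------------------
# Canonical correlation analysis (classical, QR + SVD)
# ---------------------------------------------------------------------------

class CCAResult(NamedTuple):
    A: np.ndarray       # D x K canonical mixes for the components
    B: np.ndarray       # Q x K canonical mixes for the scores
    R: float            # first-mode canonical correlation
    corrs: np.ndarray   # all K canonical correlations


def _rank_check(r_diag: np.ndarray, name: str) -> None:
    d = np.abs(r_diag)
    if d.size == 0 or d.min() < _RANK_RTOL * max(d.max(), 1.0):
        raise ValueError(f"rank-deficient {name} matrix in CCA")


def cca_first_mode(PC: np.ndarray, Y: np.ndarray) -> CCAResult:
    """All canonical pairs of (PC, Y), maximizing the first-mode Pearson R.

    Classical formulation: economy QR of the centered blocks, SVD of
    Qx'Qy; singular values are the canonical correlations. Raises on
    rank-deficient inputs and when N <= D + Q.
    """
    X = np.asarray(PC, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("PC and Y must be 2-D")
    n, d = X.shape
    q = Y.shape[1]
    if d == 0 or q == 0:
        raise ValueError("PC and Y must each have at least one column")
    if Y.shape[0] != n:
        raise ValueError("PC and Y must have the same number of rows")
    if n <= d + q:
        raise ValueError(f"need N > D + Q (N={n}, D={d}, Q={q})")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, rx = linalg.qr(Xc, mode="economic")
    qy, ry = linalg.qr(Yc, mode="economic")
    _rank_check(np.diag(rx), "PC")
    _rank_check(np.diag(ry), "Y")
    u, s, vt = linalg.svd(qx.T @ qy)
    k = min(d, q)
    A = linalg.solve_triangular(rx, u[:, :k])
    B = linalg.solve_triangular(ry, vt.T[:, :k])
    # orient each pair: first non-negligible coefficient of B's column positive
    for j in range(k):
        col = B[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * max(np.abs(col).max(), 1e-300))
        if nz.size and col[nz[0]] < 0:
            B[:, j] = -col
            A[:, j] = -A[:, j]
    corrs = np.clip(s[:k], 0.0, 1.0)
    return CCAResult(A=A, B=B, R=float(corrs[0]), corrs=corrs)


def _abs_corr(u: np.ndarray, v: np.ndarray) -> float:
    """|Pearson correlation|, 0 when either vector is degenerate."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return 0.0
    r = float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
    return min(abs(r), 1.0)


# ---------------------------------------------------------------------------
# Model-order selection and transferred evaluation
# ---------------------------------------------------------------------------

@dataclass
class AssociationModel:
    """Everything learned on the training cohort, plus transferred results."""

    x_scaler: ColumnScaler
    y_scaler: ColumnScaler
    w_pca: np.ndarray            # F_kept x D rotation
    explained_variance: float    # Ve, fraction of train variance at order D
    A: np.ndarray                # D x K canonical mixes (components)
    B: np.ndarray                # Q x K canonical mixes (scores)
    D: int
    d_grid: tuple[int, ...]
    r_train_curve: np.ndarray
    r_val_curve: np.ndarray
    n_train: int
    score_names: tuple[str, ...] = ()
    feature_meta: list = field(default_factory=list)  # metadata of kept columns
    R_test: float | None = None
    p_value: float | None = None

    @property
    def behavior_weights(self) -> np.ndarray:
        """First canonical column over the (z-scored) behavior scores."""
        return self.B[:, 0].copy()

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        """Project raw features onto the trained principal components."""
        return self.x_scaler.transform(X) @ self.w_pca

    def canonical_pair(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = self.transform_x(X) @ self.A[:, 0]
        v = self.y_scaler.transform(Y) @ self.B[:, 0]
        return u, v


def select_model_order(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    d_grid: Sequence[int],
    feature_meta: Sequence | None = None,
    score_names: Sequence[str] | None = None,
) -> AssociationModel:
    """Fit PCA+CCA on train for every candidate order and pick the one that
    maximizes validation R with the training mixes (ties -> smallest D).

    ``train`` and ``val`` hold raw (unscaled, complete) feature and score
    matrices; z-scoring of both is learned on train only. PCA is fitted once
    at the largest feasible order and truncated per candidate (principal
    components are nested).
    """
    d_grid = list(d_grid)
    if not d_grid:
        raise ValueError("empty model-order grid")
    X_tr, Y_tr = train
    X_va, Y_va = val
    X_tr = np.asarray(X_tr, dtype=float)
    Y_tr = np.asarray(Y_tr, dtype=float)
    if np.isnan(Y_tr).any() or np.isnan(np.asarray(Y_va, float)).any():
        raise ValueError("scores must be imputed before model fitting")
    n_tr, q = Y_tr.shape
    xs = ColumnScaler.fit(X_tr)
    ys = ColumnScaler.fit(Y_tr)
    Xz_tr = xs.transform(X_tr)
    Yz_tr = ys.transform(Y_tr)
    Xz_va = xs.transform(np.asarray(X_va, dtype=float))
    Yz_va = ys.transform(np.asarray(Y_va, dtype=float))
    q_kept = Yz_tr.shape[1]
    f_kept = Xz_tr.shape[1]
    d_cap = min(f_kept, n_tr - q_kept - 1)
    grid = sorted({int(d) for d in d_grid if 1 <= d <= d_cap})
    if not grid:
        raise ValueError(
            f"no candidate order in [1, {d_cap}] (grid {d_grid[:5]}...)"
        )
    pca = PCA(n_components=max(grid), svd_solver="full").fit(Xz_tr)
    pc_tr = pca.transform(Xz_tr)
    pc_va = pca.transform(Xz_va)
    r_train, r_val, ccas = [], [], []
    for d in grid:
        res = cca_first_mode(pc_tr[:, :d], Yz_tr)
        r_train.append(res.R)
        r_val.append(_abs_corr(pc_va[:, :d] @ res.A[:, 0], Yz_va @ res.B[:, 0]))
        ccas.append(res)
    best = int(np.argmax(r_val))  # argmax returns the first (smallest D) tie
    d_star = grid[best]
    res = ccas[best]
    if feature_meta is not None:
        feature_meta = [m for m, keep in zip(feature_meta, xs.kept) if keep]
    if score_names is not None:
        score_names = [s for s, keep in zip(score_names, ys.kept) if keep]
    return AssociationModel(
        x_scaler=xs,
        y_scaler=ys,
        w_pca=pca.components_[:d_star].T.copy(),
        explained_variance=float(pca.explained_variance_ratio_[:d_star].sum()),
        A=res.A,
        B=res.B,
        D=d_star,
        d_grid=tuple(grid),
        r_train_curve=np.asarray(r_train),
        r_val_curve=np.asarray(r_val),
        n_train=n_tr,
        score_names=tuple(score_names) if score_names is not None else (),
        feature_meta=list(feature_meta) if feature_meta is not None else [],
    )


def evaluate_test(test: tuple[np.ndarray, np.ndarray], model: AssociationModel) -> float:
    """Transferred first-mode canonical correlation on held-out data.

    z-scoring, PCA rotation and the canonical mixes all come from training;
    the returned R is sign-flipped to be non-negative and stored on the model.
    """
    X_te, Y_te = test
    Y_te = np.asarray(Y_te, dtype=float)
    if Y_te.shape[1] != model.y_scaler.mean.shape[0]:
        raise ValueError("test scores have a different column set than training")
    if np.isnan(Y_te).any():
        raise ValueError("test scores must be imputed")
    u, v = model.canonical_pair(np.asarray(X_te, dtype=float), Y_te)
    r = _abs_corr(u, v)
    model.R_test = r
    return r


def permutation_pvalue(
    test: tuple[np.ndarray, np.ndarray],
    model: AssociationModel,
    n_perm: int = 2000,
    seed: int = 0,
    mode: str = "transfer",
    train: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Permutation p-value of the transferred association.

    ``mode='transfer'`` (default) permutes the test-set score rows with the
    trained model held fixed, testing exactly the reported statistic;
    ``mode='refit'`` instead refits the CCA on training data with permuted
    training scores and evaluates each refit on the intact test set (requires
    ``train``). p uses the add-one rule (1 + #{R_perm >= R_test}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X_te, Y_te = test
    n_te = np.asarray(Y_te).shape[0]
    if n_te < 5:
        raise ValueError("permutation test needs at least 5 test subjects")
    r_obs = model.R_test if model.R_test is not None else evaluate_test(test, model)
    rng = np.random.default_rng(seed)
    if mode == "transfer":
        u, v = model.canonical_pair(np.asarray(X_te, float), np.asarray(Y_te, float))
        uc = u - u.mean()
        su = u.std()
        sv = v.std()
        if su == 0 or sv == 0:
            r_perm = np.zeros(n_perm)
        else:
            idx = np.argsort(rng.random((n_perm, n_te)), axis=1)
            vp = v[idx]  # permuting Y rows permutes V1 rows
            r_perm = np.abs((vp - v.mean()) @ uc) / (n_te * su * sv)
    elif mode == "refit":
        if train is None:
            raise ValueError("mode='refit' requires the training data")
        X_tr, Y_tr = train
        pc_tr = model.transform_x(np.asarray(X_tr, float))
        Yz_tr = model.y_scaler.transform(np.asarray(Y_tr, float))
        pc_te = model.transform_x(np.asarray(X_te, float))
        Yz_te = model.y_scaler.transform(np.asarray(Y_te, float))
        r_perm = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(Yz_tr.shape[0])
            res = cca_first_mode(pc_tr, Yz_tr[perm])
            r_perm[b] = _abs_corr(pc_te @ res.A[:, 0], Yz_te @ res.B[:, 0])
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    p = (1.0 + float(np.sum(r_perm >= r_obs))) / (1.0 + n_perm)
    model.p_value = p
    return p
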