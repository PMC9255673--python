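"""Synthetic cohorts with hierarchically modular connectomes and planted
brain-behavior associations.

The generator emulates the inputs of a multiscale connectome-to-behavior
study at desk scale: per-subject functional connectivity (FC, Pearson
correlations estimated from simulated time series) and structural
connectivity (SC, Poisson streamline counts) over ``V`` nodes arranged in a
balanced block tree, anatomical macroregion and resting-state-network labels
per node, and a behavioral score table carrying a planted linear association
of canonical correlation ``rho_true`` with connectivity features of
designated "signal" modules.

Generative model
----------------
Node time series follow a hierarchical factor model: node ``i`` at time ``t``

    z_i(t) = a_i * sum_d sqrt(c_d) * G_{b_d(i)}(t) + sqrt(1 - a_i^2 C) * eps_i(t)

where ``G`` are shared block factors at each tree depth ``d`` and ``c_d`` is
the extra within-block correlation contributed by depth ``d`` (two nodes
whose deepest shared block is at depth ``s`` have population correlation
``sum_{d<=s} c_d``; ``C`` is the total). The amplitude ``a_i`` is 1 except
for nodes of a designated signal module, where ``a^2 = 1 + gamma*eta/C``
with ``eta`` a per-subject standard-normal latent trait: within-signal-module
correlations become ``(C_pair/C)(C + gamma*eta)``, a zero-mean modulation
that leaves the group-average tree unbiased while expressing the trait in
the signal module and all modules nested inside it. SC entries are Poisson
with mean ``sc_rate_by_depth[shared depth]``, scaled by ``exp(gamma_sc*eta)``
within signal modules. The behavioral latent is the standardized sum of the
z-scored realized within-module features (mean |FC| / mean SC) of the signal
modules, so its association with the feature matrix is recoverable by
construction, and two signal modules carry the *same* trait (redundancy,
which virtual deletions can then reveal as compensation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MACROREGION_NAMES",
    "NETWORK_NAMES",
    "UNASSIGNED",
    "DOMAINS",
    "SynthSpec",
    "BehaviorTable",
    "Cohort",
    "generate_behavior",
    "generate_cohort",
    "blocks_at_depth",
    "assign_macroregions",
    "assign_networks",
    "signal_module_for_macroregion",
]

#: The eight anatomical macroregions used to constrain the brain partition.
MACROREGION_NAMES = (
    "frontal",
    "parietal",
    "occipital",
    "temporal",
    "insula",
    "cingulate",
    "cerebellum",
    "subcortical",
)

#: The seven canonical resting-state networks.
NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "salience",
    "limbic",
    "frontoparietal",
    "default_mode",
)

UNASSIGNED = "unassigned"

DOMAINS = ("cognition", "motor", "sensation")

#: Latent trait values are clipped to +-ETA_CLIP sigma before modulating
#: connectivity, so factor loadings stay within the unit-variance budget.
ETA_CLIP = 3.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Balanced block tree geometry
# ---------------------------------------------------------------------------

def _leaf_blocks(n_nodes: int, branching: Sequence[int]) -> list[np.ndarray]:
    n_leaves = int(np.prod(branching))
    return [np.asarray(b, dtype=int) for b in np.array_split(np.arange(n_nodes), n_leaves)]


def blocks_at_depth(n_nodes: int, branching: Sequence[int], depth: int) -> list[np.ndarray]:
    """Node index sets of the tree blocks at ``depth`` (1 = coarsest split)."""
    if not 1 <= depth <= len(branching):
        raise ValueError(f"depth must be in [1, {len(branching)}], got {depth}")
    leaves = _leaf_blocks(n_nodes, branching)
    stride = int(np.prod(branching[depth:])) if depth < len(branching) else 1
    n_blocks = len(leaves) // stride
    return [np.concatenate(leaves[j * stride : (j + 1) * stride]) for j in range(n_blocks)]


def _block_index_of_node(n_nodes: int, branching: Sequence[int], depth: int) -> np.ndarray:
    """Depth-``depth`` block index for every node."""
    out = np.empty(n_nodes, dtype=int)
    for j, nodes in enumerate(blocks_at_depth(n_nodes, branching, depth)):
        out[nodes] = j
    return out


def _shared_depth_matrix(n_nodes: int, branching: Sequence[int]) -> np.ndarray:
    """Deepest tree depth at which each node pair shares a block (0 = root only)."""
    S = np.zeros((n_nodes, n_nodes), dtype=int)
    for d in range(1, len(branching) + 1):
        b = _block_index_of_node(n_nodes, branching, d)
        S = np.maximum(S, d * (b[:, None] == b[None, :]))
    return S


def _label_names(base: Sequence[str], n: int, prefix: str) -> list[str]:
    names = list(base[:n])
    while len(names) < n:
        names.append(f"{prefix}_{len(names)}")
    return names


def _macroregion_depth(branching: Sequence[int], n_macroregions: int) -> int:
    """Shallowest depth with at least ``n_macroregions`` blocks (deepest otherwise)."""
    for d in range(1, len(branching) + 1):
        if int(np.prod(branching[:d])) >= n_macroregions:
            return d
    return len(branching)


def assign_macroregions(
    n_nodes: int, branching: Sequence[int], n_macroregions: int = 8
) -> np.ndarray:
    """Assign macroregion labels round-robin over tree blocks.

    Labels are assigned at the shallowest depth whose block count reaches
    ``n_macroregions``, so each block carries exactly one label and every
    label groups one or more whole blocks (anatomical labels need not be
    contiguous subtrees, mirroring how anatomy cuts across functional
    hierarchy).
    """
    names = _label_names(MACROREGION_NAMES, n_macroregions, "region")
    depth = _macroregion_depth(branching, n_macroregions)
    labels = np.empty(n_nodes, dtype=object)
    for j, nodes in enumerate(blocks_at_depth(n_nodes, branching, depth)):
        labels[nodes] = names[j % n_macroregions]
    return labels


def assign_networks(n_nodes: int, branching: Sequence[int], n_networks: int = 7) -> np.ndarray:
    """Assign resting-state-network labels round-robin over leaf blocks.

    Every ``(n_networks+1)``-th leaf block is left :data:`UNASSIGNED`, standing
    in for nodes that do not overlap any canonical network at >= 50%.
    """
    names = _label_names(NETWORK_NAMES, n_networks, "network")
    labels = np.empty(n_nodes, dtype=object)
    leaves = _leaf_blocks(n_nodes, branching)
    for j, nodes in enumerate(leaves):
        if j % (n_networks + 1) == n_networks:
            labels[nodes] = UNASSIGNED
        else:
            labels[nodes] = names[j % n_networks]
    return labels


def signal_module_for_macroregion(
    n_nodes: int,
    branching: Sequence[int],
    macroregion: str,
    n_macroregions: int = 8,
    which: int = 0,
) -> tuple[int, ...]:
    """Node set of the ``which``-th tree block labeled ``macroregion``.

    Convenience for planting a signal module wholly inside one macroregion:
    the returned set is a block of the tree (hence present in the module
    catalog at some scales) and all its nodes carry the requested label.
    """
    depth = _macroregion_depth(branching, n_macroregions)
    labels = assign_macroregions(n_nodes, branching, n_macroregions)
    hits = [
        tuple(int(i) for i in nodes)
        for nodes in blocks_at_depth(n_nodes, branching, depth)
        if labels[nodes[0]] == macroregion
    ]
    if not hits:
        raise ValueError(f"no block labeled {macroregion!r}")
    return hits[which]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTable:
    """Subjects x scores table; missing cells are NaN."""

    Y: np.ndarray
    score_names: tuple[str, ...]
    domain_of_score: tuple[str, ...]

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D (subjects x scores)")
        q = self.Y.shape[1]
        if q < 1:
            raise ValueError("need at least one score")
        if len(self.score_names) != q or len(self.domain_of_score) != q:
            raise ValueError("score_names/domain_of_score length mismatch with Y")
        self.score_names = tuple(self.score_names)
        self.domain_of_score = tuple(self.domain_of_score)

    @property
    def n_scores(self) -> int:
        return self.Y.shape[1]

    def copy(self) -> "BehaviorTable":
        return BehaviorTable(self.Y.copy(), self.score_names, self.domain_of_score)

    def select(self, columns: Sequence[int]) -> "BehaviorTable":
        cols = list(columns)
        return BehaviorTable(
            self.Y[:, cols],
            tuple(self.score_names[j] for j in cols),
            tuple(self.domain_of_score[j] for j in cols),
        )


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic cohort (deterministic given ``seed``).

    ``fc_within_minus_between[d]`` is the extra within-block correlation
    gained at tree depth ``d+1``; ``sc_rate_by_depth[s]`` is the expected
    streamline count for a node pair whose deepest shared block is at depth
    ``s`` (``s = 0`` means the pair only shares the root).
    """

    n_subjects: int
    n_nodes: int = 200
    branching: tuple[int, ...] = (4, 5, 2)
    fc_within_minus_between: tuple[float, ...] = (0.15, 0.10, 0.05)
    sc_rate_by_depth: tuple[float, ...] = (2.0, 6.0, 15.0, 30.0)
    n_timepoints: int = 300
    rho_true: float = 0.0
    signal_modules: tuple[tuple[int, ...], ...] = ()
    signal_modalities: tuple[str, ...] = ("fc", "sc")
    fc_signal_strength: float = 0.08
    sc_signal_strength: float = 0.25
    n_scores: int = 8
    score_mixing: float = 0.3
    missing_rate: float = 0.0
    n_macroregions: int = 8
    n_networks: int = 7
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "branching", tuple(int(b) for b in self.branching))
        object.__setattr__(
            self, "fc_within_minus_between", tuple(float(c) for c in self.fc_within_minus_between)
        )
        object.__setattr__(
            self, "sc_rate_by_depth", tuple(float(r) for r in self.sc_rate_by_depth)
        )
        object.__setattr__(
            self,
            "signal_modules",
            tuple(tuple(sorted(int(i) for i in m)) for m in self.signal_modules),
        )
        object.__setattr__(self, "signal_modalities", tuple(self.signal_modalities))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if not 0.0 <= self.rho_true < 1.0:
            raise ValueError("rho_true must lie in [0, 1)")
        if any(b < 2 for b in self.branching):
            raise ValueError("every branching factor must be >= 2")
        if int(np.prod(self.branching)) > self.n_nodes:
            raise ValueError(
                f"branching {self.branching} implies {int(np.prod(self.branching))} leaf "
                f"blocks > {self.n_nodes} nodes"
            )
        if len(self.fc_within_minus_between) != len(self.branching):
            raise ValueError("fc_within_minus_between must have one entry per tree depth")
        if any(c < 0 for c in self.fc_within_minus_between):
            raise ValueError("correlation contrasts must be non-negative")
        if len(self.sc_rate_by_depth) != len(self.branching) + 1:
            raise ValueError("sc_rate_by_depth must have len(branching)+1 entries")
        if any(r < 0 for r in self.sc_rate_by_depth):
            raise ValueError("SC rates must be non-negative")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.n_scores < 1:
            raise ValueError("n_scores must be >= 1")
        if not 0.0 <= self.score_mixing < 1.0:
            raise ValueError("score_mixing must lie in [0, 1)")
        seen: set[int] = set()
        for m in self.signal_modules:
            if len(m) < 2:
                raise ValueError("signal modules must contain >= 2 nodes")
            if min(m) < 0 or max(m) >= self.n_nodes:
                raise ValueError("signal module node index out of range")
            if seen & set(m):
                raise ValueError("signal modules must be pairwise disjoint")
            seen |= set(m)
        if not set(self.signal_modalities) <= {"fc", "sc"}:
            raise ValueError("signal_modalities must be a subset of {'fc', 'sc'}")
        if self.rho_true > 0 and not self.signal_modules:
            raise ValueError("rho_true > 0 requires at least one signal module")
        if self.signal_modules and not self.signal_modalities:
            raise ValueError("signal modules declared but no signal modality")
        c_total = sum(self.fc_within_minus_between)
        if c_total >= 0.95:
            raise ValueError("sum of correlation contrasts must stay below 0.95")
        if self.signal_modules and "fc" in self.signal_modalities:
            if c_total <= 0:
                raise ValueError("an FC signal needs a positive correlation contrast")
            if c_total + ETA_CLIP * self.fc_signal_strength > 0.98:
                raise ValueError(
                    "fc_signal_strength too large for the unit-variance budget"
                )
            if c_total - ETA_CLIP * self.fc_signal_strength < 0.01:
                raise ValueError(
                    "fc_signal_strength too large: within-module correlation "
                    "would vanish at low trait values"
                )

    @property
    def depth(self) -> int:
        return len(self.branching)


@dataclass
class Cohort:
    """A synthetic (or loaded) study population: paired FC/SC matrices over a
    common node set, node labels, and a behavioral table."""

    subject_ids: tuple[str, ...]
    fc: np.ndarray  # (N, V, V) float, symmetric, unit diagonal
    sc: np.ndarray  # (N, V, V) int, symmetric, zero diagonal
    node_ids: tuple[str, ...]
    macroregion_of_node: np.ndarray
    network_of_node: np.ndarray
    behavior: BehaviorTable
    macroregion_names: tuple[str, ...] = ()
    network_names: tuple[str, ...] = ()
    planted_latent: np.ndarray | None = None

    def __post_init__(self):
        self.subject_ids = tuple(self.subject_ids)
        self.node_ids = tuple(self.node_ids)
        self.macroregion_of_node = np.asarray(self.macroregion_of_node, dtype=object)
        self.network_of_node = np.asarray(self.network_of_node, dtype=object)
        if not self.macroregion_names:
            self.macroregion_names = tuple(dict.fromkeys(self.macroregion_of_node))
        if not self.network_names:
            self.network_names = tuple(
                l for l in dict.fromkeys(self.network_of_node) if l != UNASSIGNED
            )
        self.macroregion_names = tuple(self.macroregion_names)
        self.network_names = tuple(self.network_names)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def validate(self) -> None:
        """Check the structural invariants of the container; raise ValueError."""
        n, v = self.n_subjects, self.n_nodes
        if self.fc.shape != (n, v, v) or self.sc.shape != (n, v, v):
            raise ValueError("FC/SC shapes inconsistent with subject/node counts")
        if len(self.macroregion_of_node) != v or len(self.network_of_node) != v:
            raise ValueError("node label lengths inconsistent with node count")
        if self.behavior.Y.shape[0] != n:
            raise ValueError("behavior table row count != number of subjects")
        if not np.allclose(self.fc, np.transpose(self.fc, (0, 2, 1))):
            raise ValueError("FC matrices must be symmetric")
        if not np.allclose(self.sc, np.transpose(self.sc, (0, 2, 1))):
            raise ValueError("SC matrices must be symmetric")
        diag = np.diagonal(self.fc, axis1=1, axis2=2)
        if not np.all(diag == 1.0):
            raise ValueError("FC diagonals must be exactly 1")
        if np.any(np.diagonal(self.sc, axis1=1, axis2=2) != 0):
            raise ValueError("SC diagonals must be exactly 0")
        if self.fc.min() < -1.0 or self.fc.max() > 1.0:
            raise ValueError("FC entries must lie in [-1, 1]")
        if self.sc.min() < 0:
            raise ValueError("SC entries must be non-negative")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("zero-variance vector cannot be standardized")
    return (x - float(np.mean(x))) / sd


def generate_behavior(
    latent: np.ndarray,
    rho_true: float,
    n_scores: int,
    seed,
    mixing: float = 0.3,
    score_names: Sequence[str] | None = None,
    domain_of_score: Sequence[str] | None = None,
) -> BehaviorTable:
    """Behavioral scores carrying a planted association with ``latent``.

    Score 1 is ``rho_true * z(latent) + sqrt(1 - rho_true^2) * noise``; the
    remaining columns mix score 1 with fresh noise at coefficient ``mixing``,
    so the optimal direction of association with the latent is score 1 alone.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 1:
        raise ValueError("latent must be a 1-D vector")
    if not 0.0 <= rho_true < 1.0:
        raise ValueError("rho_true must lie in [0, 1)")
    if n_scores < 1:
        raise ValueError("n_scores must be >= 1")
    zl = _standardize(latent)  # raises on zero variance
    rng = _as_rng(seed)
    n = latent.shape[0]
    Y = np.empty((n, n_scores), dtype=float)
    Y[:, 0] = rho_true * zl + math.sqrt(1.0 - rho_true**2) * rng.standard_normal(n)
    if n_scores > 1:
        z1 = _standardize(Y[:, 0])
        for q in range(1, n_scores):
            Y[:, q] = mixing * z1 + math.sqrt(1.0 - mixing**2) * rng.standard_normal(n)
    if score_names is None:
        score_names = tuple(f"score_{q + 1:02d}" for q in range(n_scores))
    if domain_of_score is None:
        domain_of_score = tuple(DOMAINS[q % len(DOMAINS)] for q in range(n_scores))
    return BehaviorTable(Y, tuple(score_names), tuple(domain_of_score))


def _module_mean_offdiag(stack: np.ndarray, nodes: Sequence[int], diag_value: float) -> np.ndarray:
    """Per-subject mean over off-diagonal within-module entries of a (N,V,V) stack."""
    idx = np.asarray(nodes, dtype=int)
    s = len(idx)
    sub = stack[:, idx[:, None], idx[None, :]]
    return (sub.sum(axis=(1, 2)) - s * diag_value) / (s * (s - 1))


def _inject_missing(Y: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Remove cells completely at random, never emptying a row and keeping
    every column at least half observed. Mutates ``Y`` in place."""
    n, q = Y.shape
    target = int(round(rate * n * q))
    if target == 0:
        return
    row_obs = np.full(n, q)
    col_obs = np.full(q, n)
    col_floor = n - math.ceil(0.5 * n)
    order = rng.permutation(n * q)
    removed = 0
    for flat in order:
        if removed >= target:
            break
        i, j = divmod(int(flat), q)
        if row_obs[i] <= 1 or col_obs[j] <= col_floor:
            continue
        Y[i, j] = np.nan
        row_obs[i] -= 1
        col_obs[j] -= 1
        removed += 1


def generate_cohort(spec: SynthSpec) -> Cohort:
    """Generate a full synthetic cohort, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, v, t = spec.n_subjects, spec.n_nodes, spec.n_timepoints
    depth = spec.depth
    c = np.asarray(spec.fc_within_minus_between, dtype=float)
    c_total = float(c.sum())
    block_maps = [_block_index_of_node(v, spec.branching, d) for d in range(1, depth + 1)]
    n_blocks = [int(np.prod(spec.branching[:d])) for d in range(1, depth + 1)]

    # Per-subject latent trait modulating signal-module connectivity.
    eta = rng.standard_normal(n)
    eta_c = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    fc_signal = bool(spec.signal_modules) and "fc" in spec.signal_modalities
    sc_signal = bool(spec.signal_modules) and "sc" in spec.signal_modalities

    sig_mask = np.zeros(v, dtype=bool)
    for m in spec.signal_modules:
        sig_mask[list(m)] = True
    # amplitude^2 of the shared-factor part for signal nodes: within-module
    # correlation becomes C + gamma*eta (zero-mean modulation)
    amp2 = 1.0 + spec.fc_signal_strength * eta_c / c_total if c_total > 0 else np.ones(n)

    # --- FC: finite-sample correlation of hierarchical factor time series ---
    fc = np.empty((n, v, v), dtype=float)
    for s in range(n):
        common = np.zeros((t, v))
        for d in range(depth):
            if c[d] > 0:
                G = rng.standard_normal((t, n_blocks[d]))
                common += math.sqrt(c[d]) * G[:, block_maps[d]]
        amp = np.ones(v)
        if fc_signal:
            amp[sig_mask] = math.sqrt(amp2[s])
        noise_sd = np.sqrt(1.0 - amp**2 * c_total)
        ts = amp[None, :] * common + noise_sd[None, :] * rng.standard_normal((t, v))
        A = np.corrcoef(ts, rowvar=False)
        A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(A, 1.0)
        fc[s] = A

    # --- SC: Poisson counts with tree-distance dependent rates ---
    shared = _shared_depth_matrix(v, spec.branching)
    base_rate = np.asarray(spec.sc_rate_by_depth, dtype=float)[shared]
    iu = np.triu_indices(v, 1)
    sc = np.zeros((n, v, v), dtype=np.int64)
    for s in range(n):
        rate = base_rate
        if sc_signal:
            rate = base_rate.copy()
            factor = math.exp(spec.sc_signal_strength * eta_c[s])
            for m in spec.signal_modules:
                idx = np.asarray(m, dtype=int)
                rate[np.ix_(idx, idx)] *= factor
        draws = rng.poisson(rate[iu])
        M = np.zeros((v, v), dtype=np.int64)
        M[iu] = draws
        sc[s] = M + M.T

    # --- Behavior with planted association ---
    latent: np.ndarray | None = None
    if spec.signal_modules:
        parts = []
        for m in spec.signal_modules:
            if "fc" in spec.signal_modalities:
                parts.append(_standardize(_module_mean_offdiag(np.abs(fc), m, 1.0)))
            if "sc" in spec.signal_modalities:
                parts.append(_standardize(_module_mean_offdiag(sc.astype(float), m, 0.0)))
        latent = _standardize(np.sum(parts, axis=0))
    behavior_latent = latent if latent is not None else rng.standard_normal(n)
    behavior = generate_behavior(
        behavior_latent, spec.rho_true, spec.n_scores, rng, mixing=spec.score_mixing
    )
    if spec.missing_rate > 0:
        _inject_missing(behavior.Y, spec.missing_rate, rng)

    macro = assign_macroregions(v, spec.branching, spec.n_macroregions)
    net = assign_networks(v, spec.branching, spec.n_networks)
    macro_names = tuple(_label_names(MACROREGION_NAMES, spec.n_macroregions, "region"))
    net_names = tuple(_label_names(NETWORK_NAMES, spec.n_networks, "network"))
    return Cohort(
        subject_ids=tuple(f"sub-{i:04d}" for i in range(n)),
        fc=fc,
        sc=sc,
        node_ids=tuple(f"node_{i:04d}" for i in range(v)),
        macroregion_of_node=macro,
        network_of_node=net,
        behavior=behavior,
        macroregion_names=macro_names,
        network_names=net_names,
        planted_latent=latent,
    )
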