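"""Signed modularity, its Louvain maximization, and network cartography.

Community structure in functional networks with positive and negative
edges is scored with the signed modularity quality function

    Q = (1/v+) * sum_ij (w+_ij - e+_ij) delta(M_i, M_j)
        - (1/(v+ + v-)) * sum_ij (w-_ij - e-_ij) delta(M_i, M_j)

where w+/w- are the positive part / negative magnitude of the weights,
s+-_i their nodal strengths, v+- their totals and e+-_ij =
s+-_i s+-_j / v+- the expected weights under a random null.  Nodal
roles per window are summarized by the within-module degree z-score and
the (positive-weight) participation coefficient, forming the
cartographic (z, P) profile used for state estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .fc import TimeResolvedFC


def _check_signed_graph(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidInputError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-9):
        raise InvalidInputError("weight matrix must be symmetric")
    if np.any(np.diag(w) != 0):
        raise InvalidInputError("weight matrix must have a zero diagonal")
    return w


def _check_partition(assignment, n: int) -> np.ndarray:
    a = np.asarray(assignment, dtype=int)
    if a.shape != (n,):
        raise InvalidInputError("partition must assign every node")
    return a


@dataclass
class Partition:
    """Module assignment with labels contiguous from 1."""

    assignment: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        _, a = np.unique(a, return_inverse=True)
        self.assignment = a + 1

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())


def signed_modularity_matrix(w: np.ndarray, resolution: float = 1.0) -> np.ndarray:
    """Matrix B with Q(partition) = sum of B over same-module pairs."""
    w = _check_signed_graph(w)
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp = wp.sum()
    vn = wn.sum()
    if vp == 0:
        raise InvalidInputError("graph has no positive weights")
    sp = wp.sum(axis=1)
    bp = (wp - resolution * np.outer(sp, sp) / vp) / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        bn = (wn - resolution * np.outer(sn, sn) / vn) / (vp + vn)
    else:
        bn = 0.0
    return bp - bn


def signed_modularity(w: np.ndarray, partition, resolution: float = 1.0) -> float:
    """Signed modularity Q of a partition (sums over all ordered pairs)."""
    w = _check_signed_graph(w)
    a = partition.assignment if isinstance(partition, Partition) else partition
    a = _check_partition(a, w.shape[0])
    b = signed_modularity_matrix(w, resolution)
    same = a[:, None] == a[None, :]
    return float(b[same].sum())


def _louvain_once(b: np.ndarray, rng: np.random.Generator,
                  tol: float = 1e-10) -> np.ndarray:
    """One Louvain run on a generic symmetric quality matrix ``b``.

    Local moves in random node order followed by aggregation, repeated
    until no move improves the quality by more than ``tol``.
    """
    n0 = b.shape[0]
    node_to_comm = np.arange(n0)
    b_cur = b.copy()
    while True:
        n = b_cur.shape[0]
        comm = np.arange(n)
        improved = False
        moved = True
        while moved:
            moved = False
            for i in rng.permutation(n):
                row = b_cur[i].copy()
                row[i] = 0.0
                gains = np.bincount(comm, weights=row, minlength=n)
                gains -= gains[comm[i]]
                best = int(np.argmax(gains))
                if gains[best] > tol and best != comm[i]:
                    comm[i] = best
                    moved = True
                    improved = True
        if not improved:
            break
        _, comm = np.unique(comm, return_inverse=True)
        node_to_comm = comm[node_to_comm]
        k = int(comm.max()) + 1
        if k == n:
            break
        oh = _one_hot(comm, k)
        b_cur = oh.T @ b_cur @ oh
    return node_to_comm


def _one_hot(comm: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((len(comm), k))
    m[np.arange(len(comm)), comm] = 1.0
    return m


def maximize_modularity(w: np.ndarray, n_restarts: int = 100,
                        resolution: float = 1.0,
                        seed: int | np.random.Generator = 0
                        ) -> tuple[float, Partition]:
    """Best (Q, partition) over Louvain restarts with random sweep orders.

    The returned Q is the maximum of the quality function across
    restarts; identical seeds give identical results.
    """
    w = _check_signed_graph(w)
    b = signed_modularity_matrix(w, resolution)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    best_q = -np.inf
    best_a = np.zeros(w.shape[0], dtype=int)
    for _ in range(n_restarts):
        a = _louvain_once(b, rng)
        same = a[:, None] == a[None, :]
        q = float(b[same].sum())
        if q > best_q:
            best_q = q
            best_a = a
    # never return worse than the trivial partitions
    for trivial in (np.arange(w.shape[0]), np.zeros(w.shape[0], dtype=int)):
        same = trivial[:, None] == trivial[None, :]
        q = float(b[same].sum())
        if q > best_q:
            best_q = q
            best_a = trivial
    return best_q, Partition(assignment=best_a)


def within_module_zscore(w: np.ndarray, partition,
                         positive_only: bool = False) -> np.ndarray:
    """Within-module degree z-score per node.

    kappa_i is node i's summed weight to nodes of its own module
    (signed weights by default, switchable to the positive part);
    z_i standardizes kappa within the module.  Modules of size one or
    zero spread get z = 0.
    """
    w = _check_signed_graph(w)
    if positive_only:
        w = np.where(w > 0, w, 0.0)
    a = partition.assignment if isinstance(partition, Partition) else partition
    a = _check_partition(a, w.shape[0])
    z = np.zeros(w.shape[0])
    for m in np.unique(a):
        sel = a == m
        if sel.sum() < 2:
            continue
        kappa = w[np.ix_(sel, sel)].sum(axis=1)
        sd = kappa.std()
        if sd > 0:
            z[sel] = (kappa - kappa.mean()) / sd
    return z


def participation_coefficient(w: np.ndarray, partition) -> np.ndarray:
    """Participation coefficient over positive weights.

    P_i = 1 - sum_m (kappa+_{i,m} / kappa+_i)^2; nodes with zero
    positive strength get P = 0.
    """
    w = _check_signed_graph(w)
    wp = np.where(w > 0, w, 0.0)
    a = partition.assignment if isinstance(partition, Partition) else partition
    a = _check_partition(a, w.shape[0])
    total = wp.sum(axis=1)
    frac_sq = np.zeros(w.shape[0])
    for m in np.unique(a):
        km = wp[:, a == m].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_sq += np.where(total > 0, (km / total) ** 2, 0.0)
    p = np.where(total > 0, 1.0 - frac_sq, 0.0)
    return np.clip(p, 0.0, 1.0)


@dataclass
class CartographyProfile:
    """Per-window modularity and nodal (z, P) cartography."""

    modularity: np.ndarray      # (W,)  Q_t
    zscores: np.ndarray         # (W, N)
    participation: np.ndarray   # (W, N)
    partitions: list[Partition]

    @property
    def mean_participation(self) -> np.ndarray:
        """Mean P_t over nodes, one value per window."""
        return self.participation.mean(axis=1)


def cartography(trfc: TimeResolvedFC, n_restarts: int = 100,
                resolution: float = 1.0, seed: int = 0,
                zscore_positive_only: bool = False) -> CartographyProfile:
    """Community detection and (z, P) metrics for every FC window."""
    w_count, n, _ = trfc.matrices.shape
    q = np.empty(w_count)
    zs = np.empty((w_count, n))
    ps = np.empty((w_count, n))
    parts: list[Partition] = []
    root = np.random.default_rng(seed)
    seeds = root.spawn(w_count)
    for t in range(w_count):
        qt, part = maximize_modularity(trfc.matrices[t], n_restarts=n_restarts,
                                       resolution=resolution, seed=seeds[t])
        q[t] = qt
        parts.append(part)
        zs[t] = within_module_zscore(trfc.matrices[t], part,
                                     positive_only=zscore_positive_only)
        ps[t] = participation_coefficient(trfc.matrices[t], part)
    return CartographyProfile(modularity=q, zscores=zs, participation=ps,
                              partitions=parts)
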