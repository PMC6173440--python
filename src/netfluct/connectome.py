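"""Structural connectomes: representation, normalization, nulls, and I/O.

A structural connectome couples a symmetric nonnegative weight matrix
(fiber density between cortical regions) with a matrix of fiber lengths
in millimetres and a per-node assignment to intrinsic connectivity
systems (CON, DMN, LIM, DAN, VAN, SMN, VIS by default).  Weights are
normalized so the mean of the non-zero edges is one before they drive
the oscillator model; fiber lengths set inter-node conduction delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .errors import ConvergenceError, InvalidInputError

CANONICAL_SYSTEMS = ("CON", "DMN", "LIM", "DAN", "VAN", "SMN", "VIS")

_SYM_ATOL = 1e-9


@dataclass
class StructuralConnectome:
    """Weighted structural brain network with fiber lengths.

    Parameters
    ----------
    weights : (N, N) ndarray
        Symmetric nonnegative connection weights (fiber density;
        unitless once normalized), zero diagonal.
    lengths : (N, N) ndarray
        Symmetric fiber lengths in mm, strictly positive exactly where
        ``weights`` is positive.
    node_ids : sequence of str
        Node labels (cortical parcels).
    system_labels : sequence of str
        Per-node intrinsic-system assignment.
    hemisphere : sequence of str, optional
        Per-node hemisphere labels ("L"/"R").
    """

    weights: np.ndarray
    lengths: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    system_labels: list[str] = field(default_factory=list)
    hemisphere: list[str] | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.weights.shape[0]
        if not self.node_ids:
            self.node_ids = [f"node{i:03d}" for i in range(n)]
        if not self.system_labels:
            self.system_labels = [CANONICAL_SYSTEMS[i % len(CANONICAL_SYSTEMS)]
                                  for i in range(n)]
        self.node_ids = list(self.node_ids)
        self.system_labels = list(self.system_labels)
        if self.hemisphere is not None:
            self.hemisphere = list(self.hemisphere)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        w, l = self.weights, self.lengths
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidInputError("weights must be a square matrix")
        if l.shape != w.shape:
            raise InvalidInputError("lengths must match weights in shape")
        if len(self.node_ids) != w.shape[0]:
            raise InvalidInputError("node_ids length mismatch")
        if len(self.system_labels) != w.shape[0]:
            raise InvalidInputError("system_labels length mismatch")
        if not np.allclose(w, w.T, atol=_SYM_ATOL):
            raise InvalidInputError("weights must be symmetric")
        if not np.allclose(l, l.T, atol=_SYM_ATOL):
            raise InvalidInputError("lengths must be symmetric")
        if np.any(np.diag(w) != 0):
            raise InvalidInputError("weights must have a zero diagonal")
        if np.any(w < 0):
            raise InvalidInputError("weights must be nonnegative")
        if np.any(l < 0):
            raise InvalidInputError("lengths must be nonnegative")
        edge = w > 0
        if np.any(l[edge] <= 0):
            raise InvalidInputError("lengths must be positive on every edge")

    @property
    def mean_fiber_length(self) -> float:
        """Mean fiber length over edges with non-zero weight (mm)."""
        mask = np.triu(self.weights, 1) > 0
        if not mask.any():
            raise InvalidInputError("connectome has no edges")
        return float(np.triu(self.lengths, 1)[mask].mean())

    def strengths(self) -> np.ndarray:
        """Weighted degree (strength) of every node."""
        return self.weights.sum(axis=1)

    def degrees(self) -> np.ndarray:
        """Binary degree of every node."""
        return (self.weights > 0).sum(axis=1)


@dataclass
class SurrogateConnectome(StructuralConnectome):
    """Degree- and strength-preserving randomization of a connectome."""

    source_seed: int | None = None
    rewiring_iterations: int = 0
    strength_correlation: float = float("nan")


def fiber_density(streamline_count: float, area_a: float, area_b: float) -> float:
    """Fiber density: streamline count over the geometric mean of areas.

    Compensates for the effect of region size on streamline counts.

    Parameters
    ----------
    streamline_count : nonnegative number
    area_a, area_b : float
        Surface areas (mm^2) of the two regions; must be positive.
    """
    if area_a <= 0 or area_b <= 0:
        raise InvalidInputError("surface areas must be strictly positive")
    if streamline_count < 0:
        raise InvalidInputError("streamline count must be nonnegative")
    return float(streamline_count / np.sqrt(area_a * area_b))


def normalize_weights(sc: StructuralConnectome) -> StructuralConnectome:
    """Rescale weights so the mean of all non-zero edge weights is one.

    Zero entries stay zero; relative edge ratios are preserved. The
    operation is idempotent.
    """
    mask = sc.weights > 0
    if not mask.any():
        raise InvalidInputError("cannot normalize an all-zero weight matrix")
    mean_nz = sc.weights[mask].mean()
    return replace(sc, weights=sc.weights / mean_nz)


def _edge_list(weights: np.ndarray, lengths: np.ndarray):
    iu, ju = np.triu_indices(weights.shape[0], 1)
    on = weights[iu, ju] > 0
    return iu[on], ju[on], weights[iu, ju][on], lengths[iu, ju][on]


def _double_edge_swaps(edges: np.ndarray, n: int, n_swaps: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving double-edge swaps on an undirected edge list.

    ``edges`` is an (E, 2) int array; rows are rewired in place-style
    (a copy is returned).  Attribute columns must be carried by the
    caller via the row index, which is untouched.
    """
    edges = edges.copy()
    present = set(map(tuple, np.sort(edges, axis=1)))
    e = len(edges)
    done = 0
    attempts = 0
    max_attempts = 40 * n_swaps
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        p, q = rng.integers(0, e, size=2)
        if p == q:
            continue
        a, b = edges[p]
        c, d = edges[q]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed: (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        e1 = (min(a, d), max(a, d))
        e2 = (min(c, b), max(c, b))
        if e1 in present or e2 in present:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(e1)
        present.add(e2)
        edges[p] = e1
        edges[q] = e2
        done += 1
    return edges


def rewire_surrogate(sc: StructuralConnectome, seed: int,
                     swaps_per_edge: int = 10,
                     correlation_threshold: float = 0.95,
                     max_attempts: int = 1000) -> SurrogateConnectome:
    """Random null connectome preserving degrees and (approx.) strengths.

    The binary topology is randomized by iterative double-edge swaps,
    which preserve every node's binary degree exactly.  The original
    (weight, length) pairs are then re-assigned to the rewired edge
    slots by rank-matching: the edge whose endpoint-strength product is
    largest receives the largest weight, which approximately preserves
    each node's strength.  Candidates are regenerated until the Pearson
    correlation between original and surrogate strength sequences
    exceeds ``correlation_threshold``.

    Raises
    ------
    ConvergenceError
        If no candidate reaches the threshold within ``max_attempts``;
        the best correlation achieved is attached to the exception.
    """
    iu, ju, w, l = _edge_list(sc.weights, sc.lengths)
    if len(w) < 2:
        raise InvalidInputError("need at least two independent edges to rewire")
    edges = np.column_stack([iu, ju])
    s_orig = sc.strengths()
    order_w = np.argsort(w)[::-1]          # weights descending
    n_swaps = swaps_per_edge * len(w)
    rng = np.random.default_rng(seed)
    best = -1.0
    for attempt in range(max_attempts):
        new_edges = _double_edge_swaps(edges, sc.n_nodes, n_swaps, rng)
        # iterative greedy re-ranking: repeatedly hand the largest
        # remaining weight to the edge with the largest product of
        # residual endpoint strengths, then debit both endpoints
        w_desc = w[order_w]
        l_desc = l[order_w]
        resid = s_orig.astype(float).copy()
        remaining = np.arange(len(w))
        w_new = np.empty_like(w)
        l_new = np.empty_like(l)
        for t in range(len(w)):
            prod = (resid[new_edges[remaining, 0]]
                    * resid[new_edges[remaining, 1]])
            pick = remaining[int(np.argmax(prod))]
            w_new[pick] = w_desc[t]
            l_new[pick] = l_desc[t]
            resid[new_edges[pick, 0]] -= w_desc[t]
            resid[new_edges[pick, 1]] -= w_desc[t]
            remaining = remaining[remaining != pick]
        W = np.zeros_like(sc.weights)
        L = np.zeros_like(sc.lengths)
        W[new_edges[:, 0], new_edges[:, 1]] = w_new
        L[new_edges[:, 0], new_edges[:, 1]] = l_new
        W += W.T
        L += L.T
        r = float(np.corrcoef(s_orig, W.sum(axis=1))[0, 1])
        if r > best:
            best = r
        if r > correlation_threshold:
            return SurrogateConnectome(
                weights=W, lengths=L,
                node_ids=list(sc.node_ids),
                system_labels=list(sc.system_labels),
                hemisphere=None if sc.hemisphere is None else list(sc.hemisphere),
                source_seed=seed, rewiring_iterations=n_swaps,
                strength_correlation=r)
    raise ConvergenceError(
        f"no surrogate reached strength correlation > {correlation_threshold} "
        f"in {max_attempts} attempts (best {best:.4f})", best=best)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_matrix_text(path, matrix: np.ndarray, node_ids, sep: str = "\t") -> None:
    """Write a square matrix as delimited text with a node-id header row."""
    pd.DataFrame(matrix, columns=list(node_ids)).to_csv(path, sep=sep, index=False)


def read_matrix_text(path, sep: str | None = None):
    """Read a delimited square matrix; returns (matrix, node_ids)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def save_connectome_hdf5(path, sc: StructuralConnectome) -> None:
    """Write weights/lengths/labels to a single binary container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=sc.weights)
        f.create_dataset("lengths", data=sc.lengths)
        f.create_dataset("labels", data=np.array(sc.system_labels, dtype="S"))
        f.create_dataset("node_ids", data=np.array(sc.node_ids, dtype="S"))
        if sc.hemisphere is not None:
            f.create_dataset("hemisphere", data=np.array(sc.hemisphere, dtype="S"))


def load_connectome_hdf5(path) -> StructuralConnectome:
    with h5py.File(path, "r") as f:
        hemi = None
        if "hemisphere" in f:
            hemi = [s.decode() for s in f["hemisphere"][()]]
        return StructuralConnectome(
            weights=f["weights"][()],
            lengths=f["lengths"][()],
            node_ids=[s.decode() for s in f["node_ids"][()]],
            system_labels=[s.decode() for s in f["labels"][()]],
            hemisphere=hemi)
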