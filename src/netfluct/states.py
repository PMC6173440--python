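"""Network states of time-resolved functional connectivity.

Two state definitions are supported: (i) segregated vs integrated
states from k-means (k = 2) clustering of the per-window joint
histogram of within-module degree z-scores and participation
coefficients, the higher-participation cluster being "integrated"; and
(ii) high / middle / low modularity periods from per-run terciles of
Q_t.  State sequences are summarized by transition probabilities, mean
dwell times, per-state median FC centroids, between-state t-score
contrasts over intrinsic-system pairs (FDR corrected), similarity of
centroids to structural connectivity, and global absolute FC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .connectome import StructuralConnectome
from .errors import (InsufficientDataError, InvalidInputError,
                     UndefinedCorrelationError)
from .fc import FCMatrix, TimeResolvedFC
from .metrics import CartographyProfile

SEGREGATED = "segregated"
INTEGRATED = "integrated"
MODULARITY_LEVELS = ("high", "middle", "low")

HIST_BINS = 100
Z_RANGE = (-5.0, 5.0)
P_RANGE = (0.0, 1.0)


@dataclass
class StateSequence:
    """Per-window state labels at the sliding-window step (2.16 s)."""

    labels: np.ndarray
    step_seconds: float = 2.16
    degenerate: bool = False

    def __post_init__(self):
        self.labels = np.asarray(self.labels)

    @property
    def n_windows(self) -> int:
        return len(self.labels)

    @property
    def states(self) -> list:
        return sorted(set(self.labels.tolist()))


@dataclass
class StateSummary:
    """Transition matrix, dwell times, occupancy and centroids."""

    states: list
    transition_matrix: np.ndarray
    mean_dwell_windows: dict
    mean_dwell_seconds: dict
    occupancy: dict
    centroids: dict = field(default_factory=dict)


def _bin_index(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Half-open binning [edge, next_edge) with out-of-range clipping."""
    idx = np.floor((values - lo) / (hi - lo) * HIST_BINS).astype(int)
    return np.clip(idx, 0, HIST_BINS - 1)


def joint_histogram(profile: CartographyProfile) -> np.ndarray:
    """Per-window 100 x 100 joint histogram of (z, P) over nodes.

    Bin ranges are -5 < z < 5 and 0 < P < 1; values outside fall into
    the nearest edge bin, so every window's counts sum to N.
    """
    w, n = profile.zscores.shape
    hist = np.zeros((w, HIST_BINS, HIST_BINS), dtype=np.int64)
    for t in range(w):
        zi = _bin_index(profile.zscores[t], *Z_RANGE)
        pi = _bin_index(profile.participation[t], *P_RANGE)
        np.add.at(hist[t], (zi, pi), 1)
    return hist


def estimate_seg_int_states(histograms: np.ndarray,
                            participation: np.ndarray,
                            n_restarts: int = 500,
                            seed: int = 0,
                            step_seconds: float = 2.16) -> StateSequence:
    """Segregated/integrated labels from k-means on joint histograms.

    Windows are clustered on the flattened histograms (Euclidean
    distance, k = 2, best inertia over ``n_restarts`` random
    initializations).  The cluster whose windows have the greater mean
    participation coefficient is labeled integrated.  If all windows
    are identical the output is flagged degenerate (single state).
    """
    w = histograms.shape[0]
    if w < 2:
        raise InvalidInputError("need at least two windows")
    x = histograms.reshape(w, -1).astype(float)
    if np.allclose(x, x[0]):
        warnings.warn("all windows identical; single-cluster degenerate output",
                      RuntimeWarning, stacklevel=2)
        return StateSequence(labels=np.array([SEGREGATED] * w),
                             step_seconds=step_seconds, degenerate=True)
    km = KMeans(n_clusters=2, n_init=n_restarts, init="random",
                random_state=np.random.RandomState(seed), algorithm="lloyd")
    raw = km.fit_predict(x)
    mean_p = participation.mean(axis=1)
    p0 = mean_p[raw == 0].mean()
    p1 = mean_p[raw == 1].mean()
    integrated_cluster = 0 if p0 > p1 else 1
    labels = np.where(raw == integrated_cluster, INTEGRATED, SEGREGATED)
    return StateSequence(labels=labels, step_seconds=step_seconds)


def modularity_period_labels(q_series: np.ndarray,
                             step_seconds: float = 2.16) -> StateSequence:
    """High / middle / low modularity periods by per-run terciles of Q_t.

    Windows with Q strictly above the upper tercile are "high", strictly
    below the lower tercile "low", the rest (including boundary ties)
    "middle".  The labeling is invariant to any strictly monotone
    transform of Q.
    """
    q = np.asarray(q_series, dtype=float)
    if len(q) < 3:
        raise InvalidInputError("need at least three windows")
    lo, hi = np.quantile(q, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(q > hi, "high", np.where(q < lo, "low", "middle"))
    return StateSequence(labels=labels, step_seconds=step_seconds)


def transition_stats(seq: StateSequence,
                     states: list | None = None) -> StateSummary:
    """Transition probabilities and mean dwell times of a label sequence.

    ``transition_matrix[i, j]`` estimates P(next = j | current = i)
    from consecutive window pairs.  Mean dwell is the mean length of
    consecutive same-state runs, in windows and in seconds (windows
    times the window step).  States never observed get NaN rows/dwell.
    """
    if seq.n_windows < 2:
        raise InvalidInputError("need at least two windows")
    labels = seq.labels
    if states is None:
        states = seq.states
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    counts = np.zeros((k, k))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[index[a], index[b]] += 1
    rows = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        trans = np.where(rows[:, None] > 0, counts / np.where(rows[:, None] > 0,
                                                              rows[:, None], 1),
                         np.nan)

    runs: dict = {s: [] for s in states}
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            runs[labels[start]].append(t - start)
            start = t
    dwell_w = {s: (float(np.mean(r)) if r else float("nan"))
               for s, r in runs.items()}
    dwell_s = {s: d * seq.step_seconds for s, d in dwell_w.items()}
    occ = {s: float((labels == s).mean()) for s in states}
    return StateSummary(states=list(states), transition_matrix=trans,
                        mean_dwell_windows=dwell_w, mean_dwell_seconds=dwell_s,
                        occupancy=occ)


def state_centroids(trfc: TimeResolvedFC, seq: StateSequence) -> dict:
    """Per-state centroid FC: elementwise median over the state's windows."""
    if seq.n_windows != trfc.n_windows:
        raise InvalidInputError("label/window count mismatch")
    out = {}
    for s in seq.states:
        sel = seq.labels == s
        if not sel.any():
            warnings.warn(f"state {s!r} has no windows; centroid undefined",
                          RuntimeWarning, stacklevel=2)
            continue
        out[s] = FCMatrix(values=np.median(trfc.matrices[sel], axis=0))
    return out


def _system_pair_means(matrix: np.ndarray, labels: np.ndarray,
                       systems: list) -> np.ndarray:
    """Mean edge weight within each ordered pair of systems (diagonal excluded)."""
    s = len(systems)
    out = np.full((s, s), np.nan)
    for a in range(s):
        for b in range(a, s):
            ia = np.nonzero(labels == systems[a])[0]
            ib = np.nonzero(labels == systems[b])[0]
            block = matrix[np.ix_(ia, ib)]
            if a == b:
                iu, ju = np.triu_indices(len(ia), 1)
                vals = block[iu, ju]
            else:
                vals = block.ravel()
            if len(vals):
                out[a, b] = out[b, a] = float(np.mean(vals))
    return out


@dataclass
class ContrastResult:
    """Between-state system-pair contrast: t-scores and significance."""

    systems: list
    t_scores: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray     # boolean mask after FDR


def between_state_contrast(centroids_first: list, centroids_second: list,
                           system_labels, alpha: float = 0.05) -> ContrastResult:
    """Paired t-scores of first-state minus second-state centroid weights.

    Centroid weights are averaged within each system pair per sample;
    the paired t-statistic of the difference (first minus second, e.g.
    segregated minus integrated) is computed across samples and masked
    by Benjamini-Hochberg FDR at ``alpha`` over all unique system-pair
    cells.  Positive t means larger in the first-named state.
    """
    if len(centroids_first) != len(centroids_second):
        raise InvalidInputError("sample lists must have equal length")
    if len(centroids_first) < 3:
        raise InsufficientDataError("need at least 3 samples for the contrast")
    labels = np.asarray(system_labels)
    systems = sorted(set(labels.tolist()))
    s = len(systems)
    diffs = []
    for ca, cb in zip(centroids_first, centroids_second):
        ma = ca.values if isinstance(ca, FCMatrix) else np.asarray(ca)
        mb = cb.values if isinstance(cb, FCMatrix) else np.asarray(cb)
        diffs.append(_system_pair_means(ma, labels, systems)
                     - _system_pair_means(mb, labels, systems))
    diffs = np.array(diffs)                      # (samples, s, s)

    iu, ju = np.triu_indices(s)
    tvals = np.full((s, s), np.nan)
    pvals = np.full((s, s), np.nan)
    flat_p = []
    for a, b in zip(iu, ju):
        d = diffs[:, a, b]
        res = stats.ttest_1samp(d, 0.0)
        tvals[a, b] = tvals[b, a] = res.statistic
        pvals[a, b] = pvals[b, a] = res.pvalue
        flat_p.append(res.pvalue)
    flat_p = np.array(flat_p)
    ok = np.isfinite(flat_p)
    reject_flat = np.zeros(len(flat_p), dtype=bool)
    if ok.any():
        reject_flat[ok] = multipletests(flat_p[ok], alpha=alpha,
                                        method="fdr_bh")[0]
    sig = np.zeros((s, s), dtype=bool)
    for (a, b), r in zip(zip(iu, ju), reject_flat):
        sig[a, b] = sig[b, a] = r
    return ContrastResult(systems=systems, t_scores=tvals, p_values=pvals,
                          significant=sig)


def sc_fc_similarity(sc: StructuralConnectome, fc: FCMatrix | np.ndarray) -> float:
    """Pearson correlation of FC with SC over structurally connected edges."""
    f = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
    iu, ju = np.triu_indices(sc.n_nodes, 1)
    mask = sc.weights[iu, ju] > 0
    if mask.sum() < 3:
        raise InsufficientDataError("need at least 3 non-zero SC edges")
    x = sc.weights[iu, ju][mask]
    y = f[iu, ju][mask]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("constant edge weights")
    return float(stats.pearsonr(x, y).statistic)


def global_absolute_fc(trfc: TimeResolvedFC, seq: StateSequence) -> dict:
    """Mean absolute edge weight over all edges and windows of each state."""
    if seq.n_windows != trfc.n_windows:
        raise InvalidInputError("label/window count mismatch")
    n = trfc.matrices.shape[1]
    iu, ju = np.triu_indices(n, 1)
    out = {}
    for s in seq.states:
        sel = seq.labels == s
        if sel.any():
            out[s] = float(np.abs(trfc.matrices[sel][:, iu, ju]).mean())
    return out
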