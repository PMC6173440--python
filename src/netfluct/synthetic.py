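"""Synthetic study inputs with known ground truth.

Two generators make every downstream stage testable without any data
download: a modular weighted connectome with geometric fiber lengths
laid out in two mirrored "hemisphere" blocks, and reference BOLD runs
carrying a planted hidden-Markov state structure (state-specific
covariance, stated transition probabilities, Gaussian observation
noise).  The connectome stands in for a tractography-derived group
connectome; the BOLD generator stands in for preprocessed empirical
resting-state runs whose network states are to be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import CANONICAL_SYSTEMS, StructuralConnectome, normalize_weights
from .errors import InvalidInputError


@dataclass
class SyntheticConnectomeSpec:
    """Parameters of the modular synthetic connectome.

    Defaults emulate the scale of a 114-parcel cortical connectome:
    seven modules (one per intrinsic system), lognormal edge weights,
    and Euclidean fiber lengths from coordinates drawn inside a
    brain-sized box split into two mirrored hemisphere blocks.
    """

    n_nodes: int = 114
    n_modules: int = 7
    intra_density: float = 0.6
    inter_density: float = 0.1
    weight_lognormal_params: tuple[float, float] = (0.0, 0.6)
    coordinate_box: tuple[float, float, float] = (70.0, 170.0, 120.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 1:
            raise InvalidInputError("n_modules must be >= 1")
        if not (0 < self.inter_density <= self.intra_density <= 1):
            raise InvalidInputError(
                "need 0 < inter_density <= intra_density <= 1")
        if self.n_nodes < 2 * self.n_modules:
            raise InvalidInputError("too few nodes for the module count")
        if self.weight_lognormal_params[1] <= 0:
            raise InvalidInputError("lognormal sigma must be positive")


def generate_connectome(spec: SyntheticConnectomeSpec) -> StructuralConnectome:
    """Sample a modular weighted connectome with geometric lengths.

    Nodes split evenly into two mirrored hemisphere blocks; each module
    has members in both hemispheres clustered around mirrored spatial
    centers, so fiber lengths (Euclidean inter-node distances) are
    short within modules and long between hemispheres.  Edges are
    Bernoulli with ``intra_density`` within modules and
    ``inter_density`` between; weights are lognormal.  The returned
    weights are normalized (mean non-zero weight = 1).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    modules = np.arange(n) % spec.n_modules
    half = n // 2
    hemi = np.array(["L"] * half + ["R"] * (n - half))

    bx, by, bz = spec.coordinate_box
    centers = rng.uniform([10, -by / 2, -bz / 2],
                          [bx / 2, by / 2, bz / 2],
                          size=(spec.n_modules, 3))
    coords = centers[modules] + rng.normal(0, 12.0, size=(n, 3))
    coords[:, 0] = np.abs(coords[:, 0])
    coords[hemi == "L", 0] *= -1.0        # mirror left hemisphere in x

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))

    mu, sigma = spec.weight_lognormal_params
    same = modules[:, None] == modules[None, :]
    p = np.where(same, spec.intra_density, spec.inter_density)
    iu, ju = np.triu_indices(n, 1)
    on = rng.random(len(iu)) < p[iu, ju]
    w_vals = rng.lognormal(mu, sigma, size=on.sum())

    weights = np.zeros((n, n))
    weights[iu[on], ju[on]] = w_vals
    weights += weights.T
    lengths = np.where(weights > 0, np.maximum(dist, 1.0), 0.0)

    labels = [CANONICAL_SYSTEMS[m % len(CANONICAL_SYSTEMS)] if spec.n_modules <= 7
              else f"M{m + 1}" for m in modules]
    sc = StructuralConnectome(weights=weights, lengths=lengths,
                              node_ids=[f"node{i:03d}" for i in range(n)],
                              system_labels=labels, hemisphere=list(hemi))
    return normalize_weights(sc)


def planted_modules(spec: SyntheticConnectomeSpec) -> np.ndarray:
    """Ground-truth module assignment used by :func:`generate_connectome`."""
    return np.arange(spec.n_nodes) % spec.n_modules


# ---------------------------------------------------------------------------
# Planted-state BOLD
# ---------------------------------------------------------------------------

def make_state_covariances(n_nodes: int, n_modules: int = 4,
                           segregation_strength: float = 1.0,
                           base_within: float = 0.45,
                           base_between: float = 0.28,
                           scale: float = 1.0) -> list[np.ndarray]:
    """Covariances for a segregated and an integrated planted state.

    Both states share the same modular block skeleton (so community
    detection finds a stable partition in either state); the segregated
    state raises within-module and suppresses between-module
    correlation by ``segregation_strength``, while the integrated state
    keeps substantial cross-module correlation.  By construction the
    segregated state yields lower participation coefficients, giving a
    known ordering for state-labeling tests.  Returned in the order
    [segregated, integrated].
    """
    modules = np.arange(n_nodes) % n_modules
    same = modules[:, None] == modules[None, :]

    def corr(within, between):
        c = np.where(same, within, between).astype(float)
        np.fill_diagonal(c, 1.0)
        # ensure PD via eigenvalue floor
        w, v = np.linalg.eigh(c)
        if w.min() <= 1e-8:
            c = v @ np.diag(np.maximum(w, 1e-6)) @ v.T
            d = np.sqrt(np.diag(c))
            c = c / np.outer(d, d)
        return c * scale

    s = np.clip(segregation_strength, 0.0, 1.0)
    seg = corr(base_within + 0.25 * s, base_between * (1 - 0.9 * s))
    integ = corr(base_within, base_between)
    return [seg, integ]


@dataclass
class SyntheticBoldSpec:
    """Parameters of the planted hidden-Markov BOLD generator."""

    n_nodes: int = 114
    n_timepoints: int = 1200
    tr_seconds: float = 0.72
    states: list[np.ndarray] = field(default_factory=list)
    state_names: list[str] = field(default_factory=list)
    markov_transition: np.ndarray | None = None
    observation_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not self.states:
            self.states = make_state_covariances(self.n_nodes)
            self.state_names = ["segregated", "integrated"]
        if not self.state_names:
            self.state_names = [f"state{i}" for i in range(len(self.states))]
        if self.markov_transition is None:
            s = len(self.states)
            # stay probability 0.995 per TR: mean dwell 200 TRs (144 s
            # at TR 0.72 s), comfortably longer than the window support
            t = np.full((s, s), 0.005 / max(s - 1, 1))
            np.fill_diagonal(t, 0.995 if s > 1 else 1.0)
            self.markov_transition = t
        self.markov_transition = np.asarray(self.markov_transition, dtype=float)

    def validate(self) -> None:
        s = len(self.states)
        if self.markov_transition.shape != (s, s):
            raise InvalidInputError("transition matrix shape mismatch")
        if not np.allclose(self.markov_transition.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidInputError("transition rows must sum to 1")
        if np.any(self.markov_transition < 0):
            raise InvalidInputError("transition probabilities must be >= 0")
        for c in self.states:
            c = np.asarray(c)
            if c.shape != (self.n_nodes, self.n_nodes):
                raise InvalidInputError("covariance shape mismatch")
            if not np.allclose(c, c.T, atol=1e-9):
                raise InvalidInputError("covariance must be symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise InvalidInputError("covariance must be positive definite")


def generate_state_bold(spec: SyntheticBoldSpec):
    """Sample reference BOLD with a planted hidden-Markov state path.

    Each TR draws the hidden state from the Markov chain, then the
    regional sample from that state's multivariate Gaussian, plus white
    observation noise.  Returns ``(bold, true_state_sequence)`` where
    ``bold`` is a :class:`~netfluct.hemodynamics.BoldDataset` and the
    state sequence is an int array of length ``n_timepoints``.
    """
    from .hemodynamics import BoldDataset   # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_states = len(spec.states)
    chols = [np.linalg.cholesky(np.asarray(c)) for c in spec.states]

    states = np.empty(spec.n_timepoints, dtype=int)
    states[0] = rng.integers(n_states)
    for t in range(1, spec.n_timepoints):
        states[t] = rng.choice(n_states, p=spec.markov_transition[states[t - 1]])

    signal = np.empty((spec.n_nodes, spec.n_timepoints))
    z = rng.standard_normal((spec.n_timepoints, spec.n_nodes))
    for t in range(spec.n_timepoints):
        signal[:, t] = chols[states[t]] @ z[t]
    signal += rng.normal(0, spec.observation_noise_sd, size=signal.shape)

    bold = BoldDataset(signal=signal, tr_seconds=spec.tr_seconds,
                       run_label=f"synthetic-seed{spec.seed}")
    return bold, states
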