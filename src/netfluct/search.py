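"""Two-stage model parameter search and the surrogate-connectome control.

Stage 1 scans a (coupling k, mean delay tau_bar) grid, scoring each set
by (i) the correlation of sample-averaged modeled long-timescale FC
with the reference FC (over all node pairs and over structurally
connected pairs) and (ii) the KS distance between modeled and
reference FCD distributions; sets with direct-pair correlation > 0.33
and KS < 0.33 survive.  Stage 2 compares the SD over time of mean
participation P_t and modularity Q_t against reference SDs via
fluctuation ratios and keeps the set whose mean ratios are jointly
closest to one.  The surrogate control re-fits k on degree- and
strength-preserving rewired connectomes so their global synchrony
matches the original, then compares fluctuation ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import StructuralConnectome, SurrogateConnectome, rewire_surrogate
from .errors import InvalidInputError, NetfluctError
from .fc import ks_distance
from .oscillator import KuramotoConfig, integrate_kuramoto, order_parameter
from .pipeline import SimulationSettings, run_sample

SEED_CAP = 2 ** 31 - 1


@dataclass
class ParameterGrid:
    """Search grid over coupling k and mean delay tau_bar (ms).

    Defaults reproduce the full 28 x 16 = 448-set grid (k from 2.5 to
    70 in steps of 2.5; tau_bar from 2 to 17 ms in steps of 1 ms).
    """

    coupling_values: np.ndarray = field(
        default_factory=lambda: np.arange(2.5, 70.0 + 1e-9, 2.5))
    mean_delay_values_ms: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 17.0 + 1e-9, 1.0))

    def __post_init__(self):
        self.coupling_values = np.asarray(self.coupling_values, dtype=float)
        self.mean_delay_values_ms = np.asarray(self.mean_delay_values_ms,
                                               dtype=float)
        for v in (self.coupling_values, self.mean_delay_values_ms):
            if len(v) == 0 or np.any(np.diff(v) <= 0):
                raise InvalidInputError("grid values must be strictly increasing")

    @property
    def n_sets(self) -> int:
        return len(self.coupling_values) * len(self.mean_delay_values_ms)

    def sets(self):
        for k in self.coupling_values:
            for tau in self.mean_delay_values_ms:
                yield float(k), float(tau)


@dataclass
class ReferenceSummaries:
    """Reference-side quantities the search compares against."""

    long_fc: np.ndarray           # (N, N) Fisher-z
    fcd: np.ndarray               # flat correlation sample
    sd_mean_participation: float
    sd_modularity: float
    synchrony: float = float("nan")


def fluctuation_ratio(model_series: np.ndarray,
                      empirical_reference_sd: float) -> float:
    """SD of the model's per-window metric over the reference SD."""
    series = np.asarray(model_series, dtype=float)
    if series.size < 2:
        raise InvalidInputError("model series needs at least 2 windows")
    if empirical_reference_sd <= 0:
        raise InvalidInputError("reference SD must be positive")
    return float(series.std() / empirical_reference_sd)


def fc_pattern_correlation(fc_a: np.ndarray, fc_b: np.ndarray,
                           edge_mask: np.ndarray | None = None) -> float:
    """Correlation of two FC matrices over upper-triangle (optionally masked)."""
    n = fc_a.shape[0]
    iu, ju = np.triu_indices(n, 1)
    xa, xb = fc_a[iu, ju], fc_b[iu, ju]
    if edge_mask is not None:
        sel = edge_mask[iu, ju]
        xa, xb = xa[sel], xb[sel]
    return float(np.corrcoef(xa, xb)[0, 1])


def _sample_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, SEED_CAP, size=n)


def run_stage1(sc: StructuralConnectome, grid: ParameterGrid,
               reference: ReferenceSummaries, settings: SimulationSettings,
               n_samples: int = 10, seed: int = 0) -> pd.DataFrame:
    """Stage-1 scores per parameter set.

    Modeled long-timescale FC is averaged over the samples before
    correlating with the reference; the modeled FCD pools every
    sample's retained window-pair correlations.
    """
    direct = sc.weights > 0
    rows = []
    rng = np.random.default_rng(seed)
    for k, tau in grid.sets():
        seeds = rng.integers(0, SEED_CAP, size=n_samples)
        fc_sum = None
        fcd_all = []
        sync = []
        for s in seeds:
            res = run_sample(sc, k, tau, int(s), settings,
                             with_cartography=False)
            fc_sum = (res.long_fc.values if fc_sum is None
                      else fc_sum + res.long_fc.values)
            fcd_all.append(res.fcd.correlations)
            sync.append(res.order.synchrony)
        fc_mean = fc_sum / n_samples
        fcd_pooled = np.concatenate(fcd_all)
        rows.append({
            "coupling": k, "mean_delay_ms": tau,
            "corr_all": fc_pattern_correlation(fc_mean, reference.long_fc),
            "corr_direct": fc_pattern_correlation(fc_mean, reference.long_fc,
                                                  direct),
            "ks_fcd": ks_distance(fcd_pooled, reference.fcd),
            "synchrony": float(np.mean(sync)),
            "n_samples": n_samples,
            "seeds": ",".join(str(int(s)) for s in seeds),
        })
    return pd.DataFrame(rows)


def stage1_select(results: pd.DataFrame, corr_threshold: float = 0.33,
                  ks_threshold: float = 0.33) -> pd.DataFrame:
    """Sets with direct-pair FC correlation > 0.33 and FCD KS < 0.33.

    Both inequalities are strict; an empty selection is returned as an
    empty frame rather than an error.
    """
    sel = results[(results["corr_direct"] > corr_threshold)
                  & (results["ks_fcd"] < ks_threshold)]
    return sel.reset_index(drop=True)


def run_stage2(sc: StructuralConnectome, candidates: pd.DataFrame,
               reference: ReferenceSummaries, settings: SimulationSettings,
               n_samples: int = 100, seed: int = 0) -> pd.DataFrame:
    """Per-candidate fluctuation ratios of mean P_t and Q_t SDs."""
    rows = []
    rng = np.random.default_rng(seed)
    for _, cand in candidates.iterrows():
        k, tau = float(cand["coupling"]), float(cand["mean_delay_ms"])
        seeds = rng.integers(0, SEED_CAP, size=n_samples)
        rp, rq = [], []
        for s in seeds:
            res = run_sample(sc, k, tau, int(s), settings,
                             with_cartography=True)
            rp.append(fluctuation_ratio(res.profile.mean_participation,
                                        reference.sd_mean_participation))
            rq.append(fluctuation_ratio(res.profile.modularity,
                                        reference.sd_modularity))
        rows.append({
            "coupling": k, "mean_delay_ms": tau,
            "ratio_meanP": float(np.mean(rp)),
            "ratio_Q": float(np.mean(rq)),
            "ratio_meanP_sd": float(np.std(rp)),
            "ratio_Q_sd": float(np.std(rq)),
            "n_samples": n_samples,
            "seeds": ",".join(str(int(s)) for s in seeds),
        })
    return pd.DataFrame(rows)


def stage2_select(results: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """Best set: mean |1 - ratio| over the two metrics, minimized.

    Over- and under-shoot are penalized symmetrically; ties break to
    the smallest coupling, then the smallest delay.  Returns the
    winning row as a dict plus the full ranking.
    """
    if len(results) == 0:
        raise InvalidInputError("stage-2 needs at least one candidate")
    df = results.copy()
    df["score"] = 0.5 * (np.abs(1.0 - df["ratio_meanP"])
                         + np.abs(1.0 - df["ratio_Q"]))
    ranking = df.sort_values(["score", "coupling", "mean_delay_ms"],
                             kind="mergesort").reset_index(drop=True)
    return ranking.iloc[0].to_dict(), ranking


def run_grid(sc: StructuralConnectome, grid: ParameterGrid,
             reference: ReferenceSummaries, settings: SimulationSettings,
             n_samples_stage1: int = 10, n_samples_stage2: int = 100,
             seed: int = 0):
    """Full two-stage search; returns (stage1, stage2, selection dict)."""
    stage1 = run_stage1(sc, grid, reference, settings,
                        n_samples=n_samples_stage1, seed=seed)
    survivors = stage1_select(stage1)
    if len(survivors) == 0:
        warnings.warn("no parameter set passed stage 1", RuntimeWarning,
                      stacklevel=2)
        return stage1, pd.DataFrame(), None
    stage2 = run_stage2(sc, survivors, reference, settings,
                        n_samples=n_samples_stage2, seed=seed + 1)
    selection, ranking = stage2_select(stage2)
    return stage1, ranking, selection


def reference_from_model(sc: StructuralConnectome, coupling: float,
                         mean_delay_ms: float, settings: SimulationSettings,
                         n_samples: int = 3, seed: int = 0
                         ) -> ReferenceSummaries:
    """Reference summaries computed from the model's own output.

    Used for self-recovery experiments: summaries generated at a known
    (k, tau_bar) stand in for the empirical reference.
    """
    seeds = _sample_seeds(seed, n_samples)
    fc_sum = None
    fcd_all, sdp, sdq, sync = [], [], [], []
    for s in seeds:
        res = run_sample(sc, coupling, mean_delay_ms, int(s), settings,
                         with_cartography=True)
        fc_sum = (res.long_fc.values if fc_sum is None
                  else fc_sum + res.long_fc.values)
        fcd_all.append(res.fcd.correlations)
        sdp.append(res.sd_mean_participation)
        sdq.append(res.sd_modularity)
        sync.append(res.order.synchrony)
    return ReferenceSummaries(long_fc=fc_sum / n_samples,
                              fcd=np.concatenate(fcd_all),
                              sd_mean_participation=float(np.mean(sdp)),
                              sd_modularity=float(np.mean(sdq)),
                              synchrony=float(np.mean(sync)))


def reference_from_bold(bold_runs, settings: SimulationSettings,
                        seed: int = 0) -> ReferenceSummaries:
    """Reference summaries from reference BOLD runs (empirical-like data)."""
    from .pipeline import analyze_bold
    fc_sum = None
    fcd_all, sdp, sdq = [], [], []
    for i, bold in enumerate(bold_runs):
        res = analyze_bold(bold, settings, seed=seed + i,
                           with_cartography=True)
        fc_sum = (res.long_fc.values if fc_sum is None
                  else fc_sum + res.long_fc.values)
        fcd_all.append(res.fcd.correlations)
        sdp.append(res.sd_mean_participation)
        sdq.append(res.sd_modularity)
    return ReferenceSummaries(long_fc=fc_sum / len(list(bold_runs)),
                              fcd=np.concatenate(fcd_all),
                              sd_mean_participation=float(np.mean(sdp)),
                              sd_modularity=float(np.mean(sdq)))


def mean_synchrony(sc: StructuralConnectome, coupling: float,
                   mean_delay_ms: float, settings: SimulationSettings,
                   seed: int = 0) -> float:
    """Mean order parameter of one (shorter) simulation run."""
    config = KuramotoConfig(coupling=coupling, mean_delay_ms=mean_delay_ms,
                            duration_s=settings.transient_discard_s + 40.0,
                            dt_ms=settings.dt_ms,
                            noise_sd_rad_s=settings.noise_sd_rad_s,
                            transient_discard_s=settings.transient_discard_s,
                            natural_frequency_hz=settings.natural_frequency_hz,
                            seed=seed)
    traj = integrate_kuramoto(sc, config)
    return order_parameter(traj).synchrony


def surrogate_synchrony_match(surrogate: SurrogateConnectome,
                              target_synchrony: float,
                              fixed_mean_delay_ms: float,
                              k_grid, settings: SimulationSettings,
                              seed: int = 0) -> tuple[float, pd.DataFrame]:
    """Coupling k whose mean order parameter is closest to the target.

    The mean delay stays fixed at the original connectome's value;
    every k in the grid is simulated on the surrogate.  Ties in
    |synchrony - target| break to the smallest k; a diverging k is
    skipped with a warning.
    """
    k_grid = np.asarray(list(k_grid), dtype=float)
    if len(k_grid) == 0:
        raise InvalidInputError("k grid must be non-empty")
    rows = []
    for k in k_grid:
        try:
            s = mean_synchrony(surrogate, float(k), fixed_mean_delay_ms,
                               settings, seed=seed)
        except NetfluctError as exc:
            warnings.warn(f"k = {k} skipped: {exc}", RuntimeWarning,
                          stacklevel=2)
            continue
        rows.append({"coupling": float(k), "synchrony": s,
                     "abs_error": abs(s - target_synchrony)})
    if not rows:
        raise InvalidInputError("every k in the grid failed to simulate")
    table = pd.DataFrame(rows)
    best = table.sort_values(["abs_error", "coupling"],
                             kind="mergesort").iloc[0]
    return float(best["coupling"]), table


@dataclass
class SurrogateComparison:
    """Fluctuation ratios on the original vs surrogate connectomes."""

    original_ratio_meanP: float
    original_ratio_Q: float
    surrogate_ratio_meanP: np.ndarray
    surrogate_ratio_Q: np.ndarray
    matched_couplings: np.ndarray


def surrogate_fluctuation_comparison(sc: StructuralConnectome, coupling: float,
                                     mean_delay_ms: float,
                                     reference: ReferenceSummaries,
                                     settings: SimulationSettings,
                                     n_surrogates: int = 3,
                                     n_samples: int = 2,
                                     k_grid=None,
                                     seed: int = 0) -> SurrogateComparison:
    """Directional surrogate control on fluctuation magnitudes.

    For each rewired surrogate, k is re-fit so global synchrony matches
    the original's, then fluctuation ratios of mean P_t and Q_t are
    computed with the same reference SDs as for the original.
    """
    if k_grid is None:
        k_grid = np.arange(2.5, 70.0 + 1e-9, 2.5)
    rng = np.random.default_rng(seed)

    def ratios(connectome, k, seeds):
        rp, rq = [], []
        for s in seeds:
            res = run_sample(connectome, k, mean_delay_ms, int(s), settings,
                             with_cartography=True)
            rp.append(fluctuation_ratio(res.profile.mean_participation,
                                        reference.sd_mean_participation))
            rq.append(fluctuation_ratio(res.profile.modularity,
                                        reference.sd_modularity))
        return float(np.mean(rp)), float(np.mean(rq))

    target = reference.synchrony
    if not np.isfinite(target):
        target = mean_synchrony(sc, coupling, mean_delay_ms, settings,
                                seed=int(rng.integers(SEED_CAP)))

    orig_p, orig_q = ratios(sc, coupling,
                            rng.integers(0, SEED_CAP, size=n_samples))
    sur_p, sur_q, ks = [], [], []
    for i in range(n_surrogates):
        surrogate = rewire_surrogate(sc, seed=int(rng.integers(SEED_CAP)))
        k_fit, _ = surrogate_synchrony_match(
            surrogate, target, mean_delay_ms, k_grid, settings,
            seed=int(rng.integers(SEED_CAP)))
        p, q = ratios(surrogate, k_fit,
                      rng.integers(0, SEED_CAP, size=n_samples))
        sur_p.append(p)
        sur_q.append(q)
        ks.append(k_fit)
    return SurrogateComparison(original_ratio_meanP=orig_p,
                               original_ratio_Q=orig_q,
                               surrogate_ratio_meanP=np.array(sur_p),
                               surrogate_ratio_Q=np.array(sur_q),
                               matched_couplings=np.array(ks))
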