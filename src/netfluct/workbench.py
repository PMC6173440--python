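"""Experiment configuration, orchestration and file manifests.

An experiment is a key-value document (YAML on disk) with one section
per stage.  Unknown keys are rejected; every run writes a resolved
copy of the configuration with all defaults materialized, and a
manifest listing every produced file with its content hash and the
seeds used.  All randomness flows from the global seed through a
documented per-stage derivation.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import connectome as conn
from . import search as searchmod
from .errors import InvalidInputError
from .fc import WindowSpec, fcd_distribution, long_timescale_fc, time_resolved_fc
from .hemodynamics import BoldDataset
from .metrics import cartography
from .pipeline import SimulationSettings, simulate_bold_sample
from .states import (estimate_seg_int_states, joint_histogram,
                     modularity_period_labels, state_centroids,
                     transition_stats)
from .synthetic import (SyntheticBoldSpec, SyntheticConnectomeSpec,
                        generate_connectome, generate_state_bold)

log = logging.getLogger("netfluct")

STAGES = ("synth", "simulate", "analyze", "search", "surrogate")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "netfluct-out",
    "stages": ["synth", "simulate", "analyze"],
    "connectome": {
        "n_nodes": 40,
        "n_modules": 4,
        "intra_density": 0.6,
        "inter_density": 0.1,
        "weight_lognormal_mu": 0.0,
        "weight_lognormal_sigma": 0.6,
    },
    "reference_bold": {
        "n_timepoints": 400,
        "tr_seconds": 0.72,
        "n_states": 2,
        "observation_noise_sd": 0.2,
    },
    "simulation": {
        "coupling": 20.0,
        "mean_delay_ms": 8.0,
        "dt_ms": 1.0,
        "noise_sd_rad_s": 0.0,
        "run_length_timepoints": 160,
        "tr_seconds": 0.72,
        "transient_discard_s": 20.0,
    },
    "analysis": {
        "window": {
            "rect_width_trs": 66,
            "gauss_sigma_trs": 9.0,
            "step_trs": 3,
            "kernel_halfwidth_trs": 8,
        },
        "louvain_restarts": 10,
        "kmeans_restarts": 100,
    },
    "search": {
        "coupling_values": [10.0, 20.0, 40.0, 60.0],
        "mean_delay_values_ms": [2.0, 8.0, 14.0],
        "n_samples_stage1": 2,
        "n_samples_stage2": 2,
        "reference_coupling": 20.0,
        "reference_mean_delay_ms": 8.0,
        "reference_n_samples": 2,
    },
    "surrogate": {
        "n_surrogates": 2,
        "n_samples": 2,
        "k_grid": [5.0, 10.0, 20.0, 40.0, 60.0],
    },
}


@dataclass
class ExperimentConfig:
    """Validated experiment configuration with defaults materialized."""

    data: dict

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "ExperimentConfig":
        merged = copy.deepcopy(DEFAULT_CONFIG)
        if overrides:
            _merge_checked(merged, overrides, path="")
        cfg = cls(data=merged)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        return cls.from_dict(doc)

    def validate(self) -> None:
        stages = self.data["stages"]
        for s in stages:
            if s not in STAGES:
                raise InvalidInputError(f"unknown stage {s!r}")
        # dependency order: downstream stages need their producers
        need = {"simulate": "synth", "analyze": "simulate",
                "search": "synth", "surrogate": "synth"}
        for s, dep in need.items():
            if s in stages and dep not in stages:
                raise InvalidInputError(
                    f"stage {s!r} requires stage {dep!r} in the same run")
        if not isinstance(self.data["seed"], int):
            raise InvalidInputError("seed must be an integer")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        ss = np.random.SeedSequence([self.data["seed"], STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2 ** 31 - 1))

    def simulation_settings(self) -> SimulationSettings:
        sim = self.data["simulation"]
        ana = self.data["analysis"]
        return SimulationSettings(
            run_length_timepoints=sim["run_length_timepoints"],
            tr_seconds=sim["tr_seconds"],
            dt_ms=sim["dt_ms"],
            noise_sd_rad_s=sim["noise_sd_rad_s"],
            transient_discard_s=sim["transient_discard_s"],
            window=WindowSpec(**ana["window"]),
            louvain_restarts=ana["louvain_restarts"])


def _merge_checked(base: dict, overrides: dict, path: str) -> None:
    for key, value in overrides.items():
        if key not in base:
            raise InvalidInputError(f"unknown configuration key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise InvalidInputError(f"{path + key!r} must be a mapping")
            _merge_checked(base[key], value, path + key + ".")
        else:
            base[key] = value


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: ExperimentConfig, output_dir=None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written as ``manifest.json``): per stage
    the list of produced files with content hashes, plus the seed that
    stage used.  Any stage failure aborts with the stage name in the
    exception message; files already produced stay on disk.
    """
    out = Path(output_dir or config.data["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    resolved = out / "resolved-config.yaml"
    resolved.write_text(yaml.safe_dump(config.data, sort_keys=False))

    manifest: dict = {"stages": {}, "seed": config.data["seed"]}
    state: dict = {}
    ordered = [s for s in STAGES if s in config.data["stages"]]
    for stage in ordered:
        seed = config.stage_seed(stage)
        log.info("stage=%s seed=%d", stage, seed)
        try:
            files = _STAGE_FUNCS[stage](config, out, seed, state)
        except Exception as exc:
            manifest["error"] = f"stage {stage!r} failed: {exc}"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        manifest["stages"][stage] = {
            "seed": seed,
            "files": {str(f.relative_to(out)): _sha256(f) for f in files},
        }
    manifest["stages"]["config"] = {"files": {
        "resolved-config.yaml": _sha256(resolved)}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_synth(cfg: ExperimentConfig, out: Path, seed: int, state: dict):
    c = cfg.data["connectome"]
    spec = SyntheticConnectomeSpec(
        n_nodes=c["n_nodes"], n_modules=c["n_modules"],
        intra_density=c["intra_density"], inter_density=c["inter_density"],
        weight_lognormal_params=(c["weight_lognormal_mu"],
                                 c["weight_lognormal_sigma"]),
        seed=seed)
    sc = generate_connectome(spec)
    state["connectome"] = sc
    conn.save_connectome_hdf5(out / "connectome.h5", sc)
    conn.write_matrix_text(out / "weights.tsv", sc.weights, sc.node_ids)
    conn.write_matrix_text(out / "lengths.tsv", sc.lengths, sc.node_ids)

    r = cfg.data["reference_bold"]
    bspec = SyntheticBoldSpec(n_nodes=c["n_nodes"],
                              n_timepoints=r["n_timepoints"],
                              tr_seconds=r["tr_seconds"],
                              observation_noise_sd=r["observation_noise_sd"],
                              seed=seed + 1)
    bold, states_true = generate_state_bold(bspec)
    state["reference_bold"] = bold
    with h5py.File(out / "reference_bold.h5", "w") as f:
        f.create_dataset("bold", data=bold.signal)
        f.create_dataset("true_states", data=states_true)
        f.attrs["tr_seconds"] = bold.tr_seconds
    return [out / "connectome.h5", out / "weights.tsv", out / "lengths.tsv",
            out / "reference_bold.h5"]


def _stage_simulate(cfg: ExperimentConfig, out: Path, seed: int, state: dict):
    sc = state["connectome"]
    sim = cfg.data["simulation"]
    settings = cfg.simulation_settings()
    bold, order = simulate_bold_sample(sc, sim["coupling"],
                                       sim["mean_delay_ms"], seed, settings)
    state["bold"] = bold
    with h5py.File(out / "simulation.h5", "w") as f:
        f.create_dataset("bold", data=bold.signal)
        f.create_dataset("order_magnitude", data=order.magnitude)
        f.attrs["tr_seconds"] = bold.tr_seconds
        f.attrs["synchrony"] = order.synchrony
        f.attrs["metastability"] = order.metastability
    np.savetxt(out / "bold.tsv", bold.signal, delimiter="\t")
    return [out / "simulation.h5", out / "bold.tsv"]


def _stage_analyze(cfg: ExperimentConfig, out: Path, seed: int, state: dict):
    bold: BoldDataset = state["bold"]
    settings = cfg.simulation_settings()
    ana = cfg.data["analysis"]
    fc_long = long_timescale_fc(bold)
    trfc = time_resolved_fc(bold, settings.window)
    fcd = fcd_distribution(trfc)
    profile = cartography(trfc, n_restarts=ana["louvain_restarts"], seed=seed)
    hist = joint_histogram(profile)
    step_s = settings.window.step_trs * bold.tr_seconds
    seq = estimate_seg_int_states(hist, profile.participation,
                                  n_restarts=ana["kmeans_restarts"],
                                  seed=seed, step_seconds=step_s)
    terciles = modularity_period_labels(profile.modularity, step_seconds=step_s)
    summary = transition_stats(seq)
    summary.centroids = state_centroids(trfc, seq)

    with h5py.File(out / "analysis.h5", "w") as f:
        f.create_dataset("fc_long", data=fc_long.values)
        f.create_dataset("fc_windows", data=trfc.matrices)
        f.create_dataset("fcd", data=fcd.correlations)
        f.create_dataset("modularity", data=profile.modularity)
        f.create_dataset("mean_participation", data=profile.mean_participation)
        for name, cent in summary.centroids.items():
            f.create_dataset(f"centroid_{name}", data=cent.values)
    with open(out / "states.tsv", "w") as f:
        f.write("window\tseg_int\tmodularity_period\tQ\tmeanP\n")
        for i in range(seq.n_windows):
            f.write(f"{i}\t{seq.labels[i]}\t{terciles.labels[i]}\t"
                    f"{profile.modularity[i]:.6f}\t"
                    f"{profile.mean_participation[i]:.6f}\n")
    with open(out / "state_summary.tsv", "w") as f:
        f.write("state\toccupancy\tdwell_windows\tdwell_seconds\n")
        for s in summary.states:
            f.write(f"{s}\t{summary.occupancy[s]:.4f}\t"
                    f"{summary.mean_dwell_windows[s]:.3f}\t"
                    f"{summary.mean_dwell_seconds[s]:.3f}\n")
    return [out / "analysis.h5", out / "states.tsv", out / "state_summary.tsv"]


def _stage_search(cfg: ExperimentConfig, out: Path, seed: int, state: dict):
    sc = state["connectome"]
    s = cfg.data["search"]
    settings = cfg.simulation_settings()
    grid = searchmod.ParameterGrid(
        coupling_values=np.asarray(s["coupling_values"]),
        mean_delay_values_ms=np.asarray(s["mean_delay_values_ms"]))
    reference = searchmod.reference_from_model(
        sc, s["reference_coupling"], s["reference_mean_delay_ms"], settings,
        n_samples=s["reference_n_samples"], seed=seed)
    stage1, stage2, selection = searchmod.run_grid(
        sc, grid, reference, settings,
        n_samples_stage1=s["n_samples_stage1"],
        n_samples_stage2=s["n_samples_stage2"], seed=seed + 1)
    stage1.to_csv(out / "stage1.tsv", sep="\t", index=False)
    files = [out / "stage1.tsv"]
    if len(stage2):
        stage2.to_csv(out / "stage2.tsv", sep="\t", index=False)
        files.append(out / "stage2.tsv")
    (out / "selection.json").write_text(json.dumps(selection, indent=2,
                                                   default=str))
    files.append(out / "selection.json")
    state["selection"] = selection
    return files


def _stage_surrogate(cfg: ExperimentConfig, out: Path, seed: int, state: dict):
    sc = state["connectome"]
    s = cfg.data["surrogate"]
    sim = cfg.data["simulation"]
    settings = cfg.simulation_settings()
    reference = searchmod.reference_from_model(
        sc, sim["coupling"], sim["mean_delay_ms"], settings,
        n_samples=s["n_samples"], seed=seed)
    comp = searchmod.surrogate_fluctuation_comparison(
        sc, sim["coupling"], sim["mean_delay_ms"], reference, settings,
        n_surrogates=s["n_surrogates"], n_samples=s["n_samples"],
        k_grid=s["k_grid"], seed=seed + 1)
    with open(out / "surrogate_comparison.tsv", "w") as f:
        f.write("which\tratio_meanP\tratio_Q\tmatched_k\n")
        f.write(f"original\t{comp.original_ratio_meanP:.4f}\t"
                f"{comp.original_ratio_Q:.4f}\t{sim['coupling']}\n")
        for i, (p, q, k) in enumerate(zip(comp.surrogate_ratio_meanP,
                                          comp.surrogate_ratio_Q,
                                          comp.matched_couplings)):
            f.write(f"surrogate{i}\t{p:.4f}\t{q:.4f}\t{k}\n")
    return [out / "surrogate_comparison.tsv"]


_STAGE_FUNCS = {"synth": _stage_synth, "simulate": _stage_simulate,
                "analyze": _stage_analyze, "search": _stage_search,
                "surrogate": _stage_surrogate}
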