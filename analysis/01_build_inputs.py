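#!/usr/bin/env python
"""Build the study inputs: a modular synthetic connectome and reference BOLD.

The connectome stands in for a 114-parcel group-level structural
network (two mirrored hemisphere blocks, seven systems, lognormal
fiber-density weights, Euclidean fiber lengths); the reference BOLD
carries a planted two-state hidden-Markov structure so that the
state-estimation stages can be validated against known ground truth.
Writes delimited matrices plus an HDF5 container under results/inputs/.
"""

import math
from pathlib import Path

import h5py
import numpy as np

from netfluct.connectome import save_connectome_hdf5, write_matrix_text
from netfluct.synthetic import (SyntheticBoldSpec, SyntheticConnectomeSpec,
                                generate_connectome, generate_state_bold)

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 7


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticConnectomeSpec(n_nodes=114, n_modules=7, seed=SEED)
    sc = generate_connectome(spec)
    save_connectome_hdf5(OUT / "connectome.h5", sc)
    write_matrix_text(OUT / "weights.tsv", sc.weights, sc.node_ids)
    write_matrix_text(OUT / "lengths.tsv", sc.lengths, sc.node_ids)

    edges = int((np.triu(sc.weights, 1) > 0).sum())
    print(f"connectome: {sc.n_nodes} nodes, {edges} edges, "
          f"density {2 * edges / (sc.n_nodes * (sc.n_nodes - 1)):.3f}, "
          f"mean fiber length {sc.mean_fiber_length:.1f} mm")
    nz = sc.weights[sc.weights > 0]
    print(f"normalized weights: mean non-zero {nz.mean():.6f} (target 1)")

    bspec = SyntheticBoldSpec(n_nodes=114, n_timepoints=1200, seed=SEED + 1)
    bold, states = generate_state_bold(bspec)
    with h5py.File(OUT / "reference_bold.h5", "w") as f:
        f.create_dataset("bold", data=bold.signal)
        f.create_dataset("true_states", data=states)
        f.attrs["tr_seconds"] = bold.tr_seconds
    occ = np.bincount(states, minlength=2) / len(states)
    print(f"reference BOLD: {bold.n_nodes} x {bold.n_timepoints} at "
          f"TR {bold.tr_seconds} s; planted occupancy "
          f"segregated {occ[0]:.2f} / integrated {occ[1]:.2f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
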