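# Methods

`netfluct` implements an end-to-end pipeline for asking how much of the
fluctuation in the *global network topology* of functional connectivity
(FC) — swings between segregated and integrated organization, and
between high and low modularity — can be produced by a stationary
dynamical model of resting-state cortical activity wired by structural
connectivity (SC).

## Model

### Delay-coupled phase oscillators

Each cortical region n carries a phase θ_n(t) obeying

    dθ_i/dt = 2πf + k Σ_j C_ij sin(θ_j(t − τ_ij) − θ_i(t)),

with a common natural frequency f = 60 Hz (gamma band), global
coupling constant k, SC weights C normalized so the mean non-zero edge
weight is one, and conduction delays τ_ij = L_ij / v proportional to
fiber length.  The velocity v is parameterized through the mean delay
τ̄ = L̄ / v, where L̄ is the mean fiber length over edges.  The system
is integrated with the deterministic Heun method, or the stochastic
Heun method when white phase noise (σ = 1.25 rad/s) is enabled; the
step size defaults to 0.2 ms (tests and desk-scale runs use 1 ms).
Initial phases are uniform on [0, 2π); the delay history is filled by
running the uncoupled system (a linear phase ramp) for the maximum
delay span; the first 20 s of coupled dynamics are discarded.  Global
dynamics are summarized by the order parameter R(t): its temporal mean
is the synchrony, its temporal SD the metastability.

Numerical choices: per-edge delays are rounded to integration steps
with a floor of one step; the integrator stores sin/cos ring buffers so
the delayed coupling term needs no trigonometry in the inner loop; the
stochastic Heun increment σ√dt·ξ is applied to predictor and corrector
alike.  Divergence (non-finite phase) raises an error naming the step.

### Hemodynamics

Regional activity is r_n(t) = sin θ_n(t), decimated to 1 kHz, and
passed through the Balloon/Windkessel model: per node,

    ds/dt = z − κs − γ(f − 1),   df/dt = s,
    τ0 dv/dt = f − v^{1/α},      τ0 dq/dt = f·E(f)/E0 − v^{1/α} q/v,

with E(f) = 1 − (1 − E0)^{1/f} and BOLD readout
y = V0 (k1(1 − q) + k2(1 − q/v) + k3(1 − v)).  Defaults are the
canonical single-compartment values κ = 0.65 s⁻¹, γ = 0.41 s⁻¹,
τ0 = 0.98 s, α = 0.32, E0 = 0.34, V0 = 0.02, (k1, k2, k3) =
(7E0, 2, 2E0 − 0.2); all are configurable because variants of this
parameterization circulate.  The ODEs are integrated with Heun at the
1 kHz input rate from the resting fixed point (s, f, v, q) =
(0, 1, 1, 1), which maps to y = 0 under zero input.

Modeled BOLD is then preprocessed like reference BOLD: zero-phase
second-order Butterworth band-pass with cutoffs 1/(66·TR) ≈ 0.021 Hz
and 0.1 Hz (the low cutoff equals the reciprocal of the sliding-window
width, excluding fluctuations slower than one window), decimation to
TR = 0.72 s, truncation to the run length, and global-signal
regression (per-node residual after regressing the across-node mean
with intercept).

## Functional connectivity and topology metrics

FC is the Pearson correlation of regional BOLD, Fisher z-transformed
(|r| is clipped at 1 − 1e−15 with a warning on degenerate inputs).
Time-resolved FC uses a tapered sliding window: a rectangle of 66 TRs
(47.52 s) convolved with a Gaussian of σ = 9 TRs truncated at ±8 TRs
(support 82 TRs), stepped by 3 TRs (2.16 s), with taper-weighted means
and covariances inside each window.  On a 1200-volume run trimmed of
its first 10 s (14 volumes) this produces 369 windows; the ±8-TR
truncation is the reconciliation that reproduces that count and is a
package choice where the kernel extent was otherwise unspecified.

Functional connectivity dynamics (FCD) is the distribution of Pearson
correlations between the Fisher-z upper-triangle vectors of window
pairs; pairs whose center separation is strictly less than the 66-TR
rectangle width are discarded.  Distributions are compared with the
two-sample Kolmogorov–Smirnov distance.

Community structure per window is scored by the signed modularity

    Q = (1/v⁺) Σ (w⁺_ij − e⁺_ij) δ(M_i, M_j)
        − (1/(v⁺ + v⁻)) Σ (w⁻_ij − e⁻_ij) δ(M_i, M_j),

maximized by a hand-implemented Louvain procedure on the signed
modularity matrix (random node sweep order, aggregation until no gain
above 1e−10, resolution γ = 1) with the best quality over restarts
kept (100 restarts at full scale, fewer in the desk-scale presets).
The per-window cartography is the within-module degree z-score (signed
weighted degree by default, switchable to positive-only — the source
convention is ambiguous) and the participation coefficient over
positive weights, P_i = 1 − Σ_m (κ⁺_{i,m}/κ⁺_i)², with degenerate
cases (singleton modules, zero spread, zero positive strength) mapped
to 0.

## Network states

Per window, node (z, P) values are binned into a 100 × 100 joint
histogram over −5 < z < 5, 0 < P < 1 (out-of-range values are clipped
into edge bins so each window's counts sum to N).  Windows are
clustered with k-means (k = 2, Euclidean distance on raw count
vectors, best inertia over 500 random restarts at full scale); the
cluster with the greater mean participation is labeled *integrated*.
High/middle/low modularity periods are per-run terciles of Q_t with
strict inequalities, so boundary ties fall into *middle*; the labeling
is invariant to monotone transforms of Q_t.

State sequences are summarized by the empirical transition matrix over
consecutive windows, mean dwell time (mean run length, reported in
windows and in seconds at 2.16 s per step — the source's unit is not
stated, so both are provided), occupancy, per-state centroids
(elementwise median of windowed FC during the state), global absolute
FC (mean |z| over edges and windows), centroid similarity to SC
(Pearson over structurally connected edges), and between-state
contrasts: centroid weights averaged within each intrinsic-system pair
per sample, paired t-scores of the first-minus-second state difference
across samples, Benjamini–Hochberg FDR at 0.05 across the unique
system-pair cells.

## Parameter search

Stage 1 scans the (k, τ̄) grid — 2.5 to 70 by 2.5 and 2 to 17 ms by
1 ms at full scale, 448 sets — with 10 samples per set, and keeps sets
whose sample-averaged long-timescale FC correlates > 0.33 with the
reference over structurally connected pairs while the FCD KS distance
stays < 0.33 (both strict).  Stage 2 re-simulates survivors (100
samples per set at full scale) and computes the ratio of each sample's
SD over time of mean P_t and of Q_t to the reference SDs.  The winner
minimizes the mean of |1 − ratio| over the two metrics — a symmetric
deviation score chosen here because the source states the goal
("highest similarity") without a formula; ties break to the smaller k,
then the smaller τ̄.

The surrogate control rewires the connectome by degree-preserving
double-edge swaps and re-assigns the original (weight, length) pairs
to the new edges by iterative greedy rank-matching against residual
endpoint strengths, keeping candidates only when the original and
surrogate strength sequences correlate above 0.95.  Carrying each
weight's fiber length with it keeps the delay-length distribution
fixed.  On each surrogate the coupling k is re-fit over the k grid so
the mean order parameter matches the original's (mean delay held
fixed; ties to the smallest k), after which fluctuation ratios are
compared.

## Synthetic study inputs

The connectome generator emulates a 114-parcel group connectome: two
mirrored hemisphere blocks, modules clustered around mirrored spatial
centers inside a brain-sized coordinate box, Bernoulli edges
(intra-module density 0.6, inter 0.1 by default), lognormal weights,
Euclidean fiber lengths, and normalized weights.  It does not emulate
consensus thresholding, distance-dependent connection probability
beyond what the geometry induces, or inter-subject variability.

The reference-BOLD generator plants a two-state hidden Markov process:
per TR the state follows a Markov chain (stay probability 0.995,
i.e. mean dwell 200 TRs = 144 s, comfortably longer than the window
support), and the signal is drawn from the state's multivariate
Gaussian plus white observation noise (SD 0.2).  The two covariances
share one modular skeleton; the segregated state has within/between
module correlation 0.70/0.028 and the integrated state 0.45/0.28, so
the integrated state has higher participation by construction.  The
defaults use 114 nodes; the skeleton is held fixed across states so
that community detection finds a stable partition and the planted
contrast appears in P rather than in the partition count.  Real
resting-state runs differ in ways the generator ignores — scanner
drift, motion, physiological noise, graded rather than discrete state
changes — so passing recovery tests demonstrates correctness of the
estimation machinery, not performance on empirical data.

## Desk-scale presets and what they show

Full-scale settings (114 nodes, 1186 TRs per run, dt = 0.2 ms, 100
Louvain restarts, 500 k-means restarts, 448-set grid with 10/100
samples) are faithful but far beyond a desk run.  The test and
analysis presets therefore use a 40-node, 4-module connectome,
480-TR runs at dt = 1 ms, 10 Louvain and 50 k-means restarts, a 4 × 3
grid with 2 samples per set, and the noise variant (σ = 1.25 rad/s) —
noise makes the desk-scale dynamics ergodic, so FC summaries reproduce
across seeds at run lengths where the deterministic system still
remembers its initial condition.  The working point (k, τ̄) = (60, 2 ms)
sits in this connectome's partially synchronized metastable regime
(synchrony ≈ 0.87), which is where windowed FC is reproducible enough
for the two-stage search to be discriminative.  Self-recovery of a
generating parameter set on this grid validates the search logic, not
the biological parameter values.

## Known limitations

- At desk scale the SD over windows of mean P_t and Q_t is dominated
  by windowed-correlation estimation noise (the same 66-TR windows
  estimate many fewer effective samples at 40–60 nodes than at full
  scale), which compresses differences between structured and rewired
  connectomes; see the surrogate-control discussion in the analysis
  scripts.
- The Balloon/Windkessel parameter set is one canonical choice; the
  source family has variants, hence every parameter is exposed.
- Identical natural frequencies mean the noiseless system can freeze
  into phase-locked states at low coupling; the noise variant avoids
  this and is the default in desk-scale work.
- The Louvain implementation is dense-matrix based and intended for
  networks up to a few hundred nodes, matching the parcellation scale.
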