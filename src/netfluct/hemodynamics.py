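"""Balloon/Windkessel hemodynamic forward model and BOLD preprocessing.

Oscillator phases are mapped to regional neural activity r_n(t) =
sin(theta_n(t)) sampled at 1 kHz, converted to BOLD through the
Balloon/Windkessel ODE system (vasodilatory signal s, inflow f, venous
volume v, deoxyhemoglobin q), then put through the same preprocessing
as reference BOLD: zero-phase band-pass (default 1/(66 TR) to 0.1 Hz),
decimation to the repetition time, truncation to the run length, and
global-signal regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal as spsignal

from .errors import InvalidInputError, NumericalError
from .oscillator import PhaseTrajectory


@dataclass
class NeuralActivity:
    """Regional activity in [-1, 1] at 1 kHz."""

    activity: np.ndarray        # (N, T)
    sample_rate_hz: float = 1000.0


@dataclass
class BoldDataset:
    """Region x time BOLD signal at a stated TR (or raw 1 kHz output)."""

    signal: np.ndarray          # (N, T)
    tr_seconds: float
    run_label: str = ""

    @property
    def n_nodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]


@dataclass
class BalloonParams:
    """Balloon/Windkessel parameters (canonical single-compartment values).

    signal_decay kappa and feedback gamma in 1/s, transit time tau0 in
    s, vessel stiffness alpha (0 < alpha < 1), resting oxygen
    extraction E0 and venous volume fraction V0, BOLD readout
    coefficients (k1, k2, k3).  All overridable via configuration.
    """

    signal_decay: float = 0.65
    feedback: float = 0.41
    transit_time: float = 0.98
    stiffness: float = 0.32
    resting_extraction: float = 0.34
    resting_volume: float = 0.02
    bold_coefficients: tuple[float, float, float] | None = None
    integration_dt_s: float = 1e-3

    def __post_init__(self):
        if self.bold_coefficients is None:
            e0 = self.resting_extraction
            self.bold_coefficients = (7.0 * e0, 2.0, 2.0 * e0 - 0.2)
        self.validate()

    def validate(self) -> None:
        for name in ("signal_decay", "feedback", "transit_time",
                     "integration_dt_s"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not 0 < self.stiffness < 1:
            raise InvalidInputError("stiffness alpha must be in (0, 1)")
        if not 0 < self.resting_extraction < 1:
            raise InvalidInputError("resting extraction E0 must be in (0, 1)")
        if self.resting_volume <= 0:
            raise InvalidInputError("resting volume V0 must be positive")


def phases_to_activity(traj: PhaseTrajectory) -> NeuralActivity:
    """r_n(t) = sin(theta_n(t)), decimated to 1 kHz.

    The trajectory's sample rate must be an integer multiple of 1 kHz;
    decimation keeps every ``rate/1000``-th sample starting at index 0.
    """
    factor = traj.sample_rate_hz / 1000.0
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise InvalidInputError(
            f"sample rate {traj.sample_rate_hz} Hz is not an integer "
            "multiple of 1 kHz")
    step = int(round(factor))
    return NeuralActivity(activity=np.sin(traj.phases[:, ::step]),
                          sample_rate_hz=1000.0)


@njit(cache=True)
def _balloon_kernel(z, dt, kappa, gamma, tau0, alpha, e0, v0, k1, k2, k3, y):
    """Heun integration of the Balloon/Windkessel ODEs, all nodes at once.

    Returns -1 on success, or the step index at which the state left
    its physical bounds (v <= 0 or q <= 0).
    """
    n, t_len = z.shape
    inv_alpha = 1.0 / alpha
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    ds = np.empty(n)
    df = np.empty(n)
    dv = np.empty(n)
    dq = np.empty(n)
    for t in range(t_len):
        for i in range(n):
            ds[i] = z[i, t] - kappa * s[i] - gamma * (f[i] - 1.0)
            df[i] = s[i]
            vout = v[i] ** inv_alpha
            dv[i] = (f[i] - vout) / tau0
            dq[i] = (f[i] * (1.0 - (1.0 - e0) ** (1.0 / f[i])) / e0
                     - vout * q[i] / v[i]) / tau0
        for i in range(n):
            sp = s[i] + dt * ds[i]
            fp = f[i] + dt * df[i]
            vp = v[i] + dt * dv[i]
            qp = q[i] + dt * dq[i]
            if vp <= 0.0 or qp <= 0.0 or fp <= 0.0:
                return t
            dsp = z[i, t] - kappa * sp - gamma * (fp - 1.0)
            dfp = sp
            voutp = vp ** inv_alpha
            dvp = (fp - voutp) / tau0
            dqp = (fp * (1.0 - (1.0 - e0) ** (1.0 / fp)) / e0
                   - voutp * qp / vp) / tau0
            s[i] = s[i] + 0.5 * dt * (ds[i] + dsp)
            f[i] = f[i] + 0.5 * dt * (df[i] + dfp)
            v[i] = v[i] + 0.5 * dt * (dv[i] + dvp)
            q[i] = q[i] + 0.5 * dt * (dq[i] + dqp)
            if v[i] <= 0.0 or q[i] <= 0.0 or f[i] <= 0.0:
                return t
            y[i, t] = v0 * (k1 * (1.0 - q[i]) + k2 * (1.0 - q[i] / v[i])
                            + k3 * (1.0 - v[i]))
    return -1


def balloon_windkessel(activity: NeuralActivity,
                       params: BalloonParams | None = None) -> BoldDataset:
    """Convert neural activity to raw BOLD at the activity sample rate.

    Per-node hemodynamic states start from rest (s, f, v, q) =
    (0, 1, 1, 1), which is a fixed point under zero input, and the
    BOLD readout is y = V0*(k1*(1-q) + k2*(1-q/v) + k3*(1-v)).
    """
    if params is None:
        params = BalloonParams()
    z = np.ascontiguousarray(activity.activity, dtype=np.float64)
    if not np.isfinite(z).all():
        raise InvalidInputError("activity contains non-finite values")
    # integrate at the activity's own sampling interval (1 ms at 1 kHz);
    # params.integration_dt_s documents the intended rate
    dt = 1.0 / activity.sample_rate_hz
    k1, k2, k3 = params.bold_coefficients
    y = np.empty_like(z)
    bad = _balloon_kernel(z, dt, params.signal_decay, params.feedback,
                          params.transit_time, params.stiffness,
                          params.resting_extraction, params.resting_volume,
                          k1, k2, k3, y)
    if bad >= 0:
        raise NumericalError(
            f"hemodynamic state left physical bounds at step {bad}")
    return BoldDataset(signal=y, tr_seconds=dt, run_label="raw-bold")


def preprocess_bold(raw: BoldDataset,
                    band: tuple[float, float] | None = None,
                    target_tr_s: float = 0.72,
                    run_length_timepoints: int | None = None) -> BoldDataset:
    """Band-pass, decimate to TR, truncate, and regress out the global signal.

    ``band`` defaults to (1 / (66 * target_tr), 0.1) Hz so the low
    cutoff equals the reciprocal of the sliding-window width.  The
    filter is a zero-phase second-order Butterworth applied
    forward-backward; decimation keeps every round(TR / dt) samples
    (the band-pass has already removed content above 0.1 Hz); the
    across-node mean signal (plus intercept) is regressed out of every
    node by least squares.
    """
    if band is None:
        band = (1.0 / (66.0 * target_tr_s), 0.1)
    low, high = band
    fs = 1.0 / raw.tr_seconds
    if fs < 2.0 * high:
        raise InvalidInputError(
            f"input sample rate {fs:.3f} Hz cannot resolve the {high} Hz cutoff")
    sos = spsignal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = spsignal.sosfiltfilt(sos, raw.signal, axis=1)

    step = int(round(target_tr_s * fs))
    if step < 1:
        raise InvalidInputError("target TR below the input sampling interval")
    decimated = filtered[:, ::step]

    if run_length_timepoints is not None:
        if decimated.shape[1] < run_length_timepoints:
            raise InvalidInputError(
                f"requested {run_length_timepoints} time points but only "
                f"{decimated.shape[1]} available")
        decimated = decimated[:, :run_length_timepoints]

    return BoldDataset(signal=regress_global_signal(decimated),
                       tr_seconds=target_tr_s,
                       run_label=raw.run_label or "preprocessed")


def regress_global_signal(signal: np.ndarray) -> np.ndarray:
    """Residual of each node after regressing out the across-node mean.

    The regressor matrix is [global mean, intercept]; residuals are
    exactly orthogonal to the global mean of the input.
    """
    g = signal.mean(axis=0)
    x = np.column_stack([g, np.ones_like(g)])
    beta, *_ = np.linalg.lstsq(x, signal.T, rcond=None)
    return signal - (x @ beta).T


def trim_initial(bold: BoldDataset, seconds: float = 10.0) -> BoldDataset:
    """Drop the first ceil(seconds / TR) volumes of a run."""
    drop = int(np.ceil(seconds / bold.tr_seconds))
    if drop >= bold.n_timepoints:
        raise InvalidInputError("trim would remove the whole run")
    return BoldDataset(signal=bold.signal[:, drop:], tr_seconds=bold.tr_seconds,
                       run_label=bold.run_label)
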