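"""Simulated BOLD runs carrying a known k-fold directional modulation.

The generative model is the inverse of the measurement model: each voxel v
has a preferred orientation theta_v drawn around the group orientation in
k-fold angle space; during a translation with direction phi the neural
signal is amplitude_v * cos(k*(phi - theta_v)) as a boxcar over the event,
convolved with the canonical double-gamma HRF, on top of a baseline, a
linear drift and AR(1) Gaussian noise with stationary standard deviation
``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .config import SimulationConfig
from .design import convolved_regressor, double_gamma_hrf
from .trajectory import Trajectory


@dataclass
class BoldRun:
    """Voxels x scans signal matrix with acquisition and ground-truth metadata."""

    data: np.ndarray
    tr: float
    ground_truth: Optional[dict] = None
    mask_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldRun.data must be voxels x scans")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun.data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]


def draw_orientations(
    sim: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Voxel orientations around the group orientation, von Mises in k-fold space."""
    kappa = sim.orientation_concentration
    if kappa is None or np.isinf(kappa):
        return np.full(sim.n_voxels, sim.group_orientation % sim.period)
    mu = np.deg2rad(sim.fold * sim.group_orientation)
    psi = rng.vonmises(mu, kappa, size=sim.n_voxels)
    return (np.rad2deg(psi) / sim.fold) % sim.period


def _quadrature_signal(events, k, theta_deg, amplitudes, n_scans, tr, hrf):
    """Sum over events of amplitude * cos(k*(phi - theta)) boxcars, convolved.

    Exploits linearity: the per-voxel series is
    amplitude * (cos(k*theta) * C_cos + sin(k*theta) * C_sin)
    with C_sin/C_cos the convolved quadrature columns.
    """
    trans = events[events["trial_type"] == "translation"]
    if len(trans) == 0:
        return np.zeros((len(theta_deg), n_scans))
    on = trans["onset"].to_numpy(float)
    dur = trans["duration"].to_numpy(float)
    ang = np.deg2rad(k * trans["direction"].to_numpy(float))
    c_sin = convolved_regressor(on, dur, np.sin(ang), n_scans, tr, hrf=hrf)
    c_cos = convolved_regressor(on, dur, np.cos(ang), n_scans, tr, hrf=hrf)
    kt = np.deg2rad(k * np.asarray(theta_deg))
    amp = np.broadcast_to(np.asarray(amplitudes, float), kt.shape)
    return (amp * np.cos(kt))[:, None] * c_cos + (amp * np.sin(kt))[:, None] * c_sin


def ar1_noise(
    n_voxels: int,
    n_scans: int,
    sd: float,
    ar1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((n_voxels, n_scans))
    w = rng.standard_normal((n_voxels, n_scans)) * sd * np.sqrt(1.0 - ar1**2)
    w[:, 0] = rng.standard_normal(n_voxels) * sd  # stationary start
    return lfilter([1.0], [1.0, -ar1], w, axis=1)


def simulate_bold(
    trajectory: Trajectory,
    sim: SimulationConfig,
    seed: int,
    mask_labels: Optional[Sequence] = None,
) -> BoldRun:
    """Simulate one BOLD run over the given trajectory; deterministic given seed.

    If ``sim.orientation_drift`` is nonzero, every voxel's orientation shifts
    by that amount for events starting at or after the run midpoint.
    """
    rng = np.random.default_rng(seed)
    run_length = trajectory.config.run_length
    n_scans = int(np.ceil(run_length / sim.tr))
    events = trajectory.events
    theta = draw_orientations(sim, rng)
    amp = np.broadcast_to(np.asarray(sim.modulation_amplitude, float), theta.shape)
    hrf = double_gamma_hrf()

    if sim.orientation_drift:
        mid = run_length / 2.0
        first = events[events["onset"] < mid]
        second = events[events["onset"] >= mid]
        signal = _quadrature_signal(first, sim.fold, theta, amp, n_scans, sim.tr, hrf)
        signal += _quadrature_signal(
            second, sim.fold, theta + sim.orientation_drift, amp, n_scans, sim.tr, hrf
        )
    else:
        signal = _quadrature_signal(events, sim.fold, theta, amp, n_scans, sim.tr, hrf)

    drift = sim.drift_slope * np.arange(n_scans)
    noise = ar1_noise(sim.n_voxels, n_scans, sim.noise_sd, sim.ar1_coefficient, rng)
    data = sim.baseline + drift[None, :] + signal + noise
    truth = {
        "fold": sim.fold,
        "group_orientation": float(sim.group_orientation % sim.period),
        "theta": theta.tolist(),
        "amplitude": np.asarray(amp, float).tolist(),
    }
    labels = np.asarray(mask_labels) if mask_labels is not None else None
    return BoldRun(data=data, tr=sim.tr, ground_truth=truth, mask_labels=labels)
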