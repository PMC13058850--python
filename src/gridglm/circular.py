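"""Circular arithmetic in a k-fold periodic angle space (period 360/k degrees)."""

from __future__ import annotations

import numpy as np


class UndefinedOrientationError(ValueError):
    """A circular mean (or orientation) has no defined value."""


def period(k: int) -> float:
    return 360.0 / k


def wrap(theta, k: int):
    """Map angles into the fundamental domain [0, 360/k)."""
    return np.asarray(theta) % period(k)


def circ_dist(a, b, k: int):
    """Absolute circular distance in the k-fold space, in [0, 180/k]."""
    p = period(k)
    return np.abs((np.asarray(a) - np.asarray(b) + p / 2.0) % p - p / 2.0)


def weighted_mean_orientation(theta, weights, k: int, tol: float = 1e-12):
    """Amplitude-weighted circular mean orientation and resultant length.

    Angles are mapped to k*theta, averaged as unit vectors scaled by their
    weights, and the resultant angle divided by k.  Raises
    :class:`UndefinedOrientationError` when the resultant vector vanishes
    (perfectly dispersed orientations) or no positive weight remains.
    """
    theta = np.asarray(theta, dtype=float)
    w = np.asarray(weights, dtype=float)
    if theta.size == 0:
        raise UndefinedOrientationError("no valid orientations to average")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise UndefinedOrientationError("total weight is zero")
    ang = np.deg2rad(k * theta)
    c = float(np.sum(w * np.cos(ang)))
    s = float(np.sum(w * np.sin(ang)))
    resultant = np.hypot(c, s) / wsum
    if resultant < tol:
        raise UndefinedOrientationError(
            "resultant length below tolerance: mean orientation undefined"
        )
    phi = np.rad2deg(np.arctan2(s, c)) / k
    return float(phi % period(k)), float(resultant)


def rayleigh_test(angles_rad):
    """Rayleigh test for non-uniformity of circular data.

    Returns (Z, p, R_bar) with Z = n * R_bar**2 and the standard
    small-sample series approximation for p, clipped to (0, 1].
    """
    a = np.asarray(angles_rad, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("Rayleigh test requires at least 2 angles")
    r_bar = float(np.hypot(np.cos(a).sum(), np.sin(a).sum())) / n
    z = n * r_bar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return float(z), p, r_bar
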