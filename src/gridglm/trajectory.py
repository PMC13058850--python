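"""Passive-navigation trajectory generation and spatial-coverage diagnostics.

A trajectory is an alternating sequence of translational movements (at fixed
allocentric direction) and in-place rotations inside a square virtual room,
followed by a trailing rest that pads the schedule to the exact run length.
Translation directions are balanced over fixed-width angular bins (3-4
segments per 10-degree bin under the default configuration), consecutive
directions always differ, and every turn is the shortest arc between
successive headings with a magnitude inside [min_rotation, max_rotation] --
in particular exact reversals are excluded, which is what makes the 170
degree maximum attainable.

Coordinate convention: origin at a room corner, x rightward, y upward,
direction 0 deg = +x, counterclockwise positive.  Positions are continuous
virtual meters; coverage bins are 1 x 1 vm, indexed half-open [i, i+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EnvironmentConfig

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "direction",
    "x_start",
    "y_start",
    "x_end",
    "y_end",
]

_MAX_ATTEMPTS = 500
_MAX_SEARCH_STEPS = 4_000  # cheap randomized restarts beat deep backtracking


class TrajectoryError(RuntimeError):
    """Raised when no trajectory satisfying the constraints can be built."""


class _Infeasible(Exception):
    pass


@dataclass
class Trajectory:
    """Timed event table plus the configuration and seed that produced it."""

    events: pd.DataFrame
    config: EnvironmentConfig
    seed: int

    @property
    def translations(self) -> pd.DataFrame:
        return self.events[self.events.trial_type == "translation"]

    def direction_bin_counts(self) -> np.ndarray:
        """Number of translation segments per direction bin."""
        cfg = self.config
        bins = (self.translations.direction.to_numpy() // cfg.bin_width).astype(int)
        return np.bincount(bins, minlength=cfg.n_bins)


def _signed_arc(delta: float) -> float:
    """Shortest signed arc in (-180, 180]."""
    return -((-delta + 180.0) % 360.0 - 180.0)


def _max_run(x: float, y: float, ux: float, uy: float, cfg: EnvironmentConfig) -> float:
    """Longest in-room translation from (x, y) along unit vector (ux, uy)."""
    lo, hi = cfg.margin, cfg.room_side - cfg.margin
    tx = np.inf
    if ux > 1e-12:
        tx = (hi - x) / ux
    elif ux < -1e-12:
        tx = (lo - x) / ux
    ty = np.inf
    if uy > 1e-12:
        ty = (hi - y) / uy
    elif uy < -1e-12:
        ty = (lo - y) / uy
    return max(0.0, min(tx, ty))


def _sample_directions(cfg: EnvironmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-bin balanced directions, uniform within each bin."""
    base, extra = divmod(cfg.n_segments, cfg.n_bins)
    counts = np.full(cfg.n_bins, base, dtype=int)
    if extra:
        counts[rng.choice(cfg.n_bins, size=extra, replace=False)] += 1
    dirs = [
        rng.uniform(b * cfg.bin_width, (b + 1) * cfg.bin_width, size=c)
        for b, c in enumerate(counts)
    ]
    return np.concatenate(dirs)


def _build_path(cfg: EnvironmentConfig, rng: np.random.Generator):
    """Order the sampled directions and place segments inside the room.

    Depth-first search with randomized candidate order; a direction is
    admissible if the turn from the previous heading is a legal shortest arc
    and the room leaves at least the minimum segment length along it.
    """
    dirs = _sample_directions(cfg, rng)
    n = len(dirs)
    lmin, lmax = cfg.segment_length_range
    rad = np.deg2rad(dirs)
    ux, uy = np.cos(rad), np.sin(rad)
    lo, hi = cfg.margin, cfg.room_side - cfg.margin
    used = np.zeros(n, dtype=bool)
    order: list[int] = []
    lengths: list[float] = []
    positions = [(cfg.room_side / 2.0, cfg.room_side / 2.0)]
    steps = 0

    def candidates(prev_dir, x, y):
        ok = ~used
        if prev_dir is not None:
            turn = np.abs((dirs - prev_dir + 180.0) % 360.0 - 180.0)
            ok &= (turn >= cfg.min_rotation) & (turn <= cfg.max_rotation)
        with np.errstate(divide="ignore"):
            tx = np.where(ux > 0, (hi - x) / ux, np.where(ux < 0, (lo - x) / ux, np.inf))
            ty = np.where(uy > 0, (hi - y) / uy, np.where(uy < 0, (lo - y) / uy, np.inf))
        ok &= np.minimum(tx, ty) >= lmin
        return np.flatnonzero(ok)

    def dfs(prev_dir):
        nonlocal steps
        if len(order) == n:
            return True
        x, y = positions[-1]
        cand = candidates(prev_dir, x, y)
        rng.shuffle(cand)
        for i in cand:
            steps += 1
            if steps > _MAX_SEARCH_STEPS:
                raise _Infeasible("segment-ordering search exceeded its step budget")
            reach = _max_run(x, y, ux[i], uy[i], cfg)
            length = min(rng.uniform(lmin, lmax), reach)
            used[i] = True
            order.append(i)
            lengths.append(length)
            positions.append((x + length * ux[i], y + length * uy[i]))
            if dfs(dirs[i]):
                return True
            used[i] = False
            order.pop()
            lengths.pop()
            positions.pop()
        return False

    if not dfs(None):
        raise _Infeasible(
            "no admissible ordering of direction bins (turn limits "
            f"[{cfg.min_rotation}, {cfg.max_rotation}] deg with minimum segment "
            f"length {lmin} vm in a {cfg.room_side} vm room)"
        )
    return dirs[order], np.asarray(lengths), positions


def _schedule(cfg: EnvironmentConfig, dirs, lengths, positions) -> pd.DataFrame:
    rows = []
    t = 0.0
    for i, (d, length) in enumerate(zip(dirs, lengths)):
        if i > 0:
            turn = _signed_arc(d - dirs[i - 1])
            dur = abs(turn) / cfg.rotation_speed
            x, y = positions[i]
            rows.append((t, dur, "rotation", turn, x, y, x, y))
            t += dur
        dur = length / cfg.translation_speed
        x0, y0 = positions[i]
        x1, y1 = positions[i + 1]
        rows.append((t, dur, "translation", d, x0, y0, x1, y1))
        t += dur
    if t > cfg.run_length + 1e-9:
        raise _Infeasible(
            f"scheduled movement ({t:.2f} s) exceeds the run length "
            f"({cfg.run_length} s)"
        )
    x, y = positions[-1]
    rows.append((t, cfg.run_length - t, "rest", np.nan, x, y, x, y))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def generate_trajectory(config: EnvironmentConfig, seed: int) -> Trajectory:
    """Generate a balanced passive-navigation trajectory.

    Deterministic given (config, seed).  Raises :class:`TrajectoryError`
    naming the violated constraint if no trajectory can be found after a
    bounded number of attempts.
    """
    rng = np.random.default_rng(seed)
    last: Exception | None = None
    for _ in range(_MAX_ATTEMPTS):
        try:
            dirs, lengths, positions = _build_path(config, rng)
            events = _schedule(config, dirs, lengths, positions)
            return Trajectory(events=events, config=config, seed=seed)
        except _Infeasible as exc:
            last = exc
    raise TrajectoryError(
        f"could not build a trajectory after {_MAX_ATTEMPTS} attempts: {last}"
    )


def _mark_coverage(covered, x, y, heading_deg, cfg):
    """Mark bins covered from one sampled pose (disc, plus cone if moving)."""
    nx = covered.shape[0]
    reach = cfg.coverage_cone_length if heading_deg is not None else cfg.coverage_radius
    i0 = max(0, int(np.floor(x - reach)))
    i1 = min(nx, int(np.ceil(x + reach)) + 1)
    j0 = max(0, int(np.floor(y - reach)))
    j1 = min(nx, int(np.ceil(y + reach)) + 1)
    if i0 >= i1 or j0 >= j1:
        return
    xc = np.arange(i0, i1) + 0.5
    yc = np.arange(j0, j1) + 0.5
    dx = xc[:, None] - x
    dy = yc[None, :] - y
    d2 = dx * dx + dy * dy
    hit = d2 <= cfg.coverage_radius**2
    if heading_deg is not None:
        ang = np.rad2deg(np.arctan2(dy, dx))
        dev = np.abs((ang - heading_deg + 180.0) % 360.0 - 180.0)
        hit |= (d2 <= cfg.coverage_cone_length**2) & (dev <= cfg.coverage_cone_width / 2.0)
    covered[i0:i1, j0:j1] |= hit


def compute_coverage(
    trajectory: Trajectory,
    config: EnvironmentConfig | None = None,
    path_step: float = 0.5,
    rotation_step: float = 2.0,
) -> float:
    """Fraction of 1 x 1 vm room bins swept by the coverage geometry.

    A bin counts as covered if at any sampled pose its center lies within
    ``coverage_radius`` of the position, or (while moving or turning) inside
    the forward cone of ``coverage_cone_length`` and full width
    ``coverage_cone_width``.  The path is sampled every ``path_step`` vm
    along translations and every ``rotation_step`` degrees during rotations;
    rest poses contribute the disc only.
    """
    cfg = config or trajectory.config
    nx = int(round(cfg.room_side))
    covered = np.zeros((nx, nx), dtype=bool)
    events = trajectory.events
    if len(events) == 0:
        warnings.warn("empty trajectory: coverage is 0", stacklevel=2)
        return 0.0
    for ev in events.itertuples():
        if ev.trial_type == "translation":
            length = float(np.hypot(ev.x_end - ev.x_start, ev.y_end - ev.y_start))
            n_pts = max(2, int(np.ceil(length / path_step)) + 1)
            for f in np.linspace(0.0, 1.0, n_pts):
                _mark_coverage(
                    covered,
                    ev.x_start + f * (ev.x_end - ev.x_start),
                    ev.y_start + f * (ev.y_end - ev.y_start),
                    ev.direction,
                    cfg,
                )
        elif ev.trial_type == "rotation":
            # sweep the cone through the turn; heading interpolates the arc
            prev = events[
                (events.trial_type == "translation") & (events.onset < ev.onset)
            ]
            if len(prev) == 0:
                continue
            h0 = float(prev.direction.iloc[-1])
            n_pts = max(2, int(np.ceil(abs(ev.direction) / rotation_step)) + 1)
            for f in np.linspace(0.0, 1.0, n_pts):
                _mark_coverage(covered, ev.x_start, ev.y_start, h0 + f * ev.direction, cfg)
        else:  # rest: stationary disc
            _mark_coverage(covered, ev.x_start, ev.y_start, None, cfg)
    return float(covered.sum()) / float(nx * nx)
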