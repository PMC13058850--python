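import math

import numpy as np
import pandas as pd
import pytest

from gridglm.bold import BoldRun, simulate_bold
from gridglm.circular import UndefinedOrientationError, circ_dist
from gridglm.config import SimulationConfig
from gridglm.design import build_design, build_test_design
from gridglm.glm import fit_glm
from gridglm.gridcode import (
    analyze_run,
    estimate_orientations,
    gls_magnitude,
    mean_orientation,
    run_participant,
    split_run,
)


class TestEstimateOrientations:
    @pytest.mark.parametrize(
        "bs, bc, theta, amp",
        [
            (0.0, 1.0, 0.0, 1.0),
            (1.0, 0.0, 15.0, 1.0),  # 90 deg / 6
            (-1.0, 0.0, 45.0, 1.0),  # -15 wrapped into [0, 60)
            (3.0, 4.0, math.degrees(math.atan2(3.0, 4.0)) / 6.0, 5.0),
        ],
    )
    def test_quadrant_aware_arctangent(self, bs, bc, theta, amp):
        est = estimate_orientations([bs], [bc], k=6)
        assert est.theta[0] == pytest.approx(theta, abs=1e-12)
        assert est.amplitude[0] == pytest.approx(amp, abs=1e-12)

    def test_zero_betas_flagged_and_excluded(self):
        est = estimate_orientations([0.0, 1.0], [0.0, 0.0], k=6)
        assert not est.valid[0] and est.valid[1]
        assert np.isnan(est.theta[0])
        phi, _ = mean_orientation(est.theta[est.valid], est.amplitude[est.valid], 6)
        assert phi == pytest.approx(15.0)


class TestMeanOrientation:
    def test_single_and_symmetric_pairs(self):
        assert mean_orientation([10.0], [1.0], 6)[0] == pytest.approx(10.0)
        assert mean_orientation([0.0, 10.0], [1.0, 1.0], 6)[0] == pytest.approx(5.0)

    def test_antipodal_pair_undefined(self):
        with pytest.raises(UndefinedOrientationError):
            mean_orientation([0.0, 30.0], [1.0, 1.0], 6)

    def test_weighted_mean_matches_dense_maximization(self):
        """phi_bar maximizes sum_v a_v cos(k(theta_v - phi)) over a dense grid."""
        theta = np.array([0.0, 10.0])
        w = np.array([3.0, 1.0])
        phi, _ = mean_orientation(theta, w, 6)
        grid = np.arange(0.0, 60.0, 0.01)
        score = (w[:, None] * np.cos(np.deg2rad(6 * (theta[:, None] - grid[None, :])))).sum(0)
        assert abs(phi - grid[score.argmax()]) <= 0.01


class TestSplitRun:
    def test_even_split_and_truncation(self):
        data = np.zeros((1, 600))
        events = pd.DataFrame(
            [
                [10.0, 3.0, "translation", 40.0],
                [299.5, 3.0, "translation", 90.0],
                [400.0, 3.0, "translation", 180.0],
            ],
            columns=["onset", "duration", "trial_type", "direction"],
        )
        (h1, e1), (h2, e2) = split_run(BoldRun(data, tr=1.0), events)
        assert h1.n_scans == 300 and h2.n_scans == 300
        assert len(e1) == 2 and len(e2) == 1
        # straddling event stays in the first half, truncated at the boundary
        assert e1.iloc[1].duration == pytest.approx(0.5)
        assert e2.iloc[0].onset == pytest.approx(100.0)
        assert len(e1) + len(e2) == len(events)

    def test_partition_covers_every_event_once(self, default_trajectory):
        run = BoldRun(np.zeros((1, 620)), tr=1.0)
        (_, e1), (_, e2) = split_run(run, default_trajectory.events)
        assert len(e1) + len(e2) == len(default_trajectory.events)


class TestGlsMagnitude:
    def test_matched_filter_recovers_amplitude(self, default_trajectory, noiseless_run):
        """Whole-run GLM2 with phi_bar = theta* returns the planted amplitude;
        the anti-phase reference flips the sign."""
        run, sim = noiseless_run
        cell = gls_magnitude(run, default_trajectory.events, sim.group_orientation, 6)
        assert cell.magnitude == pytest.approx(sim.modulation_amplitude, abs=1e-6)
        anti = gls_magnitude(
            run, default_trajectory.events, sim.group_orientation + 30.0, 6
        )
        assert anti.magnitude == pytest.approx(-sim.modulation_amplitude, abs=1e-6)

    def test_empty_roi_fails(self, default_trajectory, noiseless_run):
        run, _ = noiseless_run
        with pytest.raises(ValueError, match="empty ROI"):
            gls_magnitude(run, default_trajectory.events, 0.0, 6,
                          roi_mask=np.zeros(run.n_voxels, bool))

    def test_first_half_self_test_nonnegative(self, default_trajectory, noiseless_run):
        """Diagnostic mode: scoring the estimation half against its own
        orientation gives a non-negative magnitude on planted data."""
        run, _ = noiseless_run
        (h1, e1), _ = split_run(run, default_trajectory.events)
        design = build_design(e1, 6, h1.n_scans, h1.tr)
        fit = fit_glm(h1, design)
        est = estimate_orientations(fit.beta("sin"), fit.beta("cos"), 6)
        phi, _ = mean_orientation(est.theta[est.valid], est.amplitude[est.valid], 6)
        cell = gls_magnitude(h1, e1, phi, 6)
        assert cell.magnitude >= 0


class TestAnalyzeRun:
    def test_exact_recovery_noiseless(self, default_trajectory, noiseless_run):
        run, sim = noiseless_run
        est, cell = analyze_run(run, default_trajectory.events, 6)
        assert est.phi_bar == pytest.approx(sim.group_orientation, abs=1e-6)
        assert cell.magnitude == pytest.approx(sim.modulation_amplitude, abs=1e-6)

    def test_rotational_equivariance(self, default_trajectory, noiseless_run):
        """Shifting every event direction by delta shifts phi_bar by delta
        modulo the fold period."""
        run, sim = noiseless_run
        delta = 13.0
        ev = default_trajectory.events.copy()
        tmask = ev.trial_type == "translation"
        ev.loc[tmask, "direction"] = (ev.loc[tmask, "direction"] + delta) % 360
        est, _ = analyze_run(run, ev, 6)
        expected = (sim.group_orientation + delta) % 60.0
        assert circ_dist(est.phi_bar, expected, 6) < 1e-6

    def test_orientation_matches_sse_grid_search(self, default_trajectory):
        """Per-voxel orientations equal a brute-force grid search minimizing
        the residual sum of squares of the single-modulator model."""
        sim = SimulationConfig(n_voxels=10)
        run = simulate_bold(default_trajectory, sim, seed=21)
        (h1, e1), _ = split_run(run, default_trajectory.events)
        design = build_design(e1, 6, h1.n_scans, h1.tr)
        fit = fit_glm(h1, design)
        est = estimate_orientations(fit.beta("sin"), fit.beta("cos"), 6)
        grid = np.arange(0.0, 60.0, 0.1)
        sse = np.full((grid.size, run.n_voxels), np.inf)
        for i, theta in enumerate(grid):
            d = build_test_design(e1, 6, float(theta), h1.n_scans, h1.tr, base=design)
            coef, res, *_ = np.linalg.lstsq(d.matrix, h1.data.T, rcond=None)
            # theta and theta + 30 give mirror fits with negated amplitude;
            # keep the branch with a non-negative modulation amplitude
            amp = coef[d.names.index("aligned")]
            sse[i, amp >= 0] = res[amp >= 0]
        best = grid[sse.argmin(axis=0)]
        assert np.all(circ_dist(best, est.theta, 6) <= 0.1)


class TestRunParticipant:
    def test_two_identical_runs_average_to_one(self, default_trajectory, noiseless_run):
        run, _ = noiseless_run
        masks = {"left": np.array([True, True, False, False]),
                 "right": np.array([False, False, True, True])}
        pair = [(run, default_trajectory.events)] * 2
        res = run_participant(pair, masks, folds=(6,))
        for _, row in res.participant.iterrows():
            per_run = res.cells[
                (res.cells.hemisphere == row.hemisphere) & (res.cells.fold == row.fold)
            ].magnitude
            assert row.magnitude == pytest.approx(per_run.iloc[0])
            assert per_run.nunique() == 1

    def test_swapped_masks_swap_labels(self, default_trajectory):
        sim = SimulationConfig(n_voxels=6)
        run = simulate_bold(default_trajectory, sim, seed=4)
        m1 = np.arange(6) < 3
        runs = [(run, default_trajectory.events)]
        a = run_participant(runs, {"left": m1, "right": ~m1}, folds=(6,))
        b = run_participant(runs, {"left": ~m1, "right": m1}, folds=(6,))
        av = a.cells.set_index("hemisphere").magnitude
        bv = b.cells.set_index("hemisphere").magnitude
        assert av["left"] == pytest.approx(bv["right"])
        assert av["right"] == pytest.approx(bv["left"])

    def test_overlapping_masks_rejected(self, default_trajectory, noiseless_run):
        run, _ = noiseless_run
        masks = {"left": np.array([True, True, False, False]),
                 "right": np.array([False, True, True, True])}
        with pytest.raises(ValueError, match="overlap"):
            run_participant([(run, default_trajectory.events)], masks, folds=(6,))
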