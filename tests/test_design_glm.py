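import numpy as np
import pandas as pd
import pytest

from gridglm.config import SimulationConfig
from gridglm.bold import simulate_bold
from gridglm.design import (
    DesignError,
    DesignMatrix,
    MICROTIME_DT,
    build_design,
    build_test_design,
    convolved_regressor,
    double_gamma_hrf,
)
from gridglm.glm import fit_glm


def single_event(direction, onset=10.0, duration=3.0):
    return pd.DataFrame(
        [[onset, duration, "translation", direction]],
        columns=["onset", "duration", "trial_type", "direction"],
    )


class TestBuildDesign:
    @pytest.mark.parametrize(
        "direction, zero_col, unit_col",
        [(0.0, "sin", "cos"), (15.0, "cos", "sin")],  # 6*15 deg = 90 deg
    )
    def test_quadrature_weights_at_cardinal_angles(self, direction, zero_col, unit_col):
        design = build_design(single_event(direction), k=6, n_scans=60, tr=1.0)
        assert np.abs(design.column(zero_col)).max() < 1e-9
        np.testing.assert_allclose(
            design.column(unit_col), design.column("translation"), atol=1e-9
        )

    def test_unit_impulse_reproduces_hrf(self):
        design = build_design(
            single_event(0.0, onset=0.0, duration=MICROTIME_DT), k=6,
            n_scans=40, tr=1.0,
        )
        hrf = double_gamma_hrf()
        sampled = hrf[np.round(np.arange(40) / MICROTIME_DT).astype(int).clip(0, hrf.size - 1)]
        sampled = np.where(np.arange(40) < 32, sampled, 0.0)
        np.testing.assert_allclose(design.column("cos"), sampled, atol=1e-9)

    def test_event_beyond_window_rejected(self):
        with pytest.raises(DesignError, match="618"):
            build_design(single_event(0.0, onset=618.0, duration=5.0),
                         k=6, n_scans=620, tr=1.0)

    def test_aligned_modulator_values(self):
        """GLM2 modulator is +1 at phi = phi_bar, -1 in anti-phase, 0 in
        quadrature."""
        phi_bar = 20.0
        for offset, factor in [(0.0, 1.0), (30.0, -1.0), (15.0, 0.0)]:
            design = build_test_design(
                single_event(phi_bar + offset), k=6, phi_bar=phi_bar,
                n_scans=60, tr=1.0,
            )
            np.testing.assert_allclose(
                design.column("aligned"),
                factor * design.column("translation"),
                atol=1e-9,
            )


class TestFitGlm:
    def test_noiseless_planted_betas_exact(self, default_trajectory, noiseless_run):
        run, sim = noiseless_run
        design = build_design(default_trajectory.events, k=6,
                              n_scans=run.n_scans, tr=run.tr)
        fit = fit_glm(run, design)
        k_theta = np.deg2rad(6 * sim.group_orientation)
        np.testing.assert_allclose(
            fit.beta("sin"), 0.8 * np.sin(k_theta), atol=1e-6)
        np.testing.assert_allclose(
            fit.beta("cos"), 0.8 * np.cos(k_theta), atol=1e-6)

    def test_matches_normal_equations_oracle(self, default_trajectory):
        design = build_design(default_trajectory.events, k=6, n_scans=620, tr=1.0)
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, 620))
        fit = fit_glm(data, design)
        x = design.matrix
        oracle = np.linalg.solve(x.T @ x, x.T @ data.T).T
        np.testing.assert_allclose(fit.betas, oracle, atol=1e-8)

    def test_pure_noise_betas_centered(self, default_trajectory):
        sim = SimulationConfig(modulation_amplitude=0.0, n_voxels=1000)
        run = simulate_bold(default_trajectory, sim, seed=11)
        design = build_design(default_trajectory.events, k=6,
                              n_scans=run.n_scans, tr=run.tr)
        fit = fit_glm(run, design)
        b = fit.beta("sin")
        assert abs(b.mean()) < 4 * b.std(ddof=1) / np.sqrt(b.size)

    def test_linear_drift_absorbed_exactly(self, default_trajectory, noiseless_run):
        run, _ = noiseless_run
        design = build_design(default_trajectory.events, k=6,
                              n_scans=run.n_scans, tr=run.tr)
        base = fit_glm(run, design)
        drifted = run.data + 0.37 * np.arange(run.n_scans)[None, :]
        fit = fit_glm(drifted, design)
        np.testing.assert_allclose(fit.beta("sin"), base.beta("sin"), atol=1e-6)
        np.testing.assert_allclose(fit.beta("cos"), base.beta("cos"), atol=1e-6)

    def test_direction_shift_rotates_quadrature_betas(self, default_trajectory,
                                                      noiseless_run):
        """Adding delta to every event direction rotates (b_sin, b_cos) by
        k*delta in the quadrature plane."""
        run, _ = noiseless_run
        delta = 7.0
        ev = default_trajectory.events
        shifted = ev.copy()
        tmask = shifted.trial_type == "translation"
        shifted.loc[tmask, "direction"] = (shifted.loc[tmask, "direction"] + delta) % 360
        d0 = build_design(ev, k=6, n_scans=run.n_scans, tr=run.tr)
        d1 = build_design(shifted, k=6, n_scans=run.n_scans, tr=run.tr)
        f0, f1 = fit_glm(run, d0), fit_glm(run, d1)
        a = np.deg2rad(6 * delta)
        np.testing.assert_allclose(
            f1.beta("sin"),
            np.cos(a) * f0.beta("sin") + np.sin(a) * f0.beta("cos"),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            f1.beta("cos"),
            -np.sin(a) * f0.beta("sin") + np.cos(a) * f0.beta("cos"),
            atol=1e-8,
        )

    def test_rank_deficient_design_names_columns(self):
        x = np.ones((20, 2))
        x[:, 1] = np.arange(20)
        dup = np.column_stack([x, x[:, 1]])
        design = DesignMatrix(dup, ["intercept", "drift_linear", "copy"],
                              tr=1.0, fold=6)
        with pytest.raises(DesignError, match="collinear"):
            fit_glm(np.zeros((2, 20)), design)
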