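"""Bayesian-optimisation driver: design size, incumbent bookkeeping,
crash handling, determinism, low-dimensional convergence, bootstrap."""

import numpy as np
import pytest

from cardiobo.bo import (
    BOConfig,
    BayesianOptimizer,
    BootstrapResult,
    InitialisationError,
    residual_bootstrap,
    run_bo,
)
from cardiobo.synth import SubjectSpec, make_subject

FAST = dict(gp_restarts=2, gp_refit_restarts=1, acq_starts=32, acq_refine=4,
            acq_maxfev=30)


@pytest.fixture(scope="module")
def small_subject():
    spec = SubjectSpec(theta_true=(1.2, 0.95, 1.1, 1.0), strain_noise_sd=0.0,
                       volume_noise_sd_ml=0.0, seed=11)
    obs, geom, _ = make_subject(spec)
    return spec, obs, geom


class TestConfig:
    def test_defaults_match_study_setup(self):
        cfg = BOConfig()
        assert cfg.n_init == 40          # 10*d rule of thumb for d=4
        assert cfg.n_iter == 500
        assert cfg.n_init + cfg.n_iter == 540

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_init": 3},
            {"box": ((1.0, 0.5),) * 4},
            {"surrogate": "both"},
            {"objective": "fO3"},
            {"v30_source": "oracle"},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            BOConfig(**kw)

    def test_fixed_dimensions_via_equal_bounds(self):
        cfg = BOConfig(box=((0.1, 5.0), (0.1, 5.0), (1.0, 1.0), (1.0, 1.0)),
                       n_init=10)
        assert cfg.free_mask.tolist() == [True, True, False, False]


class TestRun:
    def test_evaluation_count_and_trace(self, small_subject):
        _, obs, geom = small_subject
        cfg = BOConfig(n_init=8, n_iter=5, objective="fO2", seed=4, **FAST)
        theta, state = run_bo(cfg, geom, obs)
        assert state.n_evaluations == 13
        trace = state.trace()
        assert len(trace) == 13
        # incumbent equals the running minimum of successful evaluations
        run_min = np.fmin.accumulate(np.where(np.isnan(trace["objective"]),
                                              np.inf, trace["objective"]))
        assert np.allclose(trace["incumbent"], run_min)
        assert np.all(np.diff(trace["incumbent"]) <= 0)

    def test_seeded_determinism(self, small_subject):
        _, obs, geom = small_subject
        cfg = BOConfig(n_init=8, n_iter=4, objective="fO2", seed=9, **FAST)
        _, s1 = run_bo(cfg, geom, obs)
        _, s2 = run_bo(cfg, geom, obs)
        assert np.array_equal(np.stack(s1.theta), np.stack(s2.theta))
        assert s1.total == s2.total

    def test_crash_bookkeeping(self, small_subject):
        """Crashed queries grow only the classifier data, not the GP data."""
        _, obs, geom = small_subject
        # box straddling the soft crash corner; Klotz objective via simulator
        cfg = BOConfig(box=((0.1, 2.0),) * 4, n_init=12, n_iter=6,
                       objective="fO2_klotz", v30_source="simulator", seed=2,
                       **FAST)
        opt = BayesianOptimizer(cfg).fit(obs, geom)
        st = opt.state_
        n_ok = int(np.sum(st.successes()))
        assert st.crash_count == st.n_evaluations - n_ok
        assert opt.surrogate_.X_train_.shape[0] == n_ok
        if st.crash_count:
            assert opt.classifier_ is not None
            assert opt.classifier_.X_train_.shape[0] == st.n_evaluations

    def test_all_crashing_design_aborts_with_advice(self, small_subject):
        _, obs, geom = small_subject
        # a box buried in the soft crash corner: every design point fails
        box = ((0.1, 0.13), (0.1, 0.13), (0.1, 0.13), (1.0, 1.0))
        cfg = BOConfig(box=box, n_init=4, n_iter=1, objective="fO2", seed=0,
                       **FAST)
        with pytest.raises(InitialisationError, match="widen or soften"):
            BayesianOptimizer(cfg).fit(obs, geom)

    def test_emulator_mode_requires_emulator(self, small_subject):
        with pytest.raises(ValueError):
            BayesianOptimizer(BOConfig(objective="fO2_klotz", v30_source="emulator"))

    def test_partial_and_target_modes_agree_on_data(self, small_subject):
        _, obs, geom = small_subject
        for mode in ("target", "partial"):
            cfg = BOConfig(n_init=8, n_iter=2, objective="fO2", surrogate=mode,
                           seed=5, **FAST)
            opt = BayesianOptimizer(cfg).fit(obs, geom)
            assert np.isfinite(opt.ymin_)
            assert opt.surrogate_.gps_[0].X_train_.shape[0] == int(
                np.sum(opt.state_.successes())
            )
            assert len(opt.surrogate_.gps_) == (1 if mode == "target" else 25)

    def test_2d_convergence_noise_free(self):
        """With theta3, theta4 fixed at truth, 20+60 evaluations reach a
        near-zero objective in most seeds (6 seeds run; >= 5 expected, the
        8-out-of-10 proportion rounded up)."""
        spec = SubjectSpec(theta_true=(1.2, 0.95, 1.0, 1.0), strain_noise_sd=0.0,
                           volume_noise_sd_ml=0.0, seed=11)
        obs, geom, _ = make_subject(spec)
        box = ((0.1, 5.0), (0.1, 5.0), (1.0, 1.0), (1.0, 1.0))
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = BOConfig(box=box, n_init=20, n_iter=60, objective="fO2",
                           seed=seed)
            _, state = run_bo(cfg, geom, obs)
            if state.ymin < 1e-3:
                hits += 1
        assert hits >= 5


class TestCompareWithHGO:
    def test_comparison_fields(self, small_subject):
        from cardiobo.hgo import HGOConfig, run_hgo

        _, obs, geom = small_subject
        cfg = BOConfig(n_init=10, n_iter=5, objective="fO2", seed=3, **FAST)
        opt = BayesianOptimizer(cfg).fit(obs, geom)
        hgo = run_hgo(HGOConfig(variant="original", step_budget=15), geom, obs)
        cmp = opt.compare_with_hgo(hgo)
        inc = np.asarray(opt.state_.incumbent)
        assert cmp["y_at_imin_hgo"] == inc[min(hgo.n_evaluations, len(inc)) - 1]
        if cmp["i_at_ymin_hgo"] is not None:
            assert inc[cmp["i_at_ymin_hgo"] - 1] <= hgo.ymin


class TestResidualBootstrap:
    def test_noise_free_is_degenerate(self, small_subject):
        spec, obs, geom = small_subject
        res = residual_bootstrap(spec.theta_true, obs, geom, B=12, seed=1,
                                 n_design=30)
        assert res.degenerate
        assert np.allclose(res.estimates, res.estimates[0])

    def test_seeded_determinism(self, small_subject):
        spec, obs, geom = small_subject
        r1 = residual_bootstrap(spec.theta_true, obs, geom, B=8, seed=5,
                                n_design=25)
        r2 = residual_bootstrap(spec.theta_true, obs, geom, B=8, seed=5,
                                n_design=25)
        assert np.array_equal(r1.estimates, r2.estimates)

    def test_intervals_nested_and_grow_with_noise(self):
        """Wider observation noise gives wider bootstrap intervals
        (median over seeds), and higher-coverage intervals contain lower."""
        widths = []
        for sd in (0.002, 0.01, 0.03):
            w_seeds = []
            for seed in (0, 1, 2):
                spec = SubjectSpec(theta_true=(1.2, 0.95, 1.1, 1.0),
                                   strain_noise_sd=sd, volume_noise_sd_ml=0.0,
                                   seed=40 + seed)
                obs, geom, _ = make_subject(spec)
                res = residual_bootstrap(spec.theta_true, obs, geom, B=30,
                                         seed=seed, n_design=30)
                lo50, hi50 = res.intervals[0.5]
                lo90, hi90 = res.intervals[0.9]
                assert np.all(lo90 <= lo50 + 1e-12)
                assert np.all(hi90 >= hi50 - 1e-12)
                w_seeds.append(np.mean((hi90 - lo90)[:3]))  # theta4 is inert
            widths.append(np.median(w_seeds))
        assert widths[0] < widths[1] < widths[2]
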