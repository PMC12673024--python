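"""Two-step inverse method: radius ratio, radius fit, ECF fit."""

import numpy as np
import pytest

from cardiotwin.params import R_BOUNDS_UM
from cardiotwin.personalize import (
    CableScalingQrsModel,
    FitSettings,
    PatientRecord,
    fit_ecf,
    fit_radius,
    personalize_pair,
    relative_radius_change,
)


class TestRadiusRatio:
    def test_unchanged_inputs_give_unity(self):
        assert relative_radius_change(11.6, 11.6, 0.24, 0.24) == 1.0

    def test_rising_ecv_at_fixed_thickness_shrinks_radius(self):
        rho = relative_radius_change(11.0, 11.0, 0.24, 0.30)
        assert rho < 1.0

    def test_median_cohort_inputs_reproduce_frozen_value(self):
        # sqrt[(9.5 * 0.720) / (11.6 * 0.758)] evaluated directly
        rho = relative_radius_change(11.6, 9.5, 0.242, 0.280)
        assert rho == pytest.approx(0.8820, abs=5e-4)

    @pytest.mark.parametrize("args", [
        (0.0, 9.5, 0.24, 0.28), (11.6, -1.0, 0.24, 0.28),
        (11.6, 9.5, 0.0, 0.28), (11.6, 9.5, 0.24, 1.0),
    ])
    def test_nonphysical_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            relative_radius_change(*args)


def _grid_scan_min_admissible(model_pre, model_post, t_pre, t_post, rho,
                              step=0.01):
    """Brute-force oracle: smallest grid radius admissible for both models."""
    lo = max(R_BOUNDS_UM[0], R_BOUNDS_UM[0] / rho)
    hi = min(R_BOUNDS_UM[1], R_BOUNDS_UM[1] / rho)
    for r in np.arange(lo, hi + step / 2, step):
        if (model_pre.qrs(r, 0.0) <= t_pre
                and model_post.qrs(r * rho, 0.0) <= t_post):
            return r
    return None


class TestRadiusFit:
    @pytest.fixture()
    def models(self, baseline):
        return (CableScalingQrsModel(88.0, 0.24, baseline),
                CableScalingQrsModel(92.0, 0.28, baseline))

    def test_bisection_matches_grid_scan_oracle(self, models):
        mp, mq = models
        settings = FitSettings()
        for t_pre, t_post, rho in [(95.0, 97.0, 0.88), (90.0, 99.0, 1.0),
                                   (100.0, 96.0, 0.95)]:
            r_fit, r_post, flag = fit_radius(mp, mq, t_pre, t_post, rho,
                                             settings)
            r_grid = _grid_scan_min_admissible(mp, mq, t_pre, t_post, rho)
            assert r_grid is not None
            assert abs(r_fit - r_grid) <= settings.r_tol_um + 0.01
            assert r_post == rho * r_fit

    def test_equal_models_and_unit_ratio_reduce_to_single_fit(self, baseline):
        m = CableScalingQrsModel(90.0, 0.25, baseline)
        r1, r2, _ = fit_radius(m, m, 95.0, 95.0, 1.0)
        assert r1 == r2
        # single-model scan
        grid = _grid_scan_min_admissible(m, m, 95.0, 95.0, 1.0)
        assert abs(r1 - grid) <= FitSettings().r_tol_um + 0.01

    def test_unreachable_target_flags_upper_bound(self, models):
        mp, mq = models
        with pytest.warns(UserWarning, match="largest admissible radius"):
            r, _, flag = fit_radius(mp, mq, 60.0, 60.0, 1.0)
        assert flag
        assert r == pytest.approx(R_BOUNDS_UM[1])

    def test_nonmonotone_model_detected(self, baseline):
        class Bad:
            def qrs(self, r, ecf):
                return 90.0 + 0.0 * r  # flat: not strictly decreasing
        with pytest.raises(RuntimeError, match="not decreasing"):
            fit_radius(Bad(), Bad(), 90.0, 90.0, 1.0)

    def test_infeasible_ratio_rejected(self, models):
        mp, mq = models
        with pytest.raises(ValueError, match="no radius"):
            fit_radius(mp, mq, 95.0, 95.0, 0.3)


class TestEcfFit:
    def test_exact_target_keeps_ecf_zero(self, baseline):
        m = CableScalingQrsModel(90.0, 0.25, baseline)
        q0 = m.qrs(12.0, 0.0)
        ecf, q = fit_ecf(m, 12.0, q0)
        assert ecf == 0.0 and q == q0

    def test_grid_walk_matches_full_enumeration(self, baseline):
        m = CableScalingQrsModel(90.0, 0.25, baseline)
        settings = FitSettings()
        for target_off in (1.0, 3.0, 7.5, 20.0):
            target = m.qrs(13.0, 0.0) + target_off
            ecf, q = fit_ecf(m, 13.0, target, settings)
            grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 6)
            errs = np.array([abs(m.qrs(13.0, e) - target) for e in grid])
            best = grid[int(np.argmin(errs))]
            assert ecf == pytest.approx(best)
            # local optimality against both neighbors
            k = int(round(ecf / 0.05))
            for kk in (k - 1, k + 1):
                if 0 <= kk <= 20:
                    assert abs(q - target) <= errs[kk] + 1e-9

    def test_overlong_model_qrs_reports_residual_at_zero(self, baseline):
        m = CableScalingQrsModel(90.0, 0.25, baseline)
        target = m.qrs(13.0, 0.0) - 5.0
        ecf, q = fit_ecf(m, 13.0, target)
        assert ecf == 0.0
        assert q > target


class TestPersonalizePair:
    def _records(self, qrs_pre, qrs_post, wt=(11.6, 9.5), ecv=(0.24, 0.28)):
        pre = PatientRecord("P1", "F", "pre", qrs_pre, ecv[0], wt[0])
        post = PatientRecord("P1", "F", "post", qrs_post, ecv[1], wt[1])
        return pre, post

    def test_noise_free_forward_targets_recovered_on_the_grids(self, baseline):
        mp = CableScalingQrsModel(88.0, 0.24, baseline)
        mq = CableScalingQrsModel(88.0, 0.28, baseline)
        rho = relative_radius_change(11.6, 9.5, 0.24, 0.28)
        r_true = 14.0
        ecf_post_true = 0.10
        pre, post = self._records(mp.qrs(r_true, 0.0),
                                  mq.qrs(rho * r_true, ecf_post_true))
        res = personalize_pair(pre, post, mp, mq)
        assert abs(res.r_pre_um - r_true) <= FitSettings().r_tol_um
        assert res.ecf_pre == 0.0
        assert abs(res.ecf_post - ecf_post_true) <= 0.05 + 1e-9
        assert res.r_post_um == res.rho * res.r_pre_um  # machine precision

    def test_mismatched_patient_ids_rejected(self, baseline):
        m = CableScalingQrsModel(90.0, 0.25, baseline)
        pre, _ = self._records(95.0, 95.0)
        post = PatientRecord("OTHER", "F", "post", 95.0, 0.28, 9.5)
        with pytest.raises(ValueError, match="different patients"):
            personalize_pair(pre, post, m, m)

    def test_qrs_above_inclusion_limit_rejected(self):
        with pytest.raises(ValueError, match="110 ms"):
            PatientRecord("P1", "M", "pre", 120.0, 0.24, 11.0)
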