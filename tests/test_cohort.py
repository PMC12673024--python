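"""Synthetic cohort generator, derived volumes, statistics."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats as sps

from cardiotwin.cohort import (
    SyntheticCohortSpec,
    derived_volumes,
    generate_cohort,
    mann_whitney,
    bulls_eye,
    spearman,
    summarize,
    wilcoxon_signed_rank,
)
from cardiotwin.personalize import CableScalingQrsModel, relative_radius_change


@pytest.fixture(scope="module")
def cable_cohort(baseline):
    factory = lambda ecv: CableScalingQrsModel(90.0, ecv, baseline)  # noqa: E731
    return generate_cohort(SyntheticCohortSpec(n_patients=30), 11,
                           factory, factory), factory


class TestGenerator:
    def test_same_spec_and_seed_reproduce_the_cohort(self, baseline):
        factory = lambda ecv: CableScalingQrsModel(90.0, ecv, baseline)  # noqa: E731
        a = generate_cohort(SyntheticCohortSpec(n_patients=6), 5, factory,
                            factory)
        b = generate_cohort(SyntheticCohortSpec(n_patients=6), 5, factory,
                            factory)
        assert a.truth.equals(b.truth)
        assert a.records_frame().equals(b.records_frame())

    def test_noise_free_targets_equal_forward_model(self, cable_cohort):
        coh, factory = cable_cohort
        for (pre, post), (_, tr) in zip(coh.records, coh.truth.iterrows()):
            assert pre.qrs_ms == pytest.approx(
                factory(pre.ecv).qrs(tr.r_pre_um, tr.ecf_pre), abs=1e-12)
            assert post.qrs_ms == pytest.approx(
                factory(post.ecv).qrs(tr.r_post_um, tr.ecf_post), abs=1e-12)

    def test_ecv_rises_after_surgery_in_most_patients(self, cable_cohort):
        coh, _ = cable_cohort
        rises = [post.ecv > pre.ecv for pre, post in coh.records]
        assert np.mean(rises) >= 0.9

    def test_wall_thickness_shrinks_more_in_females(self, cable_cohort):
        coh, _ = cable_cohort
        red = {"F": [], "M": []}
        for pre, post in coh.records:
            red[pre.sex].append(1.0 - post.wall_thickness_mm
                                / pre.wall_thickness_mm)
        assert np.median(red["F"]) > np.median(red["M"])

    def test_ground_truth_ratio_closes_the_loop(self, cable_cohort):
        """rho in the truth table equals the radius-ratio computed from
        the generated wall thickness / ECV records."""
        coh, _ = cable_cohort
        for (pre, post), (_, tr) in zip(coh.records, coh.truth.iterrows()):
            rho = relative_radius_change(pre.wall_thickness_mm,
                                         post.wall_thickness_mm,
                                         pre.ecv, post.ecv)
            assert tr.rho == pytest.approx(rho, abs=1e-12)
            assert tr.r_post_um == pytest.approx(tr.rho * tr.r_pre_um,
                                                 abs=1e-12)

    def test_binding_timepoint_has_zero_true_ecf(self, cable_cohort):
        coh, _ = cable_cohort
        for _, tr in coh.truth.iterrows():
            assert tr["ecf_pre" if tr.binding == "pre" else "ecf_post"] == 0.0


class TestDerivedVolumes:
    def test_worked_example(self):
        dv = derived_volumes(100.0, 0.25, 2.0)
        assert dv.matrix_volume_indexed_ml_m2 == pytest.approx(12.5)
        assert dv.cell_volume_indexed_ml_m2 == pytest.approx(37.5)
        assert dv.lv_mass_indexed_g_m2 == pytest.approx(52.5)

    def test_partition_identity_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.uniform(50, 250)
            e = rng.uniform(0.1, 0.5)
            dv = derived_volumes(v, e, rng.uniform(1.4, 2.4))
            assert dv.matrix_volume_ml + dv.cell_volume_ml == pytest.approx(
                v, abs=1e-12)
            assert dv.lv_mass_g == pytest.approx(1.05 * v, abs=1e-12)

    def test_zero_ecv_limit(self):
        assert derived_volumes(120.0, 0.0, 1.8).matrix_volume_ml == 0.0


class TestStats:
    def test_signed_rank_matches_independent_sign_enumeration(self):
        """n = 6 exact p equals a from-scratch 2^6 enumeration."""
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, 6)
        res = wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in np.ndindex(*([2] * 6))]
        ws = np.array(ws, dtype=float)
        p_oracle = min(1.0, 2 * min((ws <= w_obs + 1e-12).mean(),
                                    (ws >= w_obs - 1e-12).mean()))
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.exact

    def test_signed_rank_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(8)
        for n in (6, 9, 12):
            d = rng.normal(0.3, 1.0, n)
            ours = wilcoxon_signed_rank(d).p_value
            theirs = sps.wilcoxon(d, method="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank(np.ones(6), np.ones(6))
        assert res.p_value == 1.0
        assert res.degenerate

    def test_mann_whitney_matches_scipy_exact(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 7)
        ours = mann_whitney(a, b)
        theirs = sps.mannwhitneyu(a, b, method="exact")
        assert ours.p_value == pytest.approx(theirs.pvalue, abs=1e-12)
        assert ours.exact

    def test_spearman_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        y = 0.7 * x + rng.normal(scale=0.5, size=6)
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)

        def r_of(a, b):
            a = a - a.mean(); b = b - b.mean()
            return (a * b).sum() / np.sqrt((a ** 2).sum() * (b ** 2).sum())

        r_obs = r_of(rx, ry)
        count = sum(abs(r_of(rx, np.array(p))) >= abs(r_obs) - 1e-12
                    for p in permutations(ry))
        assert res.statistic == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(count / 720.0, abs=1e-12)

    def test_perfect_monotone_association(self):
        res = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.statistic == 1.0

    def test_paired_shift_detected_with_high_power(self):
        """n = 200 pairs, 0.3-SD shift: Wilcoxon rejects at 5% in > 90%
        of replicates; with no shift the type-I rate is near 5%."""
        rng = np.random.default_rng(123)
        n_rep = 200
        hits_power = hits_null = 0
        for _ in range(n_rep):
            base_v = rng.normal(0, 1, 200)
            hits_power += wilcoxon_signed_rank(
                base_v + 0.3 + rng.normal(0, 0.1, 200)).p_value < 0.05
            hits_null += wilcoxon_signed_rank(
                rng.normal(0, 1, 200)).p_value < 0.05
        assert hits_power / n_rep > 0.9
        assert abs(hits_null / n_rep - 0.05) < 0.04


class TestSummaries:
    def test_median_and_iqr_definition(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s["median"] == 3 and s["q1"] == 2 and s["q3"] == 4

    def test_quartiles_against_order_statistic_oracle(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=101)
        s = summarize(v)
        vs = np.sort(v)
        assert s["median"] == pytest.approx(vs[50])
        assert s["q1"] == pytest.approx(vs[25])  # linear interp, exact index
        assert s["q3"] == pytest.approx(vs[75])

    def test_bulls_eye_difference_panel(self, small_biv, small_segmentation):
        from cardiotwin.mesh import measure_wall_thickness
        mesh, coords = small_biv
        wt = measure_wall_thickness(mesh, coords, small_segmentation)
        df = bulls_eye(wt, wt)
        assert len(df) == 17
        ok = ~np.isnan(df.difference_mm)
        assert np.allclose(df.difference_mm[ok], 0.0)
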