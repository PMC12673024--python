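"""Forward engines: strand monodomain, tet monodomain, eikonal, measurements."""

import numpy as np
import pytest

from cardiotwin.mesh import build_slab
from cardiotwin.params import TissueParameters, effective_conductivity
from cardiotwin.propagation import (
    ActivationMap,
    CvCalibrator,
    EikonalMesh,
    StimulusProtocol,
    measure_cv,
    run_eikonal,
    run_monodomain,
    run_strand,
    strand_cv,
    total_activation_time,
    velocity_tensors,
)

D_FIBER = 1.031e-3  # cm^2/ms, default-parameter fiber diffusivity


@pytest.fixture(scope="module")
def default_diffusivity(baseline):
    return effective_conductivity(TissueParameters(), baseline).diffusivity


class TestStrand:
    def test_default_cv_in_physiological_band(self, default_diffusivity):
        cv = strand_cv(default_diffusivity[0])
        assert 40.0 <= cv <= 90.0

    def test_zero_conductivity_activates_only_stimulated_nodes(self):
        res = run_strand(0.0, length_mm=10.0, t_end_ms=30.0)
        act = np.isfinite(res.activation_ms)
        assert act.sum() >= 2
        assert act.sum() <= 12  # stimulated region only
        assert not res.captured

    def test_runs_are_deterministic(self, default_diffusivity):
        a = run_strand(default_diffusivity[0], length_mm=8.0)
        b = run_strand(default_diffusivity[0], length_mm=8.0)
        assert np.array_equal(a.activation_ms, b.activation_ms,
                              equal_nan=True)

    def test_cv_converges_under_mesh_refinement(self):
        """Halving the strand spacing changes CV by < 2%."""
        cv1 = strand_cv(D_FIBER, h_mm=0.1)
        cv2 = strand_cv(D_FIBER, h_mm=0.05)
        assert cv2 == pytest.approx(cv1, rel=0.02)


class TestCalibrator:
    def test_cache_hit_is_identical(self, shared_calibrator):
        p = TissueParameters(12.0, 0.25, 0.1)
        assert shared_calibrator.cv(p, "fiber") == shared_calibrator.cv(p, "fiber")

    def test_fiber_faster_than_transverse(self, shared_calibrator):
        p = TissueParameters()
        assert shared_calibrator.cv(p, "fiber") > shared_calibrator.cv(p, "transverse")

    def test_nonconductive_tissue_flagged_zero(self, shared_calibrator):
        assert shared_calibrator.cv(TissueParameters(ecf=1.0), "fiber") == 0.0

    def test_scaled_mode_matches_direct_strand_run(self, baseline):
        """The sqrt(D) rescaling of the reference strand agrees with an
        actual strand run at scaled resolution (continuum self-similarity
        of the cable equation)."""
        direct = CvCalibrator(baseline, mode="direct")
        scaled = CvCalibrator(baseline, mode="scaled")
        p = TissueParameters(r_um=11.0)
        assert scaled.cv(p, "fiber") == pytest.approx(direct.cv(p, "fiber"),
                                                      rel=0.02)


@pytest.fixture(scope="module")
def cube():
    m = build_slab(15.0, 15.0, 15.0, 1.0)
    em = EikonalMesh(m.nodes, m.tets)
    nel = m.n_elements
    frame = (np.tile([1.0, 0, 0], (nel, 1)), np.tile([0.0, 1, 0], (nel, 1)),
             np.tile([0.0, 0, 1], (nel, 1)))
    return m, em, frame


class TestEikonal:
    def test_uniform_speed_matches_euclidean_distance(self, cube):
        m, em, (f, s, n) = cube
        v = 0.6
        M, V = velocity_tensors(f, s, n, np.array([v, v, v]))
        src = np.array([int(np.argmin(np.linalg.norm(m.nodes, axis=1)))])
        amap = run_eikonal(em, M, V, [(src, 0.0)])
        exact = np.linalg.norm(m.nodes - m.nodes[src[0]], axis=1) / v
        far = exact > 5.0 / v
        rel = np.abs(amap.times_ms[far] - exact[far]) / exact[far]
        assert rel.max() < 0.02

    def test_multi_source_is_pointwise_minimum(self, cube):
        m, em, (f, s, n) = cube
        M, V = velocity_tensors(f, s, n, np.array([0.8, 0.4, 0.4]))
        i1 = int(np.argmin(np.linalg.norm(m.nodes, axis=1)))
        i2 = int(np.argmin(np.linalg.norm(m.nodes - np.array([15.0, 15, 15]),
                                          axis=1)))
        a1 = run_eikonal(em, M, V, [(np.array([i1]), 0.0)])
        a2 = run_eikonal(em, M, V, [(np.array([i2]), 0.0)])
        both = run_eikonal(em, M, V, [(np.array([i1]), 0.0),
                                      (np.array([i2]), 0.0)])
        expected = np.minimum(a1.times_ms, a2.times_ms)
        # first-arrival bound holds everywhere; where the two fronts
        # collide, the face interpolation mixes values from both fronts
        # and may undershoot by up to about one cell of travel time
        assert np.all(both.times_ms <= expected + 1e-9)
        one_cell_ms = 1.0 / 0.4
        assert np.abs(both.times_ms - expected).max() < one_cell_ms
        away = np.abs(a1.times_ms - a2.times_ms) > 2 * one_cell_ms
        assert np.allclose(both.times_ms[away], expected[away], atol=1e-6)

    def test_planar_source_gives_planar_isochrones(self, cube):
        m, em, (f, s, n) = cube
        M, V = velocity_tensors(f, s, n, np.array([0.6, 0.6, 0.6]))
        src = np.flatnonzero(m.nodes[:, 0] < 1e-9)
        amap = run_eikonal(em, M, V, [(src, 0.0)])
        # times depend on x only
        for x in (5.0, 10.0, 15.0):
            sel = np.abs(m.nodes[:, 0] - x) < 1e-9
            t = amap.times_ms[sel]
            assert t.std() < 0.02 * t.mean()
            assert t.mean() == pytest.approx(x / 0.6, rel=0.02)

    def test_onset_translation_invariance(self, cube):
        m, em, (f, s, n) = cube
        M, V = velocity_tensors(f, s, n, np.array([0.6, 0.6, 0.6]))
        src = np.array([0])
        a0 = run_eikonal(em, M, V, [(src, 0.0)])
        a10 = run_eikonal(em, M, V, [(src, 10.0)])
        assert total_activation_time(a0) == pytest.approx(
            total_activation_time(a10), abs=1e-9)

    def test_nonpositive_speed_rejected(self, cube):
        m, em, (f, s, n) = cube
        with pytest.raises(ValueError, match="positive"):
            velocity_tensors(f, s, n, np.array([0.6, 0.0, 0.6]))


class TestMonodomain3D:
    def test_coarse_mesh_rejected_in_full_ionic_mode(self):
        m = build_slab(10.0, 5.0, 5.0, 1.0)
        D = np.zeros((m.n_elements, 3, 3))
        proto = StimulusProtocol(sites=[(np.array([0, 1]), 0.0)])
        with pytest.raises(ValueError, match="too coarse"):
            run_monodomain(m.nodes, m.tets, D, proto)

    def test_zero_conductivity_confines_activation(self):
        m = build_slab(5.0, 1.0, 1.0, 0.5)
        D = np.zeros((m.n_elements, 3, 3))
        src = np.flatnonzero(m.nodes[:, 0] < 0.6)
        proto = StimulusProtocol(sites=[(src, 0.0)], quiescent_ms=50.0)
        amap = run_monodomain(m.nodes, m.tets, D, proto, t_end_ms=20.0)
        act = np.isfinite(amap.times_ms)
        assert np.all(act[src])
        assert not np.any(act[~np.isin(np.arange(m.n_nodes), src)])

    def test_bar_cv_close_to_strand_at_matched_resolution(self, baseline):
        """Quasi-1-D bar through the FEM engine agrees with the 1-D
        strand reference at the same spacing within a few percent."""
        h = 0.4
        m = build_slab(12.0, 2 * h, 2 * h, h)
        nel = m.n_elements
        D = np.zeros((nel, 3, 3))
        D[:, 0, 0] = D_FIBER
        D[:, 1, 1] = D[:, 2, 2] = 1.36e-4
        src = np.flatnonzero(m.nodes[:, 0] < 0.6)
        proto = StimulusProtocol(sites=[(src, 0.0)], quiescent_ms=200.0)
        amap = run_monodomain(m.nodes, m.tets, D, proto, dt_diffusion=0.02)
        x = m.nodes[:, 0]
        t1 = np.nanmean(amap.times_ms[np.abs(x - 3.2) < 1e-6])
        t2 = np.nanmean(amap.times_ms[np.abs(x - 9.6) < 1e-6])
        cv_bar = 0.64 / (t2 - t1) * 1000.0
        cv_strand = strand_cv(D_FIBER, h_mm=h)
        assert cv_bar == pytest.approx(cv_strand, rel=0.05)


class TestMeasurements:
    def test_total_activation_time_definition(self):
        amap = ActivationMap(times_ms=np.array([0.0, 30.0, 88.0]), onset_ms=0.0)
        assert total_activation_time(amap) == 88.0

    def test_unactivated_fraction_raises_listing_count(self):
        t = np.full(100, 50.0)
        t[:5] = np.nan
        amap = ActivationMap(times_ms=t, onset_ms=0.0)
        with pytest.raises(RuntimeError, match="5 unactivated"):
            total_activation_time(amap)

    def test_probe_cv_arithmetic(self):
        amap = ActivationMap(times_ms=np.array([0.0, 30.0]), onset_ms=0.0)
        meas = measure_cv(amap, 0, 1, distance_mm=20.0)
        assert meas.cv_cm_s == pytest.approx(66.7, abs=0.05)
        assert meas.valid

    def test_swapped_probes_keep_magnitude_but_flag_invalid(self):
        amap = ActivationMap(times_ms=np.array([0.0, 30.0]), onset_ms=0.0)
        fwd = measure_cv(amap, 0, 1, 20.0)
        rev = measure_cv(amap, 1, 0, 20.0)
        assert rev.cv_cm_s == pytest.approx(fwd.cv_cm_s)
        assert fwd.valid and not rev.valid

    def test_activation_map_round_trip(self, tmp_path):
        t = np.array([0.0, 1.5, np.nan, 3.25])
        amap = ActivationMap(times_ms=t, onset_ms=0.0)
        p = tmp_path / "act.txt"
        amap.save(p)
        back = ActivationMap.load(p)
        assert np.allclose(back.times_ms, t, equal_nan=True)
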