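"""Two-step personalization of tissue parameters from QRS duration.

Given a patient's QRS duration (the fitting target), ECV (a set input
measured by CMR) and the relative change in cell radius between the
pre- and post-operative time points (derived from wall thickness and
ECV), the method:

1. finds the shortest admissible cell radius R such that the model's
   QRS duration (total activation time under the physiological
   five-site pattern) is no longer than the patient's QRS, with
   the pre/post radii locked to the ratio rho and both radii inside the
   histological admissible range; and
2. if the model QRS is still shorter than the target (typically in the
   time point whose radius constraint is not the binding one), raises
   the extracellular conductivity factor ECF on a 5% grid to minimize
   the |model - patient| QRS difference.

QRS(R) is strictly decreasing (a larger radius conducts faster) and
QRS(ECF) strictly increasing, which the fit verifies and exploits.

Fitting is written against a minimal model protocol: any object with a
``qrs(r_um, ecf) -> float`` method can be fitted; the packaged
implementation evaluates a calibrated anisotropic eikonal front on a
biventricular mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .params import (
    R_BOUNDS_UM,
    BaselineConductivities,
    TissueParameters,
)
from .propagation.activation import measure_cv, total_activation_time
from .propagation.calibrate import CvCalibrator
from .propagation.eikonal import EikonalMesh, run_eikonal, velocity_tensors

__all__ = [
    "PatientRecord",
    "FitSettings",
    "PersonalizationResult",
    "QrsModel",
    "EikonalQrsModel",
    "CableScalingQrsModel",
    "relative_radius_change",
    "fit_radius",
    "fit_ecf",
    "personalize_pair",
]


@dataclass(frozen=True)
class PatientRecord:
    """One patient time point: fitting targets and tissue inputs."""

    patient_id: str
    sex: str                    # 'F' | 'M'
    timepoint: str              # 'pre' | 'post'
    qrs_ms: float
    ecv: float                  # fraction in (0, 1)
    wall_thickness_mm: float    # LV average
    lv_volume_ml: float = float("nan")
    bsa_m2: float = float("nan")
    segment_thickness_mm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be pre/post, got {self.timepoint}")
        if self.qrs_ms > 110.0:
            raise ValueError(
                f"QRS {self.qrs_ms} ms exceeds the 110 ms inclusion limit "
                "(bundle-branch-block range)")
        if not (0.0 < self.ecv < 1.0):
            raise ValueError(f"ECV must be in (0,1), got {self.ecv}")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be positive")


@dataclass(frozen=True)
class FitSettings:
    r_tol_um: float = 0.05
    ecf_step: float = 0.05
    r_bounds_um: tuple[float, float] = R_BOUNDS_UM
    engine: str = "eikonal"          # 'eikonal' | 'monodomain'
    check_monotonicity: bool = True


@dataclass
class PersonalizationResult:
    patient_id: str
    r_pre_um: float
    r_post_um: float
    rho: float
    ecf_pre: float
    ecf_post: float
    model_qrs_pre_ms: float
    model_qrs_post_ms: float
    qrs_error_pre_ms: float
    qrs_error_post_ms: float
    cv_pre_cm_s: float = float("nan")
    cv_post_cm_s: float = float("nan")
    r_at_bound: bool = False
    ecf_at_zero_pre: bool = False
    ecf_at_zero_post: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


class QrsModel(Protocol):
    def qrs(self, r_um: float, ecf: float) -> float: ...


class EikonalQrsModel:
    """QRS surrogate: calibrated anisotropic eikonal total activation time.

    Conduction velocities along the fiber / transverse / sheet-normal
    axes come from the strand-monodomain calibration at the queried
    (R, ECV, ECF); the five-site activation pattern then yields the
    total activation time of the biventricular mesh.  Evaluations are
    cached on (R, ECF) rounded to fine grids.
    """

    def __init__(self, mesh, landmarks, ecv: float,
                 baseline: BaselineConductivities,
                 calibrator: CvCalibrator | None = None,
                 emesh: EikonalMesh | None = None):
        if mesh.fibers is None:
            raise ValueError("mesh needs fibers; call assign_fibers first")
        self.mesh = mesh
        self.landmarks = landmarks
        self.ecv = float(ecv)
        self.baseline = baseline
        self.calibrator = calibrator or CvCalibrator(baseline)
        self.emesh = emesh or EikonalMesh(mesh.nodes, mesh.tets)
        self._cache: dict[tuple, float] = {}
        self._cv_cache: dict[tuple, float] = {}

    @classmethod
    def factory(cls, mesh, landmarks, baseline: BaselineConductivities,
                calibrator: CvCalibrator | None = None):
        """``ecv -> model`` factory sharing mesh structures and the CV cache."""
        calibrator = calibrator or CvCalibrator(baseline)
        emesh = EikonalMesh(mesh.nodes, mesh.tets)
        return lambda ecv: cls(mesh, landmarks, ecv, baseline,
                               calibrator=calibrator, emesh=emesh)

    def _tensors(self, r_um: float, ecf: float):
        params = TissueParameters(r_um=r_um, ecv=self.ecv, ecf=ecf)
        speeds = np.array(self.calibrator.velocity_triple_mm_ms(params))
        if np.any(speeds <= 0):
            return None
        return velocity_tensors(self.mesh.fibers, self.mesh.sheets,
                                self.mesh.sheet_normals, speeds)

    def qrs(self, r_um: float, ecf: float) -> float:
        key = (round(r_um, 6), round(ecf, 6))
        if key in self._cache:
            return self._cache[key]
        tensors = self._tensors(r_um, ecf)
        if tensors is None:
            val = float("inf")  # non-propagating tissue
        else:
            amap = run_eikonal(self.emesh, tensors[0], tensors[1],
                               self.landmarks.eas)
            val = total_activation_time(amap)
        self._cache[key] = val
        return val

    def apical_cv(self, r_um: float, ecf: float) -> float:
        """CV (cm/s) between the septal probes under RV apical pacing."""
        key = (round(r_um, 6), round(ecf, 6))
        if key in self._cv_cache:
            return self._cv_cache[key]
        tensors = self._tensors(r_um, ecf)
        if tensors is None:
            return float("nan")
        amap = run_eikonal(self.emesh, tensors[0], tensors[1],
                           [(self.landmarks.rv_apex, 0.0)])
        meas = measure_cv(amap, self.landmarks.cv_probe_a,
                          self.landmarks.cv_probe_b,
                          self.landmarks.probe_distance_mm)
        cv = meas.cv_cm_s if meas.valid else float("nan")
        self._cv_cache[key] = cv
        return cv


class CableScalingQrsModel:
    """Analytic QRS model from continuous cable theory.

    CV scales as sqrt(D) in the continuous limit and the total
    activation time of a fixed activation pattern scales as 1/CV, so

        QRS(R, ECF) = qrs_ref * sqrt(D_fiber(ref) / D_fiber(R, ECV, ECF))

    with the reference at the default tissue parameters.  Strictly
    decreasing in R and increasing in ECF; infinite at ECF = 1.  Useful
    as a fast forward model for fitting-logic checks and mesh-free
    cohort generation.
    """

    def __init__(self, qrs_ref_ms: float, ecv: float,
                 baseline: BaselineConductivities):
        from .params import effective_conductivity
        self.qrs_ref_ms = float(qrs_ref_ms)
        self.ecv = float(ecv)
        self.baseline = baseline
        self._d_ref = effective_conductivity(
            TissueParameters(baseline.r_ref_um, baseline.ecv_ref, 0.0),
            baseline).diffusivity[0]

    def qrs(self, r_um: float, ecf: float) -> float:
        from .params import effective_conductivity
        d = effective_conductivity(
            TissueParameters(r_um=r_um, ecv=self.ecv, ecf=ecf),
            self.baseline).diffusivity[0]
        if d <= 0.0:
            return float("inf")
        return self.qrs_ref_ms * float(np.sqrt(self._d_ref / d))


def relative_radius_change(wt_pre_mm: float, wt_post_mm: float,
                           ecv_pre: float, ecv_post: float) -> float:
    """Pre-to-post cell radius ratio rho from wall thickness and ECV.

    Myocyte volume per unit wall area scales as WT * (1 - ECV); with the
    myocyte count and length unchanged between time points, volume
    scales as R^2, giving::

        rho = sqrt( WT_post (1 - ECV_post) / [ WT_pre (1 - ECV_pre) ] )
    """
    for name, v in (("wt_pre", wt_pre_mm), ("wt_post", wt_post_mm)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    for name, v in (("ecv_pre", ecv_pre), ("ecv_post", ecv_post)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0,1), got {v}")
    return float(np.sqrt((wt_post_mm * (1.0 - ecv_post))
                         / (wt_pre_mm * (1.0 - ecv_pre))))


def _assert_monotone_decreasing(model: QrsModel, r_lo: float, r_hi: float) -> None:
    q_lo, q_hi = model.qrs(r_lo, 0.0), model.qrs(r_hi, 0.0)
    if not q_lo > q_hi:
        raise RuntimeError(
            f"QRS(R) is not decreasing on [{r_lo}, {r_hi}] um "
            f"({q_lo} -> {q_hi} ms); the radius fit assumes monotonicity")


def fit_radius(model_pre: QrsModel, model_post: QrsModel,
               qrs_target_pre_ms: float, qrs_target_post_ms: float,
               rho: float, settings: FitSettings = FitSettings()
               ) -> tuple[float, float, bool]:
    """Shortest admissible R_pre with R_post = rho * R_pre.

    Returns (r_pre, r_post, at_bound).  The minimal R_pre is the
    smallest radius for which BOTH models produce a QRS no longer than
    their targets; if even the upper bound fails, the upper bound is
    returned flagged (the ECF stage is then skipped for the failing
    model).  QRS(R) decreasing makes the admissible set an interval
    [r*, r_max]; a bisection to ``r_tol_um`` finds r*.
    """
    if rho <= 0:
        raise ValueError(f"radius ratio must be positive, got {rho}")
    lo_b, hi_b = settings.r_bounds_um
    # both radii must stay in bounds: r_pre in [lo, hi]
    lo = max(lo_b, lo_b / rho)
    hi = min(hi_b, hi_b / rho)
    if lo > hi:
        raise ValueError(
            f"radius ratio {rho:.3f} admits no radius with both time "
            f"points inside [{lo_b}, {hi_b}] um")
    if settings.check_monotonicity:
        _assert_monotone_decreasing(model_pre, lo, hi)
        _assert_monotone_decreasing(model_post, lo * rho, hi * rho)

    def admissible(r_pre: float) -> bool:
        return (model_pre.qrs(r_pre, 0.0) <= qrs_target_pre_ms
                and model_post.qrs(r_pre * rho, 0.0) <= qrs_target_post_ms)

    if not admissible(hi):
        warnings.warn(
            "even the largest admissible radius leaves the model QRS above "
            "target; returning the bound", stacklevel=2)
        return hi, hi * rho, True
    if admissible(lo):
        return lo, lo * rho, True  # lower bound binds
    a, b = lo, hi  # a inadmissible, b admissible
    while b - a > settings.r_tol_um:
        mid = 0.5 * (a + b)
        if admissible(mid):
            b = mid
        else:
            a = mid
    return b, b * rho, False


def fit_ecf(model: QrsModel, r_um: float, qrs_target_ms: float,
            settings: FitSettings = FitSettings()) -> tuple[float, float]:
    """ECF on the 5% grid minimizing |model QRS - target| at fixed R.

    Returns (ecf, model_qrs).  QRS(ECF) is non-decreasing, so the walk
    stops at the first worsening step; ties break toward smaller ECF.
    If QRS(ECF=0) already exceeds the target the step is skipped by
    contract and ECF stays 0 with the residual reported.
    """
    q0 = model.qrs(r_um, 0.0)
    if q0 > qrs_target_ms:
        return 0.0, q0
    best_ecf, best_q = 0.0, q0
    best_err = abs(q0 - qrs_target_ms)
    n_steps = int(round(1.0 / settings.ecf_step))
    prev_q = q0
    for k in range(1, n_steps + 1):
        ecf = k * settings.ecf_step
        q = model.qrs(r_um, ecf)
        if q < prev_q - 1e-9:
            raise RuntimeError(
                f"QRS(ECF) decreased at ECF={ecf:.2f}; the ECF fit assumes "
                "monotonicity")
        err = abs(q - qrs_target_ms)
        if err < best_err - 1e-12:
            best_ecf, best_q, best_err = ecf, q, err
        if q > qrs_target_ms:
            break  # QRS non-decreasing: no later step can improve
        prev_q = q
    return best_ecf, best_q


def personalize_pair(record_pre: PatientRecord, record_post: PatientRecord,
                     model_pre, model_post,
                     settings: FitSettings = FitSettings()
                     ) -> PersonalizationResult:
    """Full two-step personalization of one pre/post patient pair."""
    if record_pre.patient_id != record_post.patient_id:
        raise ValueError("pre/post records belong to different patients")
    if (record_pre.timepoint, record_post.timepoint) != ("pre", "post"):
        raise ValueError("records must be the (pre, post) pair in order")
    rho = relative_radius_change(record_pre.wall_thickness_mm,
                                 record_post.wall_thickness_mm,
                                 record_pre.ecv, record_post.ecv)
    r_pre, r_post, at_bound = fit_radius(
        model_pre, model_post, record_pre.qrs_ms, record_post.qrs_ms, rho,
        settings)
    ecf_pre, q_pre = fit_ecf(model_pre, r_pre, record_pre.qrs_ms, settings)
    ecf_post, q_post = fit_ecf(model_post, r_post, record_post.qrs_ms, settings)
    res = PersonalizationResult(
        patient_id=record_pre.patient_id,
        r_pre_um=r_pre, r_post_um=r_post, rho=rho,
        ecf_pre=ecf_pre, ecf_post=ecf_post,
        model_qrs_pre_ms=q_pre, model_qrs_post_ms=q_post,
        qrs_error_pre_ms=q_pre - record_pre.qrs_ms,
        qrs_error_post_ms=q_post - record_post.qrs_ms,
        r_at_bound=at_bound,
        ecf_at_zero_pre=ecf_pre == 0.0,
        ecf_at_zero_post=ecf_post == 0.0,
    )
    for attr, model, r, ecf in (("cv_pre_cm_s", model_pre, r_pre, ecf_pre),
                                ("cv_post_cm_s", model_post, r_post, ecf_post)):
        if hasattr(model, "apical_cv"):
            setattr(res, attr, model.apical_cv(r, ecf))
    return res
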