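"""CV calibration: map tissue parameters to direction-wise conduction velocity.

Each (R, ECV, ECF) triple and propagation axis is mapped to a conduction
velocity by running a fine-resolution monodomain strand with that axis'
diffusivity.  Results are memoized, keyed by the rounded parameters, so
repeated queries during personalization are free.  The strand spacing is
shrunk with the diffusivity (wavefront width scales with sqrt(D)) to keep
the discretization error roughly constant across the parameter range.
"""

from __future__ import annotations

import numpy as np

from ..params import BaselineConductivities, TissueParameters, effective_conductivity
from .strand import strand_cv

__all__ = ["CvCalibrator", "AXIS_INDEX"]

AXIS_INDEX = {"fiber": 0, "transverse": 1, "normal": 2}


class CvCalibrator:
    """Memoized strand-monodomain calibration of CV(R, ECV, ECF, axis)."""

    def __init__(self, baseline: BaselineConductivities,
                 h_mm: float = 0.1, length_mm: float = 20.0,
                 variant: str = "epicardial", mode: str = "scaled"):
        if mode not in ("scaled", "direct"):
            raise ValueError(f"unknown calibration mode {mode!r}")
        self.baseline = baseline
        self.h_mm = h_mm
        self.length_mm = length_mm
        self.variant = variant
        self.mode = mode
        self._cache: dict[tuple, float] = {}
        # reference fiber diffusivity for resolution scaling
        self._d_ref = effective_conductivity(
            TissueParameters(baseline.r_ref_um, baseline.ecv_ref, 0.0),
            baseline).diffusivity[0]

    def _reference_cv(self) -> float:
        key = ("ref", self.h_mm, self.length_mm, self.variant)
        if key not in self._cache:
            self._cache[key] = strand_cv(self._d_ref,
                                         length_mm=self.length_mm,
                                         h_mm=self.h_mm,
                                         variant=self.variant)
        return self._cache[key]

    def cv_from_diffusivity(self, d_cm2_ms: float) -> float:
        """CV (cm/s) of a strand with diffusivity ``d``; 0 if no capture.

        The cable equation is exactly self-similar under x -> lambda*x,
        D -> lambda^2*D, and the strand spacing tracks sqrt(D) to keep
        the discretization error constant, so CV(D) equals the single
        calibrated reference run rescaled by sqrt(D / D_ref) (mode
        'scaled', default).  Mode 'direct' runs a strand per diffusivity
        and is kept for validation.
        """
        key = ("D", self.mode, round(float(d_cm2_ms), 12))
        if key in self._cache:
            return self._cache[key]
        if d_cm2_ms <= 0.0:
            self._cache[key] = 0.0
            return 0.0
        if self.mode == "scaled":
            cv = self._reference_cv() * float(np.sqrt(d_cm2_ms / self._d_ref))
        else:
            # keep h / wavefront-width constant; floor keeps counts sane
            h = float(np.clip(self.h_mm * np.sqrt(d_cm2_ms / self._d_ref),
                              0.02, self.h_mm))
            cv = strand_cv(d_cm2_ms, length_mm=self.length_mm, h_mm=h,
                           variant=self.variant)
        if np.isnan(cv):
            cv = 0.0  # non-capture flagged as zero CV
        self._cache[key] = cv
        return cv

    def cv(self, params: TissueParameters, direction: str = "fiber") -> float:
        """CV (cm/s) along ``direction`` in {'fiber','transverse','normal'}."""
        if direction not in AXIS_INDEX:
            raise ValueError(f"unknown direction {direction!r}")
        d = effective_conductivity(params, self.baseline).diffusivity[
            AXIS_INDEX[direction]]
        return self.cv_from_diffusivity(d)

    def velocity_triple_mm_ms(self, params: TissueParameters) -> tuple[float, float, float]:
        """(v_fiber, v_transverse, v_normal) in mm/ms for the eikonal engine."""
        return tuple(self.cv(params, ax) * 0.01 for ax in AXIS_INDEX)
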