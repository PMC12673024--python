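"""Cohort summaries: derived LV volumes, median/IQR, bull's-eye tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..mesh.aha import WallThicknessMap

__all__ = ["DerivedVolumes", "derived_volumes", "summarize", "bulls_eye"]

MYOCARDIUM_DENSITY_G_PER_ML = 1.05


@dataclass(frozen=True)
class DerivedVolumes:
    """LV mass and extracellular-matrix / cell volume split, BSA-indexed."""

    lv_mass_g: float
    lv_mass_indexed_g_m2: float
    matrix_volume_ml: float
    matrix_volume_indexed_ml_m2: float
    cell_volume_ml: float
    cell_volume_indexed_ml_m2: float


def derived_volumes(lv_volume_ml: float, ecv: float, bsa_m2: float
                    ) -> DerivedVolumes:
    """Mass = 1.05 g/mL x volume; matrix = ECV x volume; cell = (1-ECV) x volume."""
    if lv_volume_ml <= 0 or bsa_m2 <= 0:
        raise ValueError("LV volume and BSA must be positive")
    if not (0.0 <= ecv <= 1.0):
        raise ValueError(f"ECV must be in [0,1], got {ecv}")
    mass = MYOCARDIUM_DENSITY_G_PER_ML * lv_volume_ml
    matrix = lv_volume_ml * ecv
    cell = lv_volume_ml * (1.0 - ecv)
    return DerivedVolumes(
        lv_mass_g=mass, lv_mass_indexed_g_m2=mass / bsa_m2,
        matrix_volume_ml=matrix,
        matrix_volume_indexed_ml_m2=matrix / bsa_m2,
        cell_volume_ml=cell,
        cell_volume_indexed_ml_m2=cell / bsa_m2)


def summarize(values) -> dict:
    """Median and interquartile range (linear-interpolation quartiles)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no observations to summarize")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "n": int(v.size)}


def bulls_eye(wt_pre: WallThicknessMap, wt_post: WallThicknessMap
              ) -> pd.DataFrame:
    """17-segment table with pre, post and post-pre difference columns."""
    df = pd.DataFrame({
        "segment": np.arange(1, 18),
        "pre_mm": wt_pre.thickness_mm,
        "post_mm": wt_post.thickness_mm,
    })
    df["difference_mm"] = df["post_mm"] - df["pre_mm"]
    return df
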