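"""Tissue-parameter sensitivity: how R, ECV and ECF shape conduction.

Re-creates the sensitivity analysis behind the parametrization: strand
conduction velocity as each parameter is swept with the others held at
their defaults.  The expected directions are CV increasing in R and in
ECV, decreasing in ECF (fibrotic occlusion of the extracellular space),
with propagation failing outright when the extracellular space becomes
non-conductive (ECF = 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import (  # noqa: F401  (re-exported module surface)
    BaselineConductivities,
    MonodomainConductivity,
    TissueParameters,
    effective_conductivity,
    load_baseline,
)
from .propagation.calibrate import CvCalibrator

__all__ = [
    "TissueParameters",
    "BaselineConductivities",
    "MonodomainConductivity",
    "effective_conductivity",
    "load_baseline",
    "sensitivity_table",
]


def sensitivity_table(
    r_values_um=np.linspace(9.6, 17.8, 5),
    ecv_values=np.linspace(0.15, 0.35, 5),
    ecf_values=np.linspace(0.0, 0.9, 5),
    baseline: BaselineConductivities | None = None,
    calibrator: CvCalibrator | None = None,
    direction: str = "fiber",
) -> pd.DataFrame:
    """Sweep each parameter; one row per evaluated point.

    Columns: parameter, value, r_um, ecv, ecf, diffusivity_cm2_ms,
    cv_cm_s (0 with captured=False when propagation fails), captured,
    plus a per-parameter ``monotone`` flag repeated on its rows.
    """
    baseline = baseline or load_baseline()
    cal = calibrator or CvCalibrator(baseline)
    rows = []
    sweeps = [
        ("R", [TissueParameters(r_um=float(r)) for r in r_values_um]),
        ("ECV", [TissueParameters(ecv=float(e)) for e in ecv_values]),
        ("ECF", [TissueParameters(ecf=float(e)) for e in ecf_values]),
    ]
    for name, plist in sweeps:
        for p in plist:
            d = effective_conductivity(p, baseline).diffusivity[
                {"fiber": 0, "transverse": 1, "normal": 2}[direction]]
            cv = cal.cv(p, direction)
            rows.append(dict(parameter=name,
                             value={"R": p.r_um, "ECV": p.ecv,
                                    "ECF": p.ecf}[name],
                             r_um=p.r_um, ecv=p.ecv, ecf=p.ecf,
                             diffusivity_cm2_ms=d, cv_cm_s=cv,
                             captured=cv > 0.0))
    df = pd.DataFrame(rows)
    for name, increasing in (("R", True), ("ECV", True), ("ECF", False)):
        sub = df[(df.parameter == name) & df.captured]
        dcv = np.diff(sub.cv_cm_s.to_numpy())
        mono = bool(np.all(dcv > 0) if increasing else np.all(dcv < 0))
        df.loc[df.parameter == name, "monotone"] = mono
    return df
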