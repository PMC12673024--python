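"""Tissue parameters and their mapping to monodomain conductivities.

The tissue substrate is described by three scalars:

``R``
    myocyte radius in µm.  In the cylindrical-cell idealization the
    surface-to-volume ratio is ``beta = 2 / R``, so a larger radius means
    less membrane per unit volume and therefore faster conduction
    (cellular hypertrophy accelerates conduction).
``ECV``
    extracellular volume fraction (0–1).  Scales the extracellular
    conductivity relative to its value at the reference ECV.
``ECF``
    extracellular conductivity factor (0–1).  Fraction of the
    extracellular path occluded by fibrotic content: 0 leaves the
    extracellular conductivity unaltered, 1 makes the extracellular
    space non-conductive.

Monodomain effective conductivity per axis is the harmonic combination
``sigma_i * sigma_e / (sigma_i + sigma_e)`` and the diffusivity is
``D = sigma_mono / (beta * Cm)`` (cm²/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "TissueParameters",
    "BaselineConductivities",
    "MonodomainConductivity",
    "R_BOUNDS_UM",
    "effective_conductivity",
    "load_baseline",
]

#: Admissible myocyte radius range (µm) used during personalization,
#: mean ± 1 SD of radii measured histologically in aortic-stenosis patients.
R_BOUNDS_UM = (9.6, 17.8)

AXES = ("fiber", "transverse", "normal")


@dataclass(frozen=True)
class TissueParameters:
    """(R, ECV, ECF) triple governing tissue conductivity."""

    r_um: float = 15.45
    ecv: float = 0.258
    ecf: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r_um > 0):
            raise ValueError(f"cell radius must be positive, got {self.r_um}")
        if not (0.0 < self.ecv < 1.0):
            raise ValueError(f"ECV must be in (0, 1), got {self.ecv}")
        if not (0.0 <= self.ecf <= 1.0):
            raise ValueError(f"ECF must be in [0, 1], got {self.ecf}")

    def within_personalization_bounds(self) -> bool:
        lo, hi = R_BOUNDS_UM
        return lo <= self.r_um <= hi

    def with_(self, **kw) -> "TissueParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class BaselineConductivities:
    """Reference conductivities (S/m) per axis plus normalization constants."""

    sigma_i: tuple[float, float, float] = (0.17, 0.019, 0.019)
    sigma_e: tuple[float, float, float] = (0.62, 0.24, 0.24)
    cm_uf_per_cm2: float = 1.0
    r_ref_um: float = 15.45
    ecv_ref: float = 0.258

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_i) or any(s <= 0 for s in self.sigma_e):
            raise ValueError("baseline conductivities must be positive")
        if self.cm_uf_per_cm2 <= 0:
            raise ValueError("membrane capacitance must be positive")


@dataclass(frozen=True)
class MonodomainConductivity:
    """Effective monodomain conductivities and diffusivities per axis."""

    sigma_mono: tuple[float, float, float]  # S/m
    beta_per_cm: float  # surface-to-volume ratio, 1/cm
    diffusivity: tuple[float, float, float]  # cm^2/ms
    propagating: bool = True

    def as_array(self) -> np.ndarray:
        return np.asarray(self.diffusivity, dtype=float)


def _harmonic(si: float, se: float) -> float:
    if si <= 0.0 or se <= 0.0:
        return 0.0
    return si * se / (si + se)


def effective_conductivity(
    params: TissueParameters, baseline: BaselineConductivities | None = None
) -> MonodomainConductivity:
    """Map (R, ECV, ECF) to monodomain conductivity and diffusivity.

    Per axis, the extracellular conductivity scales with the extracellular
    volume fraction and is reduced by fibrotic occupancy::

        sigma_e_eff = sigma_e0 * (ECV / ECV_ref) * (1 - ECF)

    while the intracellular conductivity is unchanged.  The radius enters
    only through the surface-to-volume ratio ``beta = 2 / R``.  At
    ``ECF = 1`` the extracellular space is non-conductive and the result
    is a valid zero-conductivity (non-propagating) medium.
    """
    if baseline is None:
        baseline = load_baseline()
    scale_e = (params.ecv / baseline.ecv_ref) * (1.0 - params.ecf)
    sigma_mono = tuple(
        _harmonic(si, se * scale_e)
        for si, se in zip(baseline.sigma_i, baseline.sigma_e)
    )
    r_cm = params.r_um * 1e-4
    beta = 2.0 / r_cm
    # D [cm^2/ms] = 10 * sigma [S/m] / (beta [1/cm] * Cm [uF/cm^2])
    diffusivity = tuple(
        10.0 * s / (beta * baseline.cm_uf_per_cm2) for s in sigma_mono
    )
    return MonodomainConductivity(
        sigma_mono=sigma_mono,
        beta_per_cm=beta,
        diffusivity=diffusivity,
        propagating=all(d > 0.0 for d in diffusivity),
    )


def load_baseline(path: str | None = None) -> BaselineConductivities:
    """Load baseline conductivities from a YAML file (packaged default)."""
    if path is None:
        ref = resources.files("cardiotwin.data") / "baseline_conductivities.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return BaselineConductivities(
        sigma_i=tuple(raw["sigma_i"]),
        sigma_e=tuple(raw["sigma_e"]),
        cm_uf_per_cm2=float(raw["cm"]),
        r_ref_um=float(raw["r_ref"]),
        ecv_ref=float(raw["ecv_ref"]),
    )
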