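"""Activation maps, the QRS surrogate, and CV probe measurements.

The model's QRS duration is approximated by the total activation time of
the ventricles: the span between the earliest stimulus onset and the
latest nodal activation.  CV is measured between two probes a known
geodesic distance apart under apical pacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ActivationMap", "CvMeasurement", "total_activation_time", "measure_cv"]

UNACTIVATED = np.nan


@dataclass
class ActivationMap:
    """Per-node first-activation times in ms (NaN marks unactivated nodes)."""

    times_ms: np.ndarray
    onset_ms: float = 0.0  # earliest stimulus onset

    @property
    def n_nodes(self) -> int:
        return self.times_ms.size

    @property
    def activated_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.times_ms)))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# node activation_ms\n")
            for i, t in enumerate(self.times_ms):
                fh.write(f"{i} {t:.6g}\n")

    @classmethod
    def load(cls, path: str) -> "ActivationMap":
        data = np.loadtxt(path)
        data = np.atleast_2d(data)
        times = np.full(int(data[:, 0].max()) + 1, np.nan)
        times[data[:, 0].astype(int)] = data[:, 1]
        return cls(times_ms=times, onset_ms=float(np.nanmin(times)))


@dataclass
class CvMeasurement:
    probe_a: int
    probe_b: int
    distance_cm: float
    delta_t_ms: float
    cv_cm_s: float
    valid: bool


def total_activation_time(amap: ActivationMap, min_fraction: float = 0.99) -> float:
    """Total activation time in ms: max(activation) - earliest onset.

    Raises if less than ``min_fraction`` of the nodes activated, listing
    how many were missed (propagation failure is a result, not a number).
    """
    frac = amap.activated_fraction
    if frac < min_fraction:
        n_miss = int(np.sum(~np.isfinite(amap.times_ms)))
        raise RuntimeError(
            f"only {frac:.1%} of nodes activated ({n_miss} unactivated); "
            "total activation time undefined")
    return float(np.nanmax(amap.times_ms) - amap.onset_ms)


def measure_cv(amap: ActivationMap, probe_a: int, probe_b: int,
               distance_mm: float) -> CvMeasurement:
    """CV (cm/s) between two probes: geodesic distance / activation delay.

    The measurement is flagged invalid when either probe is unactivated or
    the downstream probe activates first (front arriving from the wrong
    side); the magnitude is still reported for diagnostics.
    """
    ta, tb = amap.times_ms[probe_a], amap.times_ms[probe_b]
    d_cm = distance_mm * 0.1
    if not (np.isfinite(ta) and np.isfinite(tb)) or tb == ta:
        return CvMeasurement(probe_a, probe_b, d_cm, float("nan"),
                             float("nan"), valid=False)
    dt = float(tb - ta)
    cv = d_cm / abs(dt) * 1000.0
    return CvMeasurement(probe_a, probe_b, d_cm, dt, cv, valid=dt > 0)
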