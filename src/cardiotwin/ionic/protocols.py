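"""Single-cell pacing protocols and action-potential metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tp06

__all__ = ["SingleCellResult", "run_single_cell", "apd90"]

#: Default stimulus: 2 ms pulse, roughly 2x diastolic threshold (pA/pF).
STIM_AMPLITUDE = 52.0
STIM_DURATION_MS = 2.0


@dataclass
class SingleCellResult:
    time_ms: np.ndarray
    vm_mv: np.ndarray
    apd90_ms: float
    resting_potential_mv: float
    peak_potential_mv: float
    n_beats_run: int
    steady_state: bool
    captured: bool

    def save_trace(self, path: str) -> None:
        np.savetxt(path, np.column_stack([self.time_ms, self.vm_mv]),
                   header="time_ms vm_mv", comments="# ")


def apd90(time_ms: np.ndarray, vm: np.ndarray) -> float:
    """Action potential duration at 90% repolarization for one beat.

    The beat is assumed to start at rest; APD90 is the time from the
    upstroke (max dV/dt) to the crossing of ``V_peak - 0.9*(V_peak - V_rest)``.
    Returns NaN if no action potential is present.
    """
    vrest = vm[0]
    vpeak = float(np.max(vm))
    if vpeak < 0.0:  # no depolarization
        return float("nan")
    upstroke_idx = int(np.argmax(np.diff(vm)))
    v90 = vpeak - 0.9 * (vpeak - vrest)
    after_peak = np.argmax(vm)
    below = np.flatnonzero(vm[after_peak:] <= v90)
    if below.size == 0:
        return float("nan")
    cross = after_peak + below[0]
    # linear interpolation of the crossing time
    if cross > 0 and vm[cross - 1] > v90:
        t0, t1 = time_ms[cross - 1], time_ms[cross]
        w = (vm[cross - 1] - v90) / (vm[cross - 1] - vm[cross])
        t_cross = t0 + w * (t1 - t0)
    else:
        t_cross = time_ms[cross]
    return float(t_cross - time_ms[upstroke_idx])


def run_single_cell(
    variant: str = "epicardial",
    pacing_cl_ms: float = 600.0,
    n_beats: int = 3,
    dt: float = 0.02,
    quiescent_ms: float = 1000.0,
    stim_amplitude: float = STIM_AMPLITUDE,
    stim_duration_ms: float = STIM_DURATION_MS,
    record_stride: int = 10,
) -> SingleCellResult:
    """Pace a single myocyte: quiescent interval then S1 at ``pacing_cl_ms``.

    Pacing stops early once steady state is reached (APD90 change < 1 ms
    between consecutive beats).  Metrics are taken from the last beat.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    state = tp06.initial_state(variant, n_cells=1)
    p = tp06.variant_params(variant)
    no_stim = np.zeros(1)
    stim = np.array([stim_amplitude])

    n_quiet = int(round(quiescent_ms / dt))
    for _ in range(n_quiet):
        tp06.reaction_step(state, no_stim, dt, p)

    steps_per_beat = int(round(pacing_cl_ms / dt))
    stim_steps = int(round(stim_duration_ms / dt))
    beat_traces: list[np.ndarray] = []
    apds: list[float] = []
    steady = False
    beats_run = 0
    for beat in range(n_beats):
        trace = np.empty(steps_per_beat // record_stride + 1)
        trace[0] = state[0, tp06.IV]
        k = 1
        for step in range(steps_per_beat):
            cur = stim if step < stim_steps else no_stim
            tp06.reaction_step(state, cur, dt, p)
            if (step + 1) % record_stride == 0:
                trace[k] = state[0, tp06.IV]
                k += 1
        trace = trace[:k]
        beat_traces.append(trace)
        t = np.arange(trace.size) * dt * record_stride
        apds.append(apd90(t, trace))
        beats_run = beat + 1
        if beat > 0 and np.isfinite(apds[-1]) and np.isfinite(apds[-2]) \
                and abs(apds[-1] - apds[-2]) < 1.0:
            steady = True
            break

    last = beat_traces[-1]
    t_last = np.arange(last.size) * dt * record_stride
    apd = apds[-1]
    captured = bool(np.isfinite(apd)) and float(np.max(last)) > 0.0
    return SingleCellResult(
        time_ms=t_last,
        vm_mv=last,
        apd90_ms=float(apd),
        resting_potential_mv=float(last[0]),
        peak_potential_mv=float(np.max(last)),
        n_beats_run=beats_run,
        steady_state=steady,
        captured=captured,
    )
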