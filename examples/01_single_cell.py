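"""Pace a single ventricular myocyte and report action-potential metrics.

The ten Tusscher-Panfilov membrane model is paced at a 600 ms cycle
length after a quiescent second.  APD90 is the action-potential
duration at 90% repolarization; the resting potential should sit near
-86 mV for a healthy human ventricular cell.
"""

from cardiotwin.ionic import run_single_cell

res = run_single_cell(variant="epicardial", pacing_cl_ms=600.0, n_beats=4)
print(f"resting potential : {res.resting_potential_mv:7.2f} mV")
print(f"peak potential    : {res.peak_potential_mv:7.2f} mV")
print(f"APD90             : {res.apd90_ms:7.1f} ms")
print(f"steady state      : {res.steady_state} after {res.n_beats_run} beats")
# A capture failure (no depolarization) would be flagged:
print(f"captured          : {res.captured}")
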