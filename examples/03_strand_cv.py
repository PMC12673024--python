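"""Conduction velocity on a 1-D strand and the cable-theory check.

A paced strand of coupled myocytes yields the conduction velocity for a
given diffusivity.  Continuous cable theory predicts CV proportional to
sqrt(D): doubling the diffusivity should multiply CV by sqrt(2) = 1.414.
"""

import numpy as np

from cardiotwin.params import TissueParameters, effective_conductivity, load_baseline
from cardiotwin.propagation import strand_cv

base = load_baseline()
d0 = effective_conductivity(TissueParameters(), base).diffusivity[0]
cv1 = strand_cv(d0)
cv2 = strand_cv(2 * d0)
print(f"fiber diffusivity       : {d0:.3e} cm2/ms")
print(f"CV at default parameters: {cv1:.1f} cm/s "
      "(physiological band 40-90 cm/s)")
print(f"CV at doubled D         : {cv2:.1f} cm/s")
print(f"ratio                   : {cv2 / cv1:.4f}  (sqrt(2) = {np.sqrt(2):.4f})")
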