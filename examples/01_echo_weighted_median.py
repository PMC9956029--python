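"""The descriptor's core idea on the reference 3x3 window.

A window of clean signal (75) with speckle-corrupted pixels (135, 160):
the plain median picks a noisy value, the echo-weighted median does not.
"""

import numpy as np

from echopat import KernelSpec, echo_weights, weighted_median

window = np.array([[135, 75, 75], [135, 75, 75], [160, 135, 135]], dtype=float)
spec = KernelSpec(3, 3)  # default sigma_x = sigma_y = 1.2

w = echo_weights(spec)
print("echo weights (repetition counts):")
print(w)
print("plain median:        ", weighted_median(window.ravel(), np.ones(9, dtype=int)))
print("echo-weighted median:", weighted_median(window.ravel(), w.ravel()))
print()
print("The centre pixel is repeated 3x and its edge-neighbours 2x, so the")
print("median of the 15-element expanded multiset lands on the clean 75")
print("instead of the noisy 135.")
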