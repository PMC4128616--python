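"""Walk through the two-rule quality trimmer on a constructed read.

The read has the canonical shape of a capillary read: a 25-base
low-quality start, a long clean body, and two isolated weak calls deep in
the body.  Rule (a) finds the first 20-base window past base 25 in which
every QV exceeds 20; rule (b), scanning only after 350 bases past that
point, cuts before the first 20-base window containing more than one call
below QV 20.
"""

import numpy as np

from tracepure import Read, TrimParams, subqv_fraction, trim_read

qualities = np.full(600, 40)
qualities[:25] = 8            # 5' ramp
qualities[425] = qualities[430] = 5   # two weak calls past the scan floor

read = Read("walkthrough", "A" * 600, qualities)
result = trim_read(read, TrimParams())

print("status          :", result.status)
print("5' trim start   :", result.start, "(0-based; first retained base)")
print("3' cut point    :", result.end)
print("retained length :", result.retained_length, "bases")
count, fraction = subqv_fraction(result.read.qualities)
print("sub-QV20 calls  : %d of %d (%.2f%%)"
      % (count, result.retained_length, 100 * fraction))
print()
print("The two weak calls sit at offsets 400 and 405 from the trim point;")
print("the first 20-base window holding both starts at offset 386, so the")
print("read is cut there and the weak calls never enter the purity count.")
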