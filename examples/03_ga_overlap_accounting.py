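"""Account for how much geographic atrophy arose from former drusen.

Reproduces the published single-eye pixel accounting — baseline drusen
2,452 px, final GA 4,161 px, overlap 381 px — and prints the two derived
percentages.
"""

import numpy as np

from drusenkit import ga_overlap

drusen = np.zeros(120 * 120, dtype=bool)
ga = np.zeros(120 * 120, dtype=bool)
drusen[:2452] = True
ga[2452 - 381 : 2452 - 381 + 4161] = True

res = ga_overlap(drusen.reshape(120, 120), ga.reshape(120, 120))
print(f"baseline drusen area : {res.drusen_px:>6} px")
print(f"final GA area        : {res.ga_px:>6} px")
print(f"overlap              : {res.overlap_px:>6} px")
print(f"share of GA from former drusen : {res.pct_of_ga_rounded}% "
      f"({res.pct_of_ga:.2f}% unrounded)")
print(f"share of drusen converting to GA: {res.pct_of_drusen_rounded}% "
      f"({res.pct_of_drusen:.2f}% unrounded)")
# Only a small minority of the atrophy sits on former drusen pixels, and
# only a small minority of baseline drusen ends up inside the atrophy —
# drusen regression is mostly not a precursor of GA at the pixel level.
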