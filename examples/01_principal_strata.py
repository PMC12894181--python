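"""Principal-strata accounting from a 2x2 enrolment-by-assignment table.

Under monotonicity, the shares of always-takers, never-takers and
compliers are identified directly from the contingency table of
treatment received (D) against randomised assignment (Z).
"""

import numpy as np

import ivforest as iv

# counts[d, z]: rows = not enrolled / enrolled, columns = control / treated
counts_2009 = np.array([[929, 525], [99, 512]])
tab = iv.CrossTab(counts_2009)

print("contingency table (N =", tab.n, ")")
print(tab.to_frame())
print("within-column percentages:\n", tab.col_pct)

shares = iv.strata_shares(tab, "one_decimal_percent")
print(f"\nalways-takers {shares.p_always}%  never-takers {shares.p_never}%  "
      f"compliers {shares.p_complier}%")
print("The complier share is the complement of the rounded always/never "
      "shares; it equals the first-stage difference P(D=1|Z=1) - P(D=1|Z=0).")

raw = iv.strata_shares(tab, "raw")
print(f"unrounded first stage: {raw.p_complier:.4f}")
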