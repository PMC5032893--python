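"""Stage 2: per-region Distinctiveness, Dominance, and Regional Integrity.

Distinctiveness asks how exclusively a region's genetic clusters occur there
(a rescaled location quotient); Dominance asks how internally homogeneous the
region is (Simpson index).  Both are chance-adjusted so 0 means "what random
labelling would give" and 1 perfect structure; their product is Regional
Integrity, the confidence that an isonymy group marks real population
structure.
"""

import numpy as np
import pandas as pd

import isoregion as ir
from isoregion.correspondence import Contingency

# A hand-made cross-tabulation: region A is pure, B mixes two clusters,
# C holds a cluster that also spills into B.
table = Contingency(pd.DataFrame(
    [[90, 0, 0],
     [0, 40, 20],
     [0, 10, 60]],
    index=["A", "B", "C"], columns=["c1", "c2", "c3"]))

t = ir.integrity_table(table)
print(t.round(3))
# A scores RI = 1: all of cluster c1, nothing else.  B and C trade off
# Distinctiveness (c2/c3 straddle both) against Dominance (B is 2:1 mixed).

print("\nadjustment by hand for region B:")
dom_b = ir.dominance(table)["B"]
print(f"  DOM = {dom_b:.3f}; expected 1/L = {1/3:.3f}; "
      f"adjusted = {ir.adjust_index(dom_b, 1/3):.3f}")
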