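"""Pairwise isonymy and the population-weighted Ward taxonomy on a toy register.

Isonymy eta_ij sums, over shared surnames, the product of bearer counts in the
two areas, normalised by twice the product of the area totals; 0.5 is the
maximum (a single identical surname on both sides), 0 means no shared name.
"""

import pandas as pd

import isoregion as ir

counts = ir.SurnameCounts(pd.DataFrame({
    "area_id": ["i", "i", "j", "j", "k"],
    "surname": ["Smith", "Jones", "Smith", "Evans", "Evans"],
    "count":   [2,       2,       1,       3,       5],
}))

eta = ir.compute_isonymy(counts)
print("isonymy matrix:")
print(eta.to_frame().round(4))
# i-j share only Smith: eta = (2*1)/(2*4*4) = 0.0625; i-k share nothing: 0.

dist = ir.isonymy_to_distance(eta)  # -log(eta), zeros floored first
tax = ir.ward_taxonomy(dist, weights=[10, 10, 10], dialect="D")
print("\nmerge tree (newick):", tax.to_newick())
print("cut at k=2:", ir.cut(tax, 2).labels)
# j and k (sharing Evans) join first; i, carrying the unrelated Smith/Jones
# pool, stays separate at k=2.
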