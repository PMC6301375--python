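"""Survey statistics: do study authors prefer some annotation sources?

Six observers each rank four annotation sources (a gold standard, two
curators, one machine) by how well the annotations capture their
original character descriptions.
"""

import numpy as np

from eqsim import RankTable, anderson_a, friedman_f, paired_signed_rank

sources = ["GOLD", "C1", "C2", "MACHINE"]
# each row: ranks given by one observer (1 = best)
ranks = np.array([
    [1, 2, 3, 4],
    [1, 3, 2, 4],
    [2, 1, 3, 4],
    [1, 2, 4, 3],
    [1, 3, 2, 4],
    [2, 1, 3, 4],
])
table = RankTable(sources=sources, ranks=ranks)

a, df_a, p_a = anderson_a(table)
f, df_f, p_f = friedman_f(table)
print(f"Anderson A = {a:.3f} (df={df_a}, p={p_a:.4f})  -- full rank distribution")
print(f"Friedman F = {f:.3f} (df={df_f}, p={p_f:.4f})  -- mean ranks")
for src, mr in zip(table.sources, table.mean_ranks()):
    print(f"  mean rank {src:8s} {mr:.2f}")
# Low mean rank = preferred.  Here the gold standard is consistently
# ranked near the top and the machine near the bottom; both statistics
# reject rank uniformity at the 5% level.

p = paired_signed_rank([0.9, 0.8, 0.95, 0.7, 0.85], [0.6, 0.5, 0.9, 0.4, 0.7])
print(f"paired signed-rank p (5 states, one condition always higher) = {p}")
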