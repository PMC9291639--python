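"""Enumerate the feasible complete orderings of dual-agent dose grids.

A combination grid with K doses of drug A and L doses of drug B admits
many total orders consistent with within-agent monotonicity (the linear
extensions of the grid poset).  Their number is what makes the ordering
uncertain: a design cannot know which of them generated the data.
"""

import pobench as pb

for K, L in [(2, 2), (2, 4), (3, 3), (3, 5)]:
    grid = pb.DoseGrid(K, L)
    count = pb.count_linear_extensions(grid)
    print(f"{K}x{L} grid: {count} feasible complete orderings")

# the two orderings of the 2x2 grid, as rank matrices (rank 1 = least toxic)
oset = pb.enumerate_linear_extensions(pb.DoseGrid(2, 2))
for s in range(oset.S):
    print(f"ordering {s}: ranks row-major {oset.ranks[s].tolist()}")

# positions incomparable to many others carry less information about the
# complete ordering and get smaller power-likelihood weights
print("3x3 weights:\n", pb.compute_weights(pb.DoseGrid(3, 3)))
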