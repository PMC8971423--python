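"""Walk the neighborhood-entropy score stack on a tiny worked example.

A fully infected 3-node path a–b–c: the two leaves have fewer chances to
have been infected by someone else, so their neighborhood entropy NE
exceeds the center's and both leaves form the core convex set (the SLBNE
prediction).  Prints the per-node table: xi (infected-neighbor intensity),
IE (its entropy), eta (infection degree), AE (adjacency entropy, negative
when a contribution ratio exceeds 1) and NE = AE - 4*IE.
"""

from entroloc import (
    ContactNetwork,
    InfectionSnapshot,
    compute_entropy_table,
    core_convex_set,
)

net = ContactNetwork.from_edges([("a", "b"), ("b", "c")])
snapshot = InfectionSnapshot(network=net, infected=frozenset("abc"))
table = compute_entropy_table(snapshot, alpha=4.0)
print(table.scores.round(5))
core = core_convex_set(snapshot, table)
print(f"core convex set (local NE maxima): {sorted(core.members)}")
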