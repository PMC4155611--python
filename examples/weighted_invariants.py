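"""Weighted graph invariants on a small example, checked against brute force.

A star with a heavy center shows how vertex weights change the classical
picture: the cheapest dominating set is the three light leaves, not the
single center that classical domination would pick.
"""

import networkx as nx

import protier as p

g = nx.star_graph(3)  # center 0, leaves 1..3
weights = {0: 5.0, 1: 1.0, 2: 1.0, 3: 1.0}
nx.set_node_attributes(g, weights, "weight")

lower, upper = p.weighted_domination(g)
print(f"weighted domination: lower = {lower}, upper = {upper}")
print(f"  (classical domination number of a star is 1 — the center;")
print(f"   with weights, the three unit leaves dominate for total 3.0)")
print(f"max weighted degree : {p.max_weighted_degree(g)}  (a leaf sees the heavy center)")
print(f"weighted diameter   : {p.weighted_diameter(g)}  (leaf -> leaf pays 5 + 1)")
print(f"circumference       : {p.circumference(g)}  (stars are acyclic)")

for name in ("weighted_lower_domination", "weighted_upper_domination", "weighted_diameter"):
    oracle = p.brute_force_oracle(g, name)
    print(f"exhaustive oracle {name}: {oracle}")
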