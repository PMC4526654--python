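"""Attractor landscape of a random Boolean network.

Generates a seeded 10-node network (in-degree 2, AND/OR/NOT rules) and
enumerates its attractors by exhaustive asynchronous exploration of all
2^10 states — the same engine the SIN model runs on.
"""

from sinboole import build_stg, find_attractors, random_network
from sinboole.synthetic import RandomNetSpec

net = random_network(RandomNetSpec(n=10, k=2, seed=7))
stg = build_stg(net)
print(f"{stg.n_states} states, {stg.n_transitions} asynchronous transitions")
for i, att in enumerate(find_attractors(net)):
    on = [n for n, b in att.states[0].as_dict().items() if b]
    print(f"attractor {i}: {att.kind}, {len(att)} state(s); first state ON = {on}")
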