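"""Cause-effect analysis of the human-talent sub-criteria.

Runs the total-influence chain on the aggregated direct-relation matrix:
normalization, T = N (I - N)^-1, row/column sums, and the significant-link
threshold.  Dispatchers (D - R > 0) drive the network; receivers absorb
influence.
"""

from ifmcdm import load_fixture, run_chain

elements, Z = load_fixture("human_talent_direct_relation")
result = run_chain(Z, elements)

print(result.to_frame().round(3).to_string(index=False))
print(f"\nsignificance threshold theta = {result.theta:.3f}")
for src, dst, t in result.links:
    print(f"  {src} -> {dst}  (t = {t:.3f})")

# Prominence (D + R) measures how central an element is in the influence
# network; a positive relation (D - R) marks a cause worth intervening on.
graph = result.to_network()
print(f"\ndigraph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} significant links")
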