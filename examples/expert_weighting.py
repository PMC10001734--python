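"""Weight a panel of experts by their knowledge-degree IFNs.

Builds the six-member case-study panel (five rated "very relevant", one
"relevant") and prints each member's relative weight.  The weights govern
how strongly each expert's pairwise judgments count in the aggregation.
"""

from ifmcdm import expert_weights, load_fixture

panel = load_fixture("expert_panel")
weights = expert_weights(panel)

for profile, w in zip(panel, weights):
    mu, nu, pi = profile.importance.as_tuple()
    print(f"{profile.id}: importance ({mu:.2f}, {nu:.2f}, {pi:.2f}) -> weight {w:.6f}")

# The five senior experts each carry ~17.1% of the panel's voice and the
# sixth ~14.3%; the weights sum to 1.
print(f"sum of weights: {weights.sum():.6f}")
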