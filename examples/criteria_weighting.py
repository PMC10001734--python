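"""Derive local priorities from aggregated pairwise judgments.

Loads the aggregated IFN judgment matrix for the healthcare-equipment
sub-criteria, checks its consistency, and extracts entropy-based local
weights from the row-mean IFNs.
"""

from ifmcdm import consistency_ratio, entropy_weights, load_fixture, row_ifn

agg = load_fixture("equipment_aggregated_judgments")

report = consistency_ratio(agg)
print(f"consistency ratio: {report.cr:.3f} "
      f"({'acceptable' if report.consistent else 'revise judgments'})")

rows = row_ifn(agg)
for element, ifn in zip(agg.elements, rows):
    print(f"{element}: row IFN ({ifn.mu:.3f}, {ifn.nu:.3f}, {ifn.pi:.3f})")

weights = entropy_weights(rows, agg.elements)
for element in agg.elements:
    print(f"{element}: local weight {weights.local[element]:.3f}")
# A CR below 0.10 means the pooled judgments are coherent enough to trust;
# the local weights are the cluster's relative priorities and sum to 1.
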