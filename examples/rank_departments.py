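"""Rank three emergency departments with the combined compromise solution.

Loads the 35-KPI decision matrix (with global weights and benefit/cost
directions), runs CoCoSo at lambda = 0.5, and prints the performance index
and ranking together with each department's weakest indicators.
"""

from ifmcdm import cocoso, load_fixture

M = load_fixture("decision_matrix")
result = cocoso(M, lam=0.5)

print(result.to_frame().round(3).to_string(index=False))
print(f"\nranking (best first): {' > '.join(result.ranking())}")

for alt in result.alternatives:
    weak = result.weak_subcriteria[alt]
    print(f"{alt}: weakest sub-criteria {weak[:5]}")

# M is the overall performance index: the geometric-plus-arithmetic blend
# of the three appraisal scores.  Sub-criteria with normalized value near 0
# are the department's natural intervention points.
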