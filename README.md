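# ifmcdm

Intuitionistic-fuzzy multi-criteria decision analysis for performance
evaluation under expert uncertainty, built around three composable stages:

1. **IF-AHP weighting** — expert panels judge decision elements pairwise on
   a linguistic scale; judgments are intuitionistic fuzzy numbers (IFNs)
   `(μ, ν, π)` carrying membership, non-membership, and hesitancy with
   `μ + ν + π = 1`. Each expert receives a weight
   `ω_k ∝ μ_k + π_k μ_k / (μ_k + ν_k)` from their knowledge-degree IFN,
   judgments are pooled cell-wise with the intuitionistic fuzzy weighted
   average `IFWA(μ) = 1 − Π(1 − μ_k)^{ω_k}`, `IFWA(ν) = Π ν_k^{ω_k}`,
   consistency is checked with Saaty's ratio `CR = ((λ_max − n)/(n − 1))/RI`,
   and local priorities come from an intuitionistic fuzzy entropy measure;
   global weights compose multiplicatively down the hierarchy.
2. **IF-DEMATEL influence analysis** — influence judgments are defuzzified
   through `μ(x) = ½(1 + μ − ν)` and the triangular mapping
   `x = l + μ(x)(m − l)` on support (0, 4), averaged across the panel,
   normalized by the largest row/column sum, and propagated through the
   total-influence matrix `T = N(I − N)⁻¹`. Row sums **D** (influence
   dispatched) and column sums **R** (influence received) give each
   element's *prominence* `D + R` and *relation* `D − R`; elements with
   `D − R > 0` are causes ("dispatchers"), the rest effects ("receivers").
   Links with `t_ij` above the matrix mean `θ = Σ t_ij / n²` form the
   impact digraph.
3. **CoCoSo ranking** — alternatives measured on weighted, min-max
   normalized KPIs are scored by additive (`S_i = Σ w_j r_ij`) and power
   (`P_i = Σ r_ij^{w_j}`) comparability, combined into three appraisal
   scores and the compromise index
   `M_i = (M_ia M_ib M_ic)^{1/3} + (M_ia + M_ib + M_ic)/3`,
   which ranks the alternatives and, per alternative, flags the weakest
   sub-criteria as intervention points.

The package ships the complete printed record of a case study evaluating
three hospital emergency departments on 8 criteria and 35 sub-criteria
during a respiratory-disease outbreak, plus a seeded synthetic expert-panel
generator, so every stage is testable end to end without external data.

Audience: health-systems and operations analysts ranking service units
from expert judgment plus KPI data, and anyone needing a tested
IF-AHP / IF-DEMATEL / CoCoSo reference implementation.

## Worked example

Rank the three case-study departments (`examples/rank_departments.py`):

```python
from ifmcdm import cocoso, load_fixture

M = load_fixture("decision_matrix")       # 3 departments x 35 KPIs
result = cocoso(M, lam=0.5)
print(result.to_frame().round(3).to_string(index=False))
```

```
alternative     S      P    Ma    Mb    Mc     M  rank
         D1 0.737 27.896 0.350 2.604 0.933 2.243     2
         D2 0.784 29.904 0.375 2.781 1.000 2.400     1
         D3 0.554 21.913 0.275 2.000 0.732 1.740     3
```

`S` and `P` are the additive and power comparabilities, `Ma/Mb/Mc` the
appraisal scores (D2 attains both maxima, hence `Mc = 1`; D3 both minima,
hence `Mb = 2`), and `M` the final performance index: D2 is the strongest
department, D3 needs the most intervention. `result.weak_subcriteria`
lists each department's near-worst indicators, e.g. D1's shortfalls in
life-support certification (SH21) and bed availability (SH5).

Cause-effect analysis of the human-talent cluster
(`examples/influence_network.py`):

```
element      D      R  prominence  relation       role
   SH19 16.532 16.394      32.926     0.138 dispatcher
   SH20 17.222 16.377      33.599     0.844 dispatcher
   SH21 15.898 16.973      32.871    -1.075   receiver
   SH22 16.256 16.164      32.420     0.093 dispatcher
```

Staffing levels (SH19, SH20, SH22) drive the cluster; life-support
certification (SH21) is the effect. The threshold `θ = 4.119` selects six
significant links for the impact digraph.

There is one short script per capability under `examples/`, and a thin CLI
(`ifmcdm weights|dematel|cocoso|evaluate|generate|fixtures`) for running
the same stages from CSV files; see `ifmcdm --help`.

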