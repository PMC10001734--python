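# Methods

This note documents the models implemented in `ifmcdm`, the parameters
that matter, the numerical choices made where the published record of the
method is silent, and what the synthetic generator does and does not
emulate.

## Intuitionistic fuzzy numbers and scales

An IFN is a pair `(μ, ν)` with `μ, ν ∈ [0, 1]` and `μ + ν ≤ 1`; the
hesitancy `π = 1 − μ − ν` is always recomputed, never stored, so the
triple cannot drift out of the simplex. Validity is checked with an
absolute tolerance of `1e-9` to absorb rounding in aggregated values.

Three linguistic scales ship as built-ins:

| scale | labels | crisp support |
|---|---|---|
| `ahp_relevance` | much less … much more relevant | (0, 1) |
| `dematel_influence` | no … very high influence | (0, 4) |
| `expert_importance` | very irrelevant … very relevant | (0, 1) |

Scales are overridable via a JSON file (`load_scale`). The triangular
support accepts an optional third parameter `u`, but the linear
defuzzification `x = l + μ(x)(m − l)` never uses it; it is carried only so
externally specified triangular numbers round-trip.

**Defuzzification chain.** The `C_φ` operator collapses an IFN to a
classical membership by splitting the hesitancy: `μ_φ = μ + φπ`. We fix
`φ = 0.5` — the value minimising the Euclidean distance between the IFN
and its classical image — giving `μ(x) = ½(1 + μ − ν)`. Chained with the
influence scale's support (0, 4), the five influence labels map to the
crisp scores {0.4, 1.5, 2.1, 3.1, 3.6}. The (0, 4) support is the one the
packaged case study uses; both it and `φ` are parameters, not constants.

**IFWA.** Aggregation uses `μ = 1 − Π(1 − μ_k)^{w_k}`, `ν = Π ν_k^{w_k}`
with weights on the simplex. Products are evaluated in log space; the
convention `0^w = 0` for `w > 0` means one certain judgment (`ν_k = 0`)
with positive weight zeroes the pooled non-membership. A rounding guard
clamps `Π ν^w ≤ Π (1−μ)^w` so the output always satisfies the IFN
invariants.

## Weighting stage (IF-AHP)

- **Expert weights.** Score `μ_k + π_k μ_k/(μ_k + ν_k)`, normalized.
  Undefined when `μ_k = ν_k = 0` (fully hesitant expert) — rejected rather
  than patched, since such a profile carries no usable information.
- **Consistency.** The aggregated IFN matrix has no canonical crisp form,
  so we build a Saaty-type positive reciprocal matrix: upper-triangle
  cells are defuzzified with `φ = 0.5`, the diagonal is forced to 1, and
  the lower triangle is the reciprocal of the upper. The principal
  eigenvalue then yields `CR = ((λ_max − n)/(n − 1))/RI` with Saaty's
  random indices for `n = 3..10` (extendable via `ri_table`). `CR` is 0 by
  definition for `n ≤ 2`. Inconsistent matrices (`CR ≥ 0.10`) raise a
  warning and are reported, never silently repaired: the remedy is revised
  judgments.
- **Priorities.** Per-element row IFNs are the arithmetic means of the
  row's `μ` and `ν` components (this is the reduction the case study's
  printed intermediate values follow; weighted IFWA row pooling gives
  slightly different values). The entropy
  `e_i = −(1/ln 2)[μ ln μ + ν ln ν − (1 − π) ln(1 − π) − π ln 2]`
  (with `x ln x → 0` at 0) gives `w_i ∝ 1 − e_i`, normalized to sum to 1.
  Any constant prefactor of the entropy cancels in that normalization,
  which is why a typographically ambiguous scaling in the source
  formulation is immaterial. The classical principal-eigenvector
  extraction is provided alongside (`eigenvector_weights`) and is the one
  that provably recovers a generating priority vector from consistent
  judgments.
- **Hierarchy.** Global weight = local weight × parent criterion weight;
  over a complete two-level hierarchy the globals sum to 1.

## Influence stage (IF-DEMATEL)

- Per-expert grids are defuzzified cell-wise through the chain above with
  the diagonal forced to 0 (no self-influence). The fully hesitant pair
  `(0, 0)` is used as the diagonal placeholder in IFN grids.
- Aggregation across experts is the **unweighted** mean — a deliberate
  asymmetry with the weighting stage, matching the method's definition of
  the aggregated direct-relation matrix.
- The **convergence index** is the mean absolute relative change between
  the panel mean and the mean without the last expert, over off-diagonal
  cells, divided by `n(n − 1)`; ≤ 0.05 counts as internally consistent.
  Cells whose reference value is 0 are skipped with a logged warning (the
  source is silent on zero denominators). With one expert the index is
  undefined and skipped with a warning.
- Normalization divides by `s = max(max row sum, max col sum)`; the total
  influence `T = N(I − N)⁻¹` is computed by a dense linear solve after
  checking the spectral radius of `N` is strictly below 1 — divergence is
  an error (with the radius reported), not a warning, and there is no
  pseudo-inverse fallback.
- `θ = Σ t_ij / n²` (the mean total influence); edges require `t_ij > θ`
  strictly, and `D − R = 0` exactly classifies as receiver (the dispatcher
  rule is strict).

## Ranking stage (CoCoSo)

Min-max normalization by direction; a constant column maps to `r = 1` for
every alternative ("all tied at best") so fully tied indicators still
contribute their weight to the power comparability — mapping them to 0
would silently delete their weight from `P`. `Mb` is undefined when an
alternative scores 0 on both comparabilities; this is reported as an error
with guidance rather than patched. `λ` defaults to 0.5; ranks break ties
lexicographically by alternative id. The weakness report flags
non-constant sub-criteria with `r ≤ cutoff` (default 0.1), ordered by
weight.

Performance banding of the index (high ≥ 0.75, urgent ≤ 0.25) is an
interpretation on `M` relative to the instance's maximum, since raw `M`
values are typically 1–3.4; the package reports raw `M` and leaves banding
to the caller.

## Packaged case study

The fixtures store the printed record of a three-department evaluation at
its printed precision, with two curated additions flagged
`"reconstructed"`:

- the **direction vector** of the decision matrix is not part of the
  printed record. The staffing and accessory indicators are defined as
  *quantities needed to balance demand* (shortfalls), hence cost; with
  that reading the whole chain reproduces the printed comparabilities to
  ~2 d.p. and the printed ranking. It is configurable per column.
- the **aggregated direct-relation matrix** is printed at 3 d.p., but its
  cells are panel means of six crisp scores and therefore exact multiples
  of 0.1/6; the fixture stores the exact values, which reproduce the
  printed downstream scores to 3 d.p. (the rounded cells drift in the
  third decimal).
- the printed appraisal table mixes precisions: most entries follow from
  its rounded comparability columns, one row from unrounded values. Tests
  assert each value on the route that generates it.
- the printed weight column sums to 1.004 from rounding; the loader
  renormalizes.

## Synthetic generator

`generate_panel` emulates a panel judging one cluster. Relevance judgments
encode a hidden increasing priority vector with bounded log-gaps (so every
pairwise ratio is representable as a membership in [0.05, 0.95] at the
fixed hesitancy `π = 0.1`); expert noise multiplies ratios by
`exp(N(0, noise²))`. Defaults — 6 experts, 4 elements, noise 0.1, an
importance distribution of 5:1 "very relevant" to "relevant", and an
influence-label distribution weighted toward the mid-to-high labels —
mirror the case-study panel's composition and judgment profile. Influence
grids draw labels i.i.d. per cell.

What passing tests on synthetic panels show: the algebraic invariants
(IFWA validity, conservation `ΣD = ΣR`, Neumann-series equivalence of
`T`, permutation equivariance, zero-noise parameter recovery) hold on
realistic input shapes. What they do not show: real expert panels are not
i.i.d. label draws — judgments correlate across cells and experts, and
influence structure is not exchangeable — so calibration claims about real
panels cannot be read off these tests. The lower triangle of generated
relevance matrices mirrors the upper (`1 − c`) rather than being an
independent judgment; only the upper triangle enters consistency and
priority computations.

## Numerical choices and limitations

- Tolerances: IFN validity `1e-9`; weight-vector sums `1e-6`; fixture
  comparisons `5e-4` against 3-d.p. prints.
- Eigenvalues via dense `numpy.linalg.eig`; fine for the `n ≤ 15` matrix
  orders the CR table supports.
- The two fuzzy stages share experts but not weights (influence
  aggregation is unweighted); coupling them (ANP-style supermatrices,
  weighted DEMATEL) is out of scope, as are alternative score functions
  for defuzzification and fuzzy extensions of the ranking stage.
- Problem sizes throughout tests and the acceptance script are the case
  study's own (6 experts, clusters of 3–8 elements, 3 alternatives × 35
  sub-criteria); all computations are O(n³) or better and run in
  milliseconds.
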