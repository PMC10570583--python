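# Methods

## The model

`smcrisk` ranks risk factors in a two-level hierarchy (goal → criteria →
sub-criteria) by the Analytic Hierarchy Process, with the distinguishing
feature that the pairwise judgments at the sub-criteria level are *derived
from surveillance statistics weighted by consequence severity* rather than
elicited from surveys. The assumption underlying the whole construction is
that a factor's importance is proportional to the total societal cost of
the incidents it is involved in, and that cost is adequately summarized by
a per-severity-class multiplier.

### Severity cost factors

Each severity class gets an integer cost factor: the ratio of its average
per-event cost to that of the cheapest (reference) class, rounded half-up,
floored at 1. Integer rounding is deliberate — the factors are meant as
coarse, communicable multipliers ("a fatal crash costs ~332× a
property-only crash"), not precise actuarial quantities. The normalized
severity factor of class *c* is

    s_c = k_c n_c / Σ_k k_k n_k ,

the share of cost-weighted incident counts in class *c*. It is invariant
to rescaling all monetary costs (only cost *ratios* enter) and strictly
monotone in each class's count.

The shipped US-2019 schema uses per-event costs of $1,565,000 (fatal),
$20,235 (injury) and $4,711 (property damage), giving factors 332 / 4 / 1,
and 2019 counts 33,244 / 1,916,000 / 4,806,000, giving s = (0.470, 0.326,
0.204). The fatal per-event figure is itself an aggregate-cost quotient
(≈ $52e9 over 33,244 crashes = $1,564,192); the shipped value keeps the
conventionally rounded $1,565,000, and `per_event_cost` returns unrounded
quotients so callers control presentation. Either value yields the same
integer factor 332.

### Evidence weighting

A factor's raw share of incidents in class *c* (a fraction of all
incidents of that severity attributed to the factor) is multiplied by
`s_c` and expressed in percent; the per-factor sum over classes is its
*importance score*. Shares within a criterion group are **not**
renormalized to 100%: factors do not partition incidents (one crash can
involve several factors), so the raw columns carry meaningful absolute
scale. Files may hold either already-weighted shares or raw shares plus a
severity schema; a `# weighted=` header flag distinguishes them, because
published tables typically print only the weighted form.

### Quantization onto the Saaty scale

Importance-score ratios are continuous; AHP judgments live on the discrete
1–9 scale. The quantizer maps a ratio r ≥ 1 to `floor(r)`, bumped up by
one when the fractional part reaches a threshold (default 0.25), clamped
to [1, 9]; ratios below 1 map to the reciprocal of the quantized inverse,
so reciprocity is exact by construction. The threshold is the one genuinely
free parameter of the construction: 0.25 is the simplest single-parameter
rule consistent with treating a ratio of, say, 1.36 as "moderately more
important" (→ 2) while 1.12 stays "equal" (→ 1). It is configurable, and a
per-cell override map expresses explicit expert dissent — an override on
(i, j) forces the reciprocal cell too, so overridden matrices remain valid.
The mapping is monotone on r ≥ 1 and satisfies q(r)·q(1/r) = 1.

The criteria level is different in kind: there is usually no single
statistic comparing, e.g., "environment" to "driver state", so the
criteria matrix is accepted directly as an expert judgment (exact
rationals like `"1/4"` are parsed exactly). Matrices above order 9 are
rejected by default — Saaty's scale does not discriminate beyond 9 — with
an explicit opt-out.

### Weighting, λmax and consistency

The default weight vector is the principal eigenvector, computed by power
iteration from the uniform vector with sum-normalization each step
(tolerance 1e-12 on the max component change, cap 10,000 iterations; for a
consistent matrix the iteration is exact after one step). The classical
row-mean-of-normalized-columns approximation is kept as `method="rowmean"`
because published AHP tables are often computed that way; for matrices
passing CR < 0.10 the two agree to a few parts in a thousand.

λmax is estimated as `mean_i (A w)_i / w_i`. At the exact principal
eigenvector this *is* the principal eigenvalue; it equals n exactly iff A
is consistent and is ≥ n otherwise. CI = (λmax − n)/(n − 1); CR = CI/RI
with Saaty's random indices {3: 0.58, 4: 0.90, …, 8: 1.41}; CR < 0.10
passes. Order 2 admits no independent triple, so CR is defined as 0 and
always passes; RI values for orders 9–10 (1.45, 1.49) are available behind
an `allow_extended` flag.

Reports carry consistency at two precisions: full precision, and a display
convention where CR is recomputed from λmax rounded to 4 decimals. The
display convention matches how such tables are conventionally printed
(λmax published at 4 dp, CR derived from the published value); the
full-precision report is authoritative for the CR < 0.10 gate.

### Synthesis and ranking

Global leaf weight = local leaf weight × parent criterion weight; since
each local set sums to 1, globals sum to 1. Ranking is competition-style
(ties share the smallest applicable rank; the next rank is skipped), with
ties detected after rounding weights to 3 decimals — at full precision
almost nothing ties, and 3 dp matches the precision at which the weights
are reported and consumed.

## Comparator methods

BWM and FUCOM are included to check rank robustness against the AHP route.
Both are solved in their original nonlinear min-max form (minimize the
largest constraint deviation over the open weight simplex) by SLSQP from a
deterministic list of starts (uniform, a consistency-based hint, and
corner-pulled points), cross-checked in the test suite against a
brute-force simplex grid search at orders ≤ 4. The nonlinear form is used
deliberately: ranks, not weight intervals, are being compared.

Their inputs are derived from the same severity-weighted evidence: best
and worst are the score argmax/argmin, and all comparison vectors are
quantized score ratios using the same quantizer as the AHP matrices. At
the criteria level, where only the expert matrix exists, the comparison
vectors are read directly off that matrix (best row, worst column;
consecutive entries along the priority order for FUCOM). This is one
plausible operationalization of "the same information, different
elicitation format"; comparator weights therefore inherit every choice
made upstream, and only their *ranks* should be treated as findings.

A genuine limitation: for n > 3 with inconsistent input, the nonlinear BWM
optimum is not unique — distinct weight vectors can attain the same
minimal ξ. The solver returns one optimizer deterministically; tests
compare weights to the grid oracle only where the optimum is unique, and
compare objective values otherwise.

## Synthetic data

`generate_pcm` draws ground-truth weights from a symmetric Dirichlet
(components clipped at 1e-3 and renormalized so ratio entries stay
finite-scale), builds exact ratio entries, and perturbs the upper triangle
multiplicatively by exp(ε), ε ~ N(0, σ²), mirroring ε across the diagonal
with opposite sign so reciprocity stays exact while transitivity degrades
smoothly. σ therefore dials the consistency ratio: σ = 0 gives CR = 0;
σ = 0.05 at n = 4 keeps ~95%+ of draws under CR < 0.10; mean CR rises
monotonically with σ. Optional Saaty quantization composes the generator
with the production quantizer. All randomness flows through one seeded
`numpy` generator.

What the generator emulates is the *judgment* layer only: reciprocal
matrices of varying consistency around a known ground truth. It does not
simulate surveillance data (counts, shares, severity misclassification),
so passing property tests demonstrate correctness of the weighting and
ranking machinery, not robustness to real-world data pathologies upstream
of the evidence table.

## Numerical choices and degenerate inputs

- Power iteration: tol 1e-12, max 10,000 iterations; non-convergence
  raises with the residual (positive matrices are primitive, so in
  practice this fires only on pathological near-zero entries).
- Reciprocity validation tolerance 1e-6 relative (published matrices are
  printed at ~3 significant digits); diagonal and positivity exact.
- Min-max solvers: SLSQP, ftol 1e-14, weight floor 1e-9; the reported
  ξ/χ is recomputed from the returned weights, not taken from the
  optimizer state.
- Degenerate inputs raise typed errors: all-zero severity counts, missing
  evidence cells, zero scores in ratio denominators (with the factor
  labels in the message), unweighted hierarchy nodes, matrix orders
  outside the RI table.
- Display rounding is fixed (weights 3 dp, λmax 4 dp, CR 6 dp, percent
  integer) and applied only at the report boundary; JSON reports keep full
  precision alongside, and repeated runs are byte-identical.

## Problem sizes in the test suite

Property tests run at orders 2–8 with 30–100 seeded replicates per
property, and the grid oracles sweep the simplex at a 0.01–0.02 coarse
step refined locally to 1e-4 — sizes at which the brute-force checks are
exhaustive enough to be meaningful while the whole suite stays fast.

## Known limitations

- The quantizer threshold is a modeling choice; different thresholds can
  change quantized matrices and hence ranks. Sensitivity beyond the
  threshold parameter (e.g. alternative scales) is out of scope.
- Severity cost factors are national-average approximations and change
  year to year; no inflation adjustment or cost uncertainty is modeled.
- Single-expert matrices only: no group aggregation, no fuzzy or interval
  judgments, no incomplete-matrix completion.
- Importance scores treat per-class shares as given; if a data source
  defines shares against a different denominator, the scores change
  accordingly.
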