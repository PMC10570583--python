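# smcrisk

Semi-quantitative multi-criteria risk ranking for injury surveillance data.

`smcrisk` ranks risk factors (for example, driving hazards such as impaired
driving, road design, or weather) by combining **objective incident
statistics weighted by consequence severity** with **expert judgment**,
inside an Analytic Hierarchy Process (AHP) framework. It is aimed at risk
and safety analysts who have per-factor incident shares by severity class
and want a defensible, reproducible factor ranking rather than a purely
survey-based one.

## Method

1. **Severity cost factors.** Each severity class *c* (e.g. fatal /
   injury / property-only) gets an integer cost factor
   `k_c = round(cost_c / cost_ref)` relative to the cheapest class, then a
   normalized severity factor

   ```
   s_c = k_c · n_c / Σ_k k_k · n_k
   ```

   where `n_c` is the annual incident count — the share of total
   cost-weighted incidents attributable to class *c*.

2. **Severity-weighted evidence.** A factor's raw share of incidents in
   class *c* is multiplied by `s_c`; summing over classes gives its
   *importance score*, in percent.

3. **Pairwise-comparison matrices.** Score ratios are quantized onto
   Saaty's 1–9 scale (floor, bumped up when the fractional part reaches a
   configurable threshold, default 0.25) to build positive reciprocal
   matrices `A` with `a_ij ≈ w_i / w_j`; the criteria level accepts a
   directly supplied expert matrix, and individual cells can be overridden
   by expert judgment.

4. **AHP weighting and consistency.** Priority weights are the principal
   eigenvector of `A` (power iteration; the classical row-mean
   approximation is also available). Consistency uses Saaty's ratio
   `CR = CI / RI` with `CI = (λmax − n)/(n − 1)`; matrices with
   `CR ≥ 0.10` are rejected (or warned about), and `λmax` is estimated as
   `mean_i (A·w)_i / w_i`.

5. **Synthesis and ranking.** Global leaf weight = local weight × parent
   criterion weight; competition ranking with tie detection at 3 decimals.

Best-Worst Method (BWM) and Full Consistency Method (FUCOM) solvers are
included as comparators; they share the same severity-weighted evidence
front-end, so the three methods can be compared on identical inputs.

## Worked example

The package ships the US-2019 road-crash case study (severity costs and
counts, per-factor severity shares, and the expert criteria matrix over
environment / driver state / driver behavior):

```python
from smcrisk import us2019_fixture, run_pipeline, render_report

schema, tables, config = us2019_fixture()
print(schema.cost_factors)
# {'Fatal': 332, 'Major': 4, 'Minor': 1}
print({k: round(v, 3) for k, v in schema.normalized_factors.items()})
# {'Fatal': 0.47, 'Major': 0.326, 'Minor': 0.204}

report = run_pipeline(config)
print(render_report(report, format="text"))
```

which ends with:

```
Ranking
factor       weight  percent   rank
R5            0.390      39%     1
R7            0.230      23%     2
R9            0.145      14%     3
R8            0.091       9%     4
R3            0.045       5%     5
R6            0.043       4%     6
R2            0.024       2%     7*
R4            0.024       2%     7*
R1            0.008       1%     9
```

Driving under the influence (R5) carries 39% of the total risk weight;
decision errors (R7) 23%; weather (R1) 1%. The `*` marks the two factors
tied at rank 7, and each level's report carries `λmax`, CI, RI and CR
(all four matrices here pass CR < 0.10).

The same study runs from the shell:

```
smcrisk run --config src/smcrisk/data/us2019_study.yaml -o report.json
smcrisk compare --config src/smcrisk/data/us2019_study.yaml -o comparison.json
smcrisk simulate --n 4 --sigma 0.05 --seed 42 --replicates 100 -o sim.json
```

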