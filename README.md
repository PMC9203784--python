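# crossimpact

Cross-impact matrix and network-influence analysis for systems of policy
goals, in the style of participatory "SDG Synergies" assessments.

In such an assessment, a stakeholder group scores every ordered pair of
goals on the Weimer-Jehle seven-point scale — integers from −3 (strongly
restricting) through 0 (no influence) to +3 (strongly promoting) — answering
"if progress is made on goal X, how does this influence progress on goal Y?".
The scores form a **cross-impact matrix** W with an undefined diagonal
(goals are never scored against themselves); read as a weighted directed
network G = (N, L), it supports questions such as *which goal most strongly
drives the whole agenda?* and *which synergies and trade-offs only appear at
second order?*

`crossimpact` provides:

- validated construction of seven-point cross-impact matrices from score
  lists, DataFrames or CSV, with precise error reporting;
- network influence analysis — for each goal g:
  - first-order influence (weighted out-degree) `D_g^Out = Σ_j w_gj`,
  - second-order influence along length-2 paths
    `I²(A→D) = Σ_i w_Ai · w_iD` (with `I²(g→g)` the feedback-loop strength),
  - total net influence `I_g^Total = D_g^Out + Σ_{j≠g} w_gj · D_j^Out`,
  - competition-ranked goal lists with rank shifts between the first-order
    and total orderings, and focal-goal perspectives;
- interaction classification (synergy / trade-off / neutral) and matrix
  composition summaries;
- multi-group workshop score reconciliation: discrepancy detection between
  breakout groups and consensus resolution (manual decisions, median, or
  rounded mean);
- direction-recoded paired-observation Pearson correlation of goal-indicator
  time series (values re-oriented so that larger always means progress; years
  paired by exact match, no interpolation);
- seeded synthetic-data generators for matrices, noisy group scores and
  indicator series, plus bundled fixtures from the Cambodia CSDG assessment
  (the 17-goal registry, the child-health row/column of the matrix, and the
  key-indicator table).

All influence arithmetic is exact integer arithmetic.

## Worked example

The bundled Cambodia fixture embeds the child-health (goal 3, alias `CH`)
row and column of the assessed matrix; the remaining cells are unknown and
here left at zero (child health's own statistics do not depend on them):

```python
from crossimpact import CrossImpactModel
from crossimpact.synthetic import cambodia_child_health_matrix

results = CrossImpactModel(cambodia_child_health_matrix()).fit()
persp = results.focal("CH")
print(persp.first_order_out["1"], persp.first_order_out["15"], persp.feedback)
print(results.influence.loc["3", ["out_degree", "in_degree", "total"]].to_dict())
```

prints

```
3 0 30
{'out_degree': 16, 'in_degree': 29, 'total': 46}
```

meaning: child health strongly promotes goal 1 (no poverty, score +3), has
no direct influence on goal 15 (life on land, score 0), carries a positive
second-order feedback loop of +30 (progress on child health indirectly
reinforces itself through the other goals), sums +16 of direct influence
onto the network and receives +29 from it.

Correlating recoded indicator trends:

```python
from crossimpact import progress_correlation
from crossimpact.synthetic import cambodia_indicator_series, get_indicator

series = cambodia_indicator_series()
res = progress_correlation(get_indicator(series, "3", "mortality"),
                           get_indicator(series, "15", "Forest"))
print(round(res.r, 4), res.n_overlap, res.years)
```

prints

```
-0.8834 4 (2000, 2005, 2010, 2015)
```

falling under-five mortality (progress) coincided with falling forest cover
(regress): a strong negative progress correlation over the four shared
observation years.

A command-line interface mirrors the library
(`crossimpact validate | analyze | rank | perspective | classify |
consensus | simulate | correlate | export`); run `crossimpact --help`.

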