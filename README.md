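# epiprior

A multi-criteria decision-analysis (MCDA) engine for **One Health
prioritisation of epidemic-prone disease risks and diseases**. It is
built for the facilitators of co-creation workshops in which
stakeholders from human, animal and environmental health jointly decide
which risk factors and which diseases deserve scarce surveillance and
control resources. The engine takes the workshop's raw elicitation
files and produces auditable shortlists, criterion weights, composite
scores, and per-group and combined rankings.

## The method

Two candidate streams — *risk factors* and *diseases* — run through the
same five stages:

1. **Selection.** Each participant votes to include or exclude every
   candidate; candidates are shortlisted by total include votes. Ties
   at the cutoff are kept and flagged, never silently dropped.
2. **Criterion weighting (AHP).** Each group compares the stream's
   weighted criteria pairwise on the Saaty 1–9 ratio scale (risk:
   *scope of exposure*, *frequency of exposure*, *mitigation strategy*;
   disease: *severity*, *prevalence*, *transmissibility*, *preventive
   and control strategy*). The full positive reciprocal matrix
   (3×3 = 9 cells for risks, 4×4 = 16 for diseases) is expanded from
   the elicited upper triangle and the weights **w** are its principal
   eigenvector, normalised to Σwᵢ = 1. Judgment reliability is reported
   as the consistency ratio CR = [(λ_max − n)/(n − 1)] / RI(n); CR > 0.1
   is flagged.
3. **Scoring.** Each group scores every shortlisted item 1–3 on each
   criterion against a fixed three-level rubric (larger is always
   riskier/worse — note a score of 3 on the strategy criteria means *no*
   strategy exists).
4. **Composite scores.** Per item and group,
   `composite = (Σ_c s_c · w_c) × m`, where *m* is the raw 1–3 score on
   the stream's unweighted multiplier criterion (*potential for
   outbreak* for risks, *disease burden* for diseases). Composites lie
   in [1, 9].
5. **Ranking.** Composites are min-max normalised within each group,
   `(x − min)/(max − min)`, ranked per group with competition ranking
   (ties share a rank: 1, 1, 3), and combined across groups as the mean
   of the normalised scores. Ties are reported for stakeholder
   consensus and can be resolved through audited manual overrides.

A synthetic-workshop generator (`epiprior.simulate`) produces complete,
seeded input bundles with controllable group count, judgment
consistency and score distributions, and a weight-recovery experiment
measuring how well AHP recovers known true weights under judgment
noise.

## Worked example

Generate a synthetic 5-group workshop and run the full pipeline:

```sh
epiprior simulate --seed 11 --out demo
epiprior run --workshop demo
```

The run writes `shortlist_*.csv`, `weights.csv`, `composites.csv`,
`ranking_*.csv`, `report.txt`/`report.html` and `run_log.json` into
`demo/`. The report begins:

```
Disease stream
--------------
Top 5 by combined rank (mean-normalised):
rank  item  label                             combined_score
----  ----  --------------------------------  --------------
1     DZ10  Kyasanur forest disease           0.7308
2     DZ06  Crimean-Congo haemorrhagic fever  0.7141
3     DZ22  Candidate disease 22              0.5954
4     DZ28  Candidate disease 28              0.4500
5     DZ21  Candidate disease 21              0.4334

Consistency flags (CR > 0.1): none
Ties requiring consensus: none
Degenerate groups (all composites equal): none
```

Reading this: DZ10 had the highest mean min-max-normalised disease
burden score across the five groups (0.73 of the way from each group's
worst to best item, averaged); no group's pairwise judgments exceeded
the CR = 0.1 reliability threshold; and no ties need stakeholder
resolution. `weights.csv` holds each group's criterion weights with
λ_max, CI and CR, e.g.

```
group,stream,criterion,weight,lambda_max,CI,CR,flag
G1,disease,severity,0.52392275931511567,4.0022296564803543,...,0
```

Library use mirrors the CLI:

```python
import epiprior as ep

bundle = ep.load_bundle("demo")
ep.run_pipeline(bundle, upto="ranking")
print(bundle.rankings["disease"].combined_rank)
```

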