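# ipcnet

Tools for studying how the modelled complexity of paediatric patient cases
relates to health professionals' perceived complexity and their preferences
for interprofessional collaboration (IPC), using factorial vignette design,
per-participant correlation aggregation and social-network analysis of
team-member co-selections.

The package is aimed at health-services researchers running (or re-running)
vignette questionnaires of this shape: respondents score systematically
modelled patient cases on 0–100 sliders, indicate whether an
interprofessional team meeting is needed, and select the team members who
should certainly attend.

## What it implements

**Case design.** Vignettes vary the five ICF domains (personal factors,
environmental factors, body functions, activities, participation) over
three complexity levels, a 3⁵ = 243 full factorial. Modelled complexity of
a case is the sum (5–15) and product (1–243) of its levels. A questionnaire
design is a 13-case subset balanced on per-domain level counts (low and
high five times each, medium three times, with one domain at 5/5/3); the
fixed 13-case design of the reference study is built in, decodable from its
case ids via the canonical base-3 encoding
`case_id = 1 + Σ_d (level_d − 1)·3^(5−d)`.

**Synthetic cohorts.** Because the original questionnaire responses are not
public, a simulator generates respondent cohorts with the structure the
analysis assumes: per-respondent baselines μ_j, complexity sensitivities
β_j, noise σ_j and completion probabilities π_j, logistic meeting
indication, and logistic per-member team selection with core members
near-always chosen and peripheral members increasingly chosen as complexity
rises.

**Analysis.** Per respondent: mean-centring (MC) of the slider scores and
within-respondent mid-rank transformation (RT); then a Pearson correlation
r_j per respondent for each variable pair, aggregated with weights w_j =
completed cases:

    R_weighted = Σ w_j r_j / Σ w_j
    95 % CI_weighted = R_weighted ± 1.96 · s_w   (truncated to [−1, 1])

with s_w the weighted SD of the r_j — the interval describes
inter-individual variation. Per case, a co-selection network over the fixed
15-member roster (edge weight = respondents selecting both members) with
from-scratch degree, Brandes betweenness and component-restricted closeness
centralities, density 2E/(N(N−1)), and Kendall tau-b associations between
density and modelled/perceived complexity.

## Worked example

```python
from ipcnet import (PipelineConfig, run_pipeline)

report = run_pipeline(PipelineConfig(seed=1, n_respondents=110))
c = report["counts"]
print(c["retained_respondents"], round(c["meeting_yes_pct"], 1))
s = report["correlations"]["sum~perceived"]
print(round(s["r_weighted"], 3), round(s["ci_low"], 3), round(s["ci_high"], 3))
print(round(report["density_vs_complexity"]["density~sum"]["tau"], 3))
```

prints

```
101 49.3
0.741 0.233 1.0
0.931
```

Of 110 simulated respondents, 101 complete more than half the cases and
enter the analysis; 49.3 % of their case responses indicate a team meeting.
The weighted correlation between rank-transformed modelled sum complexity
and MC/RT perceived complexity is 0.741, with a weighted CI of [0.233, 1]
whose width reflects the simulated spread in individual sensitivities (the
upper truncation at 1 is typical when strong responders saturate). Kendall
tau-b of 0.931 says per-case team-network density rises almost
monotonically with modelled complexity.

The same pipeline is available from the shell:

```
ipcnet design --paper --out design.csv
ipcnet simulate --design design.csv --n 110 --seed 1 --out responses.csv
ipcnet preprocess --design design.csv --responses responses.csv --out processed.csv
ipcnet correlate --processed processed.csv --out correlations.json
ipcnet network --design design.csv --responses responses.csv --out networks/
ipcnet run --seed 1 --out run/        # all stages, writes run/report.json
```

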