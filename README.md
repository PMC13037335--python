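# pcskit

Polyconnectomic scoring of individual functional connectomes, and the
family-clustered statistical models that turn those scores into
neural-vulnerability analyses.

## The problem

Resting-state fMRI summarises a person's brain as a functional connectome:
the matrix of Pearson correlations between the mean BOLD signals of atlas
parcels.  Meta-analyses of patient–control studies provide, for the same
atlas, a *connectome summary statistic* (CSS) template: a Cohen's d per
connection describing how that edge differs in a disorder such as major
depression.  The **polyconnectomic score** (PCS) collapses the comparison of
an individual connectome with such a template into one number,

```
PCS = (1/n) Σᵢ βᵢ · Cᵢ        over the n edges with βᵢ ≠ 0
```

where Cᵢ is the individual's correlation at edge i and βᵢ the template
weight.  Correlations enter raw (no Fisher-Z) and no further scaling is
applied.  A higher score means the individual's connectivity pattern aligns
more closely with the disorder-related pattern — a continuous vulnerability
index, not a diagnosis.

pcskit implements the score, the template format and its contribution
summaries (top edges, within/between-network blocks), and the inference
layer of a two-wave twin-cohort study design: standardized linear
mixed-effects models with a family random intercept, stress × score
moderation with conditional slopes at ±1 SD and a fixed-effects ΔR²,
change-score construction, Bonferroni correction, balanced tertile
subgrouping, and covariate-adjusted group ANCOVA.  Because the cohorts such
analyses are built on are access-restricted, the package ships a synthetic
twin-family generator with planted, recoverable ground truth — parcel time
series whose covariance is shifted along the template pattern in proportion
to a latent vulnerability that also moderates stress–symptom coupling — so
every stage is testable end to end.  See `docs/methods.md` for the model
details and what the generator does and does not emulate.

Audience: researchers working with connectome-based risk scores or
simulation-validated mixed-model pipelines, and anyone needing a fully
synthetic but statistically faithful twin-cohort testbed.

## Worked example

```python
import numpy as np
from pcskit.connectome_fc import EdgeVector, edge_index_pairs
from pcskit.pcs_scoring import CSSTemplate, compute_pcs

labels = ["a", "b", "c"]
template = CSSTemplate(
    template_id="demo", atlas_id="atlas3",
    weights=np.array([2.0, 0.0, -1.0]),           # one silent edge
    edge_index=edge_index_pairs(3), parcel_labels=labels,
    network_partition={p: "net" for p in labels},
)
edges = EdgeVector("subj", np.array([0.5, -0.2, 0.1]), edge_index_pairs(3))
res = compute_pcs(edges, template)
print(res.score, res.n_nonzero)
```

prints `0.45 2`: two informative edges, (2·0.5 + (−1)·0.1)/2 = 0.45.  The
middle edge has weight 0 and cannot move the score.

## The analysis study

The numbered drivers under `analysis/` run the full synthetic study — a
407-subject twin cohort (298 returning at follow-up, ~20 months later) plus
an 80-subject clinical-like arm — through simulation, connectome
construction, scoring against four templates, and the model stages:

```
python analysis/01_simulate_cohort.py       --seed 1
python analysis/02_connectomes_and_scores.py --seed 1
python analysis/03_baseline_models.py       --seed 1
python analysis/04_longitudinal_models.py   --seed 1
python analysis/05_sensitivity_templates.py --seed 1
python analysis/06_clinical_exploration.py  --seed 1
python analysis/07_report.py                --seed 1
```

At seed 1 the longitudinal stage prints, among others:

```
298 subjects with both waves; fitted 24 models
  moderation delta_depression ~ delta_stress x score: beta = 0.095,
  dR2 = 0.0097, p = 0.034 (n.s. after correction); simple slopes 0.394 -> 0.585
```

— the score moderates the coupling between rising stress and rising
depressive symptoms (the planted interaction is 0.15 on the latent scale;
the estimate is attenuated because the score is a noisy proxy of the latent
vulnerability), and the simple-slope spread shows the coupling is about
half again as strong at +1 SD of the score as at −1 SD.  The sensitivity
stage shows the three alternative disorder templates do not moderate
(all p > 0.3), and the clinical stage finds the strongest stress–severity
association in the high-score tertile plus a significant covariate-adjusted
score elevation in the clinical arm (F = 4.30, p = 0.039).

The same stages are available as a console tool (`pcskit simulate|fc|score|
analyze|report --seed 1 --out-dir results/study`), and every stage writes
plain CSV/TSV files plus a JSON manifest, so intermediate results are
inspectable and two runs with the same config are byte-identical.

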