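# oscnet

Oscillation-resolved, graph-theoretic nodal analysis of resting-state
brain networks.

Resting-state BOLD fluctuations carry information in distinct frequency
bands: slow-5 (0.01–0.027 Hz), slow-4 (0.027–0.073 Hz) and slow-3
(0.073–0.198 Hz).  Clinical connectomics studies — for example of
Parkinson's disease across early and middle stages — ask whether
specific brain regions change their network role *within particular
bands*, which a single broadband analysis can blur or miss.  `oscnet`
is for researchers running (or methodologically probing) that kind of
analysis: it builds band-limited functional connectomes from ROI time
series, computes sparsity-integrated nodal graph metrics, and runs the
full covariate-adjusted group-inference stack on top, with a synthetic
cohort generator that makes every stage testable end to end.

## The method

For each subject and band, the 112-region parcellation yields a
Pearson correlation matrix between band-filtered ROI time courses,
Fisher r-to-z transformed.  Each matrix is binarized at sparsities
S ∈ {0.05, 0.10, …, 0.50} by keeping the round(S·6216) strongest edges,
and three nodal metrics are computed on every graph:

* degree centrality  k_i = Σ_j a_ij
* betweenness centrality  b_i = Σ_{s≠i≠t} σ_st(i)/σ_st
* nodal efficiency  E_i = (1/(N−1)) Σ_{j≠i} 1/d_ij

each integrated over the grid into a threshold-free AUC per node.
Group differences in nodal AUCs are tested with a GLM (age, sex, head
motion as covariates) at the false-positive threshold p < 1/N = 1/112
≈ 0.009, Bonferroni-shared across pairwise group contrasts; significant
nodes feed partial-correlation screens against motor scores (tremor =
UPDRS items 20–21; akinesia/rigidity = items 22–27 + 31, each
controlling the other) and logistic-regression discrimination
summarized by an ROC curve and its Youden operating point.  Band-wise
fALFF (the band's amplitude fraction of the full spectrum) is computed
alongside as a local-activity counterpart.

The synthetic generator plants band-specific hub effects on the latent
correlation scale and can tie their per-subject severity to a clinical
subscale, so null calibration and effect recovery of the entire
pipeline are measurable.  See `docs/methods.md` for the model,
assumptions, and design choices.

## Worked example

```python
from oscnet import CohortSpec, OscillationNodalModel
from oscnet.cohort import CovariateModel, default_parkinson_effects

effects, link = default_parkinson_effects()   # slow-5 putamen increase (MPD),
                                              # slow-3 occipital decrease driving AR score
spec = CohortSpec(
    n_per_group={"MPD": 20, "NC": 20},
    planted_effects=effects,
    covariate_model=CovariateModel(motor_link=link),
    seed=42,
)
results = OscillationNodalModel.from_cohort_spec(spec).fit()
print(results.summary())

tab = results.contrast_table("degree", "slow-5", contrast=("MPD", "NC"))
print(tab.loc[tab["significant"], ["node", "t_value", "p_value", "direction"]])
```

Output:

```
Oscillation-resolved nodal network analysis
==============================================
nodes: 112   sparsity grid: 0.05..0.50 (10 points)
bands: slow-3, slow-4, slow-5
metrics: degree, betweenness, efficiency
subjects included/total: 36/40
  NC: 19
  MPD: 17
exclusions by rule: {'motion': 1, 'cognition': 3, 'scrubbing': 0}
nodal significance threshold (single contrast): 0.009

     node   t_value   p_value direction
22     22  3.502305  0.001424    MPD>NC
34     34 -3.635726  0.000994    MPD<NC
59     59 -5.029818  0.000020    MPD<NC
91     91 -3.670391  0.000905    MPD<NC
100   100  2.941713  0.006127    MPD>NC
108   108  3.086734  0.004240    MPD>NC
```

Four of forty subjects were excluded by the motion and
education-weighted MMSE rules.  Node 100 is the left putamen-analog —
one of the two planted slow-5 hubs — detected with the planted
direction (MPD > NC) below the 0.009 threshold.  At this deliberately
small demonstration size the right putamen (node 101) narrowly misses
the threshold and a handful of other nodes pass, partly spillover onto
the planted partner community and partly the ~1 false positive per
analysis that the 1/112 threshold is designed to admit; at the study's
group sizes (49/36) both hubs are recovered in ~95% of replicate
cohorts with off-band rates near the null level (see
`oscnet.experiments`).

A YAML-driven command line covers the same pipeline for scripted runs:
`oscnet run --config config.yaml --seed 7`, with `simulate`, `metrics`
and `stats` subcommands and NIfTI ROI extraction for image inputs.

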