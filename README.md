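# agingphases

Discovery and characterization of latent aging phases from fused
multi-omics similarity networks.

## The problem

Human aging is usually modeled as a smooth progression indexed by
chronological age, yet molecular data suggest it moves through
discrete stages: groups of individuals whose transcriptomes and
methylomes resemble each other more than their birth dates would
predict. This package implements an end-to-end analysis that

1. **discovers** such stages without using age labels, by fusing
   per-omics subject-similarity networks (Similarity Network Fusion)
   and spectral clustering of the fused network, with the number of
   clusters chosen by the eigen-gap criterion;
2. **orders and validates** the stages as aging phases: clusters are
   ranked by median chronological age, a linear methylation clock
   quantifies biological vs chronological age, and a quartile rule
   flags subjects who are chronologically old but molecularly young
   (and vice versa);
3. **characterizes** the phases biologically: gene-set *predictivity*
   (cross-validated accuracy of a bagged-tree classifier restricted to
   a set's genes) traces which hallmark-style pathways are informative
   in which phase, hierarchical clustering of those profiles recovers
   the succession of primary → secondary → integrative hallmarks, and
   PLAGE pathway activity with a grouping ANOVA shows phases segregate
   pathway signal better than plain age bins;
4. **quantifies transcriptional noise**: the drop in pairwise
   whole-profile correlation between subjects of the last phase;
5. **tracks individuals over time**: a classifier trained on the top
   differential features per omics layer assigns follow-up samples to
   phases (multiclass performance scored by the Hand–Till AUC) and a
   transition summary reports stability and direction of movement.

Because no public cohort ships with the package, it includes a
synthetic-cohort generator (`agingphases.simulate`) whose defaults
emulate the statistical structure the analysis targets: 86 adults aged
21–76, four latent phases along a hidden biological-age axis, nine
phase-patterned gene sets in three archetypes, a 200-CpG linear clock,
two measurement batches, and doubled residual noise in the last phase.
Every generated cohort carries its ground truth, so every stage of the
pipeline is testable against known answers.

## Worked example

```python
import agingphases as ap

cohort = ap.generate_cohort(ap.CohortConfig(seed=0))
ages = cohort.metadata.set_index("subject_id")["chron_age"]

disc = ap.discover_phases([cohort.expr, cohort.meth], ages=ages, seed=0)
print(disc.n_clusters)                  # 4 (eigen-gap = 0.740 at K=4)
print(disc.assignment.summary)
#        n  median_age  mean_age
# phase
# 1     19        26.8      27.8
# 2     22        42.5      42.8
# 3     20        55.2      54.5
# 4     25        69.2      68.4
```

On this cohort the recovered phases match the latent truth exactly
(adjusted Rand index 1.000) and chronological age segregates strongly
across them (ANOVA F = 239.8, p = 1.8e-40). Clock validation on the
same cohort: "young-like" outliers (chronologically old for their
phase) average −7.0 years of clock-minus-chronological deviation,
"old-like" ones +1.7 years; the phase-3 → phase-4 transcriptional-noise
contrast drops the median inter-subject correlation from 0.965 to 0.920
(one-sided rank-sum p = 1.7e-44); and on a 3-year follow-up of 31
subjects the phase classifier reports 90% stability with three forward
and zero backward transitions.

The `examples/` directory walks through each capability as a narrative
script with printed output:

| script | shows |
| --- | --- |
| `01_simulate_cohort.py` | cohort anatomy, ground truth, GMT round-trip, clock accuracy |
| `02_phase_discovery.py` | SNF, eigen-gap K selection, phase ordering, recovery ARI |
| `03_clocks_and_outliers.py` | quartile outlier rule, clock deviations, group tests, logistic association |
| `04_hallmark_succession.py` | predictivity profiles, succession clustering, PLAGE + grouping ANOVA |
| `05_transcriptional_noise.py` | within-phase correlation drop and its exchangeable-null control |
| `06_longitudinal_followup.py` | phase classifier, Hand–Till AUC, transition matrix |

## Layout

- `src/agingphases/` — library: `io`, `simulate`, `preprocess`,
  `fusion`, `phases`, `enrichment`, `predictivity`, `noise`,
  `longitudinal`, `pipeline`
- `examples/` — narrative walkthroughs (run with `python examples/...`)
- `scripts/acceptance.py` — end-to-end reproduction script
- `docs/methods.md` — model, algorithms, parameter choices, limitations
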