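# netreconf

Rest-to-task brain network reconfiguration analysis for ROI-level fMRI time
series.

When the brain switches from the resting state to a task state, its
functional network reorganises: global efficiency rises, modularity falls,
and the interplay between task-**act**ivated regions (Act) and the
complementary **l**ess-**act**ivated regions (L-Act) changes. `netreconf`
implements the full analysis chain needed to quantify that reconfiguration —
from raw ROI time series to connectivity networks to graph statistics and
group inference — together with a seeded synthetic-cohort generator that
plants a known reconfiguration, so every stage of the pipeline can be
validated against ground truth at desk scale.

The package is aimed at researchers analysing paired rest/task ROI time
series (e.g. parcellated BOLD data acquired in two phase encodings) and at
methodologists who want a tested, reproducible reference implementation of
the underlying graph statistics.

## The analysis

Per subject and state, ROI time series are band-pass filtered
(0.009–0.08 Hz), nuisance-regressed (motion-like confounds and their
derivatives, tissue means) and, for task runs, residualised against the mean
task activity. Connectivity is Pearson correlation with Fisher z transform;
the two phase-encoding networks are averaged, negative connections set to
zero, and the matrix binarised at fixed edge densities (5/10/15%). On the
binary network *A* the package computes:

- **Global efficiency** — E = (1/(N(N−1))) Σ_{i≠j} 1/d_ij with d_ij the
  shortest path length (Dijkstra; unreachable pairs contribute 0). *Areal*
  efficiency applies the same formula to the subgraph induced by the Act or
  L-Act region.
- **Interaction strength** — I = (1/(K·L)) Σ_{i∈Act, j∈L-Act} A_ij, the
  normalised count of edges crossing between the Act region (size K) and the
  L-Act region (size L).
- **Modularity** — Q = (1/2w) Σ_{ij} [A_ij − γ·w_i w_j/(2w)] δ(g_i, g_j),
  maximised by best-of-100-restarts Louvain at resolution γ = 1.
- **Fractional modularity** — Q_f, the portion of the Q summation
  contributed by node pairs engaging a region, under a *both-nodes* or
  *at-least-one-node* eligibility rule, optionally normalised by the
  eligible-pair count C(k, 2) or by the region size k. Unnormalised, the
  at-least-one sum of a region plus the both-nodes sum of its complement
  reconstructs Q exactly.
- **Participation coefficient and flexibility** — PC_i = 1 − Σ_m
  (k_im/k_i)², and node flexibility F_k = PC_task,k − PC_rest,k, averaged
  within functional subnetworks.

Act masks come from a two-level GLM: per-subject fixed-effects z statistics
of each ROI against the haemodynamic task regressor, then a group one-sample
test thresholded at z > 2.32 (positive direction only). Group inference uses
paired t tests, 10,000-permutation sign-flip tests, Benjamini–Hochberg (or
Storey) FDR correction, a two-way repeated-measures ANOVA on Act vs L-Act
fractional modularity, and partial correlations adjusted for sex and age.
Consensus ("representative") partitions across subjects are built from a
permutation-null-thresholded module-allegiance matrix, and partitions are
compared with the pair-counting z-Rand score.

## Worked example

```python
import netreconf as nr

spec = nr.CohortSpec(n_subjects=12, seed=42)          # synthetic cohort
cohort = nr.gen_cohort(spec)
config = nr.PipelineConfig(cohort=spec, densities=(0.15,), restarts=50,
                           n_perm=2000, seed=42)
model = nr.NetworkReconfiguration.from_cohort(cohort, config=config)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Rest-to-task network reconfiguration
====================================================
subjects: 12   densities: [0.15]

State means (over subjects):
state                         rest    task
density metric
0.15    E_global            0.3009  0.4260
        E_lact              0.3297  0.4284
        I                   0.0315  0.0521
        Q                   0.7602  0.5801
        ...

Group tests:
 density task   metric                 test  statistic        p    p_fdr  n
    0.15 task E_global             paired_t   4.779773 0.000572 0.001429 12
    0.15 task E_global   paired_permutation   0.125118 0.002999      NaN 12
    0.15 task        Q             paired_t  -4.906139 0.000467 0.001429 12
    0.15 task        I             paired_t   2.883632 0.014874 0.020872 12
    0.15 task   E_lact             paired_t   2.819008 0.016697 0.020872 12
    ...
```

Reading the output: in the task state the cohort's global efficiency rises
(0.30 → 0.43, paired t = 4.78, FDR-corrected p = 0.0014) while modularity
falls (0.76 → 0.58) — the planted reconfiguration the generator encodes. The
L-Act region's internal efficiency rises alongside the global change, and
the Act/L-Act interaction strength shifts significantly. `results.metrics`
holds the tidy per-subject table, `results.node_pc` the participation
coefficients, `results.flexibility` the node flexibility, and
`results.plot_efficiency()` draws the per-state box plot.

The same pipeline is scriptable from the shell:

```bash
netreconf simulate --out cohort_dir --seed 1
netreconf run-all --out out_dir --seed 1
```

with stage-wise subcommands (`preprocess`, `activation`, `connectome`,
`metrics`, `modularity`, `stats`) that exchange plain-text TSV/MTX/JSON
artifacts.

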