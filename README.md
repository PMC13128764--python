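# cortclust

Unsupervised phenotyping of early postoperative cortisol trajectories
after transsphenoidal surgery for Cushing's disease.

After resection of an ACTH-secreting pituitary adenoma, serum cortisol
is measured every 6 h (up to 96 h) to judge whether the corticotroph
axis is shutting down.  Interpretation is complicated by missing data:
values after replacement steroids begin are clinically meaningless and
must be discarded, and patients start steroids at different times.
`cortclust` is aimed at endocrine-neurosurgery researchers who want to
ask, on such ragged time series, *how many distinct recovery
trajectories exist and what distinguishes the patients following them*.

The toolkit:

- **k-POD clustering** of partially observed trajectory matrices —
  k-means made robust to missing cells by alternating centroid-based
  completion with Lloyd updates — as a scikit-learn-style estimator
  (`KPOD`), with cluster quality measured by the fit-integrity statistic
  `fit = 1 − WCSS/TSS` computed over observed cells only;
- **elbow-based selection of K** with the full fit curve reported for
  visual inspection (`elbow_select`);
- **restart-stability convergence diagnostics** that flag samples too
  small or too homogeneous to cluster (`diagnose_convergence`);
- a **two-pass procedure** (`TwoPassTrajectoryClusterer`): cluster the
  full follow-up, find the contiguous run of timepoints where the
  clusters separate significantly, re-cluster within that window;
- **trajectory features** (initial 6 h cortisol, nadir, 6→18 h descent
  velocity) and a **group-comparison battery** (Welch t / one-way ANOVA
  / chi-square, each with summary-statistic entry points) corrected by
  Benjamini–Hochberg step-up;
- a **synthetic cohort generator** reproducing the published cluster
  profiles (three remission clusters mixed 23/15/39 of n = 77, one
  non-remission profile of n = 17), steroid censoring and sporadic
  missingness, so the whole pipeline is exercisable without any data
  download.

## Worked example

Simulate the default remission cohort, cluster it end to end, and
compare covariates across the recovered clusters:

```sh
cortclust full --seed 0 --out demo/
```

prints

```
n=77 K=3 window=[6.0, 12.0, 18.0, 24.0, 30.0, 36.0] battery m=23 alpha=0.0196 -> demo
```

meaning: all 77 synthetic patients had at least one observed value; the
elbow on the fit curve `[0.0, 0.483, 0.65, 0.712, 0.764, 0.808]`
(K = 1..6) selects **K = 3**; the per-timepoint ANOVAs across the
pass-1 clusters are significant at every grid point
(p from 1.7e-18 to 1.4e-6), so the re-clustering window spans the whole
6–36 h grid; and the covariate battery ran m = 23 tests with a BH
threshold of 0.0196.  `demo/` then contains per-patient labels,
centroid curves, the window report, the per-timepoint test table, the
battery table, and three figures (cluster mean ± SD curves, per-cluster
spaghetti, observed/censored counts per timepoint).  In the battery
table the trajectory-derived features separate the clusters — e.g.

```
variable,test,group0,group1,group2,p_value,significant
descent_velocity,anova,1.4 ± 1.2,-0.1 ± 1.3,1.3 ± 2.5,0.0074,*
```

one recovered cluster *rises* before falling (negative descent
velocity), the hallmark of the published slow-decline phenotype, while
demographic and tumor variables do not separate.

The same objects are available programmatically:

```python
import cortclust as cc

cohort = cc.generate_cohort(cc.default_remission_config(seed=0))
out = cc.two_pass_cluster(cohort, seed=0)
out["elbow"].selected_k      # 3
out["window"].timepoints     # array([ 6., 12., 18., 24., 30., 36.])
out["pass2"].fit             # 0.650
```

On the small homogeneous non-remission cohort the same call raises
`NonConvergenceError` with a machine-readable reason — the package's
operationalization of "clustering failed to converge for this group".

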