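# olfica

Group spatial ICA and task-modulated functional connectivity (ICA–gPPI) for
olfactory task fMRI, with a synthetic cohort simulator for end-to-end
validation.

## The problem

Odor identification declines early in Alzheimer's disease, and carriers of
the ApoE ε4 allele are at elevated genetic risk. A way to probe the neural
side of this is to scan older adults while they smell and identify odorants,
decompose the task BOLD into brain networks, and ask how network engagement
and network coupling during correct (*hit*) versus incorrect (*miss*)
identifications depend on ε4 carrier status, odor-identification ability
(SDOIT score, 0–8) and mean odor familiarity (1–10) — including their
interactions.

`olfica` implements that analysis chain as a tested, reusable pipeline:

1. **Group spatial ICA** — two-stage PCA reduction (subject-level to *l₁*
   dimensions, then group-level to *C*), MDL model-order selection on the
   eigenspectrum, natural-gradient **infomax** unmixing, **ICASSO** stability
   selection (re-run from random starts, cluster pooled estimates by |r|,
   keep centrotypes with quality index *I_q*), and **GICA3**
   back-reconstruction of subject maps/timecourses (subject maps average
   exactly to the aggregate map). Maps are z-scored over the mask.
2. **Temporal sorting** — components are ranked by the mean over
   subjects/runs of |Pearson r| between their timecourses and the generic
   HRF-convolved stimulus regressor (a short, 10-s double-gamma kernel);
   components with |r| > .2 are retained as task-relevant, and per-subject
   hit/miss activation betas are estimated by multiple regression.
3. **TMFC (hybrid ICA–gPPI)** — per subject and retained component, a
   voxelwise GLM with hit, miss and seed (component timecourse) main effects,
   the centered seed × centered condition interaction regressors, and a full
   nuisance block: 24-parameter motion expansion, 5 aCompCor components,
   spike regressors at FD > 1 mm or standardized DVARS > 2, and a 0.01-Hz
   DCT high-pass basis. The interaction betas are the TMFC maps.
4. **Group statistics** — one-sample t maps of subject component maps
   (voxel p < .0001, cluster extent k ≥ 100); moderated multiple regression
   of activation betas and TMFC maps on ApoE, SDOIT, familiarity, sex and age
   with ApoE×SDOIT, ApoE×familiarity, SDOIT×familiarity and the three-way
   interaction (continuous predictors mean-centered; voxel p < .001,
   k ≥ 75 for maps); marginal-means tables for plotting interactions.
5. **Synthetic cohort generator** — no public dataset accompanies the design,
   so the package ships a first-class simulator: 2 runs/subject, 8 odorants ×
   4 presentations per run in 16-s stimulation+choice events with 16-s
   baselines, TR = 2 s, logistic hit probability in SDOIT, planted spatial
   networks with covariate-moderated hit amplitudes (three-way coefficient
   0.078 by default) and a hit-specific seed→target coupling gain for the
   gPPI stage, AR(1) + drift + thermal noise, and reproducible per-subject
   seeds.

## Worked example

```bash
olfica simulate --out data --n-subjects 12 --seed 5 --reps-per-run 2
olfica run --dataset-dir data --output-dir deriv --ica-order 5 --icasso-runs 5
```

prints

```
retained 4/5 components: [2, 3, 4, 0]
retained components: [2, 3, 4, 0]
results written to deriv
```

and `deriv/task_relevance.tsv` holds the sorting table:

```
component  mean_abs_corr  retained
2          0.598          True
3          0.579          True
4          0.559          True
0          0.457          True
1          0.151          False
```

Four recovered networks correlate strongly with the expected hemodynamic
response and pass the |r| > .2 retention rule; the fifth (component 1,
|r| = 0.151) is the covariate-moderated network, whose hit amplitude is
reduced in ε4 carriers — in this 12-subject draw it falls below the
retention threshold, exactly the kind of boundary behaviour the rule
produces on real cohorts. The manifest records ICASSO stability
(`iq: [0.985, 0.968, 0.967, 0.966, 0.965]` here), the retained set, every
threshold, and a hash for reproducibility; `condition_betas.tsv` and the
per-component cluster tables follow the same layout as the group analyses.

As a library:

```python
from olfica import CohortSpec, generate_cohort, run_group_ica

cohort = generate_cohort(CohortSpec(n_subjects=10, reps_per_run=2), seed=1)
mask = cohort.ground_truth.analysis_mask
mats = [np.vstack([b.data[mask].T for b in runs]) for runs in cohort.bold]
cset = run_group_ica(mats, c=5, n_runs=10, base_seed=0)
cset.stability_iq          # ICASSO quality indices, all > 0.95 here
```

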