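# bhq

Quotient scoring of brain maps and the full statistical battery of a
two-group pre/post lifestyle-intervention study, exercised end to end on
synthetic neuroimaging cohorts.

## The problem

Diffusion-MRI fractional anisotropy (FA) and voxel-based gray-matter (GM)
volume are widely used markers of white-matter integrity and brain structure.
A convenient way to summarize them per person is an IQ-style quotient: after
spatial normalization, every voxel of an individual map is standardized
against a reference population,

    Q(v) = 100 + 15 * (x(v) - mean(v)) / sd(v),

where `mean` and `sd` are voxelwise images over the reference scan pool. The
quotient image is averaged within the regions of a labeled atlas, and the
unweighted mean across regions gives a participant-level score (FA-BHQ from
FA maps; GM-BHQ from smoothed, intracranial-volume-proportional GM maps).
By construction the defining cohort has mean 100 and SD 15 under the
population-SD convention, so about 95% of people score between 70 and 130.

Intervention studies built on these scores use a standard battery: baseline
pooled two-sample t-tests, a 2x2 Time-by-Group mixed-ANOVA interaction with
partial eta squared (algebraically the squared pooled t on change scores),
within-group paired t-tests with Cohen's d = t/sqrt(n), Pearson tests of
brain-change vs behavior-change correlations, Fisher r-to-z comparisons of
those correlations between groups, Benjamini-Hochberg control over the
regional family, and a noncentral-t power analysis. This package implements
every one of those pieces from its defining formula, plus a synthetic cohort
generator so the whole pipeline is testable without any scan data.

## Worked example

Simulate a trial at the design size (35 per group, pre/post, latent-coupled
change structure), fit the battery, and read off the headline numbers:

```python
from bhq import SimConfig, generate_cohort_frame, analyze_study

frame, manifest = generate_cohort_frame(SimConfig(seed=1))
results = analyze_study(frame)

row = results.longitudinal.set_index("measure").loc["fa_bhq"]
print(f"F = {row['F']:.3f}, p = {row['p_interaction']:.3f}, "
      f"partial eta^2 = {row['partial_eta_sq']:.3f}")

ci = results.correlations["intervention"]
r = ci[(ci.behavior == "poms_va") & (ci.brain == "fa_bhq")].iloc[0]
print(f"vigor change correlation: r = {r['r']:.3f}, p = {r['p']:.3f}")

z = results.fisher.query("behavior == 'poms_va' and brain == 'fa_bhq'").iloc[0]
print(f"Fisher z vs control: z = {z['z']:.3f}, one-sided p = {z['p_one_sided']:.3f}")
```

which prints, for this seed:

```
F = 12.692, p = 0.001, partial eta^2 = 0.157
vigor change correlation: r = 0.361, p = 0.033
Fisher z vs control: z = 2.773, one-sided p = 0.003
```

The interaction F says the intervention group's whole-brain FA quotient rose
relative to control; partial eta squared is its ANOVA effect size; the
correlation links individual FA-quotient gains to gains on the POMS
vigor-activity subscale inside the intervention group, and the Fisher z says
that coupling is absent in the control group. `results.summary()` renders
the full report (baseline table, per-region interactions with BH-adjusted
p-values, both correlation matrices, the Fisher panel).

The same run is available from the shell, including NIfTI volume rendering
and scoring:

```bash
bhq run --preset paper --seed 1 --out runs/demo
bhq simulate --preset desk --out sim/ --seed 3
bhq score --maps sim/volumes --atlas sim/atlas.nii.gz --modality fa --out scores.csv
bhq analyze --scores scores.csv --behavior sim/behavior_long.csv --out report/
bhq verify --out verify.csv
```

`bhq verify` recomputes every published statistic of the study this battery
models that is a closed-form function of other printed numbers (330+ checks)
and reports pass/fail; one printed table entry is internally inconsistent at
the source and is flagged as such.

## Layout

- `bhq.grids` — volume/atlas/reference containers and NIfTI-1 I/O
- `bhq.quotient` — smoothing, ICV normalization, reference fields, quotient
  and regional aggregation
- `bhq.simulate` — synthetic cohorts: atlas, FA/tissue volumes, behavioral
  battery, latent change coupling, CES-D screening
- `bhq.stats` — the formula-level test implementations
- `bhq.study` — `InterventionStudy` model and `StudyResults`
- `bhq.verify` / `bhq.printed` — recomputation of the published statistics
- `bhq.pipeline` / `bhq.cli` — orchestration and the `bhq` command

See `docs/methods.md` for the generative model, parameter choices and
limitations.
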