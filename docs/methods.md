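# Methods

## Quotient scoring

A scalar brain map on a common spatial grid is standardized voxelwise
against a reference pool: `Q = 100 + 15 (x - mean)/sd`. Choices that the
published description leaves open, and how this implementation resolves
them:

- **SD convention.** Default is the population SD (`ddof=0`), which makes
  the defining cohort score exactly mean 100 / SD 15 at every voxel — the
  property the scale is named for. Sample SD (`ddof=1`) is a switch
  (`sd_convention="sample"`).
- **Reference pool.** Default is every scan of every participant at both
  timepoints; a pre-only pool is available (`reference_pool="pre"`). The
  choice shifts the scale's origin but not within-study contrasts.
- **Mask.** Voxels with `sd <= 1e-6` or `mean <= 0` are excluded and their
  quotients reported missing, rather than producing unbounded values.
  A cohort of identical maps therefore fails with a clear error instead of
  dividing by zero.
- **Aggregation.** Unweighted voxel mean within each atlas label, unweighted
  mean across labels for the whole-brain score; a volume-weighted mode
  exists but is off by default. Regions with no in-mask voxels are missing
  and are dropped from the whole-brain mean.
- **Smoothing.** Separable Gaussian, sigma = FWHM/sqrt(8 ln 2) per axis
  converted from mm to voxels, reflect boundary (conserves total intensity
  on the small grids used here). GM maps are smoothed before the
  intracranial-volume division; FA smoothing is on by default
  (`smooth_fa=False` to disable). Default FWHM 8 mm.
- **GM path.** ICV is the plain sum of the GM + WM + CSF maps; proportional
  GM is the smoothed GM map divided by that scalar. Because all three maps
  share a participant's global scale factor, the division removes head-size
  differences exactly in the generator and approximately in real data.

Quotients are affine-invariant: rescaling every raw input map by the same
`a x + b` (a > 0) leaves all scores unchanged, because mean and SD images
transform with the data. This is asserted numerically in the suite.

## The statistical battery

All statistics are computed from their defining formulas; scipy provides
only reference distributions. The 2x2 mixed-ANOVA interaction is computed
from the within-subject time-contrast decomposition (subject as the random
blocking factor); its F equals the squared pooled two-sample t on change
scores, an identity the suite checks to 1e-8 relative error against an
independently coded t-test, and the implementation is cross-validated
against pingouin's mixed ANOVA. Partial eta squared is `F df1/(F df1 + df2)`.
Paired tests use `pre - post` differences, so on a higher-is-better measure
an improvement prints as a negative t (tables in this field print that
sign; running text often quotes magnitudes); Cohen's d is exactly
`t/sqrt(n)`. The two-sample baseline test is pooled-variance Student t
(Welch optional) — pooled reproduces the published baseline t values from
their printed summary statistics at 3 decimals. Benjamini-Hochberg is the
standard step-up, applied by default to the family of regional FA
interaction p-values; its output matches an exhaustive brute-force
step-up and statsmodels' `fdr_bh` on random inputs. The Fisher r-to-z
comparison uses `z = (atanh r1 - atanh r2)/sqrt(1/(n1-3) + 1/(n2-3))`.

**Sidedness flag.** The study context this battery models declares
two-sided tests but quotes Fisher-comparison p-values that match one-sided
normal tails (z = 2.680 with p = .004, z = -1.642 with p = .05). Both tails
are therefore reported, and the results object carries a note naming the
discrepancy.

**Power analysis.** The paired-test sample size solver finds the smallest n
whose noncentral-t power (ncp = d sqrt(n), df = n-1, two-sided critical
value) reaches the target by doubling + bisection; power is nondecreasing
in n over the searched range (checked exhaustively for d = .3). For d = .5,
alpha = .05, power = .80 it returns 34 (power .808 at 34 vs .795 at 33).

## Synthetic cohorts

The generator emulates the outputs of a full preprocessing chain
(segmentation, normalization, tensor fitting) rather than the chain itself:
maps arrive already aligned on a common grid. The design is a two-group
pre/post trial with n = 35 per group by default; default effect magnitudes
are set to the published trial's values (baseline FA offset 2.0 quotient
points with the intervention group lower; intervention change +0.525
points; control drift -0.402; within-group change SD 1.7; change-score
couplings +.35 for vigor and -.35 for TMT part B; CES-D screening rate 18/89
with one imaging failure), so the "paper" preset and the plain defaults
coincide.

Structure, all drawn from one seeded `numpy` generator (same seed + config
gives bit-identical output):

- **Baseline.** Participant-by-region FA level = group offset + a shared
  between-subject component (SD 3.5 points) + an independent per-region
  component (SD 6 points). With 8 regions this yields a whole-brain
  between-subject SD of ~4.1 points, matching the scale of published
  baseline tables; an 8-region parcellation cannot make the whole-brain SD
  smaller than the shared floor, a deliberate desk-scale compromise.
- **Change.** One latent "responsiveness" factor `u ~ N(0,1)` per
  participant drives both the (global) brain change `delta_g + a u + e` and
  each coupled behavioral change `b_m u + f_m` in the intervention group;
  loadings are solved from `r = a b / sqrt((a^2+s_e^2)(b^2+s_f^2))` with the
  latent share fixed at `a = brain_change_sd * max(1/sqrt 2, max|r|)` and
  are recorded in the output manifest. Control-group behavioral change has
  the same marginal SD with zero coupling. The brain change is global
  across regions — regional effect heterogeneity is not modeled.
- **Rendering.** Points are painted into raw FA units at
  `k = fa_subject_sd / sqrt(shared^2 + region^2)` raw units per point
  (default 0.03 raw FA per between-subject SD), plus iid voxel noise
  (default SD 0.01), clipped to [0, 1]; tissue maps are smooth radial
  templates (WM core, GM shell, CSF rim) scaled by a participant ICV factor
  and a GM trait, clipped nonnegative. The atlas partitions an inscribed
  ellipsoid into connected blobs by multi-source breadth-first growth from
  random seeds.
- **Behavior.** POMS subscales are five 0-4 items, generated as rounded,
  [0, 20]-clipped Gaussians; trail-making times are floored at 5 s, part B
  is part A plus a positive gap, and both groups share a practice effect on
  part A. TMT B-A is derived per participant.
- **Screening.** The recruited pool contains the retained 2n participants
  plus extras whose CES-D is at or above 16 (rate 18/89 by default) or whose
  imaging failed; `apply_exclusions` removes them with a per-person log.
  Group assignment happens before exclusion; the retained set is balanced
  by construction, mirroring a trial that reached equal arms after
  screening.

**Scale note.** Voxelwise quotient scoring pegs one voxel-level
between-subject SD at 15 points. Because the generator's per-region
component is partially averaged out in the whole-brain mean, scored
whole-brain values are a cohort-specific multiple of the generator's latent
points (about 2x at the defaults, and smoothing changes the voxel SD).
Standardized statistics — t, F, eta squared, correlations — are invariant to
this factor, which is why calibration tests run on the generator's
score-level fast path (`generate_cohort_frame`, identical latent model, no
voxel rendering) while volume-path agreement is checked per participant
after estimating the conversion from the reference SD image.

**What passing tests do and do not show.** The generator's maps have
Gaussian noise, perfectly aligned grids, piecewise-constant regions and a
global change field; real FA maps have spatially correlated noise,
registration error, tract-specific effects and non-Gaussian tails. Passing
calibration here validates the arithmetic of the pipeline and the exactness
of its identities, not robustness to those real-data features.

## Problem sizes in the suite

Monte-Carlo tests run at: 1000 null replicates at n = 35/group for type-I
calibration of the interaction test (binomial 95% band around .05); 500
replicates for change-correlation recovery (tolerance +-.03 around .35);
2000/400 latent-level replicates for effect-size unbiasedness; a 10,000
participant single-region cohort for the 70-130 coverage band; full volume
rendering and scoring at 16^3 grids with 4-8 regions and 6-16 participants
per group. The default end-to-end run renders 24^3 voxel volumes for 70
participants at both timepoints in a few seconds.

## Known limitations

- No regional heterogeneity of the intervention effect, no simulation of
  raw diffusion signal, scanner artifacts, registration error, or tissue
  segmentation; real AAL/JHU atlases are replaced by synthetic connected
  parcellations (with the eight default region names borrowed from the
  white-matter tracts such studies report).
- Behavioral baselines carry no group offset, so baseline behavioral
  differences (which the published trial did show for TMT B-A) arise only
  by sampling.
- The whole-brain quotient SD of a rendered cohort is region-count-limited
  (floor 15/sqrt(R) points), so volume-path baseline contrasts are not on
  the same points scale as the published tables; the score-level fast path
  is, and is the surface the battery is calibrated on.
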