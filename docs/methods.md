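# Methods

This note records the models, the numerical choices, and the reasoning
behind every tuned constant in `petseg`.  It is the companion to the code;
nothing here is needed to *use* the package.

## 1. Imaging model

Volumes are 3-D scalar grids with anisotropic voxel spacing in mm; voxel
centers sit at `index * spacing` and all physical computations (spheres,
shells, dilations, gradients) are done in that mm space.  Two grid
geometries are exercised throughout: isotropic 4×4×4 mm and anisotropic
3.1819×3.1819×2 mm, representative of two reconstruction protocols.

SUV conversion is the bare body-weight normalization
`SUV = concentration / (injected_activity / body_weight)` with activity in
Bq and weight in g, assuming decay correction is already applied.

## 2. Phantoms

A phantom emulates a *post-reconstruction* PET image at summary level:

1. piecewise-constant uptake: background SUV 1, ellipsoidal tumor
   components at SUV 5–13, optional hot confounder organs (kidney/heart
   analogs) adjacent to the lesion;
2. multiplicative smooth texture inside the tumor (Gaussian random field,
   correlation length 10–18 mm, relative sd 0.08–0.25) modeling
   heterogeneous uptake;
3. isotropic Gaussian PSF blur, default FWHM 6.5 mm (harmonized whole-body
   FDG protocols), σ = FWHM / 2.3548;
4. additive Gaussian noise (sd 0.05–0.15 SUV).

The pre-blur tumor support is the ground truth; its 8 mm Euclidean
dilation is the "rough pre-marked mask" observers work inside.  In
confounder scenarios the rough mask deliberately annexes part of the hot
organ — the failure mode where a careless contour bleeds into myocardium
or renal pelvis.  The default 20-lesion suite alternates the two grids,
guarantees one >300 mL lesion, includes two-lobe shapes every 5th lesion
and a confounder every 7th.

No projection-space simulation is attempted.  The downstream analysis
needs realistic *threshold behaviour* on blurred, noisy uptake maps —
partial-volume rounded edges, texture-driven intra-tumor variation, hot
neighbors — and the image-space approximation provides exactly that.  It
does **not** support conclusions about reconstruction algorithms, scanner
hardware, or count statistics.

## 3. Segmentation algorithms

All thresholds are strictly greater-than and restricted to the rough mask.

- **41MAX**: voxels above 41% of the in-mask SUVmax.
- **SUV4 / SUV2.5**: fixed cuts at 4.0 / 2.5 SUV.
- **AUTO** (contrast-adapted): fixed-point iteration of
  `T = B + 0.5·(SUVpeak − B)` where the local background `B` is the mean
  image value in a shell 2–10 mm outside the current volume of interest.
  SUVpeak is the highest mean over a 1 mL (1.2 cm diameter, radius 6 mm)
  spherical neighborhood, computed with spacing-aware voxel-center
  membership.  Because the raw update is piecewise-constant in `T` on a
  discrete grid, it can 2-cycle on noisy data; the implementation damps
  the update (`T ← T + 0.6·(T_raw − T)`) while judging convergence on the
  undamped residual, so on noiseless piecewise-constant data the reported
  threshold equals the analytic fixed point to the 1e-3 SUV tolerance.
- **Gradient image**: Gaussian-derivative gradient magnitude in SUV/mm,
  sigma of one voxel pitch per axis.  Plain central differences are
  noise-dominated on PET; the Gaussian-derivative form is the standard
  regularized estimator.

## 4. Observer models

Each simulated observer is an `ObserverProfile` whose knobs map one-to-one
onto the effects the analysis measures.

- **Interactive threshold / gradient-guided**: the observer chooses a
  percent-of-SUVmax slider value equal to the *overlap-optimal* percent
  (argmax Jaccard against ground truth over a 0.25-step grid) plus a
  personal bias and zero-mean Gaussian noise; the chosen value is rounded
  to the slider's whole-percent steps and clipped to [0, 100].  The
  gradient view constrains the choice more tightly:
  `sd_gradient ≤ sd_threshold ≤ sd_manual` is enforced as a profile
  invariant.
- **Manual**: an interactive start with the largest sd, followed by
  independent Bernoulli toggling of boundary voxels (face-connectivity
  inner and outer shells) at the profile's edit rate.  Novices edit more,
  and in confounder scenarios their additions may annex flagged hot-organ
  voxels outside the rough mask; experienced observers never leave it.
- **Select-the-best**: with probability `select_accuracy_p` the observer
  picks the panel member with the highest Jaccard against ground truth,
  otherwise uniformly one of the other three.

Every lesion × observer × strategy cell gets its own RNG stream seeded
from a CRC32 of the cell identifiers XORed with the global seed, so
adding lesions or observers never perturbs existing cells.

This model is synthetic plumbing, not perceptual science: "visual
satisfaction" is anchored to an objective optimum plus noise.  It supports
studying how the *evaluation machinery* responds to interaction-dependent
variability; it does not support claims about real human readers.

### Default cohort calibration

The default panel (three experienced, three novice observers) uses:

| parameter | experienced | novice |
|---|---|---|
| slider bias (percent points) | 0, +0.15, −0.15 | +0.3, −0.3, +0.15 |
| sd gradient / threshold / manual | 0.2 / 4 / 6 | 0.28 / 6 / 10 |
| manual boundary edit rate | 0.03 | 0.08 |
| select-the-best accuracy | 0.92 | 0.78 |

These are tuning choices with no empirical counterpart; they were
calibrated **once**, before the acceptance checks were frozen, by sweeping
candidate cohorts over 40 independently seeded scenario suites and keeping
the configuration that most stably reproduced the qualitative ordering the
design encodes (agreement select_best ≥ gradient ≥ threshold ≥ manual,
with the first two statistically indistinguishable and both separated from
the last two).  Two structural observations from that sweep:

- Because select-the-best observers often pick the *same* panel member,
  its pairwise-Jaccard distribution has a large atom at exactly 1.  A rank
  test will always separate it from a purely continuous distribution, so
  the gradient strategy can only be statistically indistinguishable if it
  has a matching atom — which the whole-percent slider quantization
  provides naturally (tiny gradient sd ⇒ repeated identical integer
  choices).
- With only 20 lesions the select-the-best error count is a small
  binomial; unlucky clumping of errors makes the select-vs-gradient test
  significant in roughly a quarter of random suites.  That residual
  instability is a property of the design's sample size, not of the
  implementation; the default seed (0) reproduces the pattern.

## 5. Evaluation and statistics

- **Consensus**: per lesion × strategy, the majority-vote mask (strictly
  more than half of the voters; by default only experienced observers
  vote, configurable to all).
- **Pairwise metrics**: Jaccard and the symmetric percentage MATV
  difference `100·|v₁−v₂| / mean(v₁,v₂)` over all 15 observer pairs.
- **Vs-consensus metrics**: sensitivity `TP/(TP+FN)`, positive predictive
  value `TP/(TP+FP)` (the consensus supplies the positives), their mean,
  and reference-based percentage differences `100·(ref − obs)/ref` for
  SUVmax, SUVmean, MATV and TLG.  The sign convention makes an observed
  value far above the reference strongly negative.
- **Tests**: strategy comparisons use pairwise two-group Kruskal-Wallis
  tests (equivalent to tie-corrected rank-sum), six per metric family,
  corrected with Benjamini-Hochberg at a 10% FDR per family; a global
  4-group KW is emitted for context.  Observer comparisons use Wilcoxon
  signed-rank tests paired by lesion (zeros dropped, exact null for
  n ≤ 25).  All tests delegate to `scipy.stats` / `statsmodels`; the test
  suite cross-checks them against hand-rolled rank-formula and sign-
  enumeration oracles.

## 6. Limitations

- Image-space phantom: no count statistics, no reconstruction artifacts,
  noise is Gaussian and stationary.
- Observer realism: biases, sds and edit rates are calibration constants,
  not fits to reader data; only the *qualitative* orderings they produce
  are meaningful.
- Statistical outcomes at any single seed are stochastic; conclusions
  should be read across seeds, and the package makes that cheap (a full
  study runs in seconds).
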