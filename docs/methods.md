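# Methods

## The modelling problem

An obligately dependent species can only occur where its host occurs, so a
climate-envelope model fitted to its occurrences entangles two signals:
the species' own climatic response and the host's. When climate change
shifts suitability, a climate-only projection implicitly assumes the host
follows everywhere — which it need not. The package implements four ways
of projecting the dependent species' future range and the machinery to
compare them on data with known ground truth.

All layers live on a rectangular grid of equal-weight cells in row-major
order; range sizes are cell counts, and all change percentages are
relative to the number of *observed* currently occupied cells. The
modelled current binary maps are reported but not used for gain/loss
accounting (a flag enables the modelled-current variant for sensitivity
analysis).

## Ensemble envelope models

Each species' model is an ensemble of learners fitted to presence/absence
on the 70% training share of a seeded, unstratified random split;
probabilities are combined by the arithmetic mean. Two learners are built
in, deliberately heterogeneous:

- `glm_poly2` — logistic regression on linear + quadratic terms of every
  predictor, fitted by iteratively reweighted least squares with a ridge
  penalty of 1e-6 on the standardised non-intercept terms. The penalty
  keeps perfectly separable data finite; Newton steps are backtracked on
  the penalised deviance. Coefficients, and their standard errors from the
  penalised Fisher information, are reported on the raw feature scale
  (features are standardised internally and the linear map is applied to
  both the coefficient vector and its covariance).
- `sre` — surface range envelope: presence iff every predictor lies in the
  `[q, 1-q]` quantile interval of presence-only training values
  (`q = 0.025` by default). Predictions are hard 0/1.

Any object with `fit(X, y)` / `predict_proba(X)` can be registered as an
additional learner. Zero-variance predictors are dropped at fit time with
a logged warning, which is also what makes a constant host-probability
covariate degrade the explanatory approach gracefully to the climate-only
model.

Variable importance is permutation-based: the mean over `n_perm` seeded
permutations of `1 - Pearson r` between reference predictions and
predictions with one variable's values shuffled across cells. Identical
prediction vectors count as r = 1 (a permutation that changes nothing has
no importance); a constant vector counts as r = 0 (the permutation
destroyed all signal). Ensemble importance is computed on the combined
predictions, not averaged over members; per-member importances remain
available by passing a member.

## Evaluation and thresholding

AUC is the midrank Mann–Whitney statistic. Omission is the fraction of
observed presences predicted absent, commission the fraction of observed
absences predicted present; both are computed on the 30% test cells at
the recorded threshold, while thresholds themselves come from the 70%
model-building cells. Two threshold rules exist:

- **prevalence** (default): the presence fraction of the model-building
  data;
- **mean_probability**: the observed probability value whose
  presence fraction best matches the mean predicted probability, found by
  exhaustive scan over the observed values (ties to the smaller cutoff).

Binarisation puts ties on the presence side (`p >= t`), fixed so binary
maps are bit-reproducible.

## The four approaches

- **none**: climate-only ensemble, thresholded at the dependent species'
  prevalence.
- **overlap**: cellwise AND of the two species' thresholded maps, each at
  its own prevalence. Current-period maps are intersected the same way.
  AUC is undefined for an intersection of binary maps, so the dependent
  model's AUC is carried over; omission/commission are recomputed against
  the intersected current map on the dependent species' test cells.
- **explanatory**: the host's modelled *current* probability (never
  observed host presence) enters as one predictor; the future projection
  substitutes the host's future probability.
- **reference_area**: training is restricted to cells with observed host
  presence, giving P(dep | host, climate); the final map multiplies this
  conditional probability by the host's modelled probability for the same
  period. The multiplication is applied to the current period too, for
  symmetry, although only the future product is strictly required by the
  scheme; reports flag this. The threshold is the dependent species'
  prevalence within the calibration model-building cells and evaluation
  uses calibration test cells, scored on the final (product) map, with the
  conditional map stored alongside.

The host model is always the climate-only ensemble; there is no recursion.

Exact consequences worth knowing: the overlap future range is a subset of
the climate-only future range for any shared dependent model and
thresholds, so its gain percentage can never exceed the baseline's; and
the reference-area map is bounded above by both of its factors.

## MESS screening

Projection climates are screened against the calibration sample (for the
reference-area scheme: the climate at its training cells) with the
piecewise similarity formula; "fraction strictly below" defines the
percentile, ties counting as not-below. Similarity is the minimum
component over variables; negative values are exactly the cells where
some variable leaves the calibration range. Negative cells are flagged as
a non-analogue mask in reports and the projection is never truncated.
A constant reference sample yields component 0 at the constant and a
-1e9 sentinel elsewhere, with a warning.

## Uncertainty attribution

The factorial outcome table holds one relative change
`(gains - losses) / current cells` per (algorithm, approach) pair, each
from a *single-member* projection. Hierarchical partitioning fits OLS
with dummy-encoded factors for every subset of factors; goodness of fit
is R²; a factor's independent contribution is the average R² increase
over all entry orderings (for two factors,
`I_A = [R²(A) + R²(A,B) - R²(B)] / 2`), its joint contribution is
`R²({k}) - I_k`, and shares normalise the independent contributions to
100%. Raw values are reported alongside the shares because the
normalisation convention is not universal. Small negative independent
contributions are mathematically possible and reported as-is. For two
factors `I_A + I_B = R²(A,B)` holds algebraically and is asserted to
1e-10 in the tests.

## The virtual-species generator

Climate variables are linear gradients along an axis plus
Gaussian-kernel-smoothed white noise (correlation length in cells,
standard deviation rescaled after smoothing); the future period adds a
per-variable shift and redraws the noise from a derived stream. Species
responses are quadratic-logistic; true occupancy is Bernoulli in the
suitability, masked by host occupancy when the interaction is obligate.
Observation passes occupancy through a Bernoulli detection thinning
(default 1) and a surveyed-cell subsample (default 1, i.e. a census),
matching the treatment of atlas data as presence–absence truth.

### The default scenario

60×60 grid. `temperature` runs 2→14 along rows (row 0 is the pole) with
+2 future warming; `moisture` runs 600→900 along columns with −150 future
drying. The host peaks at 7° with a narrow thermal breadth
(η = 3 − 0.5(T−7)² + 0.02(M−750)); the dependent species, conditional on
its host, peaks at 9° with a broad breadth and a moderate ceiling
(η = 0.2 − 0.07(T−9)²). Three features of this design carry the science:

1. warming pushes both thermal bands poleward, creating genuine gains;
2. drying contracts the host toward the moist columns, and because the
   host's moisture limit is plainly expressed in its own current data its
   fitted model projects that contraction;
3. the dependent species' *conditional* suitability ceiling is moderate
   (~0.55), which attenuates the host's moisture imprint on the
   dependent's observed data — the logit slope an observer sees is the
   host's times `(1 − p_host) / (1 − p_dep · p_host)` — so a climate-only
   model of the dependent underestimates how strongly the future clips
   its host, and projects systematically larger gains than the three
   coupled schemes.

The moderate conditional ceiling also bounds discrimination inside the
host's range: reference-area AUCs on calibration test cells are
intrinsically lower (~0.6) than the other approaches' (~0.88), because
within-range occupancy is close to a coin flip the model cannot predict.

A second packaged scenario (`uncertainty_config`) keeps the climate but
makes the host widespread, thermally broad and indifferent to moisture,
so the four approaches nearly coincide and the spread among projections
is dominated by the choice of algorithm. It is the natural fixture for
variance attribution: with the two heterogeneous built-in learners the
algorithm share of explained variance is ~99% there.

### What the generator does not emulate

Dispersal limits and population dynamics, sampling bias, spatial
aggregation of survey effort, disequilibrium between species and climate,
and observation error in the climate layers. Passing tests therefore
demonstrate the correctness and internal logic of the estimators and the
coupling schemes under the stated generative model, not their performance
on real atlas data.

## Numerical conventions and problem sizes

- All randomness flows through explicit seeds; scenario sub-streams are
  derived from the scenario seed via seed sequences.
- Default problem sizes keep every stage interactive: 3 600-cell grids,
  2-member ensembles, 20-replicate stochastic checks, 10 permutation
  rounds for importance. All scale linearly in cells and members.
- Missing climate propagates: a cell missing any variable is excluded
  from fitting and projected as missing; binary maps carry the missing
  mask.
- Cells with unknown occurrence status are excluded from fitting,
  prevalence and gain/loss counts; projected-suitable unknown cells are
  reported as a separate flagged count.
- The "geotiff" output format is a multi-band TIFF whose description tag
  carries the variable names, period, threshold, cell ids and the
  optional affine geo-transform as JSON; CSV outputs carry the same
  metadata in a JSON sidecar and round-trip floats exactly via
  17-significant-digit formatting.

## Known limitations

- Only two uncertainty factors (algorithm, approach) are partitioned;
  climate model, emission scenario and threshold choice are acknowledged
  sources the design does not cross.
- The explanatory scheme's host predictor is collinear with climate by
  construction; its fitted coefficient is not interpretable as an
  interaction strength.
- The surface range envelope yields hard 0/1 probabilities, so
  single-member SRE "ensembles" have degenerate AUCs on test data.
- Unlimited dispersal is assumed throughout: every climatically suitable
  cell counts as reachable.
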