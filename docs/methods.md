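# Methods

## State-space view of movement

The package treats hourly animal movement as a noisy dynamical system: the
deterministic component of the next position is a function of the current
configuration, and observation/behavioural noise perturbs it. The state
presented to the model for focal animal *i* is the interaction vector
v(s_i(t)) — offsets to the m nearest conspecifics and n nearest
heterospecifics, distance-ordered within each species block — plus a
location covariate vector w (one-hot vegetation class, thermal stress
standardised to zero mean/unit variance over the training window, and a
winter indicator). Rows lacking a full neighbour set or a next-hour fix
are skipped, never imputed, and every skip is counted by reason; this is
the "sufficient number of neighbours" convention, and it means row counts
shrink as m and n grow.

The regression target is the hourly displacement, not the absolute
position: the rotation composition below is only coordinate-free for
displacements about the current position, and displacements are the
quantity with biological meaning at this cadence.

## Rotation-equivariant RBF surface

A single scalar surface f supplies both displacement components:

    F(v; w) = [f(v; w), 0] + R [f(R^-1 v; w), 0]

with R the anticlockwise quarter-turn applied blockwise to every 2-D
offset. f is fitted on the union of the original rows (target: the
x-displacement) and the −90°-rotated rows (target: the y-displacement), so
one set of parameters serves both components.

Exact equivariance F(Rv) = R·F(v) additionally requires f to be odd under
180° rotation of its vector inputs. The surface is therefore odd by
construction: its design consists of the linear terms in v together with
antisymmetrised basis columns φ(x) = (b(x) − b(R²x))/2. Constant and
covariate-only terms are even and vanish identically — a configuration
with no directional information predicts zero displacement, and covariates
influence the prediction only through basis functions that mix v and w.
This also keeps the selection objective consistent with the reported
predictor: fitting raw basis columns and discarding their even part after
the fact leaves systematic residual structure that makes greedy and
exhaustive selection disagree.

Basis families are the Gaussian exp(−r²/2σ²), the Ricker wavelet
(1 − r²/σ²)·exp(−r²/2σ²), and the "tophat" exp(−(r/σ)^(2q)) — a sharpened
(q > 1) or flattened (q < 1) Gaussian; default q = 2. Candidate centres
are sampled from the training inputs and scales from the {10, 25, 50,
75}% quantiles of pairwise input distances on a subsample (default
dictionary size 60, seeded).

## Description-length selection

Model complexity is charged with a two-part description length in nats:

    DL = (N/2) ln(max(RSS, 1e-12)/N) + λ (k/2) ln N

with k the number of free weights (v-linear terms plus one per basis) and
λ = 1 by default. This is the Schwarz-style approximation to description-
length coding: the first term is the code length of the residuals under a
Gaussian model, the second the cost of transmitting k parameters to
precision 1/√N. Selection alternates greedy forward passes (add the
candidate with the greatest residual reduction, computed exactly via
orthogonalised candidate columns) and backward pruning (refit without each
active basis), stopping only when no single add or prune lowers DL; the
lowest DL visited wins. On dictionaries small enough to enumerate, this
procedure finds the global DL minimum whenever the signal is clearly
expressed in the dictionary (tested against exhaustive subset search).

Numerical choices: least squares via SVD with relative rank threshold
1e−10; rank-deficient designs are solved minimum-norm with a warning; all
randomised steps (dictionary draws, subsampling) are seeded.

## Interaction diagrams

For each row, Δ is the mean distance to the n′ nearest target-species
neighbours and p the mean distance from the predicted next position to
those same neighbours held at their current positions; p − Δ is the
predicted change in separation (negative = attraction, positive =
repulsion). Although the defining sums run over n′ neighbours, both
quantities are divided by n′ so curves for different n′ share one distance
scale.

The curve evaluates, at each grid distance d (default 0–300 m in 5 m
steps), the median of a Gaussian kernel density over the p − Δ values of
rows whose Δ lies near d: rows are weighted by a Gaussian kernel in Δ
(default bandwidth 10 m, truncated at 4 bandwidths), the density over
p − Δ uses Silverman's bandwidth, and its median is found by root-finding
on the mixture CDF. Grid points with fewer than 30 rows within one
bandwidth are left undefined rather than extrapolated. Whether to pool in
hard distance bins or smooth in the distance direction was an open choice;
kernel windowing in distance was chosen for continuity of the curves.
Curve comparisons report per-distance differences, zero-crossing
(attraction↔repulsion) distances by linear interpolation, and
seeded bootstrap percentile bands from resampling rows — a descriptive
uncertainty statement, not a formal test.

## Synthetic data generator

The generator is a zonal (Couzin-style) swarm: per sub-step each animal
moves speed·unit(w_rep + w_ali + w_att + w_env) plus isotropic noise,
where repulsion sums unit vectors away from neighbours within the
repulsion radius, alignment averages neighbour headings in the
intermediate shell, attraction sums unit vectors toward neighbours in the
outer shell, and w_env climbs the gradient of vegetation preference minus
thermal avoidance (deer weight thermal stress 1.6× sheep). Positions
reflect at the plot boundary (the stock-proof fence). Twelve Euler
sub-steps per hour keep the dynamics stable at realistic speeds; hourly
snapshots are emitted as tracks.

Defaults encode the study conditions: 60 sheep + 20 deer on a 1000 × 1040 m
plot; speeds 32 (sheep) and 40 (deer) m/h, putting simulated daily travel
in the several-hundred-metres range; repulsion radius 15 m within species
and 30 m between species with couplings (8, 8, 14); alignment to 75 m
(intra-species only); attraction to 200 m with couplings (1.0, 1.3, 0.35).
The inter-species structure — wider, stronger short-range repulsion and
weaker long-range attraction than within species, deer more cohesive than
sheep — is deliberate: it is the qualitative interaction pattern the
analysis should recover, and the end-to-end tests check exactly that. The
larger inter-species repulsion radius reflects that mixed-species pairs
hold greater separations than conspecifics; with a single shared radius
the crowding equilibrium of 60 sheep pins nearest-neighbour spacing
against the repulsion edge and no ordering of the curves at short range
can be expressed.

The observation model adds isotropic Gaussian noise with per-coordinate
σ = 14/√(−2·ln 0.05) ≈ 5.72 m, so the radial error is Rayleigh and 95% of
fixes fall within 14 m of the truth — the collar accuracy of the study —
then thins to the fix interval and applies dropout. The vegetation mosaic
grows six classes from seeded patch centres (nearest-seed assignment under
per-seed growth-rate jitter), and the thermal-stress stack is a smooth
zero-mean spatial field plus seasonal and diurnal cosines (winter mean
above summer, pre-dawn peak) with a species offset hook.

What the generator does **not** emulate: terrain and slope, the real
plot's geometry and vegetation map, energetic costs, asynchronous or
serially correlated GPS error, uncollared animals influencing collared
ones, and behavioural modes (resting/grazing bouts). Tests passing on this
generator therefore show that the estimator recovers interaction structure
*of the zonal form it assumes from data of this noise level and volume* —
not that real sheep and deer follow a zonal model.

A separate harness iterates an explicit one-step kernel
(position ← position + kernel(v) + noise) so the fitted interaction curve
can be compared against a known ground truth, and a balanced animal-day
generator draws daily distances from the species × season mixed model at
the study's printed effect magnitudes (intercept 751.74, deer +184.74,
winter −240.1, interaction +129.83 m/day; animal SD 327.8, residual SD
966.4) for recovery tests of the statistical pipeline.

## Movement statistics

Daily distance sums Euclidean steps between consecutive available fixes
whose endpoints share a calendar day; days break at local midnight and a
step spanning midnight contributes to neither day (no interpolation
anywhere). The season rule is configurable because two conventions are in
circulation for this system; the default maps April–November to summer,
and a named preset (`SEASON_RULE_TABLE1`) maps May–November to summer.

The mixed model (species, season, interaction; animal random intercept) is
estimated by REML via statsmodels MixedLM. Satterthwaite degrees of
freedom, the REML likelihood-ratio χ² for the random intercept (computed
without the boundary-mixture correction, matching common package
defaults), least-squares means with 95% intervals and Bonferroni-adjusted
pairwise comparisons (6 contrasts over the 4 cells) are computed from the
closed-form REML quantities of the random-intercept model: the
fixed-effect covariance C(θ) = (Σ_g X_g′V_g⁻¹X_g)⁻¹ with V_g = σ_e²I +
σ_a²J per animal, the Satterthwaite df 2·v²/Var(v) for v = c′C(θ)c with
gradients by central differences and Var(θ̂) from the finite-difference
REML Hessian. One pytest cross-checks the whole fit against lme4/lmerTest
through Rscript.

Monthly predictability is the one-step RMS error √(mean squared error
over rows and both coordinates) per (month, species) stratum; empty strata
are flagged, not dropped. D(k) is the mean over animals of the distance to
the k-th nearest neighbour in a synchronous snapshot.

## Problem sizes

The test suite and the acceptance script run everything at sizes chosen to
exercise the estimators well inside a single CPU: selection-oracle checks
on 300-row datasets with 8-candidate dictionaries (exhaustive enumeration
of 256 subsets); known-kernel recovery with 100 animals over 500 h
(~50,000 rows); zonal-swarm recovery with the full 60 + 20 animals over
240 h across 5 seeds; GPS calibration with 10⁵ draws; mixed-model recovery
over 20–50 replicates of 40 animals × 80 days.

## Known limitations

* The description-length form is a Schwarz-style approximation; coding
  schemes that price basis centres and scales individually would penalise
  differently and can select different model sizes.
* Covariates enter only through basis functions; a purely additive
  covariate effect on displacement magnitude is inexpressible by design
  (it would break equivariance).
* The diagrams take neighbours as static over the prediction step; at
  separations comparable to the hourly displacement this understates
  mutual approach.
* Greedy selection matches exhaustive search when the dictionary expresses
  the signal cleanly; with highly collinear candidates and weak signal,
  pairs of bases can jointly beat any single addition and greedy stops
  early.
* Thermal stress is a single scalar proxy field; no attempt is made to
  model the meteorology that produces it.
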