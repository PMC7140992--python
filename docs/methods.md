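# Methods

## The audit model

The package treats a replicated landmark study as a variance-decomposition
problem. Each record is one digitisation of one specimen under a known
acquisition condition (device, presentation tilt, observer, trial). After
generalized Procrustes superimposition, each record is a point in the
$2k$-dimensional space of aligned coordinates, and the audit asks how the
dispersion of those points splits between biology (species, individuals) and
acquisition (device, observer, trial, presentation).

### Superimposition

GPA centers every configuration, scales it to unit centroid size, and
iterates (rotate all shapes onto the consensus; recompute the consensus;
rescale it to unit centroid size) until the Procrustes distance between
successive consensus shapes falls below `tol` (default `1e-8`, `max_iter`
100). The first configuration initialises the consensus, so output is
deterministic for a given input order; the aligned set as a whole retains an
arbitrary global orientation, which cancels in every statistic the package
reports (distances, sums of squares, classifications). Rotations are proper
(determinant +1) by default because chiral structures such as left/right
molars must not be reflected onto each other; `allow_reflection=True` is
available. No tangent-space projection is applied before statistics —
analyses use the Procrustes-aligned coordinates directly, matching common
practice in the tooling this pipeline emulates; `tangent_project` provides
the orthogonal projection for users who want it (for small shape variation
the two differ negligibly, well below the error effects being measured).
Non-convergence is a flagged condition (`converged=False` plus a warning),
not an exception, since a near-converged consensus is still usable.

### Procrustes ANOVA

The decomposition is sequential (Type I) along an ordered factor list in
which each term refines the grouping of its predecessors — the natural
structure of the replication hierarchy species > individuals > device >
observers > trials. Effect sums of squares are differences between
successive group-mean projections, pooled over all $2k$ coordinates, so the
$R^2$ values plus the residual always sum to one exactly. Balanced nested
degrees of freedom follow: species $k_s - 1$; individuals $N - k_s$; device
$N(d-1)$; observers $Nd(o-1)$; trials $Ndo(t-1)$. (Published audits of this
design sometimes interchange the individuals/device df entries; this
implementation follows the balanced algebra.)

Inference uses the residual randomization permutation procedure: for each
term, the residuals of the reduced model containing all preceding terms are
permuted whole-record, the statistic recomputed, and
$p = (\#\{\text{permuted} \ge \text{observed}\} + 1)/(n_{perm} + 1)$, with
ties counted as exceedances (conservative) and 999 permutations as the
default. The test statistic is the F ratio against the residual of the
model in which the term enters (everything below it pooled). In the fully
saturated nested hierarchy the deepest term leaves no residual, so no F is
reported for it and its permutation statistic is the effect mean square;
its permutation p-value remains well defined. Effect sizes $Z$ are computed
on log-transformed statistics against the permutation distribution
(observed value included), a convention-dependent choice documented here
because other conventions (untransformed F, exclusion of the observed
value) shift $Z$ slightly without affecting $p$ or $R^2$.

### Repeatability

Pairwise comparisons of two replicate datasets are jointly re-superimposed
(one GPA over the $2N$ records) and decomposed into among-individual and
within-individual (replicate, $m = 2$) variation. Repeatability pools the
coordinates through the trace-based mean squares of that table:
$s^2_{within} = MS_{within}$,
$s^2_{among} = (MS_{among} - MS_{within})/m$ floored at zero (a sampling
fluctuation below zero is reported as $R = 0$, never negative), and
$R = s^2_{among}/(s^2_{among} + s^2_{within})$, clamped to $[0, 1]$. When
both components vanish (identical constant data) $R$ is undefined and
reported as NaN rather than a misleading 0.

### Discriminant classification

LDA runs on the flattened aligned coordinates. Because superimposition
removes four degrees of freedom, the data are first projected onto the
principal components whose variance exceeds `1e-10` times the largest;
fitting and classification happen in that score space and axes are
back-projected for reporting. Posteriors are Gaussian with the pooled
within-group covariance:
$P(g \mid x) \propto \pi_g \exp(-\tfrac12 d^2_M(x; \mu_g, W))$, priors
proportional to group sizes by default. Exactly tied posteriors (a
measure-zero event logged when it occurs) resolve to the first group in
label sort order for determinism. Leave-one-out cross-validation refits the
full pipeline-internal model (including the rank reduction) on each fold.
PGM error percentages are $100 \times$ misclassified$/N$, kept unrounded
internally; all reported percentages round to one decimal, half away from
zero, and repeatability/$R^2$ columns to two decimals.

Stepwise selection is forward by Wilks' $\Lambda$ with the partial-F entry
test $F = (\Lambda_{p}/\Lambda_{p+1} - 1)(n - g - p)/(g - 1)$ and
`alpha_enter = 0.05` by default — the classic criterion, chosen because
stepwise discriminant tooling varies and no single convention is canonical.

### Occurrence likelihood

Unknowns are superimposed **jointly** with their training dataset before the
model is fitted (they are appended to the dataset, not aligned post hoc to a
frozen consensus; the latter is available as a separate utility path via
`opa_align`). Assignments with maximum posterior below the threshold
(default 0.95) are vetted out; a species is "likely present" only when its
vetted assignment percentage strictly exceeds the training set's LOOCV error
percentage. The fossil PGM change between two datasets is computed on raw
(unvetted) assignments — the change statistic measures classification
stability, and vetting would make its denominator vary between comparisons;
a vetted variant is trivially obtainable from the per-dataset reports.

### Thin-plate splines

Interpolating TPS with kernel $U(r) = r^2 \log r^2$ ($U(0) = 0$), solved
from the standard bordered system; no smoothing parameter, since the grids
are meant to pass exactly through the landmarks. Bending energy is the
quadratic form of the non-affine weights with the kernel matrix, clipped at
zero against roundoff; it is invariant to adding any affine function of the
reference to the target. Grids default to 24 × 24 nodes over the reference
bounding box expanded by 10% — a purely visual choice.

## The synthetic study generator

`StudySpec` defaults describe a study of 5 species × 50 individuals with 21
landmarks, each individual digitised under 2 devices × 2 observers × 2
trials (eight replicate datasets) plus one tilted presentation set, and 31
unknowns drawn from a mixture concentrated (48%) on the first species. The
template is a smoothly perturbed elongated closed outline normalised to unit
centroid size, with latent z relief (sd 0.05) used only by the tilt
mechanism.

Displacement scales (per coordinate, on the unit-size template):

| parameter           | default | role |
|---------------------|---------|------|
| `species_effect_sd`   | 0.008  | between-species shape separation |
| `individual_sd`       | 0.02   | biological among-individual variation |
| `device_bias_sd`      | 0.008  | systematic per-device field |
| `observer_bias_sd`    | 0.017  | systematic per-observer field |
| `session_noise_sd`    | 0.0125 | random per-digitisation noise |
| `tilt_range_deg`      | 5–20   | out-of-plane presentation angles |

Device and observer effects are *systematic*: one Gaussian displacement
field drawn per source and applied to every specimen measured under it —
this is what distinguishes instrument/personnel bias from digitising noise.
The defaults were chosen once, from the variance algebra of the nested
design, so that the expected error ordering is
individuals > interobserver > intraobserver(session) > device with species
separation comparable to device error — the closely-related-species regime
in which acquisition error genuinely threatens classification. The tilted
set rotates each individual's latent 3D shape about the two in-plane axes
(orthographic projection; a perspective model is deliberately out of scope)
by angles drawn uniformly from `tilt_range_deg` with random sign; the
magnitudes are a documented free choice, since haphazard manual tilting has
no canonical distribution. Unknowns receive session noise from a single
nominal device/observer, mimicking a fossil series photographed and
digitised once.

What the generator does **not** emulate: lens/field distortion gradients,
image-resolution effects, correlated placement errors along outline
segments, observer learning over trials, and missing landmarks. Passing
tests therefore demonstrate that the estimators recover planted additive
structure of realistic magnitude under the replicated design — not that any
particular real system behaves additively.

## Problem sizes and runtime choices

The test suite exercises parameter-recovery properties at the full default
design (2,000 records) where the computation is cheap (GPA and the nested
decomposition vectorise well) and at reduced sizes (5–12 individuals per
species, 8–10 landmarks) for end-to-end pipeline checks, keeping the whole
suite under a minute. The acceptance script runs the complete audit at the
full default design with 199 permutations per term; permutation counts only
sharpen p-value resolution and do not affect the reported $R^2$, means, or
classification quantities.

## Known limitations

- The nested decomposition requires a hierarchically refining factor order;
  crossed random-effects designs (and their ML/REML variance estimates) are
  out of scope.
- The tilted presentation set participates only in pairwise comparisons; it
  cannot be placed in the nested hierarchy.
- Repeatability assumes balanced replication ($m$ equal for all
  individuals).
- With strongly rank-deficient training sets (few specimens per group
  relative to $2k$), LOOCV error estimates are themselves noisy; the audit
  reports them as-is.
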