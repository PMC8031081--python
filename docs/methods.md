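# Methods

## The descriptor

A binding site is an n × 3 cloud of heavy-atom coordinates (Å).  Its
principal axes are the eigenvectors of the coordinate covariance
Sₓ = n⁻¹ Σ (xᵢ − x̄)(xᵢ − x̄)′, ordered by decreasing eigenvalue; the
descriptor is the 3 × 3 covariance of the n × 3 matrix of atom-to-axis
Euclidean distances.  It is invariant to rotation, translation and
reflection of the input coordinates (distances to unsigned axes are
reflection-blind), covariant under scaling (S ↦ s²S), and invariant to atom
order.  It sees only second-order structure: two sites with the same
per-axis distance covariance are indistinguishable, whatever their
higher-order geometry (see Limitations).

### Conventions

- **Covariance divisors.**  The coordinate covariance used for the axes is
  the population form (divisor n); the divisor does not affect the axes.
  The distance covariance — the descriptor itself — uses the sample form
  (divisor n − 1) by default, matching the convention used for the
  group-level fits; `divisor="n"` switches to the population form, which
  rescales every descriptor by (n − 1)/n.  One convention must be used
  throughout a study; mixing them shifts descriptors of small sites.
- **Axis signs and degeneracy.**  Distances are sign-blind, so axis signs
  are fixed only for reproducibility of the frame (largest-magnitude
  component positive, ties by earliest index).  When eigenvalues nearly
  coincide (relative gap < 1e-8) the axes are not unique; a
  `DegenerateFrameWarning` is emitted and the descriptor is then
  convention-dependent.  Eigendecomposition is performed on the symmetrised
  matrix (S + S′)/2 to absorb floating-point asymmetry.
- **vecd.**  The 6-vector form scales the three off-diagonals by √2, making
  vectorisation an isometry: ‖vecd(S)‖² = ‖S‖²_F.  (The identity sometimes
  written with trace(S) on the left holds only for the Frobenius norm; the
  package enforces and tests the Frobenius identity.)
- **Radius of gyration.**  Default is the standard RMS distance of atoms to
  the centroid; `definition="sd"` gives the literal standard deviation of
  those distances, which differs whenever the mean distance is nonzero.

## Site extraction

A site is all polymer (ATOM-record) heavy atoms whose minimum Euclidean
distance to any heavy atom of the selected ligand is ≤ 5.3 Å — the cutoff
established experimentally in the benchmark literature this package follows.
Hydrogens (rarely present in X-ray structures), waters, and hetero groups
other than the selected ligand are excluded so that the definition is
reproducible across depositions.  Alternate locations resolve to the
highest-occupancy copy (ties: first in file); only model 1 of multi-model
files is read.  A selector matching several ligand copies is an error
requiring explicit chain/residue disambiguation — silently picking a copy
would silently change the site.  Sites with fewer than 4 atoms are rejected
(no nondegenerate 3-D covariance exists).

## Group models and classifiers

Each ligand group is summarised by the sample mean and covariance of its
members' 6-vectors.  A full-rank 6 × 6 covariance needs at least 7 members;
smaller or ill-conditioned groups (condition number > 1e12) receive a ridge
Σ̂ + εI with ε = 1e-6 × mean(diag Σ̂), recorded on the model and announced
by a `SmallGroupWarning`.  Distances are the squared Mahalanobis form
(no square root), computed via Cholesky solves; the squared form is
monotone-equivalent for nearest-mean assignment and is what the logistic
classifier receives as predictors.  Nearest-mean ties resolve to the first
label in the fixed group ordering (AMP, ATP, FAD, FMN, GLC, HEM, NAD, PO4,
Steroid) and are flagged.

The multinomial logistic classifier is parameterised with a reference
category (default AMP; its coefficient row is 0) and fitted by L-BFGS-B on
the exact penalised negative log-likelihood with analytic gradient.
Predictors are standardised internally and the coefficients mapped back to
the original scale: Mahalanobis distances to tight small-group covariances
span several orders of magnitude, and raw-scale quasi-Newton steps stall.
The default slope penalty l2 = 1e-6 (applied on the standardised scale,
intercepts unpenalised) is near-MLE but keeps quasi-separated fits finite.
At l2 = 0 separation is detected — coefficients exceeding 50 on the
standardised scale, or an essentially zero mean deviance (< 1e-6), where no
finite MLE exists — and the fit is flagged unconverged with guidance to set
l2 > 0 rather than returning blown-up coefficients as if they were stable.

With J groups and J distance predictors the model has (J−1)(J+1) parameters;
for a 100-site, 9-group dataset that is 80 parameters, and training error
then measures capacity, not signal.  The pipeline's `fit` refuses a logistic
fit when parameters ≥ observations/1.25 unless forced.

## Noise validation

Leave-one-out cross-validation is unusable here: removing one member from a
5–6-member group radically changes its covariance.  Robustness is instead
probed by simulation: every atom coordinate is shifted by independent
N(0, τ²) noise (τ in Å — against a 5.3 Å site radius, τ near 1 is a large
perturbation; a flag interprets τ as the variance instead), the perturbed
sites are re-encoded and classified against the models fitted to the
original data (models are never refitted per replication), and the error is
recorded per replication.  Defaults: 100 replications per τ; 95% bands are
the empirical 2.5/97.5 percentiles across replications, with mean ± 1.96·se
available as an option.  Encoding failures are counted and reported, never
silently dropped.  All randomness flows from one seeded generator, making
runs bit-reproducible.

## Cleaning and diagnostics

Outlier flagging replaces visual MDS-based removal with a reproducible
rule: a member is flagged when its within-group squared Mahalanobis distance
exceeds the chi-square(6) upper-α quantile (default α = 0.001), with one
refit-and-rescan pass.  Two caveats are inherent to the rule: flagging never
removes more than 10% of a group without an explicit override, and with a
sample covariance a point's squared distance is bounded by ≈ (n−1)²/n, so
the default α is unreachable in groups smaller than ~25 members (use a
milder α there).  Clustered contamination can also mask itself by inflating
the covariance along its own direction — the rule is a reproducible proxy,
not a robust estimator.

Heterogeneous groups can be split for model building by k-means on the
6-vectors (k = 2 by default, 10 restarts, fixed seed; sublabels named by
decreasing cluster size), and evaluation merges sublabels back through a
merge map so the evaluation unit never changes.  Identical vectors fall back
to no split, with a warning.

Classical (Torgerson) MDS — double-centering of squared Euclidean distances
between 6-vectors, then a top-k eigendecomposition — provides the
diagnostic maps.  Inputs are genuinely Euclidean, so top eigenvalues are
non-negative and a rank-k configuration is reproduced exactly; axes are
oriented so the largest-loading coordinate is positive (the usual MDS sign
indeterminacy).

## Synthetic data

The generator emulates groups of binding-site point clouds: a group template
is three generating standard deviations (Å) along orthogonal directions, an
atom-count range, and a small jitter of the scales; each site is a filled
anisotropic Gaussian cloud rotated and translated randomly, so raw
coordinates never share a frame.  Gaussian clouds are the minimal sufficient
generator because the descriptor sees only second-order structure; a
hollow-ellipsoid shell sampler (`shell=True`) gives more pocket-like
geometry.  The `default` preset has nine templates with the benchmark's
group sizes (9, 14, 10, 6, 5, 16, 15, 20, 5) and Å-realistic scales chosen
once so the group descriptor means are well separated relative to
within-group spread (training error ≤ 5% across seeds); the `null` preset
gives all groups one template.  What a green test on synthetic data
establishes is that the pipeline recovers the structure the generator put
in; it does not establish performance on real sites, whose clouds are
non-Gaussian, chemically patterned and curved (pockets are concavities) —
that is what the downloadable benchmark walkthrough is for.

Two protocol notes, found empirically and worth knowing when extending the
package: on the null preset, *training-set* classification is far below
chance error (~0.4, not 8/9) because each group's own members shape its
covariance — chance-level behaviour holds for held-out data, which is how
the package's null checks are run; and certainty under the null shows a
small negative correct-vs-incorrect shift on held-out data (a selection
effect of conditioning on the argmax), so "certainty is uninformative under
the null" is checked as an effect size near 0.5 AUC, not as an exact zero.

## Limitations

- The descriptor cannot recover atom correspondences or produce
  superpositions, and it ignores chemistry (elements, charges) entirely.
- Only linear (second-order) variation is encoded; curved pocket shapes
  project onto the principal axes and are not modelled as surfaces.
- Nearly-isotropic sites have ill-defined axes; the descriptor is then
  convention-dependent (a warning is emitted).
- Group models need enough members for a stable 6 × 6 covariance; the ridge
  keeps small groups usable but shrinks their Mahalanobis geometry.
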