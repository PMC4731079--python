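# Methods

## Models

### Grouped finishing times: the ADDP family

Runners are grouped by age and gender (index `j`).  Finishing time `x_ji`
(minutes) is modeled as an infinite Gaussian mixture whose mixing weights
`pi_k` are *shared* across groups while the component locations move with
the group:

    x_ji | c_ji = k  ~  N(mu_k + shift, sigma_x^2)

* `mu_k ~ N(mu0, sigma0^2)` carries the overall time scale of cluster `k`
  (elite, competitive, mainstream, ...).
* The group shift follows a zero-mean Gaussian process over age with a
  squared-exponential kernel
  `K(l, j) = sigma_theta^2 exp(-(l - j)^2 / (2 nu^2)) + kappa 1[l = j]`,
  so neighbouring ages share their handicap smoothly.  Genders get
  independent GPs (block-diagonal kernel), except in the interaction
  variant.
* Weights come from a Dirichlet process, `pi ~ GEM(alpha)`: the weight of
  a performance tier is the same for 25-year-old men and 60-year-old
  women; only its location moves.  This is what makes tiers comparable
  across groups and is the heart of the grading construction.
* A single noise variance `sigma_x^2 ~ InvGamma(a, b)` is shared by all
  clusters so that clusters are totally ordered by their means.

Four variants differ in the shift structure:

| variant          | location                                | extra latent state |
|------------------|-----------------------------------------|--------------------|
| `basic`          | `mu_k + theta_j`                        | —                  |
| `hierarchical`   | `mu_k + theta_j`, weights `pi_rk` per race (HDP over races) | global stick `v`, per-race `pi_r` |
| `interaction`    | `mu_k + theta_j + g (delta + omega_j)`  | gender effect `delta ~ N(0, sigma_g^2)`, interaction `omega ~ N(0, Sigma_omega)` |
| `cluster_shifts` | `mu_k + theta_jk`, one GP per cluster   | shift matrix `theta_jk` |

Only sums such as `mu_k + theta_j` (plus gender terms) enter the
likelihood: `mu` and `theta` are not separately identified and the priors
(`sigma0^2 >> sigma_theta^2`, enforced at configuration time) resolve the
split softly.  All reporting is therefore in identified terms: cluster
locations displayed at a reference group, shift contrasts
`theta_j - theta_ref`, and grading tables.

### Pacing profiles: HDP with Dirichlet likelihood

Each runner's cumulative split times are converted to the fraction of
total time spent in each course interval — a simplex vector `x_ji` — so
that runners are clustered by pacing *shape*, not speed.  The likelihood
is `x_ji | c_ji = k ~ Dirichlet(tau * p_k)` with pattern prior
`p_k ~ Dirichlet(epsilon * l_1, ..., epsilon * l_D)` whose base measure is
proportional to interval lengths `l_d` (constant pace is the prior
centre).  `tau` acts as an inverse variance: larger values resolve finer
pacing distinctions into more clusters.  Groups (age-group x gender) share
the patterns through a hierarchical DP — `G0 ~ DP(gamma, H)`,
`G_j ~ DP(alpha, G0)` — and differ only in mixing weights `pi_j`.

### Finish-time prediction

With `D` observed records, training profiles are truncated at interval
`D` and renormalized; by the Dirichlet aggregation property the
renormalized head of a `Dirichlet(tau p)` vector is exactly
`Dirichlet(tau p_1, ..., tau p_D)`, so the truncated model is consistent
with the full one.  Per archived posterior state, a test runner's cluster
membership combines the group weights `pi_j` (prior) with the Dirichlet
likelihood of their renormalized head; each cluster contributes a
projection factor `q_k`, the *median* over its training members of
(finish time) / (elapsed time at D) — the median resists outliers.  The
prediction is `elapsed_D x sum_k prob_k q_k`, averaged over archived
states; a cluster with no training members falls back to the global
median quotient.  Predictions are exactly scale-equivariant in the
runner's elapsed times because only time fractions enter the weights.

## Inference

All models use Gibbs sampling with Neal's Algorithm 8 for the
non-conjugate assignment step: ten auxiliary clusters with fresh prior
draws stand in for the unrepresented ones, an item joins occupied cluster
`k` with prior mass `n_k` (or `n_rk + alpha v_k` in the hierarchical
Chinese-restaurant-franchise form) and each auxiliary with mass
`alpha / 10` (or `alpha v_rem / 10`).  Auxiliary parameters are drawn once
per sweep — their full conditional given zero occupancy is the prior, so
per-sweep refreshment is a valid Gibbs step — which lets the per-sweep
likelihood matrix be computed vectorised; a cluster emptied mid-sweep
re-enters the auxiliary pool carrying its parameter (Neal's singleton
rule) and promotions are replenished with fresh draws.

Conditionals for cluster means, shifts, gender terms and the noise
variance are conjugate (normal–normal and normal–inverse-gamma); the
pattern vectors `p_k` are not (the Dirichlet *parameter*, not its mean,
carries `p_k`) and are updated by Metropolis–Hastings with a
`Dirichlet(s p_k)` random-walk proposal.  The proposal concentration `s`
adapts per cluster during burn-in by doubling/halving toward a 20–40%
acceptance rate and is frozen afterwards.

Concentration parameters carry `Gamma(shape 1, scale 10)` priors.  A
single DP's `alpha` is resampled by the Escobar–West auxiliary-variable
scheme; the HDP's lower-level `alpha` by Teh's `(w_r, s_r)` auxiliary
scheme, and the top-level `gamma` by Escobar–West applied to the simulated
table counts, themselves drawn by the Antoniak Bernoulli recursion.

**Initialization.** Records start in roughly a dozen clusters (quantile
bins of the raw times; k-means on profiles for the pattern model) rather
than a single cluster.  Single-site Gibbs merges redundant clusters
quickly but splits a merged cluster extremely slowly when the likelihood
is sharp, so an over-clustered start mixes far better; the stationary
distribution is unaffected.  The noise variance starts at the
within-bin residual variance, concentrations at 1.

**Label switching and spurious clusters.** Archived states store clusters
sorted by mean.  For posterior summaries, transient clusters below a 0.5%
occupancy threshold are dropped state by state, the modal cluster count
over the averaging window selects the states to summarise, and clusters
are matched across states by minimum-cost assignment on |mean difference|
against a running reference (means are the identified, slowly-mixing
block, so they are the matching metric).  Grading tables are invariant to
the additive `mu`/`theta` non-identifiability by construction.

## Defaults and units

The package works in minutes; readers convert hours on ingest.  The
reference prior configuration is expressed on an hours scale —
`mu0 = 5 h`, `sigma0^2 = 1 h^2` (2-hour finishers within 3 sd, 9-hour
within reach), shift-kernel variance `0.05 h^2` (shift sd on the order of
13 minutes), lengthscale `nu = 10` years, jitter `1e-6`, `a = b = 1`,
`sigma_g^2 = 0.05 h^2`, `Sigma_omega = Sigma_theta / 2` — and estimator
defaults are those values converted (x60 on means, x3600 on variances,
including the inverse-gamma scale `b`); `paper_hyperparameters(unit)`
exposes both scales.  For the pattern model, `tau = 5000`,
`epsilon = 0.2 km^-1`, and the default interval scheme is eight 5-km legs
plus the final 2.195 km.  Sampler settings: 10 auxiliary clusters, thin 5,
averaging window the final 20% of iterations unless configured.

## Synthetic data

`gen_finish_times` runs the generative model forward: one GP shift draw
per gender (or per cluster), multinomial assignments from the true
weights (optionally per race), Gaussian noise.  The marathon-like preset —
five clusters at (150, 199, 233, 270, 330) minutes with weights
(0.01, 0.13, 0.33, 0.33, 0.20), ages 18–69, a 30-minute gender gap,
6-minute within-cluster noise — is shaped after published summaries of
big-city marathon fields so demonstrations look like race data; it is a
preset, not asserted truth.  `gen_split_profiles` draws cluster
memberships from per-group mixing, profiles from `Dirichlet(tau p_k)` and
finishing times from a lognormal (median ≈ 260 min, log-sd 0.18).

What the generators do *not* emulate: the sub-4-hour psychological spike
and valley in real finishing-time histograms (a shared-variance Gaussian
mixture cannot represent it), course-specific features such as elevation,
weather, or field-selection effects, and recording artifacts
(unsynchronised timing mats, missing splits).  Passing recovery tests
therefore certifies the inference machinery under the models' own
assumptions, not the adequacy of those assumptions for any particular
race.

## Numerical choices

* Dirichlet densities are undefined on the simplex boundary: profiles and
  proposals are floored at 1e-10 and renormalized before scoring.
* The GP kernel jitter (`kappa`) guards the Cholesky factorisations; a
  zero-jitter kernel with duplicate covariate positions raises rather
  than silently regularising.
* Assignment probabilities are computed with a max-subtracted softmax;
  an all-zero mass vector raises a degenerate-distribution error.
* `sample_table_count` uses the O(n) Bernoulli recursion, vectorised.
* Verification problem sizes (a few-thousand-record cohorts, a few
  thousand sweeps) are chosen so the whole suite re-runs comfortably on a
  single CPU; they recover the generative parameters to the tolerances
  asserted in the tests.

## Known limitations

* Single-site Gibbs mixes slowly between partition modes even with the
  over-clustered start; very long runs may retain a duplicated cluster
  inside one true component (visible as a transient low-weight twin).
  Split-merge or slice samplers are deliberately out of scope.
* The `cluster_shifts` variant's GP prior mean defaults to zero; with it,
  only `mu_k + theta_jk` is identified and reported.
* The pattern model's likelihood treats intervals as exchangeable given
  the pattern; it does not model serial correlation of fatigue within a
  runner beyond what the pattern itself captures.
* The `.mat` ingest discovers conventional variable names; deposited
  files with a different internal layout produce a descriptive error
  listing what was found rather than a best-effort guess.
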