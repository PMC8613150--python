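# Methods

## Individual eye-movement HMMs

One hidden Markov model is estimated per subject per stimulus from that
subject's fixation sequences. Hidden state *k* is a region of interest (ROI)
with Gaussian emission N(μₖ, Σₖ) over fixation coordinates (pixels, origin at
the stimulus top-left, y downward — the dominant convention of eye-tracker
exports; no screen-to-image transformation is applied, and fixations outside
the stimulus bounds are kept by default, since Gaussian emissions tolerate
them). A prior vector π governs the starting ROI and a row-stochastic matrix
A the ROI-to-ROI dynamics.

Estimation is mean-field variational Bayes with the conjugate family:

* π ~ Dirichlet(α₀), rows of A ~ Dirichlet(ε₀);
* (μₖ, Λₖ) ~ Normal–Wishart(m₀, β₀, W₀, ν₀), Λₖ the emission precision.

The E-step runs forward–backward with the usual expected-log-parameter
surrogates (digamma forms); the M-step applies the standard conjugate count
updates. The ELBO is the sum over sequences of the surrogate forward
log-normalisers minus the KL divergences of each posterior factor from its
prior, and is non-decreasing over iterations — the invariant is tested at
tolerance 1e-8 relative. All probability computations are in the log domain
with log-sum-exp.

**Hyperparameter defaults** (units: pixels where applicable):

| parameter | default | why |
|---|---|---|
| α₀, ε₀ | 1 | uniform Dirichlet; no preference among ROIs |
| m₀ | stimulus centre | no spatial preference |
| β₀ | 1 | weak confidence in m₀ |
| ν₀ | 5 | weakest proper value giving a finite expected covariance in 2-D |
| W₀ | ((D/16)² ν₀)⁻¹ I | prior ROI s.d. ≈ D/16, D = stimulus diagonal — scale-aware: a "compact region" of a typical stimulus |

When no stimulus size is supplied the bounding box of the observed fixations
is used. The defaults matter mostly for small samples; with dozens of
fixations per state the data dominate.

**Initialisation and restarts.** Each restart seeds the responsibilities from
a k-means partition of the pooled fixation points (seeded per restart);
priors and transitions start from uniform pseudo-counts. Default 10 restarts;
the highest-ELBO fit is kept. Convergence: relative ELBO change < 1e-5 or 200
iterations.

**Model-order selection and pruning.** The number of ROIs is chosen by
refitting over an inclusive range (default 2–4) and keeping the highest
ELBO; ties within 1e-6 go to the smaller count. States whose total expected
responsibility falls below `min_weight` (default 1.0 expected fixations) are
pruned, with π and A renormalised over survivors. A pruned-but-unused state
retains only its Dirichlet pseudo-count mass, so pruning perturbs held-in
log-likelihoods by a fraction of a percent (≈2×10⁻² nats per sequence under
the α₀ = ε₀ = 1 defaults), not to machine precision. Point estimates use
posterior means: π and A from Dirichlet means, Σₖ = Wₖ⁻¹/(νₖ − 3).

On single-Gaussian data the selected model is the least complex in the range
(K = 2); under uniform Dirichlet priors the two states typically share the
mass of the single cluster rather than one emptying, so "effective one-state"
behaviour shows up as minimal selected complexity, not as a pruned state.

## Co-clustering the HMM grid

Given the subject × stimulus grid of individual HMMs, subjects are clustered
with **one assignment per subject shared across all stimuli**, and one
representative (reduced) HMM is produced per (group, stimulus).

The primitive is a closed-form variational lower bound on the expected
log-likelihood of virtual samples: for base HMM b and reduced HMM r,
n·E_b[log p(y₁..T | r)] is bounded below using the expected Gaussian cross
log-likelihoods between each base/reduced state pair,

E_{N(μ_b,Σ_b)}[ln N(y; μ_r, Σ_r)] =
−½(d ln 2π + ln|Σ_r| + tr(Σ_r⁻¹Σ_b) + (μ_b−μ_r)ᵀΣ_r⁻¹(μ_b−μ_r)),

combined by a backward recursion over the virtual-sequence length with
log-sum-exp over reduced states (the optimal variational state
correspondence) and averaged over the base chain. No sequences are sampled.
The bound is exact for identical single-state models (−ln 2π − 1 per
observation in 2-D for standard-normal emissions) and is verified against
Monte-Carlo estimates in the tests.

**Virtual-sample weights.** Each grid cell is weighted by n_virtual = the
number of real training sequences behind that HMM and t_virtual = the median
training-sequence length, so subjects with more evidence weigh more.

**VHEM (fixed G).** EM alternates: responsibilities per subject ∝ group
weight × exp(Σ over stimuli of the bound); representative-HMM updates from
responsibility-weighted aggregation of the expected initial-state counts,
transition counts and emission moments produced by the same variational
correspondence. The objective (sum of per-subject log-sum-exp terms) is
non-decreasing — asserted at 1e-8 relative. An empty cluster is re-seeded
once from the worst-fitting subject; if it empties again the model continues
with G−1 groups and a warning.

**VBHEM (automatic G).** Dirichlet priors are placed on group weights
(concentration 1/G_max, so superfluous groups shrink; no prior on the number
of groups itself), Dirichlet priors on the representative HMMs' initial and
transition parameters and Normal–Wishart on their Gaussians (same defaults
as the individual fits). The E-step substitutes expected-log parameters and
the Normal–Wishart expectation of the Gaussian cross term; the objective is
the responsibility log-sum-exp minus all posterior-prior KL terms — a bound
on the expected marginal log-likelihood, comparable across G. Each G in the
range (default 1–5) is fitted; the highest bound wins (ties within 1e-6 to
the smaller G), and groups whose posterior weight collapses below half a
subject are removed before reporting the group count.

**Representative complexity.** The number of states per representative HMM
defaults to the median state count of that stimulus's individual HMMs, with
half-integer medians rounded up (the richer model); per-stimulus overrides
are accepted. Representative states with aggregated virtual weight below the
same `min_weight` rule are pruned after convergence.

**Initialisation.** Restart 0 clusters subjects by k-means on the matrix of
pairwise expected-log-likelihood bounds and seeds each group's representative
HMMs from the member nearest the centre (resized to the target state count by
splitting heavy states with jittered means or dropping light ones); further
restarts use random seed subjects. Default 5 restarts.

## Likelihood-based measures

Sequence log-likelihoods are exact (forward recursion, log domain). The
per-subject group log-likelihood is the **mean per-sequence** value by
default (a per-fixation option exists for very unequal lengths; summation is
also available). KL between two group patterns is estimated from observed
data — the mean difference in log-likelihood of one group's sequences under
the two representative HMMs — because no closed form exists for KL between
HMMs; a sampling-based variant draws virtual sequences from one model
instead. SKL symmetrises the two directions. The cluster score
(L₁−L₂)/(|L₁|+|L₂|) is bounded in [−1, 1] because |L₁−L₂| ≤ |L₁|+|L₂|.

Split-half reliability computes the per-subject metric on two stimulus
halves using the *same* full-data representative HMMs restricted to each
half's stimuli (a refit per half is possible but not the default), correlates
across subjects with Pearson r — the correlation the Spearman–Brown formula
2r/(1+r) assumes — and corrects. Splits are alternating, random (stratified
by stimulus label when labels are present), or by label.

## Synthetic ground truth

The generator emulates the structure the model assumes: per (group,
stimulus) HMMs whose ROI means are shared base positions plus group-specific
offsets placed so corresponding ROIs of neighbouring groups are exactly
`separation` pixels apart; isotropic ROI s.d. 25 px; transition styles
ranging from explorative (self-transition weight 0.1) to focused (0.7),
mirroring the qualitative contrast such analyses discover in scene viewing.
With `separation = 0` all groups share one HMM per stimulus — the null
model. Sequence lengths are uniform on 8–18 by default (mean ≈ 13 fixations
per trial, the regime of passive scene viewing at ~5 s per image); fixations
are not clipped to the stimulus bounds, matching the modelling assumption.

What the generator does **not** emulate: non-Gaussian (fat-tailed) fixation
scatter, centre bias, saccadic momentum, within-subject drift across trials,
or stimulus-dependent ROI counts. Passing recovery tests therefore shows the
estimators are correct under their own assumptions, not that real scene
data satisfy them.

Default study conditions in the tests: 2 groups × 10 subjects × 5 stimuli,
200-px separation, 3–5 trials per stimulus — small enough to run in seconds
yet separated enough that recovery is expected to be exact. The null
reliability check uses a larger 30-subject panel with 2 stimuli, since the
sampling noise of a correlation across few subjects would otherwise swamp
the near-zero expectation.

## Numerical choices and limitations

* All forward/backward recursions in log space; probabilities floored at
  1e-300 before logs where models may contain structural zeros.
* Aggregated representative covariances are symmetrised and given a 1e-6
  eigenvalue floor against degenerate aggregation.
* Determinism: every stochastic routine takes a seed; identical seeds give
  bit-identical results, and model archives (HDF5 arrays + JSON metadata
  with format version and sha256 checksum) round-trip exactly.
* The hierarchical-EM bound is a lower bound, not the exact expected
  log-likelihood; group comparisons inherit its slack, which grows as the
  state correspondence between models blurs.
* The co-clustering assignment is a single hard/soft label per subject; it
  cannot represent subjects whose grouping genuinely differs by stimulus.
* Group-count selection depends on the Dirichlet concentration on group
  weights (1/G_max); very small planted separations can legitimately merge
  groups.
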