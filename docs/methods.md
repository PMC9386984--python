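# Methods

## The problem

Single-primer repeat-amplicon assays (FAST-SeqS-style) amplify on the order
of 10^4 dispersed LINE-1 repeat loci with one primer pair and sequence the
product shallowly. The number of aligned reads per locus is informative
about somatic copy number, but two nuisance effects dominate the raw
counts: a locus-specific amplification/alignment bias spanning orders of
magnitude, and sample-specific overdispersion relative to binomial
counting noise. `repeatcn` models both explicitly and infers a *relative*
copy number (RCN) profile — copy number scaled so that the
bias-weighted genome average is 1 — together with a posterior over the
number of distinct copy-number states, which is what lets a flat (normal)
sample be distinguished from an altered one.

## Count model

For a sample with total aligned reads `n`, the count at locus `l` is

    theta_l ~ Beta(s * c_l * m_l,  s * (1 - c_l * m_l))
    y_l     ~ Binomial(n, theta_l)

- `m_l` — locus count-proportion bias: the expected fraction of reads at
  locus `l` in a diploid sample; `sum_l m_l = 1`.
- `c_l` — relative copy number at the locus; `E[theta_l] = c_l * m_l`, so
  doubling the copy number doubles the expected read fraction.
- `s` — inverse dispersion (beta-binomial concentration). The count
  variance is the binomial variance inflated by `(s+n)/(s+1)`:
  `Var(y) = (1 + (n-1)/(s+1)) * (mu - mu^2/n)` with `mu = n c m`; as
  `s -> inf` binomial noise is recovered.

`theta` is always integrated out analytically (beta-binomial likelihood);
no stage of the samplers draws it. The log-pmf is evaluated through
log-rising-factorials with an asymptotic branch for very large arguments,
which keeps the near-binomial regime (`s` up to 1e12 and beyond) accurate
to better than 1e-9 pointwise — formulations that subtract two log-beta
values lose that limit to cancellation.

A hard validity constraint `0 < c_l * m_l < 1` (both beta parameters
positive) is enforced by rejecting Metropolis-Hastings proposals that
violate it, never by clipping.

## Control fit (bias inference)

Controls are assumed diploid, i.e. `c = 1` everywhere. Given a panel of
`K` controls the posterior over `(m, s_1..s_K)` is sampled by
Metropolis-Hastings under independent `Beta(1, 1)` priors on each `m_l`
and `Gamma(shape 1.5, scale 1e6)` priors on each `s_k`:

- per-locus logit-scale random walks on `m_l`, accepted locus by locus
  (valid because the likelihood factorises over loci given `s`);
- per-control log-scale random walks on `s_k`.

Step sizes adapt toward ~30% acceptance during burn-in only; the retained
chain is a valid fixed-kernel MCMC. The chain starts from pooled empirical
proportions for `m` and a method-of-moments overdispersion estimate for
`s`. No simplex constraint is applied during sampling — the priors are
independent per locus — and the per-locus posterior modes (Gaussian KDE,
Silverman bandwidth, 401-point grid over the sample range) are rescaled to
sum to one only at summary time. Default run length 20,000 iterations with
5,000 burn-in.

## Copy-number sampler

Given the fitted bias `m̂` and one sample's counts, copy number is
modelled by a sticky hierarchical-Dirichlet-process HMM: each chromosome
arm is an independent Markov chain over a shared, in principle unbounded,
set of hidden states; state `u` carries an RCN value `c_u ~ Gamma(shape 3,
scale 1)`. The transition prior has mean

    E[pi_{u,v}] = (1 - rho) * beta_v + rho * delta_{u,v}

with global weights `beta ~ GEM(gamma=1)`, self-transition weight
`rho ~ Beta(100000, 100)` (mean ~0.999, encoding strong spatial
persistence) and total concentration `(alpha+kappa) ~ Gamma(shape 2000,
scale 10)`. The sample has its own inverse dispersion
`s~ ~ Gamma(1.5, 1e6)`.

Inference uses the weak-limit truncation at `K_max` states (default 25; a
warning is raised if the truncation is ever saturated). One sweep:

1. **Blocked path update** — beta-binomial log-emissions for every
   (locus, state), then an exact forward-backward joint draw of the state
   path, arm by arm. Single-locus arms use the initial distribution only.
2. **Weights and transitions** — Chinese-restaurant table counts with the
   sticky override correction, then Dirichlet draws of `beta`, each
   transition row (concentration `alpha*beta + kappa*delta_u` plus counts)
   and the initial distribution (no stickiness).
3. **State RCNs** — log-scale random-walk MH for each populated state;
   unpopulated states are redrawn from the Gamma base distribution, which
   is what lets the populated-state count grow.
4. **Dispersion** `s~` — log-scale MH against the full assigned-state
   likelihood.
5. **rho and (alpha+kappa)** — logit-/log-scale MH against the Dirichlet
   densities of the current transition rows plus their priors. Under the
   very strong stated priors these move little; the simple random-walk
   update was chosen over auxiliary-variable schemes for that reason.

Initialisation is the null profile (all loci in one state at RCN 1,
moment-matched dispersion), which is the natural origin and makes the
flat-sample behaviour exact. Defaults: 50,000 iterations, 20,000 burn-in,
thinning 5; a shorter 30,000/5,000 preset is intended for dilution-series
screening.

## Summaries

Two complementary summaries:

- **Marginal**: per locus, the RCN draws of its assigned state are pooled
  over the chain; the reported value is the KDE mode and the interval the
  equal-tailed quantiles (default 95%, a conventional choice — the level
  is configurable).
- **State-based**: the modal populated-state count `k` is taken over the
  chain (ties to the smaller count), iterations with exactly `k` populated
  states are kept, and label switching is resolved by Stephens' iterative
  KL scheme on the hard assignments, each step solved as a k x k linear
  assignment (Hungarian algorithm). Draws are pre-aligned by sorting
  states on their RCN, which already fixes well-separated chains; the KL
  rounds handle the rest, to a fixed point (at most 100 rounds). Each
  locus is then assigned its most frequent relabelled state (ties to the
  lower index).

The relabeling permutes labels only — the multiset of (RCN, assignment)
values within an iteration is untouched.

## Read-processing pipeline

From FASTQ to counts: minimum-Hamming-distance primer search over all
full-overlap windows (leftmost tie wins; reads whose best window exceeds 5
mismatches are dropped), trimming through the primer and truncation to
`100 - primer_length` bases (shorter remainders dropped), rejection of
reads with any base under Phred 20 or any `N`, and collapse to unique
sequences with multiplicities. Alignment is delegated to an external
unique-mapping aligner; unique sequences are exported as FASTA with counts
in the headers and alignments are read back from SAM/BAM or a 4-column
table. The count matrix is assembled over the union of aligned loci
across samples (absent loci count 0; distinct sequences hitting one locus
are summed), and loci selection removes non-autosomal/unplaced loci and
any locus with a zero count in any control. Arm labels come from a
user-suppliable boundary table (half-open, BED-like); a GRCh38 table with
approximate centromere splits is packaged.

## Synthetic data

The simulator draws from exactly the model above: log-normal locus biases
(sigma 1.0 by default, mimicking the orders-of-magnitude spread of real
amplicon panels; a flat-Beta generator is available), beta-binomial
control counts at RCN 1, and piecewise-constant profiles specified as
(locus count, RCN) segments. Purity mixing is linear on the RCN scale,
`c_eff = p*c + (1-p)*1`, rescaled so `sum(c_eff * m) = 1` — pinning the
truth to the same relative scale the model infers. Dilution series are
built at count level: the required tumour reads are
`round(desired_purity * total / source_purity)` and the remainder comes
from a control pool, each drawn without replacement (multivariate
hypergeometric), which is distributionally identical to subsampling reads
under unique alignment.

What the simulator does *not* emulate: alignment artefacts and
multi-mapping loss, batch effects between control panels, GC/fragment-size
covariates, and subclonal heterogeneity (a locus has one RCN). Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the stated noise model, not robustness to every artefact
of real libraries.

## Test problem sizes and numerical choices

The recovery fixtures used by the test suite: an 8-control panel (L=500,
2e5 reads, s=1e4, 4,000 MH iterations) for bias recovery; a four-state
profile (L=1000, states {0.5, 1, 1.5, 3}, 250 loci per state across eight
arms, 2e6 reads, 5,000 sweeps) for copy-number recovery; and a dilution
ladder (L=400, purities 0.3/0.1/0.03/0, three replicates, 1,500 sweeps)
for detection behaviour. The four-state fixture balances its states
because rank correlation against a discrete truth is bounded by the tie
structure: with 75% of loci at RCN 1, even `truth + epsilon` noise cannot
exceed r_s ~ 0.88, regardless of estimator quality; with balanced states
the tie ceiling is ~0.97 and the sampler reaches ~0.978.

Numerical guards: Dirichlet draws with tiny concentrations are floored at
1e-300 before normalisation; -inf emissions mark invalid (state, locus)
pairs and the path sampler errors only if a locus has no valid state;
degenerate (constant) traces return their constant as the mode. KDE
bandwidth is the normal-reference rule `0.9 min(sd, IQR/1.34) T^{-1/5}`.

## Known limitations

- The weak-limit truncation is an approximation to the full Dirichlet
  process; `K_max = 25` is far above the populated counts seen in
  practice, and posteriors are insensitive to raising it (tested).
- `rho` and `(alpha+kappa)` mix slowly under their near-degenerate priors;
  this matches the intended behaviour (the priors are meant to dominate)
  but these hyperparameters should not be interpreted as data-driven.
- Per-control dispersions are weakly identified from a single panel;
  recovery is accurate only to ~10-25% relative error, and the bias vector
  is the robust quantity.
- The marginal summary can smear loci that mix between states; the
  state-based summary is the sharper instrument when the state count is
  well determined.
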