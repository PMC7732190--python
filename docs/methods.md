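# Methods

This note records the models, defaults, numerical choices, and known
limitations of `lbasim`.  It is the package's own account of its science;
every number referenced here is computed by the test suite or by
`scripts/acceptance.py` at run time.

## Substitution models

All models are continuous-time reversible Markov chains on the 20 amino
acids (fixed alphabet order `ARNDCQEGHILKMFPSTWYV`; code 20 = gap/unknown,
treated as fully missing).  A rate matrix is built as
`Q_ij = s_ij * pi_j` from a symmetric exchangeability matrix `s` and a
stationary profile `pi`, normalized so that one unit of branch length is
one expected substitution per site at stationarity
(`-sum_i pi_i Q_ii = 1`).  Detailed balance holds by construction, so all
likelihoods carry unrooted semantics (the pulley principle): rooting of
stored trees is presentational only, and the optimizer internally
suppresses a bifurcating root.

Bundled exchangeabilities are the published LG matrix (with its published
stationary frequencies) and the Poisson (all-equal) matrix; the CAT-F81
analog combines Poisson exchangeabilities with a profile mixture.  Profile
entries of zero are clamped to 1e-10 and renormalized before a rate matrix
is built.

Rate heterogeneity across sites uses the standard discrete-gamma scheme: k
equal-probability categories (default k = 4), each category's rate equal
to its conditional mean computed from the regularized incomplete gamma
function, rescaled so the mean rate is exactly 1.  The gamma shape used
throughout the experiments is alpha = 0.8, a value typical of phylogenomic
amino-acid alignments; it is configurable everywhere.

Compositional heterogeneity across sites enters through the frequency
mode:

* `single` — one profile (LG's own, or +F empirical frequencies observed
  in the alignment);
* `mixture` — a finite set of profiles with simplex weights; the site
  likelihood averages over components (and rate categories) before the
  log is taken.  Profiles are always fixed; weights may optionally be
  re-estimated by EM at fixed branch lengths.  Estimating the profiles
  themselves (as CAT does by Dirichlet-process MCMC) is out of scope;
* `per_site` — one fixed profile per alignment column.  This mode houses
  the PMSF approximation: given a guide tree, each site's
  mixture-component posterior is computed exactly, and the
  posterior-weighted average of the component profiles becomes the site's
  profile.  Following standard practice, the guide tree is the fitted tree
  of the homogeneous model.

## Likelihood computation and optimization

Per-site likelihoods use Felsenstein pruning over unique site patterns
with per-node rescaling of conditional vectors (accumulated in log space),
so deep or long trees do not underflow.  Transition matrices come from the
symmetrized spectral decomposition of `Q`, computed once per component
(batched over components, and over sites in per-site mode).

Branch lengths are optimized by exact coordinate ascent.  Edges are
visited in an Euler-tour order in which "down" partial vectors are
refreshed on subtree exit and "up" partials are threaded along the tour,
so every one-dimensional optimization sees exact partials and the total
log-likelihood is monotone non-decreasing across cycles; a cycle-level
guard restores the previous lengths if numerical round-off ever produces a
decrease.  Along one edge the likelihood is `sum_m ab_m exp(lambda_m t)`
with partials folded into the eigenbasis, so each trial length costs one
small matrix-vector product; the scalar search is bounded Brent on
[1e-8, 20] substitutions/site.  In per-site mode the fold-in is evaluated
in single precision — ample for locating a one-dimensional optimum — while
all reported likelihoods are double precision.  Non-convergence within
`max_cycles` is flagged on the result, not raised; under the coarse
tolerances used for candidate screening (`tol = 1e-2`, 6 cycles) the flag
is routine and harmless, because competing topologies differ by tens to
hundreds of log-likelihood units.

The gamma shape is fitted, when requested, by bounded one-dimensional
search on [0.05, 10], interleaved with branch-length cycles (one
alternation by default).

## Topology machinery

Full tree search is replaced by evaluation of a small named candidate set
— for the questions this package targets only two resolutions compete —
optionally refined by greedy best-improvement NNI search (with a
split-signature cache so revisited topologies are not refit).  Ties break
deterministically by candidate order.  Mixture-model candidate evaluation
uses the two-pass PMSF protocol (guide = homogeneous fit, warm-starting
the per-site fits from the guide's branch lengths); this mirrors how large
empirical datasets are analyzed in practice and is roughly five times
faster than direct mixture optimization at equal accuracy.

Bootstrap support is the standard nonparametric site-resampling bootstrap
over the candidate set.  By default candidate branch lengths are fitted
once on the original alignment and each replicate re-scores candidates by
resampled sums of per-site log-likelihoods — algebraically identical to
re-evaluating with fixed branch lengths, at a fraction of the cost
(the RELL idea); full re-optimization within every replicate is available
via a flag and agrees with the fast path on strong-signal data.

## The synthetic study system

`synthetic_data.make_backbone` builds a 12-taxon, four-clade tree: 3
outgroup taxa (terminals 1.2), 3 focal-clade taxa (terminals 1.0), and two
3-taxon ingroup clades (terminals 0.25), every internal branch 0.04
substitutions/site.  The `farris` arrangement attaches the focal clade
next to the outgroup; `felsenstein` tucks it inside, sister to one ingroup
clade.  The two arrangements share an identical branch-length multiset, so
recovery differences between them cannot be a tree-length artifact.  The
branch-length magnitudes are package calibration choices selected once to
land in the LBA-sensitive regime — long terminals roughly 4-5 times the
short ones, internals near the resolution limit of a few thousand sites —
and are not estimates of any particular empirical dataset.

Heterogeneous generating models draw 20 profiles from a symmetric
Dirichlet(0.2) with uniform weights.  Low concentration yields sparse
profiles (a handful of amino acids dominate each), which is exactly the
property that produces convergent substitutions a homogeneous model
misreads.  Presets `C10-like`/`C60-like` are reproducible Dirichlet sets
of 10/60 components for use as inference-side mixtures.  A caveat
discovered during development and worth stating: a *mismatched* random
profile set (for example C10-like profiles on data generated from a
different 20-profile set) can fit worse than plain LG+G, because random
sparse profiles — unlike the empirically estimated C-series — carry no
guarantee of covering the generating compositions.  The heterogeneous
inference model used in the experiments is therefore the generating
mixture itself, playing the role an empirically fitted C-series set plays
when it approximates a fitted CAT model on real data.

Gene sets of graded quality scale terminal branches by 0.5 -> 2.0 and
internal branches by 1.5 -> 0.5 linearly across 20 genes of 500 sites:
best-end genes have short terminals and long internals (the regime that
resists LBA), worst-end genes the reverse.

Replicate ensembles emulate simulating from a posterior sample of
parameter draws: each replicate multiplies every branch by an i.i.d.
lognormal factor (sd 0.05 in log space, applied by the experiment drivers)
and uses an RNG stream derived deterministically from (seed, replicate).
Per-site profile and rate-category assignments are i.i.d.; no indels are
simulated (likelihood analyses treat gaps as missing anyway).

What the generator does *not* emulate: taxon-specific compositional
drift, heterotachy, alignment error, or missing data — passing tests
therefore show the machinery reproduces the asymmetry when compositional
site-heterogeneity is the only violation, not that real datasets contain
no other violations.

## Experiment defaults and problem sizes

The shipped experiments run at desk scale, chosen so the full suite
completes on a single core:

* **Branch-length bias** — one 5,000-site heterogeneous simulation on the
  Farris arrangement, branch lengths refit under LG+G and under the
  mixture (via PMSF).  The homogeneous model shortens every branch long
  enough for its maximum-likelihood estimate to stand clear of sampling
  noise (>= 0.25 here, about half the true length at the long end), and
  the relative shortfall grows with branch length.  The 0.04 internals
  sit below MLE noise at these sizes, so no directional claim is tested
  for them.
* **Recovery asymmetry** — 50 replicates x 2,000 sites per arrangement.
  Felsenstein-zone data: the homogeneous model picks the wrong tree in
  most replicates while the mixture recovers the truth; Farris-zone data:
  both models recover the truth in essentially every replicate.  At these
  sizes an occasional Farris-zone replicate carries no signal on the tiny
  central branch and the two candidates tie to within numerical
  resolution, so mixture-side recovery is asserted at >= 90% rather than
  literally 100%.
* **Mixing** — 8 pairs x 5 proportions x 2,000 sites, mixture inference
  (PMSF).  The winner rate is monotone in the mixture proportion and the
  50/50 point leans toward the Farris-zone tree — the quantitative face of
  the asymmetry.
* **Taxon removal** — the acoelomorph-analog variant gives the focal clade
  one slow taxon (terminal 0.3) and two fast ones (terminals 2.0);
  dropping the fast pair raises correct recovery under the homogeneous
  model by tens of points.
* **Cross-validation** — 10 repetitions of train 10,000 / test 2,000
  disjoint site draws on a 12,000-site heterogeneous alignment, fixed
  topology, branch lengths and gamma shape refit per repetition (mixture
  fitting via PMSF on the training sites; held-out scoring always under
  the full mixture, since per-site profiles do not transfer across site
  sets).  The heterogeneous model wins every repetition by thousands of
  log-likelihood units.
* **Gene ranking** — 20 genes x 500 sites; gene trees are NNI hill climbs
  from random-addition starts (capped at 8 rounds) under LG+G; the
  Spearman correlation between the monophyly-score rank and the generating
  quality gradient exceeds 0.6 by a wide margin.

## Numerical choices and degenerate inputs

* Branch-length bounds [1e-8, 20]; identical sequences drive a branch to
  the lower bound (resolved to the scalar-search tolerance `xatol`).
* All-gap sites contribute log-likelihood 0; all-gap alignments are legal.
* Mixture weights and profiles are validated to simplex tolerance 1e-12 on
  construction; gamma category means to 1e-10.
* Multifurcating newick input is rejected by default; an option resolves
  polytomies arbitrarily with zero-length branches (guide trees here are
  binary, with the customary trifurcating root for unrooted trees).
* Site-pattern compression is automatic except in per-site-profile mode,
  where every column is its own pattern.
* Memory scales as (components x rate categories x sites x 20) doubles
  per internal node during optimization; direct C60-scale mixture
  optimization on long alignments is therefore best routed through PMSF.

## Limitations

* Profiles are never estimated from data; the CAT model's
  Dirichlet-process machinery is intentionally absent.
* ML point estimates replace Bayesian posteriors throughout; claims about
  central tendencies of branch lengths carry over, credible intervals do
  not.
* Candidate-set evaluation (plus NNI) stands in for full tree search; with
  the bundled 12-taxon backbones the NNI neighborhood is ample, but the
  package has no SPR/TBR and is not a general tree-search tool.
* The ultrafast-bootstrap algorithm is not implemented; support values are
  plain nonparametric bootstrap frequencies.
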