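# Methods

This note documents the statistical models implemented in `aafphylo`, the
choices made where the design was open, what the simulators do and do not
emulate, and the known limits of the analytic approximations — including
several places where our own Monte-Carlo experiments show the closed-form
models to be measurably approximate.

## Distance estimation

The estimand *d* is the expected number of mutation events (substitutions
plus indels) per site separating two genomes. Each site mutates as a
Poisson process, so a k-mer survives unchanged with probability e^(-kd) and
the shared fraction of canonical k-mers estimates it:
D = -(1/k)·ln(n_s/n_t). n_t is the *smaller* of the two distinct-k-mer
totals because deletions destroy more k-mers (l + k - 1) than insertions
create, biasing the larger-genome total.

Degenerate pairs with n_s = 0 are capped with a half-count continuity
correction, D = -(1/k)·ln(0.5/n_t), and flagged; an infinite distance would
poison the weighted fit.

**Back substitutions.** With transition probability w_s and per-target
transversion probability w_t (w_s + 2w_t = 1), the probability that m hits
at one site produce no net change is γ_m (γ_0 = 1, γ_1 = 0,
γ_2 = w_s² + 2w_t², γ_3 = 2w_s²w_t + 4w_t³; higher terms are negligible and
the series is truncated at m = 3). Solving
(Σ_m γ_m D^m e^(-D)/m!)^k = n_s/n_t for D by bracketed root finding on
[0, 2] (scipy `brentq`, xtol 1e-10) recovers d exactly; the plain estimator
understates d = 0.2 by 3.86% (reported as 4%), independent of k because the
series enters only through ratio^k. The correction is off by default — at
the divergences the method is recommended for (d < 0.1) it changes D by
under 2% — and togglable with configurable w_s, w_t (defaults 0.5, 0.25,
the κ = 2 HKY values at equal base frequencies).

**WLS weights.** For fixed n_t, n_s is approximately binomial, making
log(n_s/n_t) approximately normal with variance
σ² ≈ (1/n_t)(1 - e^(-kD))/e^(-kD) on the D scale. The fit minimises
Σ ω(kD̂)(D - D̂)² with ω the *reciprocal* of that expression
(inverse-variance weighting; the alternative reading — weights equal to the
variance — would up-weight the noisiest long distances and contradicts the
objective's purpose). D̂ is floored at 1e-6 inside ω so zero distances keep
a finite weight.

## Tree fitting

The fitted tree minimises the weighted sum of squares over unrooted
topologies and non-negative branch lengths. The search is:

1. neighbor-joining starting topology (scikit-bio);
2. branch lengths by non-negative least squares (scipy `nnls`) on the
   path-incidence system, with ω recomputed from the current fitted
   distances and iterated to convergence (relative objective change
   < 1e-8, ≤ 20 iterations; if a reweighting step increases the objective
   the previous iterate is kept);
3. nearest-neighbor-interchange hill climbing: internal edges in canonical
   bipartition order, two NNI alternatives each, first strictly improving
   move taken, repeat until none improves.

Local optimality is the contract, not global; on noiseless additive
matrices the optimum is exact, and on noisy 5-taxon matrices the search
matches exhaustive enumeration of all 15 topologies in our tests.
Tie-breaks keep the incumbent, which together with the canonical taxon
ordering makes the result invariant to input order. Negative branch
lengths never arise (active-set non-negativity).

**Tip correction** is applied only after the topology is fitted (the
weights belong to the *observed* counts) and only to terminal branches,
floored at zero with a warning. With heterogeneous sequencing, each pair's
correction uses the parameters of its lower-n_t taxon and every tip is
trimmed by the mean over pairs.

**Tree comparison.** Branch score distance matches edges by bipartition,
charges edges private to one tree their full length, and reports the square
root of the sum of squared differences (the PHYLIP treedist convention; the
plain sum is available via `sqrt=False`/`--no-sqrt`). Topological mistakes
are the internal bipartitions of one tree absent from the other — half the
Robinson-Foulds distance for binary trees.

## K-mer homoplasy

Identical k-mers at non-homologous locations inflate n_s/n_t above
e^(-kd). With q(j) the fraction of distinct k-mers having j total copies
(j ≥ 1) in the shorter genome, and P = 2(0.5 - u + u²)^k the chance two
random loci carry the same canonical k-mer:

    1 - p1 = Σ_j (1 - e^(-kd))^j q(j)          all copies mutated
    p2     = (1 - e^(-kd)) (1 - (1-P)^g)       mutation re-creates the k-mer
    p3     = 0.5 e^(-kd) Σ_j (1 - (1-P)^g)^j q(j)
    p_h    = p1 + (1-p1) p2 + (1-p1)(1-p2) p3

The exponent is the *total* copy number: only under this indexing does the
Binomial(g, P) spectrum reproduce the random-genome closed forms (a
binomial-theorem identity our tests verify numerically). All (1-x)^g terms
are computed as exp(g·log1p(-x)), stable to g = 1e10.

**Known approximation.** Stratified Monte-Carlo experiments (see
`tests/test_acceptance.py`) show the p1 channel
is accurate per copy class, but p2/p3 assume a k-mer's copy count in one
genome is independent of its chance presence elsewhere in the other. For
closely related genomes these are strongly anti-correlated — a k-mer that
is single-copy in A would, were it also present non-homologously in B,
almost surely be multi-copy in A too — so the closed form overpredicts
sharing by up to ~3% (relative) where mutation-mediated homoplasy dominates
(g = 1e5, k = 9-11 at d ≤ 0.1). For k large enough that homoplasy is
negligible — the regime `select_k` targets — the prediction is exact to
Monte-Carlo error.

**Choosing k.** `select_k` returns the smallest k whose relative excess
p_h/e^(-kd) - 1 at d = d_max falls below `tol = 0.05`. The tolerance was
calibrated once so that random 1 Gbp genomes yield k = 19 (the k=19 excess
is 4.2% at d = 0.1; k=18 is 14%). The threshold k moves by ≤ 2 between
d = 0.02 and d = 0.1 — the recommendation depends only weakly on
divergence. Because the true d is unknown when k is chosen, d_max should
come from a quick first pass at a conservative large k. With an empirical
spectrum per k (`spec_by_k`), the same rule uses the genome's actual
complexity; low-complexity genomes need larger k than the random-genome
curve suggests.

## Coverage, sequencing error, filtering

All sampling results flow from two Poisson rates per k-mer locus: covering
read starts L = c(r-k+1)/r and error-free coverings λ = L(1-E)^k.
Retention is P(Poisson ≥ m) with m = 1, or m = 2 when singletons are
filtered: p_ef = P(Pois(λ) ≥ 2)/P(Pois(L) ≥ 2), whose algebraic equivalence
to the explicit difference-of-exponentials form is unit-tested. False k-mers arise at rate
p_ta = L(1 - (1-E)^k) per true k-mer (total) and
p_sa = L(1 - (1 - E/3)^(kd)) (shared); filtering sets both to ~0. The
observed/true ratios are p_t = p_r·p_e + p_ta and p_s = (p_r·p_e)² + p_sa,
giving the distance bias -(1/k)·ln(p_s/p_t), the variance
(1/k²)[log(1 + (q_s(1-q_s)+p_sa)/(n_s(q_s+p_sa)²)) + (total term)], and the
tip correction. The variance's second term uses 1/n_s by default even
though a symmetry argument suggests 1/n_t; the variant is available via
the `nt_variant` keyword. p_sa needs a provisional distance and is
evaluated at the observed-data estimate; because p_sa varies only weakly
with d over the bias range, iterating the substitution changes nothing
material.

Monte-Carlo validation (circular read placement, matching the model's
stationarity assumption; the default simulator is linear and its ~r/g edge
deficit is accepted) shows:

* retention (p_r, p_rf, p_e, p_ef) and the unfiltered false-total rate p_ta
  are exact to 3 SE across c = 1..10, E ∈ {0, 0.01};
* filtered false k-mers are not exactly zero — duplicate identical
  sequencing errors leave ~1% of n_t at 10X/1% error — "vanishingly small"
  is accurate only as an order of magnitude;
* the bias prediction runs ~8% high at c = 5, E = 1%: p_sa counts only
  error-k-mers of one genome matching true k-mers of the other, while the
  symmetric direction and error-error matches roughly double the
  false-shared rate;
* the variance prediction runs ~3× low: it treats k-mer retention as
  independent across k-mers, but a read retains a block of r-k+1 adjacent
  k-mers at once. The read-overlap factors (1 + (r-k)/L) and (1 + w) that
  the parametric bootstrap adds are exactly the missing structure. The
  variance formula is therefore used only *comparatively* — the
  filter-or-not crossover (between 5X and 8X for k = 11..15 at r = 76,
  E = 1%) and the WLS weighting are unaffected by a common scale factor.
  One more verbatim-form quirk: with errors and no filtering the variance
  has a shallow minimum near 7-8X rather than decreasing monotonically.

The pipeline's default filtering rule follows the crossover: on when every
taxon has ≥ 5X coverage, off otherwise, always user-overridable.

## Bootstrap

Stage 1 (sampling variance) resamples each taxon's reads with replacement;
stage 2 additionally resamples round(M/k) rows of the merged
presence/absence table — 1 in k because adjacent k-mers overlap (each
nucleotide sits in up to k k-mers), the block-bootstrap correction. Our
tests confirm the row bootstrap reproduces the across-realisation
evolutionary variance of D for a single pair. For *contrasts* between
overlapping pairs (what topology support actually depends on) it is
conservative: subsampling destroys the shared-history correlation that
makes cherry contrasts precise.

The parametric bootstrap perturbs the distance matrix directly. Stage 1
adds independent Gaussian noise with the overlap-corrected sampling SD,
multiplied by 2 — deliberately conservative, since the analytic SD can be
off by ~50% either way. Stage 2 adds correlated Gaussian noise: per-pair
variance (1/(k²n_t))[(e^(kD)-1) + 2Σ_{i<k}(e^(iD)-1)] (the k-mer-overlap
generalisation of the WLS variance; equal to it at k = 1), and covariance
between pairs equal to their shared tree-path length times the geometric
mean of the pairs' variance per unit path length (the scaling constant is
not fixed by theory; this choice makes the diagonal consistent and the
matrix nearly PSD — tiny negative eigenvalues are clipped, logged).
Contaminated distances are floored at 0; replicate trees are refit with the
NJ restart each time. Support is reported as replicate counts per internal
bipartition, stage 2 headline with stage 1 in parentheses, percentages in
Newick output.

Because stage 1 is inflated 2× and the two modes model contrast noise
differently, parametric support is systematically *lower* than
nonparametric on marginal nodes under low coverage, and can be higher on
cherry contrasts where the row bootstrap is conservative; saturated nodes
agree exactly. The two modes should be read as deliberately-conservative
(parametric) versus resampling-based (nonparametric) assessments, not as
interchangeable numbers.

## Simulators

`random_genome` draws i.i.d. bases from GC content u. `evolve_sequence`
applies per-site Poisson(d) substitution counts through the HKY conditional
transition matrix (κ = 2 by default — we read "transition bias 2" as the
HKY rate ratio κ, so at u = 0.5 half of all substitutions are transitions)
and indels at a combined 10% of the substitution rate, insertions and
deletions equally likely, lengths uniform on 1..5, positions uniform,
inserted bases i.i.d. from the base frequencies. Branch lengths are
expected substitutions per site — the same scale as D. Multi-hit
substitutions are real events here, so validation experiments compare
observed sharing against e^(-k·d_eff) with d_eff = -ln(Σ γ_m d^m e^(-d)/m!),
the effective identity distance the process realises (at d = 0.1,
d_eff = 0.0981; 30-replicate estimates at k = 17 hit it to 4 decimal
places).

`simulate_reads` places N = round(cg/r) reads uniformly (linear by
default, circular for the sampling-model oracles), flips each base with
probability E to one of the three alternatives uniformly, and returns a
read matrix; FASTQ output has constant quality. No quality-score model, GC
coverage bias, PCR duplicates or insert-size structure — mates are
independent reads. Consequently, passing tests demonstrate correctness
under the models' own assumptions; real libraries violate them in the
directions the limitations above describe.

The benchmark 12-taxon tree (`BENCHMARK_TREE_12`) is a primate-like ladder
with cherries, base-to-tip depth ~0.1 and internal edges down to 0.002 —
short deep branches are what makes topology recovery non-trivial. Random
ancestors lack the repeat structure of real genomes, so experiments that
hinge on repeats interacting with sequencing error (e.g. filtering's
benefit at high coverage) show weaker effects here than on real data.

## Problem sizes in the validation suite

Chosen to exercise each claim at the smallest informative scale: topology
recovery uses 100 replicates of 160 kbp ancestors (plus 5 replicates at
640 kbp to show k = 9 homoplasy failure); homoplasy prediction uses three
100 kbp pairs across k = 9..17; the sampling oracle uses a 50 kbp genome
with 6-12 read redraws per setting and 80 for variances; the filtering
study 50 replicates at 80 kbp; tip correction 20 replicates; bootstrap
comparisons B = 50 on one 80 kbp dataset per regime. All seeds are fixed;
every experiment regenerates its data at run time.
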