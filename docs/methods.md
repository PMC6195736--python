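# Methods

## The substitution model

The package models substitution *counts* directly rather than a
continuous-time Markov rate matrix.  The process at each site is assumed
memoryless: counts in disjoint time intervals are independent, so given
all rate-relevant covariates the count in a state with exposure time *e*
is Poisson with mean λ·e.  The log rate is linear in the covariates and
the exposure enters as an offset with coefficient fixed at 1.  Latent
rate variation (clade effects, unmodeled biochemistry) is accommodated by
the NB2 negative binomial, the marginal law of a Poisson whose rate is
multiplied by a Gamma(shape, 1/shape) variate; a markedly lower NB AIC
than Poisson AIC is therefore a diagnostic that relevant factors are
missing from the model, not merely a better fit.

Rates are small relative to branch durations, so the probability of two
substitutions in one state on one branch is negligible; the model treats
the exposure of a state as ending at the branch's end even when an event
occurs mid-branch.

## States, exposure and attribution conventions

A state bundles everything rate-relevant about a site at a moment on the
tree: the static factors (gene, cluster, region class, codon position,
directionality, numeric site covariates) and the dynamic ones (codon and
derived amino acid/nucleotide, flanking neighbors, CpG status).  The
exposure table has one row per (site, dynamic state) with summed exposure
and counts.

Two conventions make the accounting exact and mutually consistent:

- **Parent-state attribution.**  A branch's whole duration is credited to
  the state at the branch's start (the parent node).  Substitution counts
  are credited to the same row — including the rare second event at one
  site on one branch, which conceptually belongs to the state whose rate
  was at risk for the branch.  Event *classification* (transition vs
  transversion, synonymous vs non-synonymous) uses the sequential
  context, i.e. the parent sequence with the branch's earlier tokens
  applied, so the recorded ancestral base always matches.
- **Branch-end placement in the simulator.**  The generator draws each
  branch-site count from the branch-start state's rate and applies the
  events at the branch end, so simulator and estimator share one
  convention and the fitted likelihood is exactly the generating one.

Rows with zero exposure and zero counts never exist; rows with zero
exposure but positive counts (second events) are excluded from fits,
since their offset is undefined.

## Sequence orientation

All sequence-derived factors — codon, neighbors, CpG — are evaluated on
the genome orientation as written (the heavy-strand reference), for
light-strand genes too; the strand difference is carried by the
directionality indicator instead.  This keeps the invariant that a
coding state's nucleotide equals its codon at the codon position, at the
cost of reading light-strand codons in non-biological orientation; for
model selection on synthetic data the convention is immaterial because
generator and estimator share it, but annotations for real light-strand
genes should be interpreted accordingly.  The genome is circular:
neighbors wrap around the origin.  Overlapping regions are resolved by
annotation order (first region listed owns the site); coordinates are
1-based inclusive throughout.

## Genetic code

Translation uses the vertebrate mitochondrial code (ATA→Met, TGA→Trp,
AGA/AGG→stop), with stop as an ordinary 21st amino-acid symbol: a change
into or out of a stop codon is non-synonymous, nothing is filtered.  Each
codon position has exactly one transition and two transversions among its
three alternatives; the per-codon table of possible synonymous and
non-synonymous changes drives the extra offset log(#A + r·#B) used when
the two responses are modeled separately, with r the empirical
transversion/transition ratio of the analyzed events (overridable).

## Node-time estimation

Branch durations are estimated by maximizing the identity-link Poisson
likelihood Σ_b [c_b·log μ_b − μ_b] with μ_b = t_parent − t_child, tips
pinned at t = 0 and the rate normalized to one substitution per time
unit — the normalization *is* the uncalibrated choice and removes the
scale non-identifiability.  The problem is concave with linear ordering
constraints and is solved by SLSQP from a feasible deterministic start
(each node initialized to the maximum cumulative count on any downward
path); a floor of 1e-9 inside the logarithm handles zero-count branches
at the boundary.  Estimation error in times is not propagated into the
downstream regressions.  Doubling all counts exactly doubles all times.

## Regression engine

Fits go through statsmodels: IRLS GLM for Poisson, the discrete NB2
likelihood for the negative binomial, with convergence declared at
relative tolerance 1e-8 within 100 iterations.  Design matrices are built
deterministically — intercept, each categorical factor's sorted
non-reference levels (lexicographically first level is the reference),
then numeric covariates — and aliased columns are removed by an
order-preserving rank filter (earlier columns win), with the dropped
names recorded on the fit.

Negative-binomial estimation has two robustness layers.  The score for
overdispersion at α = 0 is ½·Σ[(y−μ̂)² − y] evaluated at the Poisson
solution; when it is non-positive the NB maximum lies on the
equidispersion boundary, where the NB likelihood equals the Poisson one,
so the Poisson solution is returned with α = 0 and one extra parameter
counted in the AIC.  Otherwise α is estimated jointly by BFGS; if that
fails to converge, a bounded profile-likelihood search over fixed α
(each evaluation an IRLS GLM fit) is tried before the fit is declared
non-converged.  The dispersion always counts as one AIC parameter.

## Gene clustering

Two genes are compared by (1) Kruskal-Wallis on per-site counts, (2) a
2-df likelihood-ratio test of separate intercept-only NB fits (own mean
and own dispersion) against one pooled fit, and (3) a Wald test of the
gene indicator in a pooled NB regression.  Test 2's 2 df and test 3's
Wald form are this package's reading of the procedure; tests 2 and 3
probe similar but not identical nulls.  A pair is joined only if all
three p-values are at least alpha_total / C(n_genes, 2) (0.05/78 for the
13 protein-coding genes).  Clusters are connected components of the
similarity graph; because pairwise similarity is not transitive,
components that are not cliques are flagged in the report rather than
broken by an invented tie-break.  A test that cannot be computed returns
NaN and is treated as a rejection, never as silent similarity.

## Model search

Each applicable factor takes one of {omit, include, partition}.  Three
containment rules prune the grid: a non-omitted codon forces amino acid
and nucleotide out (the codon determines both); gene and cluster are
never both present; partitioning by codon position coerces the two
neighbor factors to share one option (the coupling applies only when
both neighbors are in the factor set, so reduced searches behave).  With
three response schemes (all counts; transitions/transversions;
synonymous/non-synonymous, coding regions only — the paired schemes fit
two regressions on the same design) the protein-coding space is
11·5·21·3³ = 31,185; rRNA/control, which drop codon factors and
directionality and the synonymy scheme, have 3⁵·2 = 486; tRNA keeps
directionality, tripling to 1,458.  Specifications where one factor
determines another (gene present together with directionality, which
only separates the one light-strand gene) are flagged as redundant but
kept, so the counts above are stable.  Sub-models are spawned only for
factor values realized in the data; when the codon is in the model and
the data is partitioned by position, neighbor predictors keep only the
out-of-codon side (left at position 1, right at position 3, neither at
position 2).

Degenerate sub-models — one usable state, or zero substitutions — score
(logL, df) = (0, 1), except a single state with events, which gets the
saturated Poisson likelihood with df 1; non-converged fits score the
saturated per-state Poisson (λ_i = c_i, df = number of states).  These
fallbacks keep the summed AIC finite so a search always completes, and
failures are counted, never raised.  Ranking is by minimum of the two
family AICs, ties broken by fewer parameters, then by specification
order; results are independent of execution order.  A seeded
`max_models` sample supports desk-scale smoke runs of the larger spaces.

## Synthetic data

The generator is the in-silico twin of the fitted model.  Trees are
random coalescent-style topologies with all tips at time 0; while k
lineages remain the next merge waits an exponential time with mean
2·branch_time_mean/k, making the expected total tree length equal
branch_time_mean times the branch count (default mean 1 expected
substitution per branch).  The default toy genome is ~2.9 kb and echoes
the mtDNA region mix: four protein-coding genes (one light-strand), an
rRNA, a tRNA, two control sub-regions and a short unannotated spacer.
Covariates are a standard-normal conservation-like score and a Bernoulli
domain flag.  Default rate parameters: intercept −4 (log substitutions
per site per unit time, giving a few events per site over a
100-200-tip tree, the regime the method targets), codon-position effects
−0.7/+0.9, a +0.6 right-neighbor-G effect, CpG +0.5, and
transversion:transition odds r = 0.0455 matching the strong transition
bias of human mtDNA.  Position-dependent (interaction) effects can be
specified with compound `codon_position*factor` keys; they generate data
under which by-position partitioning is genuinely AIC-optimal, which the
model-recovery studies exploit.  Per-site Gamma multipliers with finite
shape produce negative-binomial marginals for the dispersion diagnostic.

What the generator does not emulate: realistic mtDNA base composition or
codon usage, selection and demography, clade-specific (non-stationary)
rates, indels and heteroplasmy, and back-mutation annotation semantics.
Passing tests therefore demonstrate correctness of the accounting,
estimation and selection machinery under the model's own assumptions,
not that those assumptions hold for any particular real dataset.

## Numerical and procedural choices

- All randomness flows from one integer seed per run; seeded runs are
  byte-reproducible, and search results do not depend on evaluation
  order.
- Exposure conservation (per-site exposures sum to the total tree
  length) holds to 1e-9 relative tolerance and is asserted in tests.
- The AIC identity aic = 2k − 2·logL is maintained on every fit result.
- Indel tokens in branch tables are skipped with a warning; tokens
  flagged as back mutations are treated as ordinary substitutions.
  Ancestral-base mismatches during propagation are hard errors naming
  the branch and site.
- Multiple substitutions at one site on one branch are accepted in
  listed order.
- Statistical study sizes in the test suite (tree sizes of 8-250 tips,
  20-2,000 replicates per property) are chosen so each study resolves
  its effect with comfortable Monte Carlo margin on a single CPU.

## Known limitations

- Wald confidence intervals are used throughout; near-boundary dispersion
  estimates get no interval.
- The exposure convention ignores intra-branch state changes; at the
  event densities the model targets this is a second-order effect, but
  it would bias estimates on trees with very long, event-rich branches.
- The full 31,185-spec protein-coding search over a large table is a
  cluster-scale computation; the package parallelizes naturally over
  specifications but ships no scheduler.
- Control-region sub-region boundaries are taken from the input
  annotation; none are built in.
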