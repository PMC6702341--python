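# Methods

## The inference problem

Three parapatric populations (North, South, West) of a forest-dwelling
anuran show strong mitochondrial structure across a large river. Two
families of explanations are compared: (1) the river acted as a
long-standing barrier, with the main North/South divergence in the
Plio-Pleistocene; (2) the structure is a footprint of the last glacial
cycle, with populations contracting into one or two refugia and
expanding after the Last Glacial Maximum (LGM, ~21 kya). Each family
is expressed as three explicit demographic models (six total), and the
data decide among them by approximate Bayesian computation: simulate
datasets under each model with parameters drawn from priors, summarize
both simulations and data by the same statistic vector, retain the
simulations closest to the data, and read posterior model
probabilities off the retained set.

## Summary statistics

All diversity-type statistics reduce to two primitives: the haplotype
table and the matrix of pairwise sequence differences (gaps and IUPAC
ambiguity codes removed pair-by-pair; a column is polymorphic when it
carries two or more distinct unambiguous bases).

* Haplotype diversity Hd = n(1 − Σp²)/(n − 1), with Nei's sampling
  variance for the reported standard deviation.
* Nucleotide diversity π = k̄/L with k̄ the mean pairwise differences;
  its variance uses the standard no-recombination formula.
* Tajima's D with the 1989 constants. Monomorphic samples report
  D = 0 rather than undefined, matching how such rows are printed in
  empirical tables. At n = 3 the variance coefficients — and the
  numerator — vanish identically, so D is 0 by construction there.
* Fu's Fs uses θ̂ = k̄ and S′ = Pr(K ≥ k_obs) under the Ewens sampling
  formula, with unsigned Stirling numbers of the first kind computed by
  the exact integer recurrence and carried into log space; both tails
  of the logit ln(S′/(1−S′)) are summed by logsumexp so samples of
  several hundred sequences neither overflow nor lose precision.
  Monomorphic samples report 0; a sample with diversity but a single
  haplotype (S′ = 1) raises a degenerate-value error.
* R2 = sqrt(mean_i (U_i − k̄/2)²)/S, where U_i counts singleton alleles
  carried by sequence i, folded (an allele present in exactly one
  sequence), since ancestral states are unknown in the empirical data.
* Significance of D/Fs/R2 comes from constant-size panmictic coalescent
  replicates conditioned on the observed n and S (exactly S mutations
  per genealogy), reporting the low tail Pr(stat ≤ observed) — the
  direction that population expansion pushes all three statistics.
* AMOVA is the one-level molecular variance decomposition on pairwise
  difference counts used directly as squared Euclidean distances (the
  convention for haplotype data); Φ_ST = σ²_a/(σ²_a + σ²_w), with a
  permutation p-value from shuffling individuals among groups.
* Net between-group distance d_net = d_raw − (π_X + π_Y)/2. Groups of
  size < 2 report π = 0 and are flagged.
* The Mantel correlation is Pearson's r of the upper triangles; the
  permutation p is the fraction of row/column co-permutations with
  r ≥ observed, enumerated exhaustively when n! fits the requested
  permutation count.

The ABC summary vector takes, per locus: total π, segregating sites
(ss), Tajima's D, within-group diversity π_w (one entry per group) and
between-group diversity π_b (one per pair), all diversity-like entries
per site so loci of different lengths are comparable; ordering is
locus-major, then statistic, then alphabetical group/pair. Model
choice defaults to the subset (ss, D, π_b), the vector the POD sweep
selects on this design.

## Coalescent simulator

Time is simulated in units of 4·Ne_ref·c generations per locus, where
Ne_ref is the South (ancestral-side) present size of the parameter draw
and c the inheritance scale (1 nuclear, 0.25 mitochondrial: a quarter
as many transmitting copies). In these units a population of relative
size x coalesces k lineages at rate k(k−1)/x regardless of c, and the
per-locus mutation intensity θ = 4·Ne_ref·c·μ·L reduces to the familiar
θ_nuc = 4Neμ L and θ_mit = Neμ L. One conversion path therefore
handles years → coalescent units (t = T/(g·4·Ne_ref·c)) and the
mitochondrial/nuclear diversity ratio of 4 falls out with no special
casing (verified against E[π] = θ in tests).

Exponential growth (backward decline N(t) = Ne·e^(−αt)) is handled by
the closed-form inverse of the cumulative hazard, so waiting times are
exact, not discretized. Demographic events — joins, size changes,
growth changes — interrupt the current epoch; competing coalescence
across populations uses fresh per-epoch exponentials, valid by the
Markov property. Mutations are Poisson on total branch length under
infinite sites; each mutation opens one 0/1 column carried by the
branch's descendant leaves.

For the reference-table pipeline the genotype matrix is skipped: a
single postorder pass counts each branch's descendant leaves per group,
so a mutation's contribution to every statistic is known in O(1). The
random stream is identical in both representations, and tests verify
the statistics agree exactly with those computed from expanded FASTA
alignments.

Not modeled: recombination within loci, migration after divergence,
selection, multiple hits. The two mitochondrial loci get independent
genealogies, matching a simulation design in which each locus is drawn
independently.

## The six models and their priors

Populations North, South and West have independent present sizes
Ne ~ U(10⁴, 10⁶) diploids (the ancestral population draws from the
same window); generation time defaults to 1 year. Mutation-rate
priors: mitochondrial loci use windows of ±20% around the calibration
rates 0.28 (16S) and 0.957 (ND2) % per Myr (2.8×10⁻⁹ and 9.57×10⁻⁹
/site/generation); nuclear loci use a broad U(10⁻⁹, 5×10⁻⁹) window
since no published nuclear estimates exist for this system. These
windows, like all priors, live in `PriorSet` and are config-overridable.

* **Scenario 1 (riverine barrier, no growth).** The main North/South
  divergence T1 ~ U(0.12, 5.33) Myr (Plio-Pleistocene). Model 1 is a
  simultaneous three-way split at T1 (two joins at the same instant,
  applied West-first deterministically — here the "strictly ordered
  events" rule is relaxed to non-decreasing order on purpose).
  Models 2 and 3 split North/South at T1 and found West from South
  (model 2) or North (model 3) at T2 < T1, leaving West at its founder
  size N_f ~ U(10, Ne_source/2).
* **Scenario 2 (glacial refugia, growth).** All events inside
  (0, 21 kyr]. Model 4: a single (southern) refugium founds both
  North and West. Models 5/6: North and South persist as refugia and
  West is founded from South (5) or North (6). Persistent populations
  grow at a drawn rate α ~ U(0, 10⁻³)/generation; founded populations
  grow from N_f at founding to their present Ne, i.e. with the implied
  backward rate ln(Ne/N_f)/T floored at zero (using both the founder
  and the present-size priors without over-determining the
  trajectory). Growth switches off in the ancestral population.

The western colonization time T2 is a recent, LGM-to-present founding
in both scenarios. This is a deliberate design decision: with a free
Plio-Pleistocene T2 the colonization models become continuous
deformations of simple vicariance (T2 → T1) and the model set loses
identifiability; the recent-founding reading also matches the
inference this model family is built to express (a post-glacial
western colonization after an old riverine split). T2 < T1 is enforced
by redrawing whole parameter sets, never by truncating marginals.

## ABC engine

Distances are Euclidean on statistics normalized by their pooled median
absolute deviation (MAD; fallback SD, then 1, for degenerate columns),
so any uniform monotone rescaling of a statistic is absorbed —
verified as an invariance test. Rejection retains round(tolerance ×
rows) rows (strict distance order, stable by row index; a floor of 10
retained rows is enforced). Posteriors are the models' shares of the
retained rows; the optional "classifier" method refits a
single-hidden-layer (8 logistic units) multinomial network on the
retained rows, but plain rejection is the default because it is
exactly reproducible.

Vector selection holds out a fixed number of PODs per model and scores
each candidate subset (all subsets of 2–5 statistics by default) by the
mean of [posterior on the true model − mean posterior on the others].
Prior restriction replaces each prior window by the 2.5–97.5% quantile
range of the draws retained against the observed data, clipped to the
original window, per model. Hierarchical comparison picks the best
model within each scenario and reruns rejection on the pooled rows of
the two winners (no re-simulation — unbiased under equal priors and
cheaper); the Bayes factor is the final posterior ratio.
Cross-validation samples PODs balanced across models without
replacement, removes them from the table, classifies each, and reports
the confusion matrix. Goodness of fit retains the closest rows of the
winning model, computes principal components of their statistics
(SVD; degenerate components dropped), projects the observed vector,
and reports its Mahalanobis-distance percentile within the retained
cloud, passing at ≤ 95.

## Synthetic data and what the tests show

The default study design mirrors the empirical sampling exactly: 16S
(1035 bp, 129/19/3 North/South/West), ND2 (813 bp, 131/35/2), SiaH
(361 bp, 260/46/4), Rhod (378 bp, 292/82/4); mitochondrial loci carry
c = 0.25. The worked-example fixtures are the four western-group
alignments whose statistics are forced by their printed configurations
(n, h, S, Hd); their backgrounds are seeded so FASTA bytes are stable.

The generator emulates sample sizes, locus lengths, inheritance scaling
and infinite-sites variation. It does not emulate base composition,
rate heterogeneity, sequencing or alignment error, or phasing
uncertainty in the nuclear loci — so passing tests validate the
inference machinery under the model's own assumptions, not robustness
to those real-data complications.

Problem sizes used by the shipped experiments (chosen as scaled-down
but statistically meaningful versions of the full pipeline, which
defaults to 100,000 preliminary + 300,000 final simulations per model):
calibration checks use 2,000–3,000 replicates and accept within 3 Monte
Carlo standard errors; the model-recovery experiment builds 5,000
simulations per model on the full study design, classifies 20 PODs
generated under model 2 with T1 = 2 Myr at 1% tolerance (expecting
≥ 90% recovery), and cross-validates with 60 PODs, expecting
between-scenario confusion below within-scenario confusion — the
qualitative structure this model set produces: scenarios separate
cleanly while sibling models within a scenario overlap.

## Numerical choices and limitations

* Retained-count ties: stable sort by row index after strict distance
  order.
* Degenerate statistics never reach the distance computation: the S = 0
  conventions (D = Fs = R2 = 0) make every simulated row finite.
* Stirling rows are cached per n; the exact-integer recurrence is ~n²/2
  big-integer operations, negligible for n ≤ ~500.
* The founder-size prior is conditional on the source's drawn size
  (upper bound Ne_source/2), so restriction quantiles for N_f are
  clipped against the unconditional bounds.
* Bayes factors are posterior ratios of retained counts and become
  infinite when the losing finalist retains zero rows; they are
  reported as inf rather than truncated.
* Known limitations: no migration or secondary contact models (the
  catalog is pure splits); no recombination within nuclear loci; no
  posterior parameter estimation beyond retained-row summaries and
  prior restriction (local-linear regression adjustment is out of
  scope).
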