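# Methods

## The question and the model

Directed signaling interactions ("A activates/inhibits B") induce a
hierarchy: a gene is far upstream if it modulates many others but is
modulated by few.  `netpolarity` asks whether a gene's position along this
upstream/downstream axis predicts the strength of purifying selection on
it, measured by the nonsynonymous-to-synonymous divergence ratio
ω = dN/dS (ω « 1 under strong purifying selection), and whether any
observed polarity is a *direct* effect of position or a byproduct of
confounders known to covary with both position and ω — expression level
and breadth, codon bias (ENC), protein-interaction connectivity, and the
number of paralogs.

Hierarchy is summarized three ways per gene: in-degree (upstream
modulators), out-degree (direct targets), and H — the number of distinct
other genes reachable through directed paths of any length.  Extreme
classes are defined degreewise: upstream = (out-degree > 0, in-degree = 0),
downstream = (in-degree > 0, out-degree = 0).

## The three polarity analyses

1. **Paired target comparison.**  Every gene with at least one valued
   direct target is compared against the central value of its targets:
   the median for an odd number of targets, and for an even number one of
   the two middle order statistics chosen uniformly at random.  Averaging
   the two middle values is deliberately avoided: ω is strongly
   right-skewed and a mean of order statistics is not a value the variable
   can take.  Greater/less counts feed a two-sided sign test.
2. **Extreme-group comparison.**  Mann-Whitney U between the upstream and
   downstream classes, reporting per-group n, median and mean.
3. **Hierarchy correlation.**  Spearman rank correlation of the value with
   in-degree, out-degree and H across all network genes.

### Confound controls

For the paired and extreme-group tests, the value is replaced by its OLS
residual against a single factor (complete cases; missing rows propagate).
For the correlation view, rank-based partial correlations are used: all
variables are converted to midranks, the variable of interest (binary
upstream/downstream code, or H) and the value are each residualized on the
control ranks, and the Pearson correlation of the residuals is referred to
a t distribution on n − 2 − k degrees of freedom.  Spearman correlation of
a value against the binary position code is equivalent to the Mann-Whitney
test; the package verifies the two p-values agree within 0.02 across
random splits.

### Stratification and exclusions

Per-compartment reruns restrict the paired comparison to focal-target
pairs that share the compartment, run the extreme-group test within the
compartment, and test compartment membership against the
upstream/downstream split with Fisher's exact test; genes annotated to
exactly one compartment enter a Kruskal-Wallis comparison across
compartments.  Exclusion reruns (genes flagged for positive selection by
the M7-vs-M8 LRT after BH-FDR at q < 0.05, or configured gene sets) remove
genes from the *value* mapping only: degrees and H are computed on the
intact network, so an excluded gene still transmits reachability but
contributes no comparison.  Recomputing the hierarchy on the pruned graph
would silently change every H; the chosen convention is recorded in the
report metadata.

## Statistical conventions

* **Sign test.**  Exact two-sided binomial (minimum-likelihood convention)
  for n ≤ 25 informative pairs; for larger n the classic continuity-
  corrected normal approximation, the behavior of the major statistics
  packages for the paired sign test.  The enumeration oracle in the test
  suite pins the exact branch for all n ≤ 12.
* **Mann-Whitney.**  Normal approximation with tie and continuity
  corrections; exact enumeration is substituted automatically when both
  groups have ≤ 8 observations and the pooled sample is tie-free.
* **Spearman / partial Spearman.**  Midranks for ties; two-sided p from
  the t approximation (sample sizes here are in the hundreds).
* **Fisher.**  Two-sided by summing hypergeometric probabilities not
  exceeding the observed table's.
* **FDR.**  Benjamini-Hochberg step-up q-values.
* **Missing values.**  Complete-case per analysis, never imputed; every
  result reports the effective n actually used.
* **Ties in the paired comparison** use exact floating-point equality by
  default (`tie_tolerance = 0`), since ω inputs are low-precision; a
  tolerance knob exists in the configuration.
* **Randomness.**  One seeded generator drives the whole paired analysis;
  genes are visited in sorted order, so results are independent of input
  ordering and fully reproducible.  Only genes with an even number of
  valued targets consume a draw, so changing the seed can shift the
  greater/less tallies by at most the number of such genes.

## The synthetic generator

The generator emulates the structure the analyses target: ~1000 genes in
6 layers connected by ~2400 directed edges (density 2.4 edges/gene,
matching the scale of curated human signaling networks), drawn strictly
from shallower to deeper layers so the graph is acyclic and the full
upstream-to-downstream span exists.  Cyclic inputs are exercised
separately through hand-built fixtures; the generator stays acyclic so
that layer depth is a clean ground truth.

Attributes follow a controlled causal scheme (all couplings standardized
against realized sample moments):

* log-connectivity = γ·z(total degree) + κ·z(depth) + noise — downstream
  genes encode more connected proteins (γ = κ = 0.5, noise SD 0.6);
* log-expression level and breadth (binomial over a 25-tissue panel on
  the logit scale) increase mildly with depth (coupling 0.3);
* log ω = μ − β_conn·z(log connectivity) − β_level·z(log level) −
  β_breadth·z(breadth) + δ·z(depth) + N(0, σ), with defaults
  β_conn = 0.5, β_level = 0.15, β_breadth = 0.2, δ = 0, σ = 1.0,
  μ = −2.6 (median ω ≈ 0.07, range spanning roughly 0.001–0.8, as seen
  in mammalian ortholog comparisons);
* dS is log-normal and independent of everything; dN ≡ ω·dS so the ratio
  identity is exact; ENC, paralog counts and compartments are independent
  noise; per-field missingness is configurable (defaults approximate the
  coverage of interaction and microarray databases).

Under the defaults the polarity in ω is therefore entirely *mediated*:
depth raises connectivity and expression, which lower ω, while δ = 0
means position itself does nothing.  `generate_null_dataset` zeroes every
coupling for type-I-error work.

Two numerical points deserve emphasis:

* **Linearity of the ω-connectivity relation.**  The residual-based
  control regresses raw ω on raw connectivity.  Because the generative
  relation is log-linear, a linear fit can leave curvature that leaks
  position information into the residuals.  The default noise scales
  (σ = 1.0, connectivity noise 0.6) keep that leakage well below the
  sampling noise of the sign test at n ≈ 800 pairs, so a purely mediated
  effect is correctly nulled by the control (measured residual-control
  significance ≈ 0.05, partial-correlation control ≈ 0.02–0.05) while the
  raw test detects the mediated polarity essentially always.
* **What passing does not show.**  The generator's networks are layered
  DAGs with near-Poisson degrees; real signaling networks contain cycles,
  hubs and heavy-tailed degree distributions, and real ω estimates carry
  estimation error correlated with dS.  Calibration and recovery results
  on synthetic data therefore demonstrate correctness of the procedures
  under the modeled causal structure, not performance guarantees on any
  particular curated network.

## Known limitation: conservatism of the paired sign test on networks

The paired comparisons are not independent: a gene's value appears on the
focal side of its own comparison and inside the target sets of its
regulators.  Measured on 2500 null synthetic datasets, the paired test
rejects at ≈ 0.026 at nominal α = 0.05.  Decomposition shows the two
dependence channels pull in opposite directions: with independent focal
values but shared targets the empirical rate rises to ≈ 0.10, whereas the
full procedure's focal/target sharing nets out below nominal; fully
independent pairs sit at ≈ 0.045 (the continuity-corrected baseline).
The test is therefore mildly conservative in this setting — it
under-rejects, so its positive findings are trustworthy, but its nominal
level should not be taken at face value on dense networks.  The
extreme-group Mann-Whitney (≈ 0.040) and the H correlation (≈ 0.048) are
calibrated.

## Problem sizes used by the verification suites

Null calibration uses 500 datasets of 1000 genes; mediation recovery uses
200 datasets; graph-oracle equivalence uses 100 random digraphs of up to
50 nodes; the worked-example p-values are closed-form and instantaneous.
These sizes give Monte-Carlo standard errors of roughly 0.01 on the
reported rates.
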