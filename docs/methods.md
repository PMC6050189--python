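# Methods

## Diversity measures

All measures are effective numbers derived from Hill numbers
`qD = (Σ p_i^q)^(1/(1−q))`, evaluated with natural logarithms. Orders are
treated exactly: `q = 0` counts strictly positive frequencies (richness on
padded tables stays well defined because zero-frequency elements are
dropped first, with the `0·ln 0 = 0` convention), `|q − 1| < 1e-10` uses
the closed form `exp(H)` rather than any interpolation band, and all other
orders use the power-mean form directly. Input frequency vectors whose sum
deviates from 1 by at most 1e-6 are silently renormalised (file rounding);
larger deviations are rejected as data errors, naming the offending entry.

The package is restricted to `q ≥ 0`; Rényi/Tsallis generalisations,
negative orders and rarefaction/extrapolation estimators are out of scope.

## Hierarchical decomposition (q = 1)

Units (populations or communities) at level 1 are nested in aggregates up
to the full system at level L; any L ≥ 2 is supported and the nesting is
validated structurally (an aggregate may not span two parents). The unit
weight is its abundance share `w_j = N_+j / N_++`, so an aggregate's
weight is the sum of its members'. Level-l alpha entropy is the
weight-averaged Shannon entropy of the aggregate-pooled frequency vectors;
pooling is the weight mixture `Σ (w_c/w_g) p_c`, which for
abundance-derived weights coincides (to 1e-12, asserted in tests) with
renormalising summed raw counts. Alpha diversities are `exp(H_α)`,
gamma of a level is alpha of the level above, and betas are their ratios,
making the chain `D_γ = D_α^(1) Π_l D_β^(l)` an algebraic identity. All
derived quantities are computed from entropy differences, never from logs
of already-exponentiated numbers, to avoid cancellation.

Equal unit weights are available as an option (`equal_weights=True`,
`--equal-weights`), but size weighting is the default and the documented
formulation.

### Differentiation

The entropy gap between adjacent levels, `H_α^(l+1) − H_α^(l)`, is the
mutual information between element identity and child membership within
parents; it is bounded by the weight entropy of the children,

    W^(l) = Σ_parents w_g · H( w_c / w_g : children c of g ).

The differentiation reported at level l is the ratio of the two, clamped
to [0, 1] (the clamp only ever trims floating-point noise, since the bound
is an information-theoretic theorem). For N equally weighted children the
ceiling is `ln N`, so Δ reduces to the normalised mutual information, and
for equally large, equally diverse units with A of S elements shared by
all, Δ = 1 − A/S exactly (the true-dissimilarity property; tested over a
grid of N, S, A). Δ also never decreases when an unshared element is added
to a unit or substituted for copies of a shared one (tested on 500
randomised two-population instances). When every parent has a single child
the ceiling is zero and Δ is defined as 0. This per-parent weight-entropy
normaliser is the package's design choice for the multi-level, unequal-
weight case; it was validated against the closed-form boundary cases
above, which pin it down uniquely at equal weights.

### Degenerate systems and zero-abundance units

If the total entropy gap is ≤ 1e-12 nats (all units compositionally
identical) the decomposition reports β = 1, Δ = 0 and all-zero information
shares with an explicit `no_beta_information` flag instead of NaNs;
sub-tolerance gaps at individual levels are flushed to zero for the same
reason. Units with zero count at a particular locus are dropped from that
locus only (weights renormalise automatically through the column sums) and
a warning is logged, mirroring ordinary missing-data practice.

### Beta-information shares and multi-locus averaging

The share of total beta information at level l is the entropy-gap ratio
`(H_α^(l+1) − H_α^(l)) / (H_γ − H_α^(1))`; shares are non-negative and sum
to 1 whenever beta information exists. Genetic data are decomposed one
locus at a time and the *effective numbers* (gamma, alpha, beta) and
differentiations are then averaged arithmetically across loci; per-locus
results are retained alongside the mean. Averaging is deliberately done on
the number-equivalent scale, not on entropies, so the multiplicative chain
is a per-locus identity that is *not* preserved by the averages (a mean of
products is not the product of means) — consumers should check chains on
the per-locus values.

Diploid genotype tables are converted to allele copies (0/1/2 per
individual and allele); polyploids are not parsed. Element identifiers are
matched as exact, case-sensitive strings.

## Phylogenetic diversity

A rooted tree (Newick; quoted or unquoted labels, polytomies, zero-length
branches allowed; a missing root-edge length defaults to 0) is expanded
into a branch-by-tip incidence so that branch abundances `a_i` — the
summed relative abundances of each branch's descendant tips — are a single
matrix product. `qPD` is the effective total branch length per unit time
back to a fixed reference point; `0PD` sums the branches actually present
(`a_i > 0`, Faith's semantics — absent lineages are excluded from q = 0
but retained as zero contributions elsewhere), `1PD = T·exp(I/T)` with the
phylogenetic entropy `I = −Σ L_i a_i ln a_i`, and `2PD` satisfies the Rao
transform `2PD = T/(1 − Q/T)`, which the tests verify against an
independent pairwise-distance computation of Q.

The reference point defaults to the root age; `graft_root_edge` (CLI
`--root-edge`) moves it older. A tree is called ultrametric when its
root-to-tip depths agree to 1e-6 relative, in which case T is the depth.
For non-ultrametric trees the abundance-weighted mean branch length
`T̄ = Σ L_i a_i` is computed **once from the system-level pooled
abundances** and reused at every level: a per-aggregate T̄ would break the
identity `PD_γ^(l) = PD_α^(l+1)` and with it the multiplicative chain.
The hierarchical decomposition then mirrors the abundance one with `H`
replaced by `I/T`, and the PD differentiation divides the `I/T` gap by the
same weight-entropy ceiling `W^(l)`. On a tips-only tree with unit branch
lengths every PD quantity collapses onto its abundance counterpart
(asserted to 1e-10).

Distance-matrix-based functional or genotypic diversity is out of scope.

## Spatial simulator

The generator emulates a stationary, spatially autocorrelated pattern of
allele frequencies over a linear landscape — the kind of smooth
isolation-by-distance structure a stepping-stone model produces — without
simulating the population-genetic process itself. Defaults define the
study conditions: 32 populations nested as 4 subregions of 8 and 2 regions
of 16; 10 unlinked bi-allelic loci; 100 replicates per scenario; spatial
decay δ swept over {0.1, 0.5, 1, 2, 4, 6} from strong to effectively
absent structure.

* **Correlation.** `ρ_ij = exp(−δ·|i−j|)` on the linear population order
  (first-order autoregressive): symmetric, unit-diagonal, positive
  definite at every δ, strictly decreasing in both neighbour rank and δ.
  An alternative `scheme="literal"` builds the variance-5 covariance with
  off-diagonals `δ·max(0, 5−d)` and projects it to the nearest valid
  correlation matrix by eigenvalue flooring; it is provided for
  comparison only, since it loses positive-definiteness for large δ and
  its correlation strength grows rather than decays with δ.
* **Frequencies.** Per locus, one draw from MVN(0, ρ) with
  standard-normal marginals, truncated elementwise to [0, 1]. Truncation
  piles mass at the boundaries — about half the population-locus pairs are
  fixed for one allele, matching how the printed tail probabilities only
  make sense on the standard-normal scale. Loci monomorphic everywhere
  are retained (they contribute an effective number of 1), not redrawn.
* **Sizes.** `round(LogNormal(0,1) × Poisson(30))` per population, drawn
  once per replicate and shared across loci (so locus decompositions
  within a replicate see the same weights); zeros are redrawn. Expected
  size is `e^{1/2}·30 ≈ 49.5`. Allele abundances are the size × frequency
  products, kept fractional — only the sizes are rounded.
* **Determinism.** A single seed feeds a `SeedSequence` that spawns one
  independent child stream per δ, so the same seed reproduces every output
  bitwise and adding a δ value does not disturb the others.

What the generator does **not** emulate: mutation, migration and drift
dynamics, linkage, allele-frequency spectra of real markers, spatially
correlated population sizes (sizes are deliberately independent of the
spatial field so that genetic structure is the only spatial signal), or
sampling noise from genotyping a subset of individuals. Passing tests
therefore demonstrate the measures' numerical behaviour under a known
spatial field, not calibration against any real organism.

Under these defaults the replicate-mean ecosystem gamma diversity rises
monotonically with δ from ≈1.62 (δ = 0.1) to ≈1.82 (δ = 6) — pooling 32
nearly independent truncated-Gaussian frequencies concentrates the pooled
frequency near its mean ≈0.316, whose two-allele effective number is
exp(H(0.316)) ≈ 1.87; strong correlation instead lets whole regions drift
toward fixation together, lowering the pooled effective number. Regional
differentiation falls with δ while population-within-subregion
differentiation rises, and population-level alpha is flat in δ because the
marginal distribution of a single population's frequency does not depend
on the correlation at all.

## Problem sizes and tolerances in the test suite

The acceptance-style checks run the full default experiment (6 δ values ×
100 replicates × 10 loci, a few seconds after the vectorised decomposition
path); property suites use 20–500 randomised instances each, seeded for
reproducibility. Exact identities (chain, true dissimilarity, pooling
equivalence) are asserted at 1e-9–1e-12; the `q → 1` limit is checked
against an extended-precision symmetric numeric-limit oracle at 1e-6
relative. The trend directions of the simulation study are asserted on
replicate means (rank correlation and endpoint ordering) rather than
strict step-by-step monotonicity, which Monte-Carlo noise does not
guarantee for the differentiation components.

## Optional real-data integration

`tests/test_acceptance.py` contains an integration test against the
published Hawaiian reef-fish decomposition that activates only when
`data/hawaii/species_abundance.csv` (wide species-by-island densities) and
`data/hawaii/structure.csv` (island, region, ecosystem) are present; the
underlying survey data are publicly archived and are not redistributed
here. All other tests are self-contained.

## Known limitations

* Observed (plug-in) frequencies only: no bias correction for undetected
  species/alleles, so entropies are negatively biased under heavy
  undersampling; no confidence intervals.
* The multi-locus average is a plain arithmetic mean; loci are assumed
  independent and equally informative.
* The differentiation normaliser for unequal weights at intermediate
  levels is the package's per-parent weight-entropy construction (see
  above); alternative normalisations agreeing at equal weights exist.
* Trees must contain every element present in the table; elements are not
  pruned or imputed.
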