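# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mosaicscan`, in the order data flows through the pipeline.

## Data model

Genotypes are diploid alternate-allele dosages {0, 1, 2} with −1 for
missing; half-calls are treated as missing and phasing is ignored, since
every downstream statistic consumes population allele frequencies. All
coordinates are 0-based half-open; VCF positions are converted on read.
Multiallelic and non-SNV records are skipped with a logged count, as is any
record that would break the strictly-increasing position invariant (e.g.
split multiallelics at a repeated position).

A population's frequency at a site is (Σ dosages) / (2 × called samples),
missing when no sample is called. With an outgroup chosen for polarization,
sites where the outgroup is polymorphic or entirely missing are dropped and
frequencies are reported for the allele absent from the outgroup (the
derived allele); folding was deliberately not implemented because D and fd
are defined on derived-allele frequencies. All multi-population statistics
are per-site complete-case: a site contributes only if every required
population has a called frequency.

## D, f-statistics and the block jackknife

Patterson's D follows the ABBA/BABA product form on derived frequencies.
For tables that are *not* outgroup-polarized (e.g. simulated frequencies
with arbitrary allele coding) the allele-coding-invariant form

    D = Σ (p2−p1)(p3−pO) / Σ (p1+p2−2p1p2)(p3+pO−2p3pO)

is available (`general=True` / statistic `D_general`); the two coincide
when the outgroup's derived frequency is identically 0.

Standard errors come from a delete-one-block jackknife over contiguous
blocks of (near-)equal site count — the default 50 blocks is robust for
both dense and sparse tables; coordinate-span blocking (e.g. 5 Mb) is
available where physical linkage scale matters. Blocks whose removal
empties a statistic's denominator are merged into a neighbour and logged.
Z = estimate/SE with the significance convention |Z| > 3.3 (configurable).
The f4-ratio α = f4(A,O;X,C)/f4(A,O;B,C) takes its SE from delete-one
ratios, not error propagation, matching common practice and making the SE
directly testable by simulation.

`f2`/`f3` follow their plain definitions (mean products of frequency
differences). For graph fitting, f2 uses the finite-sample heterozygosity
correction — subtracting p̂(1−p̂)/(n−1) per population, n the called allele
count — because with a handful of diploids per population the sampling term
is of the same order as the drift signal and would otherwise bias every
fitted branch length upward.

fd substitutes the donor frequency p_D = max(p2, p3) into both the P2 and
P3 slots of the D numerator; windows with non-positive numerator are
reported missing rather than clamped to zero, following the statistic's
original definition (the value is only interpretable for positive-D
windows). Dxy is Σ [pX(1−pY) + pY(1−pX)] / L; in frequency mode the
denominator is either the called-site count or the window's accessible
length (configurable — the former is only appropriate when monomorphic
sites are absent by construction), and in alignment mode it is the mean
over inter-population sequence pairs of per-site differences divided by the
compared (non-N) length.

## Local trees and topology classes

Per-window trees are neighbor joining on Jukes-Cantor distances,
d = −(3/4)·ln(1 − (4/3)·p̂), with p̂ capped at 0.74 (saturation flagged) to
avoid infinities on random-like pairs. NJ+JC deliberately replaces
per-window maximum likelihood: the classification consumes only topology,
and a Newick import path accepts externally inferred ML trees with their
support values. Support is the percentage of column-resampling bootstrap
replicates containing each internal bipartition; the default filter keeps
windows with mean support ≥ 60 (a stricter 80 is available for analyses
that feed network inference).

Classification roots each tree on the smallest clade containing all
outgroup samples (if the outgroup is not monophyletic, the edge maximising
outgroup purity is used and the window flagged), requires every
multi-sample focal population to be monophyletic (else class OTHER),
collapses to one leaf per population, and matches the result against the
reference topologies by exact unrooted-bipartition equality — no
nearest-topology assignment, so OTHER retains everything that does not
exactly match an enumerated class. This mirrors the analysis structure of
"k most common topologies + remainder" and keeps class fractions directly
interpretable. Low-support windows are UNRESOLVED and excluded from
partitions. The ancestry partition labels each classified window
`in_set` / `background` / `unresolved` by a user-supplied set of class ids
(for a hybrid lineage: the classes placing it with its recent source).

## Quartet species trees

For ≤ 8 taxa all unrooted binary topologies are enumerated (recursive edge
insertion; 10,395 topologies at n = 8) and scored by the number of induced
input-tree quartets they contain; induced quartet splits are read off
topological path-length matrices via the four-point condition, with ties
(unresolved quartets) skipped. The maximiser is returned, ties broken by
lexicographic canonical Newick and reported. Per-branch support is the
fraction of relevant quartet observations (2+2 across the branch) agreeing
with it. This estimator is statistically consistent under the multispecies
coalescent; its exhaustive form is exact, at the cost of the taxon bound.

## Admixture graphs

A graph is a rooted DAG; ordinary edges carry drift lengths in f2 units,
admixture nodes have exactly two parents with weight α on the first and no
drift on the parent edges. Ghost (unsampled) lineages — e.g. an extinct
donor — are ordinary nodes or leaves marked `ghost`; only sampled leaves
enter the fitting basis. Path weights (the probability that a lineage from
a leaf traverses an edge) are computed by a single upward sweep, and
expected f-statistics follow the standard path algebra.

Fitting minimises Σ((obs − exp)/SE)² with a diagonal covariance (jackknife
SEs only; a documented simplification — f2 statistics sharing populations
are correlated, so the objective is not a calibrated χ², though residual
Z-scores remain individually interpretable). Because expectations are
linear in drift lengths at fixed admixture weights, free lengths are
profiled out exactly by bounded linear least squares; the outer search runs
over free admixture weights only, from 20 Latin-hypercube starts under a
fixed seed (ties by first found). A fit is deemed adequate when the worst
residual |Z| < 3. Parameters with vanishing sensitivity at the optimum are
flagged, not fatal — e.g. the two root-adjacent edges, of which only the
sum is identifiable from an f2 basis.

Identifiability shaped one protocol choice: with *all* drift lengths free,
the profiled objective can be exactly flat over an interval of admixture
weights (free lengths absorb the change subject only to non-negativity), so
"the fitted α" would be an optimizer artifact. The weight-recovery
validation therefore fits the proposed topology with its drift-length
*pattern* fixed up to one freely fitted global scale factor plus the free
admixture weight — point-identified, and unit-agnostic (the scale converts
the simulator's variance-coefficient units into f2 units; its fitted value
≈ 0.175 matches the root-distribution heterozygosity 0.1825 less drift
decay). `fit_graph` supports arbitrary free-parameter patterns.

## Permutation contrasts

The test statistic is the difference of group means of per-window values,
matching a contrast of window distributions (a site-weighted variant is
available). Labels are permuted uniformly preserving group sizes; the
one-sided P uses the add-one correction, so P ≥ 1/(n_perm+1) and P < 0.001
requires ≥ 1,000 permutations. Missing-statistic and unresolved windows are
excluded first, with counts logged. Simple label permutation ignores the
spatial autocorrelation of adjacent windows — with strongly autocorrelated
ancestry tracts the test is anticonservative; a block-aware permutation is
a known omission.

## Simulators

**Drift on a graph.** Per locus, a root frequency is drawn (default
U(0.05, 0.95)); along each edge of drift length c the frequency is updated
by the normal approximation p′ = clamp(p + N(0, c·p(1−p)), 0, 1) —
absorbing at 0/1 — and at admixture nodes mixed as α·p₁ + (1−α)·p₂; leaf
genotypes are binomial draws of 2 alleles per diploid. An explicit
Wright-Fisher binomial mode (N = 500 diploids, round(c·2N) generations per
edge) exists for cross-checking the approximation; the two agree in
second moments to within sampling error. Under this parametrization the
expected f2 per edge is c·h where h is the local heterozygosity
(h ≈ 0.1825 at the root under the default law, decaying by (1−c) per
edge) — fitted drift lengths are therefore recovered in f2 units, not raw
c. The update is a martingale, which the tests assert directly.

**Network MSC.** The species network is an ultrametric species tree
(branch lengths in coalescent units) plus hybridization events: at the top
of the hybrid species' pendant branch, each entering lineage independently
jumps to the branch above a named donor node with probability γ (mosaic at
the lineage level — exactly what produces window-to-window topology
mixtures). Within branches, lineages coalesce at rate 1 per pair per
coalescent unit. Sequences evolve by JC69 with branch lengths = coalescent
units × μ; no rate heterogeneity, indels or recombination within windows —
the pipeline consumes topology and counts, not model fit. Closed-form
checks: two populations diverged τ units give E[Dxy] ≈ 2μ(τ+1); a species
tree without hybridization gives quartet discordance (2/3)e^(−t) for an
internal branch of t units; hybrid-side window fractions equal γ in
expectation. All randomness flows through `numpy.random.default_rng`
(PCG64) from explicit integer seeds; equal seeds give bit-identical output.

What the synthetic data do *not* emulate: linked sites within loci,
ascertainment bias of SNP panels, sequencing error, missing-data structure,
selection, and population-size change along branches. Passing tests
therefore demonstrate correctness of the estimators under their generating
models, not robustness to every property of real resequencing data.

## Validation scenarios and problem sizes

The three end-to-end validations (in `mosaicscan.validation`, asserted in
`tests/test_acceptance.py`, recomputed by `scripts/acceptance.py`) use
desk-scale sizes chosen so each runs in seconds to a few minutes on one
core: 10 replicates × 50,000 loci for admixture-weight recovery under the
six-lineage ghost-source graph (3 diploids per population, 50-block f2
basis); 20 replicates × 100,000 loci for the gene-flow D test on
(((P1,P2),P3),O) with drift 0.02 per edge and a 20% P3→P2 admixture edge;
and 150 + 350 windows × 5 kb (τ = 1 vs 3, μ = 0.01) for the windowed-Dxy
permutation contrast.

One calibration finding is worth recording. In the gene-flow scenario the
expected D numerator is pinned by the graph at 0.2·c·h ≈ 7×10⁻⁴, while the
per-site noise is dominated by genotype sampling with 6 chromosomes per
population; at 100,000 loci this yields jackknife Z ≈ 3 on average, i.e.
the scenario sits *at* the 3.3 significance threshold rather than safely
above it (with true population frequencies in place of 3-diploid samples
the same scenario gives Z ≈ 19). The test asserting near-universal
significance across replicates documents this boundary honestly rather
than enlarging the sample or loci count.

## Known limitations

Diagonal f-statistic covariance in graph fitting; no graph topology
search; exhaustive-only species-tree estimation (≤ 8 taxa); label
permutation without spatial blocks; NJ+JC local trees (import path for ML
trees provided); no genotype likelihoods. These are scope choices, each
with the standard heavier-weight alternative noted above.
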