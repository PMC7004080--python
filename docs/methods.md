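# Methods

`divmig` infers the divergence history of two populations from the folded
joint allele-frequency spectrum (AFS) and supplies the marker-level
statistics that accompany such an analysis in host–symbiont systems
(sequence distances, diversity, F_ST, recombination filtering,
median-joining networks, mitotype×ribotype discordance tables).  This
note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Divergence models and scalings

Two populations descend from an ancestral population of size N_ref.  All
quantities are scaled: sizes ν₁, ν₂ relative to N_ref; times in units of
2·N_ref generations; migration M = 2·N_ref·m, where m is the fraction of
a recipient population replaced by migrants each generation (M12 denotes
migration into population 1 from population 2); θ = 4·N_ref·µ·L sets the
expected-spectrum scale.  Seven scenarios are supported:

| model | history (forward time) | free parameters (k) |
|---|---|---|
| SI   | split, isolation for T_s | ν₁ ν₂ T_s (3) |
| IM   | split, continuous gene flow for T_s | + M12 M21 (5) |
| AM   | gene flow for T_am, then isolation for T_s | + T_am (6) |
| SC   | isolation for T_s, then gene flow for T_sc | + T_sc (6) |
| IM2M/AM2M/SC2M | as above, two migration classes | + Me12 Me21 P (8/9/9) |

The 2M ("two migration-rate") variants model heterogeneous introgression
across the genome: a fraction P of sites exchanges migrants at the
neutral rates (M12, M21) while the rest — loci linked to barriers — uses
reduced effective rates (Me12, Me21).  The mixture is applied at the
spectrum level: AFS = P·AFS(M) + (1−P)·AFS(Me), matching a single global
P per model.  The free-parameter counts above are the ones used for AIC;
θ is profiled analytically (below) and is never counted.

## Expected spectra

The expected unfolded AFS entry (i, j) is (θ/2)·E[L_ij], where L_ij is
the total genealogy branch length subtending exactly i of the n₁ and j of
the n₂ sampled haplotypes.  E[L] is estimated by Monte-Carlo over K
independent structured-coalescent genealogies simulated backward in time:
per-pair coalescence rate 1/ν_d within deme d, per-lineage backward
migration rate out of deme 1 equal to M12 (and symmetrically), epochs
applied in reverse order, and all lineages merged into the ancestral deme
(size 1) at the split.  Entries are exactly linear in θ, and a fixed
engine seed (common random numbers) makes every likelihood evaluation
deterministic, so optimization runs are exactly reproducible.

Two independent oracles validate the engine and its scalings: a discrete
two-deme Wright–Fisher genealogy simulation with per-generation migrant
fractions m = M/(2·N_ref) (the forward-time definition of the backward
rates), and msprime's branch-mode AFS under the same demography.  Both
agree entrywise with the engine within combined Monte-Carlo error; the
cross-validation tolerance is 4 combined standard errors, chosen so the
family-wise false-alarm rate over the ~70 entry comparisons is
negligible.  The single-population marginal reproduces the Watterson
closed form ξ_i = θ/i.

## Composite likelihood and optimization

The observed folded spectrum is compared with a model's folded expected
spectrum through a Poisson composite log-likelihood over unmasked
entries, lnL = Σ O·ln E − E − lnΓ(O+1).  θ is profiled analytically:
E is computed at θ = 1 and rescaled by θ̂ = ΣO/ΣE, the per-spectrum
Poisson MLE, which makes lnL invariant to any rescaling of E and removes
θ from the search space.

Fitting uses multi-start optimization in log₁₀ parameter space (bounds
span orders of magnitude): hot simulated annealing (σ = 0.5 decades,
temperature 10 → 1 lnL units, geometric cooling), cold annealing
(σ = 0.08 decades, 1 → 0.05), then bounded L-BFGS-B refinement followed
by a Nelder-Mead simplex polish.  The polish exists because the
Monte-Carlo likelihood surface, though deterministic under common random
numbers, is piecewise-rough at the scale of finite-difference gradients;
the derivative-free step reliably closes the final distance to the
optimum (verified by self-fits that recover generating parameters to
within 10% and the self-fit lnL to within 0.5).  The full published-style
protocol is 80 runs × 5,000 iterations per model; tests and the
acceptance script run a desk-scale configuration (3–6 runs × 120–400
iterations, K = 1,500 genealogies, 5,000 SNPs, 2×8 haplotypes) chosen as
the smallest sizes at which the recovery properties are stable.

Runs whose estimates sit within 1% (log-scale, relative to the bound
interval) of a bound are flagged as spurious and filtered before model
selection, not silently deleted; a model whose runs all hit bounds raises
an error asking for wider bounds.  Model comparison uses AIC = 2k − 2lnL
and Akaike weights exp(−ΔAIC/2) normalized over candidates, computed via
ΔAIC so that differences of many hundreds survive floating point.
Per-model optimizer seeds derive from the model name, so a model listed
twice yields bit-identical fits and an even weight split.

## Folding and spectrum conventions

With S = n₁+n₂ total haploids, folding maps entry (i, j) with
i+j < S/2 to itself plus its complement (n₁−i, n₂−j); hinge entries
(i+j = S/2) are averaged with their complement; entries beyond the hinge
are masked.  The absorbing corners (0,0) and (n₁,n₂) are always masked.
Total unmasked mass is conserved.  Spectrum files use the dadi text
dialect (dimensions + fold state, flattened values, flattened mask).

## Synthetic data generator

The generator emulates the study conditions with known ground truth and
is the source of every test input:

* **SNP panel.** Two diploid populations (default 9 vs 5 individuals,
  the empirical sample sizes) at unlinked biallelic sites (default
  349,288, the empirical shared-site count).  Each site draws an
  independent structured-coalescent genealogy under the configured
  scenario, accepted by rejection sampling with probability proportional
  to its total branch length — the exact infinite-sites conditioning on
  observing a segregating site — after which one mutation is placed
  uniformly on the branches.  For 2M models the class draw (neutral with
  probability P) is inside the rejection loop, so accepted class
  fractions are length-weighted, consistent with the spectrum-level
  mixture used in fitting.  Per-site TMRCA and class are recorded as
  truth.
* **Sequence loci.** One genealogy per locus; finite-sites mutations are
  placed per branch as Poisson events with a Kimura two-parameter rate
  matrix (default transition/transversion ratio 2, a typical animal
  mtDNA/nuclear compromise).  The locus-wide effective size is multiplied
  by the inheritance scalar — 1.0 for nuclear loci (two phased sequences
  per individual), 0.25 for mitochondrial loci (one sequence per
  individual), reflecting haploid maternal inheritance.  Default locus
  length 518 bp matches the mitochondrial barcoding fragment.
* **Host–symbiont labels.** Each individual's symbiont label starts as
  its population (maternal cotransmission with the mitochondrion) and is
  flipped to the other lineage independently with probability
  `transfer_prob` (default 0.15 ≈ 15 discordant of 97 genotyped clams);
  flips are recorded as truth.  One label per individual: within-host
  symbiont mixtures are not modelled.

Default θ per site for the SNP panel is 0.035 (the fitted ancestral
mutation scaling divided by the shared-site count); it affects sequence
loci only, since SNP site patterns are θ-free after segregating-site
conditioning.

What the generator does **not** emulate: genotype-likelihood uncertainty
and depth-dependent ascertainment of real RAD data, missing data,
linkage within the SNP panel, sequencing error, within-host symbiont
mixtures, and selection.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own
assumptions, not robustness to those real-data complications.

## Marker-level statistics

* **K2P distance** d = −½ln(1−2P−Q) − ¼ln(1−2Q) with pairwise deletion
  of gap/N columns; saturation (non-positive logarithm arguments)
  raises rather than returning a number.
* **Haplotype diversity** H = n/(n−1)(1 − Σp²) with Nei's (1987)
  sampling variance for the reported SD.
* **F_ST** is Hudson's 1 − Hw/Hb computed from per-site allele
  frequencies (mean pairwise difference "with replacement"), so two
  populations of identical composition give exactly 0; the two
  within-population diversities are averaged with equal weight.  This
  estimator choice stands in for unstated desktop-program internals and
  is validated against a brute-force all-pairs oracle.
* **Benjamini–Yekutieli** adjustment delegates to statsmodels
  (`fdr_by`) and is checked against the hand-computed step-up formula.
* **Four-gamete filtering** marks a pair of biallelic columns
  incompatible when all four haplotype combinations occur and returns
  the leftmost longest contiguous interval with no internal incompatible
  pair, for downstream analyses that assume no intralocus recombination.
* **PCA** centres each site by 2p̂ and scales by √(2p̂(1−p̂)), dropping
  monomorphic sites.

## Median-joining networks

The network iterates: (1) the ε-relaxed minimum spanning network under
Hamming distance (ε = 0 default — the union of all minimum spanning
trees); (2) site-wise majority-consensus medians proposed from triples
with at least two MSN links, added greedily while they reduce the MST
cost of the node set; finally medians not needed for any minimal
connection (removal leaves the MST cost unchanged) are deleted.
Determinism: candidates are evaluated in lexicographic order, largest
cost reduction first with lexicographic tie-break; at sites where all
three triple members differ the median inherits the lexicographically
first member's base (a quasi-median simplification).

## Discordance classification

Individuals are assigned to host mitotype and symbiont ribotype clades
by minimum mean K2P distance to labelled references; the margin (runner-
up minus winner) must exceed a threshold (default 0), exact ties and
fully saturated queries raise rather than assign silently.  Distance-
based assignment suffices because the clades involved are deeply
separated (~9% mitochondrial divergence); phased nuclear alleles can be
assigned per sequence and combined by consensus.  The cross-tabulation
flags off-diagonal (mitotype ≠ ribotype) individuals as discordant.

## Numerical and design notes

* Reproducibility: every stochastic component is seeded; sub-seeds
  derive from a root seed via `numpy.random.SeedSequence`, and rerunning
  any generator or fit with the same configuration is bit-identical.
  The pipeline writes a manifest with a configuration hash and SHA-256
  checksums to make this verifiable.
* The rejection bound for segregating-site sampling is
  n·(total finite epoch duration + 45) coalescent units; the clamp
  probability is below 10⁻¹⁷ per site.
* The Wright–Fisher oracle refuses population sizes above 200 units and
  samples above 8 haplotypes per population: it is a validation tool
  with O(N·generations) cost, not a production engine.
* Degenerate inputs raise informative errors rather than returning
  silent values: missing genotypes before spectrum construction,
  double folding, monomorphic-only PCA, zero between-population
  diversity in F_ST, saturated K2P distances.

## Known limitations

The Monte-Carlo expected spectrum makes likelihood differences below the
engine's noise floor (≈0.1–1 lnL units at K = 1,500–50,000)
uninterpretable; model comparisons in the tests are separated by tens to
hundreds of units.  The annealing protocol's temperatures and
perturbation scales are package defaults, configurable but not tuned per
dataset.  Empirical spectra estimated from genotype likelihoods
(rather than exact counts) are outside the current reader's scope.
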