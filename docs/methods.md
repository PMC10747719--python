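# Methods

This note records the models, conventions and numerical choices behind
msatforge, in the spirit of a statistical software appendix: what each stage
assumes, which knobs matter, and what the bundled tests do and do not
demonstrate.

## Repeat detection and canonicalization

A microsatellite is modeled as a *perfect* tandem repeat: a maximal run of a
primitive 1–6 bp motif. Compound or interrupted repeats are split at each
interruption — the marker panels this toolkit targets are built on single
clean motifs, and perfect runs give an unambiguous coordinate contract
(`end − start = motif length × repeats`). The scanner finds, for each period
p, the maximal intervals where `s[i] == s[i+p]`, trims them to whole repeat
units, discards non-primitive motifs (an (ATAT) 4-mer is reported once as
(AT)), and resolves overlaps between periods longest-span-first with
(start, period) tie-breaks, so reported loci never overlap.

Detection thresholds are deliberately generous — minimum repeats
{1: 12, 2: 7, 3: 5, 4: 5, 5: 5, 6: 5} per motif length — with the stricter
marker-screening rule (motif 3–6 bp, ≥ 7 repeats, product 100–400 bp)
applied later at candidate selection. Detecting generously and filtering
reproducibly keeps the two policies independently testable.

Motifs are canonicalized to the lexicographic minimum over all rotations of
the motif and of its reverse complement, so the same repeat read in any
frame on either strand has one name. Canonicalization is idempotent and
strand-invariant by construction.

Cross-assembly matching uses ungapped, end-anchored flank identity (mean of
left and right, 50 bp windows, ≥ 95%) rather than whole-genome alignment:
at the scale this package operates, flank identity is what the downstream
assay actually requires (primers must bind both haplotypes), and it makes
the matching criterion auditable base by base. "Polymorphic" is
operationalized as *repeat counts differing between the two assemblies* —
the two haplotypes then give different product sizes, i.e. at least two
alleles.

## Primer model

Melting temperature uses the GC-fraction formula
`Tm = 64.9 + 41 (G+C − 16.4) / N` (°C, rounded to 0.01). It is biased
relative to nearest-neighbor thermodynamics, but it is deterministic,
dependency-free and hand-checkable, and the acceptance window (52–62 °C,
pair difference ≤ 3 °C) is wide enough to absorb the bias.

Primer–primer complementarity is the **longest contiguous run of
Watson–Crick pairs** over all ungapped antiparallel offsets of the two
oligos, the classic dimer criterion; a score at or above the threshold
(default 7) rejects the pair. The obvious alternative — counting *all*
paired bases at the best offset — was evaluated and discarded: measured on
the bundled reference panel it flags 99 of the 100 primer pairs that
coexist in that panel's real, experimentally validated reactions (two random
20-mers almost always align 7+ scattered complementary bases somewhere), so
it carries no information at any usable threshold. The longest-run metric
flags 7 of those 100 pairs and leaves the panel packable, matching how
multiplex design software actually treats the parameter.

Primer design is exhaustive over flank windows (length 18–27, GC 40–60%,
Tm in window, self- and cross-dimer below threshold, product in range),
ranked by |mean Tm − 57 °C| then by product-size centrality. Flanks at the
scale used (≤ 400 bp) make exhaustive search cheap and reproducible; no
heuristics, no thermodynamic ΔG, no hairpin model, no genome-wide
specificity screen (out of scope).

## Multiplex packing

A reaction is valid when: at most `max_loci_per_reaction` (10) loci; loci
sharing a dye keep an **edge-to-edge** gap of at least `min_same_dye_gap`
(40 bp) between allele size ranges; no cross-locus primer combination
reaches the complementarity threshold (7); annealing temperatures span at
most `max_ta_spread` (8 °C, the widest spread observed in the reference
panel's printed reactions). The gap is measured between range edges, not
midpoints, because the constraint exists to keep allele *bins* from
colliding on one dye channel; note the bundled panel itself contains one
same-dye pair at gap 36 under this reading (its published layout was built
with a tool whose distance convention is not documented), which is why
`validate_reaction` takes the constraint set as a parameter instead of
hard-coding it.

The optimizer seeds with first-fit-decreasing (by size-range width) — which
is always feasible — then runs simulated annealing (relocate and swap moves
over (reaction, dye) assignments, geometric cooling at 0.95, up to 100
restarts per level, all randomness from one seed) trying to realize one
reaction fewer than the incumbent, stopping at the ⌈n/10⌉ lower bound or at
the first level it cannot satisfy. Dyes are reassigned freely, including for
literature primers (relabeling a dye is a routine panel adjustment). The
returned assignment is asserted violation-free; on the bundled 33-locus
panel the optimizer finds 4-reaction layouts (the published design uses 5)
in under a second per seed. Exhaustive set-partition search confirms
optimality on all tested instances up to 8 loci.

## Ladders and genotype calling

An allelic ladder needs the smallest practical set of individuals whose
alleles jointly cover every observed allele — a set-cover problem. The
builder seeds with the greedy rule (repeatedly take the sample covering the
most uncovered (locus, allele) pairs, ties by sample order) and, for cohorts
of ≤ 30 samples, refines to the exact minimum by branch and bound with
element branching; beyond that the greedy (1 + ln a)-approximation stands.
Greedy alone is occasionally suboptimal even on ten-sample instances, and a
provably minimal cover is worth having exactly where exactness is cheap.

Size binning snaps a measured fragment to the nearest ladder allele within
a 0.5 bp tolerance (configurable; typical capillary size precision is
~0.1–0.3 bp, so 0.5 bp is a conservative default), with exact midpoint ties
resolved to the smaller allele. One binned peak is called a homozygote
(allelic dropout is not modeled), two a heterozygote, and anything
unbinnable or absent a missing call (0, 0). Amplification rate is the
percentage of samples with a non-missing call, rounded half-up to integer
percent. Stutter peaks are not modeled at the peak level; the ladder's
register is anchored to genome-predicted sizes instead, which is how the
reference panel handled its one stutter-prone locus.

## Estimator conventions

* **He** is Nei's gene diversity `1 − Σpᵢ²` from sample frequencies, no
  small-sample correction by default (`unbiased=True` applies 2n/(2n−1)) —
  matching the convention of the standard spreadsheet tools this format
  interoperates with.
* **PIC** is Botstein's `1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ²`, always strictly below He
  for polymorphic loci.
* **HWE** is the exact conditional test: the probability of a genotype
  array given allele counts is `n!/Πnᵢⱼ! · 2ʰ · Πnₐ!/(2n)!`; the p-value
  sums the probabilities of all arrays no more probable than the observed
  one. Arrays are enumerated by depth-first search up to 10⁶; larger tables
  fall back to seeded Monte-Carlo permutation of the allele vector. Tests
  are run per population × locus; cells with fewer than 10 typed samples or
  a single allele are excluded, and flags are raw p < 0.05 with no
  multiple-testing correction (the convention of the reference screen this
  package reproduces; both thresholds are parameters).
* **Nei distance**: per-locus sums J_ab, J_a, J_b are arithmetically
  averaged over loci before forming `I = J̄_ab/√(J̄_a J̄_b)`, `D = −ln I`;
  populations sharing no alleles anywhere get an infinity sentinel.
* **Gst**: the pairwise matrix (used for the NJ tree) is plain Nei Gst,
  `(H̄_T − H̄_S)/H̄_T` with locus-averaged components and no correction for
  the number of populations — the hand-verifiable form (two pops fixed for
  alternative alleles give exactly 1, mirrored (0.8, 0.2) frequencies give
  exactly 0.36). For *estimating* a differentiation parameter,
  `gst_overall` applies the Nei–Chesser `K/(K−1)` inflation to
  `D_ST = H_T − H_S`: with K sampled populations the uncorrected estimator
  converges to `F(K−1)/(K−F)`, not F (0.143 at F = 0.2, K = 3), and the
  correction removes exactly that bias. The monotone pairwise bias is
  harmless for tree building; it would be misleading for parameter
  reporting. Weir–Cockerham θ is out of scope.
* **PCoA** double-centers `−½D²` and eigendecomposes; axis percentages are
  taken over the positive-eigenvalue total, with negative eigenvalues
  reported but excluded from both coordinates and the denominator.
* **NJ** is Saitou–Nei agglomeration with the standard negative-branch
  remedy: a negative estimate is clamped to zero and its deficit moved to
  the sibling branch, preserving the joined pair's path length. Bootstrap
  support resamples loci with replacement, recomputes the Gst matrix and
  tree per replicate (from precomputed per-locus diversity components, which
  is algebraically identical to re-deriving the matrix), and reports the
  percentage of replicates containing each original bipartition.
* **Evanno ΔK** uses replicate means in the second difference:
  `ΔK = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K))`, defined for interior K of a
  consecutive run with ≥ 2 replicates each; zero variance yields an infinity
  sentinel with a warning. The clustering runs themselves are external —
  this package only consumes their (K, replicate, L) table.

## Synthetic data

`simulate_genome_pair` emulates two conspecific assemblies: implanted
primitive motifs with 7–12 repeats, a configurable fraction polymorphic
(repeat counts differing by 1–3 units), identical flanks and background
across haplotypes, background rejection-sampled to contain no detectable
SSR, and junction bases constrained so every implanted run is exactly
maximal. It does not emulate assembly errors, structural variation between
haplotypes, or imperfect repeats — so mining tests certify the scanner and
matcher logic, not robustness to misassembly.

`simulate_genotypes` is the Balding–Nichols model: ancestral frequencies
from a flat Dirichlet; population frequencies from
`Dirichlet(p_anc (1−F)/F)`, giving variance `F p(1−p)` around the ancestral
value; genotypes as two independent draws (Hardy–Weinberg within
populations); allele codes spaced one repeat unit apart starting from a
per-locus base size; optional whole-call missingness. Defaults (3
populations × 50 diploids, 50 loci, 8 alleles per locus) are a typical
panel-validation cohort. There is no mutation model, no linkage, no null
alleles and no inbreeding, so recovery tests certify the estimators under
their own assumptions, not their behavior on messy real data.

`simulate_fragments` adds Gaussian size error at 0.1 bp resolution. At the
0.5 bp binning tolerance, noise of 0.1 bp SD (a 5σ margin) gives exact
round-trip recovery at the thousand-call scale; by 0.3 bp SD the expected
per-allele miss rate (~9%) makes exact recovery statistically impossible,
which is why the round-trip contract is tested at 0 and 0.1 bp.

## Problem sizes used by the test suite

The bundled checks run at desk scale, chosen to exercise every code path
with exact or tight statistical oracles: 2 kb sequences against a
brute-force repeat scanner; ≤ 8-locus packing instances against exhaustive
set-partition search (50 instances); ≤ 12-sample ladder instances against
exhaustive minimum covers; 400 Hardy–Weinberg tables for type-I error and
50 for Monte-Carlo/enumeration agreement; 200 random additive five-taxon
matrices for NJ; Gst recovery at F ∈ {0.05, 0.2} over ten seeds of
50 loci × 3 × 50 diploids. Full-genome mining of real assemblies is
supported by the same code paths but is not part of the test suite.

## Known limitations

* Perfect repeats only; interrupted/compound SSRs are reported as separate
  runs.
* The Tm formula ignores salt and oligo concentration; use the constraint
  window, not the absolute values.
* No PCR competition or efficiency model: a violation-free packing is
  necessary, not sufficient, for a working multiplex — wet-lab validation
  remains the final arbiter.
* Single-peak calls are taken as homozygotes; allelic dropout and null
  alleles are not modeled.
* The HWE Monte-Carlo fallback gives an estimate with binomial standard
  error, not an exact value; seed it for reproducibility.
* `fst_matrix` values are downward-biased as F_ST estimates (by design, see
  above); report `gst_overall` when the parameter itself is of interest.
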