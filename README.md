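# msatforge

Microsatellite (SSR) panel engineering for non-model organisms: mine
polymorphic loci from a pair of genome assemblies, design and score primers,
pack assays into the fewest multiplex PCR reactions under fluorescent-dye and
fragment-size constraints, genotype against allelic ladders, and certify the
resulting marker panel with the standard population-genetics battery.

The package is aimed at researchers building fragment-analysis genotyping
panels — the workflow behind the published 33-locus walnut (*Juglans* spp.)
multiplex system, whose panel ships with the package as reference data — and
at anyone who needs its individual pieces: a perfect-repeat scanner, a
multiplex bin-packing optimizer, a multi-allelic Hardy–Weinberg exact test,
or an Evanno ΔK calculator.

## What it computes

**SSR mining.** Maximal perfect tandem repeats with motifs of 1–6 bp are
detected in both assemblies; motifs are canonicalized across rotation and
strand (so (GAT)n ≡ (ATC)n). Loci are matched 1:1 across assemblies by
ungapped flank identity (≥ 95%), de-duplicated, and kept when polymorphic
(repeat counts differ), with motif length 3–6 bp, ≥ 7 repeats, and a feasible
100–400 bp product.

**Primer design and scoring.** Exhaustive flank scanning under classic rules:
length 18–27 nt, GC 40–60%, Tm (= 64.9 + 41(G+C − 16.4)/N) between 52 and
62 °C with pair difference ≤ 3 °C, and primer-dimer screening by the longest
contiguous Watson–Crick run over all ungapped antiparallel alignments
(score ≥ 7 rejects).

**Multiplex design.** Packing loci into reactions is constrained bin packing:
≤ 10 loci per reaction, same-dye allele ranges ≥ 40 bp apart edge-to-edge,
no cross-locus primer pair at or above the dimer threshold, annealing spread
≤ 8 °C, three dyes (FAM/HEX/TAMRA). A first-fit-decreasing seed is refined by
seeded simulated annealing that repeatedly attempts one reaction fewer; the
result is always violation-free.

**Genotyping.** Allelic ladders are minimum covers: the smallest set of
individuals whose alleles jointly include every observed allele (exact by
branch and bound for small cohorts, greedy beyond). Raw capillary sizes are
snapped to the nearest ladder allele within 0.5 bp; one peak is a homozygote,
two a heterozygote, anything unbinnable a missing call.

**Validation statistics.** Allele frequencies; Na, Ho, and Nei's gene
diversity He = 1 − Σpᵢ²; Botstein's PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ²; the
multi-allelic HWE exact test (array probability n!/Πnᵢⱼ! · 2ʰ · Πnₐ!/(2n)!,
full enumeration with seeded Monte-Carlo fallback); Nei's distance
D = −ln I; pairwise Gst = (H_T − H_S)/H_T and a K/(K−1)-corrected overall
Gst; PCoA by double-centered eigendecomposition; neighbor joining with
locus-bootstrap support; Evanno ΔK = |L̄(K+1) − 2L̄(K) + L̄(K−1)|/sd(L(K)).

Deterministic synthetic generators (genome pairs with implanted SSR truth
tables, Balding–Nichols genotype datasets, noisy fragment calls) make every
stage testable end to end without downloads.

## Worked example

Re-optimize the published 33-locus panel with dyes and reactions freed:

```python
from msatforge import DesignConstraints, optimize_panel
from msatforge.datasets import walnut_panel

panel = walnut_panel()
assignment = optimize_panel(panel, DesignConstraints(), seed=1)
print(f"{len(panel)} loci packed into {assignment.n_reactions} reactions")
```

```
33 loci packed into 4 reactions
```

The published layout uses 5 reactions; the optimizer, free to relabel dyes,
finds a violation-free 4-reaction packing (e.g. reaction M1 carries ten loci
whose same-dye size ranges keep ≥ 40 bp gaps, with annealing temperatures
spanning 53–61 °C). Closing the loop on the statistics side:

```python
from msatforge import simulate_genotypes, gst_overall

dataset, truth = simulate_genotypes(n_pops=3, n_per_pop=50, n_loci=50,
                                    fst=0.2, seed=1)
print(f"Gst estimate: {gst_overall(dataset):.3f} (simulated F_ST = 0.2)")
```

```
Gst estimate: 0.198 (simulated F_ST = 0.2)
```

The corrected Gst recovers the simulated differentiation parameter — the
parameter-recovery check that certifies the estimator battery.

A command-line interface mirrors the library
(`msatforge mine | design-primers | design-panel | ladder | call | stats |
deltak | simulate`), e.g.:

```sh
msatforge simulate genotypes --n-pops 3 --fst 0.2 --seed 1 --out g.csv
msatforge stats --genotypes g.csv --out-dir results/
```

## Layout

| module | contents |
| --- | --- |
| `msatforge.io_formats` | FASTA, GenAlEx-style genotype CSV, panel TSV, fragment-call CSV, newick |
| `msatforge.ssr_mining` | repeat scanning, motif canonicalization, cross-assembly matching |
| `msatforge.primer_tools` | Tm, dimer scoring, exhaustive primer design |
| `msatforge.multiplex_design` | constraints, panel validation, annealing optimizer |
| `msatforge.genotyping` | allelic ladders, size binning, amplification rates |
| `msatforge.popgen_stats` | frequencies, He/Ho/Na, PIC, HWE, Nei/Gst, PCoA, NJ + bootstrap, ΔK |
| `msatforge.synth_fixtures` | seeded genome/genotype/fragment simulators |
| `msatforge.datasets` | the bundled 33-locus walnut reference panel |

See `docs/methods.md` for the statistical conventions, parameter defaults
and known limitations.
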