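"""Deterministic synthetic data for every stage of the toolkit.

Three generators emulate the inputs the pipeline consumes in production:

* :func:`simulate_genome_pair` — two haploid assemblies that differ only in
  the repeat counts of implanted microsatellites, over shared flanks, with
  SSR-free random background (rejection-sampled), standing in for two
  conspecific genome assemblies.
* :func:`simulate_genotypes` — diploid genotype datasets with controlled
  population structure under the Balding–Nichols model: each population's
  allele frequencies are drawn from a Dirichlet centred on the ancestral
  frequencies with concentration ``(1 - F)/F``, and genotypes are drawn at
  Hardy–Weinberg proportions within populations.  The differentiation
  parameter F is then recoverable by a Gst estimate, closing the loop on the
  validation statistics.
* :func:`simulate_fragments` — noisy capillary fragment sizes from a
  genotype dataset plus ladder (Gaussian size error, 0.1 bp resolution).

All generators are pure functions of their seeds: fixed seed, identical
output, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import FragmentCall, GenotypeDataset, SequenceRecord
from .ssr_mining import DEFAULT_MIN_REPEATS, canonical_motif, find_ssrs, _is_primitive
from .genotyping import Ladder

__all__ = [
    "TruthTable",
    "simulate_genome_pair",
    "simulate_genotypes",
    "simulate_fragments",
]

_BASES = np.array(list("ACGT"))


@dataclass
class TruthTable:
    """Ground truth of a simulation, for closed-loop testing."""

    loci: pd.DataFrame
    params: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(4, size=length)])


def _ssr_free_segment(rng: np.random.Generator, length: int, max_tries: int = 50) -> str:
    """Random DNA with no detectable SSR at the default thresholds."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        probe = SequenceRecord("probe", seq)
        if not find_ssrs(probe, min_repeats_by_motif_len=DEFAULT_MIN_REPEATS):
            return seq
    raise RuntimeError("could not draw an SSR-free background segment")


def _random_primitive_motif(rng: np.random.Generator, length: int) -> str:
    while True:
        motif = _random_seq(rng, length)
        if _is_primitive(motif) and len(set(motif)) > 1:
            return motif


def simulate_genome_pair(
    n_loci: int = 10,
    flank_len: int = 150,
    seed: int = 0,
    polymorphic_fraction: float = 0.6,
    motif_lens: Sequence[int] = (3, 4, 5, 6),
    spacer_len: int = 80,
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthTable]:
    """Two single-scaffold assemblies with implanted SSR loci.

    Each implanted locus has a random primitive motif, 7–12 repeats in
    assembly A and (for the first ``round(polymorphic_fraction * n_loci)``
    loci) a repeat count differing by 1–3 units in assembly B.  Flanks and
    background are identical across assemblies and rejection-sampled to be
    SSR-free; junction bases are constrained so each implanted repeat is
    exactly maximal.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if flank_len < 40:
        raise ValueError("flank_len below the primer-design minimum")
    rng = np.random.default_rng(seed)
    n_poly = round(polymorphic_fraction * n_loci)
    parts_a: list[str] = []
    parts_b: list[str] = []
    pos_a = pos_b = 0
    rows = []
    for idx in range(n_loci):
        motif = _random_primitive_motif(rng, int(rng.choice(motif_lens)))
        reps_a = int(rng.integers(7, 13))
        if idx < n_poly:
            delta = int(rng.integers(1, 4)) * int(rng.choice([-1, 1]))
            reps_b = max(7, reps_a + delta)
            if reps_b == reps_a:
                reps_b = reps_a + abs(delta)
        else:
            reps_b = reps_a
        spacer = _ssr_free_segment(rng, spacer_len)
        left = _ssr_free_segment(rng, flank_len)
        right = _ssr_free_segment(rng, flank_len)
        # keep the implanted run maximal: the base before the repeat must not
        # extend it (period p run extends left iff prev == motif[-1]) and the
        # base after must differ from motif[0]
        while left[-1] == motif[-1]:
            left = left[:-1] + str(_BASES[rng.integers(4)])
        while right[0] == motif[0]:
            right = str(_BASES[rng.integers(4)]) + right[1:]
        prefix = spacer + left
        parts_a.append(prefix + motif * reps_a + right)
        parts_b.append(prefix + motif * reps_b + right)
        start_a = pos_a + len(prefix)
        start_b = pos_b + len(prefix)
        rows.append({
            "locus": f"L{idx + 1:03d}",
            "motif": canonical_motif(motif),
            "motif_raw": motif,
            "start_a": start_a,
            "end_a": start_a + len(motif) * reps_a,
            "start_b": start_b,
            "end_b": start_b + len(motif) * reps_b,
            "repeats_a": reps_a,
            "repeats_b": reps_b,
            "polymorphic": reps_a != reps_b,
        })
        pos_a += len(parts_a[-1])
        pos_b += len(parts_b[-1])
    tail = _ssr_free_segment(rng, spacer_len)
    genome_a = [SequenceRecord("assemblyA_scaffold1", "".join(parts_a) + tail)]
    genome_b = [SequenceRecord("assemblyB_scaffold1", "".join(parts_b) + tail)]
    truth = TruthTable(
        loci=pd.DataFrame(rows),
        params={"seed": seed, "n_loci": n_loci, "flank_len": flank_len,
                "polymorphic_fraction": polymorphic_fraction},
    )
    return genome_a, genome_b, truth


def simulate_genotypes(
    n_pops: int = 3,
    n_per_pop: int = 50,
    n_loci: int = 50,
    alleles_per_locus: int = 8,
    fst: float = 0.2,
    seed: int = 0,
    missing_rate: float = 0.0,
    motif_len: int = 3,
    base_size: int = 100,
) -> tuple[GenotypeDataset, TruthTable]:
    """Balding–Nichols diploid genotypes with target differentiation ``fst``.

    Ancestral allele frequencies are drawn from a flat Dirichlet; each
    population's frequencies from ``Dirichlet(p_anc * (1 - fst) / fst)``,
    whose variance around ``p_anc`` is ``fst * p * (1 - p)``.  Genotypes are
    two independent draws per individual (Hardy–Weinberg within populations).
    Allele codes are fragment sizes ``base_size + motif_len * k`` spaced one
    repeat unit apart.  ``missing_rate`` injects whole-call missingness.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    if alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    rng = np.random.default_rng(seed)
    loci = [f"L{i + 1:03d}" for i in range(n_loci)]
    pops = [f"P{i + 1}" for i in range(n_pops)]
    samples = [f"{pop}_{j + 1:03d}" for pop in pops for j in range(n_per_pop)]
    populations = {s: s.split("_")[0] for s in samples}
    sizes = {
        loc: base_size + 10 * motif_len * i + motif_len * np.arange(alleles_per_locus)
        for i, loc in enumerate(loci)
    }
    anc = rng.dirichlet(np.ones(alleles_per_locus), size=n_loci)
    conc = (1.0 - fst) / fst
    calls: dict[tuple[str, str], tuple[int, int]] = {}
    pop_freqs = np.zeros((n_pops, n_loci, alleles_per_locus))
    for li, loc in enumerate(loci):
        for pi, pop in enumerate(pops):
            alpha = np.maximum(anc[li] * conc, 1e-6)
            pop_freqs[pi, li] = rng.dirichlet(alpha)
    for pi, pop in enumerate(pops):
        for j in range(n_per_pop):
            sample = f"{pop}_{j + 1:03d}"
            for li, loc in enumerate(loci):
                if missing_rate > 0 and rng.random() < missing_rate:
                    calls[(sample, loc)] = (0, 0)
                    continue
                pair = rng.choice(alleles_per_locus, size=2, p=pop_freqs[pi, li])
                a, b = int(sizes[loc][pair[0]]), int(sizes[loc][pair[1]])
                calls[(sample, loc)] = (min(a, b), max(a, b))
    dataset = GenotypeDataset(samples, populations, loci, calls)
    truth = TruthTable(
        loci=pd.DataFrame({
            "locus": loci,
            "alleles": [list(map(int, sizes[loc])) for loc in loci],
        }),
        params={"seed": seed, "fst": fst, "n_pops": n_pops,
                "n_per_pop": n_per_pop, "alleles_per_locus": alleles_per_locus,
                "missing_rate": missing_rate},
    )
    return dataset, truth


def simulate_fragments(
    dataset: GenotypeDataset,
    ladder: Ladder,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> list[FragmentCall]:
    """Noisy capillary fragment sizes for every call of ``dataset``.

    Each true allele acquires independent Gaussian size error (``noise_sd``
    bp) and is reported at 0.1 bp resolution; homozygotes produce a single
    peak, missing calls an empty size list.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[FragmentCall] = []
    for sample in dataset.samples:
        for locus in dataset.loci:
            if locus not in ladder.alleles:
                raise KeyError(f"locus {locus!r} absent from ladder")
            a, b = dataset.call(sample, locus)
            if a == 0:
                out.append(FragmentCall(sample, locus, ()))
                continue
            peaks = (a,) if a == b else (a, b)
            sizes = tuple(
                round(p + float(rng.normal(0.0, noise_sd)), 1) if noise_sd > 0
                else float(p)
                for p in peaks
            )
            out.append(FragmentCall(sample, locus, sizes))
    return out
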