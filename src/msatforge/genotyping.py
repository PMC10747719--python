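"""Allelic ladders, fragment-size binning and genotype assembly.

An allelic ladder is a reference mixture that contains every allele observed
at a locus; it anchors fragment-size calls to a common register so that
genotypes are comparable across runs and laboratories.  The informatic core
implemented here is (i) choosing a small set of individuals whose alleles
jointly cover every observed allele (greedy set cover), (ii) snapping raw
capillary sizes to the nearest ladder allele within a tolerance, and
(iii) assembling diploid genotype calls and per-locus amplification rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import FragmentCall, GenotypeDataset

__all__ = [
    "Ladder",
    "NO_CALL",
    "build_ladder",
    "bin_size",
    "call_genotypes",
    "amplification_rate",
]

#: Sentinel returned by :func:`bin_size` when no ladder allele is close enough.
NO_CALL = None


@dataclass
class Ladder:
    """Per-locus sorted reference allele sizes plus the covering individuals.

    ``alleles[locus]`` lists the distinct observed allele sizes in ascending
    order; ``cover`` is the sample set whose alleles jointly include every
    (locus, allele) pair.
    """

    alleles: dict[str, list[int]]
    cover: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for locus, sizes in self.alleles.items():
            if not sizes:
                raise ValueError(f"locus {locus!r} has an empty allele list")
            if sorted(set(sizes)) != list(sizes):
                raise ValueError(f"locus {locus!r}: alleles must be sorted and distinct")

    @property
    def loci(self) -> list[str]:
        return list(self.alleles)


def build_ladder(dataset: GenotypeDataset, exact_max_samples: int = 30) -> Ladder:
    """Build an allelic ladder: a minimum set of individuals covering every allele.

    The universe is the set of (locus, allele) pairs observed in the dataset.
    A greedy cover — repeatedly pick the sample covering the most uncovered
    pairs, ties broken by sample order — seeds the search; for cohorts of at
    most ``exact_max_samples`` individuals the cover is then refined to the
    exact minimum by branch and bound (element branching), so small ladders
    are provably minimal.  Beyond that size the greedy ln-approximation is
    returned as is.
    """
    universe: set[tuple[str, int]] = set()
    per_sample: dict[str, set[tuple[str, int]]] = {s: set() for s in dataset.samples}
    for locus in dataset.loci:
        typed = False
        for s in dataset.samples:
            a, b = dataset.call(s, locus)
            if a == 0:
                continue
            typed = True
            for allele in (a, b):
                universe.add((locus, allele))
                per_sample[s].add((locus, allele))
        if not typed:
            raise ValueError(f"locus {locus!r} has no typed calls")
    uncovered = set(universe)
    cover: list[str] = []
    while uncovered:
        best = max(dataset.samples,
                   key=lambda s: (len(per_sample[s] & uncovered),
                                  -dataset.samples.index(s)))
        gain = per_sample[best] & uncovered
        if not gain:  # unreachable: every pair comes from some sample
            break
        cover.append(best)
        uncovered -= gain
    if len(dataset.samples) <= exact_max_samples:
        exact = _exact_min_cover(dataset.samples, per_sample, universe, len(cover))
        if exact is not None:
            cover = exact
    alleles = {
        locus: sorted({a for (loc, a) in universe if loc == locus})
        for locus in dataset.loci
    }
    return Ladder(alleles=alleles, cover=cover)


def _exact_min_cover(
    samples: Sequence[str],
    per_sample: Mapping[str, set],
    universe: set,
    upper: int,
) -> list[str] | None:
    """Minimum set cover by depth-first element branching.

    Branches on the uncovered element held by the fewest samples; prunes with
    the bound ``chosen + ceil(uncovered / max_gain)``.  Returns a cover
    strictly smaller than ``upper``, or None if the greedy cover is already
    minimal.
    """
    holders: dict[tuple, list[str]] = {}
    for s in samples:
        for item in per_sample[s]:
            holders.setdefault(item, []).append(s)
    best: list[list[str] | None] = [None]
    bound = [upper]

    def dfs(uncovered: set, chosen: list[str]) -> None:
        if not uncovered:
            best[0] = list(chosen)
            bound[0] = len(chosen)
            return
        max_gain = max(len(per_sample[s] & uncovered) for s in samples)
        if len(chosen) + math.ceil(len(uncovered) / max_gain) >= bound[0]:
            return
        target = min(uncovered, key=lambda item: len(holders[item]))
        for s in holders[target]:
            dfs(uncovered - per_sample[s], chosen + [s])

    dfs(set(universe), [])
    return best[0]


def bin_size(
    measured_size: float,
    ladder_alleles: Sequence[float],
    tolerance: float = 0.5,
) -> float | None:
    """Snap a measured fragment size to the nearest ladder allele.

    Returns the nearest allele if it lies within ``tolerance`` bp, else
    :data:`NO_CALL`.  An exact midpoint between two alleles resolves to the
    smaller one.
    """
    if not ladder_alleles:
        raise ValueError("empty ladder")
    best = min(ladder_alleles, key=lambda a: (abs(measured_size - a), a))
    if abs(measured_size - best) <= tolerance + 1e-9:
        return best
    return NO_CALL


def call_genotypes(
    fragment_calls: Iterable[FragmentCall],
    ladder: Ladder,
    populations: Mapping[str, str] | None = None,
    tolerance: float = 0.5,
) -> GenotypeDataset:
    """Convert raw fragment calls to a diploid genotype dataset.

    Two binnable sizes give a heterozygote; a single size a homozygote (the
    allele duplicated, the standard single-peak convention); zero sizes or
    any size that fails to bin give a missing call (0, 0).  Samples keep
    their order of first appearance; loci follow the ladder order.
    """
    calls_by_sample: dict[str, dict[str, tuple[int, int]]] = {}
    samples: list[str] = []
    for fc in fragment_calls:
        if fc.locus not in ladder.alleles:
            raise KeyError(f"fragment call references unknown locus {fc.locus!r}")
        if fc.sample not in calls_by_sample:
            calls_by_sample[fc.sample] = {}
            samples.append(fc.sample)
        binned = [bin_size(s, ladder.alleles[fc.locus], tolerance) for s in fc.sizes]
        if not binned or any(b is NO_CALL for b in binned):
            genotype = (0, 0)
        elif len(binned) == 1:
            genotype = (int(binned[0]), int(binned[0]))
        else:
            a, b = int(binned[0]), int(binned[1])
            genotype = (min(a, b), max(a, b))
        calls_by_sample[fc.sample][fc.locus] = genotype
    loci = ladder.loci
    pops = {s: (populations or {}).get(s, "POP1") for s in samples}
    calls = {
        (s, loc): calls_by_sample[s].get(loc, (0, 0))
        for s in samples for loc in loci
    }
    return GenotypeDataset(samples, pops, loci, calls)


def amplification_rate(dataset: GenotypeDataset, locus: str) -> int:
    """Percent of samples with a scorable (non-missing) call at ``locus``.

    Rounded half-up to an integer percent (87/95 → 92%).
    """
    if locus not in dataset.loci:
        raise KeyError(f"unknown locus {locus!r}")
    total = len(dataset.samples)
    if total == 0:
        return 0
    typed = sum(1 for s in dataset.samples if not dataset.is_missing(s, locus))
    return int(math.floor(100.0 * typed / total + 0.5))
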