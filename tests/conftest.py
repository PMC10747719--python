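import numpy as np
import pytest

from msatforge import DesignConstraints, GenotypeDataset, PanelLocus


def make_dataset(genotypes: dict[str, dict[str, list[tuple[int, int]]]]) -> GenotypeDataset:
    """Build a dataset from {pop: {locus: [(a, b) per sample]}}.

    Every population must list the same loci with equal sample counts per
    locus.
    """
    pops = list(genotypes)
    loci = list(genotypes[pops[0]])
    samples: list[str] = []
    populations: dict[str, str] = {}
    calls: dict[tuple[str, str], tuple[int, int]] = {}
    for pop in pops:
        n = len(genotypes[pop][loci[0]])
        for i in range(n):
            s = f"{pop}_{i + 1:02d}"
            samples.append(s)
            populations[s] = pop
            for locus in loci:
                a, b = genotypes[pop][locus][i]
                calls[(s, locus)] = (min(a, b), max(a, b))
    return GenotypeDataset(samples, populations, loci, calls)


def random_panel_loci(rng: np.random.Generator, n: int) -> list[PanelLocus]:
    """Random loci with plausible size ranges, primers and annealing temps."""
    bases = np.array(list("ACGT"))
    loci = []
    for i in range(n):
        lo = int(rng.integers(90, 370))
        hi = lo + int(rng.integers(12, 35))
        fwd = "".join(bases[rng.integers(4, size=20)])
        rev = "".join(bases[rng.integers(4, size=20)])
        loci.append(PanelLocus(
            name=f"X{i + 1:02d}", fwd=fwd, rev=rev, motif="ATC",
            size_min=lo, size_max=hi, ta=float(rng.integers(55, 60)),
            dye="FAM", reaction="unassigned", source="de_novo",
        ))
    return loci


@pytest.fixture(scope="session")
def walnut_panel():
    from msatforge.datasets import walnut_panel

    return walnut_panel()


@pytest.fixture
def default_constraints():
    return DesignConstraints()
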