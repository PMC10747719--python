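"""Marker-validation population genetics for diploid microsatellite data.

The battery a new marker panel is certified with: allele frequencies and the
per-population summary statistics Na (allele count), Ho (observed
heterozygosity) and He (Nei's gene diversity, ``1 - sum p_i^2``), Botstein's
polymorphism information content (PIC), the multi-allelic Hardy–Weinberg
exact test (full enumeration with a Monte-Carlo fallback), Nei's standard
genetic distance, Gst-type fixation indices, principal coordinates analysis,
neighbor-joining trees with locus-bootstrap support, and the Evanno ΔK
statistic for choosing the number of genetic clusters from external
model-based clustering log-likelihoods.

Estimator conventions
---------------------
He is reported without small-sample correction by default (the ``unbiased``
flag applies the 2n/(2n-1) factor).  Pairwise ``fst_matrix`` is Nei's Gst,
``(H_T - H_S)/H_T`` with the three quantities averaged over loci and no
correction for the number of populations — the form whose two-population
closed cases are easy to verify by hand.  ``gst_overall`` additionally
applies the Nei–Chesser ``K/(K-1)`` correction to ``D_ST``, which removes
the downward bias of Gst when only a handful of populations is sampled and
makes the estimator recover the Balding–Nichols differentiation parameter.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .io_formats import GenotypeDataset, TreeNode

__all__ = [
    "AlleleFreqTable",
    "DistanceMatrix",
    "PcoaResult",
    "DeltaKResult",
    "allele_freqs",
    "summary_stats",
    "pic",
    "hwe_exact",
    "hwe_table",
    "nei_identity",
    "nei_distance",
    "nei_matrix",
    "fst_matrix",
    "gst_overall",
    "pcoa",
    "nj_tree",
    "bootstrap_support",
    "evanno_delta_k",
]


# ---------------------------------------------------------------------------
# allele frequencies and summary statistics
# ---------------------------------------------------------------------------


@dataclass
class AlleleFreqTable:
    """Allele frequencies per (population, locus), from typed alleles only.

    ``n[(pop, locus)]`` is the typed-sample count; when it is zero the
    frequency dict is empty and the entry is flagged undefined.
    """

    freqs: dict[tuple[str, str], dict[int, float]]
    n: dict[tuple[str, str], int]
    populations: list[str]
    loci: list[str]

    def __post_init__(self) -> None:
        for key, table in self.freqs.items():
            if self.n[key] > 0:
                total = sum(table.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"frequencies at {key} sum to {total}")
                if any(p < 0 for p in table.values()):
                    raise ValueError(f"negative frequency at {key}")

    def freq(self, population: str, locus: str) -> dict[int, float]:
        return self.freqs[(population, locus)]

    def is_defined(self, population: str, locus: str) -> bool:
        return self.n[(population, locus)] > 0

    def locus_freqs(self, population: str) -> dict[str, dict[int, float]]:
        return {loc: self.freqs[(population, loc)] for loc in self.loci}


def allele_freqs(dataset: GenotypeDataset, by_population: bool = True) -> AlleleFreqTable:
    """Tabulate allele frequencies from typed calls (missing excluded)."""
    pops = dataset.population_labels if by_population else ["ALL"]
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    counts_n: dict[tuple[str, str], int] = {}
    for pop in pops:
        samples = dataset.samples_in(pop) if by_population else dataset.samples
        for locus in dataset.loci:
            counter: dict[int, int] = {}
            n_typed = 0
            for s in samples:
                a, b = dataset.call(s, locus)
                if a == 0:
                    continue
                n_typed += 1
                counter[a] = counter.get(a, 0) + 1
                counter[b] = counter.get(b, 0) + 1
            key = (pop, locus)
            counts_n[key] = n_typed
            total = 2 * n_typed
            freqs[key] = (
                {allele: c / total for allele, c in sorted(counter.items())}
                if n_typed else {}
            )
    return AlleleFreqTable(freqs, counts_n, pops, list(dataset.loci))


def _he(p: Iterable[float]) -> float:
    return 1.0 - sum(x * x for x in p)


def summary_stats(dataset: GenotypeDataset, unbiased: bool = False) -> pd.DataFrame:
    """Per (population, locus) Na, Ho and He.

    Na is the number of distinct alleles among typed calls, Ho the observed
    heterozygote fraction, He Nei's gene diversity ``1 - sum p_i^2``
    (multiplied by ``2n/(2n-1)`` when ``unbiased``).
    """
    table = allele_freqs(dataset, by_population=True)
    rows = []
    for pop in table.populations:
        for locus in table.loci:
            n = table.n[(pop, locus)]
            p = table.freqs[(pop, locus)]
            if n == 0:
                rows.append((pop, locus, 0, 0, math.nan, math.nan))
                continue
            het = sum(
                1
                for s in dataset.samples_in(pop)
                if (c := dataset.call(s, locus))[0] != 0 and c[0] != c[1]
            )
            he = _he(p.values())
            if unbiased and n > 1:
                he *= 2 * n / (2 * n - 1)
            rows.append((pop, locus, n, len(p), het / n, he))
    return pd.DataFrame(rows, columns=["population", "locus", "n", "na", "ho", "he"])


def pic(freqs: Mapping[int, float] | Sequence[float]) -> float:
    """Botstein's polymorphism information content.

    ``PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``; zero for a
    monomorphic locus and strictly below He otherwise.
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else list(freqs),
                   dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency set")
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 1.0 - s2 - (s2 * s2 - s4)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def _normalize_genotype_counts(
    genotype_counts: Mapping[tuple[int, int], int],
) -> tuple[list[int], dict[tuple[int, int], int]]:
    counts: dict[tuple[int, int], int] = {}
    for (a, b), c in genotype_counts.items():
        if c < 0:
            raise ValueError("negative genotype count")
        if c:
            key = (min(a, b), max(a, b))
            counts[key] = counts.get(key, 0) + c
    alleles = sorted({a for pair in counts for a in pair})
    return alleles, counts


def hwe_exact(
    genotype_counts: Mapping[tuple[int, int], int],
    mc_reps: int = 100_000,
    seed: int | None = None,
    max_enumeration: int = 1_000_000,
) -> float:
    """Exact probability test of Hardy–Weinberg proportions.

    Conditional on the allele counts, a diploid genotype array has
    probability ``n! / prod(n_ij!) * 2^h * prod(n_a!) / (2n)!`` where ``h``
    is the number of heterozygotes.  The p-value is the total probability of
    all arrays no more probable than the observed one.  Arrays are fully
    enumerated when their number stays within ``max_enumeration``; otherwise
    the p-value is estimated by Monte-Carlo permutation of the allele vector
    (``mc_reps`` draws, seed-reproducible), the standard large-table
    approach.

    Raises ``ValueError`` for monomorphic input, where the test is undefined.
    """
    alleles, counts = _normalize_genotype_counts(genotype_counts)
    if len(alleles) < 2:
        raise ValueError("HWE test undefined for monomorphic input")
    n = sum(counts.values())
    if n < 1:
        raise ValueError("empty genotype table")
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    allele_counts = [0] * k
    h_obs = 0
    obs_cells = {}
    for (a, b), c in counts.items():
        i, j = index[a], index[b]
        allele_counts[i] += c
        allele_counts[j] += c
        if i != j:
            h_obs += c
        obs_cells[(i, j)] = c

    lf = [0.0] * (2 * n + 1)
    for i in range(2, 2 * n + 1):
        lf[i] = lf[i - 1] + math.log(i)
    ln2 = math.log(2.0)
    const = lf[n] + sum(lf[m] for m in allele_counts) - lf[2 * n]

    def log_prob(cells: Mapping[tuple[int, int], int], h: int) -> float:
        return const - sum(lf[c] for c in cells.values()) + h * ln2

    logp_obs = log_prob(obs_cells, h_obs)
    eps = 1e-9

    # cheap pre-gate: the free dimension of the array polytope is
    # k(k+1)/2 - k; the unconstrained count C(n + d, d) upper-bounds the
    # growth regime, so large tables go straight to Monte-Carlo
    free_dim = k * (k + 1) // 2 - k
    tractable = math.comb(n + free_dim, free_dim) <= 50 * max_enumeration

    cats = [(i, j) for i in range(k) for j in range(i, k)]
    arrays: list[float] = []  # log-probabilities of enumerated arrays
    overflow = not tractable
    node_budget = [10 * max_enumeration]

    def enumerate_arrays(pos: int, remaining: list[int], cells: dict, h: int) -> bool:
        """DFS over genotype arrays; returns False on overflow."""
        nonlocal overflow
        node_budget[0] -= 1
        if len(arrays) > max_enumeration or node_budget[0] < 0:
            overflow = True
            return False
        if pos == len(cats):
            if all(r == 0 for r in remaining):
                arrays.append(log_prob(cells, h))
            return True
        i, j = cats[pos]
        # alleles before row i can no longer be consumed
        if j == i and any(remaining[a] for a in range(i)):
            return True
        if i == j:
            cmax = remaining[i] // 2
        else:
            cmax = min(remaining[i], remaining[j])
        for c in range(cmax, -1, -1):
            if i == j:
                remaining[i] -= 2 * c
            else:
                remaining[i] -= c
                remaining[j] -= c
            cells[(i, j)] = c
            ok = enumerate_arrays(pos + 1, remaining, cells, h + (c if i != j else 0))
            del cells[(i, j)]
            if i == j:
                remaining[i] += 2 * c
            else:
                remaining[i] += c
                remaining[j] += c
            if not ok:
                return False
        return True

    if tractable:
        enumerate_arrays(0, list(allele_counts), {}, 0)
    if not overflow:
        p = sum(math.exp(lp) for lp in arrays if lp <= logp_obs + eps)
        return min(1.0, max(0.0, p))

    # Monte-Carlo permutation fallback
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(k), allele_counts)
    lf_arr = np.array(lf)
    v_obs = -sum(lf[c] for c in obs_cells.values()) + h_obs * ln2
    hits = 0
    for _ in range(mc_reps):
        perm = rng.permutation(pool)
        a = np.minimum(perm[0::2], perm[1::2])
        b = np.maximum(perm[0::2], perm[1::2])
        codes = a * k + b
        cell_counts = np.bincount(codes, minlength=k * k)
        h = int(np.count_nonzero(a != b))
        v = -float(lf_arr[cell_counts].sum()) + h * ln2
        if v <= v_obs + eps:
            hits += 1
    return hits / mc_reps


def hwe_table(
    dataset: GenotypeDataset,
    min_n: int = 10,
    alpha: float = 0.05,
    mc_reps: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """HWE exact test per (population, locus) with significance flags.

    Populations with fewer than ``min_n`` typed samples at a locus are
    excluded (p = NaN), as are monomorphic cells.  Flags are raw
    ``p < alpha`` with no multiple-testing correction.  ``mc_reps`` defaults
    lower than :func:`hwe_exact`'s because a screening table tolerates a
    larger Monte-Carlo standard error per cell.
    """
    rows = []
    for pop in dataset.population_labels:
        samples = dataset.samples_in(pop)
        for locus in dataset.loci:
            counts: dict[tuple[int, int], int] = {}
            for s in samples:
                a, b = dataset.call(s, locus)
                if a != 0:
                    key = (min(a, b), max(a, b))
                    counts[key] = counts.get(key, 0) + 1
            n_typed = sum(counts.values())
            alleles = {a for pair in counts for a in pair}
            if n_typed < min_n or len(alleles) < 2:
                rows.append((pop, locus, n_typed, math.nan, False))
                continue
            p = hwe_exact(counts, mc_reps=mc_reps, seed=seed)
            rows.append((pop, locus, n_typed, p, p < alpha))
    return pd.DataFrame(rows, columns=["population", "locus", "n", "p", "deviation"])


# ---------------------------------------------------------------------------
# genetic distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric non-negative labelled distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite & finite.T], v.T[finite & finite.T], atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v[finite] < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def nei_identity(
    freqs_a: Mapping[str, Mapping[int, float]],
    freqs_b: Mapping[str, Mapping[int, float]],
) -> float:
    """Nei's normalized genetic identity I between two populations.

    Per locus, the cross product ``J_ab = sum p_a p_b`` and homozygosities
    ``J_a``, ``J_b`` are computed; the three sums are arithmetically averaged
    over loci and combined as ``I = mean(J_ab) / sqrt(mean(J_a) mean(J_b))``.
    """
    if set(freqs_a) != set(freqs_b):
        raise ValueError("populations typed at different loci")
    jab = ja = jb = 0.0
    loci = list(freqs_a)
    if not loci:
        raise ValueError("no loci")
    for locus in loci:
        pa, pb = freqs_a[locus], freqs_b[locus]
        jab += sum(p * pb.get(allele, 0.0) for allele, p in pa.items())
        ja += sum(p * p for p in pa.values())
        jb += sum(p * p for p in pb.values())
    denom = math.sqrt((ja / len(loci)) * (jb / len(loci)))
    if denom == 0:
        return 0.0
    return (jab / len(loci)) / denom


def nei_distance(
    freqs_a: Mapping[str, Mapping[int, float]],
    freqs_b: Mapping[str, Mapping[int, float]],
) -> float:
    """Nei's standard genetic distance ``D = -ln I``.

    Zero iff the frequency tables are identical at every locus; infinity when
    the populations share no alleles anywhere (I = 0).
    """
    identity = nei_identity(freqs_a, freqs_b)
    if identity <= 0.0:
        return math.inf
    return max(0.0, -math.log(min(1.0, identity)))


def nei_matrix(dataset: GenotypeDataset) -> DistanceMatrix:
    """Pairwise Nei distance matrix between populations."""
    table = allele_freqs(dataset)
    pops = table.populations
    n = len(pops)
    d = np.zeros((n, n))
    per_pop = {}
    for pop in pops:
        per_pop[pop] = {
            loc: table.freqs[(pop, loc)]
            for loc in table.loci
            if table.is_defined(pop, loc)
        }
    for i, j in itertools.combinations(range(n), 2):
        shared = set(per_pop[pops[i]]) & set(per_pop[pops[j]])
        fa = {loc: per_pop[pops[i]][loc] for loc in shared}
        fb = {loc: per_pop[pops[j]][loc] for loc in shared}
        d[i, j] = d[j, i] = nei_distance(fa, fb)
    return DistanceMatrix(list(pops), d)


def _pair_ht_hs(table: AlleleFreqTable, pop_a: str, pop_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus total and mean within-population gene diversity for a pair."""
    ht, hs = [], []
    for locus in table.loci:
        if not (table.is_defined(pop_a, locus) and table.is_defined(pop_b, locus)):
            ht.append(math.nan)
            hs.append(math.nan)
            continue
        pa, pb = table.freqs[(pop_a, locus)], table.freqs[(pop_b, locus)]
        alleles = set(pa) | set(pb)
        mean_p = {al: (pa.get(al, 0.0) + pb.get(al, 0.0)) / 2 for al in alleles}
        ht.append(_he(mean_p.values()))
        hs.append((_he(pa.values()) + _he(pb.values())) / 2)
    return np.array(ht), np.array(hs)


def _gst_from_components(ht: np.ndarray, hs: np.ndarray) -> float:
    """Nei's Gst from per-locus components: ratio of locus averages.

    Loci with undefined frequencies or zero total diversity are skipped.
    """
    keep = np.isfinite(ht) & (ht > 0)
    if not keep.any():
        return 0.0
    mean_ht = float(ht[keep].mean())
    mean_hs = float(hs[keep].mean())
    return min(1.0, max(0.0, (mean_ht - mean_hs) / mean_ht))


def fst_matrix(dataset: GenotypeDataset) -> DistanceMatrix:
    """Pairwise Nei Gst matrix: ``(H_T - H_S) / H_T`` averaged over loci."""
    pops = dataset.population_labels
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    table = allele_freqs(dataset)
    n = len(pops)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ht, hs = _pair_ht_hs(table, pops[i], pops[j])
        d[i, j] = d[j, i] = _gst_from_components(ht, hs)
    return DistanceMatrix(list(pops), d)


def gst_overall(dataset: GenotypeDataset, k_correction: bool = True) -> float:
    """Multi-population Gst over all loci.

    ``H_S`` is the unweighted mean within-population gene diversity, ``H_T``
    the diversity of the mean allele frequencies.  With ``k_correction`` the
    between-population component ``D_ST = H_T - H_S`` is scaled by
    ``K/(K-1)`` (Nei–Chesser), removing the finite-K downward bias so the
    estimate recovers the Balding–Nichols differentiation parameter.
    """
    pops = dataset.population_labels
    k = len(pops)
    if k < 2:
        raise ValueError("need at least two populations")
    table = allele_freqs(dataset)
    num = den = 0.0
    used = 0
    for locus in dataset.loci:
        defined = [p for p in pops if table.is_defined(p, locus)]
        if len(defined) < 2:
            continue
        kk = len(defined)
        freq_list = [table.freqs[(p, locus)] for p in defined]
        alleles = set().union(*freq_list)
        mean_p = {al: sum(f.get(al, 0.0) for f in freq_list) / kk for al in alleles}
        ht = _he(mean_p.values())
        hs = sum(_he(f.values()) for f in freq_list) / kk
        if ht <= 0:
            continue
        dst = ht - hs
        if k_correction:
            dst *= kk / (kk - 1)
        num += dst
        den += hs + dst
        used += 1
    if used == 0 or den == 0:
        return 0.0
    return min(1.0, max(0.0, num / den))


# ---------------------------------------------------------------------------
# principal coordinates analysis
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` has one column per positive eigenvalue (axes ordered by
    decreasing eigenvalue); ``percent_variance`` is the share of each
    positive eigenvalue in the positive-eigenvalue total.  Negative
    eigenvalues (non-Euclidean input) are reported in ``eigenvalues`` but
    excluded from the denominator and carry no coordinates.
    """

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray


def pcoa(distance_matrix: DistanceMatrix, eps: float = 1e-10) -> PcoaResult:
    """Classical metric multidimensional scaling (Gower's PCoA).

    The squared distance matrix is double-centered (``-1/2 J D^2 J``) and
    eigendecomposed; coordinates are eigenvectors scaled by the square root
    of their eigenvalues.
    """
    d = distance_matrix.values
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains infinities")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > eps * scale
    pos_sum = eigvals[positive].sum()
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    percent = (100.0 * eigvals[positive] / pos_sum) if pos_sum > 0 else eigvals[positive]
    return PcoaResult(list(distance_matrix.labels), coords, eigvals, percent)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(distance_matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining on a labelled distance matrix.

    Returns an unrooted binary tree (root trifurcation).  Negative branch
    length estimates are clamped to zero with the deficit moved to the
    sibling branch, preserving the joined pair's path length.
    """
    labels = list(distance_matrix.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = distance_matrix.values.astype(float).copy()
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite entries")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    active = list(range(len(labels)))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for ak in active:
            if ak in (i, j):
                continue
            d[u, ak] = d[ak, u] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def bootstrap_support(
    dataset: GenotypeDataset,
    reps: int = 1000,
    seed: int | None = None,
) -> TreeNode:
    """NJ tree on the Gst matrix with locus-bootstrap support values.

    Loci are resampled with replacement ``reps`` times; for each replicate
    the pairwise Gst matrix and NJ tree are recomputed, and each internal
    branch of the full-data tree receives the percentage of replicates whose
    tree contains the same bipartition.  Seed-reproducible.
    """
    if len(dataset.loci) < 2:
        raise ValueError("bootstrap over loci needs at least 2 loci")
    pops = dataset.population_labels
    if len(pops) < 3:
        raise ValueError("bootstrap support needs at least 3 populations")
    table = allele_freqs(dataset)
    n_loci = len(dataset.loci)
    pairs = list(itertools.combinations(range(len(pops)), 2))
    ht = np.zeros((len(pairs), n_loci))
    hs = np.zeros((len(pairs), n_loci))
    for pi, (i, j) in enumerate(pairs):
        ht[pi], hs[pi] = _pair_ht_hs(table, pops[i], pops[j])

    def matrix_from(sel: np.ndarray) -> DistanceMatrix:
        d = np.zeros((len(pops), len(pops)))
        for pi, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = _gst_from_components(ht[pi, sel], hs[pi, sel])
        return DistanceMatrix(list(pops), d)

    base_tree = nj_tree(matrix_from(np.arange(n_loci)))
    base_parts = base_tree.bipartitions()
    counts = {part: 0 for part in base_parts}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        sel = rng.integers(n_loci, size=n_loci)
        parts = nj_tree(matrix_from(sel)).bipartitions()
        for part in base_parts:
            if part in parts:
                counts[part] += 1

    all_leaves = frozenset(base_tree.leaf_names())

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if node is not base_tree and 1 < len(below) < len(all_leaves) - 1:
            part = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            node.support = round(100.0 * counts[part] / reps)
        return below

    annotate(base_tree)
    return base_tree


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------


@dataclass
class DeltaKResult:
    """Evanno second-difference statistic per interior K."""

    table: pd.DataFrame  # columns: k, n_reps, mean_l, sd_l, delta_k
    optimal_k: int


def evanno_delta_k(
    replicates: Mapping[int, Sequence[float]] | pd.DataFrame,
) -> DeltaKResult:
    """Evanno ΔK from replicate clustering log-likelihoods L(K).

    ``ΔK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))`` for each
    interior K of a consecutive run of K values, each with at least two
    replicates.  A zero standard deviation yields an infinity sentinel with a
    warning.  The K with the largest ΔK is reported as optimal.  ΔK is
    invariant under adding a constant to all L.
    """
    if isinstance(replicates, pd.DataFrame):
        grouped = {int(k): g["L"].to_list() for k, g in replicates.groupby("K")}
    else:
        grouped = {int(k): list(v) for k, v in replicates.items()}
    ks = sorted(grouped)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    for k in ks:
        if len(grouped[k]) < 2:
            raise ValueError(f"K={k}: need at least 2 replicates for a standard deviation")
    means = {k: float(np.mean(grouped[k])) for k in ks}
    sds = {k: float(np.std(grouped[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            delta = math.nan
        else:
            second = abs(means[k + 1] - 2 * means[k] + means[k - 1])
            if sds[k] == 0:
                warnings.warn(f"K={k}: zero variance across replicates; ΔK is infinite")
                delta = math.inf if second > 0 else math.nan
            else:
                delta = second / sds[k]
        rows.append((k, len(grouped[k]), means[k], sds[k], delta))
    table = pd.DataFrame(rows, columns=["k", "n_reps", "mean_l", "sd_l", "delta_k"])
    interior = table.dropna(subset=["delta_k"])
    if interior.empty:
        raise ValueError("no interior K with a defined ΔK")
    optimal = int(interior.loc[interior["delta_k"].idxmax(), "k"])
    return DeltaKResult(table, optimal)
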