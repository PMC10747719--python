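"""Comparative mining of perfect microsatellites from two genome assemblies.

The discovery pipeline scans each assembly for maximal perfect tandem repeats
(motif 1–6 bp), unifies motifs across rotation and strand into a canonical
form, matches loci between the two assemblies by flank identity, removes
redundant loci, and keeps polymorphic candidates that satisfy the marker
screening rules (motif length 3–6 bp, more than six repeats, and a feasible
PCR product of 100–400 bp).

A locus is *polymorphic* when the two assemblies carry different repeat
counts over identical (>= 95% identical) flanks — the two haplotypes then
yield PCR products of different sizes, i.e. at least two alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import SequenceRecord

__all__ = [
    "SsrLocus",
    "LocusMatch",
    "DEFAULT_MIN_REPEATS",
    "canonical_motif",
    "revcomp",
    "find_ssrs",
    "flank_identity",
    "match_loci",
    "dedupe_loci",
    "select_candidates",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Detection-time minimum repeat count per motif length.  Detection is
#: deliberately generous; the stricter screening rule (motif 3–6 bp,
#: repeats >= 7) is applied later by :func:`select_candidates`.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 7, 3: 5, 4: 5, 5: 5, 6: 5}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Canonical representative of a repeat motif.

    The canonical form is the lexicographic minimum over all rotations of the
    motif and all rotations of its reverse complement, so that e.g. (GAT)n,
    (ATG)n and (ATC)n — the same repeat read in different frames or on the
    opposite strand — share one name.  Idempotent by construction.
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside 1–6")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} has non-ACGT characters")
    variants = _rotations(motif) + _rotations(revcomp(motif))
    return min(variants)


def _rotations(s: str) -> list[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


def _is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter one."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class SsrLocus:
    """A maximal perfect tandem repeat with its flanking sequence.

    ``start``/``end`` are 0-based half-open coordinates on ``seq_id``;
    ``end - start == len(motif_raw) * repeats``.  ``motif`` is canonical,
    ``motif_raw`` is the motif as read on the forward strand.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    repeats: int
    flank_left: str = ""
    flank_right: str = ""
    motif_raw: str = ""

    def __post_init__(self) -> None:
        period = len(self.motif_raw or self.motif)
        if self.end - self.start != period * self.repeats:
            raise ValueError(
                f"locus {self.seq_id}:{self.start}-{self.end}: span "
                f"{self.end - self.start} != motif length {period} × "
                f"repeats {self.repeats}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


def find_ssrs(
    record: SequenceRecord,
    min_motif: int = 1,
    max_motif: int = 6,
    min_repeats_by_motif_len: Mapping[int, int] | None = None,
    flank_len: int = 100,
) -> list[SsrLocus]:
    """Report all maximal perfect SSR runs in ``record``.

    A run of period ``p`` starting at ``a`` with ``r`` repeats covers
    ``[a, a + r*p)``; runs are maximal (extending either end breaks
    perfection) and only primitive motifs are reported, so a poly-AT tract
    appears once with motif "AT", never as the 4-mer "ATAT".  When maximal
    runs of different periods overlap, the longer run wins (ties broken by
    start, then shorter period), so no two reported loci overlap.  Flanks of
    up to ``flank_len`` bp are attached, clipped at the sequence ends.
    """
    thresholds = dict(DEFAULT_MIN_REPEATS)
    if min_repeats_by_motif_len:
        thresholds.update(min_repeats_by_motif_len)
    if any(v < 2 for v in thresholds.values()):
        raise ValueError("minimum repeat thresholds must be >= 2")
    s = record.residues
    n = len(s)
    candidates: list[tuple[int, int, int, str]] = []  # (start, end, period, motif)
    for p in range(min_motif, max_motif + 1):
        min_reps = thresholds.get(p)
        if min_reps is None:
            continue
        k = 0
        limit = n - p
        while k < limit:
            if s[k] != s[k + p]:
                k += 1
                continue
            a = k
            while k < limit and s[k] == s[k + p]:
                k += 1
            # match run [a, k) -> repeat region [a, k + p)
            region_len = k + p - a
            r = region_len // p
            if r >= min_reps:
                motif = s[a : a + p]
                if "N" not in motif and _is_primitive(motif):
                    candidates.append((a, a + r * p, p, motif))
    kept: list[tuple[int, int, int, str]] = []
    for cand in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[2])):
        a, b, _, _ = cand
        if all(b <= ka or a >= kb for ka, kb, _, _ in kept):
            kept.append(cand)
    loci = [
        SsrLocus(
            seq_id=record.id,
            start=a,
            end=b,
            motif=canonical_motif(motif),
            repeats=(b - a) // p,
            flank_left=s[max(0, a - flank_len) : a],
            flank_right=s[b : b + flank_len],
            motif_raw=motif,
        )
        for a, b, p, motif in sorted(kept)
    ]
    return loci


# ---------------------------------------------------------------------------
# cross-assembly matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusMatch:
    """A locus paired across the two assemblies by flank identity."""

    locus_a: SsrLocus
    locus_b: SsrLocus
    flank_identity: float
    polymorphic: bool

    def __post_init__(self) -> None:
        if self.locus_a.motif != self.locus_b.motif:
            raise ValueError("matched loci must share a canonical motif")


def flank_identity(locus_a: SsrLocus, locus_b: SsrLocus, flank_len: int = 50) -> float:
    """Mean of left/right flank identities under ungapped end-anchored comparison.

    Left flanks are anchored at the repeat (compared right-aligned), right
    flanks left-aligned; identity per side = matches / aligned length, where
    the aligned length is the shorter of the two flanks (clipped at contig
    ends), capped at ``flank_len``.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    la = locus_a.flank_left[-flank_len:]
    lb = locus_b.flank_left[-flank_len:]
    ra = locus_a.flank_right[:flank_len]
    rb = locus_b.flank_right[:flank_len]
    sides = []
    for x, y, right_anchor in ((la, lb, True), (ra, rb, False)):
        m = min(len(x), len(y))
        if m == 0:
            sides.append(0.0)
            continue
        if right_anchor:
            x, y = x[-m:], y[-m:]
        else:
            x, y = x[:m], y[:m]
        sides.append(sum(a == b for a, b in zip(x, y)) / m)
    return (sides[0] + sides[1]) / 2


def match_loci(
    loci_a: Sequence[SsrLocus],
    loci_b: Sequence[SsrLocus],
    flank_len: int = 50,
    min_identity: float = 0.95,
) -> list[LocusMatch]:
    """Greedy 1:1 matching of loci between two assemblies.

    Candidate pairs must share a canonical motif; their mean flank identity
    must reach ``min_identity``.  Pairs are committed best-identity-first
    (ties by coordinate order) and each locus is used at most once.  A match
    is polymorphic iff the repeat counts differ.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    scored: list[tuple[float, int, int]] = []
    for i, a in enumerate(loci_a):
        for j, b in enumerate(loci_b):
            if a.motif != b.motif:
                continue
            ident = flank_identity(a, b, flank_len)
            if ident >= min_identity:
                scored.append((ident, i, j))
    scored.sort(key=lambda t: (-t[0], loci_a[t[1]].seq_id, loci_a[t[1]].start,
                               loci_b[t[2]].seq_id, loci_b[t[2]].start))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[LocusMatch] = []
    for ident, i, j in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = loci_a[i], loci_b[j]
        matches.append(LocusMatch(a, b, ident, polymorphic=a.repeats != b.repeats))
    matches.sort(key=lambda m: (m.locus_a.seq_id, m.locus_a.start))
    return matches


def _concat_identity(a: SsrLocus, b: SsrLocus) -> float:
    """Identity of concatenated flanks, end-anchored at the repeat."""
    sides = []
    for x, y, right_anchor in (
        (a.flank_left, b.flank_left, True),
        (a.flank_right, b.flank_right, False),
    ):
        m = min(len(x), len(y))
        if m == 0:
            continue
        if right_anchor:
            x, y = x[-m:], y[-m:]
        else:
            x, y = x[:m], y[:m]
        sides.append((sum(p == q for p, q in zip(x, y)), m))
    if not sides:
        return 0.0
    return sum(hit for hit, _ in sides) / sum(m for _, m in sides)


def dedupe_loci(matches: Sequence[LocusMatch], min_identity: float = 0.95) -> list[LocusMatch]:
    """Collapse redundant matched loci (near-identical flanks).

    Matches whose assembly-A flanks are pairwise >= ``min_identity`` identical
    form a redundancy cluster (single linkage); from each cluster only the
    locus with the longest repeat run survives, ties broken by
    (seq_id, start).  Output is sorted by (seq_id, start).
    """
    n = len(matches)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = matches[i].locus_a, matches[j].locus_a
            if a.motif == b.motif and _concat_identity(a, b) >= min_identity:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    survivors: list[LocusMatch] = []
    for members in clusters.values():
        best = min(
            members,
            key=lambda i: (
                -max(matches[i].locus_a.repeats, matches[i].locus_b.repeats),
                matches[i].locus_a.seq_id,
                matches[i].locus_a.start,
            ),
        )
        survivors.append(matches[best])
    survivors.sort(key=lambda m: (m.locus_a.seq_id, m.locus_a.start))
    return survivors


def select_candidates(
    matches: Iterable[LocusMatch],
    motif_len_range: tuple[int, int] = (3, 6),
    min_repeats: int = 7,
    product_range: tuple[int, int] = (100, 400),
    min_primer_len: int = 18,
) -> list[LocusMatch]:
    """Apply the marker screening rules to polymorphic matches.

    Keeps matches whose motif length lies in ``motif_len_range``, whose repeat
    count reaches ``min_repeats`` in at least one assembly (the "more than six
    repeats" rule), and whose repeat-plus-flank window admits a PCR product
    within ``product_range``: the smallest achievable product places both
    primers against the repeat (span + 2 × ``min_primer_len``), the largest
    uses the full window.
    """
    lo, hi = motif_len_range
    pmin, pmax = product_range
    kept: list[LocusMatch] = []
    for m in matches:
        if not m.polymorphic:
            continue
        if not lo <= len(m.locus_a.motif) <= hi:
            continue
        if max(m.locus_a.repeats, m.locus_b.repeats) < min_repeats:
            continue
        a = m.locus_a
        window = len(a.flank_left) + a.span + len(a.flank_right)
        smallest = a.span + 2 * min_primer_len
        if max(pmin, smallest) > min(pmax, window):
            continue
        kept.append(m)
    return kept
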