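"""Primer scoring and flank-anchored primer design for SSR candidate loci.

Melting temperatures use the classic GC-fraction formula
``Tm = 64.9 + 41 * (G+C - 16.4) / N`` — deterministic, hand-checkable, and
adequate here because the design window (52–62 °C) absorbs its bias relative
to nearest-neighbor thermodynamics.

Primer–primer complementarity is scored as the longest contiguous run of
Watson–Crick pairs over all ungapped antiparallel alignments of the two
oligos — the classic primer-dimer criterion.  A score at or above the design
threshold (default 7) marks a pair as dimer-prone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .ssr_mining import LocusMatch, revcomp

__all__ = [
    "PrimerPair",
    "melting_temperature",
    "complementarity_score",
    "design_primers",
]

logger = logging.getLogger(__name__)

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair for one locus.

    Both primers are stored 5'→3': the reverse primer anneals to the plus
    strand downstream of the repeat, i.e. it is the reverse complement of a
    window of the right flank.  ``product_len`` is the amplicon size on the
    reference haplotype.
    """

    fwd: str
    rev: str
    tm_f: float
    tm_r: float
    product_len: int

    def __post_init__(self) -> None:
        for label, p in (("forward", self.fwd), ("reverse", self.rev)):
            if not 18 <= len(p) <= 27:
                raise ValueError(f"{label} primer length {len(p)} outside 18–27")


def melting_temperature(primer: str) -> float:
    """GC-fraction melting temperature in °C, rounded to 0.01.

    ``Tm = 64.9 + 41 * (G + C - 16.4) / N`` for an oligo of length N.
    """
    primer = primer.upper()
    if len(primer) < 10:
        raise ValueError("primer shorter than 10 nt")
    if set(primer) - set("ACGT"):
        raise ValueError(f"primer contains non-ACGT characters: {primer!r}")
    gc = primer.count("G") + primer.count("C")
    return round(64.9 + 41.0 * (gc - 16.4) / len(primer), 2)


def complementarity_score(p1: str, p2: str) -> int:
    """Longest contiguous Watson–Crick duplex between two oligos.

    The two sequences are slid against each other antiparallel (5'→3' against
    3'→5') without gaps; the score is the maximum, over all offsets, of the
    longest run of consecutive complementary aligned bases.  Symmetric in its
    arguments and bounded by ``min(len(p1), len(p2))``.
    """
    p1, p2 = p1.upper(), p2.upper()
    if not p1 or not p2:
        raise ValueError("empty primer")
    q = p2[::-1]  # antiparallel orientation
    n, m = len(p1), len(q)
    best = 0
    for off in range(-(m - 1), n):
        run = 0
        lo = max(0, off)
        hi = min(n, off + m)
        for i in range(lo, hi):
            if (p1[i], q[i - off]) in _PAIRS:
                run += 1
                if run > best:
                    best = run
            else:
                run = 0
    return best


def design_primers(
    match: LocusMatch,
    product_range: tuple[int, int] = (100, 400),
    length_range: tuple[int, int] = (18, 27),
    gc_range: tuple[float, float] = (0.40, 0.60),
    tm_range: tuple[float, float] = (52.0, 62.0),
    max_tm_diff: float = 3.0,
    complementarity_threshold: int = 7,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Design primer pairs for a matched SSR locus by exhaustive flank scan.

    Every window of the left flank is considered as a forward primer and
    every reverse-complemented window of the right flank as a reverse primer.
    A pair is accepted when both primers satisfy the length, GC and Tm
    bounds, their Tm difference is at most ``max_tm_diff``, self- and
    cross-complementarity stay below ``complementarity_threshold``, and the
    product size lies in ``product_range``.  Results are ranked by closeness
    of the mean Tm to 57 °C, then by product-size centrality; at most
    ``max_pairs`` are returned.  An empty result logs a reason code.
    """
    locus = match.locus_a
    left, right = locus.flank_left, locus.flank_right
    span = locus.span
    lmin, lmax = length_range
    pmin, pmax = product_range

    def windows(flank: str, is_left: bool):
        out = []
        for length in range(lmin, lmax + 1):
            for start in range(0, len(flank) - length + 1):
                seq = flank[start : start + length]
                # distance from primer's outer end to the repeat boundary
                dist = len(flank) - start if is_left else start + length
                out.append((seq, dist))
        return out

    def acceptable(seq: str) -> float | None:
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        if not gc_range[0] <= gc <= gc_range[1]:
            return None
        tm = melting_temperature(seq)
        if not tm_range[0] <= tm <= tm_range[1]:
            return None
        if complementarity_score(seq, seq) >= complementarity_threshold:
            return None
        return tm

    fwd_cands = []
    for seq, dist in windows(left, True):
        tm = acceptable(seq)
        if tm is not None:
            fwd_cands.append((seq, dist, tm))
    rev_cands = []
    for seq, dist in windows(right, False):
        primer = revcomp(seq)
        tm = acceptable(primer)
        if tm is not None:
            rev_cands.append((primer, dist, tm))

    if not fwd_cands or not rev_cands:
        logger.info(
            "design_primers(%s:%d-%d): no_single_primer (fwd=%d rev=%d)",
            locus.seq_id, locus.start, locus.end, len(fwd_cands), len(rev_cands),
        )
        return []

    center = (pmin + pmax) / 2
    pairs: list[tuple[tuple[float, float], PrimerPair]] = []
    for fseq, fdist, ftm in fwd_cands:
        for rseq, rdist, rtm in rev_cands:
            if abs(ftm - rtm) > max_tm_diff:
                continue
            product = fdist + span + rdist
            if not pmin <= product <= pmax:
                continue
            if complementarity_score(fseq, rseq) >= complementarity_threshold:
                continue
            key = (abs((ftm + rtm) / 2 - 57.0), abs(product - center))
            pairs.append((key, PrimerPair(fseq, rseq, ftm, rtm, product)))
    if not pairs:
        logger.info(
            "design_primers(%s:%d-%d): no_compatible_pair",
            locus.seq_id, locus.start, locus.end,
        )
        return []
    pairs.sort(key=lambda t: (t[0], t[1].fwd, t[1].rev))
    return [p for _, p in pairs[:max_pairs]]
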