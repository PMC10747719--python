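"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or definition,
deliberately sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# motif canonicalization
# ---------------------------------------------------------------------------


def canonical_motif_by_enumeration(motif: str) -> str:
    rc = "".join(COMP[c] for c in reversed(motif))
    variants = []
    for s in (motif, rc):
        for i in range(len(s)):
            variants.append(s[i:] + s[:i])
    return min(variants)


# ---------------------------------------------------------------------------
# SSR scanning
# ---------------------------------------------------------------------------


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def brute_force_ssrs(seq: str, thresholds: dict[int, int]) -> list[tuple[int, int, str]]:
    """All maximal perfect repeat runs by per-start extension, then the same
    longest-first non-overlap resolution the scanner defines.

    Returns (start, end, forward-strand motif) triples.
    """
    n = len(seq)
    cands = []
    for p, min_reps in thresholds.items():
        for a in range(n - p):
            motif = seq[a : a + p]
            if "N" in motif or not _primitive(motif):
                continue
            # left-maximality: the period-p match run must not extend to a-1
            if a > 0 and a - 1 + p < n and seq[a - 1] == seq[a - 1 + p]:
                continue
            r = 0
            while seq[a + r * p : a + (r + 1) * p] == motif:
                r += 1
            if r >= min_reps:
                cands.append((a, a + r * p, motif))
    kept: list[tuple[int, int, str]] = []
    for cand in sorted(cands, key=lambda c: (-(c[1] - c[0]), c[0], len(c[2]))):
        a, b, _ = cand
        if all(b <= ka or a >= kb for ka, kb, _ in kept):
            kept.append(cand)
    return sorted(kept)


# ---------------------------------------------------------------------------
# primer complementarity
# ---------------------------------------------------------------------------


def longest_duplex_by_alignment(p1: str, p2: str) -> int:
    """Longest contiguous complementary run, built from explicit alignments."""
    best = 0
    q = p2[::-1]
    for off in range(-(len(q) - 1), len(p1)):
        pairs = []
        for i, c in enumerate(p1):
            j = i - off
            if 0 <= j < len(q):
                pairs.append(COMP[c] == q[j])
        run = 0
        for hit in pairs:
            run = run + 1 if hit else 0
            best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# multiplex packing
# ---------------------------------------------------------------------------


def _block_feasible(block, cons, gap, incompat, tas, ndyes) -> bool:
    if len(block) > cons.max_loci_per_reaction:
        return False
    if any(incompat[i][j] for i, j in itertools.combinations(block, 2)):
        return False
    if len(block) >= 2 and max(tas[i] for i in block) - min(tas[i] for i in block) > cons.max_ta_spread:
        return False

    def color(pos: int, dyes: dict[int, int]) -> bool:
        if pos == len(block):
            return True
        i = block[pos]
        for d in range(ndyes):
            if all(gap[i][j] >= cons.min_same_dye_gap
                   for j in block[:pos] if dyes[j] == d):
                dyes[i] = d
                if color(pos + 1, dyes):
                    return True
                del dyes[i]
        return False

    return color(0, {})


def brute_force_min_reactions(loci, cons) -> int:
    """Minimum reaction count by set-partition enumeration (n <= ~9)."""
    from msatforge.multiplex_design import size_gap, dimer_score

    n = len(loci)
    gap = [[size_gap(a, b) for b in loci] for a in loci]
    incompat = [[dimer_score(a, b) >= cons.complementarity_threshold if a is not b else False
                 for b in loci] for a in loci]
    tas = [l.ta for l in loci]
    ndyes = len(cons.dyes)
    best = [n]

    def rec(i: int, blocks: list[list[int]]) -> None:
        if len(blocks) >= best[0]:
            return
        if i == n:
            best[0] = len(blocks)
            return
        for block in blocks:
            block.append(i)
            if _block_feasible(block, cons, gap, incompat, tas, ndyes):
                rec(i + 1, blocks)
            block.pop()
        blocks.append([i])
        rec(i + 1, blocks)
        blocks.pop()

    rec(0, [])
    return best[0]


# ---------------------------------------------------------------------------
# set cover
# ---------------------------------------------------------------------------


def brute_force_min_cover(sample_sets: dict[str, set], universe: set) -> int:
    """Smallest number of samples whose sets cover the universe."""
    names = list(sample_sets)
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            if set().union(*(sample_sets[s] for s in combo)) >= universe:
                return size
    raise ValueError("universe not coverable")


# ---------------------------------------------------------------------------
# random additive trees
# ---------------------------------------------------------------------------


def random_tree_distances(rng, labels):
    """Random unrooted binary tree over ``labels``: returns (dist, bipartitions).

    ``dist[a][b]`` is the path length; bipartitions are min-side frozensets of
    the internal edges.
    """
    class N:
        def __init__(self, name=None):
            self.name = name
            self.children = []
            self.length = 0.0

    nodes = [N(l) for l in labels]
    while len(nodes) > 2:
        idx = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[idx[0]], nodes[idx[1]]
        parent = N()
        a.length = 0.1 + float(rng.random()) * 1.9
        b.length = 0.1 + float(rng.random()) * 1.9
        parent.children = [a, b]
        nodes = [nodes[k] for k in range(len(nodes)) if k not in idx] + [parent]
    root = N()
    if len(nodes) == 2:
        for child in nodes:
            child.length = 0.1 + float(rng.random()) * 1.9
            root.children.append(child)
    else:
        root = nodes[0]

    dist = {a: {} for a in labels}
    below: dict[int, frozenset] = {}

    def collect(node) -> dict[str, float]:
        if not node.children:
            below[id(node)] = frozenset([node.name])
            return {node.name: 0.0}
        sub = [collect(c) for c in node.children]
        for s, c in zip(sub, node.children):
            for k in s:
                s[k] += c.length
        for x, y in itertools.combinations(range(len(sub)), 2):
            for la, da in sub[x].items():
                for lb, db in sub[y].items():
                    dist[la][lb] = dist[lb][la] = da + db
        merged = {}
        for s in sub:
            merged.update(s)
        below[id(node)] = frozenset(merged)
        return merged

    collect(root)
    all_set = frozenset(labels)
    parts = set()

    def walk(node, is_root=True):
        for c in node.children:
            walk(c, False)
        if not is_root and node.children:
            side = below[id(node)]
            if 1 < len(side) < len(all_set) - 1:
                parts.add(min(side, all_set - side, key=lambda s: (len(s), sorted(s))))

    walk(root)
    for a in labels:
        dist[a][a] = 0.0
    return dist, parts
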