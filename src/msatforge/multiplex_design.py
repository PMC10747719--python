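"""Multiplex PCR panel design as constrained bin packing.

Loci are assigned to reactions and fluorescent dye channels so that, within a
reaction, (i) at most ``max_loci_per_reaction`` loci coexist, (ii) loci
sharing a dye keep an edge-to-edge gap of at least ``min_same_dye_gap`` bp
between their allele size ranges (so allele bins never collide on one
channel), (iii) no cross-locus primer pair reaches the dimer
``complementarity_threshold``, and (iv) annealing temperatures span at most
``max_ta_spread`` °C.  The optimizer minimizes the number of reactions.

The search is first-fit-decreasing greedy seeding followed by simulated
annealing (relocate / swap moves, geometric cooling) that repeatedly tries to
pack the loci into one reaction fewer; all randomness is driven by a single
seed, so results are reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import PanelLocus, VALID_DYES
from .primer_tools import complementarity_score

__all__ = [
    "DesignConstraints",
    "Violation",
    "PanelAssignment",
    "InfeasibleLocusError",
    "size_gap",
    "dimer_score",
    "validate_reaction",
    "validate_panel",
    "optimize_panel",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Parameter set governing multiplex packing."""

    max_loci_per_reaction: int = 10
    min_same_dye_gap: int = 40
    complementarity_threshold: int = 7
    dyes: tuple[str, ...] = VALID_DYES
    max_ta_spread: float = 8.0

    def __post_init__(self) -> None:
        if self.max_loci_per_reaction < 1:
            raise ValueError("max_loci_per_reaction must be >= 1")
        if self.min_same_dye_gap < 0 or self.complementarity_threshold < 1:
            raise ValueError("constraint parameters must be positive")
        if self.max_ta_spread <= 0:
            raise ValueError("max_ta_spread must be positive")
        if not self.dyes:
            raise ValueError("dye set must be non-empty")


@dataclass(frozen=True)
class Violation:
    """One violated packing rule inside a reaction.

    ``kind`` is one of ``size`` (same-dye gap below minimum), ``count`` (too
    many loci), ``dimer`` (cross-locus primer complementarity at or above the
    threshold) or ``ta`` (annealing-temperature spread too wide).
    """

    kind: str
    loci: tuple[str, ...]
    detail: str


class InfeasibleLocusError(ValueError):
    """A locus cannot be placed in any reaction under the given constraints."""


def size_gap(locus_a: PanelLocus, locus_b: PanelLocus) -> int:
    """Edge-to-edge distance between two allele size ranges in bp.

    ``gap = max(size_min) - min(size_max)``; negative values mean the ranges
    overlap.
    """
    return max(locus_a.size_min, locus_b.size_min) - min(locus_a.size_max, locus_b.size_max)


def dimer_score(locus_a: PanelLocus, locus_b: PanelLocus) -> int:
    """Worst complementarity over the four cross-locus primer combinations."""
    return max(
        complementarity_score(p, q)
        for p in (locus_a.fwd, locus_a.rev)
        for q in (locus_b.fwd, locus_b.rev)
    )


def validate_reaction(
    loci: Sequence[PanelLocus],
    constraints: DesignConstraints = DesignConstraints(),
    dimer_scores: Mapping[frozenset[str], int] | None = None,
) -> list[Violation]:
    """Check one reaction's loci (each carrying a dye) against the constraints.

    Returns one :class:`Violation` per broken rule; an empty list means the
    reaction is valid.  ``dimer_scores`` may supply precomputed cross-locus
    complementarity scores keyed by name pairs.
    """
    violations: list[Violation] = []
    if len(loci) > constraints.max_loci_per_reaction:
        violations.append(Violation(
            "count", tuple(l.name for l in loci),
            f"{len(loci)} loci exceed the maximum of {constraints.max_loci_per_reaction}",
        ))
    for a, b in itertools.combinations(loci, 2):
        if a.dye == b.dye:
            gap = size_gap(a, b)
            if gap < constraints.min_same_dye_gap:
                violations.append(Violation(
                    "size", (a.name, b.name),
                    f"same-dye ({a.dye}) gap {gap} < {constraints.min_same_dye_gap}",
                ))
        if dimer_scores is not None:
            score = dimer_scores[frozenset((a.name, b.name))]
        else:
            score = dimer_score(a, b)
        if score >= constraints.complementarity_threshold:
            violations.append(Violation(
                "dimer", (a.name, b.name),
                f"cross-primer complementarity {score} >= "
                f"{constraints.complementarity_threshold}",
            ))
    if len(loci) >= 2:
        tas = [l.ta for l in loci]
        spread = max(tas) - min(tas)
        if spread > constraints.max_ta_spread:
            violations.append(Violation(
                "ta", tuple(l.name for l in loci),
                f"annealing spread {spread:g} > {constraints.max_ta_spread:g}",
            ))
    return violations


def validate_panel(
    loci: Sequence[PanelLocus],
    constraints: DesignConstraints = DesignConstraints(),
) -> dict[str, list[Violation]]:
    """Validate every reaction of an assigned panel; keys are reaction labels."""
    out: dict[str, list[Violation]] = {}
    for reaction in sorted({l.reaction for l in loci}):
        members = [l for l in loci if l.reaction == reaction]
        out[reaction] = validate_reaction(members, constraints)
    return out


@dataclass
class PanelAssignment:
    """Result of panel optimization: locus → (reaction label, dye)."""

    assignment: dict[str, tuple[str, str]]
    n_reactions: int

    def apply(self, loci: Iterable[PanelLocus]) -> list[PanelLocus]:
        """Return copies of ``loci`` with reaction and dye filled in."""
        out = []
        for locus in loci:
            reaction, dye = self.assignment[locus.name]
            out.append(replace(locus, reaction=reaction, dye=dye))
        return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


def _reaction_energy(members, dyes, gap, incompat, tas, cons) -> int:
    """Violation load of one reaction (0 iff valid)."""
    e = 3 * max(0, len(members) - cons.max_loci_per_reaction)
    for x in range(len(members)):
        i = members[x]
        for y in range(x + 1, len(members)):
            j = members[y]
            if incompat[i, j]:
                e += 1
            if dyes[i] == dyes[j] and gap[i, j] < cons.min_same_dye_gap:
                e += 1
    if len(members) >= 2:
        sub = [tas[i] for i in members]
        if max(sub) - min(sub) > cons.max_ta_spread:
            e += 2
    return e


def _total_energy(rxn, dye, n_rxn, gap, incompat, tas, cons) -> int:
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(rxn):
        groups.setdefault(r, []).append(i)
    return sum(_reaction_energy(m, dye, gap, incompat, tas, cons)
               for m in groups.values())


def optimize_panel(
    loci: Sequence[PanelLocus],
    constraints: DesignConstraints = DesignConstraints(),
    seed: int = 0,
    primer_pairs: Mapping[str, tuple[str, str]] | None = None,
    restarts: int = 100,
) -> PanelAssignment:
    """Pack ``loci`` into as few reactions as possible under ``constraints``.

    Dyes and reactions are (re)assigned freely.  ``primer_pairs`` may override
    the primer sequences used for dimer checks (name → (fwd, rev)).  The
    search is deterministic given the input order and ``seed``: a first-fit-
    decreasing greedy seed is refined by simulated annealing that repeatedly
    attempts a packing with one reaction fewer, with at most ``restarts``
    annealing restarts per level (geometric cooling, factor 0.95).

    The returned assignment has zero violations and never uses more reactions
    than the greedy seed.
    """
    loci = list(loci)
    n = len(loci)
    if n == 0:
        return PanelAssignment({}, 0)
    names = [l.name for l in loci]
    if len(set(names)) != n:
        raise ValueError("duplicate locus names")

    def primers(l: PanelLocus) -> tuple[str, str]:
        if primer_pairs and l.name in primer_pairs:
            return primer_pairs[l.name]
        return l.fwd, l.rev

    gap = np.zeros((n, n), dtype=np.int64)
    incompat = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        gap[i, j] = gap[j, i] = size_gap(loci[i], loci[j])
        pi, pj = primers(loci[i]), primers(loci[j])
        score = max(complementarity_score(p, q) for p in pi for q in pj)
        incompat[i, j] = incompat[j, i] = score >= constraints.complementarity_threshold
    tas = [l.ta for l in loci]
    ndyes = len(constraints.dyes)

    # a singleton reaction can never violate the pairwise rules; guard the
    # degenerate constraint sets anyway
    for i, l in enumerate(loci):
        if _reaction_energy([i], [0] * n, gap, incompat, tas, constraints):
            raise InfeasibleLocusError(
                f"locus {l.name!r} violates the constraints on its own"
            )

    # --- greedy first-fit-decreasing seed (always feasible) ---------------
    order = sorted(range(n), key=lambda i: (-(loci[i].size_max - loci[i].size_min),
                                            names[i]))
    rxn = [-1] * n
    dye = [0] * n
    n_rxn = 0
    for i in order:
        placed = False
        for r in range(n_rxn):
            members = [k for k in range(n) if rxn[k] == r]
            if len(members) >= constraints.max_loci_per_reaction:
                continue
            if any(incompat[i, k] for k in members):
                continue
            span = [tas[k] for k in members] + [tas[i]]
            if max(span) - min(span) > constraints.max_ta_spread:
                continue
            for d in range(ndyes):
                if all(gap[i, k] >= constraints.min_same_dye_gap
                       for k in members if dye[k] == d):
                    rxn[i], dye[i] = r, d
                    placed = True
                    break
            if placed:
                break
        if not placed:
            rxn[i], dye[i] = n_rxn, 0
            n_rxn += 1

    best_rxn, best_dye, best_n = list(rxn), list(dye), n_rxn

    # --- anneal downwards --------------------------------------------------
    rng = np.random.default_rng(seed)
    lower = math.ceil(n / constraints.max_loci_per_reaction)
    target = best_n - 1
    while target >= lower:
        sol = _anneal_fixed(target, n, ndyes, gap, incompat, tas, constraints,
                            rng, restarts, warm=(best_rxn, best_dye))
        if sol is None:
            break
        best_rxn, best_dye = sol
        best_n = target
        target -= 1

    used = sorted(set(best_rxn))
    label = {r: f"M{k + 1}" for k, r in enumerate(used)}
    assignment = {
        names[i]: (label[best_rxn[i]], constraints.dyes[best_dye[i]])
        for i in range(n)
    }
    result = PanelAssignment(assignment, len(used))
    # contract: the returned panel is violation-free
    check = validate_panel(result.apply(loci), constraints)
    assert all(not v for v in check.values()), "optimizer returned invalid panel"
    return result


def _anneal_fixed(n_rxn, n, ndyes, gap, incompat, tas, cons, rng, restarts, warm):
    """Search a zero-violation assignment using exactly ``n_rxn`` reactions.

    Simulated annealing over (reaction, dye) assignments; the energy is the
    total violation load, so the accepted best is monotone non-increasing
    within a restart.  Returns (rxn, dye) lists or None.
    """
    warm_rxn, warm_dye = warm
    for attempt in range(restarts):
        if attempt == 0:
            # compress the warm start: fold the emptied reactions into the rest
            rxn = [r if r < n_rxn else int(rng.integers(n_rxn)) for r in warm_rxn]
            dye = list(warm_dye)
        else:
            rxn = [int(r) for r in rng.integers(n_rxn, size=n)]
            dye = [int(d) for d in rng.integers(ndyes, size=n)]
        energy = _total_energy(rxn, dye, n_rxn, gap, incompat, tas, cons)
        if energy == 0:
            return rxn, dye
        temp = 3.0
        while temp > 0.02 and energy > 0:
            for _ in range(6 * n):
                i = int(rng.integers(n))
                if rng.random() < 0.5 and n >= 2:
                    j = int(rng.integers(n))
                    if i == j:
                        continue
                    new_rxn, new_dye = list(rxn), list(dye)
                    new_rxn[i], new_rxn[j] = rxn[j], rxn[i]
                    new_dye[i], new_dye[j] = dye[j], dye[i]
                    touched = {rxn[i], rxn[j]}
                else:
                    new_rxn, new_dye = list(rxn), list(dye)
                    new_rxn[i] = int(rng.integers(n_rxn))
                    new_dye[i] = int(rng.integers(ndyes))
                    touched = {rxn[i], new_rxn[i]}
                delta = 0
                for r in touched:
                    old_members = [k for k in range(n) if rxn[k] == r]
                    new_members = [k for k in range(n) if new_rxn[k] == r]
                    delta -= _reaction_energy(old_members, dye, gap, incompat, tas, cons)
                    delta += _reaction_energy(new_members, new_dye, gap, incompat, tas, cons)
                if delta <= 0 or rng.random() < math.exp(-delta / temp):
                    rxn, dye = new_rxn, new_dye
                    energy += delta
                    if energy == 0:
                        return rxn, dye
            temp *= 0.95
    return None
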