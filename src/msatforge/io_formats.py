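"""Readers and writers for the formats the toolkit exchanges.

Formats
-------
* FASTA genome assemblies (via Biopython ``SeqIO``), uppercased on input.
* Diploid genotype tables in a GenAlEx-style codominant CSV sheet
  (row 1: counts, row 2: titles, row 3: sample/pop headers plus locus names
  spanning paired columns).  The missing-data code is ``0``; allele codes are
  raw fragment sizes in base pairs.
* Multiplex panel definitions as TSV (one row per locus with primers, motif,
  size range, annealing temperature, dye, reaction and source).
* Fragment-size call tables (capillary-analyzer CSV export: sample, locus,
  size1, size2).
* Newick trees with branch lengths and optional integer bootstrap support.

Coordinates are 0-based half-open inside the package and 1-based inclusive in
every written file.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GenotypeDataset",
    "PanelLocus",
    "FragmentCall",
    "TreeNode",
    "read_fasta",
    "write_fasta",
    "read_genotype_table",
    "write_genotype_table",
    "read_panel",
    "write_panel",
    "read_fragment_calls",
    "write_fragment_calls",
    "write_newick",
    "read_newick",
    "VALID_DYES",
]

VALID_DYES = ("FAM", "HEX", "TAMRA")

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sequence records / FASTA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _DNA_N
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated and lowercase residues uppercased.
    Empty files, duplicate ids and non-{A,C,G,T,N} residues raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in parsed:
        residues = str(rec.seq).upper()
        if rec.id in seen:
            line = _locate_header_line(path, rec.id, occurrence=2)
            raise FormatError(f"{path}:{line}: duplicate sequence id {rec.id!r}")
        seen[rec.id] = 1
        bad = set(residues) - _DNA_N
        if bad:
            line = _locate_bad_residue_line(path, rec.id, bad)
            raise FormatError(
                f"{path}:{line}: sequence {rec.id!r} contains invalid "
                f"characters {sorted(bad)}"
            )
        if not residues:
            line = _locate_header_line(path, rec.id)
            raise FormatError(f"{path}:{line}: sequence {rec.id!r} is empty")
        records.append(SequenceRecord(rec.id, residues))
    return records


def _locate_header_line(path: Path, seq_id: str, occurrence: int = 1) -> int:
    hits = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[:1] == [seq_id]:
                hits += 1
                if hits == occurrence:
                    return lineno
    return 0


def _locate_bad_residue_line(path: Path, seq_id: str, bad: set[str]) -> int:
    in_target = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_target = line[1:].split()[:1] == [seq_id]
            elif in_target and (set(line.strip().upper()) & bad):
                return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# diploid genotype datasets / GenAlEx-style CSV
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """Diploid fragment-size genotypes for samples grouped in populations.

    ``calls[(sample, locus)]`` is an unordered pair of integer allele codes
    (fragment sizes in bp); the pair ``(0, 0)`` encodes missing data.  A call
    with exactly one zero is invalid.
    """

    samples: list[str]
    populations: dict[str, str]
    loci: list[str]
    calls: dict[tuple[str, str], tuple[int, int]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for s in self.samples:
            pop = self.populations.get(s)
            if not pop:
                raise FormatError(f"sample {s!r} has no population label")
            for loc in self.loci:
                a, b = self.calls.get((s, loc), (0, 0))
                if (a == 0) != (b == 0):
                    raise FormatError(
                        f"sample {s!r}, locus {loc!r}: half-missing call ({a}, {b})"
                    )
                if a < 0 or b < 0:
                    raise FormatError(
                        f"sample {s!r}, locus {loc!r}: negative allele code"
                    )

    def call(self, sample: str, locus: str) -> tuple[int, int]:
        return self.calls.get((sample, locus), (0, 0))

    def is_missing(self, sample: str, locus: str) -> bool:
        return self.call(sample, locus) == (0, 0)

    @property
    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.populations[s]
            if p not in seen:
                seen.append(p)
        return seen

    def samples_in(self, population: str) -> list[str]:
        return [s for s in self.samples if self.populations[s] == population]

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeDataset":
        """Dataset restricted to ``loci`` (repeats allowed, for bootstrap)."""
        names = [f"{loc}#{i}" if list(loci).count(loc) > 1 else loc
                 for i, loc in enumerate(loci)]
        calls = {}
        for s in self.samples:
            for name, loc in zip(names, loci):
                calls[(s, name)] = self.call(s, loc)
        return GenotypeDataset(list(self.samples), dict(self.populations), names, calls)


def read_genotype_table(path: str | Path, dialect: str = "genalex") -> GenotypeDataset:
    """Read a GenAlEx-style codominant genotype CSV.

    Layout: row 1 holds counts (n_loci, n_samples, n_pops, ...), row 2 titles,
    row 3 the header (``sample``, ``pop``, then one locus name over each pair
    of allele columns).  Missing cells and ``0`` both map to the missing code.
    """
    if dialect != "genalex":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise FormatError(f"{path}: too few rows for a GenAlEx sheet")
    header = rows[2]
    locus_cells = header[2:]
    if len(locus_cells) % 2:
        raise FormatError(
            f"{path}: odd number of allele columns ({len(locus_cells)}) — "
            "each locus needs two"
        )
    loci = [locus_cells[i] for i in range(0, len(locus_cells), 2)]
    if any(not name for name in loci):
        raise FormatError(f"{path}: empty locus name in header row 3")
    samples: list[str] = []
    populations: dict[str, str] = {}
    calls: dict[tuple[str, str], tuple[int, int]] = {}
    for rowno, row in enumerate(rows[3:], start=4):
        if not any(cell.strip() for cell in row):
            continue
        sample, pop = row[0].strip(), row[1].strip()
        if not sample:
            raise FormatError(f"{path}:{rowno}: empty sample id")
        if not pop:
            raise FormatError(f"{path}:{rowno}: sample {sample!r} has empty population")
        if sample in populations:
            raise FormatError(f"{path}:{rowno}: duplicate sample id {sample!r}")
        samples.append(sample)
        populations[sample] = pop
        cells = row[2:] + [""] * (2 * len(loci) - len(row) + 2)
        for i, locus in enumerate(loci):
            a = _parse_allele(cells[2 * i], path, rowno, sample, locus)
            b = _parse_allele(cells[2 * i + 1], path, rowno, sample, locus)
            if (a == 0) != (b == 0):
                raise FormatError(
                    f"{path}:{rowno}: sample {sample!r}, locus {locus!r}: "
                    f"one allele of the pair is missing ({a}, {b})"
                )
            calls[(sample, locus)] = (min(a, b), max(a, b))
    return GenotypeDataset(samples, populations, loci, calls)


def _parse_allele(cell: str, path: Path, rowno: int, sample: str, locus: str) -> int:
    cell = cell.strip()
    if cell in ("", "0", "-"):
        return 0
    try:
        value = int(cell)
    except ValueError:
        raise FormatError(
            f"{path}:{rowno}: sample {sample!r}, locus {locus!r}: "
            f"non-integer allele code {cell!r}"
        ) from None
    if value < 0:
        raise FormatError(
            f"{path}:{rowno}: sample {sample!r}, locus {locus!r}: "
            f"negative allele code {value}"
        )
    return value


def write_genotype_table(dataset: GenotypeDataset, path: str | Path,
                         title: str = "msatforge export") -> None:
    """Write ``dataset`` as a GenAlEx-style codominant CSV (see reader)."""
    pops = dataset.population_labels
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        counts = [len(dataset.loci), len(dataset.samples), len(pops)]
        counts += [len(dataset.samples_in(p)) for p in pops]
        writer.writerow(counts)
        writer.writerow([title, ""] + [""] * (2 * len(dataset.loci)))
        header = ["sample", "pop"]
        for loc in dataset.loci:
            header += [loc, ""]
        writer.writerow(header)
        for s in dataset.samples:
            row = [s, dataset.populations[s]]
            for loc in dataset.loci:
                a, b = dataset.call(s, loc)
                row += [a, b]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# multiplex panel TSV
# ---------------------------------------------------------------------------


@dataclass
class PanelLocus:
    """One assay of a multiplex panel: primers plus assay metadata."""

    name: str
    fwd: str
    rev: str
    motif: str
    size_min: int
    size_max: int
    ta: float
    dye: str
    reaction: str = "unassigned"
    source: str = "de_novo"

    def __post_init__(self) -> None:
        if self.size_min >= self.size_max:
            raise FormatError(
                f"locus {self.name!r}: size_min {self.size_min} >= size_max {self.size_max}"
            )
        if self.dye not in VALID_DYES:
            raise FormatError(
                f"locus {self.name!r}: unknown dye {self.dye!r} "
                f"(expected one of {', '.join(VALID_DYES)})"
            )
        for label, primer in (("forward", self.fwd), ("reverse", self.rev)):
            if set(primer) - _DNA:
                raise FormatError(
                    f"locus {self.name!r}: {label} primer has non-ACGT characters"
                )
            if not 15 <= len(primer) <= 30:
                raise FormatError(
                    f"locus {self.name!r}: {label} primer length {len(primer)} "
                    "outside 15–30"
                )
        if self.source not in ("de_novo", "literature"):
            raise FormatError(f"locus {self.name!r}: unknown source {self.source!r}")


_PANEL_COLUMNS = ["name", "fwd", "rev", "motif", "size_min", "size_max",
                  "ta", "dye", "reaction", "source"]


def read_panel(path: str | Path) -> list[PanelLocus]:
    """Read a panel TSV (columns: name, fwd, rev, motif, size_min, size_max,
    ta, dye, reaction, source)."""
    path = Path(path)
    loci: list[PanelLocus] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_PANEL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing panel columns {sorted(missing)}")
        seen: set[str] = set()
        for rowno, row in enumerate(reader, start=2):
            name = row["name"].strip()
            if name in seen:
                raise FormatError(f"{path}:{rowno}: duplicate locus {name!r}")
            seen.add(name)
            try:
                loci.append(PanelLocus(
                    name=name,
                    fwd=row["fwd"].strip().upper(),
                    rev=row["rev"].strip().upper(),
                    motif=row["motif"].strip().upper(),
                    size_min=int(row["size_min"]),
                    size_max=int(row["size_max"]),
                    ta=float(row["ta"]),
                    dye=row["dye"].strip(),
                    reaction=row["reaction"].strip() or "unassigned",
                    source=row["source"].strip(),
                ))
            except FormatError as exc:
                raise FormatError(f"{path}:{rowno}: {exc}") from None
    if not loci:
        raise FormatError(f"{path}: empty panel")
    return loci


def write_panel(loci: Iterable[PanelLocus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_PANEL_COLUMNS)
        for loc in loci:
            writer.writerow([loc.name, loc.fwd, loc.rev, loc.motif, loc.size_min,
                             loc.size_max, _fmt_num(loc.ta), loc.dye, loc.reaction,
                             loc.source])


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


# ---------------------------------------------------------------------------
# fragment-size call CSV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentCall:
    """Measured fragment sizes (0.1 bp resolution) for one sample at one locus.

    ``sizes`` holds one or two positive sizes; an empty tuple records a failed
    amplification.
    """

    sample: str
    locus: str
    sizes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sizes) > 2:
            raise FormatError(
                f"sample {self.sample!r}, locus {self.locus!r}: more than two sizes"
            )
        if any(s <= 0 for s in self.sizes):
            raise FormatError(
                f"sample {self.sample!r}, locus {self.locus!r}: non-positive size"
            )


def read_fragment_calls(path: str | Path) -> list[FragmentCall]:
    """Read a fragment-call CSV with columns sample, locus, size1, size2."""
    path = Path(path)
    calls: list[FragmentCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample", "locus", "size1", "size2"}
        if required - set(reader.fieldnames or []):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for rowno, row in enumerate(reader, start=2):
            sizes = []
            for key in ("size1", "size2"):
                cell = (row[key] or "").strip()
                if cell:
                    try:
                        sizes.append(round(float(cell), 1))
                    except ValueError:
                        raise FormatError(
                            f"{path}:{rowno}: non-numeric size {cell!r}"
                        ) from None
            calls.append(FragmentCall(row["sample"].strip(), row["locus"].strip(),
                                      tuple(sizes)))
    return calls


def write_fragment_calls(calls: Iterable[FragmentCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "locus", "size1", "size2"])
        for c in calls:
            sizes = [f"{s:.1f}" for s in c.sizes]
            writer.writerow([c.sample, c.locus] + sizes + [""] * (2 - len(sizes)))


# ---------------------------------------------------------------------------
# trees / newick
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """A node of an (un)rooted phylogenetic tree.

    Leaves carry ``name``; internal nodes may carry an integer bootstrap
    ``support``.  ``length`` is the branch length to the parent (ignored on
    the root).  An unrooted tree is stored as a root with three children.
    """

    name: str = ""
    length: float | None = None
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-or-canonical leaf side)."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                parts.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self)
        return parts


def _format_length(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, "g")


def write_newick(tree: TreeNode) -> str:
    """Serialize ``tree`` to newick text.

    Branch lengths use the shortest plain representation (``1`` not ``1.0``);
    integer support values are emitted as internal-node labels.  Re-parsing
    the output yields an isomorphic tree; write→read→write is byte-identical.
    """
    seen: set[int] = set()

    def render(node: TreeNode, is_root: bool) -> str:
        if id(node) in seen:
            raise ValueError("cyclic tree structure")
        seen.add(id(node))
        if node.is_leaf:
            text = node.name
        else:
            inner = ",".join(render(c, False) for c in node.children)
            label = "" if node.support is None else str(node.support)
            text = f"({inner}){label}"
        if not is_root and node.length is not None:
            text += f":{_format_length(node.length)}"
        return text

    return render(tree, True) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse newick text into a :class:`TreeNode` (via Biopython)."""
    from Bio import Phylo

    bio_tree = Phylo.read(io.StringIO(text), "newick")

    def convert(clade) -> TreeNode:
        node = TreeNode(
            name=clade.name or "",
            length=clade.branch_length,
            children=[convert(c) for c in clade.clades],
        )
        if node.children:
            conf = clade.confidence
            if conf is None and clade.name:
                # Biopython may stash the internal label in .name
                try:
                    conf = int(clade.name)
                    node.name = ""
                except ValueError:
                    conf = None
            if conf is not None and float(conf) == int(conf):
                node.support = int(conf)
        return node

    root = convert(bio_tree.root)
    root.length = None
    return root
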