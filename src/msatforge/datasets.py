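"""Bundled reference data: the published 33-locus walnut multiplex panel.

Two fixtures transcribed from the published characterization of the panel:

* ``walnut_panel()`` — the 33 loci (26 de-novo genomic, 7 literature-sourced)
  with primer sequences, repeat motifs, allele size ranges, annealing
  temperatures, dye labels and the five printed reactions M1–M5.
* ``walnut_simplex_stats()`` — per-population summary statistics (Ho, He, Na)
  of the 95-individual simplex screen across seven walnut populations, with
  the printed Hardy–Weinberg deviation flags.
* ``walnut_locus_summary()`` — total allele counts and PCR amplification
  rates per locus.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import PanelLocus, read_panel

__all__ = [
    "walnut_panel",
    "walnut_simplex_stats",
    "walnut_locus_summary",
    "hwe_flagged_loci",
]


def _data_path(name: str):
    return resources.files("msatforge").joinpath("data", name)


def walnut_panel() -> list[PanelLocus]:
    """The published 33-locus walnut panel (5 reactions, 3 dyes)."""
    with resources.as_file(_data_path("walnut_panel.tsv")) as path:
        return read_panel(path)


def walnut_simplex_stats() -> pd.DataFrame:
    """Per (locus, population) Ho/He/Na and HWE deviation flags."""
    with resources.as_file(_data_path("walnut_simplex_stats.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def walnut_locus_summary() -> pd.DataFrame:
    """Per-locus total allele count and simplex amplification rate (%)."""
    with resources.as_file(_data_path("walnut_locus_summary.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def hwe_flagged_loci(stats: pd.DataFrame) -> list[str]:
    """Loci flagged for Hardy–Weinberg deviation in at least one population."""
    flagged = stats.loc[stats["hwe_deviation"] == 1, "locus"]
    return sorted(flagged.unique())
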