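"""Bundled reference tables used for validation and worked examples.

Two TSV tables ship with the package, both describing bEND3 brain endothelial
cells labeled for 24 h with 20 uM LpPC 16:0 or LpPC O-16:0 and measured by
direct-infusion MS against spiked internal standards (means over seven
replicates):

* ``labeled_class_totals.tsv`` — per-class pmol totals (per 45,000 cells) for
  the choline-, ethanolamine- and propargylcholine-containing classes under
  the control and the two labeling conditions.
* ``ppc_species_subspecies.tsv`` — the LpPC 16:0-labeled pPC pool: per
  species, pmol by the C171 route (NL 73.09) and the azidopalmitate route
  (NL 335.26), and per subspecies the chain pair with its FA-peak-based pmol
  and its share of the species' subspecies total.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_class_totals", "load_ppc_pool", "CELLS_PER_SAMPLE"]

# All bundled amounts are normalized to this many cells per sample.
CELLS_PER_SAMPLE = 45_000


def _read(name: str) -> pd.DataFrame:
    with resources.files("clicklipid.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_class_totals() -> pd.DataFrame:
    """Class totals (pmol per 45,000 cells) per labeling condition."""
    return _read("labeled_class_totals.tsv")


def load_ppc_pool() -> pd.DataFrame:
    """Species/subspecies quantification of the LpPC 16:0-labeled pPC pool."""
    return _read("ppc_species_subspecies.tsv")
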