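"""Packaged reference tables: published DMR lists (CpG islands per blastocyst
group, 1-based inclusive fragment coordinates) and the bisulfite validation
primer panel. These are desk-scale inputs for coordinate handling, DMR-filter
and classification checks."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome import read_table_intervals

_TABLES = {
    "ZY": "dmr_islands_zy.tsv",
    "4C": "dmr_islands_4c.tsv",
    "16C": "dmr_islands_16c.tsv",
    "IVP_promoter": "dmr_islands_ivp_promoter.tsv",
}


def _data_path(name: str):
    return resources.files("methylarray.data").joinpath(name)


def load_dmr_island_table(
    which: str, *, repair_coordinates: bool = False
) -> pd.DataFrame:
    """Published differentially methylated CpG-island table for one group.

    ``which`` is one of ZY, 4C, 16C, IVP_promoter. Coordinates are converted
    to 0-based half-open; the printed 1-based columns are kept alongside.
    """
    if which not in _TABLES:
        raise KeyError(f"unknown table {which!r}; choose from {sorted(_TABLES)}")
    with resources.as_file(_data_path(_TABLES[which])) as path:
        return read_table_intervals(path, repair_coordinates=repair_coordinates)


def load_validation_primer_table() -> pd.DataFrame:
    """Bisulfite-validation primer panel (12 loci with gene, primers, product
    length and touchdown annealing program)."""
    with resources.as_file(_data_path("bisulfite_validation_primers.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str)
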