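"""Packaged reference data.

``strain_stats.tsv`` transcribes published per-strain statistics of the 16
chrysophyte strains the package's group statistics were designed around:
strain, species, trophic mode, assembly GC percentage, and BUSCO
completeness percentage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_strain_stats() -> pd.DataFrame:
    """The 16-strain table: strain, species, mode, gc_percent, busco_complete_pct."""
    with resources.files("chrysokit").joinpath("data/strain_stats.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def gc_observations() -> pd.DataFrame:
    """Tidy (strain, species, mode, value) frame of the GC column."""
    df = load_strain_stats()
    return df.rename(columns={"gc_percent": "value"})[["strain", "species", "mode", "value"]]
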