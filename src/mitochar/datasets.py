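"""Bundled reference data.

The package ships the published gene-organization table of the *Galerita
orientalis* mitogenome (GenBank ON920164.1): 13 protein-coding genes, 22
tRNAs, 2 rRNAs and the control region with 1-based inclusive coordinates on
the 16,137 bp majority strand.  Only the coordinate table is bundled; the
sequence itself must be fetched from GenBank by the user when needed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_io import AnnotationTable, read_annotation_table

GENOME_LENGTH = 16137  # bp, from the deposited assembly
GENOME_ID = "ON920164.1"


def _fixture_path():
    return resources.files("mitochar.data") / "galerita_orientalis_features.tsv"


def load_reference_annotation() -> AnnotationTable:
    """The G. orientalis gene coordinate table as an :class:`AnnotationTable`."""
    with resources.as_file(_fixture_path()) as p:
        table = read_annotation_table(p, genome_id=GENOME_ID, genome_length=GENOME_LENGTH)
    return table


def load_reference_dataframe() -> pd.DataFrame:
    """The raw bundled table, including the published Size and
    IntergenicNucleotides columns (which the pipeline recomputes)."""
    with resources.as_file(_fixture_path()) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    return df
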