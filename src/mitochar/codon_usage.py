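"""Coding-sequence extraction, translation and codon-usage statistics.

Mitochondrial PCGs start with ATN or TTG and stop with a complete TAA/TAG or
an incomplete terminal T (or TA) that is completed to TAA by mRNA
polyadenylation.  Codon counting here is over *internal* codons only: the
start codon and the (complete or incomplete) stop are excluded, so a
complete-stop gene of size s contributes s/3 − 2 codons and a T-stop gene
contributes floor(s/3) − 1.  This accounting reproduces published totals
computed from organization-table sizes.

Translation and synonymous families follow NCBI genetic code 5 (invertebrate
mitochondrial: ATA→Met, TGA→Trp, AGA/AGG→Ser).  RSCU(c) = count(c) × family
size / family total; an unused family has undefined (NaN) RSCU.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import pandas as pd
from Bio.Data import CodonTable

from .genome_io import AnnotationTable, CircularGenome, feature_sequence

__all__ = [
    "CodingSequence",
    "CodonUsageTable",
    "extract_cds",
    "extract_all_cds",
    "classify_start_stop",
    "translate",
    "count_codons",
    "rscu",
    "rscu_table",
    "plot_rscu",
]

INVERTEBRATE_MITO = 5
LEGAL_STARTS = ("ATA", "ATT", "ATG", "ATC", "TTG")

_ALL_CODONS = ["".join(p) for p in product("TCAG", repeat=3)]


def _code_tables(code_id: int):
    table = CodonTable.unambiguous_dna_by_id[code_id]
    forward = dict(table.forward_table)
    stops = set(table.stop_codons)
    return forward, stops


def translate(seq: str, genetic_code_id: int = INVERTEBRATE_MITO) -> str:
    """Translate a DNA string whose length is a multiple of 3.

    Stop codons become '*'; any codon containing N becomes 'X'.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    forward, stops = _code_tables(genetic_code_id)
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in stops:
            out.append("*")
        else:
            out.append(forward[codon])
    return "".join(out)


def synonymous_families(code_id: int = INVERTEBRATE_MITO) -> dict[str, list[str]]:
    """Amino acid → member codons under the given code (stops excluded)."""
    forward, _ = _code_tables(code_id)
    fams: dict[str, list[str]] = {}
    for codon in _ALL_CODONS:
        aa = forward.get(codon)
        if aa is not None:
            fams.setdefault(aa, []).append(codon)
    return fams


@dataclass(frozen=True)
class CodingSequence:
    """One extracted PCG on its sense strand."""

    gene: str
    nucleotides: str
    start_codon: str
    stop_codon: str  # "TAA"/"TAG" or incomplete "T"/"TA"
    stop_complete: bool

    @property
    def n_internal_codons(self) -> int:
        n_full = len(self.nucleotides) // 3
        return n_full - 2 if self.stop_complete else n_full - 1

    @property
    def internal_codons(self) -> list[str]:
        n_full = len(self.nucleotides) // 3
        last = n_full - 1 if self.stop_complete else n_full
        return [self.nucleotides[3 * i : 3 * i + 3] for i in range(1, last)]


def extract_cds(
    genome: CircularGenome, table: AnnotationTable, gene: str
) -> CodingSequence:
    """Extract a PCG's sense-strand sequence and classify its start/stop.

    A terminal TAA/TAG on a length ≡ 0 (mod 3) is a complete stop; lengths
    ≡ 1 / 2 with terminal T / TA are incomplete stops (never padded here).
    A first triplet outside the ATN/TTG convention warns but does not fail,
    since rarer starts occur in related mitogenomes.
    """
    feature = table.get(gene)
    if feature.feature_class != "PCG":
        raise ValueError(f"{gene} is a {feature.feature_class}, not a PCG")
    seq = feature_sequence(genome, feature)
    start_codon = seq[:3]
    if start_codon not in LEGAL_STARTS:
        warnings.warn(
            f"{gene}: unusual start codon {start_codon}", stacklevel=2
        )
    rem = len(seq) % 3
    if rem == 0:
        stop, complete = seq[-3:], True
        if stop not in ("TAA", "TAG"):
            warnings.warn(f"{gene}: unusual stop codon {stop}", stacklevel=2)
    else:
        stop, complete = seq[-rem:], False
        if stop not in ("T", "TA"):
            warnings.warn(
                f"{gene}: incomplete stop {stop!r} is not T/TA", stacklevel=2
            )
    return CodingSequence(
        gene=gene,
        nucleotides=seq,
        start_codon=start_codon,
        stop_codon=stop,
        stop_complete=complete,
    )


def extract_all_cds(
    genome: CircularGenome, table: AnnotationTable
) -> list[CodingSequence]:
    return [extract_cds(genome, table, f.name) for f in table.of_class("PCG")]


def classify_start_stop(cds_list: list[CodingSequence]) -> dict[str, dict[str, int]]:
    """Tally start codons and stop codons across extracted PCGs."""
    starts: dict[str, int] = {}
    stops: dict[str, int] = {}
    for cds in cds_list:
        starts[cds.start_codon] = starts.get(cds.start_codon, 0) + 1
        stops[cds.stop_codon] = stops.get(cds.stop_codon, 0) + 1
    return {"starts": starts, "stops": stops}


@dataclass
class CodonUsageTable:
    """Internal-codon counts with per-amino-acid totals and RSCU."""

    genetic_code_id: int
    codon_counts: dict[str, int]
    total_internal_codons: int

    @property
    def amino_acid_totals(self) -> dict[str, int]:
        fams = synonymous_families(self.genetic_code_id)
        return {
            aa: sum(self.codon_counts.get(c, 0) for c in codons)
            for aa, codons in fams.items()
        }


def count_codons(
    cds_list: list[CodingSequence], genetic_code_id: int = INVERTEBRATE_MITO
) -> CodonUsageTable:
    """Count internal codons (start and stop excluded) over a set of CDSs."""
    counts = {c: 0 for c in _ALL_CODONS}
    total = 0
    for cds in cds_list:
        for codon in cds.internal_codons:
            if codon in counts:
                counts[codon] += 1
                total += 1
    return CodonUsageTable(
        genetic_code_id=genetic_code_id,
        codon_counts=counts,
        total_internal_codons=total,
    )


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """RSCU per codon: count × family size / family total (NaN if unused).

    Stop codons are excluded from families; within any used family the RSCU
    values sum to the family size.
    """
    fams = synonymous_families(table.genetic_code_id)
    values: dict[str, float] = {}
    for codons in fams.values():
        fam_total = sum(table.codon_counts.get(c, 0) for c in codons)
        for c in codons:
            if fam_total == 0:
                values[c] = math.nan
            else:
                values[c] = table.codon_counts.get(c, 0) * len(codons) / fam_total
    return values


def rscu_table(table: CodonUsageTable) -> pd.DataFrame:
    """Tidy codon-usage report (RNA alphabet for display, e.g. UUA)."""
    fams = synonymous_families(table.genetic_code_id)
    values = rscu(table)
    rows = []
    for aa, codons in sorted(fams.items()):
        for c in codons:
            rows.append(
                {
                    "AminoAcid": aa,
                    "Codon": c.replace("T", "U"),
                    "Count": table.codon_counts.get(c, 0),
                    "RSCU": values[c],
                }
            )
    return pd.DataFrame(rows)


def plot_rscu(table: CodonUsageTable, path=None):
    """Stacked per-amino-acid RSCU bar chart; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = rscu_table(table).fillna(0.0)
    fig, ax = plt.subplots(figsize=(12, 4))
    amino_acids = sorted(df["AminoAcid"].unique())
    cmap = plt.get_cmap("tab20")
    for x, aa in enumerate(amino_acids):
        sub = df[df["AminoAcid"] == aa].sort_values("RSCU", ascending=False)
        bottom = 0.0
        for i, (_, row) in enumerate(sub.iterrows()):
            ax.bar(x, row["RSCU"], bottom=bottom, color=cmap(i % 20), width=0.8)
            bottom += row["RSCU"]
    ax.set_xticks(range(len(amino_acids)))
    ax.set_xticklabels(amino_acids)
    ax.set_ylabel("RSCU")
    ax.set_xlabel("Amino acid")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
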