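"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), the Perna–Kocher
strand-asymmetry statistics.  Both change sign exactly under reverse
complement.  N bases are excluded from every denominator; a zero denominator
yields NaN, never 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome_io import (
    AnnotationTable,
    CircularGenome,
    GenomeFormatError,
    VALID_BASES,
    extract_region,
)

__all__ = ["RegionStats", "base_counts", "at_skew", "gc_skew", "region_stats",
           "composition_report"]


@dataclass(frozen=True)
class RegionStats:
    """Base counts, AT/GC content and skews for one region on one strand."""

    a: int
    t: int
    g: int
    c: int
    n: int
    at_content: float
    gc_content: float
    at_skew: float
    gc_skew: float
    strand_used: str = "J"

    @property
    def length(self) -> int:
        return self.a + self.t + self.g + self.c + self.n


def base_counts(seq: str) -> dict[str, int]:
    """Exact integer counts of A, T, G, C and N."""
    seq = seq.upper()
    counts = Counter(seq)
    bad = set(counts) - VALID_BASES
    if bad:
        ch = sorted(bad)[0]
        raise GenomeFormatError(
            f"illegal character {ch!r} at position {seq.index(ch) + 1}"
        )
    return {b: counts.get(b, 0) for b in "ATGCN"}


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def at_skew(seq: str) -> float:
    """(A − T)/(A + T); NaN when A + T = 0."""
    c = base_counts(seq)
    return _ratio(c["A"] - c["T"], c["A"] + c["T"])


def gc_skew(seq: str) -> float:
    """(G − C)/(G + C); NaN when G + C = 0."""
    c = base_counts(seq)
    return _ratio(c["G"] - c["C"], c["G"] + c["C"])


def sequence_stats(seq: str, strand_used: str = "J") -> RegionStats:
    """Full composition statistics for a raw sequence."""
    c = base_counts(seq)
    informative = c["A"] + c["T"] + c["G"] + c["C"]
    return RegionStats(
        a=c["A"],
        t=c["T"],
        g=c["G"],
        c=c["C"],
        n=c["N"],
        at_content=_ratio(c["A"] + c["T"], informative),
        gc_content=_ratio(c["G"] + c["C"], informative),
        at_skew=_ratio(c["A"] - c["T"], c["A"] + c["T"]),
        gc_skew=_ratio(c["G"] - c["C"], c["G"] + c["C"]),
        strand_used=strand_used,
    )


def region_stats(
    genome: CircularGenome,
    table: AnnotationTable,
    feature_name: str,
    strand_mode: str = "feature",
) -> RegionStats:
    """Composition statistics for a named feature.

    ``strand_mode="feature"`` computes on the feature's own sense strand
    (reverse complement for N-strand genes) — the convention under which
    rRNA "AU-skews" are reported; ``strand_mode="J"`` stays on the deposited
    majority strand.
    """
    feature = table.get(feature_name)  # KeyError for unknown names
    if strand_mode == "feature":
        strand = feature.strand
    elif strand_mode == "J":
        strand = "J"
    else:
        raise ValueError(f"strand_mode must be 'feature' or 'J', got {strand_mode!r}")
    seq = extract_region(genome, feature.start, feature.end, strand)
    return sequence_stats(seq, strand_used=strand)


def composition_report(
    genome: CircularGenome, table: AnnotationTable, strand_mode: str = "feature"
) -> pd.DataFrame:
    """One row per feature plus a whole-genome row.

    Percentages are rounded to 2 decimals and skews to 3 in the ``*_pct`` /
    rounded columns; full-precision values are kept alongside.
    """
    rows = []

    def _row(name, stats: RegionStats):
        return {
            "Region": name,
            "Strand": stats.strand_used,
            "Length": stats.length,
            "A": stats.a,
            "T": stats.t,
            "G": stats.g,
            "C": stats.c,
            "N": stats.n,
            "AT_content": stats.at_content,
            "GC_content": stats.gc_content,
            "AT_skew": stats.at_skew,
            "GC_skew": stats.gc_skew,
            "AT_pct": round(stats.at_content * 100, 2),
            "GC_pct": round(stats.gc_content * 100, 2),
            "AT_skew_r": round(stats.at_skew, 3),
            "GC_skew_r": round(stats.gc_skew, 3),
        }

    rows.append(_row("genome", sequence_stats(genome.sequence)))
    for f in table.features:
        rows.append(_row(f.name, region_stats(genome, table, f.name, strand_mode)))
    return pd.DataFrame(rows)
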