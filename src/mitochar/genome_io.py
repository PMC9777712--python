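"""Sequence and annotation I/O for circular mitochondrial genomes.

Coordinates are 1-based and inclusive throughout, following the GenBank
convention used by published mitogenome organization tables.  The genome is
stored linearized (conventionally at the first base of trnI); the region
extractor supports origin-wrapping coordinates on circular genomes, although
no gene wraps the origin in the bundled reference layout.

The "J" strand is the majority strand, identified with the sequence as
deposited; "N"-strand features are analyzed on their reverse complement.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "CircularGenome",
    "FeatureRecord",
    "AnnotationTable",
    "GenomeFormatError",
    "AnnotationValidationError",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "write_annotation_table",
    "read_genbank_features",
    "extract_region",
    "reverse_complement",
    "linearize",
]

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: feature classes recognized in annotation tables
FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")


class GenomeFormatError(ValueError):
    """Malformed sequence input (illegal characters, wrong record count)."""


class AnnotationValidationError(ValueError):
    """Annotation rows violating coordinate or ordering invariants."""


def _validate_alphabet(seq: str, context: str = "sequence") -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in VALID_BASES:
            raise GenomeFormatError(
                f"illegal character {ch!r} at position {pos} in {context}"
            )


@dataclass(frozen=True)
class CircularGenome:
    """A (usually circular) DNA molecule with an uppercase ACGTN sequence."""

    id: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))
        _validate_alphabet(self.sequence, context=f"genome {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature: gene, tRNA, rRNA, or the control region.

    ``start``/``end`` are 1-based inclusive on the linearized genome;
    ``strand`` is "J" (majority) or "N" (minority).
    """

    name: str
    feature_class: str
    strand: str
    start: int
    end: int
    anticodon: str | None = None
    declared_start_codon: str | None = None
    declared_stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationValidationError(
                f"{self.name}: unknown feature class {self.feature_class!r}"
            )
        if self.strand not in ("J", "N"):
            raise AnnotationValidationError(f"{self.name}: strand must be J or N")
        if not (1 <= self.start <= self.end):
            raise AnnotationValidationError(
                f"{self.name}: invalid coordinates {self.start}..{self.end}"
            )
        if self.feature_class == "tRNA" and not self.anticodon:
            raise AnnotationValidationError(f"{self.name}: tRNA lacks an anticodon")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationTable:
    """Ordered feature records for one genome, sorted by start coordinate."""

    genome_id: str
    features: list[FeatureRecord]
    genome_length: int

    def __post_init__(self) -> None:
        bad = [
            f.name
            for prev, f in zip(self.features, self.features[1:])
            if f.start < prev.start
        ]
        if bad:
            raise AnnotationValidationError(f"features out of order at: {bad}")
        out_of_range = [f.name for f in self.features if f.end > self.genome_length]
        if out_of_range:
            raise AnnotationValidationError(
                f"features beyond genome length {self.genome_length}: {out_of_range}"
            )
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationValidationError(f"duplicate feature names: {dupes}")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> FeatureRecord:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def of_class(self, feature_class: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.feature_class == feature_class]


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    seq = seq.upper()
    _validate_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> CircularGenome:
    """Read a single-record FASTA into a :class:`CircularGenome`.

    Lowercase is uppercased and RNA U is converted to T.  Empty or
    multi-record files, and any character outside {A,C,G,T,N,U}, raise
    :class:`GenomeFormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeFormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise GenomeFormatError(
            f"{path}: expected a single record, found {len(records)}"
        )
    rec = records[0]
    return CircularGenome(id=rec.id, sequence=str(rec.seq))


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def _clean_int(text: str) -> int:
    # tolerate thousands separators as printed in organization tables
    return int(str(text).replace(",", "").replace(" ", "").strip())


def infer_feature_class(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    if low in ("cr", "at-rich", "at_rich", "d-loop", "control_region"):
        return "CR"
    return "PCG"


_LOCATION_RE = re.compile(r"^\s*([\d,]+)\s*[–—-]\s*([\d,]+)\s*$")


def read_annotation_table(
    path: str | Path, genome_id: str = "", genome_length: int | None = None
) -> AnnotationTable:
    """Read a tab-separated gene organization table.

    Expected header columns: ``Gene``, ``Strand``, and either ``Start``/``End``
    or a single ``Location`` column ("206–1234"; en-dashes and thousands
    separators tolerated).  Optional columns ``Anticodon``, ``StartCodon``,
    ``StopCodon``.  ``Size`` and ``IntergenicNucleotides`` columns, if present,
    are ignored and recomputed downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"Gene", "Strand"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationValidationError(f"{path}: missing columns {sorted(missing)}")

    feats: list[FeatureRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        name = row["Gene"].strip().lstrip("*").rstrip("*")
        if not name:
            continue
        try:
            if "Location" in df.columns and row.get("Location", "").strip():
                m = _LOCATION_RE.match(row["Location"])
                if not m:
                    raise AnnotationValidationError(
                        f"unparsable location {row['Location']!r}"
                    )
                start, end = _clean_int(m.group(1)), _clean_int(m.group(2))
            else:
                start, end = _clean_int(row["Start"]), _clean_int(row["End"])
            feats.append(
                FeatureRecord(
                    name=name,
                    feature_class=infer_feature_class(name),
                    strand=row["Strand"].strip(),
                    start=start,
                    end=end,
                    anticodon=row.get("Anticodon", "").strip() or None,
                    declared_start_codon=row.get("StartCodon", "").strip() or None,
                    declared_stop_codon=row.get("StopCodon", "").strip() or None,
                )
            )
        except (ValueError, AnnotationValidationError) as exc:
            problems.append(f"row {idx + 2} ({name!r}): {exc}")
    if problems:
        raise AnnotationValidationError(
            "invalid annotation rows:\n  " + "\n  ".join(problems)
        )
    length = genome_length if genome_length is not None else max(f.end for f in feats)
    return AnnotationTable(
        genome_id=genome_id or Path(path).stem, features=feats, genome_length=length
    )


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    """Write a table readable by :func:`read_annotation_table` (round-trips)."""
    rows = [
        {
            "Gene": f.name,
            "Strand": f.strand,
            "Start": f.start,
            "End": f.end,
            "Anticodon": f.anticodon or "",
            "StartCodon": f.declared_start_codon or "",
            "StopCodon": f.declared_stop_codon or "",
        }
        for f in table.features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_GENBANK_KEYS = {"gene", "tRNA", "rRNA", "misc_feature", "CDS", "D-loop"}


def read_genbank_features(path: str | Path) -> tuple[CircularGenome, AnnotationTable]:
    """Limited GenBank flat-file import (gene/tRNA/rRNA/CDS/misc_feature keys).

    Returns the sequence plus an annotation table; wrapping (compound)
    locations are not supported.
    """
    rec = SeqIO.read(str(path), "genbank")
    genome = CircularGenome(id=rec.id, sequence=str(rec.seq))
    feats: list[FeatureRecord] = []
    seen: set[str] = set()
    for feat in rec.features:
        if feat.type not in _GENBANK_KEYS or feat.type == "gene":
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        if name in seen:
            continue
        seen.add(name)
        if feat.type == "tRNA":
            fclass = "tRNA"
        elif feat.type == "rRNA":
            fclass = "rRNA"
        elif feat.type in ("misc_feature", "D-loop"):
            fclass = "CR"
            name = "CR"
        else:
            fclass = "PCG"
        anticodon = None
        if fclass == "tRNA":
            m = re.search(r"\(([acgtuACGTU]{3})\)", name)
            anticodon = m.group(1).upper().replace("U", "T") if m else "NNN"
        feats.append(
            FeatureRecord(
                name=name,
                feature_class=fclass,
                strand="J" if feat.location.strand != -1 else "N",
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                anticodon=anticodon,
            )
        )
    feats.sort(key=lambda f: f.start)
    table = AnnotationTable(
        genome_id=rec.id, features=feats, genome_length=genome.length
    )
    return genome, table


def extract_region(
    genome: CircularGenome, start: int, end: int, strand: str = "J"
) -> str:
    """Extract the 1-based inclusive region [start, end]; "N" returns its
    reverse complement.

    On a circular genome ``start > end`` denotes an origin-wrapping region of
    length ``end + length - start + 1``.
    """
    L = genome.length
    if not (1 <= start <= L and 1 <= end <= L):
        raise IndexError(f"coordinates {start}..{end} outside genome of length {L}")
    if start <= end:
        seq = genome.sequence[start - 1 : end]
    else:
        if not genome.is_circular:
            raise IndexError(
                f"wrapping region {start}..{end} requested on a linear genome"
            )
        seq = genome.sequence[start - 1 :] + genome.sequence[:end]
    if strand == "N":
        seq = reverse_complement(seq)
    elif strand != "J":
        raise ValueError(f"strand must be 'J' or 'N', got {strand!r}")
    return seq


def feature_sequence(genome: CircularGenome, feature: FeatureRecord) -> str:
    """Sense-strand sequence of a feature (reverse complement for N strand)."""
    return extract_region(genome, feature.start, feature.end, feature.strand)


def linearize(genome: CircularGenome, new_origin: int) -> CircularGenome:
    """Rotate a circular genome so ``new_origin`` (1-based) becomes base 1.

    Useful when a deposited sequence does not start at the conventional trnI
    first base.
    """
    if not genome.is_circular:
        raise ValueError("cannot rotate a linear genome")
    if not (1 <= new_origin <= genome.length):
        raise IndexError(f"origin {new_origin} outside genome")
    seq = genome.sequence[new_origin - 1 :] + genome.sequence[: new_origin - 1]
    return replace(genome, sequence=seq)
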