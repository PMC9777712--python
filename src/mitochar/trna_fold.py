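"""Template-anchored cloverleaf folding for mitochondrial tRNAs.

Mitochondrial tRNA genes are checked against the four-arm cloverleaf
template rather than folded thermodynamically: the anticodon loop is anchored
at the annotated anticodon triplet, the anticodon stem is extended greedily
outward, the acceptor stem is paired inward from the 5'/3' termini, and the
DHU and TPsiC arms are located as maximal hairpins in the regions between.
G-U wobbles count as pairs; up to one non-pairing apposition (U-U, A-G, or
other) is tolerated per stem and reported as a mismatch.  A DHU arm may be
absent entirely (replaced by a loop), as in many metazoan trnS1 genes.

Stem-length search ranges reflect observed mitochondrial variation:
acceptor 6-8 bp, DHU 0-5, anticodon 3-8, TPsiC 3-6.  All positions are
1-based on the tRNA sense strand; sequences are displayed in the RNA
alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import AnnotationTable, CircularGenome, feature_sequence

__all__ = [
    "CloverleafStructure",
    "StemRanges",
    "fold_cloverleaf",
    "classify_pairs",
    "classify_pair",
    "trna_summary",
    "AnchorError",
]

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

ARMS = ("acceptor", "dhu", "anticodon", "tpsic")


class AnchorError(ValueError):
    """The annotated anticodon does not occur in the tRNA sequence."""


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def is_pair(a: str, b: str) -> bool:
    """Watson-Crick or wobble G-U."""
    return (a, b) in WATSON_CRICK or (a, b) in WOBBLE


def classify_pair(a: str, b: str) -> str:
    """Label one apposition: WatsonCrick / GU / UU / AG / other."""
    a, b = to_rna(a), to_rna(b)
    if (a, b) in WATSON_CRICK:
        return "WatsonCrick"
    if (a, b) in WOBBLE:
        return "GU"
    if a == b == "U":
        return "UU"
    if {a, b} == {"A", "G"}:
        return "AG"
    return "other"


@dataclass(frozen=True)
class StemRanges:
    """Permitted stem lengths (bp) per arm."""

    acceptor: tuple[int, int] = (6, 8)
    dhu: tuple[int, int] = (0, 5)
    anticodon: tuple[int, int] = (3, 8)
    tpsic: tuple[int, int] = (3, 6)


@dataclass
class CloverleafStructure:
    """Pairing report for one tRNA; ``folded`` is False on template failure."""

    sequence: str  # RNA alphabet
    folded: bool
    failure_reason: str | None = None
    pairs: list[tuple[int, int]] = field(default_factory=list)
    acceptor_stem_len: int = 0
    dhu_stem_len: int = 0
    anticodon_stem_len: int = 0
    tpsic_stem_len: int = 0
    dhu_loop_len: int = 0
    anticodon_loop_len: int = 0
    tpsic_loop_len: int = 0
    variable_loop_len: int = 0
    anticodon: str = ""
    anticodon_position: int = 0  # 1-based start of the triplet
    mismatches: list[tuple[str, int, int, str]] = field(default_factory=list)
    arms: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def dhu_present(self) -> bool:
        return self.dhu_stem_len >= 1

    def stem_lengths(self) -> tuple[int, int, int, int]:
        return (
            self.acceptor_stem_len,
            self.dhu_stem_len,
            self.anticodon_stem_len,
            self.tpsic_stem_len,
        )

    def dot_bracket(self) -> str:
        marks = ["." for _ in self.sequence]
        for i, j in self.pairs:
            marks[i - 1], marks[j - 1] = "(", ")"
        return "".join(marks)


def _extend_stem(seq, left, right, max_len, step_left=-1, step_right=1):
    """Greedy outward/inward pairing from (left, right), 0-based, with one
    tolerated mismatch backed by at least one further pair."""
    pairs: list[tuple[int, int]] = []
    mismatches: list[tuple[int, int]] = []
    i, j = left, right
    while len(pairs) + len(mismatches) < max_len and 0 <= i < len(seq) and 0 <= j < len(seq) and i < j:
        if is_pair(seq[i], seq[j]):
            pairs.append((i, j))
        elif not mismatches:
            ni, nj = i + step_left, j + step_right
            if (
                0 <= ni < len(seq)
                and 0 <= nj < len(seq)
                and ni < nj
                and is_pair(seq[ni], seq[nj])
            ):
                mismatches.append((i, j))
            else:
                break
        else:
            break
        i += step_left
        j += step_right
    # a trailing tolerated mismatch with nothing beyond it is not part of the stem
    return pairs, mismatches


def _best_hairpin(seq, lo, hi, min_stem, max_stem, min_loop=3):
    """Maximal hairpin within seq[lo:hi] (0-based, hi exclusive).

    Candidates are ranked by stem length (desc), then fewest mismatches, then
    leftmost 5' start, then smallest loop.  A stem may carry at most one
    non-pairing apposition, never at its outermost or innermost position.
    Returns (stem5_start, stem3_start, d, mismatch_positions) or None.
    """
    best = None
    region = seq[lo:hi]
    n = len(region)
    for d in range(min(max_stem, (n - min_loop) // 2), min_stem - 1, -1):
        candidates = []
        for x in range(0, n - 2 * d - min_loop + 1):
            for y in range(x + d + min_loop, n - d + 1):
                mism = []
                ok = True
                for k in range(d):
                    a = region[x + k]
                    b = region[y + d - 1 - k]
                    if not is_pair(a, b):
                        mism.append(k)
                if len(mism) > 1 or (mism and (mism[0] == 0 or mism[0] == d - 1)):
                    ok = False
                if ok:
                    candidates.append((len(mism), x, y - x - d, x, y, mism))
        if candidates:
            candidates.sort()
            _, _, _, x, y, mism = candidates[0]
            best = (lo + x, lo + y, d, mism)
            break
    return best


def fold_cloverleaf(
    seq: str,
    anticodon: str,
    ranges: StemRanges = StemRanges(),
) -> CloverleafStructure:
    """Fold a tRNA sequence against the cloverleaf template.

    The anticodon loop is fixed at 7 nt with the anticodon central (loop
    positions 3-5); if the anticodon occurs more than once, the occurrence
    nearest the sequence midpoint anchors the fold.  Returns a structure with
    ``folded=False`` (and a reason) when no template-consistent arrangement
    exists; raises :class:`AnchorError` if the anticodon is absent.
    """
    rna = to_rna(seq)
    ac = to_rna(anticodon)
    n = len(rna)
    result = CloverleafStructure(sequence=rna, folded=False, anticodon=ac)

    occurrences = [
        i for i in range(n - 2) if rna[i : i + 3] == ac
    ]
    if not occurrences:
        raise AnchorError(f"anticodon {ac} not found in sequence")
    mid = n // 2
    ac_pos = min(occurrences, key=lambda i: (abs(i + 1 - mid), i))  # 0-based
    result.anticodon_position = ac_pos + 1

    loop_start = ac_pos - 2  # 7-nt loop, anticodon at loop offsets 2..4
    loop_end = ac_pos + 4  # inclusive
    if loop_start < 0 or loop_end >= n:
        result.failure_reason = "anticodon too close to a terminus"
        return result
    result.anticodon_loop_len = 7

    # anticodon stem: outward from the loop
    ac_pairs, ac_mism = _extend_stem(
        rna, loop_start - 1, loop_end + 1, ranges.anticodon[1]
    )
    ac_len = len(ac_pairs) + len(ac_mism)
    if ac_len < ranges.anticodon[0]:
        result.failure_reason = (
            f"anticodon stem only {ac_len} bp (minimum {ranges.anticodon[0]})"
        )
        return result
    result.anticodon_stem_len = ac_len

    # acceptor stem: inward from the termini, allowing a 0-4 nt unpaired 3'
    # tail (discriminator etc.); prefer more pairs, then the shortest tail
    best_acc = None
    for tail in range(0, 5):
        pairs, mism = _extend_stem(
            rna, 0, n - 1 - tail, ranges.acceptor[1], step_left=1, step_right=-1
        )
        score = (len(pairs) + len(mism), -len(mism), -tail)
        if best_acc is None or score > best_acc[0]:
            best_acc = (score, pairs, mism, tail)
    _, acc_pairs, acc_mism, tail = best_acc
    acc_len = len(acc_pairs) + len(acc_mism)
    if acc_len < ranges.acceptor[0]:
        result.failure_reason = (
            f"acceptor stem only {acc_len} bp (minimum {ranges.acceptor[0]})"
        )
        return result
    result.acceptor_stem_len = acc_len

    ac_stem_5_start = loop_start - ac_len  # 0-based first base of stem 5' side
    ac_stem_3_end = loop_end + ac_len  # 0-based last base of stem 3' side

    # DHU arm between the acceptor 5' stem and the anticodon stem
    dhu_region = (acc_len, ac_stem_5_start)
    dhu = None
    if ranges.dhu[1] >= 1 and dhu_region[1] - dhu_region[0] >= 2 * 1 + 3:
        dhu = _best_hairpin(
            rna, dhu_region[0], dhu_region[1], max(1, ranges.dhu[0]), ranges.dhu[1]
        )
    dhu_pairs: list[tuple[int, int]] = []
    dhu_mism: list[tuple[int, int]] = []
    if dhu is not None:
        x, y, d, mism_ks = dhu
        for k in range(d):
            i, j = x + k, y + d - 1 - k
            (dhu_mism if k in mism_ks else dhu_pairs).append((i, j))
        result.dhu_stem_len = d
        result.dhu_loop_len = y - (x + d)

    # TPsiC arm between the anticodon stem and the acceptor 3' stem
    t_region = (ac_stem_3_end + 1, n - tail - acc_len)
    t = None
    if t_region[1] - t_region[0] >= 2 * ranges.tpsic[0] + 3:
        t = _best_hairpin(
            rna, t_region[0], t_region[1], ranges.tpsic[0], ranges.tpsic[1]
        )
    t_pairs: list[tuple[int, int]] = []
    t_mism: list[tuple[int, int]] = []
    if t is None:
        result.failure_reason = "no TPsiC hairpin found"
        return result
    x, y, d, mism_ks = t
    for k in range(d):
        i, j = x + k, y + d - 1 - k
        (t_mism if k in mism_ks else t_pairs).append((i, j))
    result.tpsic_stem_len = d
    result.tpsic_loop_len = y - (x + d)
    result.variable_loop_len = x - (ac_stem_3_end + 1)

    # assemble 1-based pairs and per-arm mismatch classes
    def _commit(arm, pairs, mism):
        for i, j in pairs:
            result.pairs.append((i + 1, j + 1))
            result.arms[(i + 1, j + 1)] = arm
            # wobble G-U pairs are pairs, not stem-breaking mismatches, but
            # they are still reported among the non-canonical appositions
            if classify_pair(rna[i], rna[j]) == "GU":
                result.mismatches.append((arm, i + 1, j + 1, "GU"))
        for i, j in mism:
            result.pairs.append((i + 1, j + 1))
            result.arms[(i + 1, j + 1)] = arm
            result.mismatches.append((arm, i + 1, j + 1, classify_pair(rna[i], rna[j])))

    _commit("acceptor", acc_pairs, acc_mism)
    _commit("dhu", dhu_pairs, dhu_mism)
    _commit("anticodon", ac_pairs, ac_mism)
    _commit("tpsic", t_pairs, t_mism)
    result.pairs.sort()
    result.folded = True
    return result


def classify_pairs(structure: CloverleafStructure) -> dict[str, dict[str, int]]:
    """Per-arm tallies of pair classes (WatsonCrick/GU/UU/AG/other)."""
    if not structure.folded:
        raise ValueError("cannot classify pairs of a failed fold")
    summary: dict[str, dict[str, int]] = {arm: {} for arm in ARMS}
    seq = structure.sequence
    for i, j in structure.pairs:
        cls = classify_pair(seq[i - 1], seq[j - 1])
        arm = structure.arms[(i, j)]
        summary[arm][cls] = summary[arm].get(cls, 0) + 1
    return summary


def trna_summary(
    genome: CircularGenome, table: AnnotationTable, ranges: StemRanges = StemRanges()
) -> pd.DataFrame:
    """Fold every annotated tRNA and report lengths, stems and mismatches."""
    rows = []
    for f in table.of_class("tRNA"):
        seq = feature_sequence(genome, f)
        row = {
            "tRNA": f.name,
            "Strand": f.strand,
            "Length": len(seq),
            "Anticodon": to_rna(f.anticodon or ""),
        }
        try:
            s = fold_cloverleaf(seq, f.anticodon or "", ranges=ranges)
        except AnchorError:
            row.update({"Folded": False, "FailureReason": "anticodon not in sequence"})
            rows.append(row)
            continue
        row.update(
            {
                "Folded": s.folded,
                "FailureReason": s.failure_reason or "",
                "AcceptorStem": s.acceptor_stem_len,
                "DHUStem": s.dhu_stem_len,
                "DHUPresent": s.dhu_present,
                "AnticodonStem": s.anticodon_stem_len,
                "TPsiCStem": s.tpsic_stem_len,
                "Mismatches": ";".join(
                    f"{arm}:{i}-{j}:{cls}" for arm, i, j, cls in s.mismatches
                ),
                "DotBracket": s.dot_bracket() if s.folded else "",
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
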