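"""Tandem repeat, homopolymer and microsatellite detection for the
AT-rich control region.

The tandem-repeat detector is a simplified Benson-style scanner, not a
bit-exact Tandem Repeats Finder reimplementation: candidate arrays are seeded
by self-alignment at each lag (period), refined against a majority-vote
consensus, and scored +match_weight per match and −mismatch_penalty per
mismatch in a gap-free wraparound alignment; arrays scoring below
``min_alignment_score``, exceeding ``max_period`` or falling under
``min_copies`` copies are discarded.  The probabilistic match/indel criteria
of the original program are replaced by this deterministic score threshold,
so repeat sets on real control regions may differ from TRF's; recovery of
arrays with known coordinates is the supported accuracy contract.

Coordinates in every report are 1-based inclusive and local to the scanned
sequence (the control region is scanned on the majority strand from its 5'
end).  Tie-breaking is leftmost-longest throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import AnnotationTable, CircularGenome, extract_region
from .composition import sequence_stats

__all__ = [
    "RepeatScanParams",
    "TandemRepeat",
    "MicrosatelliteHit",
    "CRReport",
    "find_tandem_repeats",
    "longest_homopolymer",
    "find_microsatellites",
    "cr_report",
]


@dataclass(frozen=True)
class RepeatScanParams:
    """Scoring parameters, TRF-convention weights (2 7 7 ... 50 500)."""

    match_weight: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    min_alignment_score: int = 50
    max_period: int = 500
    min_copies: float = 1.9

    @classmethod
    def from_trf_string(cls, text: str) -> "RepeatScanParams":
        """Parse the seven TRF-style numbers "2 7 7 80 10 50 500".

        The match probability (80) and indel probability (10) fields are
        accepted for interface parity but unused by this deterministic
        detector.
        """
        nums = [int(x) for x in text.split()]
        if len(nums) != 7:
            raise ValueError(f"expected 7 numbers, got {len(nums)}")
        match, mismatch, indel, _pm, _pi, minscore, maxperiod = nums
        return cls(
            match_weight=match,
            mismatch_penalty=mismatch,
            indel_penalty=indel,
            min_alignment_score=minscore,
            max_period=maxperiod,
        )


@dataclass(frozen=True)
class TandemRepeat:
    """One detected array (1-based inclusive, sequence-local coordinates)."""

    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    percent_identity: float
    score: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MicrosatelliteHit:
    motif: str
    copies: int
    start: int
    end: int
    interruptions: int
    left_flank: str


@dataclass
class CRReport:
    """Control-region organization: repeats, poly-T, microsatellites."""

    cr_length: int
    at_content: float
    repeats: list[TandemRepeat]
    longest_poly_t: tuple[int | None, int]
    microsatellites: list[MicrosatelliteHit]
    tr_total_bp: int
    tr_fraction_of_cr: float
    tr_union_bp: int = 0


def _consensus_for(seq: str, start: int, end: int, period: int) -> str:
    """Majority base per period offset over seq[start:end] (0-based, excl)."""
    cols: list[dict[str, int]] = [dict() for _ in range(period)]
    for i in range(start, end):
        col = cols[(i - start) % period]
        b = seq[i]
        col[b] = col.get(b, 0) + 1
    # deterministic tie-break: highest count, then alphabetical base
    return "".join(
        min(sorted(col), key=lambda b: -col[b]) if col else "A" for col in cols
    )


def _consensus_score(
    seq: str, start: int, end: int, period: int, cons: str, params: RepeatScanParams
) -> tuple[int, int]:
    matches = sum(
        1 for i in range(start, end) if seq[i] == cons[(i - start) % period]
    )
    mismatches = (end - start) - matches
    return (
        params.match_weight * matches - params.mismatch_penalty * mismatches,
        matches,
    )


def _refine(
    seq: str, start: int, end: int, period: int, params: RepeatScanParams
) -> tuple[int, int, str]:
    """Refine candidate boundaries against the majority consensus.

    Each pass rebuilds the consensus, scores every position in a window one
    period beyond the current boundaries (+match_weight on consensus match,
    -mismatch_penalty otherwise, phase anchored at the current start), and
    keeps the maximum-scoring subarray.  Converges in a few passes and both
    trims spurious flanks and extends into adjacent matching copies.
    """
    L = len(seq)
    for _ in range(5):
        cons = _consensus_for(seq, start, end, period)
        lo = max(0, start - period)
        hi = min(L, end + period)
        best_sum, best = 0, None
        running, run_start = 0, lo
        for i in range(lo, hi):
            gain = (
                params.match_weight
                if seq[i] == cons[(i - start) % period]
                else -params.mismatch_penalty
            )
            if running <= 0:
                running, run_start = 0, i
            running += gain
            if running > best_sum:
                best_sum, best = running, (run_start, i + 1)
        if best is None:
            break
        new_start, new_end = best
        if (new_start, new_end) == (start, end):
            break
        # re-anchor the consensus phase to the new start
        shift = (new_start - start) % period
        start, end = new_start, new_end
        cons = cons[shift:] + cons[:shift]
    return start, end, _consensus_for(seq, start, end, period)


def _seed_segments(match: list[bool], params: RepeatScanParams) -> list[tuple[int, int]]:
    """High-scoring runs in a boolean self-match profile (Kadane-style)."""
    segments = []
    score = 0
    seg_start = 0
    best_score, best_end = 0, -1
    for i, m in enumerate(match):
        gain = params.match_weight if m else -params.mismatch_penalty
        if score <= 0:
            if best_end >= seg_start and best_score >= 2 * params.match_weight * 4:
                segments.append((seg_start, best_end))
            score = 0
            seg_start = i
            best_score, best_end = 0, -1
        score += gain
        if score > best_score:
            best_score, best_end = score, i
    if best_end >= seg_start and best_score >= 2 * params.match_weight * 4:
        segments.append((seg_start, best_end))
    return segments


def find_tandem_repeats(
    seq: str, params: RepeatScanParams | None = None
) -> list[TandemRepeat]:
    """Detect tandem arrays of period 1..max_period.

    Overlapping reports with different periods are retained; a report is
    dropped only when a containing report with a period dividing its own
    explains it (a period-p array trivially re-seeds at lag 2p, 3p, ...).
    """
    params = params or RepeatScanParams()
    seq = seq.upper()
    L = len(seq)
    raw: list[TandemRepeat] = []
    for p in range(1, min(params.max_period, L // 2) + 1):
        match = [seq[i] == seq[i + p] for i in range(L - p)]
        for a, b in _seed_segments(match, params):
            # self-match run [a, b] at lag p covers array region [a, b + p]
            start, end = a, min(b + p + 1, L)
            start, end, cons = _refine(seq, start, end, p, params)
            if end - start < 2 * p:
                continue
            score, matches = _consensus_score(seq, start, end, p, cons, params)
            copy_number = (end - start) / p
            if score < params.min_alignment_score:
                continue
            if copy_number < params.min_copies:
                continue
            raw.append(
                TandemRepeat(
                    start=start + 1,
                    end=end,
                    period=p,
                    copy_number=round(copy_number, 1),
                    consensus=cons,
                    percent_identity=matches / (end - start),
                    score=score,
                )
            )
    return _dedupe(raw)


def _dedupe(reports: list[TandemRepeat]) -> list[TandemRepeat]:
    reports = sorted(reports, key=lambda r: (r.start, r.period))
    kept: list[TandemRepeat] = []
    for r in reports:
        redundant = False
        for k in kept:
            if k.start == r.start and k.end == r.end and k.period == r.period:
                redundant = True
                break
            overlap = min(k.end, r.end) - max(k.start, r.start) + 1
            if (
                overlap >= 0.9 * r.length
                and k.period <= r.period
                and r.period % k.period == 0
                and k.score >= r.score * 0.5
            ):
                redundant = True
                break
        if not redundant:
            kept.append(r)
    return kept


def longest_homopolymer(seq: str, base: str) -> tuple[int | None, int]:
    """Leftmost maximal run of ``base``: (1-based position, length).

    Returns (None, 0) when the base is absent.
    """
    seq = seq.upper()
    base = base.upper()
    best_pos, best_len = None, 0
    i = 0
    while i < len(seq):
        if seq[i] == base:
            j = i
            while j < len(seq) and seq[j] == base:
                j += 1
            if j - i > best_len:
                best_pos, best_len = i + 1, j - i
            i = j
        else:
            i += 1
    return best_pos, best_len


def _perfect_runs(seq: str, motif: str) -> list[tuple[int, int, int]]:
    """Maximal perfect arrays of ``motif``: 0-based (start, end_excl, copies)."""
    m = len(motif)
    runs = []
    i = 0
    while i + m <= len(seq):
        if seq[i : i + m] == motif:
            j = i
            while j + m <= len(seq) and seq[j : j + m] == motif:
                j += m
            runs.append((i, j, (j - i) // m))
            i = j
        else:
            i += 1
    return runs


def find_microsatellites(
    seq: str,
    motifs: set[str] | list[str],
    min_copies: int = 10,
    flank: int = 25,
) -> list[MicrosatelliteHit]:
    """Maximal perfect or near-perfect (≤1 short interruption) motif arrays.

    Two perfect runs separated by fewer than ``len(motif)`` + 1 bases merge
    into one near-perfect array.  Up to ``flank`` bases of left-flanking
    context are attached to each hit.
    """
    seq = seq.upper()
    hits: list[MicrosatelliteHit] = []
    for motif in sorted(set(m.upper() for m in motifs)):
        if not (1 <= len(motif) <= 6):
            raise ValueError(f"motif length must be 1-6, got {motif!r}")
        runs = _perfect_runs(seq, motif)
        merged: list[tuple[int, int, int, int]] = []  # start, end, copies, interruptions
        for start, end, copies in runs:
            if merged:
                ps, pe, pc, pi = merged[-1]
                gap = start - pe
                if 0 < gap <= len(motif) and pi == 0:
                    merged[-1] = (ps, end, pc + copies, 1)
                    continue
            merged.append((start, end, copies, 0))
        for start, end, copies, interruptions in merged:
            if copies >= min_copies:
                hits.append(
                    MicrosatelliteHit(
                        motif=motif,
                        copies=copies,
                        start=start + 1,
                        end=end,
                        interruptions=interruptions,
                        left_flank=seq[max(0, start - flank) : start],
                    )
                )
    hits.sort(key=lambda h: h.start)
    return hits


def _union_bp(repeats: list[TandemRepeat]) -> int:
    intervals = sorted((r.start, r.end) for r in repeats)
    total = 0
    cur_start, cur_end = None, None
    for s, e in intervals:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def cr_report(
    genome: CircularGenome,
    table: AnnotationTable,
    params: RepeatScanParams | None = None,
    microsat_motifs: set[str] = frozenset({"TA"}),
    microsat_min_copies: int = 10,
) -> CRReport:
    """Assemble the control-region organization report.

    ``tr_total_bp`` sums reported repeat lengths without de-overlapping
    (overlapping arrays each contribute fully); the de-overlapped union is
    reported separately as ``tr_union_bp``.
    """
    cr_features = table.of_class("CR")
    if not cr_features:
        raise KeyError("annotation table has no CR feature")
    cr = cr_features[0]
    seq = extract_region(genome, cr.start, cr.end, "J")
    repeats = find_tandem_repeats(seq, params)
    tr_total = sum(r.length for r in repeats)
    return CRReport(
        cr_length=len(seq),
        at_content=sequence_stats(seq).at_content,
        repeats=repeats,
        longest_poly_t=longest_homopolymer(seq, "T"),
        microsatellites=find_microsatellites(
            seq, microsat_motifs, min_copies=microsat_min_copies
        ),
        tr_total_bp=tr_total,
        tr_fraction_of_cr=tr_total / len(seq) if len(seq) else 0.0,
        tr_union_bp=_union_bp(repeats),
    )


def repeats_dataframe(repeats: list[TandemRepeat]) -> pd.DataFrame:
    """TRF data-file style table of detected repeats."""
    return pd.DataFrame(
        [
            {
                "Start": r.start,
                "End": r.end,
                "Period": r.period,
                "Copies": r.copy_number,
                "ConsensusSize": len(r.consensus),
                "PercentMatches": round(100 * r.percent_identity, 1),
                "Score": r.score,
                "Consensus": r.consensus,
            }
            for r in repeats
        ]
    )
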