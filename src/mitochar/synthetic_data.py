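"""Synthetic mitogenome generator with a complete ground-truth manifest.

Generates a fully specified circular mitogenome — sequence, annotation and a
manifest of every planted feature — with the statistical structure the
characterization pipeline assumes, so each stage can be tested without any
external download.  The default spec reproduces the bundled reference gene
layout verbatim (so the annotation fixture and the synthetic genome share one
source of truth) and targets the reference composition: 78.79% AT with
AT-skew 0.037 and GC-skew −0.202 genome-wide, an 88.62% AT control region
carrying a 19 bp poly-T stretch, a (TA)24 microsatellite and seven planted
tandem repeats totaling 238 bp.

Construction notes:

* Intergenic/rRNA/CR background is drawn from the factorized per-base
  distribution implied by the content/skew targets (p_A = at·(1+skew)/2,
  etc.).  The non-CR target is analytically lowered so that the genome-wide
  expectation, CR included, equals the requested AT content; genome-wide
  values are therefore targets in expectation, with binomial noise.
* PCGs are built as declared start codon + random internal codons + declared
  stop (complete TAA/TAG or a trailing T/TA).  Internal codons are drawn
  from the non-stop codons of the invertebrate mitochondrial code with a
  fixed-point-adjusted base distribution, so the no-internal-stop property
  is exact by construction and composition stays on target.  Genes
  overlapping in the layout are reconciled by conditioning codon draws on
  already-planted bases (declared start/stop codons are written first and
  never violated).
* tRNAs are assembled arm-by-arm with exact complementary stems (optionally
  one planted U-U/A-G/G-U apposition per stem); rejection sampling ensures
  the planted structure is the unique template optimum, so the manifest's
  pairing is exact ground truth.
* Planted repeat arrays get mismatching guard bases at their flanks so
  detected boundaries equal planted boundaries.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .genome_io import AnnotationTable, CircularGenome, FeatureRecord
from . import trna_fold
from .trna_fold import CloverleafStructure, StemRanges, to_rna

__all__ = [
    "SyntheticSpec",
    "PlantedRepeat",
    "Manifest",
    "generate_genome",
    "generate_trna",
    "simulate_alignment",
    "default_spec",
]

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# spec and manifest containers

@dataclass(frozen=True)
class PlantedRepeat:
    """One tandem array to plant, in 1-based CR-local coordinates."""

    period: int
    copies: float
    cr_start: int
    identity: float = 1.0

    @property
    def length(self) -> int:
        return int(round(self.period * self.copies))

    @property
    def cr_end(self) -> int:
        return self.cr_start + self.length - 1


#: seven arrays totaling 238 bp; the second is the (TA)24 microsatellite
DEFAULT_REPEATS = (
    PlantedRepeat(period=10, copies=3.0, cr_start=41),
    PlantedRepeat(period=2, copies=24.0, cr_start=136),
    PlantedRepeat(period=16, copies=2.5, cr_start=260),
    PlantedRepeat(period=7, copies=4.0, cr_start=420),
    PlantedRepeat(period=9, copies=3.0, cr_start=560),
    PlantedRepeat(period=6, copies=4.5, cr_start=700),
    PlantedRepeat(period=19, copies=2.0, cr_start=840),
)

#: DHU / TPsiC stem lengths per reference tRNA (acceptor 7, anticodon 5
#: everywhere); trnS1 carries the short 2 bp DHU stem seen in the reference
DEFAULT_TRNA_STEMS: dict[str, tuple[int, int]] = {
    "trnI": (4, 5), "trnQ": (5, 5), "trnM": (5, 5), "trnW": (4, 5),
    "trnC": (3, 3), "trnY": (2, 4), "trnL2": (3, 4), "trnK": (5, 5),
    "trnD": (4, 4), "trnA": (3, 4), "trnR": (3, 4), "trnN": (4, 4),
    "trnS1": (2, 4), "trnE": (4, 4), "trnF": (4, 4), "trnH": (3, 4),
    "trnT": (4, 4), "trnP": (3, 4), "trnL1": (4, 6), "trnV": (4, 3),
    "trnS2": (3, 4), "trnG": (4, 4),
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome; defaults emulate the reference."""

    seed: int = 1
    genome_length: int = 16137
    target_at_content: float = 0.7879
    target_at_skew: float = 0.037
    target_gc_skew: float = -0.202
    cr_at_content: float = 0.8862
    cr_at_skew: float = 0.005
    cr_gc_skew: float = -0.125
    gene_layout: AnnotationTable | None = None  # None -> bundled reference
    planted_repeats: tuple[PlantedRepeat, ...] = DEFAULT_REPEATS
    poly_t_length: int = 19
    poly_t_cr_start: int = 111
    microsatellite: tuple[str, float] = ("TA", 24.0)
    trna_stems: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_TRNA_STEMS)
    )


@dataclass
class TrnaTruth:
    """Planted structure of one tRNA (sense-strand local coordinates)."""

    name: str
    sequence: str  # DNA, sense strand
    structure: CloverleafStructure


@dataclass
class Manifest:
    """Ground truth sufficient to predict every downstream module's output."""

    spec: SyntheticSpec
    layout: AnnotationTable
    codon_counts: dict[str, int]
    total_internal_codons: int
    cds_info: dict[str, dict]
    trnas: dict[str, TrnaTruth]
    repeats: tuple[PlantedRepeat, ...]
    repeat_arrays: dict[int, str]  # index -> planted array sequence
    poly_t: tuple[int, int]  # CR-local 1-based start, length
    microsatellite: tuple[str, int, int]  # motif, copies, CR-local start


# ---------------------------------------------------------------------------
# composition machinery

def _base_probs(at: float, at_skew: float, gc_skew: float) -> dict[str, float]:
    gc = 1.0 - at
    return {
        "A": at * (1 + at_skew) / 2,
        "T": at * (1 - at_skew) / 2,
        "G": gc * (1 + gc_skew) / 2,
        "C": gc * (1 - gc_skew) / 2,
    }


def _sample_bases(rng: np.random.Generator, probs: dict[str, float], n: int) -> list[str]:
    p = np.array([probs[b] for b in _BASES])
    p = p / p.sum()
    return list(rng.choice(_BASES, size=n, p=p))


def _weighted_choice(
    rng: np.random.Generator, probs: dict[str, float], choices: list[str]
) -> str:
    """One base from ``choices``, weighted by the target distribution (so
    constrained guard positions do not drift the composition)."""
    w = np.array([probs[b] for b in choices])
    w = w / w.sum()
    return choices[int(rng.choice(len(choices), p=w))]


def _nonstop_codons(code_id: int = 5) -> list[str]:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    stops = set(table.stop_codons)
    return [
        a + b + c
        for a in "TCAG"
        for b in "TCAG"
        for c in "TCAG"
        if a + b + c not in stops
    ]


def _adjusted_codon_probs(
    target: dict[str, float], code_id: int = 5
) -> tuple[list[str], np.ndarray]:
    """Non-stop codon distribution whose per-base marginal matches ``target``.

    Fixed-point iteration on the per-base weights: excluding the (AT-rich)
    stop codons from a product distribution would otherwise bias composition
    below the target.
    """
    codons = _nonstop_codons(code_id)
    q = dict(target)
    for _ in range(200):
        w = np.array([q[c[0]] * q[c[1]] * q[c[2]] for c in codons])
        p = w / w.sum()
        marg = {b: 0.0 for b in _BASES}
        for prob, codon in zip(p, codons):
            for ch in codon:
                marg[ch] += prob / 3
        if max(abs(marg[b] - target[b]) for b in _BASES) < 1e-10:
            break
        for b in _BASES:
            if marg[b] > 0:
                q[b] *= target[b] / marg[b]
        z = sum(q.values())
        q = {b: v / z for b, v in q.items()}
    return codons, p


def _conditional_codon(
    rng: np.random.Generator,
    codons: list[str],
    probs: np.ndarray,
    pattern: tuple[str | None, str | None, str | None],
) -> str:
    mask = np.array(
        [
            all(want is None or c[k] == want for k, want in enumerate(pattern))
            for c in codons
        ]
    )
    if not mask.any():
        raise ValueError(f"no legal codon matches pattern {pattern}")
    p = probs * mask
    p = p / p.sum()
    return codons[int(rng.choice(len(codons), p=p))]


# ---------------------------------------------------------------------------
# tRNA construction

_LOOP_BOUNDS = {"dloop": (3, 9), "dloop_nodhu": (4, 11), "var": (2, 9), "tloop": (3, 9)}


def _solve_loops(length: int, acc: int, dhu: int, ac: int, tps: int) -> tuple[int, int, int]:
    """Distribute the residual length over the D-loop, variable loop and
    T-loop (raises if the target length is infeasible for these stems)."""
    fixed = 2 * acc + 2 + 2 * dhu + 1 + 2 * ac + 7 + 2 * tps + 1
    rem = length - fixed
    dlo, dhi = _LOOP_BOUNDS["dloop" if dhu > 0 else "dloop_nodhu"]
    vlo, vhi = _LOOP_BOUNDS["var"]
    tlo, thi = _LOOP_BOUNDS["tloop"]
    if not (dlo + vlo + tlo <= rem <= dhi + vhi + thi):
        raise ValueError(
            f"tRNA length {length} infeasible for stems "
            f"(acc={acc}, dhu={dhu}, ac={ac}, tpsic={tps}): residual {rem}"
        )
    d, v, t = dlo, vlo, tlo
    rem -= d + v + t
    caps = [("d", dhi - dlo), ("t", thi - tlo), ("v", vhi - vlo)]
    vals = {"d": d, "t": t, "v": v}
    while rem > 0:
        for key, cap in caps:
            if rem > 0 and vals[key] - {"d": dlo, "t": tlo, "v": vlo}[key] < cap:
                vals[key] += 1
                rem -= 1
    return vals["d"], vals["v"], vals["t"]


_MISMATCH_BASES = {"UU": ("T", "T"), "AG": ("A", "G"), "GU": ("G", "T")}


def generate_trna(
    design: tuple[int, int, int, int],
    rng: np.random.Generator | int,
    length: int | None = None,
    anticodon: str = "CAT",
    base_probs: dict[str, float] | None = None,
    fixed: dict[int, str] | None = None,
    mismatches: dict[str, str] | None = None,
    max_tries: int = 4000,
) -> tuple[str, CloverleafStructure]:
    """Build a tRNA with stems ``design`` = (acceptor, dhu, anticodon, tpsic).

    Returns (DNA sense sequence, true structure).  ``fixed`` pins sense-local
    0-based positions to given bases (used for genes overlapping neighbors);
    ``mismatches`` plants one non-canonical apposition per listed arm, e.g.
    ``{"acceptor": "UU", "anticodon": "GU"}``.  Rejection sampling guarantees
    the planted structure is the unique template-consistent optimum.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    acc, dhu, ac, tps = design
    fixed = fixed or {}
    mismatches = mismatches or {}
    anticodon = anticodon.upper().replace("U", "T")
    probs = base_probs or _base_probs(0.7879, 0.037, -0.202)
    if length is None:
        length = 2 * acc + 2 + 2 * dhu + 1 + 2 * ac + 7 + 2 * tps + 1 + 13
    dloop, var, tloop = _solve_loops(length, acc, dhu, ac, tps)

    # index layout (0-based, sense strand)
    i = 0
    acc5 = list(range(i, i + acc)); i += acc
    s1 = list(range(i, i + 2)); i += 2
    dhu5 = list(range(i, i + dhu)); i += dhu
    dlp = list(range(i, i + dloop)); i += dloop
    dhu3 = list(range(i, i + dhu)); i += dhu
    s2 = [i]; i += 1
    ac5 = list(range(i, i + ac)); i += ac
    aclp = list(range(i, i + 7)); i += 7
    ac3 = list(range(i, i + ac)); i += ac
    vlp = list(range(i, i + var)); i += var
    t5 = list(range(i, i + tps)); i += tps
    tlp = list(range(i, i + tloop)); i += tloop
    t3 = list(range(i, i + tps)); i += tps
    acc3 = list(range(i, i + acc)); i += acc
    disc = [i]; i += 1
    assert i == length

    arm_pairs = {
        "acceptor": [(acc5[k], acc3[acc - 1 - k]) for k in range(acc)],
        "dhu": [(dhu5[k], dhu3[dhu - 1 - k]) for k in range(dhu)],
        "anticodon": [(ac5[k], ac3[ac - 1 - k]) for k in range(ac)],
        "tpsic": [(t5[k], t3[tps - 1 - k]) for k in range(tps)],
    }
    # planted-mismatch pair index per arm (never at positions the template
    # matcher cannot tolerate: hairpin termini, outermost extension step)
    mm_index: dict[str, int] = {}
    for arm, cls in mismatches.items():
        n_stem = len(arm_pairs[arm])
        if arm in ("dhu", "tpsic"):
            if n_stem < 3:
                raise ValueError(f"{arm} stem too short for a planted mismatch")
            mm_index[arm] = n_stem // 2 if 0 < n_stem // 2 < n_stem - 1 else 1
        else:
            if n_stem < 2:
                raise ValueError(f"{arm} stem too short for a planted mismatch")
            # extension order: anticodon k=0 innermost, acceptor k=0 at termini
            mm_index[arm] = min(n_stem // 2, n_stem - 2)

    anticodon_positions = aclp[2:5]

    # --- initial assignment ------------------------------------------------
    seq: list[str | None] = [None] * length
    for pos, base in fixed.items():
        seq[pos] = base
    for pos, base in zip(anticodon_positions, anticodon):
        if seq[pos] is not None and seq[pos] != base:
            raise ValueError("fixed base conflicts with anticodon placement")
        seq[pos] = base

    mm_pairs: set[tuple[int, int]] = set()
    # arms whose planted apposition actually breaks pairing (G-U wobbles are
    # pairs for the template matcher, so they do not count here)
    mm_break: set[str] = {arm for arm, cls in mismatches.items() if cls != "GU"}
    pair_partner: dict[int, int] = {}

    def _fill_pair(arm: str, k: int, a: int, b: int) -> None:
        if arm in mm_index and k == mm_index[arm]:
            cls = mismatches[arm]
            x, y = _MISMATCH_BASES[cls]
            if rng.random() < 0.5:
                x, y = y, x
            if (fixed.get(a, x) != x) or (fixed.get(b, y) != y):
                x, y = y, x
            if (fixed.get(a, x) != x) or (fixed.get(b, y) != y):
                raise ValueError(
                    f"fixed bases conflict with planted {cls} mismatch in {arm}"
                )
            seq[a], seq[b] = x, y
            mm_pairs.add((a, b))
            return
        if a in fixed and b in fixed:
            if not trna_fold.is_pair(to_rna(fixed[a]), to_rna(fixed[b])):
                # both bases pinned by overlapping neighbors: absorb the
                # conflict as this stem's one tolerated mismatch, provided
                # the template matcher can tolerate it at this position
                n_stem = len(arm_pairs[arm])
                if arm in mm_index:
                    raise ValueError(
                        f"fixed bases at {a},{b} conflict and {arm} stem "
                        "already carries a mismatch"
                    )
                tolerable = (
                    k <= n_stem - 2
                    if arm == "acceptor"
                    else k >= 1
                    if arm == "anticodon"
                    else 1 <= k <= n_stem - 2
                )
                if not tolerable:
                    raise ValueError(
                        f"fixed bases at {a},{b} cannot pair ({arm} stem)"
                    )
                mm_index[arm] = k
                mm_break.add(arm)
                mm_pairs.add((min(a, b), max(a, b)))
            seq[a], seq[b] = fixed[a], fixed[b]
        elif a in fixed:
            seq[a], seq[b] = fixed[a], _COMP[fixed[a]]
        elif b in fixed:
            seq[a], seq[b] = _COMP[fixed[b]], fixed[b]
        else:
            base = _sample_bases(rng, probs, 1)[0]
            seq[a], seq[b] = base, _COMP[base]

    for arm, pairs in arm_pairs.items():
        for k, (a, b) in enumerate(pairs):
            pair_partner[a], pair_partner[b] = b, a
            _fill_pair(arm, k, a, b)
    for pos in range(length):
        if seq[pos] is None:
            seq[pos] = _sample_bases(rng, probs, 1)[0]

    # --- check-driven surgical repair --------------------------------------
    # the planted structure must be the unique template optimum; each failed
    # check names the offending base appositions, and exactly one of them is
    # broken (or a spurious anchor mutated) per pass
    def _is_mutable(pos: int) -> bool:
        if pos in fixed or pos in anticodon_positions:
            return False
        partner = pair_partner.get(pos)
        if partner is not None:
            a, b = min(pos, partner), max(pos, partner)
            if (a, b) in mm_pairs or partner in fixed:
                return False
        return True

    def _nonpairing_choices(other: str) -> list[str]:
        return [b for b in _BASES if not trna_fold.is_pair(to_rna(b), to_rna(other))
                and not trna_fold.is_pair(to_rna(other), to_rna(b))]

    def _break_apposition(i: int, j: int) -> bool:
        """Make seq[i]/seq[j] non-pairing by changing one mutable side."""
        if not (0 <= i < length and 0 <= j < length):
            return False
        if not trna_fold.is_pair(to_rna(seq[i]), to_rna(seq[j])):
            return False  # already broken; move on to the next apposition
        # randomize which side is mutated, preferring unpaired (loop/spacer)
        # positions most of the time: stem changes ripple to their partner
        sides = [(i, j), (j, i)]
        if (i in pair_partner) == (j in pair_partner):
            if rng.random() < 0.5:
                sides.reverse()
        elif (i in pair_partner) != (rng.random() < 0.25):
            sides.reverse()
        for pos, other in sides:
            if not (0 <= pos < length) or not _is_mutable(pos):
                continue
            choices = _nonpairing_choices(seq[other])
            if not choices:
                continue
            base = _weighted_choice(rng, probs, choices)
            seq[pos] = base
            partner = pair_partner.get(pos)
            if partner is not None:
                seq[partner] = _COMP[base]
            return True
        return False

    def _resample_positions(positions) -> None:
        done: set[int] = set()
        for pos in positions:
            if pos in done or not _is_mutable(pos):
                continue
            partner = pair_partner.get(pos)
            base = _sample_bases(rng, probs, 1)[0]
            seq[pos] = base
            done.add(pos)
            if partner is not None:
                seq[partner] = _COMP[base]
                done.add(partner)

    stall: dict[str, int] = {}
    for attempt in range(max_tries):
        dna = "".join(seq)
        failure = _trna_structure_check(
            dna, anticodon, acc, dhu, ac, tps, arm_pairs, aclp, mm_break
        )
        if failure is None:
            break
        tag, appositions = failure
        if tag == "anchor":
            # mutate one mutable base of the spurious occurrence
            mutated = False
            for pos in appositions:
                p = pos if isinstance(pos, int) else pos[0]
                if _is_mutable(p):
                    choices = [b for b in _BASES if b != seq[p]]
                    seq[p] = _weighted_choice(rng, probs, choices)
                    partner = pair_partner.get(p)
                    if partner is not None:
                        seq[partner] = _COMP[seq[p]]
                    mutated = True
                    break
            if not mutated:
                raise RuntimeError("anticodon anchor conflict within fixed bases")
            continue
        # break one currently-pairing apposition, chosen at random so that
        # two competing alternatives cannot trap the walk in a 2-cycle
        order = list(appositions)
        if len(order) > 1:
            order = [order[k] for k in rng.permutation(len(order))]
        broken = any(_break_apposition(i, j) for i, j in order)
        stall[tag] = stall.get(tag, 0) + 1
        for other_tag in list(stall):
            if other_tag != tag:
                stall[other_tag] = 0
        if not broken or stall.get(tag, 0) > 8:
            # fall back to resampling the arm's own stem pairs
            group = {
                "ac_stem": [p for pr in arm_pairs["anticodon"] for p in pr] + s2 + vlp,
                "acceptor": [p for pr in arm_pairs["acceptor"] for p in pr] + s1 + disc,
                "dhu": [p for pr in arm_pairs["dhu"] for p in pr] + dlp,
                "tpsic": [p for pr in arm_pairs["tpsic"] for p in pr] + tlp,
            }[tag]
            _resample_positions(group)
            stall[tag] = 0
    else:
        raise RuntimeError(
            f"could not construct an unambiguous tRNA in {max_tries} repair "
            f"passes (design {design}, length {length})"
        )
    dna = "".join(seq)

    rna = to_rna(dna)
    structure = CloverleafStructure(
        sequence=rna,
        folded=True,
        acceptor_stem_len=acc,
        dhu_stem_len=dhu,
        anticodon_stem_len=ac,
        tpsic_stem_len=tps,
        dhu_loop_len=dloop,
        anticodon_loop_len=7,
        tpsic_loop_len=tloop,
        variable_loop_len=var,
        anticodon=to_rna(anticodon),
        anticodon_position=anticodon_positions[0] + 1,
    )
    for arm, pairs in arm_pairs.items():
        for a, b in pairs:
            structure.pairs.append((a + 1, b + 1))
            structure.arms[(a + 1, b + 1)] = arm
            cls = trna_fold.classify_pair(rna[a], rna[b])
            if cls != "WatsonCrick":
                structure.mismatches.append((arm, a + 1, b + 1, cls))
    structure.pairs.sort()
    return dna, structure


def _trna_structure_check(
    dna, anticodon, acc, dhu, ac, tps, arm_pairs, aclp, mm_break
):
    """Detect constructs where the template matcher's optimum would differ
    from the planted structure.

    Returns None when the construct is clean; otherwise ("anchor", positions)
    for a spurious anticodon occurrence, or (tag, appositions) naming the
    base appositions whose pairing causes the failure, for targeted repair.
    """
    rna = to_rna(dna)
    n = len(rna)
    planted = {
        (min(a, b), max(a, b)) for pairs in arm_pairs.values() for a, b in pairs
    }

    def _appositions(x, y, d):
        out = []
        for k in range(d):
            i, j = x + k, y + d - 1 - k
            if (min(i, j), max(i, j)) not in planted:
                out.append((i, j))
        return out

    # the planted anticodon occurrence must be the anchor the matcher selects
    occ = [i for i in range(n - 2) if rna[i : i + 3] == to_rna(anticodon)]
    mid = n // 2
    chosen = min(occ, key=lambda i: (abs(i + 1 - mid), i))
    if chosen != aclp[2]:
        return "anchor", list(range(chosen, chosen + 3))

    ranges = StemRanges()
    loop_start, loop_end = aclp[0], aclp[-1]
    # anticodon stem must extend to exactly the planted length
    pairs, mism = trna_fold._extend_stem(
        rna, loop_start - 1, loop_end + 1, ranges.anticodon[1]
    )
    planted_mm = 1 if "anticodon" in mm_break else 0
    if len(pairs) + len(mism) != ac or len(mism) != planted_mm:
        i, j = loop_start - 1 - ac, loop_end + 1 + ac
        return "ac_stem", [(i, j), (i - 1, j + 1)]

    # acceptor: the matcher's preferred 3' tail must be the planted one (1)
    best = None
    for tail in range(0, 5):
        p, m = trna_fold._extend_stem(rna, 0, n - 1 - tail, ranges.acceptor[1], 1, -1)
        score = (len(p) + len(m), -len(m), -tail)
        if best is None or score > best[0]:
            best = (score, tail, len(p) + len(m), len(m))
    _, tail, total, n_mism = best
    if tail != 1 or total != acc or n_mism != (1 if "acceptor" in mm_break else 0):
        # candidate guards: continuation of the planted stem, and the
        # first appositions of the competing 3' tails
        guards = [(acc, n - 2 - acc), (acc + 1, n - 3 - acc), (0, n - 1)]
        guards += [(0, n - 1 - t) for t in (2, 3, 4)]
        return "acceptor", [g for g in guards if g not in planted]

    # DHU region: the best hairpin must be exactly the planted one
    dhu_lo = acc  # between the acceptor 5' stem and the anticodon 5' stem
    dhu_hi = aclp[0] - ac
    found = trna_fold._best_hairpin(rna, dhu_lo, dhu_hi, 1, ranges.dhu[1])
    if dhu == 0:
        if found is not None:
            x, y, d, _ = found
            return "dhu", _appositions(x, y, d)
    else:
        x_true = arm_pairs["dhu"][0][0]
        y_true = min(b for _, b in arm_pairs["dhu"])
        if found is None:
            return "dhu", []
        x, y, d, mks = found
        if (x, y, d) != (x_true, y_true, dhu) or len(mks) != (
            1 if "dhu" in mm_break else 0
        ):
            return "dhu", _appositions(x, y, d)

    # TPsiC region
    t_lo = aclp[-1] + ac + 1
    t_hi = n - 1 - acc  # tail=1: acceptor 3' side starts at n-1-acc
    found = trna_fold._best_hairpin(rna, t_lo, t_hi, ranges.tpsic[0], ranges.tpsic[1])
    if found is None:
        return "tpsic", []
    x, y, d, mks = found
    x_true = arm_pairs["tpsic"][0][0]
    y_true = min(b for _, b in arm_pairs["tpsic"])
    if (x, y, d) != (x_true, y_true, tps) or len(mks) != (
        1 if "tpsic" in mm_break else 0
    ):
        return "tpsic", _appositions(x, y, d)
    return None


# ---------------------------------------------------------------------------
# whole-genome assembly

def default_spec(seed: int = 1) -> SyntheticSpec:
    return SyntheticSpec(seed=seed)


def _layout_or_reference(spec: SyntheticSpec) -> AnnotationTable:
    if spec.gene_layout is not None:
        return spec.gene_layout
    from .datasets import load_reference_annotation

    table = load_reference_annotation()
    return AnnotationTable(
        genome_id="synthetic",
        features=list(table.features),
        genome_length=table.genome_length,
    )


def _sense_to_j(feature: FeatureRecord, p: int) -> int:
    """Sense-local 1-based position -> 1-based J coordinate."""
    return feature.start + p - 1 if feature.strand == "J" else feature.end - p + 1


def _write_sense(genome: list, feature: FeatureRecord, p: int, base: str) -> None:
    j = _sense_to_j(feature, p)
    genome[j - 1] = base if feature.strand == "J" else _COMP[base]


def _read_sense(genome: list, feature: FeatureRecord, p: int) -> str | None:
    j = _sense_to_j(feature, p)
    b = genome[j - 1]
    if b is None:
        return None
    return b if feature.strand == "J" else _COMP[b]


def generate_genome(
    spec: SyntheticSpec,
) -> tuple[CircularGenome, AnnotationTable, Manifest]:
    """Generate (genome, annotation, manifest); deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    layout = _layout_or_reference(spec)
    L = spec.genome_length
    if layout.genome_length != L or max(f.end for f in layout) > L:
        raise ValueError("gene layout does not fit the requested genome length")

    genome: list[str | None] = [None] * L

    cr_feats = layout.of_class("CR")
    cr = cr_feats[0] if cr_feats else None
    cr_len = cr.size if cr is not None else 0
    # lower the non-CR target so the genome-wide expectation hits the target
    if cr_len and L > cr_len:
        at_noncr = (spec.target_at_content * L - spec.cr_at_content * cr_len) / (
            L - cr_len
        )
    else:
        at_noncr = spec.target_at_content
    probs_j = _base_probs(at_noncr, spec.target_at_skew, spec.target_gc_skew)
    probs_n = _base_probs(at_noncr, -spec.target_at_skew, -spec.target_gc_skew)
    probs_cr = _base_probs(spec.cr_at_content, spec.cr_at_skew, spec.cr_gc_skew)

    codons_j, codon_p_j = _adjusted_codon_probs(probs_j)
    codons_n, codon_p_n = _adjusted_codon_probs(probs_n)

    # --- step 1: declared start/stop codons of every PCG (hard constraints)
    pcgs = layout.of_class("PCG")
    for f in pcgs:
        start = (f.declared_start_codon or "ATG").upper()
        stop = (f.declared_stop_codon or "TAA").upper()
        size = f.size
        expected_rem = 0 if len(stop) == 3 else len(stop)
        if size % 3 != expected_rem:
            raise ValueError(
                f"{f.name}: size {size} inconsistent with stop codon {stop!r}"
            )
        for k, base in enumerate(start):
            _write_sense(genome, f, k + 1, base)
        for k, base in enumerate(stop):
            _write_sense(genome, f, size - len(stop) + k + 1, base)

    # --- step 2: internal codons, conditioned on already-planted bases
    codon_counts: dict[str, int] = {}
    cds_info: dict[str, dict] = {}
    # remember where each internal codon landed so a later tRNA whose stem
    # constraints clash with a neighboring gene's codon can have it redrawn
    codon_record: dict[tuple[str, int], tuple[list[int], str]] = {}
    pcg_by_name = {f.name: f for f in pcgs}
    for f in pcgs:
        stop = (f.declared_stop_codon or "TAA").upper()
        complete = len(stop) == 3
        codons, cprobs = (codons_j, codon_p_j) if f.strand == "J" else (
            codons_n, codon_p_n
        )
        n_full = f.size // 3
        last_internal = n_full - 1 if complete else n_full
        n_internal = 0
        for ci in range(1, last_internal):
            pat = tuple(_read_sense(genome, f, 3 * ci + 1 + k) for k in range(3))
            codon = _conditional_codon(rng, codons, cprobs, pat)
            positions = []
            for k, base in enumerate(codon):
                _write_sense(genome, f, 3 * ci + 1 + k, base)
                positions.append(_sense_to_j(f, 3 * ci + 1 + k) - 1)
            codon_record[(f.name, ci)] = (positions, codon)
            codon_counts[codon] = codon_counts.get(codon, 0) + 1
            n_internal += 1
        cds_info[f.name] = {
            "start_codon": (f.declared_start_codon or "ATG").upper(),
            "stop_codon": stop,
            "stop_complete": complete,
            "n_internal_codons": n_internal,
        }

    # --- step 3: tRNAs, honoring bases already planted by overlapping genes
    trnas: dict[str, TrnaTruth] = {}
    protected: set[int] = set()  # J positions inside already-planted tRNAs

    def _redraw_overlapping_codons(f: FeatureRecord) -> bool:
        """Redraw PCG internal codons inside this tRNA's span (used when the
        tRNA cannot absorb the bases as stem pairs plus one mismatch)."""
        span = set(range(f.start - 1, f.end))
        changed = False
        for (gene, ci), (positions, old_codon) in list(codon_record.items()):
            if not (span & set(positions)) or (protected & set(positions)):
                continue
            g = pcg_by_name[gene]
            for k, pos in enumerate(positions):
                if pos not in protected:
                    genome[pos] = None
            pat = tuple(
                _read_sense(genome, g, 3 * ci + 1 + k) for k in range(3)
            )
            codons, cprobs = (codons_j, codon_p_j) if g.strand == "J" else (
                codons_n, codon_p_n
            )
            new_codon = _conditional_codon(rng, codons, cprobs, pat)
            for k, base in enumerate(new_codon):
                _write_sense(genome, g, 3 * ci + 1 + k, base)
            codon_record[(gene, ci)] = (positions, new_codon)
            codon_counts[old_codon] -= 1
            codon_counts[new_codon] = codon_counts.get(new_codon, 0) + 1
            changed = True
        return changed

    for f in layout.of_class("tRNA"):
        d_stem, t_stem = spec.trna_stems.get(f.name, (4, 5))
        design = (7, d_stem, 5, t_stem)
        probs = probs_j if f.strand == "J" else probs_n
        for attempt in range(60):
            fixed = {}
            for p in range(1, f.size + 1):
                b = _read_sense(genome, f, p)
                if b is not None:
                    fixed[p - 1] = b
            try:
                dna, structure = generate_trna(
                    design,
                    rng,
                    length=f.size,
                    anticodon=f.anticodon or "CAT",
                    base_probs=probs,
                    fixed=fixed,
                )
                break
            except ValueError:
                if not _redraw_overlapping_codons(f):
                    raise
        else:
            raise RuntimeError(f"{f.name}: could not reconcile overlap constraints")
        for p, base in enumerate(dna, start=1):
            _write_sense(genome, f, p, base)
        protected.update(range(f.start - 1, f.end))
        trnas[f.name] = TrnaTruth(name=f.name, sequence=dna, structure=structure)

    # --- step 4: background for rRNAs and intergenic space (non-CR)
    cr_range = range(cr.start - 1, cr.end) if cr is not None else range(0)
    cr_set = set(cr_range)
    unfilled = [i for i in range(L) if genome[i] is None and i not in cr_set]
    for i, base in zip(unfilled, _sample_bases(rng, probs_j, len(unfilled))):
        genome[i] = base

    # --- step 5: control region with planted features
    poly_t = (spec.poly_t_cr_start, spec.poly_t_length)
    ms_motif, ms_copies = spec.microsatellite
    repeat_arrays: dict[int, str] = {}
    if cr is not None:
        cr_seq = _build_cr(rng, spec, cr_len, probs_cr, repeat_arrays)
        for k, base in enumerate(cr_seq):
            genome[cr.start - 1 + k] = base

    sequence = "".join(genome)
    cg = CircularGenome(id=f"synthetic_seed{spec.seed}", sequence=sequence)
    ms_rep = _microsat_repeat(spec)
    manifest = Manifest(
        spec=spec,
        layout=layout,
        codon_counts=codon_counts,
        total_internal_codons=sum(codon_counts.values()),
        cds_info=cds_info,
        trnas=trnas,
        repeats=spec.planted_repeats,
        repeat_arrays=repeat_arrays,
        poly_t=poly_t,
        microsatellite=(
            ms_motif,
            int(ms_copies),
            ms_rep.cr_start if ms_rep is not None else 0,
        ),
    )
    return cg, layout, manifest


def _has_low_period_structure(arr: str, period: int) -> bool:
    """True when the tiled array effectively has a smaller period (>= 70%
    self-identity at some lag below its own), which would confuse both the
    manifest and the detector."""
    for d in range(1, period):
        matches = sum(1 for i in range(len(arr) - d) if arr[i] == arr[i + d])
        if len(arr) - d > 0 and matches / (len(arr) - d) >= 0.7:
            return True
    return False


def _longest_t_run(s: str) -> int:
    best = cur = 0
    for ch in s:
        cur = cur + 1 if ch == "T" else 0
        best = max(best, cur)
    return best


def _build_cr(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    cr_len: int,
    probs_cr: dict[str, float],
    repeat_arrays: dict[int, str],
) -> str:
    """Assemble the control region: AT-rich background plus the planted
    poly-T stretch, (TA)n microsatellite and tandem arrays, with guard bases
    preventing accidental array extension or run merging."""
    seq = _sample_bases(rng, probs_cr, cr_len)

    # background must not out-compete the planted poly-T stretch
    for _ in range(50):
        changed = False
        run = 0
        for i, ch in enumerate(seq):
            run = run + 1 if ch == "T" else 0
            if run >= spec.poly_t_length - 4:
                seq[i] = "A"
                run = 0
                changed = True
        if not changed:
            break

    pt_start, pt_len = spec.poly_t_cr_start, spec.poly_t_length
    for k in range(pt_len):
        seq[pt_start - 1 + k] = "T"
    # guards: the planted run must be leftmost-maximal and exactly this long
    if pt_start - 2 >= 0:
        seq[pt_start - 2] = "A"
    if pt_start - 1 + pt_len < cr_len:
        seq[pt_start - 1 + pt_len] = "A"

    ms_motif, _ = spec.microsatellite
    for idx, rep in enumerate(spec.planted_repeats):
        p, arr_len = rep.period, rep.length
        if rep.cr_end > cr_len:
            raise ValueError(f"planted repeat {idx} overflows the control region")
        if rep is _microsat_repeat(spec):
            consensus = ms_motif
        else:
            for _ in range(500):
                consensus = "".join(_sample_bases(rng, probs_cr, p))
                tiled = (consensus * (arr_len // p + 2))[:arr_len]
                if p > 1 and _has_low_period_structure(tiled, p):
                    continue
                if _longest_t_run(tiled + tiled[: p]) >= spec.poly_t_length - 4:
                    continue
                break
            else:
                raise RuntimeError(f"could not sample a consensus for repeat {idx}")
        array = (consensus * (arr_len // p + 2))[:arr_len]
        if rep.identity < 1.0:
            n_mm = int(round(arr_len * (1 - rep.identity)))
            if n_mm:
                positions = np.linspace(p // 2, arr_len - 1 - p // 2, n_mm).astype(int)
                array = list(array)
                for pos in positions:
                    others = [b for b in _BASES if b != array[pos]]
                    array[pos] = others[int(rng.integers(len(others)))]
                array = "".join(array)
        start0 = rep.cr_start - 1
        seq[start0 : start0 + arr_len] = list(array)
        repeat_arrays[idx] = array
        # guard bases: break the period at both flanks
        for off in range(1, 4):
            left = start0 - off
            if left >= 0 and left + p < cr_len:
                if seq[left] == seq[left + p]:
                    seq[left] = _other_base(rng, seq[left + p], probs_cr)
            right = start0 + arr_len - 1 + off
            if right < cr_len and right - p >= 0:
                if seq[right] == seq[right - p]:
                    seq[right] = _other_base(rng, seq[right - p], probs_cr)

    # microsatellite guards: no stray motif copy next to the planted array,
    # and a left-flank base that can neither extend the poly-T run nor the
    # period-2 array (C/G satisfies both)
    ms = _microsat_repeat(spec)
    if ms is not None:
        start0, end0 = ms.cr_start - 1, ms.cr_end - 1
        if start0 >= 1:
            seq[start0 - 1] = "C"
        if start0 - 2 >= 0 and "".join(seq[start0 - 2 : start0]) == ms_motif:
            seq[start0 - 2] = _other_base(rng, seq[start0 - 2], probs_cr)
        if end0 + 2 < cr_len and "".join(seq[end0 + 1 : end0 + 3]) == ms_motif:
            seq[end0 + 2] = _other_base(rng, seq[end0 + 2], probs_cr)

    _suppress_background_structure(rng, spec, seq, probs_cr)
    return "".join(seq)


def _suppress_background_structure(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    seq: list[str],
    probs_cr: dict[str, float],
) -> None:
    """Break chance background arrays that would compete with the planted
    features, so the manifest stays a complete prediction of the scan output.

    AT-rich background occasionally contains tandem arrays above the score
    threshold or motif runs adjacent to the planted microsatellite; one base
    inside each such interval is mutated until none remain.
    """
    from . import repeat_scan as rs

    planted = [(r.cr_start - 1, r.cr_end - 1) for r in spec.planted_repeats]
    pt0 = spec.poly_t_cr_start - 1
    protected = set()
    for a, b in planted:
        protected.update(range(a, b + 1))
    protected.update(range(pt0, pt0 + spec.poly_t_length))

    def _overlaps_planted(a0: int, b0: int) -> bool:
        for a, b in planted:
            inter = min(b, b0) - max(a, a0) + 1
            if inter >= 0.5 * (b0 - a0 + 1):
                return True
        return False

    ms_motif, _ = spec.microsatellite
    ms = _microsat_repeat(spec)
    for _ in range(20):
        dirty = False
        for rep in rs.find_tandem_repeats("".join(seq)):
            a0, b0 = rep.start - 1, rep.end - 1
            if _overlaps_planted(a0, b0):
                continue
            free = [i for i in range(a0, b0 + 1) if i not in protected]
            if not free:
                continue
            pos = free[len(free) // 2]
            seq[pos] = _other_base(rng, seq[pos], probs_cr)
            dirty = True
        # stray motif runs: long enough to be reported on their own, or
        # close enough to the planted array to merge with it
        for a0, b0, copies in rs._perfect_runs("".join(seq), ms_motif):
            inside = ms is not None and a0 >= ms.cr_start - 1 and b0 <= ms.cr_end
            if inside:
                continue
            near = ms is not None and (
                0 <= (ms.cr_start - 1) - b0 <= len(ms_motif) + 1
                or 0 <= a0 - ms.cr_end <= len(ms_motif) + 1
            )
            if copies >= 8 or near:
                free = [i for i in range(a0, b0) if i not in protected]
                if free:
                    seq[free[len(free) // 2]] = _other_base(
                        rng, seq[free[len(free) // 2]], probs_cr
                    )
                    dirty = True
        if not dirty:
            break


def _microsat_repeat(spec: SyntheticSpec) -> PlantedRepeat | None:
    """The planted array representing the microsatellite (period = motif
    length), if any."""
    motif, _ = spec.microsatellite
    for rep in spec.planted_repeats:
        if rep.period == len(motif):
            return rep
    return None


def _other_base(
    rng: np.random.Generator, base: str, probs: dict[str, float] | None = None
) -> str:
    others = [b for b in _BASES if b != base]
    if probs is None:
        return others[int(rng.integers(len(others)))]
    return _weighted_choice(rng, probs, others)


# ---------------------------------------------------------------------------
# alignment simulation for the supermatrix stage

_JC_BASES = np.array(list("ACGT"))


def simulate_alignment(
    tree: str,
    rate: float = 1.0,
    lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Simulate gapless per-gene alignments by Jukes-Cantor evolution along a
    newick tree with branch lengths in substitutions/site (scaled by
    ``rate``).

    Returns {gene: {taxon: sequence}}; deterministic given the seed.
    """
    import dendropy

    if lengths is None:
        lengths = {f"gene{i:02d}": 300 for i in range(1, 14)}
    t = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, str]] = {}
    for gene, n_sites in lengths.items():
        root_seq = rng.integers(0, 4, size=n_sites)
        seqs: dict[int, np.ndarray] = {id(t.seed_node): root_seq}
        for node in t.preorder_node_iter():
            if node is t.seed_node:
                continue
            parent_seq = seqs[id(node.parent_node)]
            d = (node.edge.length or 0.0) * rate
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            child = parent_seq.copy()
            hit = rng.random(n_sites) < p_change
            if hit.any():
                shifts = rng.integers(1, 4, size=int(hit.sum()))
                child[hit] = (child[hit] + shifts) % 4
            seqs[id(node)] = child
        out[gene] = {
            leaf.taxon.label.replace(" ", "_"): "".join(
                _JC_BASES[seqs[id(leaf)]]
            )
            for leaf in t.leaf_node_iter()
        }
    return out
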