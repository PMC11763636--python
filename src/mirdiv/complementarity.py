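"""Pairwise complementarity scoring between miRNA sequences.

A plant miRNA can stand in for a depleted human miRNA only if the two are
functionally interchangeable, and sequence similarity is the standard proxy
for interchangeability (roughly 50% identity can suffice in animals, 80-90%
in plants).  This module scores a pair of mature miRNA sequences with a
bounded identity-style statistic:

    value = matched_positions / len(shorter sequence)  in [0, 1]

under one of three alignment modes:

* ``global``  - Needleman-Wunsch over the full lengths (default: the
  percent-similarity reading of interchangeability),
* ``local``   - Smith-Waterman best segment,
* ``duplex``  - global alignment of one sequence against the reverse
  Watson-Crick complement of the other (A:U, C:G), i.e. the score of the
  hybridization duplex; G·U wobble pairs optionally count as matches.

Scoring uses match=1, mismatch=0, gap=-1 by default.  The dynamic program
maximizes (score, matched_positions) lexicographically: among all
score-optimal alignments, the one with the most match columns defines
``matched_positions``, so the reported value is a well-defined function of
the pair rather than an artifact of traceback order.  Remaining ties prefer
diagonal over up over left moves, making every score bit-reproducible.

Plant candidates are ranked by the *margin* delta = (average complementarity
to the down-regulated human set) - (average complementarity to the
up-regulated set): a useful substitute resembles what the tumor lacks and
not what it already over-produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .io_formats import SequenceRecord

__all__ = [
    "AlignmentParams",
    "ComplementarityScore",
    "PlantRanking",
    "reverse_complement",
    "align_pair",
    "average_complementarity",
    "rank_plant_mirnas",
    "delta_exceed_fraction",
]

Mode = Literal["global", "local", "duplex"]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
#: In reverse-complement space a G·U wobble pair appears as G vs A or U vs C.
_WOBBLE_RC_PAIRS = frozenset({("G", "A"), ("U", "C")})

DEFAULT_DELTA_THRESHOLD = 0.10


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and mode for pairwise complementarity."""

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.0
    mode: Mode = "global"
    allow_wobble: bool = False

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap > self.mismatch:
            raise ValueError("gap score must not exceed the mismatch score")
        if self.mode not in ("global", "local", "duplex"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.allow_wobble and self.mode != "duplex":
            raise ValueError("G·U wobble pairing only applies to duplex mode")


@dataclass(frozen=True)
class ComplementarityScore:
    """A bounded [0,1] similarity between two sequences under one mode."""

    value: float
    mode: Mode
    matched_positions: int
    denominator: int
    score: float


@dataclass(frozen=True)
class PlantRanking:
    """A plant miRNA's average complementarity to the two human sets."""

    plant_id: str
    avg_comp_down: float
    avg_comp_up: float
    delta: float


def reverse_complement(sequence: str) -> str:
    """Reverse Watson-Crick complement over the RNA alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _as_sequence(seq: SequenceRecord | str) -> str:
    return seq.sequence if isinstance(seq, SequenceRecord) else seq


def _dp_align(
    a: str,
    b: str,
    match: float,
    mismatch: float,
    gap: float,
    local: bool,
    wobble: bool,
) -> tuple[float, int]:
    """Lexicographic-(score, matches) alignment DP.

    Returns the optimal alignment score and the match-column count of the
    score-optimal alignment with the most matches.  ``local`` switches on the
    Smith-Waterman zero floor and best-cell tracking; ``wobble`` additionally
    treats the reverse-complement-space pairs G/A and U/C as matches.
    """
    la, lb = len(a), len(b)
    if local:
        prev_s = [0.0] * (lb + 1)
    else:
        prev_s = [j * gap for j in range(lb + 1)]
    prev_m = [0] * (lb + 1)
    best_s, best_m = 0.0, 0
    for i in range(1, la + 1):
        ca = a[i - 1]
        cur_s = [0.0] * (lb + 1)
        cur_m = [0] * (lb + 1)
        if not local:
            cur_s[0] = i * gap
        for j in range(1, lb + 1):
            cb = b[j - 1]
            eq = ca == cb or (wobble and (ca, cb) in _WOBBLE_RC_PAIRS)
            # Candidate order encodes the diagonal > up > left tie preference.
            s = prev_s[j - 1] + (match if eq else mismatch)
            m = prev_m[j - 1] + eq
            s2 = prev_s[j] + gap
            if s2 > s or (s2 == s and prev_m[j] > m):
                s, m = s2, prev_m[j]
            s3 = cur_s[j - 1] + gap
            if s3 > s or (s3 == s and cur_m[j - 1] > m):
                s, m = s3, cur_m[j - 1]
            if local:
                if s < 0.0:
                    s, m = 0.0, 0
                if s > best_s or (s == best_s and m > best_m):
                    best_s, best_m = s, m
            cur_s[j] = s
            cur_m[j] = m
        prev_s, prev_m = cur_s, cur_m
    if local:
        return best_s, best_m
    return prev_s[lb], prev_m[lb]


def align_pair(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    params: AlignmentParams | None = None,
) -> ComplementarityScore:
    """Score one pair of sequences under the configured mode.

    The value is matched_positions / len(shorter input), so it is a bounded
    fraction regardless of the scoring parameters, and a perfect containment
    scores 1.0 in local mode.
    """
    params = params or AlignmentParams()
    sa, sb = _as_sequence(a), _as_sequence(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    wobble = False
    if params.mode == "duplex":
        sb = reverse_complement(sb)
        wobble = params.allow_wobble
    score, matched = _dp_align(
        sa, sb, params.match, params.mismatch, params.gap,
        local=(params.mode == "local"), wobble=wobble,
    )
    denominator = min(len(sa), len(sb))
    return ComplementarityScore(
        value=matched / denominator,
        mode=params.mode,
        matched_positions=matched,
        denominator=denominator,
        score=score,
    )


def average_complementarity(
    plant: SequenceRecord | str,
    human_set: Sequence[SequenceRecord | str],
    params: AlignmentParams | None = None,
) -> float:
    """Unweighted mean pairwise value between one plant and a human set."""
    if not human_set:
        raise ValueError("empty human set")
    return sum(align_pair(plant, h, params).value for h in human_set) / len(human_set)


def rank_plant_mirnas(
    plants: Sequence[SequenceRecord],
    down_set: Sequence[SequenceRecord | str],
    up_set: Sequence[SequenceRecord | str],
    params: AlignmentParams | None = None,
) -> list[PlantRanking]:
    """Rank plant miRNAs as substitutes for the down-regulated human set.

    Sorted by delta = avg_comp_down - avg_comp_up descending (the substitute
    criterion: closest to the depleted set, farthest from the over-expressed
    one), then by avg_comp_down descending, then plant id.
    """
    if not plants:
        raise ValueError("no plant sequences to rank")
    if not down_set or not up_set:
        raise ValueError("both human sets must be non-empty")
    rankings = []
    for plant in plants:
        down_avg = average_complementarity(plant, down_set, params)
        up_avg = average_complementarity(plant, up_set, params)
        rankings.append(
            PlantRanking(
                plant_id=plant.seq_id,
                avg_comp_down=down_avg,
                avg_comp_up=up_avg,
                delta=down_avg - up_avg,
            )
        )
    rankings.sort(key=lambda r: (-r.delta, -r.avg_comp_down, r.plant_id))
    return rankings


def delta_exceed_fraction(
    rankings: Sequence[PlantRanking], threshold: float = DEFAULT_DELTA_THRESHOLD
) -> float:
    """Fraction of plants whose |delta| exceeds the threshold.

    Measures how much of the plant library discriminates between the down-
    and up-regulated human sets at all; near zero means the library's
    miRNAs would compensate each other.
    """
    if not rankings:
        raise ValueError("no rankings")
    return sum(1 for r in rankings if abs(r.delta) > threshold) / len(rankings)
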