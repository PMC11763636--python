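"""Exhaustive alignment oracle for short sequences.

Independent of the package's dynamic program: an alignment is identified
with a monotone set of paired positions (strictly increasing in both
sequences); unpaired positions are gaps.  For global alignments every
unpaired position of either sequence is a gap; for local alignments only
positions between the first and last pair count (ends are trimmed free) and
the empty alignment scores (0, 0).  The oracle enumerates every monotone
pairing and returns the lexicographic maximum of (score, n_matches), which
is exactly what the DP is supposed to compute.

Feasible only for sequences of length <= ~8 (C(16, 8) = 12,870 pairings).
"""

from __future__ import annotations

from typing import Callable


def _default_eq(x: str, y: str) -> bool:
    return x == y


def best_alignment_bruteforce(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
    local: bool = False,
    eq: Callable[[str, str], bool] = _default_eq,
) -> tuple[float, int]:
    """Max (score, n_matches) over all alignments, by full enumeration."""
    la, lb = len(a), len(b)
    if local:
        best = (0.0, 0)
    else:
        best = (gap * (la + lb), 0)

    def rec(i0, j0, pair_score, n_pairs, n_matches, first_i, first_j):
        nonlocal best
        for i in range(i0, la):
            for j in range(j0, lb):
                is_match = eq(a[i], b[j])
                ps = pair_score + (match if is_match else mismatch)
                nm = n_matches + is_match
                np_ = n_pairs + 1
                fi = first_i if n_pairs else i
                fj = first_j if n_pairs else j
                if local:
                    n_gaps = (i - fi + 1) + (j - fj + 1) - 2 * np_
                else:
                    n_gaps = la + lb - 2 * np_
                cand = (ps + gap * n_gaps, nm)
                if cand > best:
                    best = cand
                rec(i + 1, j + 1, ps, np_, nm, fi, fj)

    rec(0, 0, 0.0, 0, 0, 0, 0)
    return best
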