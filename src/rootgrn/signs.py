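"""Edge-sign assignment from an ordered time course (lag-1 majority vote).

The first-order Markov reading of a time course: if a target moves in the
same direction one time point after its regulator moved, that transition
votes for activation (+1); opposite directions vote for repression (-1).
Votes are pooled over all transition pairs (and, by default, over zones) and
the edge takes the majority sign, with 0 recording an ambiguous (tied or
uninformative) edge.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import SignedEdge, TimeCourse, WeightedEdge
from .errors import InvalidArgument

#: deltas with absolute value at or below this (raw expression scale) are
#: treated as "no change", hence uninformative
ZERO_TOL = 1e-12


def _sgn(x: float, tol: float) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


def transition_signs(a_series: Sequence[float], b_series: Sequence[float],
                     tol: float = ZERO_TOL) -> list[int]:
    """Per-transition regulation signs of the lag-1 rule.

    For series of length T there are T-2 sign entries: entry k pairs the
    regulator's change over transition k with the target's change over
    transition k+1, i.e. ``sgn(A[k+1]-A[k]) * sgn(B[k+2]-B[k+1])``; a zero
    delta on either side makes the entry 0 (uninformative).
    """
    a = np.asarray(a_series, dtype=float)
    b = np.asarray(b_series, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgument(
            f"series must be 1-D and equal length, got {a.shape} vs {b.shape}")
    if a.size < 3:
        raise InvalidArgument(f"need >= 3 timepoints, got {a.size}")
    da = np.diff(a)
    db = np.diff(b)
    return [_sgn(da[k], tol) * _sgn(db[k + 1], tol)
            for k in range(a.size - 2)]


def majority_sign(signs: Sequence[int]) -> int:
    """Majority vote over per-transition signs; zeros are not votes.

    Returns +1 / -1 on a strict majority, else 0 (tie or no informative
    transitions).
    """
    pos = sum(1 for s in signs if s > 0)
    neg = sum(1 for s in signs if s < 0)
    if pos > neg:
        return 1
    if neg > pos:
        return -1
    return 0


def assign_signs(edges: Sequence[WeightedEdge], tc: TimeCourse,
                 per_zone: bool = False, tol: float = ZERO_TOL
                 ) -> list[SignedEdge]:
    """Annotate each edge with its majority sign and vote tally.

    By default votes are pooled across zones into one tally per edge; with
    ``per_zone=True`` each zone casts one (majority) meta-vote instead.
    Raises ``KeyError`` naming the first edge gene missing from the course.
    """
    genes = set(tc.gene_ids)
    for e in edges:
        for g in (e.regulator, e.target):
            if g not in genes:
                raise KeyError(g)

    out: list[SignedEdge] = []
    for e in edges:
        votes: list[int] = []
        for z in tc.zones:
            a = tc.gene_series(e.regulator, z)
            b = tc.gene_series(e.target, z)
            zone_signs = transition_signs(a, b, tol=tol)
            if per_zone:
                votes.append(majority_sign(zone_signs))
            else:
                votes.extend(zone_signs)
        out.append(SignedEdge(
            regulator=e.regulator, target=e.target, weight=e.weight,
            sign=majority_sign(votes),
            votes_pos=sum(1 for s in votes if s > 0),
            votes_neg=sum(1 for s in votes if s < 0),
        ))
    return out
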