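"""Detection and classification of conflicting predictions across models.

When several sub-group models (e.g. IB vs IC1) predict introns on the
same stretch of genome, overlapping hits are grouped (sharing at least
one nucleotide of genomic interval) and classified: hits with (almost)
the same boundaries and >95% shared conserved positions are a
*conflicting prediction* - two models claiming the same intron - while
the rest are *overlapping introns*, candidate twintrons with distinct
splice boundaries.  Conflicts are resolved by the best (lowest) E-value;
a small E-value margin between the alternatives flags the group as
ambiguous, the signal used to merge sub-groups that cannot be separated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .search import Hit

CONFLICTING = "conflicting_prediction"
OVERLAPPING = "overlapping_introns"


@dataclass
class ConflictGroup:
    """Overlapping hits from >= 2 models plus their classification."""

    hits: tuple[Hit, ...]
    pair_fractions: dict[tuple[int, int], float] = field(default_factory=dict)
    label: str | None = None
    winner: Hit | None = None
    margin: float | None = None  # log10(E_loser / E_winner)
    ambiguous: bool = False

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(sorted({h.model for h in self.hits}))

    @property
    def candidate_twintron(self) -> bool:
        return self.label == OVERLAPPING


def _spans_overlap(a: Hit, b: Hit) -> bool:
    # 1-based inclusive: touching intervals do not share a nucleotide
    return a.contig == b.contig and a.start <= b.end and b.start <= a.end


def group_overlaps(hits: Sequence[Hit]) -> list[ConflictGroup]:
    """Connected components of the cross-model interval-overlap graph.

    Same-model overlaps are not edges (they are resolved at search time);
    components need hits from at least two models to form a group.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if hits[i].model != hits[j].model and _spans_overlap(hits[i], hits[j]):
                union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = []
    for members in comps.values():
        if len(members) < 2:
            continue
        if len({hits[i].model for i in members}) < 2:
            continue
        members.sort(key=lambda i: (hits[i].start, hits[i].end, hits[i].model))
        groups.append(ConflictGroup(tuple(hits[i] for i in members)))
    groups.sort(key=lambda g: (g.hits[0].contig, g.hits[0].start))
    return groups


def shared_conserved_fraction(hit1: Hit, hit2: Hit) -> float:
    """Fraction of conserved (element-block) genomic positions shared by
    two hits, normalised by the smaller conserved set."""
    a = hit1.conserved_positions()
    b = hit2.conserved_positions()
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def classify(
    group: ConflictGroup,
    fraction_threshold: float = 0.95,
    coord_tolerance: int = 10,
) -> str:
    """Label a group: `conflicting_prediction` iff every cross-model hit
    pair shares > `fraction_threshold` of conserved positions AND has the
    same (or almost the same, within `coord_tolerance` nt) start and end;
    otherwise `overlapping_introns`."""
    hits = group.hits
    label = CONFLICTING
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if hits[i].model == hits[j].model:
                continue
            frac = shared_conserved_fraction(hits[i], hits[j])
            group.pair_fractions[(i, j)] = frac
            same_coords = (abs(hits[i].start - hits[j].start) <= coord_tolerance
                           and abs(hits[i].end - hits[j].end) <= coord_tolerance)
            if not (frac > fraction_threshold and same_coords):
                label = OVERLAPPING
    group.label = label
    return label


def resolve(
    group: ConflictGroup, ambiguity_orders: float = 2.0
) -> tuple[Hit, float]:
    """Pick the winning hit by lowest E-value.

    The margin is log10(E of the best competing model / E of the winner);
    margins below `ambiguity_orders` flag the group ambiguous (the two
    models cannot be told apart - the sub-group merge signal).
    """
    ranked = sorted(
        group.hits,
        key=lambda h: (h.evalue if h.evalue is not None else math.inf,
                       -h.score))
    winner = ranked[0]
    losers = [h for h in ranked[1:] if h.model != winner.model]
    if not losers or winner.evalue in (None, 0):
        margin = math.inf
    else:
        loser = losers[0]
        if loser.evalue is None:
            margin = math.inf
        else:
            margin = math.log10(loser.evalue / winner.evalue)
    group.winner = winner
    group.margin = margin
    group.ambiguous = margin < ambiguity_orders
    return winner, margin


def conflict_matrix(
    groups: Iterable[ConflictGroup],
    model_names: Sequence[str],
) -> pd.DataFrame:
    """Symmetric count table of groups per unordered model pair.

    Every group counts exactly once, attributed to the pair (winner
    model, best competing model) - for two-model groups this is simply
    the pair of models involved.  The sum over the upper triangle
    (including the diagonal) therefore equals the number of groups.
    """
    mat = pd.DataFrame(0, index=list(model_names), columns=list(model_names),
                       dtype=int)
    for g in groups:
        if g.winner is None:
            resolve(g)
        winner = g.winner.model
        others = sorted(
            (h for h in g.hits if h.model != winner),
            key=lambda h: (h.evalue if h.evalue is not None else math.inf,
                           -h.score))
        other = others[0].model if others else winner
        a, b = sorted((winner, other))
        mat.loc[a, b] += 1
        if a != b:
            mat.loc[b, a] += 1
    return mat
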