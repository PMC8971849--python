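"""Automatic construction of 3-4 level search strategies.

The choice of first-level motifs dominates search speed: well-conserved,
closely spaced, preferentially single-stranded motifs anchor candidate
regions cheaply, later levels apply the remaining constraints, and the
final level always completes the model.  Conservation is measured as
sequence-logo stack height, ``occupancy * (2 - H(p))`` bits per column
with pseudocounted base probabilities, averaged per motif (both strands
for a helix).  This occupancy-weighted information content is a
documented approximation of HMM-based logo heights.

False-positive control is an analytic heuristic: the expected number of
random matches of a motif set in a genome of length ``L`` (both strands)
is taken as ``2 * L * 2**(-I)`` where ``I`` is the summed stack height of
the chosen motifs.  Level one must stay under a configurable budget
(default 10 expected hits/Mb); middle levels add motifs until the budget
tightens to 0.1/Mb.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import StructuredAlignment
from .profiles import Background, ProfileSet, TrainStats
from .search import Level, Strategy, _Gap, _Occ, build_layout


@dataclass(frozen=True)
class MotifConservation:
    """Per-column stack heights (bits) and their mean for one motif."""

    element_id: int
    heights: tuple[float, ...]
    mean: float


def column_heights(
    model: StructuredAlignment,
    pseudocount: float = 1.0,
    background: Background | None = None,
) -> np.ndarray:
    """Gap-penalised logo stack height for every alignment column.

    ``height = occupancy * (2 - H(p))`` where p are the pseudocounted
    base probabilities of the column and occupancy is the non-gap
    fraction; clipped to [0, 2] bits.
    """
    bg = (background or Background.uniform()).array
    n_seq = model.n_sequences
    heights = np.zeros(model.n_columns)
    for c in range(model.n_columns):
        counts = np.zeros(4)
        n_nongap = 0
        for _, seq in model.sequences:
            ch = seq[c]
            if ch == "-":
                continue
            i = "ACGU".find(ch)
            if i >= 0:
                counts[i] += 1
            n_nongap += 1
        if n_nongap == 0:
            continue
        p = (counts + pseudocount * bg) / (counts.sum() + pseudocount)
        entropy = -float(np.sum(p * np.log2(p)))
        occupancy = n_nongap / n_seq
        heights[c] = min(2.0, max(0.0, occupancy * (2.0 - entropy)))
    return heights


def conservation_by_element(
    model: StructuredAlignment,
    pseudocount: float = 1.0,
    background: Background | None = None,
) -> dict[int, MotifConservation]:
    """Average stack height across each distinct motif (helix: both
    strand occurrences)."""
    heights = column_heights(model, pseudocount, background)
    out: dict[int, MotifConservation] = {}
    for e in model.elements:
        cols: list[float] = []
        for s, t in e.occurrences:
            cols.extend(heights[s:t])
        out[e.element_id] = MotifConservation(
            e.element_id, tuple(cols), float(np.mean(cols)))
    return out


def expected_random_hits_per_mb(total_info_bits: float) -> float:
    """Analytic false-positive heuristic: 2L * 2^(-I) at L = 1 Mb."""
    return 2.0 * 1e6 * 2.0 ** (-total_info_bits)


def rank_elements(
    model: StructuredAlignment,
    conservation: dict[int, MotifConservation],
    tie_window: float = 0.1,
) -> list[int]:
    """Elements by descending mean stack height; within ties (means within
    `tie_window` bits) single strands outrank helices, favouring motifs
    that are cheap to scan at early levels."""
    kinds = {e.element_id: e.kind for e in model.elements}
    by_mean = sorted(
        conservation.values(), key=lambda c: (-c.mean, c.element_id))
    tiers: list[list[MotifConservation]] = []
    for c in by_mean:
        if tiers and tiers[-1][0].mean - c.mean <= tie_window:
            tiers[-1].append(c)
        else:
            tiers.append([c])
    out: list[int] = []
    for tier in tiers:
        tier.sort(key=lambda c: (
            0 if kinds[c.element_id] == "single_strand" else 1,
            -c.mean, c.element_id))
        out.extend(c.element_id for c in tier)
    return out


def _max_pair_distance(layout: list, chosen: set[int]) -> int:
    """Worst-case genomic end-to-start distance between the outermost
    chosen occurrences, taking every variable gap at its maximum."""
    occ_idx = [it.item_idx for it in layout
               if isinstance(it, _Occ) and it.eid in chosen]
    if len(occ_idx) <= 1:
        return 0
    first, last = min(occ_idx), max(occ_idx)
    dist = 0
    for it in layout[first + 1:last]:
        dist += it.length if isinstance(it, _Occ) else it.hi
    return dist


def build_strategy(
    model: StructuredAlignment,
    pset: ProfileSet,
    tstats: TrainStats,
    conservation: dict[int, MotifConservation] | None = None,
    max_levels: int = 3,
    *,
    window_cap: int = 500,
    level1_fp_per_mb: float = 10.0,
    mid_fp_per_mb: float = 0.1,
    slack: float = 0.2,
    max_level1_size: int = 3,
    on_warning: Callable[[str], None] | None = None,
) -> tuple[Strategy, dict]:
    """Construct a 3-4 level strategy with tstat-derived cutoffs.

    Level 1 is the subset of (at most `max_level1_size`) elements with
    the highest mean stack height that fits in one bounded genomic window
    and stays under the level-1 false-positive budget.  Middle level(s)
    add next-ranked elements until the budget tightens; the final level
    completes the model.  Returns the strategy plus a rationale log.
    """
    if max_levels not in (3, 4):
        raise ValueError("max_levels must be 3 or 4")
    elements = [e.element_id for e in model.elements]
    if len(elements) < 3:
        raise ValueError("auto strategy needs a model with >= 3 elements")
    cons = conservation or conservation_by_element(
        model, pset.pseudocount, pset.background)
    layout = build_layout(model, pset, slack)
    info = {eid: float(sum(c.heights)) for eid, c in cons.items()}

    # ---- level 1: exhaustive subset choice --------------------------------
    max_size = min(max_level1_size, len(elements) - 2)
    feasible: list[tuple[tuple[int, ...], float]] = []
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(elements, size):
            if _max_pair_distance(layout, set(subset)) > window_cap:
                continue
            fp = expected_random_hits_per_mb(sum(info[e] for e in subset))
            if fp > level1_fp_per_mb:
                continue
            mean_h = float(np.mean([cons[e].mean for e in subset]))
            feasible.append((subset, mean_h))
    kinds = {e.element_id: e.kind for e in model.elements}
    warnings_log: list[str] = []
    if feasible:
        best_mean = max(m for _, m in feasible)
        tier = [(s, m) for s, m in feasible if m >= best_mean - 0.1]
        tier.sort(key=lambda sm: (
            -sum(1 for e in sm[0] if kinds[e] == "single_strand"),
            len(sm[0]), -sm[1], sm[0]))
        level1 = list(tier[0][0])
    else:
        ranked_all = rank_elements(model, cons)
        level1 = [ranked_all[0]]
        msg = ("no element subset satisfies the distance/false-positive "
               f"bounds; falling back to single element {level1[0]}")
        warnings_log.append(msg)
        if on_warning:
            on_warning(msg)

    # ---- middle level(s) ---------------------------------------------------
    remaining = [e for e in rank_elements(model, cons) if e not in level1]
    middle: list[int] = []
    for eid in remaining[:-1]:  # always keep >= 1 element for the final level
        middle.append(eid)
        fp = expected_random_hits_per_mb(
            sum(info[e] for e in level1 + middle))
        if fp <= mid_fp_per_mb:
            break
    if not middle:
        middle = [remaining[0]]
    final = [e for e in remaining if e not in middle]

    level_sets: list[list[int]] = [level1]
    if max_levels == 4 and len(middle) >= 2:
        half = (len(middle) + 1) // 2
        level_sets += [middle[:half], middle[half:]]
    else:
        level_sets.append(middle)
    level_sets.append(final)

    # admissible per-level cutoffs: the final cutoff comes from the tstat
    # training minima; each earlier level subtracts the best score the
    # still-unplaced elements could possibly contribute, so no placement
    # that would pass the final cutoff is ever pruned early (the staged
    # search stays lossless with respect to a single-level search)
    total_cutoff = tstats.cutoff_for(elements)
    cumulative: list[int] = []
    levels = []
    for ls in level_sets:
        cumulative.extend(ls)
        remaining_max = sum(pset[e].max_score for e in elements
                            if e not in cumulative)
        levels.append(Level(tuple(ls), total_cutoff - remaining_max))
    strategy = Strategy(tuple(levels))

    rationale = {
        "mean_heights": {eid: cons[eid].mean for eid in elements},
        "info_bits": info,
        "level_sets": [list(ls) for ls in level_sets],
        "level_cutoffs": [lv.cutoff for lv in levels],
        "level1_fp_per_mb": expected_random_hits_per_mb(
            sum(info[e] for e in level1)),
        "warnings": warnings_log,
    }
    return strategy, rationale
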