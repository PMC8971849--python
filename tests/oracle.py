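"""Independent reference implementations for validating the package on
small inputs: exhaustive placement enumeration for the genome search,
interval-crossing and overlap-graph checks, single-linkage clustering,
and exhaustive subset selection for strategy construction.

These deliberately re-derive the layouts and constraint checks with
their own (simple, exhaustive) logic instead of calling into the
package's search machinery.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from intronscan.alphabet import encode, revcomp_encoded
from intronscan.profiles import HelixProfile, SingleStrandProfile


# ---------------------------------------------------------------------------
# brute-force genome search

def _chain(model, pset, searched, slack):
    """(occs, gaps): searched occurrence blocks in column order with
    min/max genomic gaps between them (unsearched blocks and variable
    regions folded into the gaps)."""
    entries = [e for e in model.layout()]
    while entries and entries[0][0] == "var":
        entries = entries[1:]
    while entries and entries[-1][0] == "var":
        entries = entries[:-1]
    occs: list[tuple[int, int, int]] = []
    gaps: list[tuple[int, int]] = []
    acc_lo = acc_hi = 0
    started = False
    for ent in entries:
        if ent[0] == "occ":
            eid = ent[1]
            length = pset[eid].length
            if eid in searched:
                if started:
                    gaps.append((acc_lo, acc_hi))
                occs.append((eid, ent[2], length))
                acc_lo = acc_hi = 0
                started = True
            elif started:
                acc_lo += length
                acc_hi += length
        elif started:
            r = model.variable_regions[ent[1]]
            acc_lo += r.min_len
            acc_hi += r.max_len + math.ceil(r.max_len * slack)
    return occs, gaps


def _ss_scores(g, prof, n):
    out = np.zeros(n)
    for i in range(prof.length):
        col = g[i:i + n]
        valid = col < 4
        out[valid] += prof.log_odds[i, col[valid]]
    return out


def _helix_scores(g, prof, d, n):
    """Pair scores for 5' start p, 3' start p + d."""
    out = np.zeros(n)
    L = prof.length
    for i in range(L):
        b5 = g[i:i + n]
        b3 = g[d + L - 1 - i:d + L - 1 - i + n]
        valid = (b5 < 4) & (b3 < 4)
        out[valid] += prof.pair_log_odds[i, b5[valid], b3[valid]]
    return out


def brute_force_search(model, pset, strategy, genome_seq, contig="c",
                       both_strands=True, slack=0.2):
    """Exhaustively enumerate every admissible placement on both strands,
    apply the strategy's cumulative per-level constraints, and reduce
    overlapping placements to the best-scoring one (tie -> leftmost).

    Returns hits as dicts with forward-strand 1-based occurrence spans.
    """
    searched = set()
    levels = []
    for lv in strategy.levels:
        searched |= set(lv.elements)
        levels.append((frozenset(searched), lv.cutoff))
    occs, gaps = _chain(model, pset, searched, slack)
    raw = []
    fwd = encode(genome_seq)
    Lg = len(fwd)
    strands = [("+", fwd)]
    if both_strands:
        strands.append(("-", revcomp_encoded(fwd)))
    for strand, g in strands:
        for combo in itertools.product(
                *[range(lo, hi + 1) for lo, hi in gaps]):
            # offsets of each occurrence relative to the placement start
            offs = []
            pos = 0
            for k, (eid, which, length) in enumerate(occs):
                offs.append(pos)
                pos += length
                if k < len(combo):
                    pos += combo[k]
            span = pos
            n = Lg - span + 1
            if n <= 0:
                continue
            # per-element score arrays over the placement start
            el_scores: dict[int, np.ndarray] = {}
            helix_open: dict[int, int] = {}
            for (eid, which, length), off in zip(occs, offs):
                prof = pset[eid]
                if isinstance(prof, SingleStrandProfile):
                    el_scores[eid] = _ss_scores(g[off:], prof, n)
                elif which == 0:
                    helix_open[eid] = off
                else:
                    d = off - helix_open[eid]
                    el_scores[eid] = _helix_scores(
                        g[helix_open[eid]:], prof, d, n)
            mask = np.ones(n, dtype=bool)
            for cum, cutoff in levels:
                partial = np.zeros(n)
                for eid in cum:
                    partial += el_scores[eid]
                mask &= partial >= cutoff - 1e-9
            total = np.zeros(n)
            for arr in el_scores.values():
                total += arr
            for p0 in np.nonzero(mask)[0].tolist():
                spans = []
                for (eid, which, length), off in zip(occs, offs):
                    s0, e0 = p0 + off, p0 + off + length  # scanned, half-open
                    if strand == "+":
                        spans.append((eid, which, s0 + 1, e0))
                    else:
                        spans.append((eid, which, Lg - e0 + 1, Lg - s0))
                raw.append({
                    "contig": contig, "strand": strand,
                    "start": min(s for _, _, s, _ in spans),
                    "end": max(e for _, _, _, e in spans),
                    "spans": tuple(spans),
                    "scores": {eid: float(a[p0])
                               for eid, a in el_scores.items()},
                    "score": float(total[p0]),
                })
    # overlap reduction, independently re-implemented
    raw.sort(key=lambda h: (-round(h["score"], 6), h["contig"], h["strand"],
                            h["start"], h["end"]))
    kept = []
    for h in raw:
        clash = any(
            k["contig"] == h["contig"] and k["strand"] == h["strand"]
            and k["start"] <= h["end"] and h["start"] <= k["end"]
            for k in kept)
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h["contig"], h["strand"], h["start"], h["end"]))
    return kept


# ---------------------------------------------------------------------------
# interval geometry

def intervals_cross(a5, a3, b5, b3):
    """Two helices, given by their occurrence start columns, interleave."""
    return (a5 < b5 < a3 < b3) or (b5 < a5 < b3 < a3)


def overlap_components(intervals):
    """Transitive closure of pairwise interval overlap (1-based incl.),
    by repeated merging."""
    groups = [{i} for i in range(len(intervals))]

    def overlaps(i, j):
        (s1, e1), (s2, e2) = intervals[i], intervals[j]
        return s1 <= e2 and s2 <= e1

    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(overlaps(i, j) for i in groups[a] for j in groups[b]):
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(gp) for gp in groups]


# ---------------------------------------------------------------------------
# single-linkage clustering

def single_linkage_clusters(seqs, threshold):
    """Clusters under 'p-distance < threshold' links, by repeated merging."""

    def dist(a, b):
        pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        if not pairs:
            return 1.0
        return sum(1 for x, y in pairs if x != y) / len(pairs)

    clusters = [{i} for i in range(len(seqs))]
    changed = True
    while changed:
        changed = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if any(dist(seqs[i], seqs[j]) < threshold
                       for i in clusters[a] for j in clusters[b]):
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(c) for c in clusters]


# ---------------------------------------------------------------------------
# exhaustive level-1 subset selection

def best_level1_subset(model, conservation, info, window_cap,
                       fp_budget_per_mb, max_size, slack=0.2):
    """Exhaustive re-derivation of the level-1 motif set: feasible subsets
    (worst-case window span <= cap, expected random hits <= budget),
    maximised by mean stack height with the documented tie rules."""
    elements = [e.element_id for e in model.elements]
    kinds = {e.element_id: e.kind for e in model.elements}
    # worst-case span between outermost chosen occurrences, by columns
    entries = [e for e in model.layout()]
    while entries and entries[0][0] == "var":
        entries = entries[1:]
    while entries and entries[-1][0] == "var":
        entries = entries[:-1]

    def span(chosen):
        idx = [i for i, ent in enumerate(entries)
               if ent[0] == "occ" and ent[1] in chosen]
        if len(idx) <= 1:
            return 0
        d = 0
        for ent in entries[min(idx) + 1:max(idx)]:
            if ent[0] == "occ":
                d += ent[3][1] - ent[3][0]
            else:
                s, t = ent[2]
                # use the element-stripped maximum width plus slack, as the
                # observed max spacer cannot exceed the column width
                r = model.variable_regions[ent[1]]
                d += r.max_len + math.ceil(r.max_len * slack)
        return d

    feasible = []
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(elements, size):
            if span(set(subset)) > window_cap:
                continue
            fp = 2.0 * 1e6 * 2.0 ** (-sum(info[e] for e in subset))
            if fp > fp_budget_per_mb:
                continue
            mean_h = sum(conservation[e].mean for e in subset) / len(subset)
            feasible.append((subset, mean_h))
    if not feasible:
        return None
    best_mean = max(m for _, m in feasible)
    tier = [(s, m) for s, m in feasible if m >= best_mean - 0.1]
    tier.sort(key=lambda sm: (
        -sum(1 for e in sm[0] if kinds[e] == "single_strand"),
        len(sm[0]), -sm[1], sm[0]))
    return set(tier[0][0])
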