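"""Iterative model extension, hit deduplication, reporting and motif
tallies.

The refinement loop searches a genome collection with the current model,
drops hits that are identical or closely related to sequences already in
the alignment (p-distance clustering), inserts the best remaining hits
under the model's element columns - exact placement, no realignment,
since helices are indel-free and single strands have fixed profile
length - widens variable regions where a recovered spacer does not fit,
and repeats until the hit set stops changing.  The structured text
report lists hits by ascending E-value with conserved blocks in upper
case and variable-region lengths printed between them; the P7-style
motif tally counts exact sequence variants of a chosen motif, rendering
bulged residues between underscores (e.g. ``C_A_GACUG...CAGUCG``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .model import StructuredAlignment, VariableRegion, parse_structure_line
from .profiles import Background, ProfileSet, train, tstat
from .search import (EvalueCalibration, Hit, SearchResult, Strategy,
                     calibrate_evalues, rank_hits, search,
                     single_level_strategy)


# ---------------------------------------------------------------------------
# deduplication

def _hit_concat(hit: Hit) -> str:
    parts = []
    for eid in sorted(hit.element_seqs):
        s = hit.element_seqs[eid]
        parts.append(s[0] + s[1] if isinstance(s, tuple) else s)
    return "".join(parts).upper()


def p_distance(a: str, b: str, jukes_cantor: bool = False) -> float:
    """Pairwise distance over positions where both sequences have a base;
    optional Jukes-Cantor correction."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    if jukes_cantor:
        if p >= 0.75:
            return math.inf
        return -0.75 * math.log(1 - 4.0 * p / 3.0)
    return p


def dedupe(
    hits: Sequence[Hit],
    identity_threshold: float = 0.10,
    jukes_cantor: bool = False,
) -> list[Hit]:
    """Single-linkage clustering at p-distance < threshold over the
    concatenated element sequences; the best-E hit of each cluster is
    retained (hits are equal-length by construction)."""
    n = len(hits)
    seqs = [_hit_concat(h) for h in hits]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if p_distance(seqs[i], seqs[j], jukes_cantor) < identity_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    keep: set[int] = set()
    for members in clusters.values():
        best = min(members, key=lambda i: (
            hits[i].evalue if hits[i].evalue is not None else math.inf,
            -hits[i].score, hits[i].start))
        keep.add(best)
    return [h for i, h in enumerate(hits) if i in keep]


# ---------------------------------------------------------------------------
# model extension

def _row_concat(model: StructuredAlignment, seq: str) -> str:
    parts = []
    for e in model.elements:
        for s, t in e.occurrences:
            parts.append(seq[s:t])
    return "".join(parts).upper()


def extend_model(
    model: StructuredAlignment,
    hits: Sequence[Hit],
    *,
    identity_threshold: float = 0.10,
    evalue_max: float = 1e-5,
    max_added: int = 50,
    pset: ProfileSet | None = None,
    on_warning: Callable[[str], None] | None = None,
) -> tuple[StructuredAlignment, int]:
    """Insert retained hits as new alignment rows; returns (model, n_added).

    Hits must place every model element (partial hits are rejected with a
    warning); variable regions are widened when a recovered spacer is
    longer than the current column block, and the observed spacer ranges
    are recomputed from the extended alignment.
    """

    def warn(msg: str) -> None:
        if on_warning:
            on_warning(msg)

    needed = {e.element_id for e in model.elements}
    region_count = len(model.variable_regions)
    eligible: list[Hit] = []
    for h in hits:
        if h.evalue is not None and h.evalue > evalue_max:
            continue
        if set(h.element_seqs) != needed:
            warn(f"hit {h.contig}:{h.start}-{h.end} misses elements "
                 f"{sorted(needed - set(h.element_seqs))}; rejected")
            continue
        if set(h.region_seqs) != set(range(region_count)) and region_count:
            warn(f"hit {h.contig}:{h.start}-{h.end} misses spacer sequences; "
                 f"rejected")
            continue
        eligible.append(h)
    retained = dedupe(rank_hits(eligible), identity_threshold)
    # drop hits indistinguishable from rows already in the alignment
    existing = [_row_concat(model, seq) for _, seq in model.sequences]
    fresh = []
    for h in retained:
        cat = _hit_concat(h)
        if all(p_distance(cat, row) >= identity_threshold for row in existing):
            fresh.append(h)
    fresh = rank_hits(fresh)[:max_added]
    if not fresh:
        return model, 0

    # required width per variable region
    widths = {r.index: r.columns[1] - r.columns[0]
              for r in model.variable_regions}
    for h in fresh:
        for ridx, seq in h.region_seqs.items():
            widths[ridx] = max(widths[ridx], len(seq))

    # rebuild the alignment segment-wise with the (possibly) wider regions
    items = model.layout()
    tokens: list[str] = []
    for it in items:
        if it[0] == "occ":
            _, eid, _w, (s, t) = it
            tokens.extend(model.structure_tokens[s:t])
        else:
            tokens.extend(["."] * widths[it[1]])

    def rebuild_row(seq: str) -> str:
        parts = []
        for it in items:
            s, t = it[-1]
            chunk = seq[s:t]
            if it[0] == "var":
                chunk = chunk + "-" * (widths[it[1]] - len(chunk))
            parts.append(chunk)
        return "".join(parts)

    new_rows = [(sid, rebuild_row(seq)) for sid, seq in model.sequences]
    kept_cols = {e.element_id: None for e in model.elements}
    if pset is not None:
        for eid in kept_cols:
            prof = pset[eid]
            if hasattr(prof, "kept_columns"):
                el = model.element(eid)
                kept_cols[eid] = tuple(
                    c - el.columns5[0] for c in prof.kept_columns)
    for h in fresh:
        parts = []
        for it in items:
            if it[0] == "occ":
                _, eid, which, (s, t) = it
                seq = h.element_seqs[eid]
                seg = seq[which] if isinstance(seq, tuple) else seq
                width = t - s
                if len(seg) < width:
                    # profile dropped all-gap columns: re-insert gaps there
                    rel = kept_cols.get(eid)
                    if rel is not None and which == 0 and len(rel) == len(seg):
                        block = ["-"] * width
                        for ch, c in zip(seg, rel):
                            block[c] = ch
                        seg = "".join(block)
                    else:
                        seg = seg + "-" * (width - len(seg))
                parts.append(seg)
            else:
                spacer = h.region_seqs.get(it[1], "")
                parts.append(spacer + "-" * (widths[it[1]] - len(spacer)))
        rid = f"{h.contig}_{h.start}_{h.end}{h.strand}"
        new_rows.append((rid, "".join(parts)))
    extended = StructuredAlignment.from_sequences(model.name, new_rows, tokens)
    return extended, len(fresh)


# ---------------------------------------------------------------------------
# the refinement loop

@dataclass
class RoundLog:
    round: int
    n_hits: int
    n_added: int
    n_rows: int


def iterate(
    model: StructuredAlignment,
    genomes,
    *,
    rounds: int = 5,
    seed: int = 0,
    pseudocount: float = 1.0,
    margin: float = 1.0,
    identity_threshold: float = 0.10,
    evalue_max: float = 1e-5,
    max_added: int = 50,
    n_shuffles: int = 100,
    shuffle_len: int = 2_000,
    slack: float = 0.2,
    background: Background | None = None,
) -> tuple[StructuredAlignment, list[RoundLog]]:
    """Repeat search -> dedupe -> extend until the hit locus set stops
    changing or `rounds` are exhausted.  Hit counts are logged per round
    (they need not be monotone: retraining reshapes cutoffs)."""
    log: list[RoundLog] = []
    prev_loci: frozenset | None = None
    for r in range(1, rounds + 1):
        pset = train(model, pseudocount=pseudocount, background=background,
                     on_warning=lambda m: None)
        ts = tstat(pset, model, margin=margin)
        strat = single_level_strategy(model, ts)
        calib = calibrate_evalues(
            model, pset, strat, n_shuffles=n_shuffles,
            shuffle_len=shuffle_len, seed=seed + r, slack=slack)
        hits = search(model, pset, strat, genomes, calib, slack=slack)
        loci = frozenset((h.contig, h.strand, h.start, h.end) for h in hits)
        extended, n_added = extend_model(
            model, hits, identity_threshold=identity_threshold,
            evalue_max=evalue_max, max_added=max_added, pset=pset,
            on_warning=lambda m: None)
        log.append(RoundLog(r, len(hits), n_added, extended.n_sequences))
        converged = (loci == prev_loci) or (n_added == 0)
        model = extended
        prev_loci = loci
        if converged:
            break
    return model, log


# ---------------------------------------------------------------------------
# motif tally

@dataclass
class MotifTally:
    """Exact-variant counts of one motif across hits."""

    variants: list[tuple[str, int]]  # ordered by descending count
    predominant: str | None
    total: int
    #: per reported variant, 0-based positions differing from the
    #: predominant motif (None when lengths differ)
    differences: dict[str, tuple[int, ...] | None]


def render_motif(
    model: StructuredAlignment, hit: Hit, element_ids: Sequence[int]
) -> str:
    """Motif string for the chosen elements of one hit.

    Occurrence blocks are concatenated 5'->3'; non-adjacent blocks are
    joined with ``...``; a chosen single strand sitting directly between
    two chosen blocks is rendered between underscores (a bulge, as in the
    helix-bulge-helix P7 motif)."""
    chosen = set(element_ids)
    items = model.layout()
    occ_items = [(i, it) for i, it in enumerate(items)
                 if it[0] == "occ" and it[1] in chosen]
    kinds = {e.element_id: e.kind for e in model.elements}
    out: list[str] = []
    for n, (idx, it) in enumerate(occ_items):
        _, eid, which, _cols = it
        seq = hit.element_seqs[eid]
        seg = seq[which] if isinstance(seq, tuple) else seq
        if n > 0:
            prev_idx = occ_items[n - 1][0]
            adjacent = (idx == prev_idx + 1)
            if not adjacent:
                out.append("...")
        if kinds[eid] == "single_strand" and 0 < n < len(occ_items) - 1:
            prev_adj = idx == occ_items[n - 1][0] + 1
            next_adj = occ_items[n + 1][0] == idx + 1
            if prev_adj and next_adj:
                seg = f"_{seg}_"
        out.append(seg)
    return "".join(out)


def tally_motifs(
    model: StructuredAlignment,
    hits: Sequence[Hit],
    element_ids: int | Sequence[int],
    min_count: int = 5,
) -> MotifTally:
    """Count exact motif variants over all hits that carry the chosen
    element(s); variants below `min_count` are not reported."""
    if isinstance(element_ids, int):
        element_ids = (element_ids,)
    chosen = set(element_ids)
    counts: dict[str, int] = {}
    total = 0
    for h in hits:
        if not chosen <= set(h.element_seqs):
            continue
        motif = render_motif(model, h, element_ids)
        counts[motif] = counts.get(motif, 0) + 1
        total += 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    predominant = ordered[0][0] if ordered else None
    reported = [(m, c) for m, c in ordered if c >= min_count]
    differences: dict[str, tuple[int, ...] | None] = {}
    for m, _ in reported:
        if predominant is None or len(m) != len(predominant):
            differences[m] = None
        else:
            differences[m] = tuple(
                i for i, (a, b) in enumerate(zip(m, predominant)) if a != b)
    return MotifTally(reported, predominant, total, differences)


def tally_to_tsv(tally: MotifTally) -> str:
    lines = ["motif\tcount\tdiff_positions"]
    for m, c in tally.variants:
        d = tally.differences.get(m)
        ds = "" if d is None else ",".join(map(str, d))
        lines.append(f"{m}\t{c}\t{ds}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# structured report

_HIT_RE = re.compile(
    r"^>(?P<n>\d+)\s+E=(?P<e>\S+)\s+score=(?P<s>\S+)\s+"
    r"contig=(?P<c>\S+)\s+strand=(?P<st>[+-])\s+"
    r"span=(?P<a>\d+)-(?P<b>\d+)\s+model=(?P<m>\S+)")


def render_report(model: StructuredAlignment, hits: Sequence[Hit]) -> str:
    """Structured search report: hits sorted by ascending E-value, one
    header line and one sequence line each; element blocks in upper case
    with variable-region lengths printed between them."""
    lines = [f"# model: {model.name}",
             f"# structure: {' '.join(model.structure_tokens)}"]
    for n, h in enumerate(rank_hits(hits), start=1):
        ev = "na" if h.evalue is None else f"{h.evalue:.3g}"
        lines.append(
            f">{n} E={ev} score={h.score:.4f} contig={h.contig} "
            f"strand={h.strand} span={h.start}-{h.end} model={h.model}")
        spans = sorted(h.occ_spans, key=lambda t: t[2],
                       reverse=(h.strand == "-"))
        parts: list[str] = []
        prev_end: int | None = None
        for eid, which, s, e in spans:
            if prev_end is not None:
                gap = (s - prev_end - 1) if h.strand == "+" else (prev_end - e - 1)
                parts.append(str(abs(gap)))
            seq = h.element_seqs[eid]
            seg = seq[which] if isinstance(seq, tuple) else seq
            parts.append(seg.upper())
            prev_end = e if h.strand == "+" else s
        lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> list[dict]:
    """Recover hit coordinates and scores from a rendered report."""
    out = []
    for line in text.splitlines():
        m = _HIT_RE.match(line)
        if m:
            out.append({
                "evalue": None if m["e"] == "na" else float(m["e"]),
                "score": float(m["s"]),
                "contig": m["c"],
                "strand": m["st"],
                "start": int(m["a"]),
                "end": int(m["b"]),
                "model": m["m"],
            })
    return out
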