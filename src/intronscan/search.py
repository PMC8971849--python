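"""Multi-level profile search over genome sequences.

A *strategy* is an ordered list of 1-4 levels; each level names a set of
model elements and a cumulative score cutoff in bits.  Level 1 scans both
strands for placements of its elements whose inter-element distances
respect the model's variable-region bounds; each later level extends the
surviving placements with its own elements, enumerating admissible
positions inside the windows left between the already-placed anchors and
pruning below that level's cutoff.  The staged search pinpoints
candidate intron regions with a cheap, highly conserved anchor set and
only then applies the full set of constraints - the behaviour that makes
profile searches for group I introns tractable on whole mitochondrial
genomes.

Enumeration is exact (all admissible spacer offsets are considered, no
heuristic banding) and pruning uses admissible upper bounds, so with
lossless cutoffs the staged search returns exactly the placements a
brute-force enumeration would.

E-values use a Gumbel (extreme-value) model fitted by maximum likelihood
to the best strategy scores on shuffled i.i.d. background sequences:
``E(s) = (scanned_length / calibration_length) * exp(-(s - mu) / beta)``.
By default both strands count toward the scanned length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .alphabet import decode, encode, revcomp_encoded
from .model import GenomeRecord, StructuredAlignment
from .profiles import Background, HelixProfile, ProfileSet, SingleStrandProfile

EPS = 1e-9
#: scores are rounded to this many decimals for overlap tie-breaking so
#: that float summation order cannot flip a tie
SCORE_DECIMALS = 6


# ---------------------------------------------------------------------------
# strategy

@dataclass(frozen=True)
class Level:
    elements: tuple[int, ...]
    cutoff: float


@dataclass(frozen=True)
class Strategy:
    """Ordered search levels; each level adds elements at a cumulative
    score cutoff."""

    levels: tuple[Level, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.levels) <= 4:
            raise ValueError("a strategy has between 1 and 4 levels")
        seen: set[int] = set()
        for lv in self.levels:
            if not lv.elements:
                raise ValueError("every level must add at least one element")
            dup = seen & set(lv.elements)
            if dup:
                raise ValueError(f"elements {sorted(dup)} appear in two levels")
            seen |= set(lv.elements)

    @property
    def all_elements(self) -> tuple[int, ...]:
        out: list[int] = []
        for lv in self.levels:
            out.extend(lv.elements)
        return tuple(out)

    def to_json(self) -> str:
        return json.dumps({
            "levels": [
                {"elements": sorted(lv.elements), "cutoff": lv.cutoff}
                for lv in self.levels
            ]
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Strategy":
        doc = json.loads(text)
        return cls(tuple(
            Level(tuple(lv["elements"]), float(lv["cutoff"]))
            for lv in doc["levels"]
        ))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Strategy":
        return cls.from_json(Path(path).read_text())


def single_level_strategy(
    model: StructuredAlignment, tstats, margin: float | None = None
) -> Strategy:
    """One level containing every model element, cut off at the sum of the
    per-element training minima minus the tstat margin."""
    eids = tuple(e.element_id for e in model.elements)
    return Strategy((Level(eids, tstats.cutoff_for(eids)),))


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel location/scale fitted to per-shuffle best scores."""

    mu: float
    beta: float
    calib_len: int
    n_shuffles: int
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("Gumbel scale must be positive")

    def evalue(self, score: float, scanned_len: int) -> float:
        return (scanned_len / self.calib_len) * math.exp(
            -(score - self.mu) / self.beta)

    def score_at(self, evalue: float, scanned_len: int) -> float:
        """Score whose E-value equals `evalue` on a database of
        `scanned_len` nucleotides."""
        return self.mu - self.beta * math.log(
            evalue * self.calib_len / scanned_len)

    def to_json(self) -> str:
        return json.dumps({
            "mu": self.mu, "beta": self.beta, "calib_len": self.calib_len,
            "n_shuffles": self.n_shuffles, "both_strands": self.both_strands,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvalueCalibration":
        d = json.loads(text)
        return cls(d["mu"], d["beta"], d["calib_len"], d["n_shuffles"],
                   d.get("both_strands", True))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "EvalueCalibration":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# hits

@dataclass
class Hit:
    """A located intron candidate.

    Coordinates are 1-based inclusive on the forward strand of the contig.
    ``occ_spans`` lists ``(element_id, which, start, end)`` per placed
    occurrence in model order along the hit's strand; uppercase element
    sequences are the conserved searched blocks.
    """

    model: str
    contig: str
    strand: str
    start: int
    end: int
    score: float
    evalue: float | None
    element_scores: dict[int, float]
    occ_spans: tuple[tuple[int, int, int, int], ...]
    element_seqs: dict[int, str | tuple[str, str]]
    region_seqs: dict[int, str] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def conserved_positions(self) -> set[int]:
        """Genomic positions covered by element (uppercase) blocks."""
        out: set[int] = set()
        for _, _, s, e in self.occ_spans:
            out.update(range(s, e + 1))
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.model, "contig": self.contig, "strand": self.strand,
            "start": self.start, "end": self.end, "score": self.score,
            "evalue": self.evalue,
            "element_scores": {str(k): v for k, v in self.element_scores.items()},
            "occ_spans": [list(t) for t in self.occ_spans],
            "element_seqs": {
                str(k): (list(v) if isinstance(v, tuple) else v)
                for k, v in self.element_seqs.items()
            },
            "region_seqs": {str(k): v for k, v in self.region_seqs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hit":
        return cls(
            d["model"], d["contig"], d["strand"], d["start"], d["end"],
            d["score"], d["evalue"],
            {int(k): v for k, v in d["element_scores"].items()},
            tuple(tuple(t) for t in d["occ_spans"]),
            {int(k): (tuple(v) if isinstance(v, list) else v)
             for k, v in d["element_seqs"].items()},
            {int(k): v for k, v in d.get("region_seqs", {}).items()},
        )


class SearchResult(list):
    """List of hits with per-level scan statistics attached."""

    def __init__(self, hits: Iterable[Hit] = (), stats: list | None = None):
        super().__init__(hits)
        self.stats = stats or []


def save_hits_json(hits: Iterable[Hit], path: str | Path) -> None:
    Path(path).write_text(json.dumps([h.to_dict() for h in hits], indent=1))


def load_hits_json(path: str | Path) -> list[Hit]:
    return [Hit.from_dict(d) for d in json.loads(Path(path).read_text())]


def hits_to_tsv(hits: Iterable[Hit]) -> str:
    lines = ["model\tcontig\tstart\tend\tstrand\tscore\tevalue"]
    for h in hits:
        ev = "" if h.evalue is None else f"{h.evalue:.3g}"
        lines.append(
            f"{h.model}\t{h.contig}\t{h.start}\t{h.end}\t{h.strand}\t"
            f"{h.score:.4f}\t{ev}")
    return "\n".join(lines) + "\n"


def hits_to_bed(hits: Iterable[Hit]) -> str:
    """BED6 track: 0-based half-open, score clipped to [0, 1000]."""
    lines = []
    for h in hits:
        sc = int(max(0, min(1000, round(h.score * 10))))
        lines.append(
            f"{h.contig}\t{h.start - 1}\t{h.end}\t{h.model}\t{sc}\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# genomic layout of a model

@dataclass(frozen=True)
class _Occ:
    item_idx: int
    eid: int
    which: int  # 0 = 5' (or only) strand, 1 = helix 3' strand
    length: int


@dataclass(frozen=True)
class _Gap:
    item_idx: int
    lo: int
    hi: int
    region_index: int | None


def build_layout(
    model: StructuredAlignment, pset: ProfileSet, slack: float = 0.2
) -> list:
    """Genomic layout: occurrence blocks of fixed (profile) length
    separated by bounded variable gaps.

    Gap bounds are ``[observed_min, observed_max + ceil(observed_max *
    slack)]``; flanking variable regions outside the outermost elements do
    not constrain the search and are dropped.
    """
    entries = model.layout()
    while entries and entries[0][0] == "var":
        entries = entries[1:]
    while entries and entries[-1][0] == "var":
        entries = entries[:-1]
    items: list = []
    for entry in entries:
        idx = len(items)
        if entry[0] == "occ":
            _, eid, which, _cols = entry
            items.append(_Occ(idx, eid, which, pset[eid].length))
        else:
            _, ridx, _cols = entry
            r = model.variable_regions[ridx]
            hi = r.max_len + math.ceil(r.max_len * slack)
            items.append(_Gap(idx, r.min_len, hi, ridx))
    return items


# ---------------------------------------------------------------------------
# the scanner

class _Scanner:
    def __init__(
        self,
        model: StructuredAlignment,
        pset: ProfileSet,
        strategy: Strategy,
        slack: float = 0.2,
    ):
        self.model = model
        self.pset = pset
        self.strategy = strategy
        self.items = build_layout(model, pset, slack)
        self.occs = [it for it in self.items if isinstance(it, _Occ)]
        model_eids = {e.element_id for e in model.elements}
        for eid in strategy.all_elements:
            if eid not in model_eids:
                raise ValueError(f"strategy element {eid} not in model")
            if eid not in pset:
                raise ValueError(f"strategy element {eid} has no profile")
        self.level_occs = [
            [o for o in self.occs if o.eid in lv.elements]
            for lv in strategy.levels
        ]
        self._isum_cache: dict[tuple[int, int], tuple[int, int]] = {}

    # -- geometry ----------------------------------------------------------
    def _interval_sum(self, i: int, j: int) -> tuple[int, int]:
        """Min/max genomic span of layout items[i:j]."""
        key = (i, j)
        cached = self._isum_cache.get(key)
        if cached is not None:
            return cached
        lo = hi = 0
        for it in self.items[i:j]:
            if isinstance(it, _Occ):
                lo += it.length
                hi += it.length
            else:
                lo += it.lo
                hi += it.hi
        self._isum_cache[key] = (lo, hi)
        return lo, hi

    def _window(
        self, starts: dict[int, int], occ: _Occ, g_len: int
    ) -> tuple[int, int]:
        left = max((i for i in starts if i < occ.item_idx), default=None)
        right = min((i for i in starts if i > occ.item_idx), default=None)
        wlo, whi = 0, g_len - occ.length
        if left is not None:
            base = starts[left] + self.items[left].length
            lo1, hi1 = self._interval_sum(left + 1, occ.item_idx)
            wlo = max(wlo, base + lo1)
            whi = min(whi, base + hi1)
        if right is not None:
            lo2, hi2 = self._interval_sum(occ.item_idx + 1, right)
            rb = starts[right]
            wlo = max(wlo, rb - hi2 - occ.length)
            whi = min(whi, rb - lo2 - occ.length)
        return wlo, whi

    # -- per-position score arrays ----------------------------------------
    def _ss_array(self, g: np.ndarray, eid: int, cache: dict) -> np.ndarray:
        key = ("ss", eid)
        arr = cache.get(key)
        if arr is None:
            prof = self.pset[eid]
            m = prof.score_matrix
            L = prof.length
            n = len(g) - L + 1
            arr = np.zeros(max(n, 0))
            for i in range(L):
                arr += m[i, g[i:i + n]]
            cache[key] = arr
        return arr

    def _helix_close_ub(self, g: np.ndarray, eid: int, cache: dict) -> np.ndarray:
        """Per-position upper bound for a helix 3' strand: max over the
        (unknown) 5' partner base at every pair column."""
        key = ("hub", eid)
        arr = cache.get(key)
        if arr is None:
            prof = self.pset[eid]
            m5 = prof.score_matrix.max(axis=1)  # (L, 5) indexed by 3' base
            L = prof.length
            n = len(g) - L + 1
            arr = np.zeros(max(n, 0))
            for i in range(L):
                arr += m5[i, g[(L - 1 - i):(L - 1 - i) + n]]
            cache[key] = arr
        return arr

    def _helix_pairmax(self, g: np.ndarray, eid: int, cache: dict) -> np.ndarray:
        """Per-position bound for a helix 3' strand at p: the exact best
        pair score over the admissible 5'-strand offset band (falls back
        to the letter-max bound for very wide bands)."""
        key = ("pmax", eid)
        arr = cache.get(key)
        if arr is not None:
            return arr
        open_occ = close_occ = None
        for o in self.occs:
            if o.eid == eid:
                if o.which == 0:
                    open_occ = o
                else:
                    close_occ = o
        lo, hi = self._interval_sum(open_occ.item_idx + 1, close_occ.item_idx)
        if hi - lo > 64:
            arr = self._helix_close_ub(g, eid, cache)
            cache[key] = arr
            return arr
        prof = self.pset[eid]
        m = prof.score_matrix
        L = prof.length
        n = len(g) - L + 1
        arr = np.full(max(n, 0), -np.inf)
        for gap in range(lo, hi + 1):
            off = L + gap  # p3 - p5
            m_valid = n - off
            if m_valid <= 0:
                continue
            sc = np.zeros(m_valid)
            for i in range(L):
                sc += m[i, g[i:i + m_valid], g[off + L - 1 - i:off + L - 1 - i + m_valid]]
            np.maximum(arr[off:off + m_valid], sc, out=arr[off:off + m_valid])
        cache[key] = arr
        return arr

    def _helix_vals(
        self, g: np.ndarray, eid: int, p5: int, cand: np.ndarray
    ) -> np.ndarray:
        prof = self.pset[eid]
        m = prof.score_matrix
        L = prof.length
        out = np.zeros(cand.size)
        for i in range(L):
            out += m[i, g[p5 + i], g[cand + (L - 1 - i)]]
        return out

    def _occ_vals(
        self, g: np.ndarray, occ: _Occ, cand: np.ndarray,
        open5: dict[int, int], cache: dict,
    ) -> np.ndarray:
        prof = self.pset[occ.eid]
        if isinstance(prof, SingleStrandProfile):
            return self._ss_array(g, occ.eid, cache)[cand]
        if occ.which == 0:
            return np.zeros(cand.size)
        return self._helix_vals(g, occ.eid, open5[occ.eid], cand)

    def _static_ub(self, occ: _Occ) -> float:
        prof = self.pset[occ.eid]
        if isinstance(prof, HelixProfile) and occ.which == 0:
            return 0.0
        return prof.max_score

    # -- suffix bounds for the genome-wide level ---------------------------
    def _suffix_bound_arrays(
        self, g: np.ndarray, seq: list[_Occ], cache: dict
    ) -> list[np.ndarray | float]:
        """W[j][p] = admissible upper bound on the total score of occs
        seq[j+1:] when seq[j] starts at p."""
        k = len(seq)
        A: list[np.ndarray] = []
        for occ in seq:
            prof = self.pset[occ.eid]
            if isinstance(prof, SingleStrandProfile):
                A.append(self._ss_array(g, occ.eid, cache))
            elif occ.which == 0:
                n = len(g) - occ.length + 1
                A.append(np.zeros(max(n, 0)))
            else:
                A.append(self._helix_pairmax(g, occ.eid, cache))
        W: list[np.ndarray | float] = [0.0] * k
        B = A[k - 1]
        for j in range(k - 2, -1, -1):
            lo, hi = self._interval_sum(seq[j].item_idx + 1, seq[j + 1].item_idx)
            npos_j = len(g) - seq[j].length + 1
            wj = np.full(max(npos_j, 0), -np.inf)
            for d in range(lo, hi + 1):
                shift = seq[j].length + d
                m = min(npos_j, B.size - shift)
                if m > 0:
                    np.maximum(wj[:m], B[shift:shift + m], out=wj[:m])
            W[j] = wj
            B = A[j] + wj
        return W

    # -- enumeration order and suffix bounds --------------------------------
    def _enum_order(self, seq: list[_Occ]) -> list[_Occ]:
        """Layout order, except a helix 3' strand is placed immediately
        after its 5' strand so the exact pair score prunes early.

        Re-ordering does not change the enumerated placement set: windows
        are computed against the nearest placed anchors on both sides,
        which encodes the same chain of distance constraints.
        """
        by_eid: dict[int, dict[int, _Occ]] = {}
        for o in seq:
            by_eid.setdefault(o.eid, {})[o.which] = o
        out: list[_Occ] = []
        emitted: set[int] = set()
        for o in seq:
            if o.item_idx in emitted:
                continue
            out.append(o)
            emitted.add(o.item_idx)
            if isinstance(self.pset[o.eid], HelixProfile) and o.which == 0:
                close = by_eid[o.eid].get(1)
                if close is not None and close.item_idx not in emitted:
                    out.append(close)
                    emitted.add(close.item_idx)
        return out

    def _occ_bound_max(self, g: np.ndarray, occ: _Occ, cache: dict) -> float:
        """Genome-specific scalar upper bound on this occurrence's score
        contribution (0 for a helix 5' strand: the pair is credited at
        the 3' strand)."""
        prof = self.pset[occ.eid]
        if isinstance(prof, SingleStrandProfile):
            arr = self._ss_array(g, occ.eid, cache)
        elif occ.which == 0:
            return 0.0
        else:
            arr = self._helix_pairmax(g, occ.eid, cache)
        return float(arr.max()) if arr.size else float("-inf")

    def _local_suffix(
        self, g: np.ndarray, seq: list[_Occ], p0: int, cache: dict
    ) -> list[float]:
        """Suffix score bounds for seq[1:], restricted to the genomic
        windows reachable from seq[0] placed at p0 (tight, admissible)."""
        first = seq[0]
        base = p0 + first.length
        vals = [0.0] * len(seq)
        for j in range(1, len(seq)):
            occ = seq[j]
            prof = self.pset[occ.eid]
            if isinstance(prof, HelixProfile) and occ.which == 0:
                continue
            lo, hi = self._interval_sum(first.item_idx + 1, occ.item_idx)
            wlo = max(0, base + lo)
            whi = min(len(g) - occ.length, base + hi)
            if whi < wlo:
                vals[j] = float("-inf")
                continue
            if isinstance(prof, SingleStrandProfile):
                arr = self._ss_array(g, occ.eid, cache)
            else:
                arr = self._helix_pairmax(g, occ.eid, cache)
            vals[j] = float(arr[wlo:whi + 1].max())
        suffix = [0.0] * (len(seq) + 1)
        for j in range(len(seq) - 1, -1, -1):
            suffix[j] = suffix[j + 1] + vals[j]
        return suffix

    def _prefix_bound(
        self, g: np.ndarray, seq: list[_Occ], cache: dict
    ) -> np.ndarray:
        """P[p] = admissible bound on the total score of seq[:-1] when the
        anchor seq[-1] starts at p (mirror image of the suffix bounds)."""
        def occ_array(occ: _Occ) -> np.ndarray:
            prof = self.pset[occ.eid]
            if isinstance(prof, SingleStrandProfile):
                return self._ss_array(g, occ.eid, cache)
            if occ.which == 0:
                n = len(g) - occ.length + 1
                return np.zeros(max(n, 0))
            return self._helix_pairmax(g, occ.eid, cache)

        D = occ_array(seq[0])
        for j in range(1, len(seq)):
            lo, hi = self._interval_sum(seq[j - 1].item_idx + 1,
                                        seq[j].item_idx)
            npos_j = len(g) - seq[j].length + 1
            w = np.full(max(npos_j, 0), -np.inf)
            for d in range(lo, hi + 1):
                shift = seq[j - 1].length + d
                m = min(npos_j - shift, D.size)
                if m > 0:
                    np.maximum(w[shift:shift + m], D[:m],
                               out=w[shift:shift + m])
            if j == len(seq) - 1:
                D = w  # the anchor's own score is handled by the caller
            else:
                D = occ_array(seq[j]) + w
        return D

    def _future_bound(
        self, g: np.ndarray, anchor: _Occ, p0: int, future: list[_Occ],
        cache: dict,
    ) -> float:
        """Admissible bound on the total score of occurrences belonging to
        later levels, given an anchor occurrence placed at p0."""
        tot = 0.0
        base = p0 + anchor.length
        for occ in future:
            prof = self.pset[occ.eid]
            if isinstance(prof, HelixProfile) and occ.which == 0:
                continue
            if occ.item_idx > anchor.item_idx:
                lo, hi = self._interval_sum(anchor.item_idx + 1, occ.item_idx)
                wlo = max(0, base + lo)
                whi = min(len(g) - occ.length, base + hi)
                if whi < wlo:
                    return float("-inf")
                if isinstance(prof, SingleStrandProfile):
                    arr = self._ss_array(g, occ.eid, cache)
                else:
                    arr = self._helix_pairmax(g, occ.eid, cache)
                tot += float(arr[wlo:whi + 1].max())
            else:
                tot += self._occ_bound_max(g, occ, cache)
        return tot

    # -- placement enumeration ---------------------------------------------
    def _place(
        self, g, seq, k, starts, scores, open5, total, cutoff,
        w0, gsuffix, lsuffix, future, fb, final_cutoff,
        cache, counter, out, w0f=None, pre_global=0.0,
    ) -> None:
        if k == len(seq):
            if total >= cutoff - EPS and total + fb >= final_cutoff - EPS:
                out.append((dict(starts), dict(scores), total))
            return
        occ = seq[k]
        wlo, whi = self._window(starts, occ, len(g))
        if whi < wlo:
            return
        cand = np.arange(wlo, whi + 1)
        counter[0] += cand.size
        vals = self._occ_vals(g, occ, cand, open5, cache)
        if k == 0 and w0 is not None:
            barr = w0[cand]
        else:
            bnd = lsuffix[k + 1] if lsuffix is not None else gsuffix[k + 1]
            barr = np.full(cand.size, bnd)
        # prune against both the level's own cumulative cutoff and the
        # final cutoff (placements that cannot reach it die later anyway)
        if k == 0 and w0f is not None:
            bfin = w0f[cand] + pre_global
        else:
            bfin = barr + fb
        keep = (total + vals + barr >= cutoff - EPS) \
            & (total + vals + bfin >= final_cutoff - EPS)
        cand = cand[keep]
        vals = vals[keep]
        prof = self.pset[occ.eid]
        is_open = isinstance(prof, HelixProfile) and occ.which == 0
        for p, v in zip(cand.tolist(), vals.tolist()):
            ls = lsuffix
            fbb = fb
            if k == 0 and (len(seq) > 1 or future):
                if len(seq) > 1:
                    ls = self._local_suffix(g, seq, p, cache)
                if future:
                    fbb = self._future_bound(g, occ, p, future, cache)
                rest = ls[1] if ls is not None else 0.0
                if total + v + rest < cutoff - EPS or \
                        total + v + rest + fbb < final_cutoff - EPS:
                    continue
            starts[occ.item_idx] = p
            if is_open:
                open5[occ.eid] = p
                self._place(g, seq, k + 1, starts, scores, open5, total,
                            cutoff, w0, gsuffix, ls, future, fbb,
                            final_cutoff, cache, counter, out)
                del open5[occ.eid]
            else:
                scores[occ.eid] = v
                self._place(g, seq, k + 1, starts, scores, open5, total + v,
                            cutoff, w0, gsuffix, ls, future, fbb,
                            final_cutoff, cache, counter, out)
                del scores[occ.eid]
            del starts[occ.item_idx]

    def scan(self, g: np.ndarray) -> tuple[list, list[dict]]:
        """Enumerate all strategy-passing placements on one strand.

        Returns (placements, per-level stats); a placement is
        (starts by item index, scores by element id, total score).
        """
        cache: dict = {}
        stats: list[dict] = []
        placements: list = [({}, {}, 0.0)]
        final_cutoff = self.strategy.levels[-1].cutoff
        for li, level in enumerate(self.strategy.levels):
            seq_layout = self.level_occs[li]
            seq = self._enum_order(seq_layout)
            future = [o for lo in self.level_occs[li + 1:] for o in lo]
            future_global = sum(self._occ_bound_max(g, o, cache)
                                for o in future)
            counter = [0]
            out: list = []
            gsuffix = [0.0] * (len(seq) + 1)
            for j in range(len(seq) - 1, -1, -1):
                gsuffix[j] = gsuffix[j + 1] + self._occ_bound_max(g, seq[j], cache)
            w0 = None
            w0f = None
            pre_global = 0.0
            if li == 0 and len(seq_layout) > 1:
                # genome-wide level: position-dependent bound for the first
                # occurrence (identical in both enumeration orders)
                w0arr = self._suffix_bound_arrays(g, seq_layout, cache)[0]
                if not isinstance(w0arr, float):
                    w0 = w0arr
            if li == 0 and seq:
                # positional bounds for the final cutoff over every
                # strategy occurrence up- and downstream of the anchor
                all_eids = set(self.strategy.all_elements)
                chain = [o for o in self.occs if o.eid in all_eids]
                idx0 = next(i for i, o in enumerate(chain)
                            if o.item_idx == seq[0].item_idx)
                n0 = len(g) - seq[0].length + 1
                w0f = np.zeros(max(n0, 0))
                if len(chain) - idx0 > 1:
                    wfarr = self._suffix_bound_arrays(g, chain[idx0:], cache)[0]
                    if not isinstance(wfarr, float):
                        w0f = w0f + wfarr
                if idx0 > 0:
                    w0f = w0f + self._prefix_bound(g, chain[:idx0 + 1], cache)
            for starts, scores, total in placements:
                self._place(g, seq, 0, dict(starts), dict(scores), {}, total,
                            level.cutoff, w0, gsuffix, None, future,
                            future_global, final_cutoff, cache, counter,
                            out, w0f, pre_global)
            placements = out
            stats.append({
                "level": li + 1,
                "evaluations": counter[0],
                "survivors": len(placements),
            })
        return placements, stats

    def best_score(self, g: np.ndarray) -> float:
        """Branch-and-bound maximum total score over all placements of the
        full strategy element set (used for E-value calibration)."""
        seq_layout = [o for o in self.occs
                      if o.eid in set(self.strategy.all_elements)]
        if not seq_layout:
            return float("-inf")
        cache: dict = {}
        seq = self._enum_order(seq_layout)
        gsuffix = [0.0] * (len(seq) + 1)
        for j in range(len(seq) - 1, -1, -1):
            gsuffix[j] = gsuffix[j + 1] + self._occ_bound_max(g, seq[j], cache)
        w0arr = (self._suffix_bound_arrays(g, seq_layout, cache)[0]
                 if len(seq_layout) > 1 else 0.0)
        w0 = None if isinstance(w0arr, float) else w0arr
        best = [float("-inf")]

        def rec(k, starts, open5, total, lsuffix):
            if k == len(seq):
                if total > best[0]:
                    best[0] = total
                return
            occ = seq[k]
            wlo, whi = self._window(starts, occ, len(g))
            if whi < wlo:
                return
            cand = np.arange(wlo, whi + 1)
            vals = self._occ_vals(g, occ, cand, open5, cache)
            if k == 0 and w0 is not None:
                barr = w0[cand]
            else:
                bnd = lsuffix[k + 1] if lsuffix is not None else gsuffix[k + 1]
                barr = np.full(cand.size, bnd)
            keep = total + vals + barr > best[0] + EPS
            cand, vals, barr = cand[keep], vals[keep], barr[keep]
            order = np.argsort(-(vals + barr), kind="stable")
            prof = self.pset[occ.eid]
            is_open = isinstance(prof, HelixProfile) and occ.which == 0
            for idx in order.tolist():
                if total + vals[idx] + barr[idx] <= best[0] + EPS:
                    continue
                p = int(cand[idx])
                ls = lsuffix
                if k == 0 and len(seq) > 1:
                    ls = self._local_suffix(g, seq, p, cache)
                    if total + vals[idx] + ls[1] <= best[0] + EPS:
                        continue
                starts[occ.item_idx] = p
                if is_open:
                    open5[occ.eid] = p
                    rec(k + 1, starts, open5, total, ls)
                    del open5[occ.eid]
                else:
                    rec(k + 1, starts, open5, total + float(vals[idx]), ls)
                del starts[occ.item_idx]

        rec(0, {}, {}, 0.0, None)
        return best[0]

    # -- hit assembly -------------------------------------------------------
    def placement_to_hit(
        self, contig: str, strand: str, g: np.ndarray, placement,
    ) -> Hit:
        starts, scores, total = placement
        Lg = len(g)
        placed = sorted(starts)
        occ_spans = []
        element_seqs: dict[int, str | tuple[str, str]] = {}
        helix_parts: dict[int, dict[int, str]] = {}
        for idx in placed:
            occ = self.items[idx]
            p = starts[idx]
            s0, e0 = p, p + occ.length  # scanned coords, half-open
            seg = decode(g[s0:e0]).upper()
            if strand == "+":
                fs, fe = s0 + 1, e0
            else:
                fs, fe = Lg - e0 + 1, Lg - s0
            occ_spans.append((occ.eid, occ.which, fs, fe))
            prof = self.pset[occ.eid]
            if isinstance(prof, SingleStrandProfile):
                element_seqs[occ.eid] = seg
            else:
                helix_parts.setdefault(occ.eid, {})[occ.which] = seg
        for eid, parts in helix_parts.items():
            element_seqs[eid] = (parts[0], parts[1])
        region_seqs: dict[int, str] = {}
        for a, b in zip(placed, placed[1:]):
            between = self.items[a + 1:b]
            if len(between) == 1 and isinstance(between[0], _Gap) \
                    and between[0].region_index is not None:
                s0 = starts[a] + self.items[a].length
                e0 = starts[b]
                region_seqs[between[0].region_index] = decode(g[s0:e0]).upper()
        start = min(s for _, _, s, _ in occ_spans)
        end = max(e for _, _, _, e in occ_spans)
        return Hit(
            model=self.model.name, contig=contig, strand=strand,
            start=start, end=end, score=float(total), evalue=None,
            element_scores={k: float(v) for k, v in scores.items()},
            occ_spans=tuple(occ_spans), element_seqs=element_seqs,
            region_seqs=region_seqs,
        )


# ---------------------------------------------------------------------------
# public operations

def _overlap(a: Hit, b: Hit) -> bool:
    return (a.contig == b.contig and a.strand == b.strand
            and a.start <= b.end and b.start <= a.end)


def reduce_overlaps(hits: Sequence[Hit]) -> list[Hit]:
    """Keep the best-scoring hit of every overlapping set of placements of
    one model (ties go to the leftmost placement)."""
    order = sorted(
        hits,
        key=lambda h: (-round(h.score, SCORE_DECIMALS), h.contig, h.strand,
                       h.start, h.end),
    )
    kept: list[Hit] = []
    for h in order:
        if not any(_overlap(h, k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.strand, h.start, h.end))
    return kept


def rank_hits(hits: Sequence[Hit]) -> list[Hit]:
    """Stable sort by ascending E-value; ties broken by higher score, then
    leftmost coordinate."""
    return sorted(
        hits,
        key=lambda h: (
            h.evalue if h.evalue is not None else float("inf"),
            -round(h.score, SCORE_DECIMALS), h.contig, h.start, h.end,
        ),
    )


def search(
    model: StructuredAlignment,
    pset: ProfileSet,
    strategy: Strategy,
    genomes: Sequence[GenomeRecord],
    calibration: EvalueCalibration | None = None,
    *,
    both_strands: bool = True,
    slack: float = 0.2,
) -> SearchResult:
    """Run the multi-level strategy over every genome, both strands.

    Unsatisfiable distance bounds simply yield zero hits.  Overlapping
    placements of the model are reduced to the best-scoring one; hits are
    returned ranked by E-value (by score when no calibration is given).
    """
    scanner = _Scanner(model, pset, strategy, slack)
    hits: list[Hit] = []
    stats_total: list[dict] = []
    scanned_len = 0
    for grec in genomes:
        fwd = encode(grec.sequence)
        scanned_len += len(fwd) * (2 if both_strands else 1)
        strands = [("+", fwd)]
        if both_strands:
            strands.append(("-", revcomp_encoded(fwd)))
        for strand, g in strands:
            placements, stats = scanner.scan(g)
            for st in stats:
                while len(stats_total) < st["level"]:
                    stats_total.append({
                        "level": len(stats_total) + 1,
                        "evaluations": 0, "survivors": 0,
                    })
                agg = stats_total[st["level"] - 1]
                agg["evaluations"] += st["evaluations"]
                agg["survivors"] += st["survivors"]
            for pl in placements:
                hits.append(scanner.placement_to_hit(grec.uid, strand, g, pl))
    hits = reduce_overlaps(hits)
    if calibration is not None and scanned_len > 0:
        for h in hits:
            h.evalue = calibration.evalue(h.score, scanned_len)
    return SearchResult(rank_hits(hits), stats_total)


def calibrate_evalues(
    model: StructuredAlignment,
    pset: ProfileSet,
    strategy: Strategy,
    *,
    n_shuffles: int = 500,
    shuffle_len: int = 10_000,
    seed: int,
    background: Background | None = None,
    slack: float = 0.2,
    both_strands: bool = True,
) -> EvalueCalibration:
    """Fit a Gumbel to per-shuffle best strategy scores on i.i.d.
    background sequence (maximum-likelihood fit)."""
    bg = (background or pset.background).array
    rng = np.random.default_rng(seed)
    scanner = _Scanner(model, pset, strategy, slack)
    maxima = []
    for _ in range(n_shuffles):
        g = rng.choice(4, size=shuffle_len, p=bg).astype(np.uint8)
        s = scanner.best_score(g)
        if math.isfinite(s):
            maxima.append(s)
    if len(maxima) < 10:
        raise ValueError(
            "too few finite shuffle maxima to calibrate "
            f"({len(maxima)}); increase shuffle_len")
    mu, beta = sps.gumbel_r.fit(np.asarray(maxima))
    beta = max(float(beta), 1e-6)
    return EvalueCalibration(float(mu), beta, shuffle_len, n_shuffles,
                             both_strands)
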