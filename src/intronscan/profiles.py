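"""Per-motif probabilistic profiles and log-odds scoring.

Training is column-wise: for a single-strand motif every alignment column
gets a 4-entry base distribution, for a helix every pair-column gets a
16-entry distribution over ordered base pairs, so that compensatory
(covarying) substitutions score well even when each strand alone is
variable.  Estimation uses background-scaled pseudocounts::

    p(b | col) = (count_b + pc * bg_b) / (n_nongap + pc)

and scores are ``log2(p / bg)`` in bits.  Helices are indel-free by
construction: a training sequence with a gap inside a helix strand is
excluded from that helix's pair counts (with a warning).

``tstat`` mirrors the per-motif training-score summaries used to derive
search cutoffs: every training sequence is scored against its own
profiles and the suggested cutoff is the minimum self-score minus a
configurable margin.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .alphabet import DEGENERATE, RNA_BASES, encode
from .model import StructuredAlignment


def _warn(on_warning: Callable[[str], None] | None, msg: str) -> None:
    if on_warning is not None:
        on_warning(msg)
    else:
        warnings.warn(msg, stacklevel=3)


@dataclass(frozen=True)
class Background:
    """Null base frequencies over A, C, G, U."""

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-9 or min(self.freqs) <= 0:
            raise ValueError("background frequencies must be positive and sum to 1")

    @classmethod
    def uniform(cls) -> "Background":
        return cls()

    @classmethod
    def from_sequence(cls, seq: str) -> "Background":
        enc = encode(seq)
        counts = np.bincount(enc[enc < 4], minlength=4).astype(float)
        if counts.sum() == 0:
            return cls.uniform()
        # tiny floor keeps log-odds finite on skewed genomes
        counts += 1.0
        f = counts / counts.sum()
        return cls(tuple(f))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs)


@dataclass
class SingleStrandProfile:
    """Per-column log-odds (bits) over A,C,G,U for one single-strand motif."""

    element_id: int
    log_odds: np.ndarray  # (L, 4)
    consensus: str  # uppercase where column information >= threshold
    kept_columns: tuple[int, ...]  # alignment columns retained at training

    kind = "single_strand"

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def score_matrix(self) -> np.ndarray:
        """(L, 5) table; degenerate index 4 scores 0 (background)."""
        m = getattr(self, "_score_matrix", None)
        if m is None:
            m = np.zeros((self.length, 5))
            m[:, :4] = self.log_odds
            self._score_matrix = m
        return m

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class HelixProfile:
    """Per pair-column log-odds (bits) over ordered base pairs.

    Pair-column ``i`` pairs position ``i`` of the 5' strand with position
    ``L - 1 - i`` of the 3' strand.
    """

    element_id: int
    pair_log_odds: np.ndarray  # (L, 4, 4)

    kind = "helix"

    @property
    def length(self) -> int:
        return self.pair_log_odds.shape[0]

    @property
    def score_matrix(self) -> np.ndarray:
        """(L, 5, 5) table; any degenerate partner scores 0."""
        m = getattr(self, "_score_matrix", None)
        if m is None:
            m = np.zeros((self.length, 5, 5))
            m[:, :4, :4] = self.pair_log_odds
            self._score_matrix = m
        return m

    @property
    def max_score(self) -> float:
        return float(self.pair_log_odds.max(axis=(1, 2)).sum())


Profile = SingleStrandProfile | HelixProfile


@dataclass
class ProfileSet:
    """Trained profiles for every element of one model."""

    model_name: str
    background: Background
    profiles: dict[int, Profile]
    pseudocount: float = 1.0

    def __getitem__(self, element_id: int) -> Profile:
        return self.profiles[element_id]

    def __contains__(self, element_id: int) -> bool:
        return element_id in self.profiles

    # -- JSON serialisation (schema documented in the README) --------------
    def to_json(self) -> str:
        doc = {
            "model": self.model_name,
            "pseudocount": self.pseudocount,
            "background": list(self.background.freqs),
            "elements": [],
        }
        for eid in sorted(self.profiles):
            p = self.profiles[eid]
            if isinstance(p, SingleStrandProfile):
                doc["elements"].append({
                    "id": eid,
                    "kind": "single_strand",
                    "log_odds": p.log_odds.tolist(),
                    "consensus": p.consensus,
                    "kept_columns": list(p.kept_columns),
                })
            else:
                doc["elements"].append({
                    "id": eid,
                    "kind": "helix",
                    "pair_log_odds": p.pair_log_odds.tolist(),
                })
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProfileSet":
        doc = json.loads(text)
        profiles: dict[int, Profile] = {}
        for e in doc["elements"]:
            if e["kind"] == "single_strand":
                profiles[e["id"]] = SingleStrandProfile(
                    e["id"],
                    np.asarray(e["log_odds"], dtype=float),
                    e["consensus"],
                    tuple(e["kept_columns"]),
                )
            else:
                profiles[e["id"]] = HelixProfile(
                    e["id"], np.asarray(e["pair_log_odds"], dtype=float)
                )
        return cls(
            doc["model"],
            Background(tuple(doc["background"])),
            profiles,
            doc.get("pseudocount", 1.0),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ProfileSet":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# training

def train(
    model: StructuredAlignment,
    pseudocount: float = 1.0,
    background: Background | None = None,
    conserved_info_threshold: float = 1.0,
    on_warning: Callable[[str], None] | None = None,
) -> ProfileSet:
    """Estimate per-element profiles from the structured alignment."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if model.n_sequences == 0:
        raise ValueError("empty alignment")
    bg = background or Background.uniform()
    bga = bg.array
    rows = [encode(seq) for _, seq in model.sequences]
    gap_rows = [np.frombuffer(seq.encode(), dtype=np.uint8) == ord("-")
                for _, seq in model.sequences]

    profiles: dict[int, Profile] = {}
    for el in model.elements:
        if el.kind == "single_strand":
            s, t = el.columns5
            kept: list[int] = []
            cols_lo: list[np.ndarray] = []
            cons: list[str] = []
            for c in range(s, t):
                counts = np.zeros(4)
                for enc, gaps in zip(rows, gap_rows):
                    if not gaps[c] and enc[c] < 4:
                        counts[enc[c]] += 1
                n = counts.sum()
                if n == 0:
                    _warn(on_warning,
                          f"element {el.element_id}: column {c} is all-gap; dropped")
                    continue
                p = (counts + pseudocount * bga) / (n + pseudocount)
                kept.append(c)
                cols_lo.append(np.log2(p / bga))
                info = 2.0 + float(np.sum(p * np.log2(p)))
                base = RNA_BASES[int(np.argmax(p))]
                cons.append(base if info >= conserved_info_threshold
                            else base.lower())
            if not kept:
                raise ValueError(
                    f"element {el.element_id}: every column is all-gap")
            profiles[el.element_id] = SingleStrandProfile(
                el.element_id, np.vstack(cols_lo), "".join(cons), tuple(kept)
            )
        else:
            L = el.length5
            s5, _ = el.columns5
            s3, _ = el.columns3
            counts = np.zeros((L, 4, 4))
            n_used = 0
            for (sid, _), enc, gaps in zip(model.sequences, rows, gap_rows):
                occ5 = slice(s5, s5 + L)
                occ3 = slice(s3, s3 + L)
                if gaps[occ5].any() or gaps[occ3].any():
                    _warn(on_warning,
                          f"helix {el.element_id}: sequence {sid!r} has a gap "
                          f"inside a helix strand; excluded from pair counts")
                    continue
                e5 = enc[occ5]
                e3 = enc[occ3]
                ok = True
                for i in range(L):
                    if e5[i] >= 4 or e3[L - 1 - i] >= 4:
                        ok = False
                        break
                if not ok:
                    _warn(on_warning,
                          f"helix {el.element_id}: sequence {sid!r} has a "
                          f"non-ACGU character in a helix strand; excluded")
                    continue
                for i in range(L):
                    counts[i, e5[i], e3[L - 1 - i]] += 1
                n_used += 1
            if n_used == 0:
                _warn(on_warning,
                      f"helix {el.element_id}: no gap-free training sequence; "
                      f"profile falls back to background (zero log-odds)")
            bg_pair = np.outer(bga, bga)
            p = (counts + pseudocount * bg_pair) / (n_used + pseudocount)
            profiles[el.element_id] = HelixProfile(
                el.element_id, np.log2(p / bg_pair)
            )
    return ProfileSet(model.name, bg, profiles, pseudocount)


# ---------------------------------------------------------------------------
# scoring

def score_single_strand(profile: SingleStrandProfile, segment: str) -> float:
    """Sum of per-column log-odds for a gap-free segment (T == U)."""
    enc = encode(segment)
    if len(enc) != profile.length:
        raise ValueError(
            f"segment length {len(enc)} != profile length {profile.length}")
    return float(profile.score_matrix[np.arange(profile.length), enc].sum())


def score_helix(profile: HelixProfile, segment5: str, segment3: str) -> float:
    """Sum of pair-column log-odds; both strands must be exactly the helix
    length (deletions in helices are not allowed)."""
    e5 = encode(segment5)
    e3 = encode(segment3)
    L = profile.length
    if len(e5) != L or len(e3) != L:
        raise ValueError(
            f"helix segments must both have length {L} "
            f"(got {len(e5)}, {len(e3)})")
    m = profile.score_matrix
    return float(sum(m[i, e5[i], e3[L - 1 - i]] for i in range(L)))


# ---------------------------------------------------------------------------
# training-score summaries ("tstat")

@dataclass(frozen=True)
class ElementStats:
    mean: float
    sd: float
    min: float
    max: float
    cutoff: float


@dataclass
class TrainStats:
    """Per-element score statistics over the training sequences."""

    per_element: dict[int, ElementStats]
    total: ElementStats
    margin: float

    def cutoff_for(self, element_ids) -> float:
        """Suggested cumulative cutoff: sum of per-element training minima
        minus the margin."""
        return sum(self.per_element[eid].min for eid in element_ids) - self.margin


def self_scores(
    profiles: ProfileSet, model: StructuredAlignment
) -> dict[int, np.ndarray]:
    """Score every training sequence against its own element profiles.

    Gap (or degenerate) positions contribute 0, mirroring the background
    treatment at search time.
    """
    out: dict[int, np.ndarray] = {}
    rows = [encode(seq) for _, seq in model.sequences]
    gap_rows = [np.frombuffer(seq.encode(), dtype=np.uint8) == ord("-")
                for _, seq in model.sequences]
    for el in model.elements:
        prof = profiles[el.element_id]
        scores = np.zeros(model.n_sequences)
        if el.kind == "single_strand":
            m = prof.score_matrix
            for r, (enc, gaps) in enumerate(zip(rows, gap_rows)):
                s = 0.0
                for k, c in enumerate(prof.kept_columns):
                    if not gaps[c]:
                        s += m[k, enc[c]]
                scores[r] = s
        else:
            L = prof.length
            s5 = el.columns5[0]
            s3 = el.columns3[0]
            m = prof.score_matrix
            for r, (enc, gaps) in enumerate(zip(rows, gap_rows)):
                s = 0.0
                for i in range(L):
                    c5 = s5 + i
                    c3 = s3 + L - 1 - i
                    if not gaps[c5] and not gaps[c3]:
                        s += m[i, enc[c5], enc[c3]]
                scores[r] = s
        out[el.element_id] = scores
    return out


def tstat(
    profiles: ProfileSet, model: StructuredAlignment, margin: float = 1.0
) -> TrainStats:
    per_el = self_scores(profiles, model)
    stats: dict[int, ElementStats] = {}
    for eid, sc in per_el.items():
        stats[eid] = ElementStats(
            float(sc.mean()), float(sc.std()), float(sc.min()),
            float(sc.max()), float(sc.min()) - margin,
        )
    totals = np.sum(np.vstack(list(per_el.values())), axis=0)
    total = ElementStats(
        float(totals.mean()), float(totals.std()), float(totals.min()),
        float(totals.max()), float(totals.min()) - margin,
    )
    return TrainStats(stats, total, margin)
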