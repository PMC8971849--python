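"""Synthetic models, introns and host genomes with ground truth.

The generator emulates the study system at desk scale: structured toy
models (single strands and helices, optionally with one pseudoknotted
pairing, mirroring the P7 geometry), training alignments sampled around
a random consensus, divergent sister models standing in for closely
related sub-groups (the IC1/IC2 or IB1/2/4 situations), and A+T-rich
host genomes (fungal mitochondrial bias) with implanted introns plus a
BED ground-truth track.

Every output is a deterministic function of the seed.  Helix mutations
are compensatory with probability ``p_comp`` so that pair columns carry
covariation signal, as real helices do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import revcomp_dna, to_dna
from .model import GenomeRecord, StructuredAlignment
from .profiles import ProfileSet, train

RNA = "ACGU"
_WC_PAIRS = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic model/genome fixture.

    The defaults describe a well-conserved group-I-like model: five
    motifs (three single strands, two helices forming one pseudoknot),
    high per-column conservation, 20 training sequences, and a 70%
    A+T background mirroring fungal mtDNA composition.
    """

    seed: int = 0
    layout: tuple[str, ...] = ("ss", "helix", "ss", "helix", "ss")
    pseudoknot: bool = True
    ss_len_range: tuple[int, int] = (5, 9)
    helix_len_range: tuple[int, int] = (4, 7)
    var_region_range: tuple[int, int] = (3, 10)
    conservation: float = 0.95
    p_comp: float = 0.8
    n_training: int = 20
    background_length: int = 100_000
    at_fraction: float = 0.7
    divergence: float = 0.3
    name: str = "synthA"

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if not 0.0 < self.conservation <= 1.0:
            raise ValueError("conservation must lie in (0, 1]")
        if any(k not in ("ss", "helix") for k in self.layout):
            raise ValueError("layout entries must be 'ss' or 'helix'")


# ---------------------------------------------------------------------------
# consensus machinery

@dataclass
class _Blueprint:
    """Internal generative state of a model: per-element consensus and
    per-variable-region width."""

    layout: tuple[str, ...]
    pseudoknot: bool
    consensus: dict[int, str]  # element id -> 5' strand consensus
    lengths: dict[int, int]
    var_widths: list[int]  # one per inter-occurrence junction


def _occurrence_order(layout: tuple[str, ...], pseudoknot: bool) -> list[tuple[int, int]]:
    """(element_id, which) occurrence order along the genome.

    Helices open and close around their own variable loop; with a
    pseudoknot the first two helices interleave: A5 .. B5 .. A3 .. B3.
    """
    order: list[tuple[int, int]] = []
    for i, kind in enumerate(layout, start=1):
        if kind == "ss":
            order.append((i, 0))
        else:
            order.append((i, 0))
            order.append((i, 1))
    helices = [i for i, kind in enumerate(layout, start=1) if kind == "helix"]
    if pseudoknot and len(helices) >= 2:
        a, b = helices[0], helices[1]
        order.remove((a, 1))
        order.insert(order.index((b, 0)) + 1, (a, 1))
    return order


def _mutate_ss(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(RNA[rng.integers(0, 4)])
        else:
            out.append(ch)
    return "".join(out)


def _mutate_helix(
    seq5: str, rate: float, p_comp: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Mutate a helix given by its 5' consensus; the 3' strand starts as
    the reverse complement.  Substitutions are compensatory (a fresh
    Watson-Crick pair) with probability p_comp, otherwise one random
    strand is hit alone."""
    L = len(seq5)
    s5 = list(seq5)
    s3 = list(revcomp_rna_local(seq5))
    for i in range(L):
        if rng.random() >= rate:
            continue
        j = L - 1 - i  # partner position on the 3' strand
        if rng.random() < p_comp:
            b5, b3 = _WC_PAIRS[rng.integers(0, 4)]
            s5[i], s3[j] = b5, b3
        else:
            if rng.random() < 0.5:
                s5[i] = RNA[rng.integers(0, 4)]
            else:
                s3[j] = RNA[rng.integers(0, 4)]
    return "".join(s5), "".join(s3)


def revcomp_rna_local(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _random_blueprint(spec: FixtureSpec, rng: np.random.Generator) -> _Blueprint:
    consensus: dict[int, str] = {}
    lengths: dict[int, int] = {}
    for i, kind in enumerate(spec.layout, start=1):
        if kind == "ss":
            L = int(rng.integers(spec.ss_len_range[0],
                                 spec.ss_len_range[1] + 1))
        else:
            L = int(rng.integers(spec.helix_len_range[0],
                                 spec.helix_len_range[1] + 1))
        lengths[i] = L
        consensus[i] = "".join(RNA[rng.integers(0, 4)] for _ in range(L))
    order = _occurrence_order(spec.layout, spec.pseudoknot)
    var_widths = [int(rng.integers(spec.var_region_range[0],
                                   spec.var_region_range[1] + 1))
                  for _ in range(len(order) - 1)]
    return _Blueprint(spec.layout, spec.pseudoknot, consensus, lengths,
                      var_widths)


def _blueprint_from_model(model: StructuredAlignment) -> _Blueprint:
    """Recover a generative blueprint from a model alignment: per-column
    majority consensus and the observed variable-region widths."""
    layout = tuple(
        "ss" if e.kind == "single_strand" else "helix" for e in model.elements)
    consensus: dict[int, str] = {}
    lengths: dict[int, int] = {}
    for e in model.elements:
        s, t = e.columns5
        cols = []
        for c in range(s, t):
            counts = {b: 0 for b in RNA}
            for _, seq in model.sequences:
                if seq[c] in counts:
                    counts[seq[c]] += 1
            cols.append(max(RNA, key=lambda b: counts[b]))
        consensus[e.element_id] = "".join(cols)
        lengths[e.element_id] = t - s
    pk = any(e.pseudoknot for e in model.elements)
    items = model.layout()
    var_widths = []
    prev_occ = None
    for it in items:
        if it[0] == "occ":
            if prev_occ is not None and prev_occ[0] == "occ":
                var_widths.append(0)
            prev_occ = it
        else:
            var_widths.append(it[2][1] - it[2][0])
            prev_occ = it
    return _Blueprint(layout, pk, consensus, lengths, var_widths)


def _sample_row_parts(
    bp: _Blueprint, spec: FixtureSpec, rng: np.random.Generator
) -> tuple[dict[tuple[int, int], str], list[int]]:
    """One sampled intron: occurrence sequences plus spacer lengths."""
    rate = 1.0 - spec.conservation
    occ_seqs: dict[tuple[int, int], str] = {}
    for i, kind in enumerate(bp.layout, start=1):
        if kind == "ss":
            occ_seqs[(i, 0)] = _mutate_ss(bp.consensus[i], rate, rng)
        else:
            s5, s3 = _mutate_helix(bp.consensus[i], rate, spec.p_comp, rng)
            occ_seqs[(i, 0)] = s5
            occ_seqs[(i, 1)] = s3
    spacer_lens = [
        int(rng.integers(max(0, w - 3), w + 1)) if w > 0 else 0
        for w in bp.var_widths
    ]
    return occ_seqs, spacer_lens


def _random_rna(n: int, at_fraction: float, rng: np.random.Generator) -> str:
    p = np.array([at_fraction / 2, (1 - at_fraction) / 2,
                  (1 - at_fraction) / 2, at_fraction / 2])
    return "".join(np.array(list(RNA))[rng.choice(4, size=n, p=p)]) if n else ""


def _assemble_alignment(
    name: str,
    bp: _Blueprint,
    rows: list[tuple[dict[tuple[int, int], str], list[int]]],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> StructuredAlignment:
    order = _occurrence_order(bp.layout, bp.pseudoknot)
    tokens: list[str] = []
    for k, (eid, _which) in enumerate(order):
        tokens.extend([str(eid)] * bp.lengths[eid])
        if k < len(order) - 1 and bp.var_widths[k] > 0:
            tokens.extend(["."] * bp.var_widths[k])
    seqs: list[tuple[str, str]] = []
    for r, (occ_seqs, spacer_lens) in enumerate(rows):
        parts: list[str] = []
        for k, occ in enumerate(order):
            parts.append(occ_seqs[occ])
            if k < len(order) - 1 and bp.var_widths[k] > 0:
                n = min(spacer_lens[k], bp.var_widths[k])
                spacer = _random_rna(n, spec.at_fraction, rng)
                parts.append(spacer + "-" * (bp.var_widths[k] - n))
        seqs.append((f"t{r + 1:03d}", "".join(parts)))
    return StructuredAlignment.from_sequences(name, seqs, tokens)


# ---------------------------------------------------------------------------
# public operations

def make_model(
    spec: FixtureSpec, pseudocount: float = 1.0
) -> tuple[StructuredAlignment, ProfileSet]:
    """Draw a consensus, sample a training alignment around it, and train
    profiles.  Fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    bp = _random_blueprint(spec, rng)
    rows = [_sample_row_parts(bp, spec, rng) for _ in range(spec.n_training)]
    model = _assemble_alignment(spec.name, bp, rows, spec, rng)
    pset = train(model, pseudocount=pseudocount)
    return model, pset


def make_sister_model(
    model: StructuredAlignment,
    spec: FixtureSpec,
    divergence: float | None = None,
    name: str | None = None,
    seed: int | None = None,
    pseudocount: float = 1.0,
) -> tuple[StructuredAlignment, ProfileSet]:
    """A sister sub-group: same topology, consensus mutated at the
    divergence rate, fresh training alignment at the same conservation."""
    div = spec.divergence if divergence is None else divergence
    rng = np.random.default_rng(spec.seed + 7_777 if seed is None else seed)
    bp = _blueprint_from_model(model)
    sister_consensus: dict[int, str] = {}
    for i, kind in enumerate(bp.layout, start=1):
        if kind == "ss":
            sister_consensus[i] = _mutate_ss(bp.consensus[i], div, rng)
        else:
            s5, _ = _mutate_helix(bp.consensus[i], div, spec.p_comp, rng)
            sister_consensus[i] = s5
    bp2 = _Blueprint(bp.layout, bp.pseudoknot, sister_consensus, bp.lengths,
                     bp.var_widths)
    rows = [_sample_row_parts(bp2, spec, rng) for _ in range(spec.n_training)]
    sister = _assemble_alignment(
        name or f"{model.name}_sister", bp2, rows, spec, rng)
    return sister, train(sister, pseudocount=pseudocount)


@dataclass(frozen=True)
class Implant:
    """Ground truth for one implanted intron (0-based half-open)."""

    contig: str
    start: int
    end: int
    model: str
    strand: str


def sample_intron(
    model: StructuredAlignment, spec: FixtureSpec, rng: np.random.Generator
) -> str:
    """One intron sequence (DNA, forward orientation) sampled from the
    model: consensus with column-wise mutation, spacer lengths drawn from
    the observed variable-region ranges."""
    bp = _blueprint_from_model(model)
    occ_seqs, _ = _sample_row_parts(bp, spec, rng)
    order = _occurrence_order(bp.layout, bp.pseudoknot)
    # observed [min, max] per inter-occurrence junction, in occurrence order
    items = model.layout()
    var_ranges: list[tuple[int, int]] = []
    it_iter = iter(items)
    prev = next(it_iter)
    for it in it_iter:
        if it[0] == "var":
            r = model.variable_regions[it[1]]
            var_ranges.append((r.min_len, r.max_len))
        elif prev[0] == "occ":
            var_ranges.append((0, 0))
        prev = it
    parts: list[str] = []
    for k, occ in enumerate(order):
        parts.append(occ_seqs[occ])
        if k < len(order) - 1:
            lo, hi = var_ranges[k] if k < len(var_ranges) else (0, 0)
            n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            parts.append(_random_rna(n, spec.at_fraction, rng))
    return to_dna("".join(parts))


def implant(
    models: list[tuple[StructuredAlignment, FixtureSpec]],
    counts: dict[str, int],
    *,
    seed: int,
    background_length: int = 100_000,
    at_fraction: float = 0.7,
    contig: str = "contig1",
    min_gap: int = 60,
) -> tuple[list[GenomeRecord], list[Implant]]:
    """Build a host genome with implanted introns and ground truth.

    Introns are sampled from each model, inserted at non-overlapping loci
    on random strands; the BED-style truth carries the model of origin.
    """
    rng = np.random.default_rng(seed)
    introns: list[tuple[str, str]] = []  # (model name, dna seq fwd)
    for m, spec in models:
        for _ in range(counts.get(m.name, 0)):
            introns.append((m.name, sample_intron(m, spec, rng)))
    perm = rng.permutation(len(introns))
    introns = [introns[i] for i in perm]
    n = len(introns)
    total_intron = sum(len(s) for _, s in introns)
    bg_total = max(background_length - total_intron, (n + 1) * min_gap)
    chunk_extra = rng.multinomial(bg_total - (n + 1) * min_gap,
                                  [1.0 / (n + 1)] * (n + 1)) if n >= 0 else []
    chunks = [min_gap + int(x) for x in chunk_extra]

    p = np.array([at_fraction / 2, (1 - at_fraction) / 2,
                  (1 - at_fraction) / 2, at_fraction / 2])
    bases = np.array(list("ACGT"))

    def bg(nlen: int) -> str:
        return "".join(bases[rng.choice(4, size=nlen, p=p)]) if nlen else ""

    pieces: list[str] = []
    truth: list[Implant] = []
    pos = 0
    for i, (mname, dna) in enumerate(introns):
        piece = bg(chunks[i])
        pieces.append(piece)
        pos += len(piece)
        strand = "+" if rng.random() < 0.5 else "-"
        ins = dna if strand == "+" else revcomp_dna(dna)
        truth.append(Implant(contig, pos, pos + len(ins), mname, strand))
        pieces.append(ins)
        pos += len(ins)
    pieces.append(bg(chunks[n]))
    genome = GenomeRecord(uid=contig, organism="synthetic host",
                          taxonomy="synthetic", accession="SYN000001",
                          sequence="".join(pieces))
    return [genome], truth


def write_truth_bed(truth: list[Implant], path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.model}\t0\t{t.strand}\n")


def read_truth_bed(path) -> list[Implant]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name, _score, strand = line.split("\t")
            out.append(Implant(c, int(s), int(e), name, strand.strip()))
    return out
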