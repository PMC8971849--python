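"""Structured-alignment models: parsing, validation and format I/O.

A *model* is a structured multiple sequence alignment: aligned RNA
sequences over ``{A,C,G,U,-}`` together with a structure line that labels
every alignment column.  The structure line uses consecutive integer
labels: a label occurring as a single run of columns marks a
single-stranded motif, a label occurring as two runs marks the 5' and 3'
strands of a helix.  Columns labelled ``.`` are variable-length spacer
regions separating the conserved motifs.

Two helices whose column intervals interleave cannot be drawn as nested
brackets; the later one (by 5' start) is flagged as a pseudoknot.  In
group I introns the canonical pseudoknot is the P7 pairing, part of the
guanosine-binding catalytic core.

On-disk dialect (FASTA-like, documented in the README)::

    # model: NAME
    >structure
    1 1 1 . . 2 2 3 3 . 2 2
    >seq1
    AUGCC--GGAUU

File I/O for genomes is plain FASTA; ``to_stockholm`` exports a model as
Stockholm 1.0 with a WUSS consensus structure line in which nested
helices are rendered as angle brackets and pseudoknotted helices as
matched upper/lower-case letter pairs (``AA..aa``) so that covariance
model builders can consume the alignment.
"""

from __future__ import annotations

import io
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VAR_TOKEN = "."
MODEL_ALPHABET = set("ACGU-")


class ModelFormatError(ValueError):
    """Raised for malformed structure lines, alignments or model files."""


@dataclass(frozen=True)
class StructureElement:
    """One conserved motif: a single strand or a helix.

    Column intervals are 0-based half-open alignment coordinates.
    ``columns3`` is present only for helices (the 3' strand run).
    """

    element_id: int
    kind: str  # "single_strand" | "helix"
    columns5: tuple[int, int]
    columns3: tuple[int, int] | None = None
    pseudoknot: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("single_strand", "helix"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "helix":
            if self.columns3 is None:
                raise ValueError("helix element requires columns3")
            if self.length5 != self.length3:
                raise ModelFormatError(
                    f"helix {self.element_id}: strand lengths differ "
                    f"({self.length5} vs {self.length3})"
                )
        elif self.columns3 is not None:
            raise ValueError("single_strand element must not have columns3")

    @property
    def length5(self) -> int:
        return self.columns5[1] - self.columns5[0]

    @property
    def length3(self) -> int:
        return 0 if self.columns3 is None else self.columns3[1] - self.columns3[0]

    @property
    def occurrences(self) -> tuple[tuple[int, int], ...]:
        if self.columns3 is None:
            return (self.columns5,)
        return (self.columns5, self.columns3)


@dataclass(frozen=True)
class VariableRegion:
    """A run of ``.`` columns between motifs, with observed spacer lengths."""

    index: int
    columns: tuple[int, int]
    min_len: int
    max_len: int


@dataclass(frozen=True)
class GenomeRecord:
    """A genome/contig with the 4-field header convention tolerated on input.

    Header convention: ``>uid organism;taxonomy;accession`` where uid is a
    short unique identifier (e.g. derived from genus, species, accession).
    """

    uid: str
    organism: str = ""
    taxonomy: str = ""
    accession: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.uid:
            raise ValueError("GenomeRecord uid must be non-empty")
        if not self.sequence:
            raise ValueError(f"GenomeRecord {self.uid}: empty sequence")


def helices_cross(a5: int, a3: int, b5: int, b3: int) -> bool:
    """True iff two helices, given by their occurrence start columns,
    interleave (pseudoknot geometry)."""
    return (a5 < b5 < a3 < b3) or (b5 < a5 < b3 < a3)


def parse_structure_line(tokens: Sequence[str]) -> list[StructureElement]:
    """Parse structure tokens into elements.

    Each token is an integer label or ``.``.  Contiguous runs of a label
    form one occurrence: one run -> single strand, two runs -> helix
    (equal run lengths required).  More than two runs is a format error.
    Helices that cross an already-accepted nested helix (scanning by 5'
    start) are flagged as pseudoknots.
    """
    runs: dict[int, list[tuple[int, int]]] = {}
    i = 0
    n = len(tokens)
    while i < n:
        tok = str(tokens[i]).strip()
        if tok == VAR_TOKEN:
            i += 1
            continue
        try:
            label = int(tok)
        except ValueError:
            raise ModelFormatError(f"bad structure token {tok!r} at column {i}")
        j = i
        while j < n and str(tokens[j]).strip() == tok:
            j += 1
        runs.setdefault(label, []).append((i, j))
        i = j

    elements: list[StructureElement] = []
    for label, occ in runs.items():
        if len(occ) > 2:
            raise ModelFormatError(
                f"label {label} occurs in {len(occ)} runs (at most 2 allowed)"
            )
        if len(occ) == 1:
            elements.append(
                StructureElement(label, "single_strand", occ[0])
            )
        else:
            if occ[0][1] - occ[0][0] != occ[1][1] - occ[1][0]:
                raise ModelFormatError(
                    f"helix {label}: unequal occurrence lengths "
                    f"{occ[0][1] - occ[0][0]} vs {occ[1][1] - occ[1][0]}"
                )
            elements.append(StructureElement(label, "helix", occ[0], occ[1]))

    # pseudoknot flagging: greedy nested set by 5' start; crossers are flagged
    helices = sorted(
        (e for e in elements if e.kind == "helix"), key=lambda e: e.columns5[0]
    )
    nested: list[StructureElement] = []
    flagged: set[int] = set()
    for h in helices:
        crosses = any(
            helices_cross(
                g.columns5[0], g.columns3[0], h.columns5[0], h.columns3[0]
            )
            for g in nested
        )
        if crosses:
            flagged.add(h.element_id)
        else:
            nested.append(h)

    out = []
    for e in sorted(elements, key=lambda e: e.columns5[0]):
        if e.element_id in flagged:
            e = StructureElement(
                e.element_id, e.kind, e.columns5, e.columns3, pseudoknot=True
            )
        out.append(e)
    return out


def serialize_structure_line(
    elements: Iterable[StructureElement], n_columns: int
) -> list[str]:
    """Inverse of :func:`parse_structure_line` (identity on round trips)."""
    tokens = [VAR_TOKEN] * n_columns
    for e in elements:
        for s, t in e.occurrences:
            for c in range(s, t):
                if tokens[c] != VAR_TOKEN:
                    raise ValueError(f"overlapping elements at column {c}")
                tokens[c] = str(e.element_id)
    return tokens


@dataclass(frozen=True)
class StructuredAlignment:
    """Aligned sequences plus parsed structure; the search model."""

    name: str
    sequences: tuple[tuple[str, str], ...]  # (id, aligned string)
    structure_tokens: tuple[str, ...]
    elements: tuple[StructureElement, ...]
    variable_regions: tuple[VariableRegion, ...]

    @classmethod
    def from_sequences(
        cls,
        name: str,
        sequences: Sequence[tuple[str, str]],
        structure_tokens: Sequence[str],
    ) -> "StructuredAlignment":
        if not sequences:
            raise ModelFormatError("model has no aligned sequences")
        n = len(structure_tokens)
        for idx, (sid, seq) in enumerate(sequences):
            if len(seq) != n:
                raise ModelFormatError(
                    f"sequence {sid!r} has length {len(seq)}, "
                    f"structure line has {n} tokens"
                )
            bad = set(seq.upper()) - MODEL_ALPHABET
            if bad:
                raise ModelFormatError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )
        seqs = tuple((sid, seq.upper()) for sid, seq in sequences)
        elements = tuple(parse_structure_line(structure_tokens))
        regions = _variable_regions(seqs, structure_tokens)
        return cls(name, seqs, tuple(str(t) for t in structure_tokens),
                   elements, regions)

    @property
    def n_columns(self) -> int:
        return len(self.structure_tokens)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def element(self, element_id: int) -> StructureElement:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)

    def layout(self) -> list[tuple]:
        """Ordered column tiling of the alignment.

        Items are ``("occ", element_id, which, (start, end))`` with which
        0 for the 5' (or only) occurrence and 1 for a helix 3' strand, or
        ``("var", region_index, (start, end))``, sorted by start column.
        """
        items: list[tuple] = []
        for e in self.elements:
            for which, cols in enumerate(e.occurrences):
                items.append(("occ", e.element_id, which, cols))
        for r in self.variable_regions:
            items.append(("var", r.index, r.columns))
        items.sort(key=lambda it: it[-1][0])
        return items


def _variable_regions(
    sequences: Sequence[tuple[str, str]], tokens: Sequence[str]
) -> tuple[VariableRegion, ...]:
    regions = []
    n = len(tokens)
    i = 0
    idx = 0
    while i < n:
        if str(tokens[i]).strip() == VAR_TOKEN:
            j = i
            while j < n and str(tokens[j]).strip() == VAR_TOKEN:
                j += 1
            lengths = [
                sum(1 for c in seq[i:j] if c != "-") for _, seq in sequences
            ]
            regions.append(
                VariableRegion(idx, (i, j), min(lengths), max(lengths))
            )
            idx += 1
            i = j
        else:
            i += 1
    return tuple(regions)


# ---------------------------------------------------------------------------
# model dialect I/O

def read_model(path: str | Path) -> StructuredAlignment:
    path = Path(path)
    name = path.stem
    structure: list[str] | None = None
    sequences: list[tuple[str, str]] = []
    cur_id: str | None = None
    cur_chunks: list[str] = []
    cur_line = 0

    def flush() -> None:
        nonlocal cur_id, cur_chunks
        if cur_id is None:
            return
        joined = "".join(cur_chunks)
        nonlocal structure
        if cur_id == "structure":
            structure = joined.split()
        else:
            sequences.append((cur_id, joined))
        cur_id, cur_chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("model:"):
                    name = body.split(":", 1)[1].strip()
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0]
                cur_line = lineno
            else:
                if cur_id is None:
                    raise ModelFormatError(
                        f"{path}:{lineno}: sequence data before any '>' record"
                    )
                if cur_id == "structure":
                    cur_chunks.append(line + " ")
                else:
                    cur_chunks.append(line.strip())
    flush()
    if structure is None:
        raise ModelFormatError(f"{path}: missing '>structure' record")
    if not sequences:
        raise ModelFormatError(f"{path}: no aligned sequences")
    for sid, seq in sequences:
        if len(seq) != len(structure):
            raise ModelFormatError(
                f"{path}: sequence {sid!r} length {len(seq)} does not match "
                f"structure line ({len(structure)} tokens)"
            )
    return StructuredAlignment.from_sequences(name, sequences, structure)


def write_model(model: StructuredAlignment, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# model: {model.name}\n")
        fh.write(">structure\n")
        fh.write(" ".join(model.structure_tokens) + "\n")
        for sid, seq in model.sequences:
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Stockholm / WUSS export

def to_stockholm(model: StructuredAlignment) -> str:
    """Render the model as Stockholm 1.0 with a WUSS consensus structure.

    Nested helices become angle brackets; each pseudoknotted helix gets a
    distinct letter pair (``A``/``a``, then ``B``/``b``, ...).  Single
    strands and variable regions are dots.
    """
    ss = [VAR_TOKEN] * model.n_columns
    pk_helices = [
        e for e in model.elements if e.kind == "helix" and e.pseudoknot
    ]
    if len(pk_helices) > len(string.ascii_uppercase):
        raise ModelFormatError(
            f"{len(pk_helices)} pseudoknot helices exceed the 26 WUSS letters"
        )
    letters = iter(string.ascii_uppercase)
    for e in sorted(
        (e for e in model.elements if e.kind == "helix"),
        key=lambda e: e.columns5[0],
    ):
        if e.pseudoknot:
            up = next(letters)
            lo = up.lower()
            open_c, close_c = up, lo
        else:
            open_c, close_c = "<", ">"
        for c in range(*e.columns5):
            ss[c] = open_c
        for c in range(*e.columns3):
            ss[c] = close_c

    width = max(
        [len(sid) for sid, _ in model.sequences] + [len("#=GC SS_cons")]
    )
    lines = ["# STOCKHOLM 1.0", f"#=GF ID {model.name}"]
    for sid, seq in model.sequences:
        lines.append(f"{sid:<{width}} {seq}")
    lines.append(f"{'#=GC SS_cons':<{width}} {''.join(ss)}")
    lines.append("//")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# genome FASTA

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        parts = [p.strip() for p in desc.split(";")] if desc else []
        organism = parts[0] if parts else ""
        # taxonomy strings contain ';' themselves: the accession is the
        # last field, everything in between is taxonomy
        taxonomy = ";".join(parts[1:-1]) if len(parts) > 2 else \
            (parts[1] if len(parts) == 2 else "")
        accession = parts[-1] if len(parts) > 2 else ""
        records.append(
            GenomeRecord(
                uid=rec.id,
                organism=organism,
                taxonomy=taxonomy,
                accession=accession,
                sequence=str(rec.seq).upper(),
            )
        )
    uids = [r.uid for r in records]
    if len(set(uids)) != len(uids):
        raise ModelFormatError(f"{path}: duplicate record ids")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seqrecs = []
    for r in records:
        desc = ""
        if r.organism or r.taxonomy or r.accession:
            desc = f"{r.organism};{r.taxonomy};{r.accession}"
        seqrecs.append(
            SeqRecord(Seq(r.sequence), id=r.uid, description=desc)
        )
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")
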