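"""Core sequence types, mutation notation, and FASTA/FASTQ I/O.

Coordinate convention: all positions are 1-based and inclusive, matching the
standard nucleotide numbering used for the 52-2 polymerase ribozyme and its
relatives. Insertions are anchored to the reference position they *follow*:
``ins88_89:CA`` inserts ``CA`` between positions 88 and 89.

Input sequences may be in the DNA alphabet (deep-sequencing reads of RNA
products); ``T`` is silently converted to ``U`` and case is normalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
_VALID_INPUT = frozenset("ACGUTacgut")

__all__ = [
    "RnaSequence",
    "QualRead",
    "RegionSpec",
    "MutationSpec",
    "normalize_sequence",
    "parse_mutation",
    "format_mutation",
    "invert_mutation",
    "apply_mutations",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_mutation_file",
]


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over {A, C, G, U} with 1-based coordinates."""

    id: str
    residues: str
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-RNA characters {sorted(bad)}; "
                "use normalize_sequence() for raw input"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(
                f"position {position} outside sequence {self.id!r} (length {len(self)})"
            )
        return self.residues[position - 1]

    def subseq(self, start: int, end: int, id: str | None = None) -> "RnaSequence":
        """1-based inclusive slice."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(f"invalid slice {start}-{end} on length {len(self)}")
        return RnaSequence(id or f"{self.id}:{start}-{end}", self.residues[start - 1 : end])


@dataclass(frozen=True)
class QualRead:
    """A read with per-residue Phred quality scores (Sanger scale)."""

    seq: RnaSequence
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.seq.id!r}: {len(self.quals)} qualities for "
                f"{len(self.seq)} residues"
            )
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError(f"read {self.seq.id!r}: Phred scores must lie in [0, 60]")

    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RegionSpec:
    """Named set of 1-based inclusive intervals on a reference.

    E.g. the P7/P8 region of the polymerase: intervals (9, 17) and (83, 95).
    """

    name: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.intervals:
            if start < 1 or start > end:
                raise ValueError(f"region {self.name!r}: bad interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"region {self.name!r}: intervals overlap or are unsorted")
            prev_end = end

    @classmethod
    def from_string(cls, name: str, text: str) -> "RegionSpec":
        """Parse '9-17,83-95' style interval lists."""
        intervals = []
        for chunk in text.split(","):
            m = re.fullmatch(r"\s*(\d+)\s*-\s*(\d+)\s*", chunk)
            if not m:
                raise ValueError(f"cannot parse interval {chunk!r}")
            intervals.append((int(m.group(1)), int(m.group(2))))
        return cls(name, tuple(intervals))

    def positions(self) -> list[int]:
        """All reference positions in the region, ascending."""
        out: list[int] = []
        for start, end in self.intervals:
            out.extend(range(start, end + 1))
        return out

    def __contains__(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.intervals)

    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)

    def check_reference(self, ref: RnaSequence) -> None:
        if self.intervals and self.intervals[-1][1] > len(ref):
            raise ValueError(
                f"region {self.name!r} extends to {self.intervals[-1][1]} beyond "
                f"reference {ref.id!r} (length {len(ref)})"
            )


@dataclass(frozen=True)
class MutationSpec:
    """A single substitution, deletion, or insertion in reference coordinates.

    For insertions ``position`` is the reference position the inserted bases
    follow (``ins88_89:CA`` has position 88).
    """

    kind: str  # substitution | deletion | insertion
    position: int
    ref_base: str
    alt: str

    def __post_init__(self) -> None:
        # anchor 0 (insert before the first base) is legal only for insertions
        floor = 0 if self.kind == "insertion" else 1
        if self.position < floor:
            raise ValueError(f"mutation position must be >= {floor}, got {self.position}")
        if self.kind == "substitution":
            if len(self.ref_base) != 1 or len(self.alt) != 1 or self.ref_base == self.alt:
                raise ValueError(f"bad substitution {self.ref_base}->{self.alt}")
        elif self.kind == "deletion":
            if not self.ref_base or self.alt:
                raise ValueError("deletion needs ref_base and empty alt")
        elif self.kind == "insertion":
            if self.ref_base or not self.alt:
                raise ValueError("insertion needs empty ref_base and non-empty alt")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        for b in self.ref_base + self.alt:
            if b not in RNA_ALPHABET:
                raise ValueError(f"non-RNA base {b!r} in mutation")


def normalize_sequence(raw: str, id: str = "seq", meta: dict | None = None) -> RnaSequence:
    """Normalize raw text to a validated RnaSequence.

    Whitespace is removed, case is upcased, and T is converted to U.
    Characters outside the DNA/RNA alphabet are rejected with their offset
    (0-based, counted after whitespace removal).
    """
    stripped = "".join(raw.split())
    if not stripped:
        raise ValueError("empty sequence")
    for offset, ch in enumerate(stripped):
        if ch not in _VALID_INPUT:
            raise ValueError(f"invalid character {ch!r} at offset {offset}")
    residues = stripped.upper().replace("T", "U")
    return RnaSequence(id, residues, dict(meta or {}))


_SUB_RE = re.compile(r"([ACGU])(\d+)([ACGU])")
_DEL_RE = re.compile(r"del(\d+)([ACGU])")
_INS_RE = re.compile(r"ins(\d+)_(\d+):([ACGU]+)")


def parse_mutation(token: str) -> MutationSpec:
    """Parse mutation notation: ``C12G``, ``del17A``, ``ins88_89:CA``."""
    token = token.strip()
    norm = token.upper().replace("T", "U")
    if m := _INS_RE.fullmatch(token.replace("INS", "ins") if token.startswith("INS") else token):
        pos, nxt, bases = int(m.group(1)), int(m.group(2)), m.group(3)
        if nxt != pos + 1:
            raise ValueError(f"insertion anchor must be adjacent positions, got {token!r}")
        if pos < 1:
            raise ValueError(f"position must be >= 1 in {token!r}")
        return MutationSpec("insertion", pos, "", bases.upper().replace("T", "U"))
    if m := _DEL_RE.fullmatch(token if token.startswith("del") else token.lower()):
        pos = int(m.group(1))
        return MutationSpec("deletion", pos, m.group(2).upper().replace("T", "U"), "")
    if m := _SUB_RE.fullmatch(norm):
        return MutationSpec("substitution", int(m.group(2)), m.group(1), m.group(3))
    raise ValueError(f"cannot parse mutation token {token!r}")


def format_mutation(mut: MutationSpec) -> str:
    """Inverse of :func:`parse_mutation`."""
    if mut.kind == "substitution":
        return f"{mut.ref_base}{mut.position}{mut.alt}"
    if mut.kind == "deletion":
        return f"del{mut.position}{mut.ref_base}"
    return f"ins{mut.position}_{mut.position + 1}:{mut.alt}"


def invert_mutation(mut: MutationSpec) -> MutationSpec:
    """Mutation that undoes ``mut`` on the mutated sequence's own coordinates.

    Valid for round-trip checks when mutations are applied one at a time or in
    descending position order with non-overlapping footprints.
    """
    if mut.kind == "substitution":
        return MutationSpec("substitution", mut.position, mut.alt, mut.ref_base)
    if mut.kind == "deletion":
        return MutationSpec("insertion", mut.position - 1, "", mut.ref_base)
    # insertion of k bases after `position` -> delete them one by one; we
    # return a deletion spanning via multiple specs is not representable, so
    # callers invert insertions of length 1 directly and longer ones as lists.
    if len(mut.alt) == 1:
        return MutationSpec("deletion", mut.position + 1, mut.alt, "")
    raise ValueError("multi-base insertions invert to multiple deletions; use invert_mutations")


def invert_mutations(muts: Iterable[MutationSpec]) -> list[MutationSpec]:
    """Inverse mutation list (in a valid descending application order)."""
    out: list[MutationSpec] = []
    for m in muts:
        if m.kind == "insertion" and len(m.alt) > 1:
            for i, b in enumerate(m.alt):
                out.append(MutationSpec("deletion", m.position + 1 + i, b, ""))
        else:
            out.append(invert_mutation(m))
    return sorted(out, key=lambda m: -m.position)


def apply_mutations(seq: RnaSequence, muts: Iterable[MutationSpec]) -> RnaSequence:
    """Apply mutations to a sequence, validating reference bases.

    Mutations are applied in descending position order so that earlier
    coordinates stay valid. Substitution/deletion reference bases must match
    the sequence (a mismatch signals a stale coordinate system). Two mutations
    may not touch the same position.
    """
    muts = sorted(muts, key=lambda m: (-m.position, m.kind))
    seen: set[tuple[int, str]] = set()
    chars = list(seq.residues)
    for m in muts:
        key = (m.position, "ins" if m.kind == "insertion" else "pos")
        if key in seen:
            raise ValueError(f"overlapping mutations at position {m.position}")
        seen.add(key)
        if m.kind == "insertion":
            if not 0 <= m.position <= len(chars):
                raise IndexError(f"insertion anchor {m.position} outside sequence")
            chars[m.position : m.position] = list(m.alt)
            continue
        if not 1 <= m.position <= len(chars):
            raise IndexError(f"position {m.position} outside sequence of length {len(chars)}")
        have = chars[m.position - 1]
        if have != m.ref_base:
            raise ValueError(
                f"reference mismatch at {m.position}: sequence has {have}, "
                f"mutation {format_mutation(m)} expects {m.ref_base}"
            )
        if m.kind == "substitution":
            chars[m.position - 1] = m.alt
        else:  # deletion
            del chars[m.position - 1]
    return RnaSequence(seq.id, "".join(chars), dict(seq.meta))


# ---------------------------------------------------------------------------
# I/O: FASTA (wrapped at 60 columns) and FASTQ (Sanger Phred+33 only).
# Reads containing ambiguity codes (N etc.) are dropped and counted; the
# analyses operate on called bases only.
# ---------------------------------------------------------------------------

def _to_rna(record: SeqRecord) -> RnaSequence | None:
    try:
        return normalize_sequence(str(record.seq), id=record.id)
    except ValueError:
        return None


def read_fasta(path: str | Path, dropped: list | None = None) -> list[RnaSequence]:
    """Read a FASTA file; sequences with ambiguous bases are dropped.

    If ``dropped`` is given, ids of dropped records are appended to it.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _to_rna(rec)
        if seq is None:
            if dropped is not None:
                dropped.append(rec.id)
            continue
        out.append(seq)
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fastq(path: str | Path, dropped: list | None = None) -> list[QualRead]:
    """Read Sanger-encoded FASTQ; records with ambiguous bases are dropped."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = _to_rna(rec)
        if seq is None:
            if dropped is not None:
                dropped.append(rec.id)
            continue
        quals = tuple(rec.letter_annotations["phred_quality"])
        out.append(QualRead(seq, quals))
    return out


def write_fastq(reads: Iterable[QualRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq.residues), id=r.seq.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_mutation_file(path: str | Path) -> list[MutationSpec]:
    """One mutation token per line; blank lines and #-comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(parse_mutation(line))
    return out


def parse_mutation_list(text: str) -> list[MutationSpec]:
    """Comma-separated mutation tokens, as accepted on the command line."""
    return [parse_mutation(tok) for tok in text.split(",") if tok.strip()]
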