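"""Per-position fidelity analysis of ribozyme-synthesized RNA.

Product reads are aligned to the reference template with a semi-global
aligner (free 3'-terminal reference gaps, so partial-length products are
truncations rather than runs of deletions), every aligned column is
classified as match / mismatch / deletion / insertion per template position,
and the tallies are summarized as average fidelity, a mutation spectrum, and
a Levenshtein-distance distribution.

Insertions live on junctions between template positions and are excluded
from the positional fidelity denominator by default; the headline
"average fidelity per nucleotide position" is matches / (matches +
mismatches + deletions), coverage-weighted across positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from . import _align
from .seq_core import RnaSequence

BASES = ("A", "C", "G", "U")

__all__ = [
    "AlignedRead",
    "FidelityTable",
    "DistanceHistogram",
    "align_to_reference",
    "tally",
    "average_fidelity",
    "insertion_rate",
    "mutation_spectrum",
    "levenshtein_distribution",
]


@dataclass(frozen=True)
class AlignedRead:
    """One read aligned to the reference.

    ``ops`` is an ordered tuple of columns:
      ("match", pos) — read base equals template base at ``pos``
      ("mismatch", pos, read_base) — read base differs
      ("deletion", pos) — template base skipped by the read
      ("insertion", after_pos, read_bases) — extra read bases following
        template position ``after_pos`` (0 = before the first position)
    ``aligned_span`` is the (first, last) template position covered; a read
    ending before the template 3' end leaves the remainder uncovered
    (truncation, which does not contribute to coverage).
    """

    read_id: str
    ops: tuple
    read_length: int
    aligned_span: tuple[int, int]
    score: int

    def __post_init__(self) -> None:
        consumed = 0
        last = 0
        for op in self.ops:
            if op[0] in ("match", "mismatch", "deletion"):
                if op[1] <= last:
                    raise ValueError("reference positions not strictly increasing")
                last = op[1]
            if op[0] in ("match", "mismatch"):
                consumed += 1
            elif op[0] == "insertion":
                consumed += len(op[2])
        if consumed != self.read_length:
            raise ValueError(
                f"{self.read_id!r}: ops consume {consumed} read bases, "
                f"read length is {self.read_length}"
            )


def align_to_reference(read: RnaSequence, ref: RnaSequence) -> AlignedRead:
    """Optimal semi-global alignment of a product read to the template.

    Match +1, mismatch -1, gap -2, linear; 3'-terminal reference gaps are
    free. Deterministic: ties resolve to mismatch over indel, then to the
    left-most gap placement.
    """
    score, jend, codes, ref_pos, read_idx = _align._align_kernel(
        _align.encode(read.residues), _align.encode(ref.residues)
    )
    ops = _grouped_ops(read, codes, ref_pos, read_idx)
    covered = [op[1] for op in ops if op[0] in ("match", "mismatch", "deletion")]
    span = (covered[0], covered[-1]) if covered else (0, 0)
    return AlignedRead(
        read_id=read.id,
        ops=ops,
        read_length=len(read),
        aligned_span=span,
        score=int(score),
    )


def _grouped_ops(read: RnaSequence, codes, ref_pos, read_idx) -> tuple:
    ops: list = []
    ins_after = -1
    ins_bases: list[str] = []
    for c, rp, ri in zip(codes, ref_pos, read_idx):
        if c == _align.OP_INSERTION:
            if ins_after == rp:
                ins_bases.append(read.residues[ri])
            else:
                if ins_bases:
                    ops.append(("insertion", ins_after, "".join(ins_bases)))
                ins_after = rp
                ins_bases = [read.residues[ri]]
            continue
        if ins_bases:
            ops.append(("insertion", ins_after, "".join(ins_bases)))
            ins_after, ins_bases = -1, []
        if c == _align.OP_MATCH:
            ops.append(("match", int(rp)))
        elif c == _align.OP_MISMATCH:
            ops.append(("mismatch", int(rp), read.residues[ri]))
        else:
            ops.append(("deletion", int(rp)))
    if ins_bases:
        ops.append(("insertion", ins_after, "".join(ins_bases)))
    return tuple(ops)


@dataclass
class FidelityTable:
    """Per-template-position tallies of matches, mismatches, deletions.

    ``per_position`` has one row per reference position with columns
    ref_base, coverage, match, mm_A, mm_C, mm_G, mm_U, deletion.
    ``per_junction`` maps after-position -> (insertion events, inserted
    bases). ``per_read_length`` is a read-length histogram.
    """

    reference: RnaSequence
    per_position: pd.DataFrame
    per_junction: dict[int, tuple[int, int]]
    per_read_length: Counter
    n_reads: int
    condition: dict = field(default_factory=dict)

    def validate(self) -> None:
        pp = self.per_position
        mm = pp[[f"mm_{b}" for b in BASES]].sum(axis=1)
        if not (pp["match"] + mm + pp["deletion"] == pp["coverage"]).all():
            raise AssertionError("per-position counts do not sum to coverage")
        if (pp[["coverage", "match", "deletion"]] < 0).any().any():
            raise AssertionError("negative counts")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# insertions are anchored to the reference position they follow\n")
            self.per_position.to_csv(fh, sep="\t")
            fh.write("\n# junction\tafter_pos\tins_events\tins_bases\n")
            for pos in sorted(self.per_junction):
                ev, nb = self.per_junction[pos]
                fh.write(f"junction\t{pos}\t{ev}\t{nb}\n")


def tally(
    alignments: Iterable[AlignedRead],
    ref: RnaSequence,
    condition: dict | None = None,
) -> FidelityTable:
    """Accumulate aligned columns into a per-position fidelity table."""
    n = len(ref)
    cols = {
        "coverage": np.zeros(n, dtype=np.int64),
        "match": np.zeros(n, dtype=np.int64),
        "deletion": np.zeros(n, dtype=np.int64),
    }
    mm = {b: np.zeros(n, dtype=np.int64) for b in BASES}
    junction_events: Counter = Counter()
    junction_bases: Counter = Counter()
    lengths: Counter = Counter()
    n_reads = 0
    for aln in alignments:
        n_reads += 1
        lengths[aln.read_length] += 1
        for op in aln.ops:
            kind = op[0]
            if kind == "insertion":
                if op[1] > n:
                    raise ValueError(f"{aln.read_id!r}: insertion anchor beyond reference")
                junction_events[op[1]] += 1
                junction_bases[op[1]] += len(op[2])
                continue
            pos = op[1]
            if pos > n:
                raise ValueError(f"{aln.read_id!r}: position {pos} beyond reference")
            idx = pos - 1
            cols["coverage"][idx] += 1
            if kind == "match":
                cols["match"][idx] += 1
            elif kind == "mismatch":
                mm[op[2]][idx] += 1
            else:
                cols["deletion"][idx] += 1
    pp = pd.DataFrame(
        {
            "ref_base": list(ref.residues),
            "coverage": cols["coverage"],
            "match": cols["match"],
            **{f"mm_{b}": mm[b] for b in BASES},
            "deletion": cols["deletion"],
        },
        index=pd.RangeIndex(1, n + 1, name="pos"),
    )
    table = FidelityTable(
        reference=ref,
        per_position=pp,
        per_junction={
            pos: (junction_events[pos], junction_bases[pos]) for pos in junction_events
        },
        per_read_length=lengths,
        n_reads=n_reads,
        condition=dict(condition or {}),
    )
    table.validate()
    return table


def average_fidelity(
    table: FidelityTable,
    with_insertions: bool = False,
    per_position_mean: bool = False,
) -> float:
    """Average per-nucleotide fidelity in [0, 1].

    Default: coverage-weighted total matches / total covered positions,
    where covered = matches + mismatches + deletions. ``with_insertions``
    folds inserted bases into the error numerator (sensitivity analysis);
    ``per_position_mean`` averages per-position fidelities unweighted.
    """
    pp = table.per_position
    if pp["coverage"].sum() == 0:
        raise ValueError("empty fidelity table")
    if per_position_mean:
        covered = pp[pp["coverage"] > 0]
        return float((covered["match"] / covered["coverage"]).mean())
    matches = int(pp["match"].sum())
    covered = int(pp["coverage"].sum())
    if with_insertions:
        inserted = sum(nb for _, nb in table.per_junction.values())
        return matches / (covered + inserted)
    return matches / covered


def insertion_rate(table: FidelityTable) -> float:
    """Inserted bases per covered template position (reported separately)."""
    covered = int(table.per_position["coverage"].sum())
    inserted = sum(nb for _, nb in table.per_junction.values())
    return inserted / covered if covered else 0.0


def mutation_spectrum(table: FidelityTable) -> dict:
    """Template-base -> incorporated-base rate matrix plus indel rates.

    Rates are counts divided by total coverage of positions carrying the
    template base. ``wobble_fraction`` is the share of mismatches explained
    by G-U wobble pairing (template U read as G, template G read as U).
    """
    pp = table.per_position
    rates = pd.DataFrame(0.0, index=list(BASES), columns=list(BASES))
    del_rates = pd.Series(0.0, index=list(BASES))
    mm_total = 0
    wobble = 0
    for tb in BASES:
        rows = pp[pp["ref_base"] == tb]
        cov = int(rows["coverage"].sum())
        for ib in BASES:
            if ib == tb:
                continue
            cnt = int(rows[f"mm_{ib}"].sum())
            mm_total += cnt
            if (tb, ib) in (("U", "G"), ("G", "U")):
                wobble += cnt
            rates.loc[tb, ib] = cnt / cov if cov else np.nan
        del_rates[tb] = int(rows["deletion"].sum()) / cov if cov else np.nan
    covered = int(pp["coverage"].sum())
    inserted = sum(nb for _, nb in table.per_junction.values())
    return {
        "substitution_rates": rates,
        "deletion_rates": del_rates,
        "insertion_rate": inserted / covered if covered else np.nan,
        "wobble_fraction": wobble / mm_total if mm_total else np.nan,
        "n_mismatches": mm_total,
    }


@dataclass(frozen=True)
class DistanceHistogram:
    """Histogram of unit-cost edit distances from the reference."""

    counts: dict[int, int]
    n_reads: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_reads:
            raise ValueError("histogram counts do not sum to n_reads")
        if any(k < 0 for k in self.counts):
            raise ValueError("negative distance key")

    @property
    def mean(self) -> float:
        return sum(k * v for k, v in self.counts.items()) / self.n_reads

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("distance\tcount\n")
            for k in sorted(self.counts):
                fh.write(f"{k}\t{self.counts[k]}\n")


def levenshtein_distribution(
    reads: Sequence[RnaSequence], ref: RnaSequence
) -> DistanceHistogram:
    """Unit-cost Levenshtein distance of each read from the reference."""
    if not reads:
        raise ValueError("no reads")
    counts: Counter = Counter()
    cache: dict[str, int] = {}
    for r in reads:
        d = cache.get(r.residues)
        if d is None:
            d = edlib.align(r.residues, ref.residues, mode="NW", task="distance")[
                "editDistance"
            ]
            cache[r.residues] = d
        counts[d] += 1
    return DistanceHistogram(dict(counts), len(reads))
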