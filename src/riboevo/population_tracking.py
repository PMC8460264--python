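"""Round-by-round tracking of sequence clusters in an evolving population.

Pipeline for deep-sequencing samples of a directed-evolution experiment:
quality-filter reads, extract the region encompassing the P7 and P8 stems
(reference nucleotides 9-17 and 83-95 for the 52-2 polymerase numbering),
cluster the trimmed region keys at 100% identity with two nucleotides of
terminal slack, merge biologically equivalent clusters, and track cluster
frequencies across evolution rounds.

Clustering follows cd-hit-est semantics at -c 1.0 -U 2 -S 2: a key joins a
cluster iff it matches the representative exactly over their overlap when
one is a contiguous substring of the other, with total unmatched terminal
length <= 2 and length difference <= 2. Keys are processed in descending
abundance order (ties broken lexicographically), which is deterministic for
the fixed-length keys this region produces.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fidelity import align_to_reference
from .seq_core import QualRead, RegionSpec, RnaSequence

logger = logging.getLogger(__name__)

__all__ = [
    "RoundSample",
    "ClusterTrack",
    "FrequencyMatrix",
    "quality_filter",
    "extract_region",
    "cluster_region_keys",
    "merge_equivalent",
    "track",
    "strand_frequency_matrices",
    "strand_correlation",
]


@dataclass
class RoundSample:
    """Reads sampled from the population after one round of evolution."""

    round: int
    reads: list[QualRead]
    n_raw: int = 0
    n_kept: int = 0

    def __post_init__(self) -> None:
        if self.round < 1:
            raise ValueError("round must be >= 1")
        if self.n_raw == 0:
            self.n_raw = len(self.reads)
        if self.n_kept == 0:
            self.n_kept = len(self.reads)
        if self.n_kept > self.n_raw:
            raise ValueError("n_kept cannot exceed n_raw")


@dataclass
class ClusterTrack:
    """A sequence cluster tracked across rounds.

    ``cluster_id`` is assigned by :func:`track` as "<round>.<rank>" from the
    first round where the cluster exceeds the representation threshold.
    """

    representative: RnaSequence
    counts: dict[int, int] = field(default_factory=dict)
    freqs: dict[int, float] = field(default_factory=dict)
    cluster_id: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def rounds_present(self) -> list[int]:
        return sorted(r for r, c in self.counts.items() if c > 0)

    def max_freq(self) -> float:
        return max(self.freqs.values(), default=0.0)


@dataclass
class FrequencyMatrix:
    """Cluster-by-round frequency matrix plus per-round retained fraction."""

    values: pd.DataFrame  # rows: cluster_id, cols: round
    retained_fraction: pd.Series
    representatives: dict[str, RnaSequence] = field(default_factory=dict)

    @property
    def rounds(self) -> list[int]:
        return list(self.values.columns)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.values.index)


def quality_filter(
    sample: RoundSample,
    min_len: int = 150,
    min_phred: float = 33.0,
    mode: str = "mean",
) -> RoundSample:
    """Keep reads of length > ``min_len`` with Phred quality > ``min_phred``.

    Both comparisons are strict, so a 150-nt read is dropped. ``mode``
    selects how the per-read quality is summarized: "mean" (default) or
    "min" (every base must exceed the threshold).
    """
    if mode not in ("mean", "min"):
        raise ValueError(f"unknown phred mode {mode!r}")
    kept = []
    for r in sample.reads:
        if len(r) <= min_len:
            continue
        q = r.mean_quality() if mode == "mean" else min(r.quals)
        if q > min_phred:
            kept.append(r)
    logger.info("round %d: %d/%d reads pass quality filter", sample.round, len(kept), len(sample.reads))
    return RoundSample(sample.round, kept, n_raw=sample.n_raw, n_kept=len(kept))


def extract_region(
    read: RnaSequence,
    ref: RnaSequence,
    region: RegionSpec,
    _cache: dict | None = None,
) -> RnaSequence | None:
    """Trim an aligned read to the region of interest.

    The read is aligned to the reference (semi-global, 5'-anchored) and the
    bases aligned within each region interval are concatenated, including
    insertions anchored strictly inside an interval. Deletions shorten the
    key. Returns None for reads whose alignment does not span the whole
    region (these are logged and discarded by callers).

    The returned key carries ``meta["strand_split"]``: the number of key
    bases contributed by the first interval, used to split the key into its
    5'- and 3'-strand components.
    """
    region.check_reference(ref)
    if _cache is not None and read.residues in _cache:
        return _cache[read.residues]
    aln = align_to_reference(read, ref)
    region_positions = set(region.positions())
    last_needed = region.intervals[-1][1]
    first_needed = region.intervals[0][0]
    key = None
    if aln.aligned_span != (0, 0) and aln.aligned_span[0] <= first_needed and aln.aligned_span[1] >= last_needed:
        parts: list[str] = []
        first_len = 0
        i1_start, i1_end = region.intervals[0]
        for op in aln.ops:
            if op[0] == "match":
                if op[1] in region_positions:
                    parts.append(ref.base(op[1]))
                    if i1_start <= op[1] <= i1_end:
                        first_len += 1
            elif op[0] == "mismatch":
                if op[1] in region_positions:
                    parts.append(op[2])
                    if i1_start <= op[1] <= i1_end:
                        first_len += 1
            elif op[0] == "insertion":
                # strictly inside an interval: anchor and anchor+1 both in it
                if any(s <= op[1] < e for s, e in region.intervals):
                    parts.append(op[2])
                    if i1_start <= op[1] < i1_end:
                        first_len += len(op[2])
            # deletions contribute nothing
        key = RnaSequence(f"{read.id}|{region.name}", "".join(parts), {"strand_split": first_len})
    if _cache is not None:
        _cache[read.residues] = key
    return key


def _joins(key: str, rep: str) -> bool:
    """cd-hit-est-style join rule: identity over overlap with <= 2 nt slack."""
    if abs(len(key) - len(rep)) > 2:
        return False
    shorter, longer = (key, rep) if len(key) <= len(rep) else (rep, key)
    return shorter in longer


def cluster_region_keys(keys: Sequence[RnaSequence]) -> list[ClusterTrack]:
    """Greedy 100%-identity clustering of region keys (single round).

    Keys are processed in descending abundance (ties lexicographic); each
    joins the first existing cluster whose representative it matches under
    the slack rule, else seeds a new cluster. The representative is the most
    abundant member.
    """
    if not keys:
        raise ValueError("no keys to cluster")
    counts = Counter(k.residues for k in keys)
    meta = {}
    for k in keys:
        meta.setdefault(k.residues, k.meta)
    clusters: list[ClusterTrack] = []
    for residues, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        for cl in clusters:
            if _joins(residues, cl.representative.residues):
                cl.counts[0] = cl.counts.get(0, 0) + cnt
                break
        else:
            rep = RnaSequence(f"cluster{len(clusters)}", residues, dict(meta[residues]))
            clusters.append(ClusterTrack(representative=rep, counts={0: cnt}))
    return clusters


def _mutations_vs_region_ref(key: str, region_ref: str, positions: list[int]) -> frozenset:
    """Differences of a key from the reference region key, as tokens in
    reference coordinates. Insertions are anchored to the reference position
    of the preceding region column (0 for the region 5' end)."""
    from .fidelity import align_to_reference as _atr

    aln = _atr(RnaSequence("key", key), RnaSequence("regref", region_ref))
    muts = []
    for op in aln.ops:
        if op[0] == "match":
            continue
        if op[0] == "mismatch":
            muts.append(("sub", positions[op[1] - 1], op[2]))
        elif op[0] == "deletion":
            muts.append(("del", positions[op[1] - 1], region_ref[op[1] - 1]))
        else:
            anchor = positions[op[1] - 1] if op[1] >= 1 else 0
            muts.append(("ins", anchor, op[2]))
    # truncation relative to the region reference also counts as difference
    if aln.aligned_span != (0, 0) and aln.aligned_span[1] < len(region_ref):
        for j in range(aln.aligned_span[1], len(region_ref)):
            muts.append(("del", positions[j], region_ref[j]))
    return frozenset(muts)


def _equivalent(
    mutsA: frozenset,
    mutsB: frozenset,
    core_positions: set[int],
    junction_run: set[int],
) -> bool:
    diff = mutsA.symmetric_difference(mutsB)
    if not diff:
        return True
    # (a) insertion/deletion of A residues at the inter-strand junction;
    # the aligner left-shifts indels within the reference A run, so any
    # position of that run is accepted
    if junction_run and all(
        kind in ("ins", "del") and set(bases) == {"A"} and pos in junction_run
        for kind, pos, bases in diff
    ):
        return True
    # (b) a single substitution at one position outside the conserved core
    if all(kind == "sub" for kind, _, _ in diff):
        pos_set = {pos for _, pos, _ in diff}
        if len(pos_set) == 1 and not pos_set & core_positions:
            return True
    return False


def merge_equivalent(
    clusters: list[ClusterTrack],
    core: RegionSpec,
    region: RegionSpec,
    ref: RnaSequence,
) -> list[ClusterTrack]:
    """Merge clusters representing the same biological variant.

    Clusters whose representatives differ only by (a) the length of the
    A run at the junction between the region's two strands (reference
    positions 17/18 for the polymerase region), or (b) a single substitution
    at a position outside the conserved core (``core``; positions 11-16 and
    84-89), are merged. Counts are summed; the most abundant representative
    is kept.
    """
    positions = region.positions()
    region_ref = "".join(ref.base(p) for p in positions)
    # maximal run of reference A residues ending at the first interval's 3'
    # terminus (the 17/18 junction for the polymerase region); A indels
    # placed anywhere in this run are alignment-equivalent
    junction = region.intervals[0][1]
    junction_run = {junction}
    p = junction
    while p >= region.intervals[0][0] and ref.base(p) == "A":
        junction_run.add(p)
        p -= 1
    # also accept the anchor one position 5' of the run (insertions there)
    junction_run.add(p)
    if ref.base(junction) != "A":
        junction_run = {junction}  # only insertions right at the junction
    core_positions = set(core.positions())
    sigs = [
        _mutations_vs_region_ref(cl.representative.residues, region_ref, positions)
        for cl in clusters
    ]
    parent = list(range(len(clusters)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if find(i) != find(j) and _equivalent(sigs[i], sigs[j], core_positions, junction_run):
                parent[find(j)] = find(i)

    groups: dict[int, list[ClusterTrack]] = {}
    for i, cl in enumerate(clusters):
        groups.setdefault(find(i), []).append(cl)
    merged: list[ClusterTrack] = []
    for members in groups.values():
        members.sort(key=lambda c: (-c.total, c.representative.residues))
        head = members[0]
        out = ClusterTrack(representative=head.representative, counts=dict(head.counts))
        for other in members[1:]:
            for r, c in other.counts.items():
                out.counts[r] = out.counts.get(r, 0) + c
        merged.append(out)
    return merged


def track(
    samples: Sequence[RoundSample],
    ref: RnaSequence,
    region: RegionSpec,
    rep_threshold: float = 0.01,
    singleton_threshold: float = 0.05,
    merge_core: RegionSpec | None = None,
    min_len: int = 150,
    min_phred: float = 33.0,
    apply_quality_filter: bool = True,
) -> FrequencyMatrix:
    """Cluster each round and track cluster frequencies across evolution.

    Clusters exceeding ``rep_threshold`` (default >1%) in at least one round
    are retained, except clusters observed in exactly one round that never
    reach ``singleton_threshold`` (default 5%). Cluster ids are assigned as
    "<round>.<rank>" from the first round of above-threshold appearance,
    ranked by abundance in that round. ``merge_core`` enables equivalence
    merging with the given conserved-core region.
    """
    if not samples:
        raise ValueError("no samples")
    cache: dict = {}
    tracks: list[ClusterTrack] = []
    by_key: dict[str, ClusterTrack] = {}
    round_totals: dict[int, int] = {}
    for sample in sorted(samples, key=lambda s: s.round):
        if apply_quality_filter:
            sample = quality_filter(sample, min_len=min_len, min_phred=min_phred)
        keys = []
        n_dropped = 0
        for r in sample.reads:
            key = extract_region(r.seq, ref, region, _cache=cache)
            if key is None:
                n_dropped += 1
            else:
                keys.append(key)
        if n_dropped:
            logger.info("round %d: %d reads did not span the region", sample.round, n_dropped)
        if not keys:
            round_totals[sample.round] = 0
            continue
        round_totals[sample.round] = len(keys)
        for cl in cluster_region_keys(keys):
            cnt = cl.counts[0]
            rep = cl.representative.residues
            target = by_key.get(rep)
            if target is None:
                for t in tracks:
                    if _joins(rep, t.representative.residues):
                        target = t
                        break
            if target is None:
                target = ClusterTrack(representative=cl.representative)
                tracks.append(target)
                by_key[rep] = target
            target.counts[sample.round] = target.counts.get(sample.round, 0) + cnt

    if merge_core is not None:
        tracks = merge_equivalent(tracks, merge_core, region, ref)

    rounds = sorted(round_totals)
    for t in tracks:
        t.freqs = {
            r: (t.counts.get(r, 0) / round_totals[r]) if round_totals[r] else 0.0
            for r in rounds
        }

    # retention rules
    retained: list[ClusterTrack] = []
    for t in tracks:
        if t.max_freq() <= rep_threshold:
            continue
        present = t.rounds_present()
        if len(present) == 1 and t.max_freq() < singleton_threshold:
            continue
        retained.append(t)

    # naming: first round with freq > rep_threshold; rank by abundance there
    def first_round(t: ClusterTrack) -> int:
        return min(r for r, f in t.freqs.items() if f > rep_threshold)

    by_first: dict[int, list[ClusterTrack]] = {}
    for t in retained:
        by_first.setdefault(first_round(t), []).append(t)
    for r0, members in by_first.items():
        members.sort(key=lambda t: (-t.counts.get(r0, 0), t.representative.residues))
        for rank, t in enumerate(members, start=1):
            t.cluster_id = f"{r0}.{rank}"

    retained.sort(key=lambda t: (first_round(t), t.cluster_id))
    values = pd.DataFrame(
        [[t.freqs.get(r, 0.0) for r in rounds] for t in retained],
        index=[t.cluster_id for t in retained],
        columns=rounds,
    )
    retained_fraction = pd.Series(
        {
            r: (sum(t.counts.get(r, 0) for t in retained) / round_totals[r])
            if round_totals[r]
            else 0.0
            for r in rounds
        }
    )
    reps = {t.cluster_id: t.representative for t in retained}
    logger.info(
        "retained %d of %d clusters; mean retained fraction %.3f",
        len(retained), len(tracks), retained_fraction.mean() if len(retained_fraction) else 0.0,
    )
    return FrequencyMatrix(values, retained_fraction, reps)


def strand_frequency_matrices(
    matrix: FrequencyMatrix,
) -> tuple[FrequencyMatrix, FrequencyMatrix, dict[str, str]]:
    """Split tracked clusters into 5'- and 3'-strand variant trajectories.

    Each representative key is split at its recorded strand boundary; the
    frequencies of clusters sharing a strand variant are summed. Returns the
    5'-strand matrix, the 3'-strand matrix, and the pairing observed among
    retained clusters (5' variant -> 3' variant of the most abundant
    co-occurring cluster).
    """
    five: dict[str, np.ndarray] = {}
    three: dict[str, np.ndarray] = {}
    pairing: dict[str, str] = {}
    weight: dict[str, float] = {}
    for cid in matrix.cluster_ids:
        rep = matrix.representatives[cid]
        split = rep.meta.get("strand_split")
        if split is None:
            raise ValueError(f"representative of {cid} lacks strand_split metadata")
        s5, s3 = rep.residues[:split], rep.residues[split:]
        row = matrix.values.loc[cid].to_numpy(dtype=float)
        five[s5] = five.get(s5, 0) + row
        three[s3] = three.get(s3, 0) + row
        w = float(row.sum())
        if w > weight.get(s5, 0.0):
            weight[s5] = w
            pairing[s5] = s3
    cols = matrix.rounds
    m5 = FrequencyMatrix(
        pd.DataFrame(five, index=cols).T, matrix.retained_fraction.copy()
    )
    m3 = FrequencyMatrix(
        pd.DataFrame(three, index=cols).T, matrix.retained_fraction.copy()
    )
    return m5, m3, pairing


def strand_correlation(
    matrix5: FrequencyMatrix,
    matrix3: FrequencyMatrix,
    pairing: Mapping[str, str],
) -> dict[str, float]:
    """Pearson correlation across rounds of paired 5'/3' strand variants.

    Returns NaN for a pair when either trajectory has zero variance.
    """
    if list(matrix5.rounds) != list(matrix3.rounds):
        raise ValueError("round axes differ between strand matrices")
    out: dict[str, float] = {}
    for v5, v3 in pairing.items():
        if v5 not in matrix5.values.index or v3 not in matrix3.values.index:
            raise KeyError(f"pairing {v5}->{v3} not present in matrices")
        x = matrix5.values.loc[v5].to_numpy(dtype=float)
        y = matrix3.values.loc[v3].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[f"{v5}|{v3}"] = float("nan")
        else:
            out[f"{v5}|{v3}"] = float(stats.pearsonr(x, y)[0])
    return out
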