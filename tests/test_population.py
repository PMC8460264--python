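"""Quality filtering, region extraction, clustering, and cross-round tracking."""

import numpy as np
import pytest

from riboevo import (
    CONSERVED_CORE,
    P7P8_REGION,
    FrequencyMatrix,
    PopulationModel,
    RoundSample,
    cluster_region_keys,
    expected_frequencies,
    extract_region,
    merge_equivalent,
    quality_filter,
    simulate_rounds,
    strand_correlation,
    track,
)
from riboevo.population_tracking import _joins
from riboevo.seq_core import QualRead, RegionSpec, RnaSequence, apply_mutations, parse_mutation

import pandas as pd


def qread(residues, q=40, rid="r"):
    seq = RnaSequence(rid, residues)
    return QualRead(seq, (q,) * len(seq))


class TestQualityFilter:
    def test_length_threshold_is_strict(self):
        sample = RoundSample(1, [qread("A" * 150), qread("A" * 151)])
        kept = quality_filter(sample)
        assert [len(r) for r in kept.reads] == [151]

    def test_quality_threshold(self):
        sample = RoundSample(1, [qread("A" * 200, q=30), qread("A" * 200, q=40)])
        kept = quality_filter(sample)
        assert len(kept.reads) == 1 and kept.reads[0].mean_quality() == 40
        assert kept.n_kept == 1 and kept.n_raw == 2

    def test_min_mode_requires_every_base(self):
        seq = RnaSequence("r", "A" * 200)
        read = QualRead(seq, (40,) * 199 + (30,))
        sample = RoundSample(1, [read])
        assert len(quality_filter(sample, mode="mean").reads) == 1
        assert len(quality_filter(sample, mode="min").reads) == 0


class TestExtractRegion:
    def test_identity_read(self, fx):
        ref = fx.polymerase_ref
        key = extract_region(ref, ref, P7P8_REGION)
        expected = "".join(ref.base(p) for p in P7P8_REGION.positions())
        assert key.residues == expected
        assert len(key) == 22
        assert key.meta["strand_split"] == 9

    def test_deletion_shortens_key(self, fx):
        ref = fx.polymerase_ref
        read = apply_mutations(ref, [parse_mutation(f"del90{ref.base(90)}")])
        key = extract_region(read, ref, P7P8_REGION)
        assert len(key) == 21

    def test_insertion_lengthens_key(self, fx):
        # two-nucleotide insertion between 88 and 89, inside the 3' interval
        ref = fx.polymerase_ref
        read = apply_mutations(ref, [parse_mutation("ins88_89:CA")])
        key = extract_region(read, ref, P7P8_REGION)
        assert len(key) == 24

    def test_non_spanning_read_discarded(self, fx):
        ref = fx.polymerase_ref
        read = RnaSequence("short", ref.residues[:60])
        assert extract_region(read, ref, P7P8_REGION) is None

    def test_region_outside_reference_rejected(self, fx):
        with pytest.raises(ValueError):
            extract_region(
                fx.polymerase_ref,
                fx.polymerase_ref,
                RegionSpec("bad", ((9, 17), (83, 500))),
            )


class TestClustering:
    def test_terminal_slack_joins(self):
        keys = [RnaSequence(f"k{i}", "GCACCA") for i in range(5)]
        keys += [RnaSequence(f"s{i}", "GCACC") for i in range(2)]
        clusters = cluster_region_keys(keys)
        assert len(clusters) == 1
        assert clusters[0].representative.residues == "GCACCA"
        assert clusters[0].counts[0] == 7

    def test_internal_mismatch_separates(self):
        keys = [RnaSequence(f"k{i}", "GCACCA") for i in range(5)]
        keys += [RnaSequence(f"s{i}", "GCAGCA") for i in range(3)]
        assert len(cluster_region_keys(keys)) == 2

    def test_slack_limited_to_two(self):
        keys = [RnaSequence("a", "GCACCAG"), RnaSequence("b", "CACC")]
        assert len(cluster_region_keys(keys)) == 2  # length difference 3

    def test_greedy_result_is_valid_and_canonical(self):
        """Every member joins its representative; representatives are
        pairwise non-joinable; read order does not matter."""
        rng = np.random.default_rng(5)
        pool = ["GCACCA", "GCACC", "GCAGCA", "ACGUACG", "ACGUAC", "GCACCAGG"]
        keys = [
            RnaSequence(f"k{i}", pool[j])
            for i, j in enumerate(rng.integers(0, len(pool), 40))
        ]
        clusters = cluster_region_keys(keys)
        reps = [c.representative.residues for c in clusters]
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                assert not _joins(a, b)
        shuffled = list(keys)
        rng.shuffle(shuffled)
        again = cluster_region_keys(shuffled)
        assert sorted(c.representative.residues for c in again) == sorted(reps)
        assert sum(c.counts[0] for c in clusters) == len(keys)


def _tracks_for(fx, *variants):
    """Single-round ClusterTracks for region keys of mutated references."""
    ref = fx.polymerase_ref
    keys = []
    for muts, n in variants:
        read = apply_mutations(ref, [parse_mutation(t) for t in muts]) if muts else ref
        key = extract_region(read, ref, P7P8_REGION)
        keys.extend(RnaSequence(f"{'_'.join(muts) or 'wt'}{i}", key.residues) for i in range(n))
    return cluster_region_keys(keys)


class TestMergeEquivalent:
    def merge(self, fx, clusters):
        return merge_equivalent(clusters, CONSERVED_CORE, P7P8_REGION, fx.polymerase_ref)

    def test_junction_a_deletion_merged(self, fx):
        clusters = _tracks_for(fx, ([], 5), (["del17A"], 2))
        assert len(clusters) == 2
        assert len(self.merge(fx, clusters)) == 1

    def test_core_substitution_not_merged(self, fx):
        clusters = _tracks_for(fx, ([], 5), (["C12G"], 2))
        assert len(self.merge(fx, clusters)) == 2

    def test_single_noncore_substitution_merged(self, fx):
        ref = fx.polymerase_ref
        clusters = _tracks_for(fx, ([], 5), ([f"{ref.base(9)}9U" if ref.base(9) != 'U' else f"{ref.base(9)}9A"], 2))
        assert len(self.merge(fx, clusters)) == 1

    def test_two_noncore_substitutions_not_merged(self, fx):
        ref = fx.polymerase_ref
        m9 = f"{ref.base(9)}9U" if ref.base(9) != "U" else "U9A"
        m95 = f"{ref.base(95)}95U" if ref.base(95) != "U" else "U95A"
        clusters = _tracks_for(fx, ([], 5), ([m9, m95], 2))
        assert len(self.merge(fx, clusters)) == 2

    def test_counts_conserved(self, fx):
        clusters = _tracks_for(fx, ([], 5), (["del17A"], 2))
        merged = self.merge(fx, clusters)
        assert sum(c.total for c in merged) == 7


def _samples_from_counts(fx, genotype_muts, counts_by_round):
    """RoundSamples with exact per-genotype counts per round."""
    ref = fx.polymerase_ref
    genotypes = []
    for muts in genotype_muts:
        g = apply_mutations(ref, [parse_mutation(t) for t in muts]) if muts else ref
        genotypes.append(g)
    samples = []
    for rnd, counts in counts_by_round.items():
        reads = []
        for g_idx, n in enumerate(counts):
            reads += [
                QualRead(RnaSequence(f"r{rnd}g{g_idx}n{i}", genotypes[g_idx].residues), (40,) * len(genotypes[g_idx]))
                for i in range(n)
            ]
        samples.append(RoundSample(rnd, reads))
    return samples


class TestTrack:
    def test_single_cluster_everywhere(self, fx):
        samples = _samples_from_counts(fx, [[]], {r: [200] for r in (1, 2, 3)})
        matrix = track(samples, fx.polymerase_ref, P7P8_REGION)
        assert matrix.values.shape == (1, 3)
        assert (matrix.values == 1.0).all().all()
        assert (matrix.retained_fraction == 1.0).all()
        assert matrix.cluster_ids == ["1.1"]

    def test_sub_threshold_cluster_excluded(self, fx):
        counts = {r: [995, 5] for r in (1, 2, 3)}  # 0.5% every round
        samples = _samples_from_counts(fx, [[], ["C12G"]], counts)
        matrix = track(samples, fx.polymerase_ref, P7P8_REGION)
        assert len(matrix.cluster_ids) == 1

    def test_single_round_rules(self, fx):
        # 4% in exactly one round -> ignored; 6% in one round -> retained
        counts = {1: [1000, 0, 0], 2: [900, 40, 60], 3: [1000, 0, 0]}
        samples = _samples_from_counts(fx, [[], ["C12G"], ["A13U"]], counts)
        matrix = track(samples, fx.polymerase_ref, P7P8_REGION)
        assert len(matrix.cluster_ids) == 2
        ref = fx.polymerase_ref
        ref_key = extract_region(ref, ref, P7P8_REGION).residues
        kept_keys = {matrix.representatives[c].residues for c in matrix.cluster_ids}
        a13u = apply_mutations(ref, [parse_mutation("A13U")])
        assert extract_region(a13u, ref, P7P8_REGION).residues in kept_keys  # 6% cluster
        c12g = apply_mutations(ref, [parse_mutation("C12G")])
        assert extract_region(c12g, ref, P7P8_REGION).residues not in kept_keys  # 4% cluster

    def test_cluster_naming_by_first_threshold_round(self, fx):
        counts = {1: [1000, 0], 2: [950, 50], 3: [900, 100]}
        samples = _samples_from_counts(fx, [[], ["C12G"]], counts)
        matrix = track(samples, fx.polymerase_ref, P7P8_REGION)
        assert set(matrix.cluster_ids) == {"1.1", "2.1"}

    def test_frequencies_sum_to_one_before_retention(self, fx):
        counts = {1: [600, 250, 150]}
        samples = _samples_from_counts(fx, [[], ["C12G"], ["A13U"]], counts)
        matrix = track(samples, fx.polymerase_ref, P7P8_REGION, rep_threshold=0.0, singleton_threshold=0.0)
        assert matrix.values[1].sum() == pytest.approx(1.0)

    def test_read_order_invariance(self, fx):
        counts = {1: [300, 200], 2: [250, 250]}
        samples = _samples_from_counts(fx, [[], ["C12G"]], counts)
        m1 = track(samples, fx.polymerase_ref, P7P8_REGION)
        rng = np.random.default_rng(0)
        for s in samples:
            rng.shuffle(s.reads)
        m2 = track(samples, fx.polymerase_ref, P7P8_REGION)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_merge_never_decreases_retained_fraction(self, fx):
        counts = {1: [500, 480, 20], 2: [520, 460, 20]}
        samples = _samples_from_counts(fx, [[], ["C15G", "G85C"], ["del17A"]], counts)
        no_merge = track(samples, fx.polymerase_ref, P7P8_REGION)
        merged = track(samples, fx.polymerase_ref, P7P8_REGION, merge_core=CONSERVED_CORE)
        assert (merged.retained_fraction >= no_merge.retained_fraction - 1e-12).all()

    def test_recovery_of_simulated_trajectories(self, fx):
        """Tracked frequencies match the generator's truth within 3 SE."""
        ref = fx.polymerase_ref
        v1 = apply_mutations(ref, [parse_mutation("C15G"), parse_mutation("G85C")])
        model = PopulationModel(
            genotypes=(ref, RnaSequence("v1", v1.residues)),
            fitness=(1.0, 1.5),
            initial_freqs=(0.9, 0.1),
            pop_size=2000,
            n_rounds=6,
            seed=21,
        )
        truth = expected_frequencies(model)
        matrix = track(simulate_rounds(model), ref, P7P8_REGION)
        assert matrix.values.shape[0] == 2
        ref_key = extract_region(ref, ref, P7P8_REGION).residues
        for g_idx in range(2):
            key = extract_region(model.genotypes[g_idx], ref, P7P8_REGION).residues
            cid = next(c for c in matrix.cluster_ids if matrix.representatives[c].residues == key)
            for r_idx, rnd in enumerate(model.rounds):
                p = truth[r_idx, g_idx]
                se = np.sqrt(p * (1 - p) / model.pop_size)
                assert abs(matrix.values.loc[cid, rnd] - p) <= 3 * se + 1e-9


class TestStrandCorrelation:
    def _matrix(self, rows, rounds):
        df = pd.DataFrame.from_dict(
            {k: list(v) for k, v in rows.items()}, orient="index", columns=rounds
        )
        return FrequencyMatrix(df, pd.Series(1.0, index=rounds))

    def test_identical_trajectories(self):
        rounds = [1, 2, 3, 4]
        x = [0.1, 0.3, 0.6, 0.9]
        m5 = self._matrix({"AAA": x}, rounds)
        m3 = self._matrix({"UUU": x}, rounds)
        assert strand_correlation(m5, m3, {"AAA": "UUU"})["AAA|UUU"] == pytest.approx(1.0)

    def test_opposite_trajectories(self):
        rounds = [1, 2, 3]
        x = np.array([0.2, 0.5, 0.9])
        m5 = self._matrix({"AAA": x}, rounds)
        m3 = self._matrix({"UUU": 1 - x}, rounds)
        assert strand_correlation(m5, m3, {"AAA": "UUU"})["AAA|UUU"] == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        rounds = [1, 2, 3]
        m5 = self._matrix({"AAA": [0.5, 0.5, 0.5]}, rounds)
        m3 = self._matrix({"UUU": [0.1, 0.2, 0.3]}, rounds)
        assert np.isnan(strand_correlation(m5, m3, {"AAA": "UUU"})["AAA|UUU"])

    def test_mismatched_round_axes_rejected(self):
        m5 = self._matrix({"AAA": [0.1, 0.2]}, [1, 2])
        m3 = self._matrix({"UUU": [0.1, 0.2]}, [1, 3])
        with pytest.raises(ValueError):
            strand_correlation(m5, m3, {"AAA": "UUU"})
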