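"""Base-pair classification, stem validation, covariation verdicts, probing."""

import itertools

import numpy as np
import pytest

from riboevo import (
    PairSupport,
    ProbingProfile,
    StructureModel,
    assess_pair_support,
    classify_pair,
    load_models,
    normalize_probing,
    structure_concordance,
    transversion_pair_constructs,
    validate_stem,
)
from riboevo.seq_core import MutationSpec, RegionSpec, RnaSequence, apply_mutations, parse_mutation


class TestClassifyPair:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("G", "C", "watson_crick"), ("A", "U", "watson_crick"),
         ("G", "U", "wobble"), ("A", "C", "unpaired"), ("A", "A", "unpaired")],
    )
    def test_classes(self, a, b, expected):
        assert classify_pair(a, b) == expected

    def test_symmetric_for_all_16_pairs(self):
        for a, b in itertools.product("ACGU", repeat=2):
            assert classify_pair(a, b) == classify_pair(b, a)

    def test_invalid_base(self):
        with pytest.raises(ValueError):
            classify_pair("G", "T")


class TestValidateStem:
    def test_reference_has_six_pairs(self, fx, models):
        n, classes = validate_stem(fx.polymerase_ref, models["pseudoknot"], "P8")
        assert n == 6
        assert all(cls == "watson_crick" for _, cls in classes)

    def test_single_disruption(self, fx, models):
        mutant = apply_mutations(fx.polymerase_ref, [parse_mutation("C12G")])
        n, classes = validate_stem(mutant, models["pseudoknot"], "P8")
        assert n == 5
        assert dict(classes)[(12, 88)] == "unpaired"  # G:G

    def test_compensatory_double_restores(self, fx, models):
        double = apply_mutations(
            fx.polymerase_ref, [parse_mutation("C12G"), parse_mutation("G88C")]
        )
        n, _ = validate_stem(double, models["pseudoknot"], "P8")
        assert n == 6

    def test_wc_pair_swap_preserves_count(self, fx, models):
        """Replacing any P8 pair by another Watson-Crick pair keeps 6/6."""
        ref = fx.polymerase_ref
        for p5, p3 in models["pseudoknot"].stems["P8"]:
            for b5, b3 in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]:
                muts = []
                if ref.base(p5) != b5:
                    muts.append(MutationSpec("substitution", p5, ref.base(p5), b5))
                if ref.base(p3) != b3:
                    muts.append(MutationSpec("substitution", p3, ref.base(p3), b3))
                variant = apply_mutations(ref, muts)
                n, _ = validate_stem(variant, models["pseudoknot"], "P8")
                assert n == 6

    def test_unknown_stem_rejected(self, fx, models):
        with pytest.raises(KeyError):
            validate_stem(fx.polymerase_ref, models["pseudoknot"], "P99")

    def test_transversion_constructs(self, fx, models):
        """Each single transversion breaks exactly one pair; the combined
        double restores complementarity, for all six P8 pairs."""
        for pair in models["pseudoknot"].stems["P8"]:
            cons = transversion_pair_constructs(fx.polymerase_ref, pair)
            assert validate_stem(cons["single5"], models["pseudoknot"], "P8")[0] == 5
            assert validate_stem(cons["single3"], models["pseudoknot"], "P8")[0] == 5
            assert validate_stem(cons["double"], models["pseudoknot"], "P8")[0] == 6


class TestAssessPairSupport:
    def make(self, s5, s3, double, wt=1.0):
        return PairSupport((12, 88), wt, s5, s3, double)

    def test_restored(self):
        assert assess_pair_support(self.make(0.005, 0.01, 0.8)) == "covariation_supported"

    def test_partially_restored(self):
        assert assess_pair_support(self.make(0.005, 0.01, 0.15)) == "partially_restored"

    def test_not_restored(self):
        # the distal-pair pattern: disruption cannot be rescued
        assert assess_pair_support(self.make(0.005, 0.01, 0.02)) == "not_restored"

    def test_not_disruptive(self):
        assert assess_pair_support(self.make(0.5, 0.6, 0.9)) == "not_disruptive"

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            PairSupport((12, 88), 1.0, -0.1, 0.0, 0.0)


def toy_profile(raw24, background, positions=None):
    positions = positions or list(range(1, len(raw24) + 1))
    return ProbingProfile(
        "toy", positions, {24.0: np.array(raw24, dtype=float)},
        np.array(background, dtype=float),
    )


class TestNormalizeProbing:
    def test_worked_arithmetic(self):
        profile = toy_profile([100, 50, 200], [50, 50, 50])
        region = RegionSpec("roi", ((1, 3),))
        out = normalize_probing(profile, region)
        assert out.normalized.tolist() == pytest.approx([1 / 3, 0.0, 1.0])

    def test_all_background_warns_and_zeroes(self):
        profile = toy_profile([50, 50, 50], [50, 50, 50])
        region = RegionSpec("roi", ((1, 3),))
        with pytest.warns(UserWarning):
            out = normalize_probing(profile, region)
        assert (out.normalized == 0).all()

    def test_scale_invariance(self):
        region = RegionSpec("roi", ((1, 3),))
        a = normalize_probing(toy_profile([100, 50, 200], [50, 50, 50]), region)
        b = normalize_probing(toy_profile([700, 350, 1400], [350, 350, 350]), region)
        assert a.normalized.tolist() == pytest.approx(b.normalized.tolist())

    def test_missing_timepoint(self):
        profile = toy_profile([1, 2, 3], [0, 0, 0])
        with pytest.raises(KeyError):
            normalize_probing(profile, RegionSpec("roi", ((1, 3),)), timepoint=6.0)

    def test_negative_corrections_clamped(self):
        out = normalize_probing(
            toy_profile([10, 50, 200], [50, 50, 50]), RegionSpec("roi", ((1, 3),))
        )
        assert out.normalized.iloc[0] == 0.0


class TestStructureConcordance:
    paired_model = StructureModel("toy", {"S": ((1, 4), (2, 5))})
    anti_model = StructureModel("anti", {"S": ((3, 6),)})
    region = RegionSpec("roi", ((1, 6),))

    def cleaved_at_unpaired(self):
        # positions 3 and 6 unpaired under paired_model and fully cleaved
        profile = toy_profile([0, 0, 100, 0, 0, 100], [0] * 6)
        return normalize_probing(profile, self.region)

    def test_perfect_concordance(self):
        assert structure_concordance(
            self.cleaved_at_unpaired(), self.paired_model, self.region
        ) == pytest.approx(1.0)

    def test_anti_concordance(self):
        assert structure_concordance(
            self.cleaved_at_unpaired(), self.anti_model, self.region
        ) == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        flat = normalize_probing(toy_profile([100] * 6, [0] * 6), self.region)
        assert np.isnan(structure_concordance(flat, self.paired_model, self.region))

    def test_antisymmetry_under_complemented_pairing(self):
        """Swapping paired and unpaired positions flips the score's sign."""
        profile = normalize_probing(toy_profile([10, 0, 80, 5, 0, 100], [0] * 6), self.region)
        complement = StructureModel("comp", {"S": ((3, 6),)})  # pairs exactly the others
        a = structure_concordance(profile, self.paired_model, self.region)
        b = structure_concordance(profile, complement, self.region)
        assert a == pytest.approx(-b)

    def test_models_file_loads_and_is_consistent(self, models):
        assert models["pseudoknot"].stems["P8"] == (
            (11, 89), (12, 88), (13, 87), (14, 86), (15, 85), (16, 84)
        )
        assert "P7_distal" in models["old"].stems
        # a position can belong to only one pair within a model
        for m in models.values():
            positions = [p for pairs in m.stems.values() for pr in pairs for p in pr]
            assert len(positions) == len(set(positions))
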