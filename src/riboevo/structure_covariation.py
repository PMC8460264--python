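"""Secondary-structure models, covariation logic, and in-line probing.

The polymerase ribozyme's catalytic core admits two competing secondary
structures: the ancestral arrangement, in which nucleotides 84-89 close the
P7 stem-loop and 11-16 form the single-stranded J1/3 joining region, and the
evolved arrangement, in which those two strands pair with each other to form
the P8 stem, creating a pseudoknot. Both models ship as a declarative data
file (``data/structure_models.json``); there is no folding prediction here.

This module classifies base pairs, counts Watson-Crick support for a stem in
any sequence variant, applies the disruptive/compensatory mutation logic used
to test putative pairs, and normalizes in-line probing band intensities
(flexible, unpaired positions cleave faster than paired ones).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .seq_core import MutationSpec, RegionSpec, RnaSequence, apply_mutations

logger = logging.getLogger(__name__)

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})
# purine<->pyrimidine swap used in the covariation constructs: each base is
# transverted to its complement (C->G, G->C, A->U, U->A), so combining the
# 5' and 3' single mutations swaps the pair and restores complementarity
_TRANSVERSION = {"A": "U", "U": "A", "G": "C", "C": "G"}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

__all__ = [
    "StructureModel",
    "ProbingProfile",
    "PairSupport",
    "load_models",
    "classify_pair",
    "validate_stem",
    "transversion_pair_constructs",
    "assess_pair_support",
    "normalize_probing",
    "structure_concordance",
]


@dataclass(frozen=True)
class StructureModel:
    """A named set of stems, each an ordered list of (5' pos, 3' pos) pairs."""

    name: str
    stems: dict[str, tuple[tuple[int, int], ...]]
    regions: dict[str, RegionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for stem, pairs in self.stems.items():
            for p5, p3 in pairs:
                if not p5 < p3:
                    raise ValueError(f"{self.name}/{stem}: pair ({p5},{p3}) not 5'<3'")
                if p5 in seen or p3 in seen:
                    raise ValueError(f"{self.name}: position reused across pairs")
                seen.update((p5, p3))

    def paired_positions(self) -> set[int]:
        return {p for pairs in self.stems.values() for pair in pairs for p in pair}

    def pairedness(self, positions: list[int]) -> np.ndarray:
        paired = self.paired_positions()
        return np.array([1.0 if p in paired else 0.0 for p in positions])


def load_models(path: str | Path | None = None) -> dict[str, StructureModel]:
    """Load structure models from JSON (default: the packaged model file)."""
    if path is None:
        text = resources.files("riboevo").joinpath("data/structure_models.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    models = {}
    for name, spec in raw["models"].items():
        stems = {
            stem: tuple((int(a), int(b)) for a, b in pairs)
            for stem, pairs in spec["stems"].items()
        }
        regions = {
            rname: RegionSpec(rname, tuple((int(a), int(b)) for a, b in ivs))
            for rname, ivs in spec.get("regions", {}).items()
        }
        models[name] = StructureModel(name, stems, regions)
    return models


def classify_pair(a: str, b: str) -> str:
    """Classify two bases as watson_crick, wobble, or unpaired. Symmetric."""
    if a not in _COMPLEMENT or b not in _COMPLEMENT:
        raise ValueError(f"invalid base in pair ({a!r}, {b!r})")
    if (a, b) in WATSON_CRICK:
        return "watson_crick"
    if (a, b) in WOBBLE:
        return "wobble"
    return "unpaired"


def validate_stem(
    seq: RnaSequence, model: StructureModel, stem: str
) -> tuple[int, list[tuple[tuple[int, int], str]]]:
    """Count Watson-Crick pairs of a stem realized in a sequence variant.

    Returns (number of Watson-Crick pairs, per-pair classifications).
    """
    if stem not in model.stems:
        raise KeyError(f"model {model.name!r} has no stem {stem!r}")
    classifications = []
    n_wc = 0
    for p5, p3 in model.stems[stem]:
        cls = classify_pair(seq.base(p5), seq.base(p3))
        classifications.append(((p5, p3), cls))
        if cls == "watson_crick":
            n_wc += 1
    return n_wc, classifications


def transversion_pair_constructs(
    seq: RnaSequence, pair: tuple[int, int]
) -> dict[str, RnaSequence]:
    """The three mutagenesis constructs probing one putative pair.

    A transversion is made in the 5' strand, in the 3' strand, or in both so
    that complementarity is restored (e.g. C12-G88 -> G12-C88). Returns
    {"single5", "single3", "double"} variants of ``seq``.
    """
    p5, p3 = pair
    b5, b3 = seq.base(p5), seq.base(p3)
    alt5 = _TRANSVERSION[b5]
    alt3 = _TRANSVERSION[b3]
    m5 = MutationSpec("substitution", p5, b5, alt5)
    m3 = MutationSpec("substitution", p3, b3, alt3)
    # compensatory double: complement of the 5' transversion on the 3' strand
    m3c = MutationSpec("substitution", p3, b3, _COMPLEMENT[alt5])
    return {
        "single5": apply_mutations(seq, [m5]),
        "single3": apply_mutations(seq, [m3]),
        "double": apply_mutations(seq, [m5, m3c]),
    }


@dataclass(frozen=True)
class PairSupport:
    """Relative activities of the mutagenesis constructs for one pair."""

    pair: tuple[int, int]
    rel_activity_wt: float
    rel_single5: float
    rel_single3: float
    rel_double: float

    def __post_init__(self) -> None:
        for v in (self.rel_activity_wt, self.rel_single5, self.rel_single3, self.rel_double):
            if v < 0:
                raise ValueError("activities must be non-negative")


def assess_pair_support(
    support: PairSupport,
    disrupt_fold: float = 50.0,
    restore_frac: float = 0.5,
    partial_frac: float = 0.1,
) -> str:
    """Covariation verdict for one putative base pair.

    A pair is informative only if both single mutations are disruptive
    (activity below wt / ``disrupt_fold``). The compensatory double mutant
    then yields ``covariation_supported`` when it restores at least
    ``restore_frac`` of the reference activity, ``partially_restored`` above
    ``partial_frac``, and ``not_restored`` otherwise.
    """
    wt = support.rel_activity_wt
    threshold = wt / disrupt_fold
    if support.rel_single5 > threshold and support.rel_single3 > threshold:
        return "not_disruptive"
    if support.rel_double >= restore_frac * wt:
        return "covariation_supported"
    if support.rel_double >= partial_frac * wt:
        return "partially_restored"
    return "not_restored"


@dataclass
class ProbingProfile:
    """In-line probing band intensities for one polymerase variant.

    ``raw`` holds per-position counts for each incubation timepoint (hours);
    ``background`` is the unincubated lane. ``normalized`` is filled by
    :func:`normalize_probing`: background-corrected counts scaled to the
    position with the highest level of cleavage within the region of
    interest.
    """

    variant: str
    positions: list[int]
    raw: dict[float, np.ndarray]
    background: np.ndarray
    normalized: pd.Series | None = None

    def __post_init__(self) -> None:
        n = len(self.positions)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (n,):
            raise ValueError("background length does not match positions")
        self.raw = {t: np.asarray(v, dtype=float) for t, v in self.raw.items()}
        for t, v in self.raw.items():
            if v.shape != (n,):
                raise ValueError(f"lane at {t} hr does not match positions")


def normalize_probing(
    profile: ProbingProfile, region: RegionSpec, timepoint: float = 24.0
) -> ProbingProfile:
    """Background-correct and scale a probing lane to its cleavage maximum.

    corrected = max(raw - background, 0); normalized = corrected divided by
    the maximum corrected count over the region of interest. If no position
    in the region rises above background the profile is all-zero (flagged
    with a warning).
    """
    if timepoint not in profile.raw:
        raise KeyError(f"no lane at {timepoint} hr (have {sorted(profile.raw)})")
    corrected = np.maximum(profile.raw[timepoint] - profile.background, 0.0)
    in_region = np.array([p in region for p in profile.positions])
    if not in_region.any():
        raise ValueError(f"region {region.name!r} covers no profiled position")
    peak = corrected[in_region].max()
    if peak <= 0:
        warnings.warn(
            f"{profile.variant}: no cleavage above background in region {region.name!r}",
            stacklevel=2,
        )
        normalized = np.zeros_like(corrected)
    else:
        normalized = corrected / peak
    out = ProbingProfile(
        profile.variant, list(profile.positions), dict(profile.raw), profile.background.copy()
    )
    out.normalized = pd.Series(normalized, index=profile.positions, name=profile.variant)
    return out


def structure_concordance(
    profile: ProbingProfile, model: StructureModel, region: RegionSpec
) -> float:
    """How well a structure model explains protection from in-line cleavage.

    Point-biserial correlation, over the region's positions, between
    pairedness under the model (1 = in a stem pair) and protection
    (1 - normalized cleavage). Returns NaN when either variable has zero
    variance.
    """
    if profile.normalized is None:
        raise ValueError("profile must be normalized first")
    positions = [p for p in profile.positions if p in region]
    paired = model.pairedness(positions)
    protection = 1.0 - profile.normalized.loc[positions].to_numpy()
    if np.ptp(paired) == 0 or np.ptp(protection) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = stats.pointbiserialr(paired, protection)
    return float(r)
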