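"""Synthetic inputs with known ground truth for every pipeline stage.

Everything the analyses consume can be generated here: reference fixtures,
error-bearing product reads, per-round population samples evolving under
selection and mutation, in-line probing lane counts, and kinetic time
courses. All generators are seeded and bit-for-bit reproducible.

The fixture sequences are synthetic: they satisfy the printed length and
structure constraints of the molecules they emulate (a 33-nt hammerhead
target, a polymerase region whose P8 stem forms six Watson-Crick pairs) but
no claim of sequence identity with any laboratory construct is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticFit, TimeCourse
from .population_tracking import RoundSample
from .seq_core import QualRead, RegionSpec, RnaSequence
from .structure_covariation import ProbingProfile, StructureModel

BASES = "ACGU"
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

__all__ = [
    "ErrorModel",
    "PopulationModel",
    "FixtureSet",
    "fixtures",
    "P7P8_REGION",
    "CONSERVED_CORE",
    "simulate_products",
    "expected_frequencies",
    "simulate_rounds",
    "simulate_probing",
    "simulate_timecourse",
]

# the region encompassing the P7 and P8 stems, and the conserved core
# positions excluded from cluster-equivalence merging
P7P8_REGION = RegionSpec("P7P8", ((9, 17), (83, 95)))
CONSERVED_CORE = RegionSpec("core", ((11, 16), (84, 89)))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSet:
    """Synthetic reference sequences used throughout tests and examples."""

    hammerhead_ref: RnaSequence
    ligase_ref: RnaSequence
    polymerase_ref: RnaSequence
    polymerase_region_key: RnaSequence
    printed_template: RnaSequence


def _random_rna(rng: np.random.Generator, length: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=length)]


def _polymerase_fixture() -> RnaSequence:
    """A 182-nt synthetic polymerase-like reference, 52-2 numbering.

    Constraints baked in: P8 pairs G11-C89, C12-G88, A13-U87, C14-G86,
    C15-G85, A16-U84 (six Watson-Crick pairs); an A at position 17 so the
    junction-A equivalence rule is exercisable; an unpaired A at 90; the
    proximal P7 stem 73-78/91-96 fully paired; the old model's distal P7
    pairs (80,89),(81,88),(82,87) deliberately broken.
    """
    rng = np.random.default_rng(524252)
    chars = _random_rna(rng, 182)
    for pos, base in {
        11: "G", 12: "C", 13: "A", 14: "C", 15: "C", 16: "A", 17: "A",
        84: "U", 85: "G", 86: "G", 87: "U", 88: "G", 89: "C", 90: "A",
        80: "A", 81: "A", 82: "C",
    }.items():
        chars[pos - 1] = base
    for p5, p3 in ((73, 96), (74, 95), (75, 94), (76, 93), (77, 92), (78, 91)):
        chars[p3 - 1] = _COMP[chars[p5 - 1]]
    return RnaSequence("polymerase_synthetic", "".join(chars))


def fixtures() -> FixtureSet:
    """Deterministic fixture sequences (synthetic, constraint-satisfying)."""
    # 33-nt hammerhead-like target carrying the catalytic CUGAUGA / GAAA
    # boxes of the motif; synthetic stand-in for the selection target
    hammerhead = RnaSequence(
        "hammerhead_synthetic", "GGGUGACCCUGAUGAGGCCGAAAGGCCGAAACG"
    )
    rng = np.random.default_rng(38652)
    ligase = RnaSequence("ligase_synthetic", "".join(_random_rna(rng, 122)))
    polymerase = _polymerase_fixture()
    from .population_tracking import extract_region

    key = extract_region(polymerase, polymerase, P7P8_REGION)
    assert key is not None
    return FixtureSet(
        hammerhead_ref=hammerhead,
        ligase_ref=ligase,
        polymerase_ref=polymerase,
        polymerase_region_key=RnaSequence("polymerase_region_key", key.residues, dict(key.meta)),
        printed_template=RnaSequence("extension_product", "UGCGAAGCGUG"),
    )


# ---------------------------------------------------------------------------
# Product reads with a configurable error model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Per-position error process applied when copying a reference.

    ``sub_rate``/``del_rate`` apply per template position, ``ins_rate`` per
    junction (after each incorporated position). ``sub_matrix`` gives the
    distribution over incorporated bases conditional on the template base;
    default is uniform over the three mismatches. ``truncation`` is a
    geometric stop probability per extension step (0 = all full length).
    """

    sub_rate: float = 0.0
    del_rate: float = 0.0
    ins_rate: float = 0.0
    truncation: float = 0.0
    sub_matrix: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.del_rate, self.ins_rate, self.truncation):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if self.sub_matrix is not None:
            for tb, row in self.sub_matrix.items():
                if abs(sum(row.values()) - 1.0) > 1e-9 or row.get(tb, 0.0) != 0.0:
                    raise ValueError(f"sub_matrix row {tb} must sum to 1 over mismatches")

    @classmethod
    def with_wobble_bias(cls, sub_rate: float, bias: float, **kwargs) -> "ErrorModel":
        """Uniform mismatches except the wobble-templated ones (template U
        read as G, template G read as U), which are ``bias``-fold more
        likely — emulating misincorporation dominated by G-U wobble pairing."""
        matrix: dict[str, dict[str, float]] = {}
        for tb in BASES:
            others = [b for b in BASES if b != tb]
            w = {b: 1.0 for b in others}
            if tb == "U":
                w["G"] = bias
            elif tb == "G":
                w["U"] = bias
            total = sum(w.values())
            matrix[tb] = {b: w[b] / total for b in others}
        return cls(sub_rate=sub_rate, sub_matrix=matrix, **kwargs)

    def mismatch_distribution(self, template_base: str) -> tuple[list[str], list[float]]:
        if self.sub_matrix is None:
            others = [b for b in BASES if b != template_base]
            return others, [1.0 / 3.0] * 3
        row = self.sub_matrix[template_base]
        alts = sorted(row)
        return alts, [row[b] for b in alts]


def simulate_products(ref: RnaSequence, model: ErrorModel, n: int) -> list[QualRead]:
    """Draw ``n`` independent product reads of ``ref`` under the error model.

    Per template position the product deletes with ``del_rate``, otherwise
    substitutes with ``sub_rate`` (base via ``sub_matrix``); after each
    incorporated position an insertion of one uniform base occurs with
    ``ins_rate``, and synthesis stops with probability ``truncation``.
    Qualities are uniform Phred 40.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(model.seed)
    L = len(ref)
    u_del = rng.random((n, L))
    u_sub = rng.random((n, L))
    u_ins = rng.random((n, L))
    u_stop = rng.random((n, L))
    u_base = rng.random((n, L))  # shared draw for substitution/insertion base choice
    alt_table = {tb: model.mismatch_distribution(tb) for tb in BASES}
    cum_table = {
        tb: (alts, np.cumsum(probs)) for tb, (alts, probs) in alt_table.items()
    }
    reads: list[QualRead] = []
    for i in range(n):
        parts: list[str] = []
        for j, tb in enumerate(ref.residues):
            if u_del[i, j] >= model.del_rate:
                if u_sub[i, j] < model.sub_rate:
                    alts, cum = cum_table[tb]
                    parts.append(alts[int(np.searchsorted(cum, u_base[i, j] * cum[-1]))])
                else:
                    parts.append(tb)
                if u_ins[i, j] < model.ins_rate:
                    parts.append(BASES[int(u_base[i, j] * 4) & 3])
            if u_stop[i, j] < model.truncation and j < L - 1:
                break
        if not parts:  # a fully failed extension still yields a 1-nt stub
            parts.append(ref.residues[0])
        seq = RnaSequence(f"read{i}", "".join(parts))
        reads.append(QualRead(seq, (40,) * len(seq)))
    return reads


# ---------------------------------------------------------------------------
# Evolving population samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """Selection/mutation/sampling model for per-round population samples.

    ``genotypes`` are full-length sequences (region variants embedded in a
    common backbone); ``fitness`` weights drive the deterministic
    expected-frequency update p'_i ∝ p_i * w_i each round; ``mut_rate`` is
    the per-round probability that a lineage switches to another listed
    genotype (uniformly); ``pop_size`` reads are sampled per round
    (multinomially when ``sample`` is true, by largest-remainder rounding of
    the expected counts otherwise, emulating an infinite population).
    """

    genotypes: tuple[RnaSequence, ...]
    fitness: tuple[float, ...]
    initial_freqs: tuple[float, ...]
    mut_rate: float = 0.0
    pop_size: int = 10_000
    n_rounds: int = 14
    rounds: tuple[int, ...] = ()
    sample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.genotypes)
        if k < 1:
            raise ValueError("need at least one genotype")
        if len(self.fitness) != k or len(self.initial_freqs) != k:
            raise ValueError("fitness/initial_freqs must match genotypes")
        if any(w <= 0 for w in self.fitness):
            raise ValueError("fitness weights must be positive")
        if abs(sum(self.initial_freqs) - 1.0) > 1e-9:
            raise ValueError("initial frequencies must sum to 1")
        if not self.rounds:
            object.__setattr__(self, "rounds", tuple(range(1, self.n_rounds + 1)))
        if len(self.rounds) != self.n_rounds:
            raise ValueError("rounds labels must match n_rounds")


def expected_frequencies(model: PopulationModel) -> np.ndarray:
    """Deterministic frequency trajectory, shape (n_rounds, n_genotypes).

    One round applies selection p' ∝ p*w followed by mutation that moves a
    fraction ``mut_rate`` of each lineage uniformly onto the other
    genotypes. Row r is the expected composition of the round-r sample.
    """
    k = len(model.genotypes)
    w = np.asarray(model.fitness, dtype=float)
    p = np.asarray(model.initial_freqs, dtype=float)
    out = np.empty((model.n_rounds, k))
    for r in range(model.n_rounds):
        p = p * w
        p = p / p.sum()
        if model.mut_rate > 0 and k > 1:
            p = (1 - model.mut_rate) * p + model.mut_rate * (p.sum() - p) / (k - 1)
        out[r] = p
    return out


def simulate_rounds(model: PopulationModel) -> list[RoundSample]:
    """Per-round read samples drawn from the expected-frequency trajectory."""
    rng = np.random.default_rng(model.seed)
    freqs = expected_frequencies(model)
    samples = []
    for idx, round_no in enumerate(model.rounds):
        p = freqs[idx]
        if model.sample:
            counts = rng.multinomial(model.pop_size, p)
        else:
            exact = p * model.pop_size
            counts = np.floor(exact).astype(int)
            remainder = model.pop_size - counts.sum()
            order = np.argsort(-(exact - counts))
            counts[order[:remainder]] += 1
        reads = []
        for g_idx, cnt in enumerate(counts):
            g = model.genotypes[g_idx]
            quals = (40,) * len(g)  # shared across copies of a genotype
            for c in range(cnt):
                seq = RnaSequence(f"r{round_no}_{g.id}_{c}", g.residues)
                reads.append(QualRead(seq, quals))
        samples.append(RoundSample(round=round_no, reads=reads))
    return samples


# ---------------------------------------------------------------------------
# In-line probing lanes and kinetic time courses
# ---------------------------------------------------------------------------

def simulate_probing(
    model: StructureModel,
    region: RegionSpec,
    flex_unpaired: float = 1.0,
    flex_paired: float = 0.0,
    background: float = 50.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    timepoints: tuple[float, ...] = (3.0, 6.0, 12.0, 24.0),
    scale: float = 1000.0,
    flex_overrides: dict[int, float] | None = None,
    variant: str = "synthetic",
) -> ProbingProfile:
    """Probing lane counts for a structure: unpaired positions cleave more.

    Raw counts at timepoint t are background + flexibility * scale * t/24,
    with multiplicative lognormal noise of coefficient of variation
    ``noise_cv``. Flexibility is ``flex_paired`` for positions in a stem
    pair of ``model`` and ``flex_unpaired`` otherwise; ``flex_overrides``
    pins chosen positions (e.g. a hyperflexible unpaired linker).
    """
    if not flex_unpaired > flex_paired >= 0:
        raise ValueError("need flex_unpaired > flex_paired >= 0")
    rng = np.random.default_rng(seed)
    positions = region.positions()
    paired = model.paired_positions()
    flex = np.array(
        [
            (flex_overrides or {}).get(p, flex_paired if p in paired else flex_unpaired)
            for p in positions
        ]
    )

    def noisy(values: np.ndarray) -> np.ndarray:
        if noise_cv <= 0:
            return values.copy()
        sigma = np.sqrt(np.log(1 + noise_cv**2))
        return values * rng.lognormal(-sigma**2 / 2, sigma, size=values.shape)

    raw = {t: noisy(background + flex * scale * (t / 24.0)) for t in timepoints}
    bg = noisy(np.full(len(positions), background))
    return ProbingProfile(variant, positions, raw, bg)


def simulate_timecourse(
    truth: KineticFit,
    times: tuple[float, ...],
    unit: str = "min",
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "fraction",
) -> TimeCourse:
    """Evaluate a kinetic model at given times, with optional Gaussian noise.

    Fraction-kind values are clipped to [0, 1] after noise is added.
    """
    tc0 = TimeCourse(tuple(times), tuple(0.0 for _ in times), unit, kind="fraction")
    values = truth.predict(tc0.minutes())
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    if kind == "fraction":
        values = np.clip(values, 0.0, 1.0)
    else:
        values = np.maximum(values, 0.0)
    return TimeCourse(tuple(times), tuple(float(v) for v in values), unit, kind=kind)
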