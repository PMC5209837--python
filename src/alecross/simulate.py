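"""Synthetic data generator for backcross-based causal-mutation mapping.

Emulates the statistical structure of an adaptive-laboratory-evolution (ALE)
plus backcrossing experiment in haploid yeast:

* an evolved genome carrying a handful of spontaneous point mutations, two
  of which are causal for the selected phenotype (growth on glycerol) with
  epistatic interaction;
* meiosis of the transient diploid hybrid at the four-chromatid level —
  Poisson crossovers per chromosome, uniform positions, no interference —
  which guarantees 2:2 segregation at every site and classical two-locus
  tetrad-class frequencies;
* repeated backcrossing to the unevolved parent with phenotype-based
  segregant selection, halving the expected retention of neutral evolved
  mutations per round (0.5³ = 12.5 % after three rounds);
* per-sample genotype calls with read-depth and genotype-quality noise,
  heterozygous artifact calls in repetitive regions, and CNV flags;
* plate-monitor growth curves (lag + exponential + saturation) observed
  through the instrument's power-law G-value calibration.

All operations are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _st

from .filtering import Interval, SampleCall, VariantRecord
from .growth import GrowthCurve, od_to_g

__all__ = [
    "GenomeSpec",
    "Variant",
    "HaploidGenome",
    "PhenotypeModel",
    "CrossConfig",
    "CallNoiseModel",
    "default_genome_spec",
    "stage_seed",
    "simulate_evolved_genome",
    "plant_neutral_mutations",
    "simulate_meiosis",
    "run_backcross_program",
    "assign_phenotype",
    "simulate_genotype_calls",
    "simulate_growth_curve",
    "simulate_mapping_cohort",
    "expected_neutral_retention",
]

_BASES = ("A", "C", "G", "T")

# S288C nuclear chromosome lengths (bp), the shape template for the default genome.
_S288C_LENGTHS = {
    "I": 230218, "II": 813184, "III": 316620, "IV": 1531933,
    "V": 576874, "VI": 270161, "VII": 1090940, "VIII": 562643,
    "IX": 439888, "X": 745751, "XI": 666816, "XII": 1078177,
    "XIII": 924431, "XIV": 784333, "XV": 1091291, "XVI": 948066,
}


def stage_seed(master_seed: int, stage: int) -> int:
    """Derive a per-stage 31-bit seed from a pipeline master seed.

    Uses numpy's SeedSequence spawning so derived streams never overlap.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(stage,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout plus the neutral mutation process of the evolution.

    per_bp_mutation_rate is mutations per bp per generation (yeast's natural
    rate is 1e-10 to 1e-9); rate 0 switches the neutral process off.
    """

    chromosomes: tuple[tuple[str, int], ...]
    per_bp_mutation_rate: float = 1e-9
    generations: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        r = self.per_bp_mutation_rate
        if r != 0 and not (1e-12 <= r <= 1e-6):
            raise ValueError("mutation rate must be 0 or within [1e-12, 1e-6]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chromosome: str) -> int:
        for name, length in self.chromosomes:
            if name == chromosome:
                return length
        raise KeyError(f"unknown chromosome {chromosome!r}")


def default_genome_spec(
    total_bp: int = 12_000_000,
    per_bp_mutation_rate: float = 1e-9,
    generations: int = 50,
) -> GenomeSpec:
    """16 chromosomes with S288C-like relative lengths scaled to total_bp."""
    raw_total = sum(_S288C_LENGTHS.values())
    chroms = tuple(
        (name, max(1, int(round(length * total_bp / raw_total))))
        for name, length in _S288C_LENGTHS.items()
    )
    return GenomeSpec(chroms, per_bp_mutation_rate, generations)


@dataclass(frozen=True)
class Variant:
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    causal: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chromosome, self.position)


@dataclass(frozen=True)
class HaploidGenome:
    """One haploid strain: a GenomeSpec plus the variant alleles it carries."""

    spec: GenomeSpec
    variants: Mapping[tuple[str, int], Variant] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", dict(self.variants))
        for (chrom, pos), var in self.variants.items():
            if (chrom, pos) != var.locus:
                raise ValueError("variant keyed under wrong locus")
            if pos > self.spec.length_of(chrom):
                raise ValueError(
                    f"variant at {chrom}:{pos} beyond chromosome length"
                )

    def carries(self, locus: tuple[str, int]) -> bool:
        return locus in self.variants

    def with_variants(self, new: Sequence[Variant]) -> "HaploidGenome":
        merged = dict(self.variants)
        for var in new:
            if var.locus in merged:
                raise ValueError(f"variant collision at {var.chromosome}:{var.position}")
            merged[var.locus] = var
        return HaploidGenome(self.spec, merged)

    def private_variants(self, other: "HaploidGenome") -> list[Variant]:
        """Variants carried by self and absent from `other`."""
        return [v for k, v in self.variants.items() if k not in other.variants]


@dataclass(frozen=True)
class PhenotypeModel:
    """Two-locus epistatic lookup for glycerol growth (µ_max, lag).

    Defaults follow the allele-replacement measurements: the unevolved
    parent does not grow at all; the GUT1 mutation alone gives 0.060 h⁻¹,
    the UBR2 mutation alone 0.033 h⁻¹, and both together 0.130 h⁻¹ —
    more than the sum of the single effects.  Any non-reference allele at a
    causal locus counts as the causal allele.
    """

    mu_none: float = 0.0
    mu_gut1_only: float = 0.060
    mu_ubr2_only: float = 0.033
    mu_both: float = 0.130
    lag_none: float = 0.0
    lag_gut1_only: float = 30.0
    lag_ubr2_only: float = 40.0
    lag_both: float = 15.0
    # (GUT1-like locus, UBR2-like locus); defaults are the mapped coordinates
    causal_loci: tuple[tuple[str, int], tuple[str, int]] = (
        ("VIII", 38156),
        ("XII", 189434),
    )

    def __post_init__(self) -> None:
        mus = (self.mu_none, self.mu_gut1_only, self.mu_ubr2_only, self.mu_both)
        if any(m < 0 for m in mus):
            raise ValueError("growth rates must be non-negative")
        if self.mu_none > min(self.mu_gut1_only, self.mu_ubr2_only):
            raise ValueError("mu_none must not exceed the single-mutant rates")
        if len(set(self.causal_loci)) != 2:
            raise ValueError("the two causal loci must be distinct")

    def class_mus(self) -> dict[str, float]:
        return {
            "none": self.mu_none,
            "gut1_only": self.mu_gut1_only,
            "ubr2_only": self.mu_ubr2_only,
            "both": self.mu_both,
        }


def assign_phenotype(genome: HaploidGenome, model: PhenotypeModel) -> tuple[float, float]:
    """(µ_max h⁻¹, lag h) from presence/absence of the two causal alleles."""
    a, b = model.causal_loci
    has_a, has_b = genome.carries(a), genome.carries(b)
    if has_a and has_b:
        return (model.mu_both, model.lag_both)
    if has_a:
        return (model.mu_gut1_only, model.lag_gut1_only)
    if has_b:
        return (model.mu_ubr2_only, model.lag_ubr2_only)
    return (model.mu_none, model.lag_none)


@dataclass(frozen=True)
class CrossConfig:
    """Backcross-program parameters.

    recombination_rate is the expected crossover count per chromosome per
    meiosis (a yeast chromosome averages a handful).  Defaults mirror the
    mapping experiment: three rounds, 28 segregants screened per round,
    selection of the fastest grower.
    """

    recombination_rate: float = 6.0
    n_backcross_rounds: int = 3
    segregants_screened_per_round: int = 28
    selection_rule: str = "max_mu"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        if self.n_backcross_rounds < 0:
            raise ValueError("n_backcross_rounds must be >= 0")
        if self.segregants_screened_per_round < 1:
            raise ValueError("segregants_screened_per_round must be >= 1")
        if self.selection_rule not in ("max_mu", "random"):
            raise ValueError("selection_rule must be 'max_mu' or 'random'")


def _random_point_mutations(
    spec: GenomeSpec,
    n: int,
    rng: np.random.Generator,
    occupied: set[tuple[str, int]],
) -> list[Variant]:
    """n point mutations uniform over the genome, avoiding occupied loci."""
    names = [name for name, _ in spec.chromosomes]
    lengths = np.array([length for _, length in spec.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    out: list[Variant] = []
    taken = set(occupied)
    while len(out) < n:
        chrom = names[int(rng.choice(len(names), p=weights))]
        pos = int(rng.integers(1, spec.length_of(chrom) + 1))
        if (chrom, pos) in taken:
            continue
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(4))]
        out.append(Variant(chrom, pos, ref, alt))
        taken.add((chrom, pos))
    return out


def simulate_evolved_genome(
    parent: HaploidGenome,
    spec: GenomeSpec,
    model: PhenotypeModel,
    n_causal: int = 2,
    seed: int = 0,
) -> HaploidGenome:
    """Evolve `parent` for spec.generations: Poisson neutral mutations plus
    n_causal designated causal mutations at the phenotype model's loci.

    The neutral count is Poisson(total_bp × rate × generations).  Raises if a
    causal locus is already occupied in the parent.
    """
    if n_causal > len(model.causal_loci):
        raise ValueError("n_causal exceeds the number of model loci")
    rng = np.random.default_rng(seed)
    causal: list[Variant] = []
    for chrom, pos in model.causal_loci[:n_causal]:
        if parent.carries((chrom, pos)):
            raise ValueError(f"causal locus {chrom}:{pos} collides with an existing variant")
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(4))]
        causal.append(Variant(chrom, pos, ref, alt, causal=True))
    mean = spec.total_bp * spec.per_bp_mutation_rate * spec.generations
    n_neutral = int(rng.poisson(mean)) if mean > 0 else 0
    occupied = set(parent.variants) | {v.locus for v in causal}
    neutral = _random_point_mutations(spec, n_neutral, rng, occupied)
    return parent.with_variants(causal + neutral)


def plant_neutral_mutations(
    parent: HaploidGenome, n: int, seed: int = 0
) -> HaploidGenome:
    """Parent plus exactly n neutral point mutations at uniform positions."""
    rng = np.random.default_rng(seed)
    new = _random_point_mutations(parent.spec, n, rng, set(parent.variants))
    return parent.with_variants(new)


# ---------------------------------------------------------------------------
# Meiosis


def simulate_meiosis(
    parent_a: HaploidGenome,
    parent_b: HaploidGenome,
    cfg: CrossConfig,
    seed: int = 0,
) -> tuple[HaploidGenome, HaploidGenome, HaploidGenome, HaploidGenome]:
    """One meiosis of the a×b hybrid: four haploid spores (a tetrad).

    Four-chromatid bivalent model: each parent contributes two sister
    chromatids (physical lines 0,1 from parent a and 2,3 from parent b); a
    Poisson(recombination_rate) number of crossovers per chromosome occur at
    uniform positions, each joining one uniformly chosen line of each parent
    (no crossover or chromatid interference).  The four meiotic products are
    read off by walking each centromere rightward and switching lines at
    every crossover involving the line currently being followed — so a
    product's material at any point comes from exactly one line, the
    product↔line mapping is a permutation everywhere, and every variant site
    segregates exactly 2:2.  Products are distributed randomly over the four
    spores per chromosome (independent assortment).
    """
    if parent_a.spec != parent_b.spec:
        raise ValueError("parents must share one GenomeSpec")
    spec = parent_a.spec
    rng = np.random.default_rng(seed)
    spore_variants: list[dict[tuple[str, int], Variant]] = [{} for _ in range(4)]
    parents = (parent_a, parent_b)

    for chrom, length in spec.chromosomes:
        L = float(length)
        n_co = int(rng.poisson(cfg.recombination_rate))
        xs = np.sort(rng.uniform(0.0, L, size=n_co))
        a_lines = rng.integers(0, 2, size=n_co)
        b_lines = 2 + rng.integers(0, 2, size=n_co)
        # line switch history per product (product k starts on line k)
        switches: list[list[tuple[float, int]]] = [[] for _ in range(4)]
        line_of = [0, 1, 2, 3]  # product -> current physical line
        for x, a, b in zip(xs, a_lines, b_lines):
            pa, pb = line_of.index(int(a)), line_of.index(int(b))
            line_of[pa], line_of[pb] = int(b), int(a)
            switches[pa].append((float(x), int(b)))
            switches[pb].append((float(x), int(a)))
        assignment = rng.permutation(4)

        sites = sorted(
            {pos for g in parents for c, pos in g.variants if c == chrom}
        )
        for pos in sites:
            x = pos - 0.5  # continuous coordinate strictly inside the bp
            for k in range(4):
                line = k
                for sx, sline in switches[k]:
                    if sx >= x:
                        break
                    line = sline
                src = 0 if line < 2 else 1
                var = parents[src].variants.get((chrom, pos))
                if var is not None:
                    spore_variants[int(assignment[k])][(chrom, pos)] = var

    return tuple(HaploidGenome(spec, v) for v in spore_variants)  # type: ignore[return-value]


def expected_neutral_retention(n_rounds: int) -> float:
    """Closed-form expected fraction of unselected evolved-specific mutations
    retained after n backcross rounds: each meiosis transmits each
    heterozygous site to a given spore with probability 1/2, so 0.5^n.
    (1 − 0.5³ = 87.5 % eliminated after three rounds.)"""
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    return 0.5**n_rounds


def run_backcross_program(
    evolved: HaploidGenome,
    parent: HaploidGenome,
    cfg: CrossConfig,
    model: PhenotypeModel,
) -> tuple[HaploidGenome, list[float]]:
    """Backcross `evolved` to `parent` for cfg.n_backcross_rounds rounds.

    Each round sporulates the hybrid, screens
    cfg.segregants_screened_per_round segregants, and selects one by
    cfg.selection_rule ("max_mu": highest µ under the phenotype model, ties
    broken by lowest segregant index; "random": uniform).  Returns the final
    selected segregant and, per round, the cumulative fraction of the
    evolved strain's non-causal private mutations still retained.
    """
    if cfg.n_backcross_rounds < 1:
        raise ValueError("n_backcross_rounds must be >= 1 to run a program")
    causal_loci = set(model.causal_loci)
    neutral0 = {
        v.locus for v in evolved.private_variants(parent) if v.locus not in causal_loci
    }
    current = evolved
    retention: list[float] = []
    for rnd in range(cfg.n_backcross_rounds):
        round_seed = stage_seed(cfg.seed, rnd)
        rng = np.random.default_rng(round_seed)
        n = cfg.segregants_screened_per_round
        segregants: list[HaploidGenome] = []
        meiosis_idx = 0
        while len(segregants) < n:
            tet = simulate_meiosis(
                current, parent, cfg, seed=stage_seed(round_seed, 1000 + meiosis_idx)
            )
            segregants.extend(tet)
            meiosis_idx += 1
        segregants = segregants[:n]
        if cfg.selection_rule == "max_mu":
            mus = [assign_phenotype(s, model)[0] for s in segregants]
            best = int(np.argmax(mus))  # argmax returns the lowest tied index
        else:
            best = int(rng.integers(n))
        current = segregants[best]
        if neutral0:
            kept = sum(1 for locus in neutral0 if current.carries(locus))
            retention.append(kept / len(neutral0))
        else:
            retention.append(0.0)
    return current, retention


# ---------------------------------------------------------------------------
# Genotype calls

def _default_gq(depth: int, error_rate: float) -> int:
    """Phred-scaled genotype quality: error probability of a majority-vote
    call over `depth` reads with per-read error `error_rate`, capped at 255."""
    if depth <= 0:
        return 0
    p_gt = float(_st.binom.sf(depth / 2.0, depth, error_rate))
    p_tie = float(_st.binom.pmf(depth // 2, depth, error_rate)) if depth % 2 == 0 else 0.0
    p_err = p_gt + 0.5 * p_tie
    if p_err <= 0:
        return 255
    return min(255, max(0, int(round(-10.0 * math.log10(max(p_err, 1e-26))))))


@dataclass(frozen=True)
class CallNoiseModel:
    """Noise process for per-sample genotype calls.

    Depth is negative-binomial around mean_depth with variance
    mean + dispersion·mean² (dispersion 0 → every site at exactly
    mean_depth).  A call is a majority vote over depth reads, each wrong
    with probability base_error_rate; ties are broken by a fair coin.
    Genotype quality is the Phred score of that call's error probability
    (0–255).  Sites inside het_artifact_regions emit heterozygous ref/alt
    calls (repetitive-element artifacts); sites inside cnv_regions are
    flagged as copy-number variable in every sample.
    """

    mean_depth: float = 100.0
    depth_dispersion: float = 0.1
    base_error_rate: float = 0.001
    gq_model: Optional[Callable[[int, float], int]] = None
    het_artifact_regions: tuple[Interval, ...] = ()
    cnv_regions: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if not 0 <= self.base_error_rate <= 1:
            raise ValueError("base_error_rate must be in [0, 1]")
        object.__setattr__(self, "het_artifact_regions", tuple(self.het_artifact_regions))
        object.__setattr__(self, "cnv_regions", tuple(self.cnv_regions))

    def quality(self, depth: int, error_rate: float) -> int:
        fn = self.gq_model or _default_gq
        return fn(depth, error_rate)


def _in_regions(chrom: str, pos: int, regions: Sequence[Interval]) -> bool:
    p0 = pos - 1
    return any(c == chrom and s <= p0 < e for c, s, e in regions)


def simulate_genotype_calls(
    strains: Sequence[HaploidGenome],
    noise: CallNoiseModel,
    seed: int = 0,
    sample_names: Optional[Sequence[str]] = None,
) -> list[VariantRecord]:
    """One VariantRecord per site that is variant in any strain.

    Non-carrier strains are called with the reference allele.  Depth, call
    errors, quality, heterozygous artifacts and CNV flags follow the noise
    model.  Records are ordered by (chromosome order in the spec, position).
    """
    if not strains:
        raise ValueError("need at least one strain")
    spec = strains[0].spec
    if any(s.spec != spec for s in strains):
        raise ValueError("strains must share one GenomeSpec")
    if sample_names is None:
        sample_names = [f"S{i}" for i in range(len(strains))]
    if len(sample_names) != len(strains):
        raise ValueError("sample_names must match strains")
    rng = np.random.default_rng(seed)
    chrom_order = {name: i for i, (name, _) in enumerate(spec.chromosomes)}

    sites: dict[tuple[str, int], dict] = {}
    for genome in strains:
        for locus, var in genome.variants.items():
            entry = sites.setdefault(locus, {"ref": var.ref_allele, "alts": []})
            if var.alt_allele not in entry["alts"]:
                entry["alts"].append(var.alt_allele)

    records: list[VariantRecord] = []
    for locus in sorted(sites, key=lambda lc: (chrom_order[lc[0]], lc[1])):
        chrom, pos = locus
        entry = sites[locus]
        ref, alts = entry["ref"], tuple(entry["alts"])
        site_alleles = (ref,) + alts
        in_het = _in_regions(chrom, pos, noise.het_artifact_regions)
        in_cnv = _in_regions(chrom, pos, noise.cnv_regions)
        calls = []
        for genome, name in zip(strains, sample_names):
            var = genome.variants.get(locus)
            true_allele = var.alt_allele if var is not None else ref
            if noise.depth_dispersion == 0:
                depth = int(round(noise.mean_depth))
            else:
                k = 1.0 / noise.depth_dispersion
                p = k / (k + noise.mean_depth)
                depth = int(rng.negative_binomial(k, p))
            if in_het:
                allele: object = (ref, alts[0])
            elif depth == 0:
                allele = None
            else:
                n_wrong = int(rng.binomial(depth, noise.base_error_rate))
                wrong_majority = n_wrong * 2 > depth or (
                    n_wrong * 2 == depth and rng.random() < 0.5
                )
                if wrong_majority:
                    others = [a for a in site_alleles if a != true_allele]
                    allele = others[int(rng.integers(len(others)))]
                else:
                    allele = true_allele
            calls.append(
                SampleCall(
                    sample=name,
                    allele=allele,  # type: ignore[arg-type]
                    depth=depth,
                    quality=noise.quality(depth, noise.base_error_rate),
                )
            )
        records.append(
            VariantRecord(
                chromosome=chrom,
                position=pos,
                ref_allele=ref,
                alt_alleles=alts,
                calls=tuple(calls),
                in_cnv={name: in_cnv for name in sample_names},
            )
        )
    return records


# ---------------------------------------------------------------------------
# Growth curves

def simulate_growth_curve(
    mu_max: float,
    lag: float,
    od0: float = 0.2,
    od_cap: float = 10.0,
    noise_sd: float = 0.02,
    sample_interval: float = 40.0,
    seed: int = 0,
    duration_h: float = 72.0,
) -> GrowthCurve:
    """Plate-monitor growth curve in raw G-values.

    OD stays at od0 for t < lag, then grows logistically at rate mu_max
    toward od_cap; multiplicative log-normal noise of scale noise_sd is
    applied and the OD trace is converted to G-values by inverting the
    power-law calibration.  sample_interval is in minutes (default: one
    plate scan every 40 min).
    """
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    if od_cap <= od0:
        raise ValueError("od_cap must exceed od0")
    if mu_max < 0:
        raise ValueError("mu_max must be >= 0")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + 1e-9, sample_interval / 60.0)
    od = np.full_like(times, od0)
    growing = times >= lag
    if mu_max > 0:
        t = times[growing] - lag
        od[growing] = od_cap / (1.0 + (od_cap / od0 - 1.0) * np.exp(-mu_max * t))
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, size=od.shape))
    return GrowthCurve(times, od_to_g(od), value_kind="G")


# ---------------------------------------------------------------------------
# Whole-cohort convenience

def simulate_mapping_cohort(
    seed: int = 0,
    spec: Optional[GenomeSpec] = None,
    model: Optional[PhenotypeModel] = None,
    cross: Optional[CrossConfig] = None,
    noise: Optional[CallNoiseModel] = None,
    n_neutral: Optional[int] = None,
    sample_names: tuple[str, str, str] = ("parent", "evolved", "backcrossed"),
) -> dict:
    """ALE + backcross cohort end to end: parent, evolved strain, selected
    backcrossed segregant, and the trio's genotype-call records.

    n_neutral fixes the evolved strain's neutral mutation count; None draws
    it from the GenomeSpec's Poisson process.  Returns a dict with the three
    genomes, the records, the causal loci, and the ground-truth transmission
    of every evolved-specific mutation (True = retained in the segregant).
    """
    spec = spec or default_genome_spec()
    model = model or PhenotypeModel()
    cross = cross or CrossConfig(seed=stage_seed(seed, 2))
    noise = noise if noise is not None else CallNoiseModel()
    parent = HaploidGenome(spec)
    if n_neutral is None:
        evolved = simulate_evolved_genome(parent, spec, model, seed=stage_seed(seed, 0))
    else:
        evolved = simulate_evolved_genome(
            parent,
            GenomeSpec(spec.chromosomes, 0.0, spec.generations),
            model,
            seed=stage_seed(seed, 0),
        )
        evolved = plant_neutral_mutations(evolved, n_neutral, seed=stage_seed(seed, 1))
    selected, retention = run_backcross_program(evolved, parent, cross, model)
    records = simulate_genotype_calls(
        [parent, evolved, selected], noise, seed=stage_seed(seed, 3),
        sample_names=list(sample_names),
    )
    truth = {
        var.locus: selected.carries(var.locus)
        for var in evolved.private_variants(parent)
    }
    return {
        "parent": parent,
        "evolved": evolved,
        "backcrossed": selected,
        "records": records,
        "retention": retention,
        "causal_loci": model.causal_loci,
        "transmitted": truth,
        "sample_names": sample_names,
    }
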