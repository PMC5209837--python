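"""Variant filter cascade and backcross genotype-configuration classifier.

The mapping design sequences three haploid strains: the unevolved parent,
the evolved strain, and a segregant recovered after repeated backcrossing to
the parent.  Variants are filtered for call reliability (read depth and
Phred-scaled genotype quality), polymorphism within the trio, absence of
heterozygous artifacts (impossible genotypes in haploids, produced by
repetitive elements), and absence of copy-number variation.  Each surviving
variant is then classified by its genotype configuration: a mutation private
to the evolved strain is either *lost in backcross* (the segregant reverted
to the parental allele) or *segregating* (the segregant kept the evolved
allele) — the segregating set contains the phenotype-causal candidates.

The parent strain's called allele, not the published reference genome, is
the baseline for "evolved-specific".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

logger = logging.getLogger(__name__)

Allele = Union[str, tuple[str, str], None]
Interval = tuple[str, int, int]  # chrom, start, end — 0-based half-open (BED)


class VariantStatus(str, Enum):
    LOST_IN_BACKCROSS = "LOST_IN_BACKCROSS"
    SEGREGATING = "SEGREGATING"
    NOT_EVOLVED_SPECIFIC = "NOT_EVOLVED_SPECIFIC"
    INCONSISTENT = "INCONSISTENT"


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype call at one site.

    allele is a string for a homozygous/haploid call, an (a, b) tuple for a
    heterozygous artifact call, or None when missing.  quality is a
    Phred-scaled genotype quality in [0, 255].
    """

    sample: str
    allele: Allele
    depth: int
    quality: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.quality <= 255:
            raise ValueError("quality must be in [0, 255]")

    @property
    def is_missing(self) -> bool:
        return self.allele is None

    @property
    def is_het(self) -> bool:
        return isinstance(self.allele, tuple) and self.allele[0] != self.allele[1]

    def alleles(self) -> tuple[str, ...]:
        """Distinct non-missing allele strings in this call."""
        if self.allele is None:
            return ()
        if isinstance(self.allele, tuple):
            return tuple(dict.fromkeys(self.allele))
        return (self.allele,)


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with per-sample calls (VCF-style, 1-based position)."""

    chromosome: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    calls: tuple[SampleCall, ...]
    in_cnv: Mapping[str, bool] = field(default_factory=dict)
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.calls:
            raise ValueError("at least one sample call required")
        for alt in self.alt_alleles:
            if alt == self.ref_allele:
                raise ValueError("alt allele equal to ref allele")
        object.__setattr__(self, "alt_alleles", tuple(self.alt_alleles))
        object.__setattr__(self, "calls", tuple(self.calls))

    def call(self, sample: str) -> Optional[SampleCall]:
        for c in self.calls:
            if c.sample == sample:
                return c
        return None

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(c.sample for c in self.calls)

    @property
    def is_snp(self) -> bool:
        """Both ref and every alt are single bases; anything else is an indel."""
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 20
    min_quality: int = 60
    ploidy: int = 1
    require_polymorphic: bool = True
    drop_heterozygous: bool = True
    drop_cnv: bool = True
    cnv_mode: str = "any"  # drop if CNV in "any" vs "all" samples
    # optional allele-balance heterozygosity rule (off by default): a haploid
    # call whose minor-read fraction exceeds this is treated as heterozygous
    allele_balance_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 <= self.min_quality <= 255:
            raise ValueError("min_quality must be in [0, 255]")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.cnv_mode not in ("any", "all"):
            raise ValueError("cnv_mode must be 'any' or 'all'")


@dataclass(frozen=True)
class SampleRoles:
    parent: str
    evolved: str
    backcrossed: str

    def __post_init__(self) -> None:
        names = (self.parent, self.evolved, self.backcrossed)
        if len(set(names)) != 3:
            raise ValueError("parent, evolved and backcrossed must be distinct samples")

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.parent, self.evolved, self.backcrossed)


def position_in_regions(chromosome: str, position: int, regions: Iterable[Interval]) -> bool:
    """Membership of a 1-based variant position in 0-based half-open intervals.

    This is the single point where the VCF (1-based) and BED (0-based,
    half-open) conventions meet: position p is inside [start, end) iff
    start <= p - 1 < end.
    """
    p0 = position - 1
    return any(c == chromosome and s <= p0 < e for c, s, e in regions)


def filter_by_quality(
    records: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Retain records where every sample exceeds the depth and quality floors.

    Strict inequalities ("greater than"): depth > min_depth and
    quality > min_quality.  Records with any missing call are dropped and
    logged rather than raising.
    """
    kept = []
    for rec in records:
        if any(c.is_missing for c in rec.calls):
            logger.info(
                "dropping %s:%d at depth/quality filter: missing genotype call",
                rec.chromosome,
                rec.position,
            )
            continue
        if all(c.depth > cfg.min_depth and c.quality > cfg.min_quality for c in rec.calls):
            kept.append(rec)
    return kept


def retain_polymorphic(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Retain records showing ≥2 distinct non-missing alleles across samples."""
    kept = []
    for rec in records:
        alleles = {a for c in rec.calls for a in c.alleles()}
        if len(alleles) >= 2:
            kept.append(rec)
    return kept


def remove_heterozygous(
    records: Sequence[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Drop records where at least one sample call is heterozygous."""
    return [rec for rec in records if not any(c.is_het for c in rec.calls)]


def remove_cnv_overlap(
    records: Sequence[VariantRecord],
    cnv_regions: Optional[Mapping[str, Sequence[Interval]]] = None,
    mode: str = "any",
) -> list[VariantRecord]:
    """Drop records in predicted copy-number-variable regions.

    A record is CNV-affected in a sample when its per-sample in_cnv flag is
    set or its position falls in that sample's predicted regions.  mode "any"
    drops a record CNV-affected in at least one sample; mode "all" only when
    every sample is affected.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    cnv_regions = cnv_regions or {}
    for regions in cnv_regions.values():
        for c, s, e in regions:
            if s < 0 or e < s:
                raise ValueError(f"malformed interval {(c, s, e)}")
    kept = []
    for rec in records:
        flags = []
        for call in rec.calls:
            flagged = bool(rec.in_cnv.get(call.sample, False)) or position_in_regions(
                rec.chromosome, rec.position, cnv_regions.get(call.sample, ())
            )
            flags.append(flagged)
        affected = any(flags) if mode == "any" else all(flags)
        if not affected:
            kept.append(rec)
    return kept


def _role_allele(rec: VariantRecord, sample: str) -> Allele:
    call = rec.call(sample)
    if call is None or call.is_missing:
        raise ValueError(
            f"{rec.chromosome}:{rec.position}: missing call for role sample {sample!r}"
        )
    return call.allele


def classify_status(rec: VariantRecord, roles: SampleRoles) -> VariantStatus:
    """Genotype-configuration status of one variant in the parent/evolved/
    backcrossed trio.

    Alleles are compared as full call strings against the *parent* call (the
    published reference genome is not the baseline).  Heterozygous calls
    compare as tuples and match nothing homozygous, so a three-way disagreement
    is INCONSISTENT.
    """
    parent = _role_allele(rec, roles.parent)
    evolved = _role_allele(rec, roles.evolved)
    backcrossed = _role_allele(rec, roles.backcrossed)
    if evolved == parent:
        return VariantStatus.NOT_EVOLVED_SPECIFIC
    if backcrossed == parent:
        return VariantStatus.LOST_IN_BACKCROSS
    if backcrossed == evolved:
        return VariantStatus.SEGREGATING
    return VariantStatus.INCONSISTENT


@dataclass
class CascadeResult:
    records: list[VariantRecord]
    statuses: list[VariantStatus]
    summary: dict

    def with_status(self, status: VariantStatus) -> list[VariantRecord]:
        return [r for r, s in zip(self.records, self.statuses) if s is status]


def run_cascade(
    records: Sequence[VariantRecord],
    cfg: FilterConfig,
    roles: SampleRoles,
    cnv_regions: Optional[Mapping[str, Sequence[Interval]]] = None,
) -> CascadeResult:
    """Apply the four filters in order, then classify every surviving record.

    Summary counts are reported after each stage plus a SNP/indel breakdown
    and per-status counts of the final set.
    """
    summary: dict = {"input": len(records)}
    stage: Sequence[VariantRecord] = list(records)

    stage = filter_by_quality(stage, cfg)
    summary["after_depth_quality"] = len(stage)
    if cfg.require_polymorphic:
        stage = retain_polymorphic(stage)
    summary["after_polymorphic"] = len(stage)
    if cfg.drop_heterozygous:
        stage = remove_heterozygous(stage, cfg)
    summary["after_heterozygous"] = len(stage)
    if cfg.drop_cnv:
        stage = remove_cnv_overlap(stage, cnv_regions, mode=cfg.cnv_mode)
    summary["after_cnv"] = len(stage)

    statuses = [classify_status(rec, roles) for rec in stage]
    summary["n_snps"] = sum(1 for r in stage if r.is_snp)
    summary["n_indels"] = sum(1 for r in stage if not r.is_snp)
    for status in VariantStatus:
        summary[status.value.lower()] = sum(1 for s in statuses if s is status)
    return CascadeResult(records=list(stage), statuses=statuses, summary=summary)


def annotate_status(rec: VariantRecord, status: VariantStatus) -> VariantRecord:
    """Return a copy of the record with the status appended to its annotation."""
    note = status.value
    annotation = f"{rec.annotation};{note}" if rec.annotation else note
    return replace(rec, annotation=annotation)
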