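"""File formats: VCF 4.2 genotype tables, BED region lists, growth/assay CSV,
strain-variant and classified-variant TSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .assay import AssayTrace
from .filtering import (
    CascadeResult,
    Interval,
    SampleCall,
    SampleRoles,
    VariantRecord,
)
from .growth import GrowthCurve
from .simulate import HaploidGenome
from .tetrads import Tetrad

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# VCF (FORMAT GT:DP:GQ; haploid calls "0"/"1", heterozygous artifacts "0/1")

def write_vcf(
    records: Sequence[VariantRecord],
    path: PathLike,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write records as VCF 4.2.  Contig lengths default to the highest
    observed position per chromosome."""
    if not records:
        raise ValueError("no records to write")
    samples = records[0].samples
    if contig_lengths is None:
        contig_lengths = {}
        for rec in records:
            end = rec.position + len(rec.ref_allele)
            contig_lengths[rec.chromosome] = max(
                contig_lengths.get(rec.chromosome, 0), end
            )
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=int(length))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    for s in samples:
        header.add_sample(s)
    path = str(path)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            alleles = (rec.ref_allele,) + tuple(rec.alt_alleles)
            index = {a: i for i, a in enumerate(alleles)}
            vrec = out.new_record(
                contig=rec.chromosome,
                start=rec.position - 1,
                alleles=alleles if len(alleles) > 1 else (rec.ref_allele, "."),
            )
            for call in rec.calls:
                fmt = vrec.samples[call.sample]
                if call.allele is None:
                    fmt["GT"] = (None,)
                elif isinstance(call.allele, tuple):
                    fmt["GT"] = (index[call.allele[0]], index[call.allele[1]])
                else:
                    fmt["GT"] = (index[call.allele],)
                fmt["DP"] = call.depth
                fmt["GQ"] = call.quality
            out.write(vrec)


def read_vcf(path: PathLike) -> list[VariantRecord]:
    """Read a VCF with GT (and optionally DP/GQ) into VariantRecords.

    Diploid genotypes with two different alleles become heterozygous tuple
    calls; equal-allele diploid genotypes collapse to the single allele.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for vrec in vcf:
            alleles = vrec.alleles or ()
            ref = vrec.ref
            alts = tuple(a for a in (vrec.alts or ()) if a != ".")
            calls = []
            for name, sample in vrec.samples.items():
                gt = sample.get("GT")
                if gt is None or all(g is None for g in gt):
                    allele: object = None
                else:
                    resolved = tuple(alleles[g] for g in gt if g is not None)
                    if len(resolved) >= 2 and resolved[0] != resolved[1]:
                        allele = (resolved[0], resolved[1])
                    else:
                        allele = resolved[0]
                calls.append(
                    SampleCall(
                        sample=name,
                        allele=allele,  # type: ignore[arg-type]
                        depth=int(sample.get("DP") or 0),
                        quality=int(sample.get("GQ") or 0),
                    )
                )
            records.append(
                VariantRecord(
                    chromosome=vrec.chrom,
                    position=vrec.pos,
                    ref_allele=ref,
                    alt_alleles=alts,
                    calls=tuple(calls),
                )
            )
    return records


# ---------------------------------------------------------------------------
# BED (0-based, half-open)

def write_bed(regions: Sequence[Interval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: PathLike) -> list[Interval]:
    regions: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start), int(end)))
    return regions


# ---------------------------------------------------------------------------
# Growth curves (CSV: well, time_min, g_value) and assay traces

def write_plate_csv(curves: Mapping[str, GrowthCurve], path: PathLike) -> None:
    frames = []
    for well, curve in curves.items():
        kind = curve.value_kind
        frames.append(
            pd.DataFrame(
                {
                    "well": well,
                    "time_min": curve.times * 60.0,
                    ("g_value" if kind == "G" else "od"): curve.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plate_csv(path: PathLike) -> dict[str, GrowthCurve]:
    """One GrowthCurve per well; time_min converted to hours on read."""
    df = pd.read_csv(path)
    if "well" not in df.columns:
        df["well"] = "A1"
    value_col = "g_value" if "g_value" in df.columns else "od"
    kind = "G" if value_col == "g_value" else "OD"
    curves = {}
    for well, group in df.groupby("well", sort=False):
        group = group.sort_values("time_min")
        curves[str(well)] = GrowthCurve(
            group["time_min"].to_numpy() / 60.0,
            group[value_col].to_numpy(),
            value_kind=kind,
        )
    return curves


def read_assay_csv(path: PathLike) -> dict[str, AssayTrace]:
    """Absorbance traces keyed by phase (BACKGROUND/REACTION).
    Columns: time_min, a340, phase."""
    df = pd.read_csv(path)
    traces = {}
    for phase, group in df.groupby("phase", sort=False):
        group = group.sort_values("time_min")
        traces[str(phase)] = AssayTrace(
            group["time_min"].to_numpy(), group["a340"].to_numpy(), phase=str(phase)
        )
    return traces


# ---------------------------------------------------------------------------
# Tetrad tables (TSV)

def read_tetrads_tsv(path: PathLike, mode: str = "genotype") -> list[Tetrad]:
    """Tetrads from TSV.

    genotype mode: columns tetrad_id, segregant_id, locus_a, locus_b (0/1);
    phenotype mode: columns tetrad_id, segregant_id, mu_max[, lag] — returns
    the raw (µ, lag) tuples packed per tetrad for downstream classification.
    """
    df = pd.read_csv(path, sep="\t")
    tetrads = []
    for _, group in df.groupby("tetrad_id", sort=False):
        group = group.sort_values("segregant_id")
        if len(group) != 4:
            raise ValueError("each tetrad needs exactly 4 segregants")
        if mode == "genotype":
            tetrads.append(
                Tetrad(
                    tuple(
                        (bool(r.locus_a), bool(r.locus_b))
                        for r in group.itertuples()
                    )
                )
            )
        elif mode == "phenotype":
            tetrads.append(
                [
                    (float(r.mu_max), float(getattr(r, "lag", 0.0)))
                    for r in group.itertuples()
                ]
            )
        else:
            raise ValueError("mode must be 'genotype' or 'phenotype'")
    return tetrads


# ---------------------------------------------------------------------------
# Strain-variant and classified-variant tables

def write_genomes_tsv(
    genomes: Mapping[str, HaploidGenome], path: PathLike
) -> None:
    rows = []
    for strain, genome in genomes.items():
        for var in genome.variants.values():
            rows.append(
                {
                    "strain": strain,
                    "chromosome": var.chromosome,
                    "position": var.position,
                    "ref": var.ref_allele,
                    "alt": var.alt_allele,
                    "causal": int(var.causal),
                }
            )
    pd.DataFrame(
        rows, columns=["strain", "chromosome", "position", "ref", "alt", "causal"]
    ).to_csv(path, sep="\t", index=False)


def write_classified_tsv(
    result: CascadeResult, roles: SampleRoles, path: PathLike
) -> None:
    """Classified variant table: Chr, Position, Ref, the three role samples'
    calls, Status, ORF."""

    def show(allele) -> str:
        if allele is None:
            return "."
        if isinstance(allele, tuple):
            return "/".join(allele)
        return allele

    rows = []
    for rec, status in zip(result.records, result.statuses):
        rows.append(
            {
                "Chr": rec.chromosome,
                "Position": rec.position,
                "Ref": rec.ref_allele,
                roles.parent: show(rec.call(roles.parent).allele),
                roles.evolved: show(rec.call(roles.evolved).allele),
                roles.backcrossed: show(rec.call(roles.backcrossed).allele),
                "Status": status.value,
                "ORF": rec.annotation or ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(summary: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
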