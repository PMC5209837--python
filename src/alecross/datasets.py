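"""Packaged reference data for the CEN.PK113-7D / JL1 / F3 mapping experiment.

The evolved strain JL1 (a glycerol-utilizing derivative of CEN.PK113-7D)
was backcrossed to its parent for three rounds; the trio parent / evolved /
F3 segregant was whole-genome sequenced and run through the variant filter
cascade, leaving ten evolved-specific variants — eight lost in the
backcross and two segregating (the GUT1 and UBR2 coding mutations).

This module packages that ten-variant table, synthetic CDS fixtures for
GUT1 and UBR2 that carry the documented codons at the documented positions,
and the observed tetrad counts from the backcrossing rounds.
"""

from __future__ import annotations

import numpy as np

from .annotate import CodingSequence, CodingVariant
from .filtering import SampleCall, SampleRoles, VariantRecord

PARENT = "CEN.PK113-7D"
EVOLVED = "JL1"
BACKCROSSED = "F3"

#: Average sequencing depths of the three samples (parent, evolved, F3).
_DEPTHS = {PARENT: 85, EVOLVED: 157, BACKCROSSED: 95}

# chromosome, position, S288C reference allele, parent call, evolved call,
# F3 call, ORF annotation.  The three repeat-length indel rows carry
# synthetic reconstructions of the allele strings (the published variant
# classes, per-strain identity patterns and statuses are preserved exactly;
# the precise repeat alleles are not recoverable from the printed table).
_TRIO_ROWS = [
    ("VII", 978157, "C", "C", "T", "C", "LCS2;Missense"),
    ("VIII", 38156, "G", "G", "A", "A", "GUT1;Missense"),
    ("IX", 257480, "CAAAAC", "CAAAAC", "CAAAAAC", "CAAAAC", "RPL34B;Upstream(+1000)"),
    ("IX", 287261, "C", "A", "C", "A", "CST6;Missense"),
    ("XII", 189434, "G", "T", "C", "C", "UBR2;Nonsense"),
    ("XII", 829429, "ATGTAT", "ATGTAT", "ATGTATAT", "ATGTAT", "ORM2;Downstream(-300)"),
    ("XIII", 758921, "GTATGT", "GTATGT", "GTATGTGT", "GTATGT", "FAA4;Upstream(+1000)"),
    ("XV", 397664, "T", "C", "T", "C", "YOR034C-A;Missense"),
    ("XVI", 339778, "A", "A", "C", "A", "CAR1;Upstream(+1000)"),
    ("M", 2110, "C", "G", "C", "G", "Intergenic"),
]


def trio_roles() -> SampleRoles:
    """Sample roles of the sequenced trio."""
    return SampleRoles(parent=PARENT, evolved=EVOLVED, backcrossed=BACKCROSSED)


def trio_filtered_variants() -> list[VariantRecord]:
    """The ten post-cascade variant records of the parent/evolved/F3 trio.

    Calls are clean: depths at the samples' average sequencing depths and
    genotype qualities at the 255 cap, so the records pass the depth/quality
    filter as the published set did.
    """
    records = []
    for chrom, pos, ref, parent, evolved, f3, orf in _TRIO_ROWS:
        alleles = {PARENT: parent, EVOLVED: evolved, BACKCROSSED: f3}
        alts = tuple(dict.fromkeys(a for a in alleles.values() if a != ref))
        calls = tuple(
            SampleCall(sample=s, allele=alleles[s], depth=_DEPTHS[s], quality=255)
            for s in (PARENT, EVOLVED, BACKCROSSED)
        )
        records.append(
            VariantRecord(
                chromosome=chrom,
                position=pos,
                ref_allele=ref,
                alt_alleles=alts,
                calls=calls,
                in_cnv={s: False for s in (PARENT, EVOLVED, BACKCROSSED)},
                annotation=orf,
            )
        )
    return records


def observed_tetrad_counts() -> dict[str, int]:
    """Tetrad pattern counts scored during the backcrossing rounds:
    20 tetrads, of which 16 classified into the three Perkins patterns."""
    return {"pd": 4, "tt": 11, "npd": 1, "unclassified": 4}


# ---------------------------------------------------------------------------
# Synthetic CDS fixtures
#
# The true GUT1/UBR2 gene sequences are not packaged; these synthetic CDSs
# are constructed so that the codons at the documented variant positions
# match the documented amino acids, which is all the annotation arithmetic
# needs.  Gut1 is 709 residues, Ubr2 (full length) 1872 residues.

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _synthetic_cds(gene: str, n_residues: int, fixed: dict[int, str], seed: int) -> CodingSequence:
    rng = np.random.default_rng(seed)
    codons = [
        _SENSE_CODONS[int(i)]
        for i in rng.integers(len(_SENSE_CODONS), size=n_residues)
    ]
    codons[0] = "ATG"
    for index, codon in fixed.items():
        codons[index - 1] = codon
    codons.append("TAA")
    return CodingSequence(gene=gene, sequence="".join(codons))


def gut1_cds() -> CodingSequence:
    """Synthetic 709-residue GUT1 CDS (CEN.PK113-7D-like coding alleles).

    Codon 118 is TCT (Ser; CDS 353 = C), codons 530 and 533 are GCT/GCA
    (Ala; CDS 1588 and 1597 = G) — the residues mutated in the evolved
    strains.
    """
    return _synthetic_cds("GUT1", 709, {118: "TCT", 530: "GCT", 533: "GCA"}, seed=118)


def ubr2_cds(strain: str = "CEN.PK113-7D") -> CodingSequence:
    """Synthetic UBR2 CDS, 1872 codons before the terminal stop.

    The S288C-like allele has serine codon TCG at residue 1283 and encodes
    the full 1872-residue protein; the CEN.PK113-7D-like allele carries TAG
    there (a premature stop truncating the product by 590 residues), which
    the evolved strains revert to tryptophan (JL1) or glutamine (PW-1/PW-2).
    """
    if strain == "S288C":
        fixed = {1283: "TCG"}
    elif strain == "CEN.PK113-7D":
        fixed = {1283: "TAG"}
    else:
        raise ValueError(f"no packaged UBR2 allele for strain {strain!r}")
    return _synthetic_cds("UBR2", 1872, fixed, seed=1283)


def coding_variants_vs_cenpk() -> tuple[list[str], list[CodingVariant]]:
    """The evolved strains' GUT1/UBR2 coding variants, CEN.PK113-7D-relative.

    Returns parallel lists (strains, variants): the Gut1 S118F (JL1) and
    A533T/A530T (PW-1/PW-2) missense changes and the Ubr2 stop-codon
    substitutions at residue 1283 (stop→Trp in JL1, stop→Gln in PW-1/PW-2).
    """
    entries = [
        ("JL1", CodingVariant("GUT1", 353, "C", "T")),
        ("PW-1", CodingVariant("GUT1", 1597, "G", "A")),
        ("PW-2", CodingVariant("GUT1", 1588, "G", "A")),
        ("JL1", CodingVariant("UBR2", 3848, "A", "G")),
        ("PW-1", CodingVariant("UBR2", 3847, "T", "C")),
        ("PW-2", CodingVariant("UBR2", 3847, "T", "C")),
    ]
    return [s for s, _ in entries], [v for _, v in entries]


def ubr2_nonsense_vs_s288c() -> CodingVariant:
    """The CEN.PK-family UBR2 variant relative to S288C: the C→A change at
    CDS 3848 that creates the premature stop at residue 1283."""
    return CodingVariant("UBR2", 3848, "C", "A")
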