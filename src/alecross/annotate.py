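"""Coding-effect annotation of CDS point variants.

Maps 1-based CDS nucleotide positions to codon/residue indices, translates
reference and mutated codons with the standard genetic code, classifies the
effect (synonymous / missense / nonsense / stop-substitution), and computes
C-terminal truncation lengths for premature stop codons.

Positions are coding-strand CDS coordinates; genomic-to-CDS projection
(strand, introns) happens upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio.Seq import Seq

STOP = "*"
_BASES = frozenset("ACGT")


class Effect(str, Enum):
    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    STOP_SUBSTITUTION = "STOP_SUBSTITUTION"


@dataclass(frozen=True)
class CodingSequence:
    """A CDS from start codon through stop codon inclusive.

    Internal (premature) stop codons are permitted: alleles that encode a
    truncated product are legitimate reference sequences for annotating
    further variants (e.g. a stop-to-sense reversion), and are exposed via
    `premature_stop_residue`.
    """

    gene: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {len(seq)} not divisible by 3")
        if not seq.startswith("ATG"):
            raise ValueError(f"{self.gene}: CDS must start with ATG")
        if not set(seq) <= _BASES:
            raise ValueError(f"{self.gene}: non-ACGT characters in CDS")

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def protein_length(self) -> int:
        """Full-length residue count, terminal stop codon excluded."""
        return self.n_codons - 1

    def codon(self, index: int) -> str:
        """1-based codon extraction."""
        if not 1 <= index <= self.n_codons:
            raise ValueError(f"codon index {index} outside CDS of {self.n_codons} codons")
        return self.sequence[3 * (index - 1) : 3 * index]

    def translation(self) -> str:
        """Full translation including any internal stops, terminal stop dropped."""
        aa = str(Seq(self.sequence).translate())
        return aa[:-1] if aa.endswith(STOP) else aa

    @property
    def premature_stop_residue(self) -> Optional[int]:
        """1-based residue index of the first internal stop, or None."""
        idx = self.translation().find(STOP)
        return idx + 1 if idx >= 0 else None


@dataclass(frozen=True)
class CodingVariant:
    gene: str
    cds_position: int  # 1-based
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise ValueError("cds_position must be >= 1")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in _BASES:
                raise ValueError(f"invalid base {b!r}")


@dataclass(frozen=True)
class EffectCall:
    gene: str
    cds_position: int
    codon_index: int
    offset_in_codon: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str  # amino-acid letter or "*"
    alt_aa: str
    effect: Effect


def codon_index(cds_position: int) -> tuple[int, int]:
    """(codon, offset) for a 1-based CDS nucleotide position.

    codon = ceil(pos/3); offset = ((pos − 1) mod 3) + 1.
    """
    if cds_position < 1:
        raise ValueError("cds_position must be >= 1")
    return -(-cds_position // 3), (cds_position - 1) % 3 + 1


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def call_effect(cds: CodingSequence, var: CodingVariant) -> EffectCall:
    """Classify a single-nucleotide CDS variant by per-codon translation."""
    if var.cds_position > len(cds.sequence):
        raise ValueError(
            f"{var.gene}: position {var.cds_position} beyond CDS length {len(cds.sequence)}"
        )
    observed = cds.sequence[var.cds_position - 1]
    if observed != var.ref_base:
        raise ValueError(
            f"{var.gene}: reference mismatch at CDS position {var.cds_position}: "
            f"variant says {var.ref_base}, sequence has {observed}"
        )
    codon, offset = codon_index(var.cds_position)
    ref_codon = cds.codon(codon)
    alt_codon = ref_codon[: offset - 1] + var.alt_base + ref_codon[offset:]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if ref_aa == alt_aa:
        effect = Effect.SYNONYMOUS
    elif alt_aa == STOP:
        effect = Effect.NONSENSE
    elif ref_aa == STOP:
        effect = Effect.STOP_SUBSTITUTION
    else:
        effect = Effect.MISSENSE
    return EffectCall(
        gene=var.gene,
        cds_position=var.cds_position,
        codon_index=codon,
        offset_in_codon=offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect=effect,
    )


def truncation_length(full_protein_length: int, stop_codon_residue: int) -> int:
    """Residues missing from a prematurely terminated product.

    A stop at residue r leaves residues 1..r−1, so the truncation counts the
    stop-replaced residue itself: full − (r − 1).  E.g. a 1872-residue
    protein with a stop at residue 1283 is truncated by 590 residues.
    """
    if not 1 <= stop_codon_residue <= full_protein_length:
        raise ValueError(
            f"stop residue {stop_codon_residue} outside protein of "
            f"{full_protein_length} residues"
        )
    return full_protein_length - (stop_codon_residue - 1)


def annotate_table(
    cds_by_gene: Mapping[str, CodingSequence],
    variants: Iterable[CodingVariant],
    strains: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Effect table, one row per variant (optionally labelled by strain).

    Columns: strain (if given), gene, cds_position, ref_base, alt_base,
    codon_index, ref_codon, alt_codon, ref_aa, alt_aa, effect.
    """
    variants = list(variants)
    strain_list = list(strains) if strains is not None else None
    if strain_list is not None and len(strain_list) != len(variants):
        raise ValueError("strains must match variants one-to-one")
    rows = []
    for i, var in enumerate(variants):
        if var.gene not in cds_by_gene:
            raise KeyError(f"no CDS provided for gene {var.gene!r}")
        call = call_effect(cds_by_gene[var.gene], var)
        row = {
            "gene": call.gene,
            "cds_position": call.cds_position,
            "ref_base": var.ref_base,
            "alt_base": var.alt_base,
            "codon_index": call.codon_index,
            "ref_codon": call.ref_codon,
            "alt_codon": call.alt_codon,
            "ref_aa": call.ref_aa,
            "alt_aa": call.alt_aa,
            "effect": call.effect.value,
        }
        if strain_list is not None:
            row = {"strain": strain_list[i], **row}
        rows.append(row)
    columns = (["strain"] if strain_list is not None else []) + [
        "gene",
        "cds_position",
        "ref_base",
        "alt_base",
        "codon_index",
        "ref_codon",
        "alt_codon",
        "ref_aa",
        "alt_aa",
        "effect",
    ]
    return pd.DataFrame(rows, columns=columns)
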