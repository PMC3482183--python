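"""Functional classification of SNPs against a contig's ORF.

Categories: 5'UTR, 3'UTR, synonymous, missense, pre_terminated (a sense
codon becomes a stop: nonsense), skip_stop_codon (the stop codon becomes
a sense codon: stop-loss / read-through) and undefined (contig has no
ORF annotation).  Translation uses the standard genetic code (NCBI
table 1).  For minus-strand ORFs the reading frame runs along the
reverse complement anchored at ``cds_end``.

A change inside the stop codon that yields a different stop codon
(e.g. TAA->TGA) is classified synonymous: the protein product is
unchanged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .io import TranscriptContig

__all__ = [
    "EffectCategory",
    "Region",
    "SnpEffect",
    "SEVERITY_ORDER",
    "translate_codon",
    "locate_region",
    "classify_effect",
    "most_severe",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = frozenset("ACGT")


class EffectCategory(str, enum.Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    THREE_PRIME_UTR = "three_prime_utr"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    PRE_TERMINATED = "pre_terminated"
    SKIP_STOP_CODON = "skip_stop_codon"
    UNDEFINED = "undefined"


class Region(str, enum.Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    THREE_PRIME_UTR = "three_prime_utr"
    CODING = "coding"
    UNDEFINED = "undefined"


#: roll-up order for multi-allele sites, most severe first
SEVERITY_ORDER = (
    EffectCategory.SKIP_STOP_CODON,
    EffectCategory.PRE_TERMINATED,
    EffectCategory.MISSENSE,
    EffectCategory.SYNONYMOUS,
    EffectCategory.FIVE_PRIME_UTR,
    EffectCategory.THREE_PRIME_UTR,
    EffectCategory.UNDEFINED,
)


@dataclass(frozen=True)
class SnpEffect:
    category: EffectCategory
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    codon_index: Optional[int] = None  # 0-based codon within the ORF
    position_in_codon: Optional[int] = None  # 1, 2 or 3


def translate_codon(codon: str) -> str:
    """Standard-code translation of a 3-base codon; stops return '*'."""
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _BASES:
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    if codon in _STOPS:
        return "*"
    return _TABLE.forward_table[codon]


def locate_region(position: int, contig: TranscriptContig) -> Region:
    """UTR / coding / undefined placement of a 1-based contig position.

    For minus-strand ORFs the UTR sides swap: the 5'UTR is the
    high-coordinate flank.
    """
    if not 1 <= position <= len(contig):
        raise ValueError(
            f"position {position} outside {contig.contig_id} (length {len(contig)})"
        )
    if not contig.has_orf:
        return Region.UNDEFINED
    if position < contig.cds_start:
        return Region.FIVE_PRIME_UTR if contig.strand == "+" else Region.THREE_PRIME_UTR
    if position > contig.cds_end:
        return Region.THREE_PRIME_UTR if contig.strand == "+" else Region.FIVE_PRIME_UTR
    return Region.CODING


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify_effect(
    contig: TranscriptContig, position: int, ref_allele: str, alt_allele: str
) -> SnpEffect:
    """Classify one substitution against the contig's ORF.

    ``ref_allele``/``alt_allele`` are given in the forward-strand
    alphabet of the contig; ``ref_allele`` must match the reference base
    at ``position``.
    """
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles are identical")
    if contig.base_at(position) != ref_allele:
        raise ValueError(
            f"{contig.contig_id}:{position}: ref allele {ref_allele} does not "
            f"match reference base {contig.base_at(position)}"
        )
    region = locate_region(position, contig)
    if region is not Region.CODING:
        return SnpEffect(category=EffectCategory(region.value))

    # coding position: extract the containing codon in reading-frame order
    if contig.strand == "+":
        offset = position - contig.cds_start
    else:
        offset = contig.cds_end - position
    codon_index = offset // 3
    position_in_codon = offset % 3 + 1

    if contig.strand == "+":
        codon_start = contig.cds_start + 3 * codon_index  # 1-based
        ref_codon = contig.sequence[codon_start - 1 : codon_start + 2]
        alt_base = alt_allele
    else:
        codon_end = contig.cds_end - 3 * codon_index  # 1-based, frame-forward first base
        ref_codon = reverse_complement(
            contig.sequence[codon_end - 3 : codon_end]
        )
        alt_base = alt_allele.translate(_COMPLEMENT)

    if not set(ref_codon) <= _BASES:
        return SnpEffect(
            category=EffectCategory.UNDEFINED,
            codon_index=codon_index,
            position_in_codon=position_in_codon,
        )

    alt_codon = (
        ref_codon[: position_in_codon - 1] + alt_base + ref_codon[position_in_codon:]
    )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        category = EffectCategory.SYNONYMOUS
    elif alt_aa == "*":
        category = EffectCategory.PRE_TERMINATED
    elif ref_aa == "*":
        category = EffectCategory.SKIP_STOP_CODON
    else:
        category = EffectCategory.MISSENSE
    return SnpEffect(
        category=category,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        codon_index=codon_index,
        position_in_codon=position_in_codon,
    )


def most_severe(categories) -> EffectCategory:
    """Roll-up for multi-allele sites: the most severe category wins."""
    cats = set(categories)
    if not cats:
        raise ValueError("no categories to roll up")
    for cat in SEVERITY_ORDER:
        if cat in cats:
            return cat
    raise ValueError(f"unknown categories: {cats}")
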