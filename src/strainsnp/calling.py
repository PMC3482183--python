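"""Per-strain site calling from quality-filtered pileup columns.

The calling rule mirrors pooled-sample SNP discovery against a reference
transcriptome: a site is *callable* when its quality-filtered depth
reaches ``min_depth`` (default 10 reads); it is *polymorphic* when the
second-most-frequent allele has at least ``min_minor_support`` reads
(default 2 — one read is indistinguishable from a sequencing error),
otherwise *monomorphic* for the top allele.  Base calls below
``min_base_quality`` (default Phred 20) are discarded before counting.

Calls are biallelic: sites are reduced to their two highest-count
alleles; a third allele with supporting reads is flagged but does not
enter the call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .io import PileupSite

__all__ = [
    "AlleleCounts",
    "CallStatus",
    "SiteCall",
    "filter_bases",
    "call_site",
    "compute_maf",
    "classify_substitution",
    "call_pileup_site",
    "call_sites",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class AlleleCounts:
    """Quality-filtered read counts per nucleotide at one site."""

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0

    @property
    def filtered_depth(self) -> int:
        return self.a + self.c + self.g + self.t

    def as_dict(self) -> dict[str, int]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}

    def ranked(self) -> list[tuple[str, int]]:
        """Alleles sorted by descending count, alphabetical on ties."""
        return sorted(self.as_dict().items(), key=lambda kv: (-kv[1], kv[0]))


class CallStatus(str, enum.Enum):
    UNCALLABLE = "uncallable"
    MONOMORPHIC = "monomorphic"
    POLYMORPHIC = "polymorphic"


@dataclass(frozen=True)
class SiteCall:
    """Callability/zygosity status of one site in one strain.

    For polymorphic sites the allele pair, counts, MAF and Ts/Tv class
    are populated; for monomorphic sites only ``consensus_allele``.
    ``extra_allele`` flags a third allele that itself met the minor
    support threshold before the biallelic reduction.
    """

    contig_id: str
    position: int
    strain_id: str
    status: CallStatus
    consensus_allele: Optional[str] = None
    major_allele: Optional[str] = None
    minor_allele: Optional[str] = None
    major_count: int = 0
    minor_count: int = 0
    maf: Optional[float] = None
    substitution_class: Optional[str] = None
    filtered_depth: int = 0
    extra_allele: bool = False

    @property
    def allele_pair(self) -> Optional[frozenset]:
        if self.status is CallStatus.POLYMORPHIC:
            return frozenset((self.major_allele, self.minor_allele))
        return None


def filter_bases(site: PileupSite, min_base_quality: int = 20) -> AlleleCounts:
    """Count A/C/G/T calls with Phred >= ``min_base_quality``; N discarded."""
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for base, qual in zip(site.read_bases, site.base_qualities):
        if qual >= min_base_quality and base in counts:
            counts[base] += 1
    return AlleleCounts(counts["A"], counts["C"], counts["G"], counts["T"])


def call_site(
    counts: AlleleCounts,
    min_depth: int = 10,
    min_minor_support: int = 2,
) -> dict:
    """Apply the depth/minor-support rule to filtered allele counts.

    Returns the status fields as a dict (merged into :class:`SiteCall`
    by :func:`call_pileup_site`).  Ties in count rank are broken
    alphabetically, the earlier base becoming the major allele.
    """
    if counts.filtered_depth < min_depth:
        return {"status": CallStatus.UNCALLABLE, "filtered_depth": counts.filtered_depth}
    ranked = counts.ranked()
    (top_base, top_n), (second_base, second_n) = ranked[0], ranked[1]
    extra = ranked[2][1] >= min_minor_support
    if second_n >= min_minor_support:
        return {
            "status": CallStatus.POLYMORPHIC,
            "major_allele": top_base,
            "minor_allele": second_base,
            "major_count": top_n,
            "minor_count": second_n,
            "maf": compute_maf(top_n, second_n),
            "substitution_class": classify_substitution(top_base, second_base),
            "filtered_depth": counts.filtered_depth,
            "extra_allele": extra,
        }
    return {
        "status": CallStatus.MONOMORPHIC,
        "consensus_allele": top_base,
        "filtered_depth": counts.filtered_depth,
        "extra_allele": extra,
    }


def compute_maf(major_count: int, minor_count: int) -> float:
    """Minor allele frequency over the two called alleles only."""
    denom = major_count + minor_count
    if denom == 0:
        raise ValueError("cannot compute MAF with zero reads on both alleles")
    return minor_count / denom


def classify_substitution(allele_a: str, allele_b: str) -> str:
    """'transition' for A<->G or C<->T, 'transversion' otherwise."""
    if allele_a == allele_b:
        raise ValueError(f"identical alleles {allele_a!r}")
    pair = {allele_a, allele_b}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def call_pileup_site(
    site: PileupSite,
    strain_id: str,
    min_base_quality: int = 20,
    min_depth: int = 10,
    min_minor_support: int = 2,
) -> SiteCall:
    counts = filter_bases(site, min_base_quality=min_base_quality)
    fields = call_site(counts, min_depth=min_depth, min_minor_support=min_minor_support)
    return SiteCall(
        contig_id=site.contig_id,
        position=site.position,
        strain_id=strain_id,
        **fields,
    )


def call_sites(
    sites: Iterable[PileupSite],
    strain_id: str,
    min_base_quality: int = 20,
    min_depth: int = 10,
    min_minor_support: int = 2,
) -> Iterator[SiteCall]:
    """Call every pileup site of one strain."""
    for site in sites:
        yield call_pileup_site(
            site,
            strain_id,
            min_base_quality=min_base_quality,
            min_depth=min_depth,
            min_minor_support=min_minor_support,
        )
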