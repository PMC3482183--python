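"""Set algebra over per-strain site calls.

The comparisons this module implements:

* **intra-strain** SNPs — sites polymorphic within one strain's pooled
  reads;
* **inter-strain** SNPs — sites monomorphic within each of two strains
  but fixed for different alleles between them;
* **non-redundant** sets — the de-duplicated unions of the per-strain
  intra sets and of all pairwise inter sets;
* **strain-specific** SNPs — intra-strain SNPs polymorphic in exactly
  one strain (by default, requiring the other strains to be callable
  and non-polymorphic there: absence of coverage is not evidence of
  specificity);
* **shared** SNPs — the intersection of all per-strain intra sets,
  together with the full Venn partition of the non-redundant intra set.

SNP identity (:class:`SnpKey`) is coordinate *plus* unordered allele
pair: two strains polymorphic at the same position for different allele
pairs contribute distinct non-redundant SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .calling import CallStatus, SiteCall

__all__ = [
    "SnpKey",
    "StrainSiteMatrix",
    "build_matrix",
    "intra_strain_set",
    "inter_strain_set",
    "nonredundant_sets",
    "strain_specific_sets",
    "shared_all_set",
]


@dataclass(frozen=True, order=True)
class SnpKey:
    """Identity of a SNP: contig, position, unordered allele pair."""

    contig_id: str
    position: int
    alleles: frozenset

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError(f"SnpKey needs two distinct alleles, got {set(self.alleles)}")

    @classmethod
    def of(cls, contig_id: str, position: int, allele_a: str, allele_b: str) -> "SnpKey":
        return cls(contig_id, position, frozenset((allele_a, allele_b)))

    @property
    def allele_string(self) -> str:
        return "/".join(sorted(self.alleles))


class StrainSiteMatrix:
    """Per-site x per-strain call statuses: the substrate of the algebra.

    ``matrix[(contig_id, position)][strain_id]`` is the strain's
    :class:`~strainsnp.calling.SiteCall` at that site.  Sites with no
    call recorded for a strain are treated as uncallable for it.
    """

    def __init__(self, strains: Iterable[str]):
        self.strains: tuple[str, ...] = tuple(strains)
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain IDs")
        self._sites: dict[tuple[str, int], dict[str, SiteCall]] = {}

    def add(self, call: SiteCall) -> None:
        if call.strain_id not in self.strains:
            raise KeyError(f"unknown strain {call.strain_id!r}")
        self._sites.setdefault((call.contig_id, call.position), {})[call.strain_id] = call

    def sites(self):
        return self._sites.keys()

    def call(self, site: tuple[str, int], strain: str) -> SiteCall | None:
        return self._sites.get(site, {}).get(strain)

    def __len__(self) -> int:
        return len(self._sites)


def build_matrix(calls_by_strain: Mapping[str, Iterable[SiteCall]]) -> StrainSiteMatrix:
    """Assemble a matrix from per-strain call iterables."""
    matrix = StrainSiteMatrix(calls_by_strain.keys())
    for strain, calls in calls_by_strain.items():
        for call in calls:
            if call.strain_id != strain:
                raise ValueError(
                    f"call for strain {call.strain_id!r} listed under {strain!r}"
                )
            matrix.add(call)
    return matrix


def _check_strain(matrix: StrainSiteMatrix, strain: str) -> None:
    if strain not in matrix.strains:
        raise KeyError(f"unknown strain {strain!r}; matrix has {matrix.strains}")


def intra_strain_set(matrix: StrainSiteMatrix, strain: str) -> set[SnpKey]:
    """Sites polymorphic within one strain, keyed by its allele pair."""
    _check_strain(matrix, strain)
    out: set[SnpKey] = set()
    for site in matrix.sites():
        call = matrix.call(site, strain)
        if call is not None and call.status is CallStatus.POLYMORPHIC:
            out.add(SnpKey(site[0], site[1], call.allele_pair))
    return out


def inter_strain_set(matrix: StrainSiteMatrix, strain_a: str, strain_b: str) -> set[SnpKey]:
    """Sites monomorphic in both strains for different consensus alleles."""
    if strain_a == strain_b:
        raise ValueError("inter-strain comparison needs two distinct strains")
    _check_strain(matrix, strain_a)
    _check_strain(matrix, strain_b)
    out: set[SnpKey] = set()
    for site in matrix.sites():
        ca = matrix.call(site, strain_a)
        cb = matrix.call(site, strain_b)
        if ca is None or cb is None:
            continue
        if ca.status is CallStatus.MONOMORPHIC and cb.status is CallStatus.MONOMORPHIC:
            if ca.consensus_allele != cb.consensus_allele:
                out.add(
                    SnpKey.of(site[0], site[1], ca.consensus_allele, cb.consensus_allele)
                )
    return out


def nonredundant_sets(matrix: StrainSiteMatrix) -> tuple[set[SnpKey], set[SnpKey]]:
    """De-duplicated unions: (all intra sets, all pairwise inter sets)."""
    if len(matrix.strains) < 2:
        raise ValueError("non-redundant sets need at least two strains")
    nr_intra: set[SnpKey] = set()
    for strain in matrix.strains:
        nr_intra |= intra_strain_set(matrix, strain)
    nr_inter: set[SnpKey] = set()
    for a, b in combinations(matrix.strains, 2):
        nr_inter |= inter_strain_set(matrix, a, b)
    return nr_intra, nr_inter


def strain_specific_sets(
    matrix: StrainSiteMatrix, require_callable_others: bool = True
) -> dict[str, set[SnpKey]]:
    """Intra-strain SNPs polymorphic in exactly one strain.

    With ``require_callable_others`` (default) the other strains must be
    callable and non-polymorphic at the site; without it, they must
    merely not be polymorphic (uncallable counts as absent evidence).
    The resulting sets are pairwise disjoint either way.
    """
    if len(matrix.strains) < 2:
        raise ValueError("strain-specific filtering needs at least two strains")
    out: dict[str, set[SnpKey]] = {s: set() for s in matrix.strains}
    for site in matrix.sites():
        statuses = {s: matrix.call(site, s) for s in matrix.strains}
        poly = [
            s
            for s, c in statuses.items()
            if c is not None and c.status is CallStatus.POLYMORPHIC
        ]
        if len(poly) != 1:
            continue
        focal = poly[0]
        if require_callable_others:
            others_ok = all(
                c is not None and c.status is CallStatus.MONOMORPHIC
                for s, c in statuses.items()
                if s != focal
            )
            if not others_ok:
                continue
        call = statuses[focal]
        out[focal].add(SnpKey(site[0], site[1], call.allele_pair))
    return out


def shared_all_set(
    matrix: StrainSiteMatrix,
) -> tuple[set[SnpKey], dict[frozenset, int]]:
    """Intersection of all intra sets, plus full Venn region counts.

    The Venn partition covers all ``2**n - 1`` non-empty strain subsets;
    each non-redundant intra SNP is counted in exactly the region of
    the strains whose intra set contains it, so region counts sum to
    the size of the non-redundant intra union.
    """
    if len(matrix.strains) < 2:
        raise ValueError("shared-set analysis needs at least two strains")
    intra = {s: intra_strain_set(matrix, s) for s in matrix.strains}
    union: set[SnpKey] = set().union(*intra.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(matrix.strains) + 1):
        for subset in combinations(matrix.strains, r):
            regions[frozenset(subset)] = 0
    for key in union:
        members = frozenset(s for s in matrix.strains if key in intra[s])
        regions[members] += 1
    shared = set.intersection(*intra.values()) if intra else set()
    return shared, regions
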