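"""End-to-end orchestration: pileups -> calls -> matrix -> sets -> effects.

Also provides the truth-side mirror of the set algebra (expected intra /
inter / strain-specific sets computed directly from a simulation's truth
table), which recovery analyses compare against the called sets.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import SiteCall, call_sites
from .effects import EffectCategory, classify_effect, most_severe
from .io import TranscriptContig, read_pileup
from .sets import SnpKey, StrainSiteMatrix, build_matrix
from .simulate import FixedState, PolymorphicState, TruthVariant

__all__ = [
    "call_strain_pileup",
    "call_all_strains",
    "classify_keys",
    "truth_intra_sets",
    "truth_inter_sets",
    "truth_specific_sets",
    "calls_to_frame",
]


def call_strain_pileup(
    path: str | Path,
    strain_id: str,
    min_base_quality: int = 20,
    min_depth: int = 10,
    min_minor_support: int = 2,
) -> list[SiteCall]:
    """Decode and call every site of one strain's pileup file."""
    return list(
        call_sites(
            read_pileup(path),
            strain_id,
            min_base_quality=min_base_quality,
            min_depth=min_depth,
            min_minor_support=min_minor_support,
        )
    )


def call_all_strains(
    pileups: Mapping[str, str | Path],
    min_base_quality: int = 20,
    min_depth: int = 10,
    min_minor_support: int = 2,
) -> StrainSiteMatrix:
    """Call every strain's pileup and assemble the site x strain matrix."""
    calls = {
        strain: call_strain_pileup(
            path,
            strain,
            min_base_quality=min_base_quality,
            min_depth=min_depth,
            min_minor_support=min_minor_support,
        )
        for strain, path in pileups.items()
    }
    return build_matrix(calls)


def classify_keys(
    keys: Iterable[SnpKey], contigs: Sequence[TranscriptContig]
) -> dict[SnpKey, EffectCategory]:
    """Functional category per SNP key, rolled up over its allele pair.

    Each key's unordered allele pair is resolved against the reference:
    the allele matching the reference base is the ref allele; if neither
    matches (both alleles differ from the reference), one effect is
    computed per (ref-base, allele) substitution and the most severe
    category wins, consistent with the multi-allele roll-up rule.
    """
    by_id = {c.contig_id: c for c in contigs}
    out: dict[SnpKey, EffectCategory] = {}
    for key in keys:
        contig = by_id[key.contig_id]
        ref = contig.base_at(key.position)
        alleles = sorted(key.alleles)
        alts = [a for a in alleles if a != ref]
        cats = [
            classify_effect(contig, key.position, ref, alt).category for alt in alts
        ]
        out[key] = most_severe(cats)
    return out


# ---------------------------------------------------------------------------
# truth-side mirror of the set algebra


def truth_intra_sets(
    truth: Sequence[TruthVariant], strains: Sequence[str]
) -> dict[str, set[SnpKey]]:
    out: dict[str, set[SnpKey]] = {s: set() for s in strains}
    for t in truth:
        for strain, state in t.per_strain_state.items():
            if isinstance(state, PolymorphicState):
                out[strain].add(
                    SnpKey.of(t.contig_id, t.position, state.allele_a, state.allele_b)
                )
    return out


def truth_inter_sets(
    truth: Sequence[TruthVariant], strains: Sequence[str]
) -> dict[tuple[str, str], set[SnpKey]]:
    """Expected pairwise inter-strain sets from fixed-difference truth."""
    out: dict[tuple[str, str], set[SnpKey]] = {
        pair: set() for pair in combinations(strains, 2)
    }
    for t in truth:
        for a, b in combinations(strains, 2):
            sa, sb = t.per_strain_state[a], t.per_strain_state[b]
            if (
                isinstance(sa, FixedState)
                and isinstance(sb, FixedState)
                and sa.allele != sb.allele
            ):
                out[(a, b)].add(SnpKey.of(t.contig_id, t.position, sa.allele, sb.allele))
    return out


def truth_specific_sets(
    truth: Sequence[TruthVariant], strains: Sequence[str]
) -> dict[str, set[SnpKey]]:
    """Expected strain-specific sets: polymorphic in exactly one strain."""
    out: dict[str, set[SnpKey]] = {s: set() for s in strains}
    for t in truth:
        poly = [
            (s, st)
            for s, st in t.per_strain_state.items()
            if isinstance(st, PolymorphicState)
        ]
        if len(poly) == 1:
            strain, state = poly[0]
            out[strain].add(
                SnpKey.of(t.contig_id, t.position, state.allele_a, state.allele_b)
            )
    return out


def calls_to_frame(calls: Iterable[SiteCall]) -> pd.DataFrame:
    """Flatten calls to the TSV schema the CLI writes."""
    rows = []
    for c in calls:
        rows.append(
            {
                "contig_id": c.contig_id,
                "position": c.position,
                "strain": c.strain_id,
                "status": c.status.value,
                "consensus_allele": c.consensus_allele or "",
                "major_allele": c.major_allele or "",
                "minor_allele": c.minor_allele or "",
                "major_count": c.major_count,
                "minor_count": c.minor_count,
                "maf": "" if c.maf is None else round(c.maf, 6),
                "substitution_class": c.substitution_class or "",
                "filtered_depth": c.filtered_depth,
                "extra_allele": int(c.extra_allele),
            }
        )
    return pd.DataFrame(rows)
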