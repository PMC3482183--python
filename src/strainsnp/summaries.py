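"""Descriptive outputs: classification tables, Ts/Tv, MAF histograms,
per-contig SNP distributions, gene-interval binning, validation rates.

Percentages throughout are rounded half-up to one decimal place, the
display precision used for this kind of survey table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calling import SiteCall
from .effects import EffectCategory

__all__ = [
    "ClassificationTable",
    "DistributionReport",
    "classification_table",
    "tstv_summary",
    "maf_histogram",
    "snps_per_contig",
    "bin_genes_by_interval",
    "validation_rate",
    "round_percent",
]


def round_percent(x: float, places: int = 1) -> float:
    """Half-up percentage rounding (66.05 -> 66.1, not banker's 66.0)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# classification table


@dataclass(frozen=True)
class ClassificationTable:
    """Counts per functional category with the derived roll-ups.

    Identities enforced: coding = synonymous + non_synonymous;
    non_synonymous = missense + pre_terminated + skip_stop_codon;
    total = 5'UTR + 3'UTR + coding + undefined.
    """

    five_prime_utr: int
    three_prime_utr: int
    synonymous: int
    missense: int
    pre_terminated: int
    skip_stop_codon: int
    undefined: int

    @property
    def non_synonymous(self) -> int:
        return self.missense + self.pre_terminated + self.skip_stop_codon

    @property
    def coding(self) -> int:
        return self.synonymous + self.non_synonymous

    @property
    def total(self) -> int:
        return self.five_prime_utr + self.three_prime_utr + self.coding + self.undefined

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("5' UTR", self.five_prime_utr),
            ("3' UTR", self.three_prime_utr),
            ("Coding region", self.coding),
            ("synonymous", self.synonymous),
            ("non-synonymous", self.non_synonymous),
            ("pre-terminated", self.pre_terminated),
            ("skip-stop-codon", self.skip_stop_codon),
            ("mis-sense", self.missense),
            ("Undefined", self.undefined),
            ("Total", self.total),
        ]
        return pd.DataFrame(rows, columns=["classification", "count"])


def classification_table(
    categories: Iterable[EffectCategory | str],
) -> ClassificationTable:
    """Tabulate one category per SNP (roll-up rule already applied)."""
    counts: Counter = Counter()
    for cat in categories:
        cat = EffectCategory(cat)  # raises on unknown labels
        counts[cat] += 1
    return ClassificationTable(
        five_prime_utr=counts[EffectCategory.FIVE_PRIME_UTR],
        three_prime_utr=counts[EffectCategory.THREE_PRIME_UTR],
        synonymous=counts[EffectCategory.SYNONYMOUS],
        missense=counts[EffectCategory.MISSENSE],
        pre_terminated=counts[EffectCategory.PRE_TERMINATED],
        skip_stop_codon=counts[EffectCategory.SKIP_STOP_CODON],
        undefined=counts[EffectCategory.UNDEFINED],
    )


# ---------------------------------------------------------------------------
# Ts/Tv


@dataclass(frozen=True)
class TsTvSummary:
    n_transitions: int
    n_transversions: int
    transition_percent: Optional[float]
    transversion_percent: Optional[float]
    ratio: Optional[float]  # None marks undefined (zero denominator)

    @property
    def total(self) -> int:
        return self.n_transitions + self.n_transversions


def tstv_summary(
    calls: Iterable[SiteCall] | None = None,
    *,
    n_transitions: int | None = None,
    n_transversions: int | None = None,
) -> TsTvSummary:
    """Transition/transversion partition with percentages and ratio.

    Accepts either polymorphic calls (counted by their substitution
    class) or precomputed counts via keywords.  With zero SNPs the
    percentages are undefined (None); with zero transversions the ratio
    is undefined rather than a division error.
    """
    if calls is not None:
        if n_transitions is not None or n_transversions is not None:
            raise ValueError("pass either calls or counts, not both")
        n_ts = n_tv = 0
        for call in calls:
            if call.substitution_class == "transition":
                n_ts += 1
            elif call.substitution_class == "transversion":
                n_tv += 1
            elif call.substitution_class is not None:
                raise ValueError(
                    f"unknown substitution class {call.substitution_class!r}"
                )
    else:
        if n_transitions is None or n_transversions is None:
            raise ValueError("need both n_transitions and n_transversions")
        n_ts, n_tv = n_transitions, n_transversions
    total = n_ts + n_tv
    if total == 0:
        return TsTvSummary(0, 0, None, None, None)
    pct_ts = round_percent(100.0 * n_ts / total)
    pct_tv = round_percent(100.0 * n_tv / total)
    ratio = n_ts / n_tv if n_tv > 0 else None
    return TsTvSummary(n_ts, n_tv, pct_ts, pct_tv, ratio)


# ---------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class DistributionReport:
    """Histogram with cumulative percentages and bin metadata."""

    bin_labels: tuple
    counts: tuple
    cumulative_percent: tuple
    n: int
    metadata: dict = field(default_factory=dict, compare=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bin_labels,
                "count": self.counts,
                "cumulative_percent": self.cumulative_percent,
            }
        )


def _cumulative_percent(counts: Sequence[int], n: int) -> tuple:
    if n == 0:
        return tuple(0.0 for _ in counts)
    cum = np.cumsum(counts)
    pct = [round_percent(100.0 * c / n) for c in cum]
    if len(counts) and sum(counts) == n:
        pct[-1] = 100.0
    return tuple(pct)


def maf_histogram(mafs: Iterable[float], bin_width: float = 0.05) -> DistributionReport:
    """Histogram of minor allele frequencies over (0, 0.5].

    Bins are left-closed ([0, 0.05), [0.05, 0.10), ...) except the last,
    which is right-closed so that MAF 0.5 is counted.
    """
    values = np.asarray(list(mafs), dtype=float)
    if values.size and (values.min() <= 0 or values.max() > 0.5):
        bad = values[(values <= 0) | (values > 0.5)]
        raise ValueError(f"MAF values outside (0, 0.5]: {bad[:5]}")
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    if not np.isclose(edges[-1], 0.5):
        edges = np.append(edges, 0.5)
    counts, _ = np.histogram(values, bins=edges)  # numpy closes the last bin
    labels = tuple(
        f"[{edges[i]:.2f},{edges[i+1]:.2f}{']' if i == len(counts) - 1 else ')'}"
        for i in range(len(counts))
    )
    return DistributionReport(
        bin_labels=labels,
        counts=tuple(int(c) for c in counts),
        cumulative_percent=_cumulative_percent(counts, int(values.size)),
        n=int(values.size),
        metadata={"bin_width": bin_width, "range": (0.0, 0.5)},
    )


def snps_per_contig(
    contig_ids: Iterable[str],
    reference_contig_ids: Optional[Iterable[str]] = None,
) -> DistributionReport:
    """Distribution of SNP counts per contig.

    Classes are the exact per-contig SNP counts; the cumulative series
    is the percentage of *SNPs* (not contigs) accumulated over
    increasing count classes.  When reference IDs are supplied, contigs
    carrying zero SNPs appear as a zero class.
    """
    per_contig = Counter(contig_ids)
    n_snps = sum(per_contig.values())
    if reference_contig_ids is not None:
        for cid in reference_contig_ids:
            per_contig.setdefault(cid, 0)
    class_sizes = Counter(per_contig.values())  # snp-count class -> n contigs
    classes = sorted(class_sizes)
    snps_in_class = [c * class_sizes[c] for c in classes]
    return DistributionReport(
        bin_labels=tuple(classes),
        counts=tuple(class_sizes[c] for c in classes),
        cumulative_percent=_cumulative_percent(snps_in_class, n_snps),
        n=n_snps,
        metadata={
            "n_contigs": sum(class_sizes.values()),
            "snps_in_class": tuple(snps_in_class),
        },
    )


def bin_genes_by_interval(
    gene_map: pd.DataFrame,
    snp_gene_ids: Iterable[str],
    interval: int = 1_000_000,
) -> pd.DataFrame:
    """Bin genes along chromosomes in fixed intervals (default 1 Mb).

    Returns one row per (chrom, bin) with the count of all genes and of
    SNP-containing genes in that interval.  ``snp_gene_ids`` must be a
    subset of the gene map's ``gene_id`` column.
    """
    snp_ids = set(snp_gene_ids)
    known = set(gene_map["gene_id"])
    orphans = sorted(snp_ids - known)
    if orphans:
        raise ValueError(f"SNP gene IDs absent from gene map: {orphans}")
    df = gene_map.copy()
    df["bin"] = (df["chrom_pos"] // interval).astype(int)
    df["has_snp"] = df["gene_id"].isin(snp_ids)
    out = (
        df.groupby(["chrom", "bin"])
        .agg(n_genes=("gene_id", "size"), n_snp_genes=("has_snp", "sum"))
        .reset_index()
    )
    out["n_snp_genes"] = out["n_snp_genes"].astype(int)
    out["n_genes_without_snps"] = out["n_genes"] - out["n_snp_genes"]
    out.attrs["interval"] = interval
    return out


def validation_rate(n_validated: int, n_tested: int) -> float:
    """Percentage of assayed SNPs confirmed, half-up to one decimal."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_validated <= n_tested:
        raise ValueError("need 0 <= n_validated <= n_tested")
    return round_percent(100.0 * n_validated / n_tested)
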