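"""Readers and writers for the formats the pipeline touches.

FASTA (reference transcriptome contigs), ESTScan-style ORF coordinate
tables (TSV), samtools-mpileup 6-column text (one strain per file),
per-strain call tables (TSV) and VCF 4.2 output.

Coordinates are 1-based inclusive everywhere, following pileup/VCF
convention.  Base qualities are Phred+33; no Solexa/+64 autodetection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "TranscriptContig",
    "PileupSite",
    "read_fasta",
    "write_fasta",
    "read_orf_table",
    "write_orf_table",
    "attach_orfs",
    "parse_pileup_line",
    "read_pileup",
    "read_gene_map",
    "write_vcf",
    "read_vcf",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class TranscriptContig:
    """A reference cDNA contig, optionally carrying an ORF annotation.

    ``cds_start``/``cds_end`` are 1-based inclusive on the forward strand
    of the contig as stored; for ``strand == '-'`` the reading frame runs
    from ``cds_end`` backwards along the reverse complement, so the
    5'UTR occupies the high-coordinate flank.
    """

    contig_id: str
    sequence: str
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.has_orf:
            if self.strand not in ("+", "-"):
                raise ValueError(
                    f"{self.contig_id}: strand must be '+' or '-', got {self.strand!r}"
                )
            if not (1 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValueError(
                    f"{self.contig_id}: ORF [{self.cds_start},{self.cds_end}] "
                    f"outside contig of length {len(self.sequence)}"
                )
            if (self.cds_end - self.cds_start + 1) % 3 != 0:
                raise ValueError(
                    f"{self.contig_id}: CDS length "
                    f"{self.cds_end - self.cds_start + 1} not divisible by 3"
                )

    @property
    def has_orf(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValueError(
                f"position {position} outside {self.contig_id} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclass
class PileupSite:
    """One contig position in one strain: decoded read bases + qualities.

    ``read_bases`` holds substitution calls only (A/C/G/T/N, uppercased,
    match symbols resolved to the reference base); indel insertions,
    deletion placeholders and reference skips are parsed and discarded.
    ``base_qualities`` pairs positionally with ``read_bases``.
    """

    contig_id: str
    position: int
    reference_base: str
    depth: int
    read_bases: list[str]
    base_qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.read_bases) != len(self.base_qualities):
            raise ValueError(
                f"{self.contig_id}:{self.position}: {len(self.read_bases)} retained "
                f"calls but {len(self.base_qualities)} qualities"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[TranscriptContig]:
    """Read contigs (sequences only) from FASTA.

    IDs are taken up to the first whitespace; sequences are uppercased;
    record order is preserved.  Duplicate IDs raise ``ValueError``.
    """
    contigs: list[TranscriptContig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig ID {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(TranscriptContig(rec.id, str(rec.seq).upper()))
    return contigs


def write_fasta(contigs: Iterable[TranscriptContig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ORF table


def read_orf_table(path: str | Path) -> dict[str, tuple[int, int, str]]:
    """Read ORF coordinates: TSV with header contig_id, cds_start, cds_end, strand.

    Validates start < end, CDS length divisible by 3, and the strand
    symbol; full bounds checking happens when joined to sequences via
    :func:`attach_orfs`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    required = {"contig_id", "cds_start", "cds_end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ORF table {path} missing columns: {sorted(missing)}")
    orfs: dict[str, tuple[int, int, str]] = {}
    for row in df.itertuples(index=False):
        start, end, strand = int(row.cds_start), int(row.cds_end), str(row.strand)
        if row.contig_id in orfs:
            raise ValueError(f"duplicate ORF row for contig {row.contig_id}")
        if start >= end:
            raise ValueError(
                f"{row.contig_id}: cds_start {start} not below cds_end {end}"
            )
        if (end - start + 1) % 3 != 0:
            raise ValueError(
                f"{row.contig_id}: CDS length {end - start + 1} not divisible by 3"
            )
        if strand not in ("+", "-"):
            raise ValueError(f"{row.contig_id}: unknown strand symbol {strand!r}")
        orfs[row.contig_id] = (start, end, strand)
    return orfs


def write_orf_table(contigs: Iterable[TranscriptContig], path: str | Path) -> None:
    rows = [
        {
            "contig_id": c.contig_id,
            "cds_start": c.cds_start,
            "cds_end": c.cds_end,
            "strand": c.strand,
        }
        for c in contigs
        if c.has_orf
    ]
    pd.DataFrame(rows, columns=["contig_id", "cds_start", "cds_end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def attach_orfs(
    contigs: Sequence[TranscriptContig], orfs: dict[str, tuple[int, int, str]]
) -> list[TranscriptContig]:
    """Join ORF coordinates onto sequence-only contigs (validates bounds)."""
    out = []
    for c in contigs:
        if c.contig_id in orfs:
            start, end, strand = orfs[c.contig_id]
            out.append(
                TranscriptContig(c.contig_id, c.sequence, start, end, strand)
            )
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# samtools mpileup 6-column text


def parse_pileup_line(line: str, line_number: int | None = None) -> PileupSite:
    """Decode one samtools-mpileup text line into a :class:`PileupSite`.

    Decoding rules for the base column:

    * ``.`` / ``,`` -> the reference base;
    * ``ACGTN`` in either case -> that base, uppercased;
    * ``^`` consumes the following mapping-quality character; ``$`` is
      consumed;
    * ``+n``/``-n`` followed by *n* inserted/deleted bases are consumed
      and discarded (no quality characters belong to them);
    * ``*`` (deletion placeholder) and ``>``/``<`` (reference skips)
      are discarded together with their paired quality character.

    Retained calls pair positionally with the quality string (Phred+33).
    A count mismatch after decoding raises ``ValueError``.
    """
    where = f" (line {line_number})" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ValueError(f"pileup line has {len(fields)} fields, expected >= 6{where}")
    contig_id, pos_s, ref, depth_s, bases, quals = fields[:6]
    try:
        position = int(pos_s)
    except ValueError:
        raise ValueError(f"non-numeric position {pos_s!r}{where}") from None
    try:
        depth = int(depth_s)
    except ValueError:
        raise ValueError(f"non-numeric depth {depth_s!r}{where}") from None
    ref = ref.upper()

    calls: list[str] = []
    consuming: list[bool] = []  # True where the symbol consumes a quality char
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # '^' plus mapping-quality character
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            i += 1
            j = i
            while j < n and bases[j].isdigit():
                j += 1
            if j == i:
                raise ValueError(f"malformed indel at column {i} in base string{where}")
            run = int(bases[i:j])
            i = j + run
            continue
        if ch in ".,":
            calls.append(ref)
            consuming.append(True)
        elif ch.upper() in "ACGTN":
            calls.append(ch.upper())
            consuming.append(True)
        elif ch in "*><":
            calls.append("")  # placeholder: consumes a quality, retained nowhere
            consuming.append(True)
        else:
            raise ValueError(f"unexpected pileup symbol {ch!r}{where}")
        i += 1

    if len(consuming) != len(quals):
        raise ValueError(
            f"{contig_id}:{position}: decoded {len(consuming)} quality-consuming "
            f"symbols but quality string has {len(quals)} characters{where}"
        )
    read_bases = []
    base_qualities = []
    for call, q in zip(calls, quals):
        if call:  # drop '*', '>', '<' placeholders with their qualities
            read_bases.append(call)
            base_qualities.append(ord(q) - 33)
    return PileupSite(contig_id, position, ref, depth, read_bases, base_qualities)


def read_pileup(path: str | Path) -> Iterator[PileupSite]:
    """Iterate decoded sites from an mpileup text file (one strain)."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            yield parse_pileup_line(line, line_number=ln)


# ---------------------------------------------------------------------------
# gene map


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Read a contig->gene/chromosome mapping table.

    TSV with columns ``gene_id``, ``chrom``, ``chrom_pos`` and optionally
    ``contig_id``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "chrom_pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene map {path} missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# VCF


def write_vcf(calls, contigs: Sequence[TranscriptContig], path: str | Path) -> None:
    """Write non-redundant SNPs as VCF 4.2 via pysam.

    ``calls`` is an iterable of mappings/objects with attributes
    ``contig_id``, ``position``, ``ref``, ``alt`` and optionally
    ``info`` (dict of INFO fields among MAF, TSTV, EFFECT, strain
    allele-depth strings).  Records are sorted by contig (reference
    order) then position.  A ref allele disagreeing with the reference
    sequence raises ``ValueError``.
    """
    import pysam

    by_id = {c.contig_id: c for c in contigs}
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for c in contigs:
        header.contigs.add(c.contig_id, length=len(c.sequence))
    header.info.add("MAF", 1, "Float", "Minor allele frequency from filtered reads")
    header.info.add("TSTV", 1, "String", "transition or transversion")
    header.info.add("EFFECT", 1, "String", "Functional category against the contig ORF")
    header.info.add("SAD", ".", "String", "Per-strain allele depths as strain:allele=count")

    order = {c.contig_id: i for i, c in enumerate(contigs)}
    records = []
    for call in calls:
        cid = call["contig_id"] if isinstance(call, dict) else call.contig_id
        pos = call["position"] if isinstance(call, dict) else call.position
        ref = call["ref"] if isinstance(call, dict) else call.ref
        alt = call["alt"] if isinstance(call, dict) else call.alt
        info = (call.get("info") if isinstance(call, dict) else getattr(call, "info", None)) or {}
        if cid not in by_id:
            raise ValueError(f"unknown contig {cid} in calls")
        actual = by_id[cid].base_at(pos)
        if actual != ref:
            raise ValueError(
                f"{cid}:{pos}: call ref {ref} disagrees with reference base {actual}"
            )
        records.append((order[cid], pos, cid, ref, alt, info))
    records.sort(key=lambda r: (r[0], r[1]))

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, pos, cid, ref, alt, info in records:
            rec = vcf.new_record(contig=cid, start=pos - 1, stop=pos, alleles=(ref, alt))
            for k, v in info.items():
                rec.info[k] = v
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[dict]:
    """Read back the fields :func:`write_vcf` emits (round-trip support)."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = {}
            for k in ("MAF", "TSTV", "EFFECT", "SAD"):
                if k in rec.info:
                    v = rec.info[k]
                    info[k] = v
            out.append(
                {
                    "contig_id": rec.contig,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "info": info,
                }
            )
    return out
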