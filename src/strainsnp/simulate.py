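"""Synthetic reference contigs, implanted strain variants and pileups.

The generator emulates the regime the pipeline is built for: a
multi-contig cDNA reference with embedded ORFs, per-strain pooled allele
configurations (within-strain polymorphisms at a configurable per-base
rate, fixed between-strain differences at another), and per-strain
samtools-mpileup text with Poisson depth, Gaussian-ish Phred qualities
and a uniform base-miscall error rate.

Polymorphism is modelled at the pooled-population level (an allele
frequency per strain), matching pooled pileup semantics, not individual
genotypes.  Each site carries at most one variant type, and truth is
biallelic throughout.  All randomness flows through a seeded
``numpy.random.Generator``; the same config yields byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import TranscriptContig, write_fasta, write_orf_table

__all__ = [
    "SimulationConfig",
    "FixedState",
    "PolymorphicState",
    "TruthVariant",
    "generate_contigs",
    "implant_truth",
    "simulate_pileups",
    "write_truth_table",
    "read_truth_table",
    "run_simulation",
]

_ALPHABET = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# minimal ORF: ATG + one sense codon + stop, with 1-base UTRs each side
_MIN_ORF_CONTIG = 9 + 2


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small four-strain survey in the calling regime
    the pipeline targets: callable depth well above the 10-read floor,
    Phred quality well above the 20 filter, and a low per-base error.
    """

    n_contigs: int = 50
    contig_length_range: tuple[int, int] = (300, 600)
    orf_fraction: float = 0.8
    n_strains: int = 4
    poly_rate: float = 0.002
    fixed_diff_rate: float = 0.001
    mean_depth: float = 100.0
    base_error_rate: float = 0.001
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    seed: int = 0
    strain_names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.n_strains < 1:
            raise ValueError("n_contigs and n_strains must be positive")
        lo, hi = self.contig_length_range
        if lo < 30 or hi < lo:
            raise ValueError("contig_length_range must satisfy 30 <= min <= max")
        for name, rate in (
            ("orf_fraction", self.orf_fraction),
            ("poly_rate", self.poly_rate),
            ("fixed_diff_rate", self.fixed_diff_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {rate}")
        if self.poly_rate + self.fixed_diff_rate > 1.0:
            raise ValueError("poly_rate + fixed_diff_rate must not exceed 1")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0,1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.strain_names is not None and len(self.strain_names) != self.n_strains:
            raise ValueError("strain_names length must equal n_strains")

    @property
    def strains(self) -> tuple[str, ...]:
        if self.strain_names is not None:
            return self.strain_names
        return tuple(f"strain{i + 1}" for i in range(self.n_strains))


@dataclass(frozen=True)
class FixedState:
    """One strain fixed for a single allele at a site."""

    allele: str


@dataclass(frozen=True)
class PolymorphicState:
    """One strain segregating two alleles at pooled frequency ``freq_b``."""

    allele_a: str
    allele_b: str
    freq_b: float

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("polymorphic state needs two distinct alleles")
        if not 0.0 < self.freq_b < 1.0:
            raise ValueError("freq_b must lie strictly in (0,1)")


StrainState = Union[FixedState, PolymorphicState]


@dataclass(frozen=True)
class TruthVariant:
    """Ground-truth allele configuration of one site across strains."""

    contig_id: str
    position: int  # 1-based
    reference_allele: str
    per_strain_state: dict[str, StrainState] = field(hash=False)

    @property
    def kind(self) -> str:
        return (
            "polymorphic"
            if any(isinstance(s, PolymorphicState) for s in self.per_strain_state.values())
            else "fixed_difference"
        )


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent substream per pipeline stage, reproducible per seed
    return np.random.default_rng(np.random.SeedSequence((config.seed, stage)))


def _random_orf(rng: np.random.Generator, contig_len: int) -> tuple[str, int, int, str]:
    """Build an ORF sequence and pick placement/strand inside a contig."""
    max_cds = contig_len - 2  # at least 1-base UTR each side
    max_codons = max_cds // 3
    if max_codons < 3:
        raise ValueError(
            f"contig of length {contig_len} cannot host a minimal ORF "
            f"(need >= {_MIN_ORF_CONTIG} bases)"
        )
    n_codons = int(rng.integers(3, max_codons + 1))
    cds_len = 3 * n_codons
    # internal codons avoid stops so the frame is an honest ORF
    internal = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(_ALPHABET, size=3))
            if codon not in _STOPS:
                break
        internal.append(codon)
    orf = "ATG" + "".join(internal) + _STOPS[rng.integers(0, 3)]
    start = int(rng.integers(2, contig_len - cds_len + 1))  # 1-based; leaves both UTRs
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        orf = orf.translate(_COMPLEMENT)[::-1]
    return orf, start, start + cds_len - 1, strand


def generate_contigs(config: SimulationConfig) -> list[TranscriptContig]:
    """Generate reference contigs; an ``orf_fraction`` subset carries ORFs.

    ORFs start with ATG, end with a stop, have length divisible by 3 and
    nonempty UTR flanks; strands are drawn at random, with minus-strand
    ORFs stored as the reverse complement of the reading frame.
    """
    rng = _stage_rng(config, 0)
    lo, hi = config.contig_length_range
    if lo < _MIN_ORF_CONTIG and config.orf_fraction > 0:
        raise ValueError(
            f"contig_length_range minimum {lo} too short to host a minimal ORF"
        )
    contigs = []
    for i in range(config.n_contigs):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_ALPHABET, size=length))
        if rng.random() < config.orf_fraction:
            orf, start, end, strand = _random_orf(rng, length)
            seq = seq[: start - 1] + orf + seq[start - 1 + len(orf) :]
            contigs.append(TranscriptContig(f"contig{i + 1:05d}", seq, start, end, strand))
        else:
            contigs.append(TranscriptContig(f"contig{i + 1:05d}", seq))
    return contigs


def implant_truth(
    contigs: Sequence[TranscriptContig], config: SimulationConfig
) -> list[TruthVariant]:
    """Assign ground-truth variants independently per base.

    With probability ``poly_rate`` a site becomes polymorphic in one
    uniformly chosen strain (reference vs. a random alternate allele at
    pooled frequency uniform in [0.1, 0.5]); with probability
    ``fixed_diff_rate`` one uniformly chosen strain becomes fixed for a
    non-reference allele while the others stay fixed reference.  No site
    carries both.
    """
    rng = _stage_rng(config, 1)
    strains = config.strains
    truth: list[TruthVariant] = []
    for contig in contigs:
        u = rng.random(len(contig.sequence))
        for idx in np.flatnonzero(u < config.poly_rate + config.fixed_diff_rate):
            pos = int(idx) + 1
            ref = contig.sequence[idx]
            if ref not in "ACGT":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            focal = strains[int(rng.integers(0, len(strains)))]
            states: dict[str, StrainState] = {s: FixedState(ref) for s in strains}
            if u[idx] < config.poly_rate:
                freq_b = float(rng.uniform(0.1, 0.5))
                states[focal] = PolymorphicState(ref, alt, freq_b)
            else:
                states[focal] = FixedState(alt)
            truth.append(TruthVariant(contig.contig_id, pos, ref, states))
    return truth


def _encode_base(base: str, ref: str, forward: bool) -> str:
    if base == ref:
        return "." if forward else ","
    return base if forward else base.lower()


def simulate_pileups(
    contigs: Sequence[TranscriptContig],
    truth: Sequence[TruthVariant],
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one mpileup text file per strain; returns strain -> path.

    Per site, depth is Poisson(``mean_depth``); read bases are drawn
    from the strain's true allele frequencies and miscalled uniformly to
    another base with probability ``base_error_rate``; qualities are
    Gaussian around ``quality_mean``, truncated to [2, 41] and rounded.
    Read-start (``^`` + mapping quality) and read-end (``$``) marks are
    sprinkled in so downstream decoding is exercised; zero-depth sites
    are omitted, as samtools does by default.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_by_site = {(t.contig_id, t.position): t for t in truth}
    paths: dict[str, Path] = {}
    for s_idx, strain in enumerate(config.strains):
        rng = _stage_rng(config, 100 + s_idx)
        path = outdir / f"{strain}.pileup"
        with open(path, "w") as fh:
            for contig in contigs:
                depths = rng.poisson(config.mean_depth, size=len(contig.sequence))
                for idx in range(len(contig.sequence)):
                    depth = int(depths[idx])
                    if depth == 0:
                        continue
                    pos = idx + 1
                    ref = contig.sequence[idx]
                    state = None
                    t = truth_by_site.get((contig.contig_id, pos))
                    if t is not None:
                        state = t.per_strain_state[strain]
                    if isinstance(state, PolymorphicState):
                        alleles = (state.allele_a, state.allele_b)
                        probs = (1.0 - state.freq_b, state.freq_b)
                        bases = rng.choice(alleles, size=depth, p=probs)
                    elif isinstance(state, FixedState):
                        bases = np.full(depth, state.allele)
                    else:
                        bases = np.full(depth, ref)
                    if config.base_error_rate > 0:
                        err = rng.random(depth) < config.base_error_rate
                        for j in np.flatnonzero(err):
                            others = [b for b in "ACGT" if b != bases[j]]
                            bases[j] = others[int(rng.integers(0, 3))]
                    quals = np.clip(
                        np.rint(rng.normal(config.quality_mean, config.quality_sd, depth)),
                        2,
                        41,
                    ).astype(int)
                    forward = rng.random(depth) < 0.5
                    symbols = []
                    for j in range(depth):
                        sym = _encode_base(str(bases[j]), ref, bool(forward[j]))
                        r = rng.random()
                        if r < 0.02:
                            sym = "^" + chr(33 + int(rng.integers(0, 40))) + sym
                        elif r < 0.04:
                            sym = sym + "$"
                        symbols.append(sym)
                    qual_str = "".join(chr(33 + q) for q in quals)
                    fh.write(
                        f"{contig.contig_id}\t{pos}\t{ref}\t{depth}\t"
                        f"{''.join(symbols)}\t{qual_str}\n"
                    )
        paths[strain] = path
    return paths


def write_truth_table(truth: Iterable[TruthVariant], path: str | Path) -> None:
    rows = []
    for t in truth:
        for strain, state in t.per_strain_state.items():
            if isinstance(state, PolymorphicState):
                rows.append(
                    (t.contig_id, t.position, t.reference_allele, strain,
                     "polymorphic", state.allele_a, state.allele_b, state.freq_b)
                )
            else:
                rows.append(
                    (t.contig_id, t.position, t.reference_allele, strain,
                     "fixed", state.allele, "", "")
                )
    pd.DataFrame(
        rows,
        columns=["contig_id", "position", "reference_allele", "strain",
                 "state", "allele_a", "allele_b", "freq_b"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TruthVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "strain": str})
    out: list[TruthVariant] = []
    for (cid, pos, ref), grp in df.groupby(
        ["contig_id", "position", "reference_allele"], sort=False
    ):
        states: dict[str, StrainState] = {}
        for row in grp.itertuples(index=False):
            if row.state == "polymorphic":
                states[row.strain] = PolymorphicState(
                    row.allele_a, row.allele_b, float(row.freq_b)
                )
            else:
                states[row.strain] = FixedState(row.allele_a)
        out.append(TruthVariant(cid, int(pos), ref, states))
    return out


def run_simulation(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate contigs, truth and pileups; write all artefacts to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = generate_contigs(config)
    truth = implant_truth(contigs, config)
    pileups = simulate_pileups(contigs, truth, config, outdir)
    write_fasta(contigs, outdir / "reference.fa")
    write_orf_table(contigs, outdir / "orfs.tsv")
    write_truth_table(truth, outdir / "truth.tsv")
    return {
        "contigs": contigs,
        "truth": truth,
        "pileups": pileups,
        "reference": outdir / "reference.fa",
        "orf_table": outdir / "orfs.tsv",
        "truth_table": outdir / "truth.tsv",
    }
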