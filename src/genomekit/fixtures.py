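"""Deterministic synthetic-data generation: genomes, aligned reads with
planted mismatches/indels, feature tables in every supported dialect, and
coverage tracks with planted peaks.

Every generator is a pure function of its arguments including the seed, and
each returns a :class:`PlantedTruth` record describing exactly what was
planted so tests can verify recovery against ground truth.  Generators write
real files (SAM, FASTA, TSV) so the console applications are exercised across
the same file boundaries real users cross.

These are idealized data: uniform base composition, position-independent
error rates, Poisson background and Gaussian peak profiles.  They exercise
the algebra and accounting of the methods, not the biases of real libraries
(GC skew, PCR duplicates, mappability holes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .coverage_engine import CoverageTrack
from .errors import ContractError
from .format_io import AlignmentRecord, Feature, write_sam
from .interval_algebra import GenomicInterval

PathLike = Union[str, Path]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGenome:
    contigs: Dict[str, str]
    seed: int

    def write_fasta(self, path: PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), width):
                    fh.write(seq[k : k + width] + "\n")


@dataclass
class PlantedRead:
    name: str
    contig: str
    start: int  # 0-based leftmost reference position
    strand: str
    cigar: List[Tuple[int, str]]
    blocks: List[Tuple[int, int]]  # covered reference spans (M only)
    mismatch_positions: List[int]  # reference positions


FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


@dataclass
class PlantedPeak:
    contig: str
    center: int
    width_bp: float  # full width at half maximum, in bases
    amplitude: float  # added reads-per-base at the center

    @property
    def sigma(self) -> float:
        return self.width_bp / FWHM_PER_SIGMA


@dataclass
class PlantedTruth:
    reads: List[PlantedRead] = field(default_factory=list)
    peaks: List[PlantedPeak] = field(default_factory=list)
    features: List[Feature] = field(default_factory=list)


def make_genome(
    contig_specs: Sequence[Tuple[str, int]], seed: int
) -> SyntheticGenome:
    """Uniform-ACGT contigs; identical seed, identical genome."""
    rng = np.random.default_rng(seed)
    contigs: Dict[str, str] = {}
    for name, length in contig_specs:
        if length < 1:
            raise ContractError(f"contig {name!r}: length must be >= 1")
        contigs[name] = "".join(
            BASES[i] for i in rng.integers(0, 4, size=length)
        )
    return SyntheticGenome(contigs, seed)


# ---------------------------------------------------------------------------
# SAM generation with planted mismatches / indels
# ---------------------------------------------------------------------------


def _plan_cigar(
    rng: np.random.Generator, read_length: int, indel_rate: float
) -> List[Tuple[int, str]]:
    """Mostly pure-M alignments; occasionally one interior 1-3 base indel."""
    if indel_rate > 0 and rng.random() < indel_rate and read_length >= 4:
        size = int(rng.integers(1, 4))
        op = "I" if rng.random() < 0.5 else "D"
        if op == "I":
            m_total = read_length - size
            if m_total < 2:
                return [(read_length, "M")]
        else:
            m_total = read_length
        a = int(rng.integers(1, m_total))
        return [(a, "M"), (size, op), (m_total - a, "M")]
    return [(read_length, "M")]


def make_sam(
    genome: SyntheticGenome,
    n_reads: int,
    read_length: int,
    mismatch_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    path: Optional[PathLike] = None,
) -> Tuple[Optional[Path], PlantedTruth, List[AlignmentRecord]]:
    """Sample reads uniformly (position, strand) and write a text SAM.

    Mismatches are planted per aligned base at ``mismatch_rate`` with
    consistent MD/NM tags; ``indel_rate`` is the per-read probability of one
    small interior insertion or deletion (reflected in the CIGAR and MD).
    Returns (path, truth, records); ``path`` is None when no file was
    requested.
    """
    min_len = min(len(s) for s in genome.contigs.values())
    if read_length > min_len:
        raise ContractError(
            f"read_length {read_length} exceeds shortest contig ({min_len})"
        )
    rng = np.random.default_rng(seed)
    names = list(genome.contigs)
    truth = PlantedTruth()
    records: List[AlignmentRecord] = []
    for k in range(n_reads):
        contig = names[int(rng.integers(0, len(names)))]
        ref = genome.contigs[contig]
        cigar = _plan_cigar(rng, read_length, indel_rate)
        ref_span = sum(l for l, op in cigar if op in "MDN=X")
        start = int(rng.integers(0, len(ref) - ref_span + 1))
        strand = "-" if rng.random() < 0.5 else "+"

        seq_parts: List[str] = []
        md_parts: List[str] = []
        match_run = 0
        mismatch_positions: List[int] = []
        blocks: List[Tuple[int, int]] = []
        nm = 0
        rpos = start
        for length, op in cigar:
            if op == "M":
                blocks.append((rpos, rpos + length))
                for j in range(rpos, rpos + length):
                    base = ref[j]
                    if mismatch_rate > 0 and rng.random() < mismatch_rate:
                        alt = BASES[
                            (BASES.index(base) + int(rng.integers(1, 4))) % 4
                        ]
                        seq_parts.append(alt)
                        md_parts.append(str(match_run))
                        md_parts.append(base)  # MD stores the reference base
                        match_run = 0
                        mismatch_positions.append(j)
                        nm += 1
                    else:
                        seq_parts.append(base)
                        match_run += 1
                rpos += length
            elif op == "I":
                seq_parts.append(
                    "".join(BASES[i] for i in rng.integers(0, 4, size=length))
                )
                nm += length
            elif op == "D":
                md_parts.append(str(match_run))
                md_parts.append("^" + ref[rpos : rpos + length])
                match_run = 0
                nm += length
                rpos += length
        md_parts.append(str(match_run))
        md = "".join(md_parts)
        seq = "".join(seq_parts)
        flag = 16 if strand == "-" else 0
        rec = AlignmentRecord(
            qname=f"read_{k}",
            flag=flag,
            chrom=contig,
            pos=start,
            mapq=60,
            cigar=cigar,
            seq=seq,
            qual="I" * len(seq),
            tags={"NM": nm, "MD": md, "NH": 1},
        )
        records.append(rec)
        truth.reads.append(
            PlantedRead(
                rec.qname, contig, start, strand, cigar, blocks,
                mismatch_positions,
            )
        )
    out_path = None
    if path is not None:
        out_path = Path(path)
        write_sam(
            records,
            out_path,
            {n: len(s) for n, s in genome.contigs.items()},
        )
    return out_path, truth, records


# ---------------------------------------------------------------------------
# Peak tracks
# ---------------------------------------------------------------------------


def make_peak_track(
    contig_length: int,
    peaks: Sequence[Tuple[int, float, float]],
    noise_rate: float = 0.0,
    seed: int = 0,
    contig: str = "chr1",
    spikes: Sequence[Tuple[int, float]] = (),
) -> Tuple[CoverageTrack, PlantedTruth]:
    """Poisson background plus Gaussian-profile bumps, deterministic per seed.

    ``peaks`` entries are (center, width_bp, amplitude): width is the bump's
    full width at half maximum in bases (the convention peak widths are
    reported in; the Gaussian sigma is width/2.355) and amplitude the added
    reads-per-base at the center.  ``spikes`` are optional (position,
    amplitude) single-base impulses.  Overlapping peaks are permitted; the
    truth record keeps each one.
    """
    rng = np.random.default_rng(seed)
    dense = np.zeros(contig_length)
    if noise_rate > 0:
        dense += rng.poisson(noise_rate, size=contig_length)
    truth = PlantedTruth()
    for center, width, amplitude in peaks:
        if not 0 <= center < contig_length:
            raise ContractError(f"peak center {center} outside contig")
        sigma = width / FWHM_PER_SIGMA
        lo = max(0, int(center - 6 * sigma))
        hi = min(contig_length, int(center + 6 * sigma) + 1)
        x = np.arange(lo, hi)
        dense[lo:hi] += amplitude * np.exp(-((x - center) ** 2) / (2 * sigma**2))
        truth.peaks.append(PlantedPeak(contig, int(center), float(width), float(amplitude)))
    for pos, amplitude in spikes:
        dense[pos] += amplitude
    track = CoverageTrack(contig_lengths={contig: contig_length})
    total = track.array(contig, "total")
    fwd = track.array(contig, "forward")
    for pos in np.nonzero(dense)[0]:
        v = float(dense[pos])
        total[int(pos)] = v
        fwd[int(pos)] = v  # all mass on '+' ; strand split is not under test
    track.reads_counted = max(1, int(round(float(dense.sum()))))
    return track, truth


# ---------------------------------------------------------------------------
# Feature sets
# ---------------------------------------------------------------------------


def make_features(
    contig_lengths: Dict[str, int],
    n_features: int,
    seed: int = 0,
    min_length: int = 50,
    max_length: int = 2000,
    with_exons: bool = False,
) -> List[Feature]:
    """Random stranded features, optionally with 1-3 exon sub-blocks."""
    rng = np.random.default_rng(seed)
    names = sorted(contig_lengths)
    feats: List[Feature] = []
    for k in range(n_features):
        contig = names[int(rng.integers(0, len(names)))]
        clen = contig_lengths[contig]
        length = int(rng.integers(min_length, min(max_length, clen) + 1))
        start = int(rng.integers(0, max(1, clen - length)))
        strand = "+-."[int(rng.integers(0, 3))]
        iv = GenomicInterval(contig, start, start + length, strand)
        blocks = None
        if with_exons and length >= 60:
            n_ex = int(rng.integers(1, 4))
            cuts = sorted(
                int(rng.integers(0, length // 2)) for _ in range(2 * n_ex)
            )
            blocks = []
            for i in range(n_ex):
                s = start + cuts[2 * i] + i * (length // (2 * n_ex))
                e = min(start + length, s + max(10, cuts[2 * i + 1] - cuts[2 * i] + 10))
                if blocks and s < blocks[-1].end:
                    s = blocks[-1].end + 1
                    e = max(e, s)
                if s < start + length and s < e:
                    blocks.append(GenomicInterval(contig, s, min(e, start + length), strand))
            blocks = blocks or None
        feats.append(Feature(f"feat_{k}", f"gene_{k}", iv, blocks))
    return feats
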