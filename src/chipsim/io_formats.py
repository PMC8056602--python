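"""Readers/writers for the genomic formats the toolkit touches.

FASTA references, BED peak sets, FASTQ output and SAM/BAM alignment
records.  All coordinates are 0-based half-open (BED convention)
internally; SAM records are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pyfaidx
import pysam

__all__ = [
    "Peak",
    "AlnRecord",
    "SimRead",
    "read_fasta",
    "reference_lengths",
    "read_peaks",
    "write_peaks",
    "merge_peaks",
    "write_fastq",
    "iter_alignments",
]

PathLike = Union[str, Path]

# Base at Phred quality 30, offset 33 ('?'): the model has no
# quality-score process, so every base gets the same character.
QUAL_CHAR = "?"

_VALID = set(b"ACGTN")
_NORM_TABLE = bytes(
    (c if c in _VALID else ord("N")) for c in bytes(range(256)).upper()
)


@dataclass(frozen=True)
class Peak:
    """Scored genomic interval; ``score`` is the binding probability."""

    chrom: str
    start: int
    end: int
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlnRecord:
    """Minimal alignment record (SAM semantics, 0-based coordinates).

    ``pos`` is the leftmost aligned coordinate.  ``template_len``
    follows the SAM sign convention; |template_len| taken from the
    leftmost mate (positive value) is the fragment length.
    """

    chrom: str
    pos: int
    is_reverse: bool = False
    is_duplicate: bool = False
    is_proper_pair: bool = False
    template_len: int = 0
    mapq: int = 60


@dataclass
class SimRead:
    """A simulated read (or read pair) with its ground-truth origin."""

    name: str
    seq1: str
    qual1: str
    seq2: Optional[str] = None
    qual2: Optional[str] = None
    chrom: str = ""
    frag_start: int = 0
    frag_end: int = 0
    is_reverse: bool = False


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a FASTA file into a {name: uppercase sequence} map.

    Lowercase is normalized to uppercase and any character outside
    {A,C,G,T,N} becomes N.  Duplicate record names and empty files are
    errors.
    """
    try:
        fa = pyfaidx.Fasta(str(path), duplicate_action="stop", rebuild=True)
    except (ValueError, pyfaidx.FastaIndexingError) as exc:
        raise ValueError(f"cannot index FASTA {path}: {exc}") from exc
    seqs: Dict[str, str] = {}
    for name in fa.keys():
        raw = str(fa[name][:]).encode("ascii")
        seqs[name] = raw.translate(_NORM_TABLE).decode("ascii")
    fa.close()
    if not seqs:
        raise ValueError(f"FASTA {path} contains no records")
    return seqs


def reference_lengths(path: PathLike) -> Dict[str, int]:
    """Chromosome lengths from a FASTA or a .fai index file."""
    path = Path(path)
    if path.suffix == ".fai":
        lengths: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = line.split("\t")
                lengths[fields[0]] = int(fields[1])
        if not lengths:
            raise ValueError(f"empty .fai index: {path}")
        return lengths
    fa = pyfaidx.Fasta(str(path))
    lengths = {name: len(fa[name]) for name in fa.keys()}
    fa.close()
    if not lengths:
        raise ValueError(f"FASTA {path} contains no records")
    return lengths


def read_peaks(
    path: PathLike,
    score_column: Optional[int] = None,
    score_max: Optional[float] = None,
) -> List[Peak]:
    """Read a BED-like peak file into scored peaks.

    ``score_column`` is a 1-based column index holding the raw score
    (e.g. 5 for narrowPeak); raw scores are divided by ``score_max``
    (default 1.0) and clipped to [0, 1].  With no score column every
    peak gets probability 1.0.
    """
    denom = 1.0 if score_max is None else float(score_max)
    if denom <= 0:
        raise ValueError(f"score_max must be > 0, got {score_max}")
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            score = 1.0
            if score_column is not None:
                if len(fields) < score_column:
                    raise ValueError(
                        f"{path}:{lineno}: no column {score_column} for the score"
                    )
                try:
                    raw = float(fields[score_column - 1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
                score = min(1.0, max(0.0, raw / denom))
            try:
                peaks.append(Peak(chrom, start, end, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path: PathLike) -> None:
    """Write peaks as 5-column BED with the normalized score in column 5.

    Output re-reads losslessly with ``read_peaks(path, score_column=5)``.
    """
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t.\t{p.score!r}\n")


def merge_peaks(peaks: Sequence[Peak]) -> List[Peak]:
    """Resolve overlaps into disjoint scored segments.

    Where peaks overlap, the per-base score is the maximum over covering
    peaks; adjacent segments with equal score are coalesced.  Output is
    sorted by (chrom, start) and pairwise disjoint.
    """
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    merged: List[Peak] = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        bounds = np.unique(
            np.concatenate([[p.start for p in group], [p.end for p in group]])
        )
        best = np.full(len(bounds) - 1, -1.0)
        for p in group:
            i = np.searchsorted(bounds, p.start)
            j = np.searchsorted(bounds, p.end)
            np.maximum(best[i:j], p.score, out=best[i:j])
        # coalesce contiguous segments with identical score
        cur_start = cur_end = None
        cur_score = 0.0
        for k in range(len(best)):
            if best[k] < 0:
                if cur_start is not None:
                    merged.append(Peak(chrom, int(cur_start), int(cur_end), cur_score))
                    cur_start = None
                continue
            seg_start, seg_end, seg_score = bounds[k], bounds[k + 1], float(best[k])
            if cur_start is not None and cur_end == seg_start and cur_score == seg_score:
                cur_end = seg_end
            else:
                if cur_start is not None:
                    merged.append(Peak(chrom, int(cur_start), int(cur_end), cur_score))
                cur_start, cur_end, cur_score = seg_start, seg_end, seg_score
        if cur_start is not None:
            merged.append(Peak(chrom, int(cur_start), int(cur_end), cur_score))
    return merged


def write_fastq(
    reads: Iterable[SimRead], path_prefix: PathLike, paired: bool
) -> Tuple[Path, ...]:
    """Write reads to FASTQ: <prefix>.fastq, or <prefix>_1/_2.fastq if paired.

    Read names encode the origin fragment so ground truth is
    recoverable without auxiliary files.  Raises if a read is missing
    its mate in paired mode.
    """
    prefix = Path(path_prefix)
    if paired:
        paths = (prefix.parent / f"{prefix.name}_1.fastq",
                 prefix.parent / f"{prefix.name}_2.fastq")
        with open(paths[0], "w") as f1, open(paths[1], "w") as f2:
            for read in reads:
                if read.seq2 is None:
                    raise ValueError(f"read {read.name} lacks mate 2 in paired mode")
                f1.write(f"@{read.name}/1\n{read.seq1}\n+\n{read.qual1}\n")
                f2.write(f"@{read.name}/2\n{read.seq2}\n+\n{read.qual2}\n")
        return paths
    path = prefix.parent / f"{prefix.name}.fastq"
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.seq1}\n+\n{read.qual1}\n")
    return (path,)


def iter_alignments(
    path: PathLike,
    min_mapq: int = 0,
    region: Optional[str] = None,
) -> Iterator[AlnRecord]:
    """Stream mapped primary alignments from a SAM/BAM file as AlnRecords.

    Secondary/supplementary/unmapped records are skipped; records below
    ``min_mapq`` are skipped.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        it = af.fetch(region=region) if region else af
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            yield AlnRecord(
                chrom=rec.reference_name,
                pos=rec.reference_start,
                is_reverse=rec.is_reverse,
                is_duplicate=rec.is_duplicate,
                is_proper_pair=rec.is_proper_pair,
                template_len=rec.template_length,
                mapq=rec.mapping_quality,
            )
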