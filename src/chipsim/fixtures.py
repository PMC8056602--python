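"""Deterministic toy data: random references and structured peak sets.

Every test and demo runs from generated data, never a download.  Two
presets mirror the two broad experiment classes: transcription factors
(many short peaks, ~200 bp) and histone modifications (fewer broad
domains, ~2 kb).  The uniform-random reference carries no repeat
structure; the simulator never maps reads, so mappability is out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .io_formats import Peak, write_peaks
from .model_params import ChipModel

__all__ = ["ToySpec", "make_reference", "make_peaks", "tf_spec", "hm_spec",
           "default_model", "write_fasta"]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ToySpec:
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.5
    n_peaks: int = 50
    peak_length: Tuple[int, int] = (150, 300)  # (min, max) bp
    score_dist: str = "constant"  # "constant" | "uniform"
    score_value: float = 1.0  # constant score, or upper bound if uniform
    score_min: float = 0.2  # lower bound for the uniform score draw
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.peak_length[0] < 1 or self.peak_length[1] < self.peak_length[0]:
            raise ValueError("invalid peak_length range")
        if self.score_dist not in ("constant", "uniform"):
            raise ValueError("score_dist must be 'constant' or 'uniform'")


def tf_spec(seed: int = 0, chrom_length: int = 1_000_000) -> ToySpec:
    """Transcription-factor preset: many short (~200 bp) peaks."""
    return ToySpec(
        chrom_length=chrom_length,
        n_peaks=max(10, chrom_length // 20_000),
        peak_length=(150, 300),
        seed=seed,
    )


def hm_spec(seed: int = 0, chrom_length: int = 1_000_000) -> ToySpec:
    """Histone-modification preset: fewer broad (~2 kb) domains."""
    return ToySpec(
        chrom_length=chrom_length,
        n_peaks=max(5, chrom_length // 40_000),
        peak_length=(1500, 2500),
        seed=seed,
    )


def default_model(preset: str = "tf") -> ChipModel:
    """Hand-set model typical of a clean experiment of either class."""
    if preset == "tf":
        return ChipModel(frag_shape=4.0, frag_scale=50.0, f=0.005, s=0.4, pcr_p=0.85)
    if preset == "hm":
        return ChipModel(frag_shape=4.0, frag_scale=50.0, f=0.05, s=0.5, pcr_p=0.85)
    raise ValueError(f"unknown preset {preset!r}")


def make_reference(spec: ToySpec, path: Optional[PathLike] = None) -> Dict[str, str]:
    """Generate i.i.d. random chromosome sequences at the given GC fraction."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", np.uint8)
    seqs: Dict[str, str] = {}
    for i in range(spec.n_chroms):
        draw = rng.choice(alphabet, size=spec.chrom_length, p=probs)
        seqs[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    if path is not None:
        write_fasta(seqs, path)
    return seqs


def write_fasta(seqs: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_peaks(
    spec: ToySpec,
    ref_lengths: Dict[str, int],
    path: Optional[PathLike] = None,
) -> List[Peak]:
    """Place non-overlapping scored peaks uniformly along each chromosome.

    Lengths are uniform over ``spec.peak_length``; adjacent peaks keep a
    gap of at least 1 bp.  Raises when the requested peaks cannot fit.
    """
    rng = np.random.default_rng(spec.seed + 1)
    peaks: List[Peak] = []
    for chrom, L in ref_lengths.items():
        n = spec.n_peaks
        lengths = rng.integers(spec.peak_length[0], spec.peak_length[1] + 1, n)
        total = int(lengths.sum())
        free = L - total - (n + 1)  # >=1 bp gap between/around peaks
        if free < 0:
            raise ValueError(
                f"cannot pack {n} peaks totalling {total} bp into {chrom} ({L} bp)"
            )
        cuts = np.sort(rng.random(n)) * free
        gaps = np.floor(np.diff(np.concatenate([[0.0], cuts]))).astype(np.int64)
        if spec.score_dist == "constant":
            scores = np.full(n, spec.score_value)
        else:
            scores = rng.uniform(spec.score_min, spec.score_value, n)
        pos = 0
        for k in range(n):
            start = pos + int(gaps[k]) + 1
            end = start + int(lengths[k])
            peaks.append(Peak(chrom, start, end, float(scores[k])))
            pos = end
    if path is not None:
        write_peaks(peaks, path)
    return peaks
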