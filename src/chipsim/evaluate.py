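"""Desk-scale evaluation: binned read-count tracks, correlations between
tracks, peak-set precision/recall, and read-start enrichment.

Reads are counted by their 5' position.  Bins are fixed-width,
non-overlapping, per chromosome, with the final partial bin included;
a bin is labeled "peak" when it overlaps at least one input peak by
one or more bases, otherwise "background".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.stats

from .io_formats import Peak, merge_peaks

__all__ = [
    "BinTrack",
    "bin_counts",
    "track_correlation",
    "score_peak_recovery",
    "read_start_enrichment",
]

Positions = Union[Dict[str, np.ndarray], Iterable[Tuple[str, int]]]


@dataclass
class BinTrack:
    bin_size: int
    chroms: Tuple[str, ...]
    counts: Dict[str, np.ndarray]
    is_peak: Dict[str, np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def flat(self, subset: str = "all") -> np.ndarray:
        vals = []
        for chrom in self.chroms:
            c = self.counts[chrom]
            if subset == "all":
                vals.append(c)
            elif subset == "peak":
                vals.append(c[self.is_peak[chrom]])
            elif subset == "background":
                vals.append(c[~self.is_peak[chrom]])
            else:
                raise ValueError(f"unknown subset {subset!r}")
        return np.concatenate(vals) if vals else np.empty(0)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for i, c in enumerate(self.counts[chrom]):
                    fh.write(f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{int(c)}\n")


def _as_position_map(positions: Positions) -> Dict[str, np.ndarray]:
    if isinstance(positions, dict):
        return {c: np.asarray(p, np.int64) for c, p in positions.items()}
    acc: Dict[str, List[int]] = {}
    for chrom, pos in positions:
        acc.setdefault(chrom, []).append(pos)
    return {c: np.asarray(p, np.int64) for c, p in acc.items()}


def bin_counts(
    positions: Positions,
    ref_lengths: Dict[str, int],
    bin_size: int,
    peaks: Sequence[Peak] = (),
) -> BinTrack:
    """Count read 5' positions in non-overlapping fixed-width bins."""
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    pos_map = _as_position_map(positions)
    merged = merge_peaks(peaks) if peaks else []
    counts: Dict[str, np.ndarray] = {}
    is_peak: Dict[str, np.ndarray] = {}
    for chrom, L in ref_lengths.items():
        nbins = max(1, -(-L // bin_size))
        pos = pos_map.get(chrom)
        if pos is None or len(pos) == 0:
            counts[chrom] = np.zeros(nbins, np.int64)
        else:
            counts[chrom] = np.bincount(pos // bin_size, minlength=nbins).astype(np.int64)
        label = np.zeros(nbins, bool)
        for p in merged:
            if p.chrom != chrom:
                continue
            first = p.start // bin_size
            last = (p.end - 1) // bin_size
            label[first : min(last + 1, nbins)] = True
        is_peak[chrom] = label
    return BinTrack(bin_size, tuple(ref_lengths), counts, is_peak)


def track_correlation(a: BinTrack, b: BinTrack, subset: str = "all") -> Tuple[float, int]:
    """Pearson correlation of two identically-binned tracks.

    Returns (r, n_bins) over the selected bin subset ("peak",
    "background" or "all").  Requires identical binning, >= 3 bins in
    the subset, and non-constant counts.
    """
    if a.bin_size != b.bin_size or a.chroms != b.chroms:
        raise ValueError("tracks are binned differently")
    for chrom in a.chroms:
        if len(a.counts[chrom]) != len(b.counts[chrom]):
            raise ValueError(f"tracks disagree on bin count for {chrom}")
    x, y = a.flat(subset), b.flat(subset)
    if len(x) < 3:
        raise ValueError(f"need >= 3 bins in subset {subset!r}, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant track: correlation undefined")
    r, _ = scipy.stats.pearsonr(x.astype(float), y.astype(float))
    return float(r), int(len(x))


def _overlaps_any(p: Peak, others: Sequence[Peak]) -> bool:
    starts = np.array([o.start for o in others if o.chrom == p.chrom], np.int64)
    ends = np.array([o.end for o in others if o.chrom == p.chrom], np.int64)
    if len(starts) == 0:
        return False
    return bool(np.any((starts < p.end) & (ends > p.start)))


def score_peak_recovery(
    truth: Sequence[Peak], called: Sequence[Peak]
) -> Tuple[float, float, float]:
    """Precision / recall / F1 of a called peak set against ground truth.

    A truth peak is recovered when at least one called peak overlaps it
    (>= 1 bp); a called peak is correct when it overlaps at least one
    truth peak.  Both sets are merged internally first.  F1 is 0 when
    precision and recall are both 0; an empty called set scores (0,0,0).
    """
    if not truth:
        raise ValueError("empty truth peak set")
    truth_m = merge_peaks(truth)
    called_m = merge_peaks(called) if called else []
    if not called_m:
        return (0.0, 0.0, 0.0)
    recovered = sum(_overlaps_any(t, called_m) for t in truth_m)
    correct = sum(_overlaps_any(c, truth_m) for c in called_m)
    recall = recovered / len(truth_m)
    precision = correct / len(called_m)
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return (float(precision), float(recall), float(f1))


def read_start_enrichment(
    positions: Positions,
    peaks: Sequence[Peak],
    ref_lengths: Dict[str, int],
    flank_exclude: int = 1500,
) -> Dict[str, float]:
    """Per-base read-start density in peaks versus background.

    Background excludes a ``flank_exclude``-bp margin around every peak
    because fragments spanning a peak edge deposit read starts just
    outside it; with the flank excluded the density ratio is an
    unbiased empirical estimate of the pulldown enrichment ratio alpha
    when peak scores are 1.
    """
    pos_map = _as_position_map(positions)
    merged = merge_peaks(peaks)
    if not merged:
        raise ValueError("no peaks for enrichment measurement")
    peak_bp = bg_bp = 0
    n_peak = n_bg = 0
    n_total = 0
    for chrom, L in ref_lengths.items():
        segs = [p for p in merged if p.chrom == chrom]
        starts = np.array([p.start for p in segs], np.int64)
        ends = np.array([p.end for p in segs], np.int64)
        peak_bp += int((ends - starts).sum())
        # union of the excluded (peak + flank) zones
        z_starts: List[int] = []
        z_ends: List[int] = []
        for s, e in zip(starts - flank_exclude, ends + flank_exclude):
            s, e = max(int(s), 0), min(int(e), L)
            if z_ends and s <= z_ends[-1]:
                z_ends[-1] = max(z_ends[-1], e)
            else:
                z_starts.append(s)
                z_ends.append(e)
        zs = np.asarray(z_starts, np.int64)
        ze = np.asarray(z_ends, np.int64)
        bg_bp += L - int((ze - zs).sum())
        pos = pos_map.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        n_total += len(pos)
        if len(segs):
            k = np.searchsorted(ends, pos, side="right")
            kc = np.minimum(k, len(starts) - 1)
            in_peak = (starts[kc] <= pos) & (pos < ends[kc])
            kz = np.minimum(np.searchsorted(ze, pos, side="right"), len(zs) - 1)
            in_zone = (zs[kz] <= pos) & (pos < ze[kz])
            n_peak += int(in_peak.sum())
            n_bg += int((~in_zone).sum())
        else:
            n_bg += len(pos)
    if peak_bp == 0 or bg_bp <= 0:
        raise ValueError("degenerate peak/background partition")
    peak_density = n_peak / peak_bp
    bg_density = n_bg / bg_bp
    return {
        "peak_density": peak_density,
        "background_density": bg_density,
        "ratio": peak_density / bg_density if bg_density > 0 else float("inf"),
        "n_peak_reads": float(n_peak),
        "n_background_reads": float(n_bg),
        "n_reads": float(n_total),
    }
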