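"""Infer every model parameter from an existing experiment.

Given aligned reads plus a peak set the learners recover:

* the gamma fragment-length distribution — maximum likelihood on
  |template length| from proper pairs, or a strand cross-correlation
  heuristic for single-end data;
* ``f`` — score-weighted fraction of the genome covered by peaks;
* ``s`` — fraction of non-duplicate reads anchored inside peaks
  (the SPOT/FRIP score);
* ``p`` — from the PCR-duplicate histogram as ``p = 1/n_bar`` where
  ``n_bar = sum(i * n_i) / sum(n_i)`` and ``n_i`` counts fragments
  observed ``i`` times (the original included).

Sequencing error rates are user-set; no estimator is provided.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.signal
import scipy.stats

from .io_formats import AlnRecord, Peak, merge_peaks
from .model_params import ChipModel

__all__ = [
    "DuplicateHistogram",
    "fit_fragment_gamma",
    "estimate_fraglen_single_end",
    "estimate_pcr_p",
    "build_duplicate_histogram",
    "estimate_f",
    "estimate_s",
    "learn_all",
]

EPSILON = 1e-6  # clip f and s away from {0, 1} so alpha stays finite
MIN_GAMMA_OBS = 50
DEFAULT_SINGLE_END_SHAPE = 5.0
MAX_SHIFT = 1500


@dataclass(frozen=True)
class DuplicateHistogram:
    """counts[i] = number of distinct fragments observed i times."""

    counts: Dict[int, int]

    def __post_init__(self) -> None:
        if any(i < 1 for i in self.counts):
            raise ValueError("multiplicities must be >= 1")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("histogram counts must be >= 0")

    @property
    def n_fragments(self) -> int:
        return sum(self.counts.values())

    @property
    def n_reads(self) -> int:
        return sum(i * n for i, n in self.counts.items())


def fit_fragment_gamma(lengths: Sequence[float]) -> Tuple[float, float]:
    """Maximum-likelihood gamma fit (shape, scale) of fragment lengths.

    Lengths are |template length| from proper pairs, one per pair.
    Zero or negative entries are rejected, at least ``MIN_GAMMA_OBS``
    observations are required, and an all-identical sample (variance 0)
    is a degenerate fit and raises.
    """
    arr = np.asarray(lengths, float)
    bad = int((arr <= 0).sum())
    if bad:
        raise ValueError(f"{bad} non-positive fragment lengths; remove before fitting")
    if len(arr) < MIN_GAMMA_OBS:
        raise ValueError(
            f"need >= {MIN_GAMMA_OBS} fragment lengths for a gamma fit, got {len(arr)}"
        )
    if np.var(arr) == 0:
        raise ValueError("all fragment lengths identical; gamma fit is degenerate")
    shape, _, scale = scipy.stats.gamma.fit(arr, floc=0)
    return float(shape), float(scale)


def estimate_pcr_p(hist: DuplicateHistogram) -> float:
    """PCR no-duplicate probability p = 1 / n_bar.

    ``n_bar`` is the mean multiplicity over distinct fragments; p = 1
    exactly when no fragment has any duplicate.
    """
    total = hist.n_fragments
    if total == 0:
        raise ValueError("empty duplicate histogram")
    n_bar = hist.n_reads / total
    return 1.0 / n_bar


def build_duplicate_histogram(
    records: Iterable[AlnRecord], paired: bool = False
) -> DuplicateHistogram:
    """Group fragments sharing coordinates into a multiplicity histogram.

    Duplicate keys follow Picard semantics: (chrom, leftmost position,
    strand) for single-end records and (chrom, leftmost position,
    template length) for paired records, counted once per pair via the
    leftmost mate (positive template length).
    """
    counter: Counter = Counter()
    for rec in records:
        if paired:
            if not rec.is_proper_pair or rec.template_len <= 0:
                continue
            counter[(rec.chrom, rec.pos, rec.template_len)] += 1
        else:
            counter[(rec.chrom, rec.pos, rec.is_reverse)] += 1
    hist: Counter = Counter(counter.values())
    return DuplicateHistogram(dict(hist))


def estimate_f(peaks: Sequence[Peak], genome_length: int) -> float:
    """Bound genome fraction: score-weighted merged peak length / genome.

    Overlaps are resolved per-base at the maximum score first, so the
    estimate is invariant to redundant peak entries.
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be > 0, got {genome_length}")
    if not peaks:
        raise ValueError("empty peak list: f = 0 leaves alpha undefined")
    merged = merge_peaks(peaks)
    weighted = sum(len(p) * p.score for p in merged)
    return float(np.clip(weighted / genome_length, EPSILON, 1.0 - EPSILON))


def _dedupe(records: List[AlnRecord], paired: bool) -> List[AlnRecord]:
    """One record per duplicate group (flags honored when present)."""
    if any(r.is_duplicate for r in records):
        return [r for r in records if not r.is_duplicate]
    seen = set()
    out = []
    for rec in records:
        key = (
            (rec.chrom, rec.pos, rec.template_len)
            if paired
            else (rec.chrom, rec.pos, rec.is_reverse)
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def estimate_s(
    records: Iterable[AlnRecord],
    peaks: Sequence[Peak],
    paired: bool = False,
    min_records: int = 1000,
) -> float:
    """SPOT/FRIP score: fraction of non-duplicate reads anchored in peaks.

    Reads are anchored at their leftmost aligned coordinate; membership
    is any merged peak containing that coordinate.  The ratio is clipped
    to (EPSILON, 1-EPSILON).
    """
    if not peaks:
        raise ValueError("no peaks supplied for s estimation")
    recs = list(records)
    if paired:
        recs = [r for r in recs if r.is_proper_pair and r.template_len > 0]
    recs = _dedupe(recs, paired)
    if len(recs) < min_records:
        raise ValueError(
            f"need >= {min_records} non-duplicate records to estimate s, got {len(recs)}"
        )
    merged = merge_peaks(peaks)
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in merged}:
        segs = [p for p in merged if p.chrom == chrom]
        by_chrom[chrom] = (
            np.array([p.start for p in segs], np.int64),
            np.array([p.end for p in segs], np.int64),
        )
    n_in = 0
    for rec in recs:
        segs = by_chrom.get(rec.chrom)
        if segs is None:
            continue
        starts, ends = segs
        k = int(np.searchsorted(ends, rec.pos, side="right"))
        if k < len(starts) and starts[k] <= rec.pos:
            n_in += 1
    return float(np.clip(n_in / len(recs), EPSILON, 1.0 - EPSILON))


def estimate_fraglen_single_end(
    records: Iterable[AlnRecord],
    ref_lengths: Dict[str, int],
    readlen: int,
    max_shift: int = MAX_SHIFT,
) -> float:
    """Mean fragment length from single-end data by strand cross-correlation.

    Forward-read and reverse-read 5' coverage profiles are shifted
    copies of each other, offset by roughly the mean fragment length;
    the estimate is the shift ``d`` in ``[readlen+1, max_shift]`` that
    maximizes their Pearson correlation.  Shifts at or below ``readlen``
    belong to the phantom (read-length) peak and are excluded.
    """
    fwd: Dict[str, List[int]] = {}
    rev: Dict[str, List[int]] = {}
    n_records = 0
    for rec in records:
        n_records += 1
        if rec.is_duplicate:
            continue
        if rec.is_reverse:
            rev.setdefault(rec.chrom, []).append(rec.pos + readlen - 1)
        else:
            fwd.setdefault(rec.chrom, []).append(rec.pos)
    chroms = [
        c for c in ref_lengths
        if len(fwd.get(c, ())) + len(rev.get(c, ())) >= 1000
    ]
    if not chroms:
        raise ValueError("need at least one chromosome with >= 1000 reads")
    if not any(fwd.get(c) for c in chroms) or not any(rev.get(c) for c in chroms):
        raise ValueError("reads on only one strand; cannot cross-correlate")
    shifts = np.arange(readlen + 1, max_shift + 1)
    num = np.zeros(len(shifts))
    n_pairs = 0.0
    sum_f = sum_r = sum_f2 = sum_r2 = 0.0
    for chrom in chroms:
        L = ref_lengths[chrom]
        fv = np.bincount(
            np.clip(np.asarray(fwd.get(chrom, []), np.int64), 0, L - 1), minlength=L
        ).astype(float)
        rv = np.bincount(
            np.clip(np.asarray(rev.get(chrom, []), np.int64), 0, L - 1), minlength=L
        ).astype(float)
        # cross-correlation of the full profiles via FFT
        cc = scipy.signal.fftconvolve(rv, fv[::-1])
        center = L - 1
        lo = center + shifts[0]
        num += cc[lo : lo + len(shifts)]
        n_pairs += L
        sum_f += fv.sum()
        sum_r += rv.sum()
        sum_f2 += (fv**2).sum()
        sum_r2 += (rv**2).sum()
    mean_f, mean_r = sum_f / n_pairs, sum_r / n_pairs
    var_f = sum_f2 / n_pairs - mean_f**2
    var_r = sum_r2 / n_pairs - mean_r**2
    if var_f <= 0 or var_r <= 0:
        raise ValueError("degenerate coverage profile; cannot cross-correlate")
    r = (num / n_pairs - mean_f * mean_r) / np.sqrt(var_f * var_r)
    # per-shift correlations are noisy; smooth with a narrow triangular
    # kernel (preserves a unique peak location) before taking the argmax
    win = np.bartlett(31)
    win /= win.sum()
    r = np.convolve(np.pad(r, 15, mode="edge"), win, mode="valid")
    best = int(np.argmax(r))
    if r[best] <= 0:
        raise ValueError(
            "no cross-correlation peak beyond the read-length shift; "
            "use paired-end data to estimate the fragment length"
        )
    return float(shifts[best])


def learn_all(
    records: Iterable[AlnRecord],
    peaks: Sequence[Peak],
    ref_lengths: Dict[str, int],
    paired: bool,
    readlen: Optional[int] = None,
    min_mapq: int = 10,
    single_end_shape: float = DEFAULT_SINGLE_END_SHAPE,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
) -> Tuple[ChipModel, Dict[str, object]]:
    """Compose all estimators into a validated model.

    Returns the model plus a report with the input counts behind each
    estimate.  Records below ``min_mapq`` are excluded everywhere.
    Paired mode falls back to the single-end heuristic (with a warning)
    when no proper pairs are present; the heuristic then needs
    ``readlen``.
    """
    recs = [r for r in records if r.mapq >= min_mapq]
    if not recs:
        raise ValueError("no alignment records pass the MAPQ filter")
    aln_chroms = {r.chrom for r in recs}
    used_peaks = [p for p in peaks if p.chrom in aln_chroms]
    if len(used_peaks) < len(peaks):
        warnings.warn(
            f"ignoring {len(peaks) - len(used_peaks)} peaks on chromosomes "
            "absent from the alignments",
            stacklevel=2,
        )
    report: Dict[str, object] = {"n_records": len(recs), "n_peaks": len(used_peaks)}

    tlens = [r.template_len for r in recs if r.is_proper_pair and r.template_len > 0]
    used_paired = paired and len(tlens) >= MIN_GAMMA_OBS
    if paired and not used_paired:
        warnings.warn(
            "paired mode requested but no (or too few) proper pairs found; "
            "falling back to the single-end fragment-length heuristic",
            stacklevel=2,
        )
    if used_paired:
        shape, scale = fit_fragment_gamma(tlens)
        report["fraglen_method"] = "paired_mle"
        report["n_fragment_lengths"] = len(tlens)
    else:
        if readlen is None:
            raise ValueError("single-end fragment-length heuristic requires readlen")
        mean = estimate_fraglen_single_end(recs, ref_lengths, readlen)
        shape = single_end_shape
        scale = mean / shape
        report["fraglen_method"] = "single_end_cross_correlation (approximate)"
        report["estimated_fragment_mean"] = mean

    genome_length = sum(ref_lengths.values())
    f = estimate_f(used_peaks, genome_length)
    s = estimate_s(recs, used_peaks, paired=used_paired)
    hist = build_duplicate_histogram(recs, paired=used_paired)
    p = estimate_pcr_p(hist)
    report.update(
        {
            "genome_length": genome_length,
            "n_distinct_fragments": hist.n_fragments,
            "duplicate_histogram_head": dict(
                sorted(hist.counts.items())[:10]
            ),
        }
    )
    model = ChipModel(
        frag_shape=shape,
        frag_scale=scale,
        f=f,
        s=s,
        pcr_p=min(1.0, p),
        sub_rate=sub_rate,
        ins_rate=ins_rate,
        del_rate=del_rate,
    )
    report.update(
        {
            "frag_shape": shape,
            "frag_scale": scale,
            "frag_mean": shape * scale,
            "f": f,
            "s": s,
            "pcr_p": model.pcr_p,
            "alpha": model.alpha,
        }
    )
    return model, report
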