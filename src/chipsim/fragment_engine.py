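"""Generative core: shearing, binding assignment, pulldown, PCR.

The engine works on columnar fragment sets (:class:`FragmentArray`) so
that tens of millions of fragments per run stay cheap; a record-level
:class:`Fragment` view is provided for small-scale inspection.

Model summary
-------------
* Shearing: each simulation round (genome copy) tiles every chromosome
  with consecutive fragments of i.i.d. gamma(shape, scale) length,
  starting at a random per-copy offset so copies do not share cut sites.
* Binding: a fragment overlapping a peak (>= 1 bp) is bound with
  probability equal to the maximum score of the peaks it overlaps.
* Pulldown: weighted sampling without replacement where bound fragments
  carry weight ``alpha`` and unbound fragments weight 1, implemented as
  systematic probability-proportional-to-size sampling so that
  inclusion probabilities are exactly proportional to the weights
  (capped at 1) and exactly ``n_target`` fragments are drawn.
* PCR: each pulled fragment is emitted ``i`` times with
  ``i ~ Geometric(p)`` on {1, 2, ...}; ``p`` is the probability of no
  duplicates and the mean multiplicity is ``1/p``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterator, List, NamedTuple, Sequence, Tuple

import numpy as np

from .io_formats import Peak, merge_peaks

__all__ = [
    "Fragment",
    "FragmentArray",
    "shear_copy",
    "shear_genome",
    "assign_binding",
    "pulldown_sample",
    "pcr_amplify",
]


class Fragment(NamedTuple):
    chrom: str
    start: int
    end: int
    bound: bool = False
    copy_index: int = 0


@dataclass
class FragmentArray:
    """Columnar set of fragments over a fixed chromosome list."""

    chroms: Tuple[str, ...]
    chrom_ids: np.ndarray  # int32, index into chroms
    starts: np.ndarray  # int64, 0-based inclusive
    ends: np.ndarray  # int64, exclusive
    bound: np.ndarray  # bool
    copy_index: np.ndarray  # int32

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def take(self, idx: np.ndarray) -> "FragmentArray":
        return FragmentArray(
            self.chroms,
            self.chrom_ids[idx],
            self.starts[idx],
            self.ends[idx],
            self.bound[idx],
            self.copy_index[idx],
        )

    @classmethod
    def empty(cls, chroms: Sequence[str]) -> "FragmentArray":
        return cls(
            tuple(chroms),
            np.empty(0, np.int32),
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            np.empty(0, bool),
            np.empty(0, np.int32),
        )

    @classmethod
    def concatenate(cls, parts: Sequence["FragmentArray"]) -> "FragmentArray":
        chroms = parts[0].chroms
        for p in parts[1:]:
            if p.chroms != chroms:
                raise ValueError("cannot concatenate FragmentArrays over different chromosome lists")
        return cls(
            chroms,
            np.concatenate([p.chrom_ids for p in parts]),
            np.concatenate([p.starts for p in parts]),
            np.concatenate([p.ends for p in parts]),
            np.concatenate([p.bound for p in parts]),
            np.concatenate([p.copy_index for p in parts]),
        )

    def __iter__(self) -> Iterator[Fragment]:
        for cid, st, en, b, cp in zip(
            self.chrom_ids, self.starts, self.ends, self.bound, self.copy_index
        ):
            yield Fragment(self.chroms[cid], int(st), int(en), bool(b), int(cp))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.floor(x + 0.5), 1.0)


def shear_copy(
    ref_lengths: Dict[str, int],
    frag_shape: float,
    frag_scale: float,
    rng: np.random.Generator,
    copy_index: int = 0,
    min_final_len: int = 1,
) -> FragmentArray:
    """Shear one genome copy into consecutive gamma-length fragments.

    Per chromosome of length L the tiling starts at a uniform offset
    ``u ~ U[0, min(mean, L))`` and fragments partition ``[u, L)``
    without gaps or overlaps; the final fragment is truncated at L and
    dropped when shorter than ``min_final_len``.
    """
    if frag_shape <= 0 or frag_scale <= 0:
        raise ValueError("gamma shape and scale must be > 0")
    mean = frag_shape * frag_scale
    chroms = tuple(ref_lengths)
    per_chrom: List[FragmentArray] = []
    for cid, chrom in enumerate(chroms):
        L = ref_lengths[chrom]
        u = int(rng.uniform(0, min(mean, L)))
        lens: List[np.ndarray] = []
        covered = 0.0
        need = L - u
        while covered < need:
            n = max(16, int((need - covered) / mean * 1.2) + 8)
            block = _round_half_up(rng.gamma(frag_shape, frag_scale, n))
            lens.append(block)
            covered += block.sum()
        lengths = np.concatenate(lens)
        cum = np.cumsum(lengths)
        n_keep = int(np.searchsorted(cum, need, side="left")) + 1
        lengths = lengths[:n_keep]
        cum = cum[:n_keep]
        starts = (u + cum - lengths).astype(np.int64)
        ends = np.minimum(u + cum, L).astype(np.int64)
        keep = ends - starts >= 1
        # final-fragment rule: the truncated tail is kept only if long enough
        if keep.any() and ends[-1] - starts[-1] < min_final_len:
            keep[-1] = False
        starts, ends = starts[keep], ends[keep]
        per_chrom.append(
            FragmentArray(
                chroms,
                np.full(len(starts), cid, np.int32),
                starts,
                ends,
                np.zeros(len(starts), bool),
                np.full(len(starts), copy_index, np.int32),
            )
        )
    return FragmentArray.concatenate(per_chrom) if per_chrom else FragmentArray.empty(chroms)


def shear_genome(
    ref_lengths: Dict[str, int],
    frag_shape: float,
    frag_scale: float,
    numcopies: int,
    rng: np.random.Generator,
    min_final_len: int = 1,
) -> FragmentArray:
    """Shear ``numcopies`` genome copies (vectorized across copies)."""
    if frag_shape <= 0 or frag_scale <= 0:
        raise ValueError("gamma shape and scale must be > 0")
    mean = frag_shape * frag_scale
    chroms = tuple(ref_lengths)
    parts: List[FragmentArray] = []
    for cid, chrom in enumerate(chroms):
        L = ref_lengths[chrom]
        exp_n = L / mean
        # enough draws per copy that the tiling reaches L w.h.p.;
        # rows that fall short are redone with the scalar path
        m = int(exp_n + 10.0 * math.sqrt(max(exp_n, 1.0) / frag_shape) + 16)
        block_rows = max(1, int(2.5e7 // m))
        for row0 in range(0, numcopies, block_rows):
            rows = min(block_rows, numcopies - row0)
            lens = _round_half_up(rng.gamma(frag_shape, frag_scale, (rows, m)))
            cum = np.cumsum(lens, axis=1)
            u = np.floor(rng.uniform(0, min(mean, L), rows))
            starts = u[:, None] + cum - lens
            ends = np.minimum(u[:, None] + cum, L)
            short_rows = np.nonzero(cum[:, -1] < (L - u))[0]
            keep = (starts < L) & (ends - starts >= 1)
            # final-fragment rule per row
            fin = np.argmax(ends >= L, axis=1)
            row_idx = np.arange(rows)
            reached = ends[row_idx, fin] >= L
            fin_len = ends[row_idx, fin] - starts[row_idx, fin]
            drop_fin = reached & (fin_len < min_final_len)
            keep[row_idx[drop_fin], fin[drop_fin]] = False
            keep[np.isin(row_idx, short_rows)] = False
            r, c = np.nonzero(keep)
            parts.append(
                FragmentArray(
                    chroms,
                    np.full(len(r), cid, np.int32),
                    starts[r, c].astype(np.int64),
                    ends[r, c].astype(np.int64),
                    np.zeros(len(r), bool),
                    (row0 + r).astype(np.int32),
                )
            )
            for sr in short_rows:  # rare fallback
                one = shear_copy(
                    {chrom: L}, frag_shape, frag_scale, rng, int(row0 + sr), min_final_len
                )
                parts.append(
                    FragmentArray(
                        chroms,
                        np.full(len(one), cid, np.int32),
                        one.starts,
                        one.ends,
                        one.bound,
                        one.copy_index,
                    )
                )
    return FragmentArray.concatenate(parts) if parts else FragmentArray.empty(chroms)


def assign_binding(
    frags: FragmentArray, peaks: Sequence[Peak], rng: np.random.Generator
) -> FragmentArray:
    """Set bound flags: P(bound) = max score of overlapped peaks (else 0).

    Overlap is any-overlap (>= 1 bp).  Returns the same FragmentArray
    with ``bound`` replaced.
    """
    bound = np.zeros(len(frags), bool)
    segments = merge_peaks(peaks)
    by_chrom: Dict[str, List[Peak]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for cid, chrom in enumerate(frags.chroms):
        segs = by_chrom.get(chrom)
        if not segs:
            continue
        seg_start = np.array([s.start for s in segs], np.int64)
        seg_end = np.array([s.end for s in segs], np.int64)
        seg_score = np.array([s.score for s in segs])
        mask = frags.chrom_ids == cid
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        fs, fe = frags.starts[idx], frags.ends[idx]
        # first segment ending after the fragment start
        lo = np.searchsorted(seg_end, fs, side="right")
        hi = np.searchsorted(seg_start, fe, side="left")  # segs before fragment end
        overlaps = lo < hi
        oidx = idx[overlaps]
        if len(oidx) == 0:
            continue
        lo_o, hi_o = lo[overlaps], hi[overlaps]
        prob = seg_score[lo_o]  # covers the common single-segment case
        multi = np.nonzero(hi_o - lo_o > 1)[0]
        for k in multi:
            prob[k] = seg_score[lo_o[k] : hi_o[k]].max()
        bound[oidx] = rng.random(len(oidx)) < prob
    frags.bound = bound
    return frags


def _pps_inclusion(weights: np.ndarray, n: int) -> np.ndarray:
    """Inclusion probabilities pi_i = min(1, c*w_i) with sum(pi) == n."""
    pi = np.zeros(len(weights))
    active = np.ones(len(weights), bool)
    remaining = n
    while True:
        wsum = weights[active].sum()
        if wsum <= 0 or remaining <= 0:
            break
        c = remaining / wsum
        over = active & (weights * c >= 1.0)
        if not over.any():
            pi[active] = weights[active] * c
            break
        pi[over] = 1.0
        active &= ~over
        remaining = n - int(round(pi[~active].sum()))
    return pi


def _pps_systematic(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Systematic PPS draw of exactly n indices, P(include i) = pi_i."""
    N = len(weights)
    if n >= N:
        return np.arange(N)
    perm = rng.permutation(N)
    pi = _pps_inclusion(weights[perm], n)
    certain = pi >= 1.0
    rest = ~certain
    n_rest = n - int(certain.sum())
    chosen = [perm[certain]]
    if n_rest > 0:
        cum = np.cumsum(pi[rest])
        points = rng.uniform(0, 1) + np.arange(n_rest)
        picks = np.searchsorted(cum, points, side="right")
        picks = np.minimum(picks, len(cum) - 1)
        chosen.append(perm[np.nonzero(rest)[0][picks]])
    return np.concatenate(chosen)


def pulldown_sample(
    frags: FragmentArray,
    alpha: float,
    n_target: int,
    rng: np.random.Generator,
) -> FragmentArray:
    """Immunoprecipitation: select ``n_target`` fragments without replacement.

    Bound fragments carry weight ``alpha``, unbound weight 1, so the
    expected selected-bound fraction is
    ``alpha*f_pool / (alpha*f_pool + 1 - f_pool)`` while inclusion
    probabilities stay proportional to the weights.  If the pool is
    smaller than ``n_target`` all fragments are returned with a warning
    (raise ``numcopies`` to enlarge the pool).
    """
    if len(frags) == 0:
        raise ValueError("empty fragment pool — increase numcopies or check inputs")
    if n_target < 1:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if n_target >= len(frags):
        if n_target > len(frags):
            warnings.warn(
                f"fragment pool ({len(frags)}) smaller than pulldown target "
                f"({n_target}); returning all fragments — increase numcopies",
                stacklevel=2,
            )
        return frags.take(np.arange(len(frags)))
    weights = np.where(frags.bound, float(alpha), 1.0)
    idx = _pps_systematic(weights, n_target, rng)
    return frags.take(idx)


def pcr_amplify(
    frags: FragmentArray,
    pcr_p: float,
    rng: np.random.Generator,
) -> Tuple[FragmentArray, np.ndarray]:
    """PCR: emit each fragment i times, i ~ Geometric(pcr_p) on {1, 2, ...}.

    Returns the amplified fragments and the origin index array mapping
    each emitted fragment back to its row in ``frags`` (PCR duplicates
    share an origin index).  ``pcr_p == 1`` reproduces the input.
    """
    if not (0.0 < pcr_p <= 1.0):
        raise ValueError(f"pcr_p must be in (0, 1], got {pcr_p}")
    n = len(frags)
    if pcr_p == 1.0:
        origin = np.arange(n)
        return frags.take(origin), origin
    mult = rng.geometric(pcr_p, n)
    origin = np.repeat(np.arange(n), mult)
    return frags.take(origin), origin
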