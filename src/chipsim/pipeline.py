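"""End-to-end simulation: shear -> bind -> pulldown -> PCR -> sequence.

``simulate_placements`` runs the fragment-level model and returns the
genomic placement of every emitted read; ``simulate_reads`` additionally
generates base sequences.  Splitting the two keeps position-level
analyses (binned counts, learning round-trips) cheap — no base strings
are materialized unless FASTQ output is wanted.

A single user seed is expanded into independent per-stage streams
(shear / bind / pulldown / PCR / sequence) so a change in one stage's
logic does not perturb the draws of the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fragment_engine import (
    FragmentArray,
    assign_binding,
    pcr_amplify,
    pulldown_sample,
    shear_genome,
)
from .io_formats import Peak, SimRead, merge_peaks
from .model_params import ChipModel, ExperimentParams
from .sequencer import SeqStats, sequence_placements

__all__ = ["ReadPlacements", "SimSummary", "simulate_placements", "simulate_reads",
           "as_alignment_records", "stage_rngs"]


def stage_rngs(seed: int, n: int = 6) -> List[np.random.Generator]:
    """Expand one seed into independent per-stage generators.

    Stages: shear, bind, pulldown, PCR, strand choice, sequencing.
    """
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ReadPlacements:
    """Genomic origin of each emitted read (pair): columnar arrays."""

    chroms: Tuple[str, ...]
    chrom_ids: np.ndarray
    starts: np.ndarray  # fragment start
    ends: np.ndarray  # fragment end
    bound: np.ndarray
    copy_index: np.ndarray
    is_reverse: np.ndarray  # single-end strand; False throughout for paired
    origin_id: np.ndarray  # distinct-fragment id; PCR duplicates share it

    def __len__(self) -> int:
        return len(self.starts)

    def read5_positions(self, readlen: int, paired: bool) -> Tuple[np.ndarray, np.ndarray]:
        """(chrom_ids, positions) of read 5' anchors.

        Paired reads are anchored at the fragment start (leftmost mate);
        single-end reverse reads at the last fragment base.
        """
        if paired:
            return self.chrom_ids, self.starts
        pos = np.where(self.is_reverse, self.ends - 1, self.starts)
        return self.chrom_ids, pos


@dataclass
class SimSummary:
    fragments_total: int = 0
    dropped_short: int = 0
    dropped_n_rich: int = 0
    pool_size: int = 0
    pool_bound: int = 0
    n_selected: int = 0
    n_reads: int = 0
    topup_passes: int = 0
    bound_read_fraction: float = 0.0
    frip: float = 0.0
    seq_stats: Optional[SeqStats] = None


def _n_fraction(frags: FragmentArray, reference: Dict[str, str]) -> np.ndarray:
    """Fraction of N bases per fragment, via per-chrom prefix sums."""
    frac = np.zeros(len(frags))
    for cid, chrom in enumerate(frags.chroms):
        seq = reference.get(chrom)
        if seq is None:
            continue
        arr = np.frombuffer(seq.encode("ascii"), np.uint8)
        if not (arr == ord("N")).any():
            continue
        csum = np.concatenate([[0], np.cumsum(arr == ord("N"))])
        mask = frags.chrom_ids == cid
        idx = np.nonzero(mask)[0]
        n_in = csum[frags.ends[idx]] - csum[frags.starts[idx]]
        frac[idx] = n_in / (frags.ends[idx] - frags.starts[idx])
    return frac


def _frip(placements: ReadPlacements, peaks: Sequence[Peak], readlen: int, paired: bool) -> float:
    merged = merge_peaks(peaks)
    cids, pos = placements.read5_positions(readlen, paired)
    inside = np.zeros(len(pos), bool)
    for cid, chrom in enumerate(placements.chroms):
        segs = [s for s in merged if s.chrom == chrom]
        if not segs:
            continue
        starts = np.array([s.start for s in segs], np.int64)
        ends = np.array([s.end for s in segs], np.int64)
        m = cids == cid
        k = np.searchsorted(ends, pos[m], side="right")
        ok = (k < len(starts)) & (starts[np.minimum(k, len(starts) - 1)] <= pos[m])
        inside[np.nonzero(m)[0]] = ok
    return float(inside.mean()) if len(pos) else 0.0


def simulate_placements(
    ref_lengths: Dict[str, int],
    peaks: Sequence[Peak],
    model: ChipModel,
    params: ExperimentParams,
    reference: Optional[Dict[str, str]] = None,
    max_n_fraction: float = 0.5,
) -> Tuple[ReadPlacements, SimSummary]:
    """Run the fragment-level pipeline and place exactly ``numreads`` reads.

    The pulldown target is ``numreads * pcr_p`` distinct fragments so the
    geometric PCR step lands near ``numreads`` in expectation; surplus is
    randomly truncated and a deficit is topped up with extra pulldown
    passes over the remaining pool.
    """
    rng_shear, rng_bind, rng_pull, rng_pcr, rng_strand, _ = stage_rngs(params.seed)
    summary = SimSummary()

    usable = {c: L for c, L in ref_lengths.items() if L >= params.readlen}
    for c in ref_lengths:
        if c not in usable:
            warnings.warn(f"chromosome {c} shorter than readlen; skipped", stacklevel=2)
    if not usable:
        raise ValueError("no chromosome is at least readlen long")

    pool = shear_genome(
        usable, model.frag_shape, model.frag_scale, params.numcopies, rng_shear,
        min_final_len=1,
    )
    summary.fragments_total = len(pool)
    long_enough = pool.lengths >= params.readlen
    summary.dropped_short = int((~long_enough).sum())
    pool = pool.take(np.nonzero(long_enough)[0])
    if reference is not None:
        nfrac = _n_fraction(pool, reference)
        ok = nfrac <= max_n_fraction
        summary.dropped_n_rich = int((~ok).sum())
        if summary.dropped_n_rich:
            pool = pool.take(np.nonzero(ok)[0])
    pool = assign_binding(pool, peaks, rng_bind)
    summary.pool_size = len(pool)
    summary.pool_bound = int(pool.bound.sum())

    alpha = model.alpha
    n_pull = max(1, int(round(params.numreads * model.pcr_p)))
    selected = pulldown_sample(pool, alpha, n_pull, rng_pull)
    # single-end strand per distinct fragment, shared by PCR duplicates
    strand = rng_strand.random(len(selected)) < 0.5
    amplified, origin = pcr_amplify(selected, model.pcr_p, rng_pcr)
    placements = ReadPlacements(
        amplified.chroms, amplified.chrom_ids, amplified.starts, amplified.ends,
        amplified.bound, amplified.copy_index, strand[origin], origin.copy(),
    )
    summary.n_selected = len(selected)

    # top-up / truncate to exactly numreads; the deficit is O(sqrt(n)) so
    # the extra passes resample from the full pool (the chance of hitting
    # an already-used fragment is negligible at these sampling fractions)
    placements_list = [placements]
    total = len(placements)
    next_origin = len(selected)
    guard = 0
    pool_exhausted = len(selected) >= len(pool)
    while total < params.numreads and not pool_exhausted and guard < 20:
        guard += 1
        summary.topup_passes += 1
        deficit = params.numreads - total
        k = max(1, int(round(deficit * model.pcr_p)))
        extra = pulldown_sample(pool, alpha, k, rng_pull)
        strand_x = rng_strand.random(len(extra)) < 0.5
        amp_x, origin_x = pcr_amplify(extra, model.pcr_p, rng_pcr)
        placements_list.append(
            ReadPlacements(
                amp_x.chroms, amp_x.chrom_ids, amp_x.starts, amp_x.ends,
                amp_x.bound, amp_x.copy_index, strand_x[origin_x],
                origin_x + next_origin,
            )
        )
        next_origin += len(extra)
        total += len(amp_x)
    if len(placements_list) > 1:
        placements = ReadPlacements(
            placements.chroms,
            *[
                np.concatenate([getattr(p, f) for p in placements_list])
                for f in ("chrom_ids", "starts", "ends", "bound", "copy_index",
                          "is_reverse", "origin_id")
            ],
        )
    if total > params.numreads:
        keep = rng_pcr.permutation(total)[: params.numreads]
        keep.sort()
        placements = ReadPlacements(
            placements.chroms,
            *[getattr(placements, f)[keep]
              for f in ("chrom_ids", "starts", "ends", "bound", "copy_index",
                        "is_reverse", "origin_id")],
        )
    elif total < params.numreads:
        warnings.warn(
            f"emitted only {total} of {params.numreads} requested reads; "
            "fragment pool exhausted — increase numcopies",
            stacklevel=2,
        )
    summary.n_reads = len(placements)
    if summary.n_reads:
        summary.bound_read_fraction = float(placements.bound.mean())
        summary.frip = _frip(placements, peaks, params.readlen, params.paired)
    return placements, summary


def simulate_reads(
    reference: Dict[str, str],
    peaks: Sequence[Peak],
    model: ChipModel,
    params: ExperimentParams,
    name_prefix: str = "chipsim",
    max_n_fraction: float = 0.5,
) -> Tuple[List[SimRead], SimSummary]:
    """Full pipeline producing sequenced reads ready for FASTQ output."""
    ref_lengths = {c: len(s) for c, s in reference.items()}
    placements, summary = simulate_placements(
        ref_lengths, peaks, model, params, reference=reference,
        max_n_fraction=max_n_fraction,
    )
    rng_seq = stage_rngs(params.seed)[5]
    reads, seq_stats = sequence_placements(
        placements, reference, params.readlen, params.paired,
        model.sub_rate, model.ins_rate, model.del_rate, rng_seq,
        name_prefix=name_prefix,
    )
    summary.seq_stats = seq_stats
    return reads, summary


def as_alignment_records(
    placements: ReadPlacements, readlen: int, paired: bool
) -> List["AlnRecord"]:
    """Convert placements into idealized alignment records.

    Emulates a perfect aligner: paired reads yield one record per pair
    (leftmost mate, positive template length), single-end reads one
    record each.  Useful for closing the simulate -> learn loop without
    an external aligner.
    """
    from .io_formats import AlnRecord

    records: List[AlnRecord] = []
    for i in range(len(placements)):
        chrom = placements.chroms[placements.chrom_ids[i]]
        start = int(placements.starts[i])
        end = int(placements.ends[i])
        if paired:
            records.append(
                AlnRecord(chrom, start, is_reverse=False, is_proper_pair=True,
                          template_len=end - start, mapq=60)
            )
        else:
            rev = bool(placements.is_reverse[i])
            pos = end - readlen if rev else start
            records.append(AlnRecord(chrom, pos, is_reverse=rev, template_len=0, mapq=60))
    return records
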