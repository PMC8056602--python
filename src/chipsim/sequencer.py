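"""Sequencing step: fragments -> reads with per-base errors.

Single-end reads come from a uniformly chosen fragment end (reverse-end
reads are reverse-complemented); paired-end mate 1 reads the 5' end
forward and mate 2 the 3' end reverse-complemented, so the insert size
equals the fragment length.

The error process draws one category per *emitted* base position —
deletion, insertion, substitution or none, mutually exclusive with
probabilities (del, ins, sub, 1-del-ins-sub):

* substitution — emit a uniformly chosen different base;
* deletion — skip one template base, then emit the next unchanged;
* insertion — emit a uniformly chosen base without consuming template.

Template consumption continues until ``readlen`` bases are emitted;
if the fragment is exhausted first the read is padded with N.  Template
N bases are emitted verbatim and never altered by the error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .fragment_engine import Fragment
from .io_formats import QUAL_CHAR, SimRead

__all__ = ["sequence_fragment", "sequence_placements", "SeqStats", "revcomp"]

_BASES = b"ACGT"
_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def _revcomp_bytes(seq: bytes) -> bytes:
    return seq.translate(_COMP)[::-1]


@dataclass
class SeqStats:
    """Counters of true edit operations applied during generation."""

    bases_emitted: int = 0
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_padded: int = 0
    ops: Optional[List[str]] = None  # per-read op summaries when logging


def _read_with_errors(
    template: bytes,
    readlen: int,
    sub: float,
    ins: float,
    dele: float,
    rng: np.random.Generator,
    stats: SeqStats,
) -> bytes:
    out = bytearray(readlen)
    tpos = 0
    tlen = len(template)
    draws = rng.random(readlen)
    bases = rng.integers(0, 4, readlen)  # pre-drawn; used for sub/ins only
    t_del = dele
    t_ins = dele + ins
    t_sub = dele + ins + sub
    for j in range(readlen):
        if tpos >= tlen:
            out[j] = ord("N")
            stats.n_padded += 1
            continue
        u = draws[j]
        if u < t_del:
            stats.n_del += 1
            tpos += 1
            if tpos >= tlen:
                out[j] = ord("N")
                stats.n_padded += 1
                continue
            out[j] = template[tpos]
            tpos += 1
        elif u < t_ins:
            stats.n_ins += 1
            out[j] = _BASES[bases[j]]
        elif u < t_sub:
            tmpl = template[tpos]
            if tmpl == ord("N"):
                out[j] = tmpl  # N is never "corrected"
            else:
                choices = [c for c in _BASES if c != tmpl]
                out[j] = choices[bases[j] % 3]
                stats.n_sub += 1
            tpos += 1
        else:
            out[j] = template[tpos]
            tpos += 1
    stats.bases_emitted += readlen
    return bytes(out)


def _one_mate(
    template: bytes,
    readlen: int,
    sub: float,
    ins: float,
    dele: float,
    clean: bool,
    rng: np.random.Generator,
    stats: SeqStats,
) -> bytes:
    if clean:
        stats.bases_emitted += readlen
        if len(template) >= readlen:
            return template[:readlen]
        stats.n_padded += readlen - len(template)
        return template + b"N" * (readlen - len(template))
    return _read_with_errors(template, readlen, sub, ins, dele, rng, stats)


def sequence_fragment(
    frag: Fragment,
    reference: Dict[str, str],
    readlen: int,
    paired: bool,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
    name: str = "read",
    is_reverse: Optional[bool] = None,
    stats: Optional[SeqStats] = None,
) -> SimRead:
    """Sequence a single fragment into a read (or read pair).

    ``is_reverse`` fixes the single-end strand; when None it is drawn
    uniformly.  The fragment must be at least ``readlen`` long (shorter
    fragments are dropped upstream).
    """
    seq = reference[frag.chrom]
    if frag.start < 0 or frag.end > len(seq):
        raise RuntimeError(
            f"fragment {frag.chrom}:{frag.start}-{frag.end} outside reference bounds"
        )
    if frag.end - frag.start < readlen:
        raise ValueError("fragment shorter than readlen; drop upstream")
    if stats is None:
        stats = SeqStats()
    template_fwd = seq[frag.start : frag.end].encode("ascii")
    e_tot = sub_rate + ins_rate + del_rate
    qual = QUAL_CHAR * readlen
    if paired:
        clean1 = clean2 = e_tot == 0
        seq1 = _one_mate(template_fwd, readlen, sub_rate, ins_rate, del_rate, clean1, rng, stats)
        seq2 = _one_mate(
            _revcomp_bytes(template_fwd), readlen, sub_rate, ins_rate, del_rate, clean2, rng, stats
        )
        return SimRead(
            name=name,
            seq1=seq1.decode("ascii"),
            qual1=qual,
            seq2=seq2.decode("ascii"),
            qual2=qual,
            chrom=frag.chrom,
            frag_start=frag.start,
            frag_end=frag.end,
            is_reverse=False,
        )
    if is_reverse is None:
        is_reverse = bool(rng.random() < 0.5)
    template = _revcomp_bytes(template_fwd) if is_reverse else template_fwd
    seq1 = _one_mate(template, readlen, sub_rate, ins_rate, del_rate, e_tot == 0, rng, stats)
    return SimRead(
        name=name,
        seq1=seq1.decode("ascii"),
        qual1=qual,
        chrom=frag.chrom,
        frag_start=frag.start,
        frag_end=frag.end,
        is_reverse=is_reverse,
    )


def sequence_placements(
    placements,
    reference: Dict[str, str],
    readlen: int,
    paired: bool,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
    name_prefix: str = "chipsim",
) -> Tuple[List[SimRead], SeqStats]:
    """Sequence a batch of read placements (see :mod:`chipsim.pipeline`).

    Read names follow ``<prefix>:<chrom>:<start>-<end>:<copy>:<serial>``
    so the origin fragment and simulation round are recoverable from the
    FASTQ alone; the serial number distinguishes PCR duplicates.
    """
    stats = SeqStats()
    reads: List[SimRead] = []
    ref_bytes = {c: s.encode("ascii") for c, s in reference.items()}
    e_tot = sub_rate + ins_rate + del_rate
    n = len(placements.starts)
    clean = e_tot == 0
    qual = QUAL_CHAR * readlen
    for serial in range(n):
        chrom = placements.chroms[placements.chrom_ids[serial]]
        start = int(placements.starts[serial])
        end = int(placements.ends[serial])
        copy = int(placements.copy_index[serial])
        rev = bool(placements.is_reverse[serial])
        name = f"{name_prefix}:{chrom}:{start}-{end}:{copy}:{serial}"
        template_fwd = ref_bytes[chrom][start:end]
        if paired:
            s1 = _one_mate(template_fwd, readlen, sub_rate, ins_rate, del_rate, clean, rng, stats)
            s2 = _one_mate(
                _revcomp_bytes(template_fwd), readlen, sub_rate, ins_rate, del_rate,
                clean, rng, stats,
            )
            reads.append(
                SimRead(name, s1.decode("ascii"), qual, s2.decode("ascii"), qual,
                        chrom, start, end, False)
            )
        else:
            template = _revcomp_bytes(template_fwd) if rev else template_fwd
            s1 = _one_mate(template, readlen, sub_rate, ins_rate, del_rate, clean, rng, stats)
            reads.append(SimRead(name, s1.decode("ascii"), qual, None, None, chrom, start, end, rev))
    return reads, stats
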