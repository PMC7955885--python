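"""Centromeric satellite monomer detection and centromere calling.

The fundamental repeat unit of a tandem satellite is inferred from the
distribution of k-mer recurrence distances: in an array of period L every
exact k-mer recurs L bases downstream, so L dominates the distance
spectrum.  Harmonics (2L, 3L, ...) are suppressed by preferring the
smallest period whose count is within 5% of the mode.  Tandem arrays are
then segmented as maximal runs of positions whose k-mer recurs at the
monomer length (+/-10%), and the largest array cluster per chromosome is
called as its centromere.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TandemArray",
    "CentromereCall",
    "detect_monomer_length",
    "find_tandem_arrays",
    "call_centromeres",
]


class NoRepeatError(ValueError):
    """No recurring k-mers within the period ceiling."""


@dataclass
class TandemArray:
    chrom: str
    start: int  # 0-based half-open
    end: int
    monomer_len: int
    copy_number: float
    mean_identity: float

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class CentromereCall:
    chrom: str
    start: int
    end: int
    n_arrays: int
    total_array_bp: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        pos[kmer].append(i)
    return pos


def detect_monomer_length(seq: str, k: int = 13, max_period: int = 2000) -> int:
    """Infer the satellite monomer length from k-mer recurrence distances.

    For every k-mer occurrence whose nearest downstream recurrence lies
    within ``max_period``, the recurrence distance is recorded; the modal
    distance is the fundamental period.  Among periods whose count is
    within 5% of the mode, the smallest is returned, which suppresses the
    2L/3L harmonics a perfect array also produces.
    """
    seq = seq.upper()
    if len(seq) < 4 * max_period:
        logger.warning("sequence shorter than 4x max_period; estimate may be unstable")
    counts = np.zeros(max_period + 1, dtype=np.int64)
    last: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        j = last.get(kmer)
        if j is not None:
            d = i - j
            if d <= max_period:
                counts[d] += 1
        last[kmer] = i
    counts[0] = 0
    if counts.sum() == 0:
        raise NoRepeatError("no recurring k-mers within max_period")
    peak = counts.max()
    near_modal = np.where(counts >= 0.95 * peak)[0]
    return int(near_modal.min())


def find_tandem_arrays(
    seq: str,
    monomer_len: int,
    chrom: str = "chr1",
    k: int = 13,
    min_copies: int = 10,
    min_identity: float = 0.7,
    max_gap: int = 5000,
) -> list[TandemArray]:
    """Segment tandem arrays of a known monomer length.

    A position is "periodic" when its k-mer recurs at monomer_len +/- 10%.
    Maximal runs of periodic positions with internal gaps <= ``max_gap``
    and span >= min_copies * monomer_len become arrays.  The mean periodic
    identity is the per-site copy-to-copy match rate estimated from the
    fraction of periodic positions (fraction^(1/k)); arrays below
    ``min_identity`` are discarded.
    """
    seq = seq.upper()
    lo = monomer_len - max(1, round(0.1 * monomer_len))
    hi = monomer_len + max(1, round(0.1 * monomer_len))
    periodic: list[int] = []
    recent: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        j = recent.get(kmer)
        if j is not None and lo <= i - j <= hi:
            periodic.append(j)
            periodic.append(i)
        recent[kmer] = i
    if not periodic:
        return []
    pts = np.unique(periodic)

    arrays: list[TandemArray] = []
    run_start = pts[0]
    prev = pts[0]
    n_in_run = 1
    for p in pts[1:]:
        if p - prev <= max_gap:
            prev = p
            n_in_run += 1
            continue
        arrays.extend(
            _finish_array(seq, chrom, run_start, prev + k, n_in_run, monomer_len, k,
                          min_copies, min_identity)
        )
        run_start, prev, n_in_run = p, p, 1
    arrays.extend(
        _finish_array(seq, chrom, run_start, prev + k, n_in_run, monomer_len, k,
                      min_copies, min_identity)
    )
    return arrays


def _finish_array(
    seq, chrom, start, end, n_periodic, monomer_len, k, min_copies, min_identity
) -> list[TandemArray]:
    span = end - start
    if span < min_copies * monomer_len:
        return []
    frac = min(1.0, n_periodic / max(span, 1))
    identity = frac ** (1.0 / k)
    if identity < min_identity:
        return []
    return [
        TandemArray(
            chrom=chrom,
            start=int(start),
            end=int(end),
            monomer_len=monomer_len,
            copy_number=span / monomer_len,
            mean_identity=float(identity),
        )
    ]


def call_centromeres(
    arrays: list[TandemArray], cluster_gap: int = 100_000
) -> tuple[list[CentromereCall], float, list[str]]:
    """One centromere per chromosome: the array cluster with most array bp.

    Arrays on a chromosome whose gaps are <= ``cluster_gap`` merge into
    clusters; the cluster with the greatest total array bp wins and its
    span becomes the call.  Returns (calls, mean call length, chromosomes
    without arrays are not listed — callers compare against their own
    chromosome set).
    """
    by_chrom: dict[str, list[TandemArray]] = defaultdict(list)
    for a in arrays:
        by_chrom[a.chrom].append(a)

    calls: list[CentromereCall] = []
    for chrom in sorted(by_chrom):
        arrs = sorted(by_chrom[chrom], key=lambda a: a.start)
        clusters: list[list[TandemArray]] = [[arrs[0]]]
        for a in arrs[1:]:
            if a.start - clusters[-1][-1].end <= cluster_gap:
                clusters[-1].append(a)
            else:
                clusters.append([a])
        best = max(clusters, key=lambda c: sum(a.span for a in c))
        calls.append(
            CentromereCall(
                chrom=chrom,
                start=best[0].start,
                end=max(a.end for a in best),
                n_arrays=len(best),
                total_array_bp=sum(a.span for a in best),
            )
        )
    mean_len = float(np.mean([c.length for c in calls])) if calls else float("nan")
    return calls, mean_len, sorted(by_chrom)
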