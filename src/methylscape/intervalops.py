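"""Interval-set algebra on half-open genomic intervals.

A small sweep-line engine (sorted arrays + two-pointer scans) providing the
set operations the pipeline composes everywhere: merge, intersection pieces,
subtraction, genome complement, and overlap-pair enumeration. All operations
treat intervals as half-open and use exact string match on chromosome names.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, ValidationError

ChromSizes = Mapping[str, int]


def by_chrom(
    intervals: Sequence[GenomicInterval],
) -> Dict[str, List[Tuple[int, GenomicInterval]]]:
    """Group intervals by chromosome, keeping their input indices, sorted by start."""
    groups: Dict[str, List[Tuple[int, GenomicInterval]]] = defaultdict(list)
    for i, iv in enumerate(intervals):
        groups[iv.chrom].append((i, iv))
    for chrom in groups:
        groups[chrom].sort(key=lambda t: (t[1].start, t[1].end))
    return groups


def sort_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def total_bp(intervals: Sequence[GenomicInterval]) -> int:
    """Total bp covered, counting overlapping bp once."""
    return sum(len(iv) for iv in merge(intervals))


def merge(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> List[GenomicInterval]:
    """Merge overlapping/adjacent intervals; joins runs separated by <= ``gap`` bp."""
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom(intervals)):
        cur_s = cur_e = None
        for _, iv in by_chrom(intervals)[chrom]:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e + gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_pieces(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Base-pair intersection of two interval sets, as merged pieces."""
    am, bm = merge(a), merge(b)
    ga, gb = by_chrom(am), by_chrom(bm)
    out: List[GenomicInterval] = []
    for chrom in sorted(set(ga) & set(gb)):
        xs = [iv for _, iv in ga[chrom]]
        ys = [iv for _, iv in gb[chrom]]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """bp of ``a`` not covered by ``b`` (a \\ b), as merged pieces."""
    am = merge(a)
    gb = by_chrom(merge(b))
    out: List[GenomicInterval] = []
    for iv in am:
        cuts = [x for _, x in gb.get(iv.chrom, [])]
        pos = iv.start
        for c in cuts:
            if c.end <= iv.start or c.start >= iv.end:
                continue
            if c.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, min(c.start, iv.end)))
            pos = max(pos, c.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return sort_intervals(out)


def complement(
    intervals: Sequence[GenomicInterval], chrom_sizes: ChromSizes
) -> List[GenomicInterval]:
    """Genome complement of an interval set over the given chromosome sizes."""
    for iv in intervals:
        if iv.chrom in chrom_sizes and iv.end > chrom_sizes[iv.chrom]:
            raise ValidationError(
                f"interval [{iv.start}, {iv.end}) beyond end of {iv.chrom}"
            )
    genome = [
        GenomicInterval(chrom, 0, size) for chrom, size in chrom_sizes.items()
    ]
    return subtract(genome, intervals)


def overlap_pairs(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> List[Tuple[int, int]]:
    """Indices ``(i, j)`` of every a[i], b[j] pair overlapping by >= 1 bp."""
    ga, gb = by_chrom(a), by_chrom(b)
    pairs: List[Tuple[int, int]] = []
    for chrom in set(ga) & set(gb):
        ys = gb[chrom]
        y_starts = np.array([iv.start for _, iv in ys])
        # ends sorted together with starts; use max-prefix to allow nesting
        y_ends = np.array([iv.end for _, iv in ys])
        for ai, aiv in ga[chrom]:
            lo = 0
            hi = int(np.searchsorted(y_starts, aiv.end, side="left"))
            for k in range(lo, hi):
                if y_ends[k] > aiv.start:
                    pairs.append((ai, ys[k][0]))
    pairs.sort()
    return pairs


def overlaps_any(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask over ``a``: does each interval overlap >= 1 bp of ``b``?"""
    mask = np.zeros(len(a), dtype=bool)
    gb = by_chrom(merge(b))
    for chrom, items in by_chrom(a).items():
        ys = [iv for _, iv in gb.get(chrom, [])]
        if not ys:
            continue
        y_starts = np.array([iv.start for iv in ys])
        y_ends = np.array([iv.end for iv in ys])
        for ai, aiv in items:
            k = int(np.searchsorted(y_ends, aiv.start, side="right"))
            if k < len(ys) and y_starts[k] < aiv.end:
                mask[ai] = True
    return mask


def overlap_bp_with(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-interval bp of ``a`` covered by the merged set ``b``."""
    out = np.zeros(len(a), dtype=np.int64)
    gb = by_chrom(merge(b))
    for chrom, items in by_chrom(a).items():
        ys = [iv for _, iv in gb.get(chrom, [])]
        for ai, aiv in items:
            bp = 0
            for y in ys:
                if y.start >= aiv.end:
                    break
                if y.end > aiv.start:
                    bp += min(aiv.end, y.end) - max(aiv.start, y.start)
            out[ai] = bp
    return out


def intersect_n_way(
    sets: Sequence[Sequence[GenomicInterval]],
) -> List[GenomicInterval]:
    """bp present in every one of ``sets`` (chained pairwise intersection)."""
    if not sets:
        return []
    acc = merge(sets[0])
    for s in sets[1:]:
        acc = intersect_pieces(acc, s)
        if not acc:
            break
    return acc
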