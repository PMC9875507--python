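"""Region-anchored signal aggregation (metaplots) and per-peak mean signal.

``profile_signal`` bins a genome-positioned signal -- either a scored
interval set (e.g. ChIP/ATAC density) or a CpG methylome -- around a set of
anchor regions: in ``center`` mode within +/- ``flank_bp`` of each region
midpoint, in ``boundaries`` mode with fixed-width flank bins plus the region
body rescaled to 50 bins. Bins with no underlying signal are missing (NaN),
never zero: for methylation, zero would masquerade as unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np

from .core import GenomicInterval
from .methylome import CpGMethylome

BODY_BINS = 50


@dataclass
class ProfileMatrix:
    regions: List[GenomicInterval]
    bins: int
    bin_width: int
    values: np.ndarray  # regions x bins, NaN = missing
    anchor: str  # center | boundaries


Signal = Union[CpGMethylome, Sequence[GenomicInterval]]


def _window_values(signal: Signal, chrom: str, edges: np.ndarray) -> np.ndarray:
    """Weighted mean signal per bin delimited by ``edges`` (NaN where empty)."""
    nbins = len(edges) - 1
    out = np.full(nbins, np.nan)
    if isinstance(signal, CpGMethylome):
        sites = signal.chroms.get(chrom)
        if sites is None:
            return out
        lo = np.searchsorted(sites.pos, edges[0], side="left")
        hi = np.searchsorted(sites.pos, edges[-1], side="left")
        pos = sites.pos[lo:hi]
        raw = sites.raw_score[lo:hi]
        cov = sites.coverage[lo:hi].astype(float)
        ok = ~np.isnan(raw)
        pos, raw, cov = pos[ok], raw[ok], cov[ok]
        if len(pos) == 0:
            return out
        which = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, nbins - 1)
        wsum = np.bincount(which, weights=cov, minlength=nbins)
        vsum = np.bincount(which, weights=cov * raw, minlength=nbins)
        nonzero = wsum > 0
        out[nonzero] = vsum[nonzero] / wsum[nonzero]
        return out
    # scored interval signal: bp-overlap-weighted mean of interval scores
    spans = [
        iv for iv in signal
        if iv.chrom == chrom and iv.end > edges[0] and iv.start < edges[-1]
    ]
    if not spans:
        return out
    wsum = np.zeros(nbins)
    vsum = np.zeros(nbins)
    for iv in spans:
        score = iv.score if iv.score is not None else 1.0
        first = max(0, int(np.searchsorted(edges, iv.start, side="right")) - 1)
        last = min(nbins - 1, int(np.searchsorted(edges, iv.end, side="left")) - 1)
        for b in range(first, last + 1):
            bp = min(float(iv.end), edges[b + 1]) - max(float(iv.start), edges[b])
            if bp > 0:
                wsum[b] += bp
                vsum[b] += bp * score
    nonzero = wsum > 0
    out[nonzero] = vsum[nonzero] / wsum[nonzero]
    return out


def profile_signal(
    regions: Sequence[GenomicInterval],
    signal: Signal,
    anchor: str = "center",
    flank_bp: int = 5000,
    bin_width: int = 100,
) -> ProfileMatrix:
    """Bin signal around each region; rows follow the input region order."""
    if flank_bp % bin_width != 0:
        raise ValueError("flank_bp must be a multiple of bin_width")
    if anchor not in ("center", "boundaries"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    n_flank = flank_bp // bin_width
    rows = []
    for region in regions:
        if anchor == "center":
            mid = (region.start + region.end) // 2
            edges = mid - flank_bp + bin_width * np.arange(2 * n_flank + 1, dtype=float)
            rows.append(_window_values(signal, region.chrom, edges))
        else:
            left = region.start - flank_bp + bin_width * np.arange(n_flank + 1, dtype=float)
            body = region.start + (region.end - region.start) * np.linspace(0, 1, BODY_BINS + 1)
            right = region.end + bin_width * np.arange(n_flank + 1, dtype=float)
            rows.append(
                np.concatenate(
                    [
                        _window_values(signal, region.chrom, left),
                        _window_values(signal, region.chrom, body),
                        _window_values(signal, region.chrom, right),
                    ]
                )
            )
    values = np.vstack(rows) if rows else np.empty((0, 2 * n_flank))
    return ProfileMatrix(list(regions), values.shape[1], bin_width, values, anchor)


def aggregate_profile(pm: ProfileMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Missing-aware per-bin mean and per-bin non-missing count."""
    counts = np.sum(~np.isnan(pm.values), axis=0)
    sums = np.nansum(pm.values, axis=0)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def mean_signal_within_peaks(
    peaks: Sequence[GenomicInterval], signal: Signal
) -> np.ndarray:
    """Coverage/bp-weighted mean signal inside each peak (NaN when empty)."""
    out = np.empty(len(peaks))
    for i, peak in enumerate(peaks):
        edges = np.array([float(peak.start), float(peak.end)])
        out[i] = _window_values(signal, peak.chrom, edges)[0]
    return out


def compare_groups(
    a: np.ndarray, b: np.ndarray
) -> Tuple[float, float, int, int]:
    """Compare per-peak mean signals of two groups over shared peaks.

    Returns ``(ratio, correlation, n_used, n_excluded)`` where ``ratio`` is
    the ratio of the two group-level means (mean of b over mean of a) across
    peaks defined in both, and ``correlation`` is the Pearson correlation of
    the per-peak pairs.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("group arrays must align peak-by-peak")
    ok = ~(np.isnan(a) | np.isnan(b))
    n_used, n_excluded = int(ok.sum()), int((~ok).sum())
    if n_used == 0:
        return float("nan"), float("nan"), 0, n_excluded
    ratio = float(b[ok].mean() / a[ok].mean())
    if n_used > 1 and a[ok].std() > 0 and b[ok].std() > 0:
        corr = float(np.corrcoef(a[ok], b[ok])[0, 1])
    else:
        corr = float("nan")
    return ratio, corr, n_used, n_excluded
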