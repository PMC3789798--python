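"""Recombination-rate profiles and hotspot calling.

The local recombination rate at bin x is the mean, over unmasked off-diagonal
cells (i, j) with i, j within a window centered on x (default 5 bins = 25 kb),
of cell distance divided by physical bin separation — i.e. SGA-GD per kb.
Hotspots are local maxima of the smoothed profile that exceed the genome-wide
average rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import Site, SiteList
from .linkage import LinkageMatrix

__all__ = [
    "RecombProfile",
    "HotspotCall",
    "moving_average",
    "local_rate_profile",
    "smooth",
    "genome_average_rate",
    "call_hotspots",
    "compare_hotspot_sets",
    "write_hotspots_bed",
]


@dataclass
class RecombProfile:
    chromosome: str
    bin_size: int
    rate: np.ndarray  # SGA-GD per kb, NaN where no data
    smoothed: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.rate)

    def bin_center(self, idx: int) -> float:
        return idx * self.bin_size + self.bin_size / 2.0


@dataclass(frozen=True)
class HotspotCall:
    chromosome: str
    position: float  # bin center, bp
    rate: float  # SGA-GD per kb


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaNs, truncated at the ends.

    Positions whose whole window is NaN stay NaN."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    kernel = np.ones(window)
    half = window // 2
    n = len(x)
    # "full" + centered slice behaves correctly even when n < window
    sums = np.convolve(np.where(finite, x, 0.0), kernel, mode="full")[half : half + n]
    counts = np.convolve(finite.astype(float), kernel, mode="full")[half : half + n]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def local_rate_profile(lm: LinkageMatrix, window_bins: int = 5) -> RecombProfile:
    """Per-bin recombination rate from a consolidated, masked linkage matrix."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be odd and >= 1")
    M = lm.consolidated
    half = window_bins // 2
    n = lm.n
    kb = lm.bin_size / 1000.0
    i_idx, j_idx = np.indices((n, n))
    sep = np.abs(i_idx - j_idx)
    usable = (~lm.mask) & np.isfinite(M) & (sep > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cell_rate = np.where(usable, M / (sep * kb), np.nan)
    rate = np.full(n, np.nan)
    for x in range(n):
        lo, hi = max(0, x - half), min(n, x + half + 1)
        block = cell_rate[lo:hi, lo:hi]
        vals = block[np.isfinite(block)]
        if len(vals):
            rate[x] = vals.mean()
    return RecombProfile(chromosome=lm.chromosome, bin_size=lm.bin_size, rate=rate)


def smooth(profile: RecombProfile, window: int = 5) -> RecombProfile:
    """Moving-average smoothing over ``window`` consecutive positions."""
    return RecombProfile(
        chromosome=profile.chromosome,
        bin_size=profile.bin_size,
        rate=profile.rate,
        smoothed=moving_average(profile.rate, window),
    )


def genome_average_rate(profiles: Iterable[RecombProfile], use_smoothed: bool = True) -> float:
    """Mean rate over all non-missing positions of all supplied profiles."""
    chunks = []
    for p in profiles:
        series = p.smoothed if (use_smoothed and p.smoothed is not None) else p.rate
        chunks.append(series[np.isfinite(series)])
    allvals = np.concatenate(chunks) if chunks else np.array([])
    if len(allvals) == 0:
        raise ValueError("no finite rate values to average")
    return float(allvals.mean())


def call_hotspots(
    profile: RecombProfile,
    genome_avg: float,
    min_separation: float = 0.0,
) -> list[HotspotCall]:
    """Local maxima of the smoothed profile that exceed the genome average.

    Plateaus yield a single call at the plateau center (rounded down);
    plateaus touching the chromosome ends are not maxima.  Calls closer than
    ``min_separation`` bp are merged keeping the higher one.
    """
    if profile.smoothed is None:
        raise ValueError("profile must be smoothed before hotspot calling")
    y = profile.smoothed
    n = len(y)
    calls: list[HotspotCall] = []
    s = 0
    while s < n:
        if not math.isfinite(y[s]):
            s += 1
            continue
        e = s
        while e + 1 < n and math.isfinite(y[e + 1]) and y[e + 1] == y[s]:
            e += 1
        if s > 0 and e < n - 1:
            left = y[s - 1] if math.isfinite(y[s - 1]) else -math.inf
            right = y[e + 1] if math.isfinite(y[e + 1]) else -math.inf
            v = y[s]
            if v > left and v > right and v > genome_avg:
                mid = (s + e) // 2
                calls.append(HotspotCall(profile.chromosome, profile.bin_center(mid), float(v)))
        s = e + 1
    if min_separation > 0 and len(calls) > 1:
        kept: list[HotspotCall] = []
        for c in sorted(calls, key=lambda c: -c.rate):
            if all(abs(c.position - k.position) >= min_separation for k in kept):
                kept.append(c)
        calls = sorted(kept, key=lambda c: c.position)
    return calls


def compare_hotspot_sets(
    calls: Sequence[HotspotCall],
    reference: SiteList,
    tolerance: float = 10_000.0,
) -> tuple[float, float, list[float]]:
    """Precision/sensitivity of a call set against a reference site list.

    sensitivity = fraction of reference sites with a call within ``tolerance``
    bp on the same chromosome; precision = fraction of calls with a reference
    site within tolerance.  The third element is each reference site's
    distance to the nearest same-chromosome call (inf when none).
    """
    call_chroms = {c.chromosome for c in calls}
    ref_chroms = {s.chromosome for s in reference}
    if calls and len(reference) and not (call_chroms & ref_chroms):
        raise ValueError(
            "no chromosome shared between call set and reference; "
            f"calls use {sorted(call_chroms)}, reference uses {sorted(ref_chroms)}"
        )
    calls_by_chrom: dict[str, list[float]] = {}
    for c in calls:
        calls_by_chrom.setdefault(c.chromosome, []).append(c.position)
    ref_by_chrom = reference.per_chromosome()

    nearest: list[float] = []
    hits = 0
    for site in reference:
        pos = calls_by_chrom.get(site.chromosome, [])
        d = min((abs(site.position - p) for p in pos), default=math.inf)
        nearest.append(d)
        if d <= tolerance:
            hits += 1
    sensitivity = hits / len(reference) if len(reference) else math.nan

    matched = 0
    for c in calls:
        sites = ref_by_chrom.get(c.chromosome, [])
        d = min((abs(c.position - s.position) for s in sites), default=math.inf)
        if d <= tolerance:
            matched += 1
    precision = matched / len(calls) if calls else math.nan
    return precision, sensitivity, nearest


def write_hotspots_bed(calls: Sequence[HotspotCall], path: str | Path, bin_size: int) -> None:
    """BED-like output: chrom, bin start, bin end, rate."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in sorted(calls, key=lambda c: (c.chromosome, c.position)):
            start = int(c.position - bin_size / 2)
            fh.write(f"{c.chromosome}\t{start}\t{start + bin_size}\t{c.rate!r}\n")
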