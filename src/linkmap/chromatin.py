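"""Pericentric widths from genomic signal tracks.

Two measurements: (1) the DSB-repressed region around a centromere — per
side, how far one can walk outward before the cumulative Spo11-oligo count
reaches a threshold (default 3000); (2) the width of the centromere-centered
cohesin peak — after moving-average smoothing (default 25 positions), the
span of positions flanking the centromere where binding exceeds the global
genomic average (GGA).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .hotspots import moving_average
from .io_formats import GenomicTrack

__all__ = [
    "RepressedRegion",
    "CohesinPeak",
    "dsb_repressed_region",
    "asymmetry_score",
    "linkage_repressed_region",
    "compute_gga",
    "cohesin_peak_width",
]


@dataclass
class RepressedRegion:
    """Signal-poor region flanking a centromere, per side, in kb."""

    chromosome: str
    left_extent: float
    right_extent: float
    oligo_threshold: float

    @property
    def total(self) -> float:
        return self.left_extent + self.right_extent


@dataclass
class CohesinPeak:
    chromosome: str
    width_kb: float
    gga: float
    smoothing_window: int


def dsb_repressed_region(
    track: GenomicTrack,
    centromere: float,
    threshold: float = 3000.0,
    chromosome_length: float | None = None,
) -> RepressedRegion:
    """Cumulative-count walk outward from the centromere on each side.

    The extent on a side is the distance to the last position whose
    cumulative count (from the centromere outward) is strictly below
    ``threshold``; reaching the threshold at the first flanking position
    gives extent 0 (ties resolve toward the smaller region).  If the
    threshold is never reached, the extent runs to the chromosome end
    (``chromosome_length`` if given, else the last track position).
    """
    if len(track) == 0:
        raise ValueError(f"{track.chromosome}: empty track")
    pos, val = track.positions, track.values
    if np.any(val < 0):
        raise ValueError(f"{track.chromosome}: negative counts")
    if not (pos[0] <= centromere <= pos[-1]):
        raise ValueError(
            f"{track.chromosome}: centromere {centromere} outside track span "
            f"[{pos[0]}, {pos[-1]}]"
        )
    right_end = (chromosome_length if chromosome_length is not None else pos[-1])
    left_end = 1.0 if chromosome_length is not None else pos[0]

    def _walk(p: np.ndarray, v: np.ndarray, end: float) -> float:
        # p: distances from centromere, ascending; v aligned counts
        cum = np.cumsum(v)
        reached = np.nonzero(cum >= threshold)[0]
        if len(reached) == 0:
            return abs(end - centromere) / 1000.0
        k = reached[0]
        return p[k - 1] / 1000.0 if k > 0 else 0.0

    right_sel = pos > centromere
    left_sel = pos < centromere
    right = _walk(pos[right_sel] - centromere, val[right_sel], right_end)
    left = _walk((centromere - pos[left_sel])[::-1], val[left_sel][::-1], left_end)
    return RepressedRegion(track.chromosome, left, right, threshold)


def asymmetry_score(region: RepressedRegion) -> float:
    """Signed left-minus-right extent, kb."""
    return region.left_extent - region.right_extent


def linkage_repressed_region(
    positions: Sequence[float],
    genetic_distances: Sequence[float],
    centromere: float,
    chromosome: str = "",
    threshold: float = 50.0,
) -> RepressedRegion:
    """Linkage-based analogue of the DSB walk.

    ``genetic_distances[i]`` is the genetic distance (SGA-GD) between the
    locus at ``positions[i]`` and the centromere-proximal anchor.  Per side,
    the extent is the distance from the centromere to the first locus
    (walking outward) whose genetic distance reaches ``threshold``; loci
    never reaching it push the extent to the farthest locus on that side.
    """
    p = np.asarray(positions, dtype=float)
    g = np.asarray(genetic_distances, dtype=float)
    if p.shape != g.shape:
        raise ValueError("positions and genetic distances differ in length")

    def _side(sel: np.ndarray, outward_order: np.ndarray) -> float:
        ps, gs = p[sel][outward_order], g[sel][outward_order]
        if len(ps) == 0:
            return math.nan
        hit = np.nonzero(gs >= threshold)[0]
        bound = ps[hit[0]] if len(hit) else ps[-1]
        return abs(bound - centromere) / 1000.0

    left_sel = p < centromere
    right_sel = p > centromere
    left = _side(left_sel, np.argsort(-(p[left_sel])))
    right = _side(right_sel, np.argsort(p[right_sel]))
    return RepressedRegion(chromosome, left, right, threshold)


def compute_gga(tracks: Iterable[GenomicTrack], window: int = 25) -> float:
    """Global genomic average of smoothed binding over all supplied tracks."""
    chunks = []
    for t in tracks:
        if len(t):
            chunks.append(moving_average(t.values, window))
    if not chunks:
        raise ValueError("no track data for GGA")
    allv = np.concatenate(chunks)
    allv = allv[np.isfinite(allv)]
    return float(allv.mean())


def cohesin_peak_width(
    track: GenomicTrack,
    centromere: float,
    gga: float,
    window: int = 25,
    mode: str = "contiguous",
) -> CohesinPeak:
    """Width of the centromere-centered super-GGA binding peak, kb.

    The track is smoothed with a centered ``window``-position moving average;
    from the position nearest the centromere the peak extends while smoothed
    binding stays strictly above ``gga``.  ``mode="contiguous"`` (default)
    takes the maximal contiguous super-GGA run containing the centromere;
    ``mode="farthest"`` takes the farthest super-GGA positions on either side
    anywhere on the chromosome.  A sub-GGA centromere position yields width 0
    with a warning.
    """
    if len(track) == 0:
        raise ValueError(f"{track.chromosome}: empty track")
    pos = track.positions
    if not (pos[0] <= centromere <= pos[-1]):
        raise ValueError(
            f"{track.chromosome}: centromere {centromere} outside track span"
        )
    y = moving_average(track.values, window)
    c = int(np.searchsorted(pos, centromere))
    if c >= len(pos) or (c > 0 and centromere - pos[c - 1] <= pos[c] - centromere):
        c = c - 1 if c > 0 else 0
    if not (math.isfinite(y[c]) and y[c] > gga):
        warnings.warn(
            f"{track.chromosome}: smoothed binding at the centromere does not "
            "exceed GGA; no centromeric peak",
            stacklevel=2,
        )
        return CohesinPeak(track.chromosome, 0.0, gga, window)
    above = np.isfinite(y) & (y > gga)
    if mode == "contiguous":
        lo = c
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = c
        while hi < len(pos) - 1 and above[hi + 1]:
            hi += 1
    elif mode == "farthest":
        idx = np.nonzero(above)[0]
        lo = int(idx[idx <= c].min())
        hi = int(idx[idx >= c].max())
    else:
        raise ValueError(f"unknown mode: {mode}")
    return CohesinPeak(track.chromosome, (pos[hi] - pos[lo]) / 1000.0, gga, window)
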