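"""Centromere-linkage extent and its scaling with chromosome size.

Same-chromosome gene pairs are split into cis-pairs (same side of the
centromere) and trans-pairs (opposite sides).  Within fixed-width physical
distance bins the genetic distances are averaged; the linkage extent is the
distance of the smallest bin whose mean reaches the unlinked threshold
(50 SGA-GD).  Independent estimates come from hotspot lists (gap between the
nearest hotspots flanking the centromere) and from a classical genetic map
(closest trans pair of loci >= 50 cM apart).  Extents are then correlated
with chromosome length, optionally after excluding chromosomes whose overall
recombination rate is known to be elevated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .distances import PairDistance
from .io_formats import GenomeAnnotation, SiteList
from .linkage import bin_pairs_by_distance

__all__ = [
    "PairClass",
    "CentromereLinkage",
    "SizeCorrelation",
    "classify_pairs",
    "linkage_extent",
    "centromere_linkage_from_pairs",
    "hotspot_centromere_gap",
    "genetic_map_centromere_gap",
    "size_correlation",
]


@dataclass(frozen=True)
class PairClass:
    gene_a: str
    gene_b: str
    side: str  # "cis" | "trans"
    physical_distance_kb: float


@dataclass
class CentromereLinkage:
    chromosome: str
    extent_cis: float  # kb, NaN when unavailable
    extent_trans: float
    method: str  # "sga" | "hotspot_interval" | "genetic_map"
    control_extent: float = math.nan


@dataclass
class SizeCorrelation:
    variable: str
    R: float
    p: float
    n: int
    excluded: frozenset[str]


def classify_pairs(
    pairs: Sequence[PairDistance], annotation: GenomeAnnotation
) -> list[PairClass]:
    """Assign cis/trans side and physical distance to each gene pair.

    trans iff the centromere midpoint lies strictly between the two gene
    midpoints.  Genes spanning the centromere midpoint are resolved by their
    own midpoint, with a warning.
    """
    out = []
    for p in pairs:
        ga = annotation.gene(p.query_id)
        gb = annotation.gene(p.array_id)
        if ga.chromosome != gb.chromosome:
            raise ValueError(
                f"pair ({p.query_id}, {p.array_id}) spans chromosomes "
                f"{ga.chromosome}/{gb.chromosome}"
            )
        cen = annotation.chromosome(ga.chromosome).centromere
        a, b = ga.midpoint, gb.midpoint
        for g in (ga, gb):
            if g.start <= cen <= g.end and g.midpoint != cen:
                warnings.warn(
                    f"gene {g.gene_id} spans the centromere midpoint; "
                    "classified by its own midpoint",
                    stacklevel=2,
                )
        side = "trans" if min(a, b) < cen < max(a, b) else "cis"
        out.append(PairClass(p.query_id, p.array_id, side, abs(a - b) / 1000.0))
    return out


def linkage_extent(
    classified: Sequence[tuple[PairClass, float]],
    side: str,
    bin_size_kb: float = 5.0,
    threshold: float = 50.0,
) -> float:
    """Distance (kb, bin center) of the smallest physical-distance bin whose
    mean genetic distance reaches ``threshold``; NaN when no bin qualifies."""
    if not classified:
        raise ValueError("no classified pairs supplied")
    picked = [(pc.physical_distance_kb, gd) for pc, gd in classified if pc.side == side]
    if not picked:
        raise ValueError(f"no pairs of side {side!r}")
    d = np.array([x[0] for x in picked])
    g = np.array([x[1] for x in picked])
    centers, means, _ = bin_pairs_by_distance(d, g, bin_size_kb)
    qualifying = centers[means >= threshold]
    return float(qualifying[0]) if len(qualifying) else math.nan


def centromere_linkage_from_pairs(
    pairs_with_gd: Sequence[tuple[PairClass, float]],
    chromosome: str,
    bin_size_kb: float = 5.0,
    threshold: float = 50.0,
) -> CentromereLinkage:
    """cis and trans extents for one chromosome from classified SGA pairs."""

    def _extent(side: str) -> float:
        try:
            return linkage_extent(pairs_with_gd, side, bin_size_kb, threshold)
        except ValueError:
            return math.nan

    return CentromereLinkage(
        chromosome=chromosome,
        extent_cis=_extent("cis"),
        extent_trans=_extent("trans"),
        method="sga",
    )


def hotspot_centromere_gap(
    hotspots: SiteList, annotation: GenomeAnnotation
) -> dict[str, tuple[float, float]]:
    """Per chromosome: (gap, control) in kb.

    gap = distance between the nearest hotspots flanking the centromere (the
    minimum separation over left/right hotspot pairs); control = mean spacing
    between consecutive hotspots on the chromosome.  NaN where undefined.
    """
    out: dict[str, tuple[float, float]] = {}
    per = hotspots.per_chromosome()
    for name in annotation.chromosome_names:
        sites = per.get(name, [])
        positions = np.array([s.position for s in sites])
        cen = annotation.chromosome(name).centromere
        left = positions[positions < cen]
        right = positions[positions > cen]
        gap = (right.min() - left.max()) / 1000.0 if len(left) and len(right) else math.nan
        control = float(np.diff(positions).mean()) / 1000.0 if len(positions) >= 2 else math.nan
        out[name] = (gap, control)
    return out


def genetic_map_centromere_gap(
    map_loci: SiteList,
    annotation: GenomeAnnotation,
    per_chrom_rate: Mapping[str, float],
    threshold_cm: float = 50.0,
) -> dict[str, tuple[float, float]]:
    """Per chromosome: (gap, control) in kb from a classical genetic map.

    Loci carry bp positions and cM scores.  gap = minimum physical distance
    between trans-centromere locus pairs at least ``threshold_cm`` apart on
    the genetic map; control = ``threshold_cm`` / rate for that chromosome's
    mean cM/kb.
    """
    out: dict[str, tuple[float, float]] = {}
    per = map_loci.per_chromosome()
    for name in annotation.chromosome_names:
        sites = [s for s in per.get(name, []) if s.score is not None]
        cen = annotation.chromosome(name).centromere
        left = [s for s in sites if s.position < cen]
        right = [s for s in sites if s.position > cen]
        gap = math.inf
        for a in left:
            for b in right:
                if abs(a.score - b.score) >= threshold_cm:
                    gap = min(gap, abs(b.position - a.position))
        gap_kb = gap / 1000.0 if math.isfinite(gap) else math.nan
        rate = per_chrom_rate.get(name)
        control = threshold_cm / rate if rate and rate > 0 else math.nan
        out[name] = (gap_kb, control)
    return out


def size_correlation(
    values: Mapping[str, float],
    annotation: GenomeAnnotation,
    excluded: Iterable[str] = (),
    variable: str = "extent",
) -> SizeCorrelation:
    """Pearson correlation of a per-chromosome quantity with chromosome length.

    NaN values and excluded chromosomes are dropped; the two-sided p-value
    uses the exact t transform with n - 2 degrees of freedom.
    """
    excluded = frozenset(excluded)
    xs, ys = [], []
    for name, v in values.items():
        if name in excluded or not math.isfinite(v):
            continue
        xs.append(annotation.chromosome(name).length)
        ys.append(v)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 chromosomes after exclusion, got {len(xs)}")
    ys_arr = np.asarray(ys, dtype=float)
    xs_arr = np.asarray(xs, dtype=float)
    if np.ptp(ys_arr) == 0 or np.ptp(xs_arr) == 0:
        raise ValueError("degenerate input: constant values, correlation undefined")
    res = stats.pearsonr(xs_arr, ys_arr)
    return SizeCorrelation(
        variable=variable,
        R=float(res.statistic),
        p=float(res.pvalue),
        n=len(xs),
        excluded=excluded,
    )
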